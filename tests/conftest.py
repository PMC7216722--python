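import numpy as np
import pytest

from mihc.simulate import (default_dm_params, generate_dm_counts,
                           generate_phenotype, generate_random_tree)


def random_gaussian_instance(rng, n=12, m=6, l=2):
    """Small random design for oracle comparisons: (y, X, O)."""
    X = np.column_stack([np.ones(n), rng.normal(size=(n, l))])
    y = rng.normal(size=n)
    O = rng.dirichlet(np.ones(m) * 2.0, size=n)
    return y, X, O


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_study(tmp_path):
    """A small on-disk study (OTU TSV + newick tree + metadata TSV)."""
    n, m, depth = 20, 15, 500
    params = default_dm_params(m)
    counts = generate_dm_counts(params, n, depth, seed=7)
    tree = generate_random_tree(m, seed=8)
    y, X = generate_phenotype(counts / depth, [0, 1], beta=1.0, seed=9)

    otu_ids = [f"OTU{j + 1}" for j in range(m)]
    sample_ids = [f"S{i + 1}" for i in range(n)]
    otu_path = tmp_path / "otu.tsv"
    with open(otu_path, "w") as fh:
        fh.write("sample\t" + "\t".join(otu_ids) + "\n")
        for i, sid in enumerate(sample_ids):
            fh.write(sid + "\t" + "\t".join(str(c) for c in counts[i]) + "\n")
    tree_path = tmp_path / "tree.nwk"
    tree.write(path=str(tree_path), schema="newick",
               suppress_rooting=True, unquoted_underscores=True)
    meta_path = tmp_path / "meta.tsv"
    with open(meta_path, "w") as fh:
        fh.write("sample\toutcome\tcov1\tcov2\n")
        for i, sid in enumerate(sample_ids):
            fh.write(f"{sid}\t{y[i]:.6f}\t{X[i, 1]:.6f}\t{X[i, 2]:.6f}\n")
    return {"otu": otu_path, "tree": tree_path, "meta": meta_path,
            "n": n, "m": m}
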