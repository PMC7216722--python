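"""Reading, validation, alignment and filtering of microbiome inputs.

Assembles an OTU relative-abundance table, a rooted phylogeny and sample
metadata into a single :class:`MicrobiomeDataset` ready for association
testing.  Conventions:

* the OTU table is TSV with one label column and one label header row;
  both samples-in-rows and OTUs-in-rows layouts are accepted,
* abundances are converted to per-sample proportions (rows sum to 1),
* OTUs with mean relative abundance below a threshold (default 1e-4) are
  dropped; remaining proportions are NOT renormalised,
* the tree is pruned to the retained OTUs,
* samples with missing phenotype or covariate values are dropped with a
  warning, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-8


@dataclass
class MicrobiomeDataset:
    """Aligned inputs for a microbial group association test.

    Attributes
    ----------
    otu_matrix : (n, m) ndarray
        Relative abundances; every row sums to 1 within ``1e-8``.
    otu_ids, sample_ids : list of str
        Column and row labels of ``otu_matrix``.
    tree : dendropy.Tree or None
        Rooted phylogeny restricted to ``otu_ids`` (None for tree-free runs).
    phenotype : (n,) ndarray
        Gaussian outcome, or 0/1 for a binomial outcome.
    covariates : (n, l+1) ndarray
        Design matrix with a leading intercept column.
    family : str
        ``"gaussian"`` or ``"binomial"``.
    """

    otu_matrix: np.ndarray
    otu_ids: list
    sample_ids: list
    phenotype: np.ndarray
    covariates: np.ndarray
    tree: Optional[dendropy.Tree] = None
    family: str = "gaussian"

    def __post_init__(self):
        self.otu_matrix = np.asarray(self.otu_matrix, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        n, m = self.otu_matrix.shape
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        if m < 2:
            raise ValueError(f"need at least 2 OTUs, got {m}")
        if len(self.otu_ids) != m or len(self.sample_ids) != n:
            raise ValueError("label lengths do not match matrix shape")
        rs = self.otu_matrix.sum(axis=1)
        if np.any(np.abs(rs - 1.0) > ROW_SUM_TOL):
            bad = int(np.argmax(np.abs(rs - 1.0)))
            raise ValueError(
                f"row {self.sample_ids[bad]!r} sums to {rs[bad]:.6g}, not 1"
            )
        if np.any(np.isnan(self.phenotype)) or np.any(np.isnan(self.covariates)):
            raise ValueError("missing values in phenotype/covariates")
        if self.tree is not None:
            leaves = {t.label for t in self.tree.taxon_namespace}
            missing = [o for o in self.otu_ids if o not in leaves]
            if missing:
                raise ValueError(f"OTUs absent from tree: {missing}")

    @property
    def n(self) -> int:
        return self.otu_matrix.shape[0]

    @property
    def m(self) -> int:
        return self.otu_matrix.shape[1]


def read_otu_table(path, orientation: str = "samples_in_rows") -> pd.DataFrame:
    """Read a TSV abundance table, returned as samples x OTUs.

    Parameters
    ----------
    path : str
        TSV file with one header row and one label column.
    orientation : {"samples_in_rows", "otus_in_rows"}
        Layout of the file; ``otus_in_rows`` tables are transposed.
    """
    if orientation not in ("samples_in_rows", "otus_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicated column labels: {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=object,
                     keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated row labels: {dup}")
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    if (num.to_numpy() < 0).any():
        i, j = np.argwhere(num.to_numpy() < 0)[0]
        raise ValueError(
            f"negative abundance at row {num.index[i]!r}, column {num.columns[j]!r}"
        )
    if orientation == "otus_in_rows":
        num = num.T
    return num.astype(float)


def to_relative_abundance(counts) -> pd.DataFrame:
    """Convert a samples x OTUs count table to per-sample proportions.

    Rows already summing to 1 (within 1e-8) pass through unchanged.
    """
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(np.asarray(counts, float))
    rs = df.sum(axis=1).to_numpy(dtype=float)
    if np.any(rs <= 0):
        bad = df.index[int(np.argmax(rs <= 0))]
        raise ValueError(f"sample {bad!r} has zero total abundance")
    return df.div(rs, axis=0)


def filter_low_abundance(prop: pd.DataFrame, threshold: float = 1e-4) -> pd.DataFrame:
    """Keep OTUs whose mean relative abundance is >= ``threshold``.

    Remaining proportions are not renormalised: filtering selects the
    analysis OTUs without altering composition values.
    """
    means = prop.mean(axis=0)
    keep = means[means >= threshold].index
    if len(keep) == 0:
        raise ValueError(
            f"no OTUs retained at mean-abundance threshold {threshold}"
        )
    dropped = prop.shape[1] - len(keep)
    if dropped:
        logger.info("filtered %d low-abundance OTUs (threshold %g)", dropped, threshold)
    return prop[keep]


def read_tree(path) -> dendropy.Tree:
    """Read a rooted newick tree; missing branch lengths are treated as 0."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return tree


def prune_tree(tree: dendropy.Tree, otu_ids: Sequence[str]) -> dendropy.Tree:
    """Restrict a tree to the given leaf set, preserving path lengths."""
    labels = {t.label for t in tree.taxon_namespace}
    missing = [o for o in otu_ids if o not in labels]
    if missing:
        raise ValueError(f"tree is missing leaves for OTUs: {missing}")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(list(otu_ids))
    return pruned


def load_dataset(
    otu_path,
    metadata_path,
    phenotype: str,
    covariates: Optional[Sequence[str]] = None,
    tree_path=None,
    orientation: str = "samples_in_rows",
    family: str = "gaussian",
    min_mean_abundance: float = 1e-4,
) -> MicrobiomeDataset:
    """Read, align and filter the three input artifacts.

    Sample IDs are matched exactly (case-sensitive) between the OTU table
    and metadata; samples with missing phenotype/covariates are dropped
    with a logged warning.
    """
    table = read_otu_table(otu_path, orientation=orientation)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    if phenotype not in meta.columns:
        raise ValueError(f"phenotype column {phenotype!r} not in metadata")
    covariates = list(covariates or [])
    for c in covariates:
        if c not in meta.columns:
            raise ValueError(f"covariate column {c!r} not in metadata")

    shared = [s for s in table.index if s in meta.index]
    if len(shared) < len(table.index):
        logger.warning("dropping %d samples absent from metadata",
                       len(table.index) - len(shared))
    sub = meta.loc[shared, [phenotype] + covariates]
    complete = sub.dropna().index
    if len(complete) < len(shared):
        logger.warning("dropping %d samples with missing phenotype/covariates",
                       len(shared) - len(complete))
    keep = [s for s in shared if s in set(complete)]
    table = table.loc[keep]
    sub = sub.loc[keep]

    prop = filter_low_abundance(to_relative_abundance(table), min_mean_abundance)
    tree = None
    if tree_path is not None:
        tree = prune_tree(read_tree(tree_path), list(prop.columns))

    y = sub[phenotype].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(keep))] +
                        [sub[c].to_numpy(dtype=float) for c in covariates])
    return MicrobiomeDataset(
        otu_matrix=prop.to_numpy(),
        otu_ids=list(prop.columns),
        sample_ids=list(prop.index),
        phenotype=y,
        covariates=X,
        tree=tree,
        family=family,
    )
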