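"""Residual-permutation calibration and minimum-p omnibus tests.

The p-value machinery follows a seven-step residual permutation scheme:

1. fit the null GLM and keep residuals e0;
2. compute observed marginal statistics, the HC statistics uHC_(h) and
   wHC_(h) for each h in the candidate set, and the analytic Simes
   p-value;
3. shuffle e0 B times, reusing each shuffled vector across ALL OTUs and
   all tests (this preserves OTU-by-OTU correlation under the null) and
   recompute every statistic with the original score denominators;
4. per-test permutation p-values P = (1 + #{null > observed}) / (B + 1);
5. observed omnibus statistics: minimum p over the unweighted family +
   Simes (uHC_A), the weighted family + Simes (wHC_A), and everything
   (MiHC);
6. null omnibus statistics via leave-one-out p-values of each
   permutation against the rest (strictly greater for HC statistics,
   strictly smaller for Simes);
7. final omnibus p-values P = (1 + #{null minimum-p < observed}) / (B + 1).

Everything is vectorized over permutations; stored null artifacts are
O(B x |Gamma|).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .hc_stats import hc_deviations, hc_profile, normalize_gamma, simes_pvalue
from .null_glm import MarginalStats, NullFit, fit_null, score_stats
from .phylo_weights import PhyloWeights, build_weights

logger = logging.getLogger(__name__)


@dataclass
class PermutationNull:
    """Null statistic ensemble from B residual permutations."""

    B: int
    gamma: tuple
    null_uhc: np.ndarray                 # (B, |gamma|)
    null_simes: np.ndarray               # (B,)
    null_whc: Optional[np.ndarray] = None
    seed: Optional[int] = None


@dataclass
class MihcResult:
    """Observed statistics and p-values for every individual and omnibus test."""

    gamma: tuple
    B: int
    seed: Optional[int]
    marginals: MarginalStats
    weights: Optional[np.ndarray]          # observed w_j, None without a tree
    uhc_stats: dict                        # h -> uHC_(h)
    whc_stats: Optional[dict]
    uhc_pvalues: dict                      # h -> P_uHC(h)
    whc_pvalues: Optional[dict]
    simes_pvalue: float
    T_uhc_A: float
    T_whc_A: Optional[float]
    T_mihc: Optional[float]
    P_uhc_A: float
    P_whc_A: Optional[float]
    P_mihc: Optional[float]
    otu_ids: Optional[list] = None
    qq_unweighted: Optional[object] = None
    qq_weighted: Optional[object] = None
    note: Optional[str] = None

    @property
    def headline_pvalue(self) -> float:
        """P_MiHC, or P_uHC_A when no tree was supplied."""
        return self.P_mihc if self.P_mihc is not None else self.P_uhc_A

    def pvalue_table(self) -> list:
        """(test name, statistic, p-value) rows for serialization."""
        rows = []
        for h in self.gamma:
            rows.append((f"uHC({h})", self.uhc_stats[h], self.uhc_pvalues[h]))
        if self.whc_stats is not None:
            for h in self.gamma:
                rows.append((f"wHC({h})", self.whc_stats[h], self.whc_pvalues[h]))
        rows.append(("Simes", self.simes_pvalue, self.simes_pvalue))
        rows.append(("uHC_A", self.T_uhc_A, self.P_uhc_A))
        if self.T_whc_A is not None:
            rows.append(("wHC_A", self.T_whc_A, self.P_whc_A))
        if self.T_mihc is not None:
            rows.append(("MiHC", self.T_mihc, self.P_mihc))
        return rows

    def all_pvalues(self) -> dict:
        """Flat name -> p-value mapping across every reported test."""
        out = {name: p for name, _, p in self.pvalue_table()}
        return out

    def to_json_dict(self) -> dict:
        d = {
            "gamma": list(self.gamma),
            "B": self.B,
            "seed": self.seed,
            "tests": [
                {"test": name, "statistic": float(s), "p_value": float(p)}
                for name, s, p in self.pvalue_table()
            ],
            "headline_p_value": float(self.headline_pvalue),
            "otu_ids": self.otu_ids,
            "marginals": {
                "Z": self.marginals.Z.tolist(),
                "p": self.marginals.p.tolist(),
                "rank": self.marginals.r.tolist(),
            },
            "weights": None if self.weights is None else self.weights.tolist(),
            "note": self.note,
        }
        for attr, key in ((self.qq_unweighted, "qq_unweighted"),
                          (self.qq_weighted, "qq_weighted")):
            if attr is not None:
                d[key] = {
                    "expected": attr.expected.tolist(),
                    "observed": attr.observed.tolist(),
                    "deviation": attr.deviation.tolist(),
                    "top_otus": list(attr.top_otus),
                }
            else:
                d[key] = None
        return d


def _ranks_rows(p: np.ndarray) -> np.ndarray:
    """Ascending ranks 1..m per row; ties broken by column index (stable)."""
    order = np.argsort(p, axis=-1, kind="stable")
    r = np.empty_like(order)
    rows = np.arange(p.shape[0])[:, None]
    r[rows, order] = np.arange(1, p.shape[-1] + 1)[None, :]
    return r


def permutation_null(
    nullfit: NullFit,
    O: np.ndarray,
    weights_ctx: Optional[PhyloWeights],
    gamma,
    B: int = 5000,
    seed: Optional[int] = None,
    denom: Optional[np.ndarray] = None,
    chunk: int = 1024,
) -> PermutationNull:
    """Null HC/Simes statistics from B shuffles of the null residuals.

    Each permutation reuses one shared shuffled residual vector across all
    OTUs and all h; score denominators stay fixed at their observed
    values.  Permutation b consumes the b-th draw of a single sequential
    generator stream, so a run is reproducible regardless of chunking.
    """
    if B < 100:
        logger.warning("B=%d gives coarse p-value resolution 1/(B+1)", B)
    O = np.asarray(O, dtype=float)
    n, m = O.shape
    gamma = normalize_gamma(gamma, m)
    if denom is None:
        from .null_glm import _score_denominators

        denom = _score_denominators(nullfit, O)
    rng = np.random.default_rng(seed)
    resid = nullfit.residuals

    null_uhc = np.empty((B, len(gamma)))
    null_whc = np.empty((B, len(gamma))) if weights_ctx is not None else None
    null_simes = np.empty(B)

    done = 0
    while done < B:
        bsz = min(chunk, B - done)
        idx = np.empty((bsz, n), dtype=np.int64)
        for b in range(bsz):
            idx[b] = rng.permutation(n)
        E = resid[idx]                                  # (bsz, n)
        Z = (E @ O) / denom                             # (bsz, m)
        p = 2.0 * stats.norm.sf(np.abs(Z))
        r = _ranks_rows(p)
        d_u = hc_deviations(p, r)
        null_uhc[done:done + bsz] = hc_profile(d_u, gamma)
        null_simes[done:done + bsz] = simes_pvalue(p, r)
        if weights_ctx is not None:
            w = weights_ctx.weights(Z)
            null_whc[done:done + bsz] = hc_profile(d_u * w, gamma)
        done += bsz
    return PermutationNull(B=B, gamma=gamma, null_uhc=null_uhc,
                           null_simes=null_simes, null_whc=null_whc, seed=seed)


def per_test_pvalues(observed: np.ndarray, null_values: np.ndarray) -> np.ndarray:
    """Permutation p-values (1 + #{null > observed}) / (B + 1), columnwise."""
    null_values = np.atleast_2d(null_values)
    B = null_values.shape[0]
    counts = (null_values > np.asarray(observed)[None, :]).sum(axis=0)
    return (1.0 + counts) / (B + 1.0)


def _loo_pvalues(null_values: np.ndarray, smaller_is_extreme: bool = False) -> np.ndarray:
    """Leave-one-out p-value of each permutation against the rest.

    (1 + #{b' != b : null(b') more extreme than null(b)}) / (B + 1); with
    strict comparisons the self term never counts, so the count over all
    B equals the count over b' != b.
    """
    x = np.asarray(null_values, dtype=float)
    B = x.shape[0]
    srt = np.sort(x, axis=0)
    out = np.empty_like(x)
    cols = x.reshape(B, -1)
    scols = srt.reshape(B, -1)
    res = out.reshape(B, -1)
    for c in range(cols.shape[1]):
        if smaller_is_extreme:
            cnt = np.searchsorted(scols[:, c], cols[:, c], side="left")
        else:
            cnt = B - np.searchsorted(scols[:, c], cols[:, c], side="right")
        res[:, c] = (1.0 + cnt) / (B + 1.0)
    return out


def omnibus_pvalues(
    obs_uhc: np.ndarray,
    obs_whc: Optional[np.ndarray],
    obs_simes: float,
    perm: PermutationNull,
) -> dict:
    """Observed and null minimum-p omnibus statistics and their p-values.

    The observed Simes entry is the analytic Simes p-value; the null
    Simes entries are leave-one-out permutation p-values of the permuted
    Simes statistics (compared with strictly-smaller, since a small Simes
    statistic is extreme).
    """
    B = perm.B
    P_u = per_test_pvalues(obs_uhc, perm.null_uhc)
    P_u_null = _loo_pvalues(perm.null_uhc)
    P_s_null = _loo_pvalues(perm.null_simes[:, None], smaller_is_extreme=True)[:, 0]

    T_uA = min(P_u.min(), obs_simes)
    T_uA_null = np.minimum(P_u_null.min(axis=1), P_s_null)
    out = {
        "P_uhc": P_u,
        "T_uhc_A": float(T_uA),
        "P_uhc_A": float((1.0 + (T_uA_null < T_uA).sum()) / (B + 1.0)),
    }
    if obs_whc is not None and perm.null_whc is not None:
        P_w = per_test_pvalues(obs_whc, perm.null_whc)
        P_w_null = _loo_pvalues(perm.null_whc)
        T_wA = min(P_w.min(), obs_simes)
        T_wA_null = np.minimum(P_w_null.min(axis=1), P_s_null)
        T_mihc = min(T_uA, T_wA)
        T_mihc_null = np.minimum(T_uA_null, T_wA_null)
        out.update({
            "P_whc": P_w,
            "T_whc_A": float(T_wA),
            "P_whc_A": float((1.0 + (T_wA_null < T_wA).sum()) / (B + 1.0)),
            "T_mihc": float(T_mihc),
            "P_mihc": float((1.0 + (T_mihc_null < T_mihc).sum()) / (B + 1.0)),
        })
    return out


def mihc_test(
    O,
    y,
    X,
    family: str = "gaussian",
    tree=None,
    phylo: Optional[PhyloWeights] = None,
    otu_ids=None,
    gamma=(1, 3, 5, 7, 9),
    B: int = 5000,
    seed: Optional[int] = None,
    k_max: int = 30,
    with_qq: bool = True,
) -> MihcResult:
    """Run the full MiHC procedure on aligned arrays.

    Parameters
    ----------
    O : (n, m) relative abundances.
    y : (n,) phenotype.
    X : (n, l+1) covariate design with intercept.
    tree : dendropy.Tree, optional
        Rooted phylogeny over the OTU columns.  Alternatively pass a
        prebuilt ``phylo`` (clusters + distances).  With neither, only
        the unweighted family and Simes are computed and uHC_A is the
        headline omnibus test.
    """
    O = np.asarray(O, dtype=float)
    m = O.shape[1]
    gamma = normalize_gamma(gamma, m)
    nullfit = fit_null(y, X, family=family)
    marg = score_stats(nullfit, O, otu_ids=otu_ids)

    if phylo is None and tree is not None:
        phylo = build_weights(tree=tree, otu_ids=otu_ids, k_max=k_max)

    d_u = hc_deviations(marg.p, marg.r)
    obs_uhc = hc_profile(d_u, gamma)
    obs_simes = float(simes_pvalue(marg.p, marg.r))
    w = None
    obs_whc = None
    if phylo is not None:
        w = phylo.weights(marg.Z)
        obs_whc = hc_profile(d_u * w, gamma)

    perm = permutation_null(nullfit, O, phylo, gamma, B=B, seed=seed,
                            denom=marg.denom)
    omni = omnibus_pvalues(obs_uhc, obs_whc, obs_simes, perm)

    has_w = phylo is not None
    result = MihcResult(
        gamma=gamma,
        B=B,
        seed=seed,
        marginals=marg,
        weights=w,
        uhc_stats={h: float(s) for h, s in zip(gamma, obs_uhc)},
        whc_stats={h: float(s) for h, s in zip(gamma, obs_whc)} if has_w else None,
        uhc_pvalues={h: float(p) for h, p in zip(gamma, omni["P_uhc"])},
        whc_pvalues={h: float(p) for h, p in zip(gamma, omni["P_whc"])} if has_w else None,
        simes_pvalue=obs_simes,
        T_uhc_A=omni["T_uhc_A"],
        T_whc_A=omni.get("T_whc_A"),
        T_mihc=omni.get("T_mihc"),
        P_uhc_A=omni["P_uhc_A"],
        P_whc_A=omni.get("P_whc_A"),
        P_mihc=omni.get("P_mihc"),
        otu_ids=list(otu_ids) if otu_ids is not None else None,
        note=None if has_w else (
            "no phylogeny supplied: weighted tests skipped; "
            "uHC_A is the headline omnibus p-value"
        ),
    )
    if with_qq:
        from .viz import qq_points

        result.qq_unweighted = qq_points(marg, otu_ids=otu_ids)
        if has_w:
            result.qq_weighted = qq_points(marg, weights=w, otu_ids=otu_ids)
    return result


def run_dataset(dataset, gamma=(1, 3, 5, 7, 9), B: int = 5000,
                seed: Optional[int] = None, k_max: int = 30) -> MihcResult:
    """Convenience wrapper running :func:`mihc_test` on a MicrobiomeDataset."""
    return mihc_test(
        dataset.otu_matrix, dataset.phenotype, dataset.covariates,
        family=dataset.family, tree=dataset.tree, otu_ids=dataset.otu_ids,
        gamma=gamma, B=B, seed=seed, k_max=k_max,
    )


def write_result(result: MihcResult, tsv_path=None, json_path=None) -> None:
    """Serialize a result to a TSV p-value table and/or a JSON document."""
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("test\tstatistic\tp_value\n")
            for name, s, p in result.pvalue_table():
                fh.write(f"{name}\t{s:.10g}\t{p:.10g}\n")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(result.to_json_dict(), fh, indent=1)
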