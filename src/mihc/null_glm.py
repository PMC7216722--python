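"""Covariate-only null GLM and marginal score statistics.

The association test never fits the m-dimensional OTU model.  It fits the
null model g(mu_i) = x_i' alpha once and, for each OTU j, forms the
standardized score statistic

    Z_j = o_j' (y - mu0) / sqrt(o_j' P o_j),
    P   = W - W X (X' W X)^{-1} X' W,

where W holds the null-model variance weights.  Z_j is treated as N(0, 1)
under the marginal null, giving two-sided p-values and their ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DENOM_FLOOR = 1e-12


@dataclass
class NullFit:
    """Artifacts of the covariate-only null model fit."""

    family: str
    alpha_hat: np.ndarray      # (l+1,)
    mu0_hat: np.ndarray        # (n,)
    residuals: np.ndarray      # (n,) y - mu0
    W: np.ndarray              # (n,) variance weights (diagonal of W)
    dispersion: float
    X: np.ndarray              # (n, l+1) design


@dataclass
class MarginalStats:
    """Per-OTU score statistics, p-values, and ranks."""

    Z: np.ndarray
    p: np.ndarray
    r: np.ndarray              # ranks of p ascending, 1..m
    denom: np.ndarray          # sqrt(o_j' P o_j), fixed across permutations


def fit_null(y, X, family: str = "gaussian") -> NullFit:
    """Fit the null GLM g(mu) = X alpha.

    Gaussian uses least squares with the maximum-likelihood dispersion
    RSS/n; binomial uses IRLS (statsmodels) with dispersion fixed at 1.

    The MLE dispersion slightly inflates every |Z_j| relative to the
    unbiased RSS/(n - rank) form.  Because the residual vector also
    drives the dispersion estimate, the self-normalized statistics have
    lighter-than-normal tails; the MLE form compensates almost exactly,
    so two-sided normal marginal p-values (and hence the analytic Simes
    test) are calibrated in the far tail.  Permutation-based p-values are
    essentially invariant to this choice, as the factor is shared by the
    observed and every permuted statistic.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(f"design matrix is rank deficient (rank {rank} < {p})")
    if family == "gaussian":
        alpha, *_ = np.linalg.lstsq(X, y, rcond=None)
        mu = X @ alpha
        resid = y - mu
        phi = float(resid @ resid) / n
        W = np.full(n, phi)
        return NullFit("gaussian", alpha, mu, resid, W, phi, X)
    if family == "binomial":
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ValueError("binomial phenotype must be coded 0/1")
        if len(uniq) < 2:
            raise ValueError("binomial phenotype is constant (all "
                             f"{int(uniq[0])}); the null fit is degenerate")
        import statsmodels.api as sm

        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=100, tol=1e-8)
        except Exception as exc:  # pragma: no cover - statsmodels failure path
            raise ValueError(f"binomial null fit failed: {exc}") from exc
        if not res.converged:
            raise ValueError("binomial null fit did not converge in 100 iterations")
        mu = np.asarray(res.fittedvalues)
        W = mu * (1.0 - mu)
        if W.min() < 1e-10:
            raise ValueError(
                "degenerate binomial fit (fitted probabilities at 0/1); "
                "possible separation or constant phenotype"
            )
        return NullFit("binomial", np.asarray(res.params), mu, y - mu, W, 1.0, X)
    raise ValueError(f"unsupported family {family!r}")


def _score_denominators(nullfit: NullFit, O: np.ndarray) -> np.ndarray:
    """sqrt(o_j' P o_j) for every column of O, without forming the n x n P."""
    W = nullfit.W
    X = nullfit.X
    WX = X * W[:, None]
    XtWX = X.T @ WX
    B = WX.T @ O                       # (l+1, m)
    sol = np.linalg.solve(XtWX, B)
    quad = (O * O * W[:, None]).sum(axis=0) - (B * sol).sum(axis=0)
    return np.sqrt(np.maximum(quad, 0.0))


def rank_pvalues(p: np.ndarray, absZ: np.ndarray | None = None) -> np.ndarray:
    """Ascending ranks 1..m of p with a deterministic tie-break.

    Ties are broken by ascending |Z| (when given) then by OTU index, which
    leaves every rank-based statistic invariant but makes output stable.
    """
    m = p.shape[-1]
    idx = np.arange(m)
    if absZ is None:
        order = np.lexsort((idx, p))
    else:
        order = np.lexsort((idx, absZ, p))
    r = np.empty(m, dtype=np.int64)
    r[order] = np.arange(1, m + 1)
    return r


def score_stats(nullfit: NullFit, O, otu_ids=None) -> MarginalStats:
    """Marginal standardized score statistics for every OTU column of O."""
    O = np.asarray(O, dtype=float)
    if nullfit.dispersion <= 0:
        raise ValueError("null dispersion is 0: phenotype fits covariates exactly")
    denom = _score_denominators(nullfit, O)
    bad = np.nonzero(denom * denom <= DENOM_FLOOR)[0]
    if bad.size:
        names = ([otu_ids[j] for j in bad[:5]] if otu_ids is not None
                 else bad[:5].tolist())
        raise ValueError(
            f"degenerate score denominator for OTU(s) {names} (constant or "
            "collinear with covariates); apply a stricter abundance filter"
        )
    Z = (O.T @ nullfit.residuals) / denom
    p = 2.0 * stats.norm.sf(np.abs(Z))
    r = rank_pvalues(p, np.abs(Z))
    return MarginalStats(Z=Z, p=p, r=r, denom=denom)
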