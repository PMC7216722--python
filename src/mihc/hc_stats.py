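"""Higher criticism deviations, modulated statistics, and the Simes test.

For marginal p-values p_j with ascending ranks r_j (and optional weights
w_j), the per-OTU deviation between the expected and observed quantiles
of significance is

    d_j = w_j (r_j / m - p_j) / sqrt(p_j (1 - p_j) / m).

The original higher criticism statistic is max_j d_j; the modulated
variant averages the h largest deviations, trading sensitivity at extreme
sparsity (h = 1) against power at lower sparsity (larger h).  The Simes
statistic min_j (m p_j / r_j) is itself a valid p-value and is powerful
at excessively high sparsity.

All functions accept batched input with p-vectors along the last axis.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

P_CLAMP = 1e-12


def hc_deviations(p: np.ndarray, r: np.ndarray, w=None) -> np.ndarray:
    """Standardized expected-minus-observed significance quantile per OTU.

    p is clamped to [1e-12, 1 - 1e-12] so the denominator never vanishes;
    a clamped p_j = 1 yields a large negative deviation that can never be
    a maximum.
    """
    p = np.clip(np.asarray(p, dtype=float), P_CLAMP, 1.0 - P_CLAMP)
    r = np.asarray(r, dtype=float)
    m = p.shape[-1]
    d = (r / m - p) / np.sqrt(p * (1.0 - p) / m)
    if w is not None:
        d = np.asarray(w, dtype=float) * d
    return d


def modulated_hc(d: np.ndarray, h: int) -> np.ndarray:
    """Mean of the h largest deviations (h = 1 is the classic HC maximum)."""
    m = d.shape[-1]
    if h < 1:
        raise ValueError(f"h must be >= 1, got {h}")
    if h > m:
        logger.warning("h=%d exceeds m=%d; clipping to m", h, m)
        h = m
    top = np.sort(d, axis=-1)[..., m - h:]
    return top.mean(axis=-1)


def hc_profile(d: np.ndarray, hs) -> np.ndarray:
    """modulated_hc for every h in hs at the cost of one sort.

    Returns an array with a trailing axis of length len(hs).
    """
    hs = np.asarray(hs, dtype=np.int64)
    m = d.shape[-1]
    desc = np.sort(d, axis=-1)[..., ::-1]
    cum = np.cumsum(desc, axis=-1)
    return cum[..., hs - 1] / hs


def simes_pvalue(p: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Simes combination min_j (m p_j / r_j); a valid p-value in (0, 1]."""
    p = np.asarray(p, dtype=float)
    r = np.asarray(r, dtype=float)
    m = p.shape[-1]
    return (m * p / r).min(axis=-1)


def normalize_gamma(gamma, m: int) -> tuple:
    """Candidate sparsity set: clip entries to <= m, dedupe, sort ascending."""
    vals = sorted({min(int(h), m) for h in gamma})
    if not vals or vals[0] < 1:
        raise ValueError(f"invalid candidate set {gamma}")
    return tuple(vals)
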