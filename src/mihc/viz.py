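"""Q-Q influence diagnostics.

For each OTU the expected and observed quantiles of significance are

    expected_j = w_j (r_j / m) / sqrt(p_j (1 - p_j) / m)
    observed_j = w_j p_j       / sqrt(p_j (1 - p_j) / m)

(w = 1 in the unweighted panel).  Points on the unit diagonal carry no
association signal; the signed gap expected - observed is exactly the
higher-criticism deviation d_j, and the OTUs with the largest |gap| are
the most influential ones.  Expected is drawn on x, observed on y.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .hc_stats import P_CLAMP


@dataclass
class QqData:
    """Per-OTU Q-Q coordinates and the top influential OTUs."""

    expected: np.ndarray
    observed: np.ndarray
    deviation: np.ndarray        # expected - observed, the HC deviation d_j
    top_otus: list               # up to 10 labels, most influential first
    weighted: bool


def qq_points(marginals, weights: Optional[np.ndarray] = None,
              otu_ids: Optional[Sequence[str]] = None, top: int = 10) -> QqData:
    """Q-Q coordinates from marginal stats, optionally phylogeny-weighted.

    Influence is ranked by absolute deviation from the diagonal; up to
    ``top`` OTU labels are reported, most influential first.
    """
    p = np.clip(np.asarray(marginals.p, dtype=float), P_CLAMP, 1.0 - P_CLAMP)
    r = np.asarray(marginals.r, dtype=float)
    m = p.shape[0]
    w = np.ones(m) if weights is None else np.asarray(weights, dtype=float)
    scale = np.sqrt(p * (1.0 - p) / m)
    expected = w * (r / m) / scale
    observed = w * p / scale
    dev = expected - observed
    order = np.argsort(-np.abs(dev), kind="stable")[: min(top, m)]
    labels = list(otu_ids) if otu_ids is not None else [f"OTU{j + 1}" for j in range(m)]
    return QqData(expected=expected, observed=observed, deviation=dev,
                  top_otus=[labels[j] for j in order],
                  weighted=weights is not None)


def render_qq(qq_u: QqData, qq_w: Optional[QqData], out_path,
              annotations: Optional[dict] = None, formats=("png", "pdf")):
    """Render one- or two-panel Q-Q diagnostics to image files.

    Blue dots are OTUs, the red unit diagonal marks no influence, and
    darker-to-lighter vertical guides mark the ranked top influential
    OTUs.  ``annotations`` (e.g. test p-values) are printed in a corner
    text block.  Returns the list of files written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [(qq_u, "uHC (unweighted)")]
    if qq_w is not None:
        panels.append((qq_w, "wHC (weighted)"))
    fig, axes = plt.subplots(1, len(panels), figsize=(6 * len(panels), 5.5))
    axes = np.atleast_1d(axes)
    for ax, (qq, title) in zip(axes, panels):
        lim = float(max(qq.expected.max(), qq.observed.max())) * 1.05
        shades = np.linspace(0.15, 0.75, max(len(qq.top_otus), 1))
        labels = list(qq.top_otus)
        order = np.argsort(-np.abs(qq.deviation), kind="stable")[: len(labels)]
        for rank, j in enumerate(order):
            ax.axvline(qq.expected[j], color=str(shades[rank]), lw=0.8, zorder=1)
        ax.plot([0, lim], [0, lim], color="red", lw=1.2, zorder=2)
        ax.scatter(qq.expected, qq.observed, s=14, color="tab:blue",
                   alpha=0.8, zorder=3)
        ax.set_xlim(0, lim)
        ax.set_ylim(0, lim)
        ax.set_xlabel("expected quantile")
        ax.set_ylabel("observed quantile")
        ax.set_title(title)
        if labels:
            ax.legend(handles=[], title="top: " + ", ".join(labels[:5]),
                      loc="upper left", frameon=False, fontsize=8)
    if annotations:
        txt = "\n".join(f"{k}: {v:.3g}" if isinstance(v, float) else f"{k}: {v}"
                        for k, v in annotations.items())
        fig.text(0.995, 0.02, txt, ha="right", va="bottom", fontsize=7,
                 family="monospace")
    fig.tight_layout()
    written = []
    for ext in formats:
        path = f"{out_path}.{ext}"
        fig.savefig(path, metadata={"CreationDate": None} if ext == "pdf" else None)
        written.append(path)
    plt.close(fig)
    return written
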