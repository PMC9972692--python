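"""Diagnostic plot: corrected kinship versus overlapping-marker count with
the fitted N-sigma threshold curve."""

from __future__ import annotations

import numpy as np

from .correct_filter import ErrorModel
from .overlap import OverlapMatrix


def plot_corrected_vs_overlap(
    corrected: np.ndarray,
    overlap: OverlapMatrix,
    model: ErrorModel | None,
    path: str,
) -> None:
    """Scatter all pairs' phi* against n, highlighting pairs above threshold.

    Requires matplotlib; raises ImportError if it is not installed.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    iu = np.triu_indices(corrected.shape[0], k=1)
    phi = np.asarray(corrected, dtype=float)[iu]
    n = overlap.counts[iu].astype(float)
    ok = np.isfinite(phi) & (n > 0)
    phi, n = phi[ok], n[ok]

    fig, ax = plt.subplots(figsize=(7, 4.5))
    if model is not None:
        above = phi >= model.threshold(n)
        grid = np.geomspace(n.min(), n.max(), 200)
        ax.plot(grid, model.threshold(grid), "r-", lw=1.5,
                label=f"mean + {model.Z:g} sigma")
    else:
        above = np.zeros(len(phi), dtype=bool)
    ax.plot(n[~above], phi[~above], "k.", ms=2, alpha=0.4, label="pairs")
    if above.any():
        ax.plot(n[above], phi[above], "bo", ms=5, label="called relatives")
    ax.set_xscale("log")
    ax.set_xlabel("overlapping markers (n)")
    ax.set_ylabel("corrected kinship coefficient")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
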