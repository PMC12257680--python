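"""Diagnostic plots for one flock-year's alignment.

Four panels per series: unaligned curves, aligned curves, the Karcher mean
with the weaning anchor, and the warp functions against the identity.
matplotlib is imported lazily so the rest of the package works without it.
"""

from __future__ import annotations

import numpy as np

from .elastic import GroupAlignment

__all__ = ["plot_alignment_panels"]


def plot_alignment_panels(
    ga: GroupAlignment,
    unaligned: dict[int, np.ndarray] | None = None,
    weaning_anchor: float | None = None,
    out: str | None = None,
):
    """2x2 panel figure for one aligned group; returns the figure.

    ``unaligned`` maps animal id to the pre-alignment curve on ``ga.grid``
    (omit to skip that panel); ``out`` saves the figure to a file.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    (ax_u, ax_a), (ax_m, ax_w) = axes
    lab = f"{ga.series} {ga.flock_year} (lambda={ga.lambda_align:g})"

    if unaligned:
        for f in unaligned.values():
            ax_u.plot(ga.grid, f, lw=0.5, alpha=0.4, color="tab:grey")
    ax_u.set_title(f"unaligned curves {lab}")

    for row in ga.aligned:
        ax_a.plot(ga.grid, row, lw=0.5, alpha=0.4, color="tab:blue")
    ax_a.set_title("aligned curves")

    ax_m.plot(ga.grid, ga.mean_function, color="tab:red", lw=2)
    if weaning_anchor is not None:
        ax_m.axvline(weaning_anchor, color="tab:red", alpha=0.3, lw=6)
    ax_m.set_title("Karcher mean")

    for g in ga.warps:
        ax_w.plot(g.grid, g.values, lw=0.5, alpha=0.4, color="tab:green")
    ax_w.plot(ga.grid, ga.grid, "k--", lw=1)
    ax_w.set_title("warping functions")
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=120)
    return fig
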