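"""Figure generation: density curve, boundary markers, inbetweener band."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .densities import AttributeDensity
from .inbetweeners import BoundaryPair

__all__ = ["render_fig_panel"]


def render_fig_panel(
    density: AttributeDensity,
    pair: BoundaryPair,
    path: str | Path,
    title: str | None = None,
) -> list[Path]:
    """Plot rho(x) with both stable boundaries and the shaded region between.

    Writes both PNG and SVG next to ``path`` (extension replaced) and
    returns the written paths.
    """
    path = Path(path)
    x = np.linspace(density.a, density.b, 512)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(x, density.pdf(x), color="C0", lw=1.8, label=r"$\rho(x)$")
    ax.axvline(pair.z1_star, color="C3", ls="--", lw=1.2, label=rf"$z_1^*={pair.z1_star:.3f}$")
    ax.axvline(pair.z2_star, color="C2", ls="--", lw=1.2, label=rf"$z_2^*={pair.z2_star:.3f}$")
    lo, hi = sorted((pair.z1_star, pair.z2_star))
    if pair.z1_star < pair.z2_star:
        ax.axvspan(lo, hi, color="grey", alpha=0.25, label="inbetweeners")
    ax.set_xlabel("attribute $x$")
    ax.set_ylabel("density")
    ax.set_xlim(density.a, density.b)
    ax.set_ylim(bottom=0)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    written = []
    for ext in (".png", ".svg"):
        out = path.with_suffix(ext)
        fig.savefig(out, dpi=150)
        written.append(out)
    plt.close(fig)
    return written
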