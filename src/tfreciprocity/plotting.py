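"""Surface plots of the reciprocity over induced concentrations."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .reciprocity import SurfaceGrid

__all__ = ["render_surface", "surface_from_csv"]


def surface_from_csv(path) -> SurfaceGrid:
    """Rebuild a SurfaceGrid from a long-format sox2i,oct4i,gamma CSV."""
    df = pd.read_csv(path)
    for col in ("sox2i", "oct4i", "gamma"):
        if col not in df.columns:
            raise ValueError(f"surface CSV is missing column {col!r}")
    sox2i = np.array(sorted(df["sox2i"].unique()))
    oct4i = np.array(sorted(df["oct4i"].unique()))
    grid = df.pivot(index="sox2i", columns="oct4i", values="gamma")
    grid = grid.reindex(index=sox2i, columns=oct4i)
    return SurfaceGrid(sox2i=sox2i, oct4i=oct4i, gamma=grid.to_numpy())


def render_surface(
    surface: SurfaceGrid,
    out_path,
    reference_plane: float = -0.22,
    title: str | None = None,
) -> None:
    """3D Gamma surface with a zero plane and a flat reference plane.

    The reference plane (default -0.22, the level implied by the measured
    residence times) makes it easy to see whether a model can reach the
    observed reciprocity.  A 1x1 grid cannot be rendered as a surface.
    """
    if surface.sox2i.size < 2 or surface.oct4i.size < 2:
        raise ValueError("need at least a 2x2 grid to render a surface")
    S, O = np.meshgrid(np.log10(surface.sox2i), np.log10(surface.oct4i), indexing="ij")
    fig = plt.figure(figsize=(7, 5.5))
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(S, O, surface.gamma, cmap="viridis", alpha=0.85)
    for level, color in ((0.0, "tab:blue"), (reference_plane, "tab:brown")):
        ax.plot_surface(S, O, np.full_like(surface.gamma, level), color=color, alpha=0.25)
    ax.set_xlabel(r"$\log_{10}\,[\mathrm{Sox2}^i]$")
    ax.set_ylabel(r"$\log_{10}\,[\mathrm{Oct4}^i]$")
    ax.set_zlabel(r"$\Gamma$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
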