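"""2D/3D PCA scatter plots from eigenvector/eigenvalue files.

Points are colored by population label; axis labels carry the PC index and
the percentage of variance explained (lambda_i / sum(lambda) * 100).  Solid
mode fixes the 3D camera via elevation/azimuth; interactive mode opens a
rotatable window and is meant for desktop use only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._render import RenderResult, save_figure
from .formats_io import EigenData

__all__ = ["ScatterSpec", "variance_explained", "render_pca", "render_pca_snapshots"]

DEFAULT_ELEV = 30.0
DEFAULT_AZIM = -60.0


@dataclass
class ScatterSpec:
    """PC selection and camera parameters for a PCA scatter plot.

    PC indices are 1-based; ``pc_z`` is ignored when ``dims == 2``.
    """

    dims: int = 3
    pc_x: int = 1
    pc_y: int = 2
    pc_z: int = 3
    mode: str = "solid"  # solid | interactive
    elev: float = DEFAULT_ELEV
    azim: float = DEFAULT_AZIM
    point_size: float = 20.0

    def validate(self, k: int) -> None:
        if self.dims not in (2, 3):
            raise ValueError(f"dims must be 2 or 3, got {self.dims}")
        wanted = [self.pc_x, self.pc_y] + ([self.pc_z] if self.dims == 3 else [])
        if len(set(wanted)) != len(wanted):
            raise ValueError(f"requested PC indices must be distinct, got {wanted}")
        for pc in wanted:
            if pc < 1 or pc > k:
                raise ValueError(f"requested PC unavailable: PC{pc} (only {k} available)")
        if self.mode not in ("solid", "interactive"):
            raise ValueError(f"mode must be 'solid' or 'interactive', got {self.mode!r}")
        if self.point_size <= 0:
            raise ValueError("point_size must be positive")


def variance_explained(eigenvalues: Sequence[float]) -> list:
    """Percentage of variance per component: lambda_i / sum(lambda) * 100."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0 or np.any(lam < 0):
        raise ValueError("eigenvalues must be a non-empty non-negative vector")
    total = lam.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are zero; variance fractions undefined")
    return list(lam / total * 100.0)


def _axis_label(pc: int, pct: list) -> str:
    return f"PC{pc} ({pct[pc - 1]:.2f}%)"


def render_pca(
    data: EigenData,
    spec: ScatterSpec,
    out_path,
    palette: str = "tab10",
    fmt: Optional[str] = None,
    dpi: int = 300,
    font_size: float = 9.0,
) -> RenderResult:
    """Render a 2D or 3D PCA scatter colored by population with a legend."""
    import matplotlib.pyplot as plt
    from matplotlib import colormaps

    spec.validate(data.k)
    pct = variance_explained(data.eigenvalues)

    pops: list = []
    for p in data.pop_labels:
        if p not in pops:
            pops.append(p)
    cmap = colormaps[palette]
    ncol = getattr(cmap, "N", 10)
    colors = {p: cmap(i % ncol) for i, p in enumerate(pops)}

    X = data.components
    xs = X[:, spec.pc_x - 1]
    ys = X[:, spec.pc_y - 1]

    fig = plt.figure(figsize=(7, 6))
    if spec.dims == 3:
        ax = fig.add_subplot(projection="3d")
        zs = X[:, spec.pc_z - 1]
        for p in pops:
            sel = [i for i, q in enumerate(data.pop_labels) if q == p]
            ax.scatter(xs[sel], ys[sel], zs[sel], s=spec.point_size,
                       color=colors[p], label=p, depthshade=False)
        ax.set_zlabel(_axis_label(spec.pc_z, pct), fontsize=font_size)
        ax.view_init(elev=spec.elev, azim=spec.azim)
        camera = {"elev": float(spec.elev), "azim": float(spec.azim)}
    else:
        ax = fig.add_subplot()
        for p in pops:
            sel = [i for i, q in enumerate(data.pop_labels) if q == p]
            ax.scatter(xs[sel], ys[sel], s=spec.point_size, color=colors[p], label=p)
        camera = None
    ax.set_xlabel(_axis_label(spec.pc_x, pct), fontsize=font_size)
    ax.set_ylabel(_axis_label(spec.pc_y, pct), fontsize=font_size)
    ax.legend(fontsize=font_size, title="Population")

    axis_labels = [_axis_label(spec.pc_x, pct), _axis_label(spec.pc_y, pct)]
    if spec.dims == 3:
        axis_labels.append(_axis_label(spec.pc_z, pct))
    layout = {
        "kind": "pca-scatter",
        "dims": spec.dims,
        "axis_labels": axis_labels,
        "legend_entries": pops,
        "camera": camera,
        "point_size": spec.point_size,
        "variance_explained": pct,
    }

    if spec.mode == "interactive":  # pragma: no cover - needs a display
        plt.show()
        return RenderResult(None, layout)
    path = save_figure(fig, out_path, fmt=fmt, dpi=dpi)
    return RenderResult(path, layout)


def render_pca_snapshots(
    data: EigenData,
    spec: ScatterSpec,
    angles: Sequence,
    out_path,
    **kwargs,
) -> list:
    """Render solid 3D frames at each (elev, azim) pair, suffixing the path.

    Substitute for the interactive window in scripted/headless use: the same
    plot is exported from several camera angles.
    """
    from dataclasses import replace
    from pathlib import Path

    out_path = Path(out_path)
    results = []
    for i, (elev, azim) in enumerate(angles):
        frame_spec = replace(spec, dims=3, mode="solid", elev=elev, azim=azim)
        frame_path = out_path.with_name(f"{out_path.stem}_angle{i}{out_path.suffix}")
        results.append(render_pca(data, frame_spec, frame_path, **kwargs))
    return results
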