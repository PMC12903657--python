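"""Genome-wide SNP density: fixed-size binning against true chromosome lengths.

Each chromosome is divided into non-overlapping bins of ``bin_size`` bp and
the number of markers per bin is counted.  Chromosome extent always comes from
the genome index, never from the last genotyped marker, so sparsely genotyped
chromosome ends are drawn at their true physical scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._render import RenderResult, save_figure
from .formats_io import GenomeIndex, MarkerMap

DEFAULT_BIN_SIZE = 1_000_000  # 1 Mb

__all__ = ["ChromBins", "BinDensity", "compute_bin_counts", "render_density_heatmap",
           "DEFAULT_BIN_SIZE"]


@dataclass
class ChromBins:
    chrom: str
    length: int
    bin_size: int
    counts: np.ndarray  # non-negative ints, len == ceil(length / bin_size)


@dataclass
class BinDensity:
    """Per-chromosome bin counts, in genome-index order."""

    chroms: list  # list[ChromBins]

    @property
    def total_markers(self) -> int:
        return int(sum(c.counts.sum() for c in self.chroms))

    @property
    def max_count(self) -> int:
        return int(max((c.counts.max() if len(c.counts) else 0) for c in self.chroms))


def compute_bin_counts(markers: MarkerMap, index: GenomeIndex, bin_size: int = DEFAULT_BIN_SIZE) -> BinDensity:
    """Count markers in non-overlapping fixed-size bins per chromosome.

    A marker at 1-based position p falls in bin floor((p - 1) / bin_size); bin
    b therefore spans [b*bin_size + 1, min((b+1)*bin_size, length)].  Every
    indexed chromosome yields ceil(length / bin_size) bins even with zero
    markers.  Markers on unindexed chromosomes or beyond the indexed length
    are errors (they signal an assembly/index mismatch).
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    lengths = dict(index.entries)
    counts = {c: np.zeros(math.ceil(n / bin_size), dtype=int) for c, n in index.entries}
    for r in markers.records:
        if r.chrom not in lengths:
            raise ValueError(
                f"marker {r.snp_id!r} on chromosome {r.chrom!r} absent from genome index"
            )
        if r.bp > lengths[r.chrom]:
            raise ValueError(
                f"marker {r.snp_id!r} at position {r.bp} beyond indexed length "
                f"{lengths[r.chrom]} of chromosome {r.chrom!r}"
            )
        counts[r.chrom][(r.bp - 1) // bin_size] += 1
    return BinDensity([ChromBins(c, n, bin_size, counts[c]) for c, n in index.entries])


def render_density_heatmap(
    density: BinDensity,
    out_path,
    colormap: str = "viridis",
    fmt: Optional[str] = None,
    dpi: int = 300,
    font_size: float = 9.0,
    title: Optional[str] = None,
) -> RenderResult:
    """Render one horizontal heatmap track per chromosome, index order top-down.

    Track widths are proportional to physical chromosome length and all tracks
    share one color scale with a colorbar.
    """
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors

    if not density.chroms:
        raise ValueError("empty density: nothing to render")
    vmax = max(density.max_count, 1)
    norm = colors.Normalize(vmin=0, vmax=vmax)
    max_len = max(c.length for c in density.chroms)
    n = len(density.chroms)

    fig, ax = plt.subplots(figsize=(10, max(2.0, 0.3 * n + 1.2)))
    tracks = []
    for i, cb in enumerate(density.chroms):
        y = n - 1 - i  # first chromosome on top
        ax.imshow(
            cb.counts[np.newaxis, :],
            extent=(0, cb.length, y + 0.08, y + 0.92),
            aspect="auto",
            cmap=colormap,
            norm=norm,
            interpolation="nearest",
        )
        tracks.append({
            "chrom": cb.chrom,
            "length": cb.length,
            "n_bins": int(len(cb.counts)),
            "drawn_width": float(cb.length),
            "width_fraction": cb.length / max_len,
            "y": y,
        })
    ax.set_xlim(0, max_len)
    ax.set_ylim(0, n)
    ax.set_yticks([n - 1 - i + 0.5 for i in range(n)])
    ax.set_yticklabels([c.chrom for c in density.chroms], fontsize=font_size)
    ax.set_xlabel("Position (bp)", fontsize=font_size)
    ax.set_ylabel("Chromosome", fontsize=font_size)
    if title:
        ax.set_title(title, fontsize=font_size + 2)
    mappable = cm.ScalarMappable(norm=norm, cmap=colormap)
    cbar = fig.colorbar(mappable, ax=ax, shrink=0.8)
    cbar.set_label("SNPs per bin", fontsize=font_size)
    fig.tight_layout()

    layout = {
        "kind": "snp-density-heatmap",
        "tracks": tracks,
        "bin_size": density.chroms[0].bin_size,
        "color_scale": (0, vmax),
        "colormap": colormap,
    }
    path = save_figure(fig, out_path, fmt=fmt, dpi=dpi)
    return RenderResult(path, layout)
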