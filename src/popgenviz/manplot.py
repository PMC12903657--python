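"""Manhattan plots with automatic cumulative genomic coordinates.

Chromosomes are laid out sequentially on the x-axis: each chromosome's span is
its maximum observed bp and its offset is the sum of the spans before it, so
chromosome ranges abut without gaps.  Input statistics are plotted as given; a
-log10 transform for p-values is opt-in (the statistic column may equally be
nucleotide diversity or a selection score that must not be transformed).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._render import RenderResult, save_figure
from .formats_io import AssocRecord, AssocTable

__all__ = ["ManhattanLayout", "natural_chrom_sort", "cumulative_coordinates",
           "transform_values", "render_manhattan"]

_SPECIAL = {"X": 0, "Y": 1, "MT": 2, "M": 2}


def natural_chrom_sort(chroms: Sequence[str]) -> list:
    """Numeric identifiers ascending, then X, Y, MT, then others lexically.

    A leading "chr" prefix is ignored for ranking but preserved in output.
    """
    def key(c: str):
        body = re.sub(r"^chr", "", c, flags=re.IGNORECASE)
        if body.isdigit():
            return (0, int(body), c)
        if body.upper() in _SPECIAL:
            return (1, _SPECIAL[body.upper()], c)
        return (2, 0, c)

    return sorted(set(chroms), key=key)


@dataclass
class ManhattanLayout:
    """Cumulative coordinates plus per-chromosome offsets/spans/tick positions.

    ``points`` columns: chrom, bp, value, x, chrom_rank — sorted by
    (chromosome rank, bp).  ``chrom_info`` columns: chrom, rank, offset, span,
    tick_position.
    """

    points: pd.DataFrame
    chrom_info: pd.DataFrame

    @property
    def chrom_order(self) -> list:
        return list(self.chrom_info["chrom"])


def cumulative_coordinates(table: AssocTable, chrom_order: Optional[Sequence[str]] = None) -> ManhattanLayout:
    """Assign each record x = chromosome offset + bp.

    offset(c) = sum of spans of preceding chromosomes, span(c) = max observed
    bp on c.  Chromosome order is ``chrom_order`` when given (every observed
    chromosome must appear in it), else the natural sort.
    """
    if not table.records:
        raise ValueError("empty association table")
    df = pd.DataFrame(table.records, columns=["chrom", "bp", "value"])
    observed = list(df["chrom"].unique())
    if chrom_order is not None:
        missing = [c for c in observed if c not in set(chrom_order)]
        if missing:
            raise ValueError(
                f"records on chromosomes absent from chrom_order: {missing[:5]}"
            )
        order = [c for c in chrom_order if c in set(observed)]
    else:
        order = natural_chrom_sort(observed)

    spans = df.groupby("chrom")["bp"].max()
    info_rows = []
    offset = 0
    rank_of = {}
    for rank, c in enumerate(order):
        span = int(spans[c])
        info_rows.append({"chrom": c, "rank": rank, "offset": offset,
                          "span": span, "tick_position": offset + span / 2.0})
        rank_of[c] = (rank, offset)
        offset += span

    df["chrom_rank"] = df["chrom"].map(lambda c: rank_of[c][0])
    df["x"] = df["chrom"].map(lambda c: rank_of[c][1]) + df["bp"].astype(float)
    # value as final key makes the layout a pure function of the record multiset
    df = df.sort_values(["chrom_rank", "bp", "value"], kind="stable").reset_index(drop=True)
    return ManhattanLayout(df, pd.DataFrame(info_rows))


def transform_values(table: AssocTable, logp: bool) -> AssocTable:
    """Return the table with values mapped to -log10 when ``logp`` is set.

    p-values must lie in (0, 1]; anything else is an error naming the row.
    """
    if not logp:
        return AssocTable(list(table.records))
    out = []
    for i, r in enumerate(table.records):
        if not (0.0 < r.value <= 1.0):
            raise ValueError(
                f"-log10 transform requires p-values in (0, 1]; "
                f"row {i + 1} has value {r.value!r}"
            )
        out.append(AssocRecord(r.chrom, r.bp, -math.log10(r.value)))
    return AssocTable(out)


def render_manhattan(
    layout: ManhattanLayout,
    out_path,
    palette: str = "tab10",
    n_colors: int = 2,
    alpha: float = 1.0,
    point_size: float = 4.0,
    sug1: Optional[float] = None,
    sug2: Optional[float] = None,
    sug_colors: tuple = ("red", "blue"),
    fmt: Optional[str] = None,
    dpi: int = 300,
    font_size: float = 9.0,
    ylabel: str = "Statistic",
) -> RenderResult:
    """Scatter the layout with chromosome-alternating colors and threshold lines.

    Colors cycle with chromosome rank modulo ``n_colors``; ``sug1``/``sug2``
    draw horizontal suggestive lines on the plotted scale.
    """
    import matplotlib.pyplot as plt
    from matplotlib import colormaps

    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if n_colors < 1:
        raise ValueError("n_colors must be >= 1")
    cmap = colormaps[palette]
    ncol = getattr(cmap, "N", 10)
    cycle = [cmap(i % ncol) for i in range(n_colors)]

    fig, ax = plt.subplots(figsize=(11, 3.5))
    color_indices = {}
    for _, row in layout.chrom_info.iterrows():
        ci = int(row["rank"]) % n_colors
        color_indices[row["chrom"]] = ci
        sel = layout.points[layout.points["chrom"] == row["chrom"]]
        ax.scatter(sel["x"], sel["value"], s=point_size, color=cycle[ci],
                   alpha=alpha, linewidths=0, rasterized=len(layout.points) > 50_000)

    threshold_lines = []
    for level, color in zip((sug1, sug2), sug_colors):
        if level is not None:
            ax.axhline(level, color=color, linewidth=1.0, linestyle="--")
            threshold_lines.append(float(level))

    ax.set_xticks(layout.chrom_info["tick_position"])
    ax.set_xticklabels(layout.chrom_info["chrom"], fontsize=font_size)
    total = float(layout.chrom_info["offset"].iloc[-1] + layout.chrom_info["span"].iloc[-1])
    ax.set_xlim(0, total)
    ax.set_xlabel("Chromosome", fontsize=font_size)
    ax.set_ylabel(ylabel, fontsize=font_size)
    fig.tight_layout()

    render_layout = {
        "kind": "manhattan",
        "n_points": int(len(layout.points)),
        "color_indices": color_indices,
        "threshold_lines": threshold_lines,
        "tick_positions": [float(t) for t in layout.chrom_info["tick_position"]],
        "alpha": alpha,
        "point_size": point_size,
    }
    path = save_figure(fig, out_path, fmt=fmt, dpi=dpi)
    return RenderResult(path, render_layout)
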