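"""Runs-of-homozygosity (and CNV) track plotting with shared-region detection.

Shared regions are genomic intervals covered by segments from at least a
threshold fraction t of all individuals in the table.  The denominator is the
number of distinct individuals across all populations (pooled), matching the
semantics of the ``threshold`` argument of detectRUNS' tableRuns.  Coverage is
computed by a sweep line after per-individual merging, so one individual with
several overlapping segments counts once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from ._render import RenderResult, save_figure
from .formats_io import FormatError, GenomeIndex, IntervalRecord, IntervalTable, _iter_rows

__all__ = [
    "SharedInterval",
    "merge_individual_intervals",
    "compute_shared_intervals",
    "write_shared_intervals",
    "read_shared_intervals",
    "render_roh_plot",
]

# ceil(t*N) decides how many individuals must carry a region; the tiny guard
# keeps e.g. t=0.1, N=10 (binary 0.1*10 = 1.0000000000000002) at 1, not 2
_CEIL_GUARD = 1e-9


@dataclass(frozen=True)
class SharedInterval:
    """A maximal region covered by >= ceil(t*N) individuals.

    ``count`` is the minimum coverage over the region (the most conservative
    single number when coverage varies inside it); frequency = count / N.
    """

    chrom: str
    start: int
    end: int
    count: int
    frequency: float


def merge_individual_intervals(records: IntervalTable) -> IntervalTable:
    """Merge overlapping or book-ended intervals per (individual, chromosome).

    Intervals are 1-based closed; [100,200] and [201,250] merge (0-base gap),
    [100,200] and [202,250] do not.  Output preserves each individual's
    population label and orders records by (individual, chromosome) first
    appearance, then start.
    """
    by_key: dict = {}
    pop_of: dict = {}
    order: list = []
    for r in records.records:
        key = (r.individual, r.chrom)
        if key not in by_key:
            by_key[key] = []
            order.append(key)
        by_key[key].append((r.start, r.end))
        pop_of.setdefault(r.individual, r.population)

    merged_records = []
    for key in order:
        ind, chrom = key
        ivs = sorted(by_key[key])
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            merged_records.append(IntervalRecord(pop_of[ind], ind, chrom, s, e))
    return IntervalTable(merged_records)


def required_count(threshold: float, n_individuals: int) -> int:
    """Minimum number of carriers for a region to pass the frequency cutoff."""
    return max(1, math.ceil(threshold * n_individuals - _CEIL_GUARD))


def compute_shared_intervals(records: IntervalTable, threshold: float) -> list:
    """Detect maximal regions covered by >= ceil(threshold * N) individuals.

    N counts distinct individuals in the whole table.  Per chromosome (first
    appearance order) a sweep line adds +1 at each merged-interval start and
    -1 at end+1; maximal runs whose coverage stays at or above the required
    count are emitted sorted by start.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if not records.records:
        raise ValueError("empty interval table")
    n = len(records.individuals())
    need = required_count(threshold, n)
    merged = merge_individual_intervals(records)

    by_chrom: dict = {}
    chrom_order: list = []
    for r in merged.records:
        if r.chrom not in by_chrom:
            by_chrom[r.chrom] = []
            chrom_order.append(r.chrom)
        by_chrom[r.chrom].append((r.start, r.end))

    out = []
    for chrom in chrom_order:
        events: dict = {}
        for s, e in by_chrom[chrom]:
            events[s] = events.get(s, 0) + 1
            events[e + 1] = events.get(e + 1, 0) - 1
        positions = sorted(events)
        coverage = 0
        run_start = None
        run_min = None
        for idx, pos in enumerate(positions):
            coverage += events[pos]
            nxt = positions[idx + 1] if idx + 1 < len(positions) else None
            if coverage >= need:
                if run_start is None:
                    run_start = pos
                    run_min = coverage
                else:
                    run_min = min(run_min, coverage)
            elif run_start is not None:
                out.append(SharedInterval(chrom, run_start, pos - 1, run_min, run_min / n))
                run_start = None
        # coverage returns to 0 after the last event, so any run has closed
        assert run_start is None
    return out


def write_shared_intervals(intervals: Iterable[SharedInterval], path) -> Path:
    """Write detected regions as a tab-delimited table with header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcount\tfrequency\n")
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.count}\t{iv.frequency!r}\n")
    return path


def read_shared_intervals(path) -> list:
    out = []
    first = True
    for row, fields in _iter_rows(path):
        if len(fields) != 5:
            raise FormatError("shared-interval rows need 5 columns", row=row)
        if first:
            first = False
            if fields[0] == "chrom":
                continue
        out.append(SharedInterval(fields[0], int(fields[1]), int(fields[2]),
                                  int(fields[3]), float(fields[4])))
    return out


def render_roh_plot(
    records: IntervalTable,
    index: GenomeIndex,
    out_path,
    shared: Optional[list] = None,
    chrom: Optional[str] = None,
    show_labels: bool = True,
    threshold_line_width: float = 1.0,
    threshold_line_color: str = "black",
    segment_color: str = "#3b6ea5",
    fmt: Optional[str] = None,
    dpi: int = 300,
    font_size: float = 8.0,
) -> RenderResult:
    """Render per-individual horizontal segment lanes for one chromosome.

    Individuals are grouped by population (first-appearance order) and the
    x-axis spans the full indexed chromosome length.  Shared regions, when
    given, are marked by vertical boundary lines in the requested width and
    color.  Multi-chromosome tables must be filtered with ``chrom``.
    """
    import matplotlib.pyplot as plt

    chroms = records.chroms()
    for c in chroms:
        if c not in index:
            raise ValueError(f"chromosome {c!r} absent from genome index")
    if chrom is None:
        if len(chroms) > 1:
            raise ValueError(
                f"input spans {len(chroms)} chromosomes ({chroms}); render one "
                "chromosome at a time by passing a chromosome selector"
            )
        chrom = chroms[0]
    elif chrom not in index:
        raise ValueError(f"chromosome {chrom!r} absent from genome index")

    recs = [r for r in records.records if r.chrom == chrom]
    if not recs:
        raise ValueError(f"no intervals on chromosome {chrom!r}")

    # lane per individual, grouped by population in first-appearance order
    lanes: list = []
    lane_of: dict = {}
    pop_of: dict = {}
    for r in recs:
        if r.individual not in lane_of:
            lane_of[r.individual] = None
            pop_of[r.individual] = r.population
    pops_order: list = []
    for ind in lane_of:
        if pop_of[ind] not in pops_order:
            pops_order.append(pop_of[ind])
    for pop in pops_order:
        for ind in lane_of:
            if pop_of[ind] == pop:
                lane_of[ind] = len(lanes)
                lanes.append(ind)

    length = index.length_of(chrom)
    n_lanes = len(lanes)
    fig, ax = plt.subplots(figsize=(10, max(2.0, 0.18 * n_lanes + 1.0)))
    for r in recs:
        y = n_lanes - 1 - lane_of[r.individual]
        ax.broken_barh([(r.start, r.end - r.start + 1)], (y + 0.1, 0.8),
                       facecolors=segment_color)

    shared_markers = []
    for iv in shared or []:
        if iv.chrom != chrom:
            continue
        for x in (iv.start, iv.end):
            ax.axvline(x, color=threshold_line_color,
                       linewidth=threshold_line_width, zorder=3)
        shared_markers.append({"start": iv.start, "end": iv.end, "count": iv.count})

    # population group separators and labels on the right margin
    group_bounds = []
    cursor = 0
    for pop in pops_order:
        size = sum(1 for ind in lanes if pop_of[ind] == pop)
        group_bounds.append({"population": pop, "first_lane": cursor,
                             "last_lane": cursor + size - 1})
        ymid = n_lanes - (cursor + size / 2.0)
        ax.text(1.01, ymid / n_lanes, pop, transform=ax.transAxes,
                va="center", fontsize=font_size)
        if cursor:
            ax.axhline(n_lanes - cursor, color="grey", linewidth=0.5, linestyle=":")
        cursor += size

    ax.set_xlim(1, length)
    ax.set_ylim(0, n_lanes)
    if show_labels:
        ax.set_yticks([n_lanes - 1 - i + 0.5 for i in range(n_lanes)])
        ax.set_yticklabels(lanes, fontsize=font_size)
    else:
        ax.set_yticks([])
    ax.set_xlabel(f"Chromosome {chrom} position (bp)", fontsize=font_size)
    fig.tight_layout()

    layout = {
        "kind": "roh-tracks",
        "chrom": chrom,
        "xlim": (1, length),
        "n_lanes": n_lanes,
        "lanes": lanes,
        "groups": group_bounds,
        "tick_labels": lanes if show_labels else [],
        "shared_markers": shared_markers,
        "threshold_line_width": threshold_line_width,
        "threshold_line_color": threshold_line_color,
    }
    path = save_figure(fig, out_path, fmt=fmt, dpi=dpi)
    return RenderResult(path, layout)
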