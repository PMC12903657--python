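"""Ancestry-proportion stacked barplots with dominant-ancestry sorting.

Individuals are grouped by population (first-appearance order).  Within each
group, the dominant ancestry component is the one with the largest mean
proportion over the group (ties break to the lowest component index), and
individuals are sorted ascending by their own value of that component — a
group-level choice, so one component orders the whole block monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._render import RenderResult, save_figure
from .formats_io import AncestryTable

__all__ = ["AdmixLayout", "sort_individuals", "render_admix_barplot"]


@dataclass
class AdmixLayout:
    """Plot-ready ordering of a Q table.

    ``individuals`` holds (population, individual, proportions) in bar order;
    ``groups`` holds (population, first_index, last_index) spans; dominant
    component indices are 1-based.
    """

    individuals: list
    groups: list  # list[(population, first_index, last_index)]
    dominant_component: dict  # population -> 1-based component index

    @property
    def k(self) -> int:
        return len(self.individuals[0][2]) if self.individuals else 0


def sort_individuals(table: AncestryTable) -> AdmixLayout:
    """Group by population and sort each group ascending in its dominant component."""
    if not table.records:
        raise ValueError("empty ancestry table")
    pops: list = []
    for r in table.records:
        if r.population not in pops:
            pops.append(r.population)

    individuals = []
    groups = []
    dominant = {}
    for pop in pops:
        recs = [r for r in table.records if r.population == pop]
        means = np.mean([r.proportions for r in recs], axis=0)
        comp = int(np.argmax(means))  # argmax takes the lowest index on ties
        dominant[pop] = comp + 1
        ordered = sorted(recs, key=lambda r: r.proportions[comp])  # stable
        first = len(individuals)
        individuals.extend((r.population, r.individual, tuple(r.proportions)) for r in ordered)
        groups.append((pop, first, len(individuals) - 1))
    return AdmixLayout(individuals, groups, dominant)


def render_admix_barplot(
    layout: AdmixLayout,
    out_path,
    show_labels: bool = False,
    palette: str = "tab20",
    fmt: Optional[str] = None,
    dpi: int = 300,
    font_size: float = 8.0,
) -> RenderResult:
    """One stacked bar per individual, K segments each, grouped by population."""
    import matplotlib.pyplot as plt
    from matplotlib import colormaps

    if not layout.individuals:
        raise ValueError("empty layout")
    k = layout.k
    n = len(layout.individuals)
    Q = np.array([props for _, _, props in layout.individuals])
    cmap = colormaps[palette]
    ncol = getattr(cmap, "N", 20)
    comp_colors = [cmap(i % ncol) for i in range(k)]

    fig, ax = plt.subplots(figsize=(max(6.0, min(0.08 * n + 2, 18)), 3.5))
    x = np.arange(n)
    bottom = np.zeros(n)
    for c in range(k):
        ax.bar(x, Q[:, c], bottom=bottom, width=1.0, color=comp_colors[c],
               linewidth=0, label=f"K{c + 1}")
        bottom += Q[:, c]

    for pop, first, last in layout.groups:
        if first > 0:
            ax.axvline(first - 0.5, color="black", linewidth=0.8)
        ax.text((first + last) / 2.0, -0.06, pop, ha="center", va="top",
                fontsize=font_size, transform=ax.get_xaxis_transform())

    if show_labels:
        ax.set_xticks(x)
        ax.set_xticklabels([ind for _, ind, _ in layout.individuals],
                           rotation=90, fontsize=max(font_size - 2, 4))
        ax.tick_params(axis="x", pad=14)
    else:
        ax.set_xticks([])
    ax.set_xlim(-0.5, n - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("Ancestry proportion", fontsize=font_size)
    fig.tight_layout()

    render_layout = {
        "kind": "admixture-barplot",
        "n_individuals": n,
        "k": k,
        "n_segments": n * k,
        "bar_totals": [float(t) for t in Q.sum(axis=1)],
        "groups": list(layout.groups),
        "tick_labels": [ind for _, ind, _ in layout.individuals] if show_labels else [],
        "palette": palette,
    }
    path = save_figure(fig, out_path, fmt=fmt, dpi=dpi)
    return RenderResult(path, render_layout)
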