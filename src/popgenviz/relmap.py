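"""Relationship-matrix heatmaps and population-level averaging.

Within-population averages are taken over unordered distinct pairs inside a
group, excluding self-relationships: diagonal entries of a GRM carry the 1+F
inbreeding scale and would inflate group relatedness.  A singleton population
falls back to its sample's diagonal entry (with a warning).  Between-population
cells average every cross pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from ._render import RenderResult, save_figure
from .formats_io import RelationshipMatrix

__all__ = ["PopAverageMatrix", "population_average", "render_relationship_heatmap",
           "grouped_order"]


@dataclass
class PopAverageMatrix:
    """P x P symmetric matrix of average pairwise relationships."""

    pop_ids: list
    values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.pop_ids)


def grouped_order(matrix: RelationshipMatrix) -> list:
    """Sample indices ordered by (population first appearance, input order)."""
    pops: list = []
    for p in matrix.pop_labels:
        if p not in pops:
            pops.append(p)
    order = []
    for p in pops:
        order.extend(i for i, q in enumerate(matrix.pop_labels) if q == p)
    return order


def population_average(matrix: RelationshipMatrix) -> PopAverageMatrix:
    """Average pairwise relationships between and within populations.

    Cell (a, b), a != b: mean over all cross pairs.  Cell (a, a): mean over
    the a-group's unordered distinct pairs, diagonal excluded; a singleton
    group falls back to that sample's diagonal entry and a warning is issued.
    """
    if matrix.n == 0:
        raise ValueError("empty relationship matrix")
    pops: list = []
    for p in matrix.pop_labels:
        if p not in pops:
            pops.append(p)
    members = {p: [i for i, q in enumerate(matrix.pop_labels) if q == p] for p in pops}
    P = len(pops)
    out = np.zeros((P, P))
    V = matrix.values
    for a in range(P):
        ia = members[pops[a]]
        if len(ia) == 1:
            out[a, a] = V[ia[0], ia[0]]
            warnings.warn(
                f"population {pops[a]!r} has a single sample; within-population "
                "average falls back to its diagonal (self) relationship",
                stacklevel=2,
            )
        else:
            sub = V[np.ix_(ia, ia)]
            iu = np.triu_indices(len(ia), k=1)
            out[a, a] = sub[iu].mean()
        for b in range(a + 1, P):
            ib = members[pops[b]]
            cross = V[np.ix_(ia, ib)]
            out[a, b] = out[b, a] = cross.mean()
    return PopAverageMatrix(pops, out)


def render_relationship_heatmap(
    matrix: Union[RelationshipMatrix, PopAverageMatrix],
    out_path,
    show_labels: bool = True,
    axis_font_size: float = 8.0,
    colormap: str = "viridis",
    mask_diagonal: bool = False,
    annotate: bool = False,
    fmt: Optional[str] = None,
    dpi: int = 300,
) -> RenderResult:
    """Heatmap of a sample-level or population-level relationship matrix.

    Sample-level matrices are reordered so population blocks are contiguous.
    ``mask_diagonal`` blanks self-relationship cells; ``annotate`` prints each
    value (2 decimals) inside its cell.
    """
    import matplotlib.pyplot as plt
    import seaborn as sns

    if isinstance(matrix, PopAverageMatrix):
        labels = list(matrix.pop_ids)
        values = matrix.values
        order = list(range(matrix.n))
    else:
        order = grouped_order(matrix)
        labels = [matrix.sample_ids[i] for i in order]
        values = matrix.values[np.ix_(order, order)]
    n = len(labels)
    if values.shape != (n, n):
        raise ValueError(f"matrix shape {values.shape} is not square of size {n}")

    mask = np.zeros((n, n), dtype=bool)
    if mask_diagonal:
        np.fill_diagonal(mask, True)

    fig, ax = plt.subplots(figsize=(max(4.0, 0.12 * n + 3), max(3.5, 0.12 * n + 2.5)))
    sns.heatmap(
        values,
        mask=mask,
        cmap=colormap,
        annot=annotate,
        fmt=".2f",
        square=True,
        xticklabels=labels if show_labels else False,
        yticklabels=labels if show_labels else False,
        annot_kws={"fontsize": max(axis_font_size - 2, 4)},
        cbar_kws={"shrink": 0.8},
        ax=ax,
    )
    ax.tick_params(labelsize=axis_font_size)
    fig.tight_layout()

    n_annotations = (n * n - n) if (annotate and mask_diagonal) else (n * n if annotate else 0)
    layout = {
        "kind": "relationship-heatmap",
        "n": n,
        "labels": labels,
        "order": order,
        "labels_shown": bool(show_labels),
        "masked_cells": [(i, i) for i in range(n)] if mask_diagonal else [],
        "n_annotations": n_annotations,
        "colormap": colormap,
    }
    path = save_figure(fig, out_path, fmt=fmt, dpi=dpi)
    return RenderResult(path, layout)
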