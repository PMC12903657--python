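"""Seeded generators for every input dialect, with programmatic ground truth.

Each generator writes plain-text files in the exact dialects of
:mod:`popgenviz.formats_io` and returns the planted ground truth alongside the
paths, so tests assert against values that never round-trip through a file.
All randomness flows from ``SynthConfig.seed``; a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import formats_io as fio

__all__ = [
    "SynthConfig",
    "gen_map_and_index",
    "gen_intervals",
    "gen_relationship",
    "gen_eigen",
    "gen_ancestry",
    "gen_assoc",
]


@dataclass
class SynthConfig:
    """Scales and seed for the synthetic fixtures.

    Defaults describe a small SNP-array-like study: a few chromosomes in the
    0.5-2 Mb range, a couple dozen individuals in two populations, a handful
    of ancestry components, and a GWAS-sized association table with a few
    planted signal loci.
    """

    seed: int = 0
    n_chroms: int = 3
    chrom_length_range: tuple = (500_000, 2_000_000)
    n_markers: int = 5_000
    n_individuals: int = 20
    n_populations: int = 2
    k_components: int = 3
    n_assoc_records: int = 10_000
    n_signal: int = 5
    pop_sizes: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        for name in ("n_chroms", "n_markers", "n_individuals", "n_populations",
                     "k_components", "n_assoc_records"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_signal < 0:
            raise ValueError("n_signal must be >= 0")
        if self.pop_sizes is not None:
            if len(self.pop_sizes) != self.n_populations:
                raise ValueError("pop_sizes length must equal n_populations")
            if sum(self.pop_sizes) != self.n_individuals:
                raise ValueError("pop_sizes must sum to n_individuals")

    def resolved_pop_sizes(self) -> list:
        if self.pop_sizes is not None:
            return list(self.pop_sizes)
        base, extra = divmod(self.n_individuals, self.n_populations)
        return [base + (1 if i < extra else 0) for i in range(self.n_populations)]


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    # independent stream per generator so adding one does not shift the others
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def _pop_names(cfg: SynthConfig) -> list:
    return [f"POP{i + 1}" for i in range(cfg.n_populations)]


def _individual_names(cfg: SynthConfig) -> tuple:
    pops = _pop_names(cfg)
    sizes = cfg.resolved_pop_sizes()
    ids, labels = [], []
    for pop, size in zip(pops, sizes):
        for j in range(size):
            ids.append(f"{pop}_ind{j + 1}")
            labels.append(pop)
    return ids, labels


# ---------------------------------------------------------------------------


@dataclass
class MapIndexResult:
    map_path: Path
    index_path: Path
    index: fio.GenomeIndex
    markers_per_chrom: dict


def gen_map_and_index(cfg: SynthConfig, out_dir) -> MapIndexResult:
    """Write a PLINK .map plus genome index; markers uniform per chromosome.

    Markers are allocated to chromosomes in proportion to physical length
    (multinomial) and placed uniformly on [1, length], sorted within each
    chromosome.
    """
    rng = _rng(cfg, 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lo, hi = cfg.chrom_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_chroms)
    chroms = [str(i + 1) for i in range(cfg.n_chroms)]
    index = fio.GenomeIndex(list(zip(chroms, (int(n) for n in lengths))))

    alloc = rng.multinomial(cfg.n_markers, lengths / lengths.sum())
    records = []
    snp_counter = 1
    per_chrom = {}
    for chrom, length, k in zip(chroms, lengths, alloc):
        pos = np.sort(rng.integers(1, int(length) + 1, size=int(k)))
        per_chrom[chrom] = int(k)
        for p in pos:
            records.append(fio.MapRecord(chrom, f"rs{snp_counter}", 0.0, int(p)))
            snp_counter += 1
    markers = fio.MarkerMap(records)

    map_path = fio.write_plink_map(markers, out_dir / "markers.map")
    index_path = fio.write_genome_index(index, out_dir / "genome.idx")
    return MapIndexResult(map_path, index_path, index, per_chrom)


# ---------------------------------------------------------------------------


@dataclass
class IntervalsResult:
    path: Path
    index_path: Path
    index: fio.GenomeIndex
    planted_region: Optional[tuple]  # (chrom, start, end)
    n_carriers: int
    n_individuals: int


def gen_intervals(
    cfg: SynthConfig,
    out_dir,
    planted_fraction: float = 0.8,
    planted_length: int = 20_000,
    n_background: int = 4,
) -> IntervalsResult:
    """Write a ROH-style interval table with one planted shared region.

    A region of ``planted_length`` bp on chromosome 1 is carried by
    round(planted_fraction * N) individuals; background segments are drawn
    away from it, so coverage over the planted span equals the carrier count
    exactly.  ``planted_fraction = 0`` plants nothing.
    """
    if not (0.0 <= planted_fraction <= 1.0):
        raise ValueError(f"planted_fraction must be in [0, 1], got {planted_fraction}")
    rng = _rng(cfg, 2)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids, labels = _individual_names(cfg)
    n = len(ids)
    length = int(max(cfg.chrom_length_range[0], 10 * planted_length))
    chrom = "1"
    index = fio.GenomeIndex([(chrom, length)])

    # plant the shared region in the middle third of the chromosome
    mid = length // 2
    p_start = mid - planted_length // 2
    p_end = p_start + planted_length - 1
    n_carriers = int(round(planted_fraction * n))
    carriers = set(rng.choice(n, size=n_carriers, replace=False)) if n_carriers else set()

    gap = max(planted_length // 4, 1_000)
    left_hi = p_start - gap
    right_lo = p_end + gap
    records = []
    for i, (ind, pop) in enumerate(zip(ids, labels)):
        if i in carriers:
            records.append(fio.IntervalRecord(pop, ind, chrom, p_start, p_end))
        for _ in range(n_background):
            seg_len = int(rng.integers(2_000, 15_000))
            if rng.random() < 0.5 and left_hi - seg_len > 1:
                s = int(rng.integers(1, left_hi - seg_len))
            else:
                s = int(rng.integers(right_lo, length - seg_len))
            records.append(fio.IntervalRecord(pop, ind, chrom, s, s + seg_len - 1))
    table = fio.IntervalTable(records)

    path = fio.write_interval_table(table, out_dir / "intervals.txt")
    index_path = fio.write_genome_index(index, out_dir / "intervals.idx")
    planted = (chrom, p_start, p_end) if n_carriers else None
    return IntervalsResult(path, index_path, index, planted, n_carriers, n)


# ---------------------------------------------------------------------------


@dataclass
class RelationshipResult:
    matrix_path: Path
    ids_path: Path
    within: float
    between: float
    diagonal: float
    pop_sizes: list
    matrix: fio.RelationshipMatrix


def gen_relationship(
    cfg: SynthConfig,
    out_dir,
    within: float = 0.5,
    between: float = 0.1,
    diagonal: float = 1.0,
    noise_sd: float = 0.0,
    dialect: str = "mat",
) -> RelationshipResult:
    """Write a block-structured relationship matrix plus ids companion file.

    Off-diagonals are ``within`` inside a population block and ``between``
    across blocks, plus symmetric N(0, noise_sd) noise; diagonals are fixed at
    ``diagonal``.  Population averaging should recover (within, between) up to
    the noise.
    """
    if within <= between:
        raise ValueError("within-block value must exceed between-block value")
    rng = _rng(cfg, 3)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids, labels = _individual_names(cfg)
    n = len(ids)
    values = np.full((n, n), between, dtype=float)
    start = 0
    for size in cfg.resolved_pop_sizes():
        values[start:start + size, start:start + size] = within
        start += size
    if noise_sd > 0:
        # draw the upper triangle and mirror so each off-diagonal entry is
        # exactly N(0, noise_sd), not the halved variance of an averaged pair
        noise = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        noise[iu] = rng.normal(0.0, noise_sd, size=len(iu[0]))
        values += noise + noise.T
    np.fill_diagonal(values, diagonal)
    matrix = fio.RelationshipMatrix(ids, labels, values)

    mat_path, ids_path = fio.write_relationship(
        matrix, Path(out_dir) / f"relationship.{dialect}", dialect, Path(out_dir) / "samples.ids"
    )
    return RelationshipResult(mat_path, ids_path, within, between, diagonal,
                              cfg.resolved_pop_sizes(), matrix)


# ---------------------------------------------------------------------------


@dataclass
class EigenResult:
    evec_path: Path
    eval_path: Path
    cluster_means: np.ndarray
    cluster_sd: float
    data: fio.EigenData


def gen_eigen(
    cfg: SynthConfig,
    out_dir,
    n_pcs: int = 10,
    cluster_sd: float = 1.0,
    separation: float = 5.0,
) -> EigenResult:
    """Write .evec/.eval files with Gaussian population clusters in PC space.

    Cluster centres sit on distinct corners scaled so neighbouring means are
    ``separation`` standard deviations apart on the leading PCs; eigenvalues
    decay geometrically.
    """
    rng = _rng(cfg, 4)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids, labels = _individual_names(cfg)
    pops = _pop_names(cfg)
    means = np.zeros((cfg.n_populations, n_pcs))
    for i in range(cfg.n_populations):
        # spread centres along the first min(3, n_pcs) axes
        for d in range(min(3, n_pcs)):
            means[i, d] = separation * cluster_sd * (1.0 if (i >> d) & 1 else -1.0)
        means[i, 0] += separation * cluster_sd * i  # guarantee pairwise spacing
    rows = []
    for ind, pop in zip(ids, labels):
        mu = means[pops.index(pop)]
        rows.append(mu + rng.normal(0.0, cluster_sd, size=n_pcs))
    components = np.asarray(rows)
    eigenvalues = 10.0 * 0.7 ** np.arange(n_pcs)
    data = fio.EigenData(ids, labels, components, eigenvalues)

    evec_path, eval_path = fio.write_eigen(
        data, out_dir / "pca.evec", out_dir / "pca.eval"
    )
    return EigenResult(evec_path, eval_path, means, cluster_sd, data)


# ---------------------------------------------------------------------------


@dataclass
class AncestryResult:
    path: Path
    dominant_component: dict  # population -> 1-based component with highest alpha
    table: fio.AncestryTable


def gen_ancestry(
    cfg: SynthConfig,
    out_dir,
    alpha_dominant: float = 8.0,
    alpha_other: float = 0.5,
) -> AncestryResult:
    """Write a Q table of per-population Dirichlet draws, one dominant component.

    Population i's dominant component is (i mod K); rows are exact simplex
    points by construction.
    """
    rng = _rng(cfg, 5)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids, labels = _individual_names(cfg)
    pops = _pop_names(cfg)
    k = cfg.k_components
    dominant = {pop: (i % k) + 1 for i, pop in enumerate(pops)}
    records = []
    for ind, pop in zip(ids, labels):
        alpha = np.full(k, alpha_other)
        alpha[dominant[pop] - 1] = alpha_dominant
        props = rng.dirichlet(alpha)
        records.append(fio.AncestryRecord(pop, ind, tuple(float(p) for p in props)))
    table = fio.AncestryTable(records)
    path = fio.write_ancestry(table, out_dir / "ancestry.q")
    return AncestryResult(path, dominant, table)


# ---------------------------------------------------------------------------


@dataclass
class AssocResult:
    path: Path
    signal_loci: list  # list[(chrom, bp)] with p < 1e-7
    table: fio.AssocTable


def gen_assoc(cfg: SynthConfig, out_dir) -> AssocResult:
    """Write a GWAS-style table of uniform p-values with planted signal loci.

    ``cfg.n_signal`` records are forced below 1e-7 (uniform on [1e-9, 1e-8])
    so they exceed the conventional -log10 p > 6 suggestive line.
    """
    rng = _rng(cfg, 6)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lo, hi = cfg.chrom_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_chroms)
    chroms = [str(i + 1) for i in range(cfg.n_chroms)]
    alloc = rng.multinomial(cfg.n_assoc_records, lengths / lengths.sum())
    records = []
    for chrom, length, k in zip(chroms, lengths, alloc):
        pos = np.sort(rng.integers(1, int(length) + 1, size=int(k)))
        pvals = rng.uniform(0.0, 1.0, size=int(k))
        pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
        for p, v in zip(pos, pvals):
            records.append(fio.AssocRecord(chrom, int(p), float(v)))
    n_signal = min(cfg.n_signal, len(records))
    signal_idx = rng.choice(len(records), size=n_signal, replace=False)
    signal_loci = []
    for i in signal_idx:
        r = records[i]
        records[i] = fio.AssocRecord(r.chrom, r.bp, float(rng.uniform(1e-9, 1e-8)))
        signal_loci.append((r.chrom, r.bp))
    table = fio.AssocTable(records)
    path = fio.write_assoc_table(table, out_dir / "assoc.txt")
    return AssocResult(path, signal_loci, table)
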