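"""Readers, writers and validation for the plain-text dialects the toolkit consumes.

Every input is whitespace-delimited plain text; lines starting with ``#`` are
comments and blank lines are skipped.  All genomic coordinates are 1-based and
intervals are inclusive on both ends (the PLINK ``.hom`` convention).  Parsers
report the offending row number in every diagnostic, and a first line whose
numeric-expected columns fail numeric parsing is treated as a header.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence, Union

import numpy as np

__all__ = [
    "FormatError",
    "GenomeIndex",
    "MarkerMap",
    "MapRecord",
    "IntervalTable",
    "IntervalRecord",
    "RelationshipMatrix",
    "EigenData",
    "AncestryTable",
    "AncestryRecord",
    "AssocTable",
    "AssocRecord",
    "ValidationIssue",
    "ValidationReport",
    "read_genome_index",
    "write_genome_index",
    "read_plink_map",
    "write_plink_map",
    "read_interval_table",
    "write_interval_table",
    "read_relationship",
    "write_relationship",
    "read_eigen",
    "write_eigen",
    "read_ancestry",
    "write_ancestry",
    "read_assoc_table",
    "write_assoc_table",
    "validate",
]

SYMMETRY_TOL = 1e-9
ANCESTRY_SUM_TOL = 0.01


class FormatError(ValueError):
    """Raised when an input file violates its dialect.

    ``row`` is the 1-based line number in the file (comments and blank lines
    included in the count), when a single row is at fault.
    """

    def __init__(self, message: str, row: Optional[int] = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class MapRecord(NamedTuple):
    chrom: str
    snp_id: str
    genetic_pos: float
    bp: int


class IntervalRecord(NamedTuple):
    population: str
    individual: str
    chrom: str
    start: int
    end: int


class AncestryRecord(NamedTuple):
    population: str
    individual: str
    proportions: tuple


class AssocRecord(NamedTuple):
    chrom: str
    bp: int
    value: float


@dataclass
class GenomeIndex:
    """Ordered chromosome identifiers with physical lengths (bp).

    Entry order is the display order for every downstream plot.
    """

    entries: list  # list[(chrom, length)]

    @property
    def chroms(self) -> list:
        return [c for c, _ in self.entries]

    def length_of(self, chrom: str) -> int:
        for c, n in self.entries:
            if c == chrom:
                return n
        raise KeyError(chrom)

    def __contains__(self, chrom: str) -> bool:
        return any(c == chrom for c, _ in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class MarkerMap:
    """PLINK ``.map`` marker records, in file order."""

    records: list  # list[MapRecord]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class IntervalTable:
    """Per-individual genomic segments (ROH or CNV) with population labels."""

    records: list  # list[IntervalRecord]

    def __len__(self) -> int:
        return len(self.records)

    def individuals(self) -> list:
        seen: dict = {}
        for r in self.records:
            seen.setdefault(r.individual, None)
        return list(seen)

    def chroms(self) -> list:
        seen: dict = {}
        for r in self.records:
            seen.setdefault(r.chrom, None)
        return list(seen)


@dataclass
class RelationshipMatrix:
    """Square symmetric sample-by-sample relatedness with population labels."""

    sample_ids: list
    pop_labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class EigenData:
    """Per-sample principal-component coordinates plus component eigenvalues."""

    sample_ids: list
    pop_labels: list
    components: np.ndarray  # (N, k)
    eigenvalues: np.ndarray  # (k',) with k' >= k

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)

    @property
    def k(self) -> int:
        return self.components.shape[1]


@dataclass
class AncestryTable:
    """Per-individual K-component ancestry proportions (Q matrix rows)."""

    records: list  # list[AncestryRecord]

    @property
    def k(self) -> int:
        return len(self.records[0].proportions) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class AssocTable:
    """Per-marker (chromosome, bp, statistic) records for Manhattan layout."""

    records: list  # list[AssocRecord]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    code: str
    message: str
    row: Optional[int] = None


@dataclass
class ValidationReport:
    issues: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def add(self, severity: str, code: str, message: str, row: Optional[int] = None) -> None:
        self.issues.append(ValidationIssue(severity, code, message, row))

    def errors(self) -> list:
        return [i for i in self.issues if i.severity == "error"]


# ---------------------------------------------------------------------------
# Low-level parsing helpers
# ---------------------------------------------------------------------------


def _iter_rows(path) -> Iterator:
    """Yield (1-based line number, token list) skipping comments and blanks."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            yield lineno, stripped.split()


def _parse_int(token: str, what: str, row: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"non-integer {what}: {token!r}", row=row) from None


def _parse_float(token: str, what: str, row: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"non-numeric {what}: {token!r}", row=row) from None


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _require_columns(fields: Sequence[str], n: int, row: int) -> None:
    if len(fields) != n:
        raise FormatError(
            f"expected {n} columns, found {len(fields)}", row=row
        )


# ---------------------------------------------------------------------------
# Genome index
# ---------------------------------------------------------------------------


def read_genome_index(path) -> GenomeIndex:
    """Read a two-column (chromosome, physical length) genome index file."""
    entries = []
    seen = set()
    for row, fields in _iter_rows(path):
        _require_columns(fields, 2, row)
        chrom = fields[0]
        length = _parse_int(fields[1], "chromosome length", row)
        if length <= 0:
            raise FormatError(f"non-positive length for chromosome {chrom!r}", row=row)
        if chrom in seen:
            raise FormatError(f"duplicate chromosome {chrom!r}", row=row)
        seen.add(chrom)
        entries.append((chrom, length))
    if not entries:
        raise FormatError("no genome index entries")
    return GenomeIndex(entries)


def write_genome_index(index: GenomeIndex, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, length in index.entries:
            fh.write(f"{chrom}\t{length}\n")
    return path


# ---------------------------------------------------------------------------
# PLINK .map
# ---------------------------------------------------------------------------


def read_plink_map(path) -> MarkerMap:
    """Read a 4-column PLINK ``.map`` file (chrom, snp_id, cM, bp)."""
    records = []
    for row, fields in _iter_rows(path):
        _require_columns(fields, 4, row)
        chrom, snp_id = fields[0], fields[1]
        if not snp_id:
            raise FormatError("empty SNP identifier", row=row)
        gpos = _parse_float(fields[2], "genetic position", row)
        bp = _parse_int(fields[3], "bp position", row)
        if bp < 1:
            raise FormatError(f"bp position must be >= 1, got {bp}", row=row)
        records.append(MapRecord(chrom, snp_id, gpos, bp))
    if not records:
        raise FormatError("no marker records")
    return MarkerMap(records)


def write_plink_map(markers: MarkerMap, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in markers.records:
            gpos = repr(r.genetic_pos) if r.genetic_pos != int(r.genetic_pos) else str(int(r.genetic_pos))
            fh.write(f"{r.chrom}\t{r.snp_id}\t{gpos}\t{r.bp}\n")
    return path


# ---------------------------------------------------------------------------
# Interval table (ROH / CNV)
# ---------------------------------------------------------------------------


def read_interval_table(path) -> IntervalTable:
    """Read a 5-column (population, individual, chrom, start, end) table.

    A header row is auto-detected: when columns 4-5 of the first line do not
    parse as numbers, the line is treated as a header and skipped.
    """
    records = []
    first = True
    for row, fields in _iter_rows(path):
        _require_columns(fields, 5, row)
        if first:
            first = False
            if not (_is_number(fields[3]) and _is_number(fields[4])):
                continue  # header
        pop, ind, chrom = fields[0], fields[1], fields[2]
        start = _parse_int(fields[3], "start position", row)
        end = _parse_int(fields[4], "end position", row)
        if start < 1:
            raise FormatError(f"start must be >= 1, got {start}", row=row)
        if start > end:
            raise FormatError(f"start {start} > end {end}", row=row)
        records.append(IntervalRecord(pop, ind, chrom, start, end))
    if not records:
        raise FormatError("no interval records")
    return IntervalTable(records)


def write_interval_table(table: IntervalTable, path, header: bool = True) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write("population\tindividual\tchrom\tstart\tend\n")
        for r in table.records:
            fh.write(f"{r.population}\t{r.individual}\t{r.chrom}\t{r.start}\t{r.end}\n")
    return path


# ---------------------------------------------------------------------------
# Relationship matrix ("mat" grid and "col" long dialects)
# ---------------------------------------------------------------------------


def _read_ids_file(ids_path) -> tuple:
    """Read the 2-column ids companion file: (group/family label, individual)."""
    sample_ids = []
    groups = []
    seen = set()
    for row, fields in _iter_rows(ids_path):
        if len(fields) < 2:
            raise FormatError("ids file needs 2 columns (group, individual)", row=row)
        group, ind = fields[0], fields[1]
        if ind in seen:
            raise FormatError(f"duplicate sample id {ind!r} in ids file", row=row)
        seen.add(ind)
        groups.append(group)
        sample_ids.append(ind)
    if not sample_ids:
        raise FormatError("empty ids file")
    return sample_ids, groups


def _read_pop_file(pop_path) -> dict:
    """Read an optional 2-column (individual, population) override file."""
    mapping = {}
    for row, fields in _iter_rows(pop_path):
        if len(fields) < 2:
            raise FormatError("pop file needs 2 columns (individual, population)", row=row)
        mapping[fields[0]] = fields[1]
    return mapping


def read_relationship(path, dialect: str, ids_path, pop_path=None) -> RelationshipMatrix:
    """Read a relationship matrix in ``mat`` (N x N grid) or ``col`` (long) form.

    Population labels come from the first column of the ids file, optionally
    overridden per individual by a 2-column (individual, population) pop file.
    In the ``col`` dialect a (i, j) row is mirrored to (j, i); when both
    orientations are present they must agree within 1e-9.
    """
    if dialect not in ("mat", "col"):
        raise FormatError(f"unknown relationship dialect {dialect!r} (use 'mat' or 'col')")
    sample_ids, groups = _read_ids_file(ids_path)
    n = len(sample_ids)
    pops = list(groups)
    if pop_path is not None:
        mapping = _read_pop_file(pop_path)
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise FormatError(
                f"sample-label matching: pop file missing individuals {missing[:5]}"
            )
        pops = [mapping[s] for s in sample_ids]

    if dialect == "mat":
        rows = []
        for row, fields in _iter_rows(path):
            if len(fields) != n:
                raise FormatError(
                    f"dimensional consistency: expected {n} columns, found {len(fields)}",
                    row=row,
                )
            rows.append([_parse_float(t, "relationship value", row) for t in fields])
        if len(rows) != n:
            raise FormatError(
                f"dimensional consistency: ids file lists {n} samples but grid has {len(rows)} rows"
            )
        values = np.asarray(rows, dtype=float)
        asym = np.max(np.abs(values - values.T)) if n else 0.0
        if asym > SYMMETRY_TOL:
            raise FormatError(f"matrix not symmetric (max |A - A^T| = {asym:g})")
        # enforce exact symmetry after the tolerance check
        values = (values + values.T) / 2.0
    else:  # col
        idx = {s: i for i, s in enumerate(sample_ids)}
        values = np.full((n, n), np.nan)
        for row, fields in _iter_rows(path):
            _require_columns(fields, 3, row)
            a, b = fields[0], fields[1]
            if a not in idx:
                raise FormatError(f"sample-label matching: unknown sample {a!r}", row=row)
            if b not in idx:
                raise FormatError(f"sample-label matching: unknown sample {b!r}", row=row)
            v = _parse_float(fields[2], "relationship value", row)
            i, j = idx[a], idx[b]
            for p, q in ((i, j), (j, i)):
                if not math.isnan(values[p, q]) and abs(values[p, q] - v) > SYMMETRY_TOL:
                    raise FormatError(
                        f"conflicting values for pair ({a}, {b}): "
                        f"{values[p, q]!r} vs {v!r}",
                        row=row,
                    )
            values[i, j] = v
            values[j, i] = v
        diag_missing = [sample_ids[i] for i in range(n) if math.isnan(values[i, i])]
        if diag_missing:
            raise FormatError(
                f"missing diagonal entries for samples {diag_missing[:5]}"
            )
        if np.isnan(values).any():
            ii, jj = np.argwhere(np.isnan(values))[0]
            raise FormatError(
                f"missing pair ({sample_ids[ii]}, {sample_ids[jj]}) in col file"
            )
    return RelationshipMatrix(sample_ids, pops, values)


def write_relationship(matrix: RelationshipMatrix, path, dialect: str, ids_path) -> tuple:
    """Write matrix + ids companion file in the requested dialect."""
    path, ids_path = Path(path), Path(ids_path)
    with open(ids_path, "w") as fh:
        for pop, sid in zip(matrix.pop_labels, matrix.sample_ids):
            fh.write(f"{pop}\t{sid}\n")
    with open(path, "w") as fh:
        if dialect == "mat":
            for row in matrix.values:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")
        elif dialect == "col":
            ids = matrix.sample_ids
            for i in range(matrix.n):
                for j in range(i + 1):
                    fh.write(f"{ids[i]}\t{ids[j]}\t{float(matrix.values[i, j])!r}\n")
        else:
            raise FormatError(f"unknown relationship dialect {dialect!r}")
    return path, ids_path


# ---------------------------------------------------------------------------
# Eigenvector / eigenvalue pair
# ---------------------------------------------------------------------------


def read_eigen(evec_path, eval_path) -> EigenData:
    """Read PLINK-style ``.evec``/``.eval`` files.

    evec: group/family label, individual ID, then k numeric PC columns.
    eval: one non-negative eigenvalue per line, k' >= k of them.
    """
    sample_ids = []
    pops = []
    comp_rows = []
    k = None
    for row, fields in _iter_rows(evec_path):
        if len(fields) < 3:
            raise FormatError("evec rows need group, id and at least one PC", row=row)
        if k is None:
            k = len(fields) - 2
        elif len(fields) - 2 != k:
            raise FormatError(
                f"dimensional consistency: ragged evec row ({len(fields) - 2} PCs, expected {k})",
                row=row,
            )
        pops.append(fields[0])
        sample_ids.append(fields[1])
        comp_rows.append([_parse_float(t, "PC coordinate", row) for t in fields[2:]])
    if not sample_ids:
        raise FormatError("no samples in evec file")

    eigenvalues = []
    for row, fields in _iter_rows(eval_path):
        _require_columns(fields, 1, row)
        v = _parse_float(fields[0], "eigenvalue", row)
        if v < 0:
            raise FormatError(f"negative eigenvalue {v}", row=row)
        eigenvalues.append(v)
    if len(eigenvalues) < k:
        raise FormatError(
            f"dimensional consistency: {len(eigenvalues)} eigenvalues for {k} PC columns"
        )
    return EigenData(sample_ids, pops, np.asarray(comp_rows), np.asarray(eigenvalues))


def write_eigen(data: EigenData, evec_path, eval_path) -> tuple:
    evec_path, eval_path = Path(evec_path), Path(eval_path)
    with open(evec_path, "w") as fh:
        for pop, sid, row in zip(data.pop_labels, data.sample_ids, data.components):
            coords = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{pop}\t{sid}\t{coords}\n")
    with open(eval_path, "w") as fh:
        for v in data.eigenvalues:
            fh.write(f"{float(v)!r}\n")
    return evec_path, eval_path


# ---------------------------------------------------------------------------
# Ancestry (Q) table
# ---------------------------------------------------------------------------


def read_ancestry(path) -> AncestryTable:
    """Read a (population, individual, K proportions) table, K >= 2.

    A header is auto-detected when the proportion columns of the first line
    are non-numeric.  Each row must sum to 1 within 0.01.
    """
    records = []
    k = None
    first = True
    for row, fields in _iter_rows(path):
        if len(fields) < 4:
            raise FormatError(
                "ancestry rows need population, individual and >= 2 proportions", row=row
            )
        if first:
            first = False
            if not all(_is_number(t) for t in fields[2:]):
                continue  # header
        if k is None:
            k = len(fields) - 2
        elif len(fields) - 2 != k:
            raise FormatError(
                f"dimensional consistency: row has {len(fields) - 2} proportions, expected {k}",
                row=row,
            )
        props = tuple(_parse_float(t, "ancestry proportion", row) for t in fields[2:])
        for p in props:
            if not (0.0 <= p <= 1.0):
                raise FormatError(f"proportion {p} outside [0, 1]", row=row)
        total = sum(props)
        if not (1.0 - ANCESTRY_SUM_TOL <= total <= 1.0 + ANCESTRY_SUM_TOL):
            raise FormatError(
                f"proportions do not sum to 1 (sum = {total:g})", row=row
            )
        records.append(AncestryRecord(fields[0], fields[1], props))
    if not records:
        raise FormatError("no ancestry records")
    return AncestryTable(records)


def write_ancestry(table: AncestryTable, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in table.records:
            props = "\t".join(repr(float(p)) for p in r.proportions)
            fh.write(f"{r.population}\t{r.individual}\t{props}\n")
    return path


# ---------------------------------------------------------------------------
# Association table
# ---------------------------------------------------------------------------


def read_assoc_table(path) -> AssocTable:
    """Read a 3-column (chrom, bp, statistic) table; header auto-detected."""
    records = []
    first = True
    for row, fields in _iter_rows(path):
        _require_columns(fields, 3, row)
        if first:
            first = False
            if not (_is_number(fields[1]) and _is_number(fields[2])):
                continue  # header
        chrom = fields[0]
        bp = _parse_int(fields[1], "bp position", row)
        if bp < 1:
            raise FormatError(f"bp position must be >= 1, got {bp}", row=row)
        value = _parse_float(fields[2], "statistic", row)
        if not math.isfinite(value):
            raise FormatError(f"non-finite statistic {fields[2]!r}", row=row)
        records.append(AssocRecord(chrom, bp, value))
    if not records:
        raise FormatError("no association records")
    return AssocTable(records)


def write_assoc_table(table: AssocTable, path, header: bool = True) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write("chrom\tbp\tvalue\n")
        for r in table.records:
            fh.write(f"{r.chrom}\t{r.bp}\t{float(r.value)!r}\n")
    return path


# ---------------------------------------------------------------------------
# Validation layer
# ---------------------------------------------------------------------------


def validate(dataset, genome_index: Optional[GenomeIndex] = None) -> ValidationReport:
    """Validate a loaded domain object, returning a report rather than raising.

    Checks file-structure invariants (already enforced by the readers but
    re-checked for programmatically constructed objects), dimensional
    consistency, missing values, sample-label / chromosome matching against an
    optional genome index, and matrix symmetry.
    """
    report = ValidationReport()

    if isinstance(dataset, GenomeIndex):
        seen = set()
        for i, (chrom, length) in enumerate(dataset.entries):
            if length <= 0:
                report.add("error", "non-positive-length", f"chromosome {chrom!r} has length {length}", i + 1)
            if chrom in seen:
                report.add("error", "duplicate-chromosome", f"duplicate chromosome {chrom!r}", i + 1)
            seen.add(chrom)

    elif isinstance(dataset, MarkerMap):
        if not dataset.records:
            report.add("error", "empty", "no marker records")
        for i, r in enumerate(dataset.records):
            if r.bp < 1:
                report.add("error", "bad-position", f"marker {r.snp_id!r} bp {r.bp} < 1", i + 1)
            if not r.snp_id:
                report.add("error", "missing-values", "empty SNP identifier", i + 1)
            if genome_index is not None:
                if r.chrom not in genome_index:
                    report.add("error", "unknown-chromosome",
                               f"marker {r.snp_id!r} on chromosome {r.chrom!r} absent from index", i + 1)
                elif r.bp > genome_index.length_of(r.chrom):
                    report.add("error", "position-beyond-length",
                               f"marker {r.snp_id!r} at {r.bp} beyond chromosome {r.chrom!r} "
                               f"length {genome_index.length_of(r.chrom)}", i + 1)

    elif isinstance(dataset, IntervalTable):
        if not dataset.records:
            report.add("error", "empty", "no interval records")
        for i, r in enumerate(dataset.records):
            if r.start < 1:
                report.add("error", "bad-position", f"start {r.start} < 1", i + 1)
            if r.start > r.end:
                report.add("error", "bad-interval", f"start {r.start} > end {r.end}", i + 1)
            if genome_index is not None:
                if r.chrom not in genome_index:
                    report.add("error", "unknown-chromosome",
                               f"interval on chromosome {r.chrom!r} absent from index", i + 1)
                elif r.end > genome_index.length_of(r.chrom):
                    report.add("error", "position-beyond-length",
                               f"interval end {r.end} beyond chromosome {r.chrom!r} length", i + 1)

    elif isinstance(dataset, RelationshipMatrix):
        n = len(dataset.sample_ids)
        if dataset.values.shape != (n, n):
            report.add("error", "dimensional-consistency",
                       f"matrix shape {dataset.values.shape} does not match {n} samples")
        elif n:
            if np.isnan(dataset.values).any():
                report.add("error", "missing-values", "matrix contains missing cells")
            else:
                asym = float(np.max(np.abs(dataset.values - dataset.values.T)))
                if asym > SYMMETRY_TOL:
                    report.add("error", "symmetry", f"matrix asymmetric (max |A - A^T| = {asym:g})")
        if len(dataset.pop_labels) != n:
            report.add("error", "sample-label-matching",
                       f"{len(dataset.pop_labels)} population labels for {n} samples")

    elif isinstance(dataset, EigenData):
        n = len(dataset.sample_ids)
        if dataset.components.ndim != 2 or dataset.components.shape[0] != n:
            report.add("error", "dimensional-consistency",
                       f"component matrix shape {dataset.components.shape} for {n} samples")
        else:
            if dataset.k < 1:
                report.add("error", "dimensional-consistency", "no PC columns")
            if len(dataset.eigenvalues) < dataset.k:
                report.add("error", "dimensional-consistency",
                           f"{len(dataset.eigenvalues)} eigenvalues for {dataset.k} PCs")
        if len(dataset.pop_labels) != n:
            report.add("error", "sample-label-matching",
                       f"{len(dataset.pop_labels)} population labels for {n} samples")
        if np.any(dataset.eigenvalues < 0):
            report.add("error", "negative-eigenvalue", "eigenvalues must be non-negative")
        if np.isnan(dataset.components).any():
            report.add("error", "missing-values", "PC coordinates contain missing values")

    elif isinstance(dataset, AncestryTable):
        if not dataset.records:
            report.add("error", "empty", "no ancestry records")
        else:
            k = dataset.k
            if k < 2:
                report.add("error", "dimensional-consistency", f"K = {k} < 2")
            for i, r in enumerate(dataset.records):
                if len(r.proportions) != k:
                    report.add("error", "dimensional-consistency",
                               f"row has {len(r.proportions)} proportions, expected {k}", i + 1)
                    continue
                total = sum(r.proportions)
                if not (1 - ANCESTRY_SUM_TOL <= total <= 1 + ANCESTRY_SUM_TOL):
                    report.add("error", "row-sum", f"proportions sum to {total:g}", i + 1)
                if any(not (0 <= p <= 1) for p in r.proportions):
                    report.add("error", "range", "proportion outside [0, 1]", i + 1)

    elif isinstance(dataset, AssocTable):
        if not dataset.records:
            report.add("error", "empty", "no association records")
        for i, r in enumerate(dataset.records):
            if r.bp < 1:
                report.add("error", "bad-position", f"bp {r.bp} < 1", i + 1)
            if not math.isfinite(r.value):
                report.add("error", "missing-values", "non-finite statistic", i + 1)
            if genome_index is not None and r.chrom not in genome_index:
                report.add("error", "unknown-chromosome",
                           f"record on chromosome {r.chrom!r} absent from index", i + 1)

    else:
        report.add("error", "unknown-type", f"cannot validate object of type {type(dataset).__name__}")

    return report
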