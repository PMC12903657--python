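# Methods

This note documents the computations behind each plot family, the conventions
adopted where several are defensible, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Coordinates and file dialects

All genomic positions are 1-based and intervals are inclusive on both ends,
the convention of PLINK `.hom`/`.map` output, which these dialects mirror.
Every input is whitespace-delimited plain text; runs of spaces/tabs delimit
fields, `#` lines are comments. Header rows are auto-detected: when the
numeric-expected columns of the first line fail numeric parsing, the line is
treated as a header. Both header styles occur in the wild and no dialect here
mandates one.

The relationship-matrix reader accepts two dialects. `mat` is an N×N numeric
grid paired with a 2-column (group/family, individual) ids file; the group
column doubles as the population label. `col` is a long format of
(ID1, ID2, value) rows covering at least the lower triangle including the
diagonal; a pair given in one orientation is mirrored, and a pair given in
both orientations must agree within 1e-9. Population labels again come from
the ids file, optionally overridden by a 2-column (individual, population)
file — the columnar dialect itself has no conventional slot for them.
Missing or NA cells anywhere are errors, never imputed: silent imputation in
a relatedness matrix would corrupt downstream averages invisibly.

Validation (`formats_io.validate`) re-checks programmatically constructed
objects for the same invariants the readers enforce — symmetry within 1e-9,
dimensional consistency, missing values, label/chromosome matching against a
genome index — and returns a report instead of raising, so a CLI run can show
all problems at once.

## SNP density (mapden)

Each chromosome is cut into non-overlapping bins of `bin_size` bp (default
1 Mb, the conventional resolution for array-scale density maps). A marker at
position p belongs to bin ⌊(p−1)/bin_size⌋, so a marker exactly at
k·bin_size falls in the earlier bin; bin b spans [b·bin_size+1,
min((b+1)·bin_size, L)] and the last bin may be short. The number of bins is
⌈L/bin_size⌉ with L taken from the genome index, never from the last
genotyped marker — a sparsely genotyped chromosome end is drawn at its true
physical scale rather than truncated. A marker beyond the indexed length is
an error, not clamped: it signals a genome-assembly/index mismatch the
validation layer exists to catch. Two conservation properties follow and are
tested: bin totals equal the marker count, and halving the bin size refines
each coarse bin into children that sum back exactly.

## Shared ROH regions (rohpainter)

Per (individual, chromosome), intervals are first merged: overlapping or
book-ended segments (end+1 == next start) coalesce, a gap of one base does
not. This prevents an individual with fragmented calls from being counted
twice at one locus. A sweep line then adds +1 at every merged start and −1 at
every end+1; maximal runs where coverage ≥ ⌈t·N⌉ are emitted per chromosome.

Conventions, all tested against a per-base counting oracle:

- N is the number of distinct individuals in the whole table, populations
  pooled — the same denominator semantics as detectRUNS' `tableRuns`
  threshold. Per-population calling is deliberately out of scope; callers
  wanting it can filter the table first.
- The carrier requirement uses integer arithmetic, count ≥ ⌈t·N⌉, so a region
  at exactly the threshold frequency is included. The product t·N is guarded
  by a 1e-9 subtraction before the ceiling because binary floats can push an
  exact product marginally high (0.1 × 10 → 1.0000000000000002, which must
  require 1 carrier, not 2).
- The reported `count` is the minimum coverage across the region — the most
  conservative single number for a region whose coverage varies — and
  frequency = count/N.

Raising t never enlarges the union of emitted regions, and t = 1/N returns
exactly the merged union of all individuals' intervals; both are tested on
random instances.

## Population averaging (relmap)

The between-population cell (a, b) is the mean relationship over all |a|·|b|
cross pairs. The within-population cell averages the group's unordered
distinct pairs and excludes the diagonal: self-relationships in a GRM sit on
the 1+F inbreeding scale and would systematically inflate within-group
relatedness if mixed in. A singleton population has no distinct pairs; its
within value falls back to the sample's diagonal entry and a warning is
issued, since that number is on a different scale than the other cells. The
average is invariant under sample permutation (tested), and heatmaps order
samples by (population first-appearance, input order) so blocks render
contiguously. Annotations print at 2 decimals.

## PCA scatter (pca3d)

Variance explained is λᵢ/Σλ·100 per component, checked against exact rational
arithmetic and for scale invariance. Axis labels carry "PCk (xx.xx%)"; the
percentages are a convenience and independent of the plotted coordinates.
Default camera is (elev 30°, azim −60°), matplotlib's 3D default, and solid
mode is a pure function of its inputs: repeated renders produce byte-identical
SVG (fixed `svg.hashsalt`, date metadata stripped). Interactive mode opens a
rotatable window and is excluded from automated testing; the `--snapshot`
flag serves scripted use by exporting solid frames at a list of camera angles.

## Admixture sorting (admix)

Groups follow first appearance in the input (no alphabetical reordering —
input order usually encodes geography or cohort structure worth preserving).
Each group's dominant component is the argmax of the within-group mean
proportion vector, ties to the lowest component index, and individuals are
sorted ascending in their own value of that component with a stable sort.
Resolving dominance at the group level rather than per individual is what
makes each population block rise monotonically in one color; per-individual
argmax would interleave components and destroy the visual gradient. Sorting
is idempotent, blocks are contiguous and within-block values ascend — all
asserted directly on the layout structure.

## Manhattan layout (manplot)

Chromosome span is the maximum observed bp (no genome index is part of this
interface) and offsets accumulate with no inter-chromosome gap; x = offset +
bp, tick at offset + span/2. Natural sort handles mixed identifiers: numeric
ascending, then X, Y, MT, then anything else lexically, with a leading "chr"
prefix ignored for ranking. The layout is a pure function of the record
multiset (records are ordered by chromosome rank, bp, then value), chromosome
x-ranges are disjoint, and appending a new final chromosome never moves
earlier points. The −log10 transform is opt-in: the statistic column is
generic (p-values, nucleotide diversity, selection scores) and must never be
transformed silently. Suggestive lines are interpreted on the plotted scale.
Scatter layers rasterize automatically above 50,000 points to keep vector
exports tractable.

## Rendering and CLI

All renderers return the written path plus a layout dictionary describing
what was drawn (lanes, groups, annotations, camera, color indices, threshold
lines), so tests and downstream code can introspect figures without image
parsing. Output format is inferred from the extension or overridden with
`--f`, against a 14-format allow-list. Boolean CLI flags take explicit
`true`/`false` values rather than presence/absence switches. Exit code 0
means every requested output was written; any failure prints a one-line
diagnostic (validation errors surfaced verbatim, truncated after three).

## Synthetic data (synthgen)

The generators emulate the *structure* of real pipeline outputs: length-
proportional uniform marker placement; per-individual ROH-like segments with
one region planted in a chosen fraction of carriers (background segments are
kept away from the planted span so its coverage equals the carrier count
exactly); block-structured relationship matrices (within 0.5, between 0.1,
diagonal 1.0, optional iid Gaussian noise of the stated sd on mirrored
off-diagonals); Gaussian population clusters ≥ 5σ apart in PC space with
geometrically decaying eigenvalues; per-population Dirichlet ancestry rows
with one dominant component; and uniform p-values with a handful of loci
forced below 1e-7. Each generator returns its ground truth programmatically
so tests never re-parse it from disk.

They do not emulate linkage disequilibrium, coalescent genealogy, realistic
ROH length distributions, array ascertainment bias, or polygenic association
signal. Passing tests therefore demonstrate correctness of the layout and
detection arithmetic on inputs of realistic shape and scale, not statistical
performance on real genomes — this package draws results, it does not infer
them.

Fixture scales in the test and acceptance suites mirror typical published
panels where that is cheap: a 169-sample four-population relationship matrix
(52+21+67+29), a 120-sample two-population PCA with 10 PCs, a 24-individual
cohort filtered to 21, a 26-population K=16 Q table, and a 184-individual
seven-population ROH setting. The large-Manhattan smoke test uses 10⁵ records
— ample to exercise the cumulative layout and rasterization path, which are
linear in the record count.

## Numerical choices

- Symmetry and duplicate-pair agreement tolerance: 1e-9 absolute.
- Ancestry row sums accepted within ±0.01 of 1 (published Q matrices are
  rounded to few decimals).
- ⌈t·N⌉ guard: 1e-9 (see above).
- Degenerate inputs: all-zero density renders a uniform track; an empty
  shared-interval list writes a header-only file; all-zero eigenvalues are an
  error (variance fractions undefined).

## Limitations

Binary PLINK formats (.bed, .grm.bin), VCF ingestion and gzip transparency
are not implemented; inputs are the plain-text dialects above. No upstream
inference (PCA, ROH calling, GRM construction, admixture, GWAS) is performed.
Heatmaps are not dendrogram-reordered. Shared-region calling uses one pooled
threshold; per-population thresholds require pre-filtering.
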