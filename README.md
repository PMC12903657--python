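# popgenviz

Publication-ready figures for population genomics, from the plain-text files
standard pipelines already produce. The package targets researchers who run
PLINK, ADMIXTURE, GCTA or similar tools and then face a pile of ad-hoc
plotting scripts: it bundles the six figures nearly every population-genomics
paper needs behind one library and one CLI, with the preprocessing (binning,
cumulative coordinates, population grouping, shared-region calling) automated
and every input validated before anything is drawn.

## The six plot families

| subcommand   | figure | core computation |
|--------------|--------|------------------|
| `mapden`     | SNP density heatmap, one track per chromosome | markers counted in non-overlapping fixed-size bins; a marker at 1-based position p lands in bin ⌊(p−1)/b⌋; chromosome extent comes from a genome index file, never from the last genotyped SNP |
| `rohpainter` | runs-of-homozygosity / CNV tracks per individual | sweep-line coverage over per-individual merged intervals; maximal regions carried by ≥ ⌈tN⌉ of the N individuals are reported as shared intervals with frequency = min-coverage / N |
| `relmap`     | genomic-relationship (GRM) heatmap | optional population-level averaging: within-population cells average unordered distinct pairs (diagonals excluded — they carry the 1+F inbreeding scale), between-population cells average all cross pairs |
| `pca3d`      | 2D/3D PCA scatter | axis labels carry variance explained, λᵢ/Σλ·100; solid mode fixes (elev, azim), snapshots export several camera angles |
| `admix`      | stacked ancestry barplot (Q matrix) | individuals grouped by population; each group sorted ascending in the group's dominant component (argmax of the within-group mean proportions) |
| `manplot`    | Manhattan plot | cumulative coordinate x = chromosome offset + bp, offsets from the natural chromosome sort (1..n, X, Y, MT, others); opt-in −log10 p transform; up to two suggestive lines |

All inputs are whitespace-delimited text in PLINK-style dialects (`.map`,
genome index, 5-column interval table, `mat`/`col` relationship matrices with
an ids companion file, `.evec`/`.eval`, Q table, 3-column association table).
A validation layer checks file structure, dimensional consistency, missing
values and sample-label matching before plotting, and figures export to 14
bitmap/vector formats (pdf, svg, svgz, png, tif, tiff, jpg, jpeg, eps, pgf,
ps, raw, rgba, webp).

## Worked example

Generate a synthetic ROH study (20 individuals in two populations, one region
planted in 80% of them), call shared regions at a 70% frequency cutoff and
plot:

```sh
popgenviz synthgen intervals --seed 1 --o demo/
popgenviz rohpainter --d demo/intervals.txt --i demo/intervals.idx \
    --t 0.7 --sl true --o demo/roh.png
```

which logs

```
INFO wrote 1 shared intervals to demo/shared_intervals.txt
INFO wrote demo/roh.png
INFO wrote demo/shared_intervals.txt
```

and `demo/shared_intervals.txt` contains

```
chrom	start	end	count	frequency
1	240000	259999	16	0.8
```

— the planted 20 kb region, carried by 16 of 20 individuals (frequency 0.8 ≥
the 0.7 cutoff; `count` is the minimum coverage over the region). The same
calling is available in the library as
`rohpainter.compute_shared_intervals(table, threshold)`.

The other subcommands follow the same shape, e.g.

```sh
popgenviz mapden  --m markers.map --i genome.idx --b 1000000 --o density.pdf
popgenviz relmap  --r grm.mat --rf mat --id samples.ids --av true --a true --o rel.png
popgenviz pca3d   --evec pca.evec --eval pca.eval --elev 30 --azim -60 --o pca.svg
popgenviz admix   --d ancestry.q --sl false --o admix.png
popgenviz manplot --d gwas.txt --logp true --sug1 6 --o manhattan.png
```

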