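# resynth

Marker-based selection of complementary pairs of near-homozygous
individuals to **resynthesize** an elite, partly heterozygous genotype.

## The problem

Many crops are grown as a single high-value heterozygous genotype — F1
hybrid varieties in vegetables and field crops, clones in fruit trees and
ornamentals.  The resynthesis breeding strategy reconstructs such a
genotype from its own selfed progeny: self the elite individual, genotype a
large F2 (or later selfing generation) with a modest SNP panel in ABH
coding, and find two individuals that are each highly *homozygous* but
mutually *complementary* — A where the other is B at as many loci as
possible.  Crossing them restores heterozygosity genome-wide, yielding
progeny nearly identical to the original elite plant, into which new traits
can be introgressed.  `resynth` automates the pair search for populations
of thousands of individuals.

## The method

Genotypes are calls in {A, B, H, −} (−  = missing), individuals × ordered
markers, with a companion map assigning each marker to a chromosome.
The pipeline:

1. **Heterozygosity filter.** Individuals with het rate > `max_het`
   (default 0.5) are discarded; in an ideal F2 this removes about half the
   population.
2. **Pairwise scoring.** All k(k−1)/2 pairs of retained individuals are
   compared marker by marker.  Each locus falls in one of ten unordered
   call combinations, scored in [0, 1] by a configurable table; the sum
   over the panel is the pair's *final score*.  Three built-in tables are
   provided (SET1 intolerant to missing data, SET2 favouring homozygous
   A/B combinations, SET3 — the default — tolerant to both missing data
   and heterozygosity); a fully complementary pair reaches the *ideal
   score* `n_markers × score[A/B]`.
3. **Pair filters.** Pairs below `min_score_frac × ideal` (default 0.8)
   are discarded early; then pairs whose fraction of *invariable* loci
   (both members A, or both B — fixed wrong in all progeny) exceeds
   `max_invariable` are discarded.  Every rejection is recorded with its
   reason and the violated threshold.
4. **Similarity range.** Each accepted pair is annotated with the
   percentage interval of attainable similarity to the original hybrid:
   upper = (M − inv)·100/M, lower = (M − inv − het)·100/M, where M is the
   panel size, `inv` the invariable loci and `het` the loci where at
   least one member is heterozygous.
5. **Recombination counts (phased data).** With `--phased`, the minimal
   number of haplotype-origin switches along each chromosome is counted
   per individual (homozygote↔heterozygote 1, A↔B 2, reset at chromosome
   boundaries, missing calls skipped) and summed per pair — among
   equal-scoring pairs the fewest breakpoints are preferred.

Results are ranked by final score (descending), then total recombination
count, then pair ids, and are identical for any worker count.

A seeded F2 simulator (Poisson crossovers, Haldane map function, no
interference; equidistant markers; configurable missing-call rate) makes
the whole pipeline testable at scale without external data.

## Worked example

Simulate a small F2 (300 individuals, 8 chromosomes × 8 markers) and run
the selection:

```sh
$ resynth simulate --n-individuals 300 --n-chromosomes 8 \
    --markers-per-chromosome 8 --seed 42 --out sd_f2
seed: 42
genotypes: sd_f2.geno.tsv (300 x 64)
markers: sd_f2.markers.tsv

$ resynth select sd_f2.geno.tsv sd_f2.markers.tsv --phased \
    --min-score-frac 0.7 --max-invariable 0.05 --out run1
accepted pairs: 512 (of 11026 evaluated, ideal score 64)
pairs: run1.pairs.tsv
discarded: run1.discarded.tsv
log: run1.log
figure_png: run1.top10.png
figure_pdf: run1.top10.pdf

$ head -3 run1.pairs.tsv
id1	id2	final_score	n_invariable	het1	het2	similarity_lower_pct	similarity_upper_pct	rec1	rec2	rec_total
sim00161	sim00284	53.00	0	0.3125	0.3750	42.19	100.00	5	7	12
sim00074	sim00231	52.75	0	0.3281	0.3750	46.88	100.00	7	9	16
```

Of the 300 simulated individuals, 149 passed the 0.5 heterozygosity
filter, giving 11,026 candidate pairs.  The best pair scores 53.0 of an
ideal 64: no invariable locus, so the upper similarity bound is 100% —
every locus can return to the hybrid state in their progeny — while the
members' residual heterozygosity (0.31 and 0.38) pulls the guaranteed
lower bound down to 42%.  The `rec_*` columns count recombination
breakpoints inferred from the phased calls; `run1.top10.png/.pdf` shows
the genotype profiles of the ten best pairs grouped under chromosome
headers, and `run1.discarded.tsv` annotates every discarded individual
and pair with the filter that removed it.

Real data in the same two TSV formats (genotype table: header of marker
names, one row per individual; marker file: chromosome and marker columns
in identical order) is consumed by the same `select` command, e.g. with
`--scores SET1` or a custom two-column score-table file.

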