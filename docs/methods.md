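# Methods

## Model and procedure

`resynth` operates on an ABH-coded genotype matrix from a selfing
population (typically an F2) of a partly heterozygous elite individual.
At each biallelic marker, A and B denote the two parental homozygotes, H
the heterozygote and '-' a missing call.  The goal is to rank pairs of
individuals by how completely a cross between them would reconstitute the
elite genotype: ideally both members are fully homozygous and opposite
(A vs B) everywhere, so their F1 is heterozygous genome-wide.

The pipeline is a deterministic three-stage filter-and-rank:

1. individuals are kept when their heterozygosity rate is at most
   `max_het`;
2. every unordered pair of kept individuals receives a final score, the
   sum over markers of a per-combination score in [0, 1]; pairs under
   `min_score_fraction × ideal` are discarded first (the cheap test),
   then pairs whose invariable-locus fraction exceeds
   `max_invariable_fraction`;
3. accepted pairs are sorted by score, then (phased runs) by total
   recombination count, then by ids.

### Per-locus classes and score tables

The 4×4 ordered call pairs collapse into ten unordered classes
(A/A, B/B, H/H, -/-, H/-, A/-, B/-, A/H, B/H, A/B).  Three built-in
tables are provided:

| class | SET1 | SET2 | SET3 |
|-------|------|------|------|
| A/A, B/B | 0 | 0 | 0 |
| H/H | 0.5 | 0.25 | 0.5 |
| -/- | 0 | 0 | 0.5 |
| H/- | 0.5 | 0.25 | 0.625 |
| A/-, B/- | 0 | 0.5 | 0.75 |
| A/H, B/H | 0.75 | 0.5 | 0.75 |
| A/B | 1.0 | 1.0 | 1.0 |

SET1 zeroes every class with a missing member except H/- (its published
value, 0.5, is adopted verbatim rather than "corrected"); SET2 penalises
heterozygous combinations to favour already-fixed material; SET3, the
default, treats missing and heterozygous calls permissively and is the
appropriate choice when missing data has not been imputed away.  Because
SET1 and SET3 differ only on classes involving '-', they produce
identical scores on missing-free data — a useful internal consistency
check.  User tables are two-column TSVs (class, value); all ten classes
are required and values are validated to [0, 1].

### Similarity range

For a panel of M markers, a pair with `inv` invariable loci and `het`
loci where at least one member is heterozygous is annotated with

    upper = (M − inv) · 100 / M
    lower = (M − inv − het) · 100 / M

the upper bound being the best attainable similarity of resynthesised
progeny to the hybrid (invariable loci can never recover the
heterozygous state) and the lower bound what is guaranteed regardless of
how the heterozygous loci segregate.  An H/H locus counts once in `het`.

### Recombination counting

On phased data, each ABH sequence constrains the parental origin of the
two haplotypes along a chromosome.  The count is the minimal number of
haplotype-origin switches consistent with the calls: consecutive
non-missing calls contribute 0 within the same class, 1 for
homozygote↔heterozygote, 2 for A↔B (both haplotypes switch).  H runs are
assumed phase-preserving (H→H costs 0), which yields the minimum; the
test suite proves the transition-cost sum equal to exhaustive enumeration
over all a|b vs b|a assignments for short sequences.  Missing calls are
skipped (the transition is charged between their flanking calls) and
chromosome boundaries reset the scan.  A pair's total is the plain sum of
its members' per-haplotype counts.  Phase cannot be inferred from ABH
coding, so counting is activated only by the `--phased` flag; without it
the recombination columns are omitted.

## Defaults and their rationale

| parameter | default | reason |
|---|---|---|
| `max_het` | 0.5 | removes ≈ half of an ideal F2; individuals above it cannot be fixed quickly |
| `min_score_fraction` | 0.8 | score cut as a fraction of the ideal score; 0.8 is strict enough for dense, well-covered panels while cheap to relax |
| `max_invariable_fraction` | 0.1 | the permissive end of the useful 0–0.1 range, appropriate for small populations; use 0 to demand no invariable locus |
| het denominator | non-missing calls | robust to unequal missing-data loads between individuals; `--het-denominator all` switches to the full panel |
| score table | SET3 | tolerant to missing data and heterozygosity, the safe default on unimputed data |

All filter boundaries accept equality (an individual at exactly
`max_het` is kept, a pair at exactly the score or invariable threshold is
accepted).  Scores are printed to 2 decimals; internal arithmetic is full
precision.

## Pair engine and determinism

For k retained individuals the k(k−1)/2 pair indices are split into
contiguous chunks (size ⌈total / (8 × workers)⌉) evaluated independently
— with joblib when `workers > 1`.  Each pair's statistics are computed
identically regardless of chunk boundaries, rejection records are emitted
in pair order, and the final ranking is a global sort (score descending,
total recombination ascending on phased runs, then lexicographic ids with
id1 < id2 within a pair), so serialized output is byte-identical for any
worker count.  When the pair count exceeds a cap (default 10⁶), LOW_SCORE
rejections are aggregated into a count rather than enumerated, keeping
the discard file bounded; the cap and the aggregation are stated in the
discard file and the log.

## Synthetic data generator

`simulate_f2` emulates genotyping an F2 from a fully heterozygous F1:
per chromosome and gamete, the crossover count is Poisson with mean
length/100 cM and crossover positions are uniform — the Haldane model,
with no crossover interference and no obligate chiasma — and the starting
parental origin is Bernoulli(1/2).  Markers are equidistant at positions
(i + 0.5)/m × L, deliberately off the chromosome ends.  Consequences used
by the tests: adjacent-marker recombinant fractions follow
r = (1 − e^(−2d))/2, per-marker genotypes segregate 1:2:1, mean
crossovers per gamete are one per Morgan, and the mean per-individual
heterozygous fraction is 0.5, so a 0.5 het filter retains about half the
population.  Phase is exact by construction, which lets the recombination
counter be validated against known crossovers.  The default study-scale
configuration is 10 chromosomes × 100 cM × 50 markers; missing data is
injected per cell, independently, at a configurable rate (5% in the
standard degraded scenario).

What the generator does **not** emulate: crossover interference,
segregation distortion, genotyping error beyond missingness, linkage-map
estimation error, and later selfing generations (F3/F4).  Passing tests
on simulated data therefore demonstrate the correctness of the selection
arithmetic and the engine's invariances, not robustness to those
real-data artefacts; on real populations, imputation of missing calls
before selection is recommended.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use a 10,000 × 500 simulation
only for counting-level checks (filter retention, pair counts over 12
million) and a 1,000-individual population for full selection runs; the
Table-style top-100 statistics reported by the acceptance script are
therefore computed on a 10× smaller pool than the largest population the
engine is designed for, and their absolute means are correspondingly
slightly lower than a 10,000-individual run would give.  These sizes are
the package's own benchmark choices; the engine itself is limited only by
the O(k²) pair count.

## Known limitations

- The recombination count is a minimal-switch estimate; double crossovers
  between adjacent markers and genotyping errors are invisible to it.
- The engine materialises the pair index arrays (O(k²) memory in the
  retained-individual count); populations beyond ~10⁴ retained
  individuals need a streaming variant.
- Missing calls are never imputed; the '-'-aware score classes are the
  only handling provided.
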