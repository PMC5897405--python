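# Methods

## Repeat-length calling at anchored homopolymers

A motif site is defined by an anchor base at a fixed 1-based coordinate, a
repeat base, and a reference run length: at OriL the G at nt 5171 anchors an
11-adenine run starting at 5172; in tRNA-Arg a T near nt 9820 anchors an
8-adenine run. For each read the caller reconstructs the query sequence over
the *motif window* — one base before the anchor through six bases past the
reference run — by walking the CIGAR: M/=/X ops emit query bases at their
reference coordinates, deletions emit nothing, insertions emit their bases
when the insertion point lies inside the window (left edge inclusive, right
edge exclusive), and clips are dropped. The observed run length is the
maximal run of the repeat base after the first anchor base (a run of anchor
bases is tolerated — the motif grammar is "G+ poly A"). Because the
reconstruction is indexed by reference coordinate, the count is invariant to
where the aligner placed the indel within the run; the test suite checks
left- and right-aligned placements explicitly, plus full agreement with an
independent per-base expansion oracle on 10,000 simulated M/I/D/S reads.

Censoring rather than truncation: a read must show the full window —
anchor through a visible non-repeat terminator — to contribute. A read
ending inside the run cannot distinguish 11 A from 12 A and would bias the
spectrum downward, so it is rejected as non-spanning, not counted short.
The six-base slack accommodates expanded alleles (observed lengths up to
13–14) while keeping the spanning requirement modest.

### Thresholds

| Parameter | Default | Meaning |
|---|---|---|
| min mean read quality | 30 (Phred) | reads below are discarded |
| min read length | 30 bp | shorter reads are discarded |
| require pair | true | reads missing a mate are discarded |
| min mean motif quality | 20 (Phred) | observations below are discarded |
| min pileup base quality | 30 (Phred) | bases below are depth loss |
| heteroplasmy band | 40–90 % | point-allele alt frequency, inclusive |
| homoplasmy threshold | > 90 % | strict |

All discard rules are strict `<`, so a read at exactly the boundary is
retained; the classification band is inclusive at both 40% and 90%, with
homoplasmy strictly above 90%. These boundary semantics follow the
inequality directions of the protocol the pipeline reimplements and are
pinned by boundary tests (binary search locates the retention boundaries at
exactly Phred 30 and 20).

The per-sample statistic is exported both as `f_12` (fraction of
observations at reference length + 1, the "12 A heteroplasmy") and as the
aggregate `gt_ref_fraction` (all lengths above reference, "> 11 A");
downstream analyses default to `f_12`.

### Duplicate marking

PCR duplicates are collapsed by the coordinate key (reference, position,
CIGAR text, orientation), keeping the highest-summed-quality read per group.
This is a deliberate, simple proxy for full mate-graph duplicate marking. On
the package's own single-window amplicon simulations it is *too* aggressive:
a spanning 150 bp read has only ~130 possible start positions, so unrelated
reads collide on the key and legitimate observations are collapsed. On
fragmented whole-genome libraries the collision rate is negligible. The CLI
therefore exposes `--dedup/--no-dedup`, and recovery analyses on simulated
data run without deduplication. Mate-overlap double counting is not
corrected: both mates of a pair may contribute an observation, and the
filter report records counts so this can be audited.

## ddPCR quantification

Each droplet is an independent Poisson trial: with λ copies per droplet the
negative fraction is e^(−λ), inverted as λ = −ln(n_neg/n_tot) with
delta-method SE √((n_tot − n_neg)/(n_tot·n_neg)). A copy-number ratio
(mt-Co1/Vdac1, mt-Nd5/Vdac1) is the ratio of two λs; its 95% CI multiplies
the point ratio by exp(±1.96·√(Σ squared relative SEs)) — the log-normal
delta method, standard ddPCR practice and closed-form testable. Volume
conversion is omitted: ratios are unitless and volume cancels. A saturated
assay (no negatives) is an error; an all-negative assay gives λ = 0, and a
zero-numerator ratio is reported as 0 with undefined CI.

## Cohort statistics

- **Spearman:** ρ is the Pearson correlation of midranks. For n ≤ 9 the
  two-sided p is exact by full permutation enumeration; otherwise the
  t-approximation with n−2 df. Constant input is an error.
- **Kaplan–Meier:** product-limit estimate (via lifelines), Greenwood
  variance, median as the first time S ≤ 0.5 (undefined if never reached),
  median 95% CI from the log(−log) transform. Censored subjects leave the
  risk set at their censoring time.
- **Log-rank / Gehan:** at each distinct event time the observed events in
  one group are compared with their hypergeometric expectation;
  the statistic is (Σw(O−E))²/Σw²V with w = 1 (log-rank) or w = number at
  risk (Gehan–Breslow, emphasizing early differences), referred to χ²₁.
  Implemented vectorized so the 2,000-replicate calibration suites run in
  seconds; lifelines is the independent oracle in tests.
- **Mann–Whitney U:** midranks for ties; exact p when min(n) ≤ 8 without
  ties, else the normal approximation with tie correction (scipy backend).
- **Sample size:** the smallest per-group n at which the two-sided
  two-sample t-test reaches the target power, iterating the noncentral-t
  power function. A "10% difference in lifespan" against an assumed 20% SD
  standardizes to d = 0.5, which gives 64 per group at α = 0.05, power 0.8;
  the 20% SD assumption is a documented default, not hidden. A Monte-Carlo
  power check (10,000 normal replicates) agrees within ±0.02.

P-values are reported unadjusted throughout.

## Synthetic data

The generators exist to provide ground truth; their defaults are fixed study
conditions, not tuning knobs.

**Reads.** 150 bp single- or paired-end reads over a pseudo-random linear
reference carrying the motif at its real coordinates. Each read draws a true
allele from the mixture; slippage (default 0.005 per molecule) shifts the
observed run by a geometric(0.5) magnitude in a random direction, the
simplest model producing the observed 9 A–13 A spread around 11 A;
substitutions (default 0.002 per base, a post-trimming Illumina scale) hit
uniformly; qualities are normal (mean 35, SD 4) clipped to [2, 41]. The
length difference enters the CIGAR as a left-aligned indel at the run start,
mimicking aligner left-shifting. Every read is placed to span the full motif
window, so each is informative; non-spanning reads are constructed directly
in tests. Known departures from real data: no quality-by-cycle decay, no
chimeras, no strand bias, a single amplicon window rather than genome-wide
tiling, and fragment starts far more degenerate than a fragmented library —
which is why coordinate deduplication is switched off in recovery analyses
(above). Passing recovery tests therefore demonstrates correctness of the
counting chain under this error model, not robustness to every artifact of
real sequencing.

**Droplets.** Each droplet is Bernoulli-negative with probability e^(−λ).

**Cohort.** Per-animal heteroplasmy is truncated-normal on [0, 1] with
strain means 0.10 (B6) and 0.22 (B6-mtAKR) and SD 0.05 — a low-heteroplasmy
and a >20% strain. Lifespan is skew-normal (location 1000 d, scale 240 d,
skew −4: left-skewed with median ≈ 830 d and residual SD ≈ 158 d, realistic
for female B6 mice) plus a linear effect of −400 days per unit heteroplasmy
centred on the pooled mean het, so the 0.12 strain gap translates into a
~50-day shorter median for the high-heteroplasmy strain and a pooled
heteroplasmy–lifespan Spearman ρ near −0.19. Copy ratio is normal
(mean 100, SD 15) with slope −90 per unit het, giving ρ near −0.43.
Censoring is Bernoulli at 5%. These values were chosen once, analytically,
to embody the cohort the generator emulates; single simulated cohorts of
160 animals remain noisy (ρ SE ≈ 0.08), so the acceptance script reports
operating characteristics averaged over 30 cohorts.

## Numerical and design choices

- Coordinates are 1-based inclusive positions with half-open spans (SAM
  convention; half-open spans simplify overlap tests). Quality encoding is
  fixed to Phred+33. The reference is treated as linear over the amplicon;
  reads crossing the circular junction are out of scope.
- Secondary and supplementary alignments are skipped at parse time (counted,
  not used); hard clips are accepted and consume nothing.
- The heteroplasmy/homoplasmy classification is exposed for point alleles
  from pileups; repeat-length alleles are reported as spectra rather than
  forced through the same band, since the two representations answer
  different questions.
- Filter order (filter → dedup vs dedup → filter) does not change the
  accepted observation set on simulator output, verified by test.
- Degenerate inputs: empty read sets yield empty outputs and zero-count
  reports; an empty spectrum has no fractions and `heteroplasmy_metrics`
  refuses it; all-censored cohorts yield S ≡ 1 with undefined median.
- The shipped OriL site definition (11 A after the G anchor) is verified by
  `verify_reference_motif` against the package's own synthetic reference;
  verifying it against the C57BL/6J mtDNA assembly requires that assembly on
  disk and is not part of the desk-scale suite.

## Problem sizes

The test and acceptance runs use 5,000–20,000 reads per simulation, 100
seeds for the f₁₂ recovery sweep, 1,000–2,000 replicates for calibration
suites, 20,000 droplets per assay, and 30 cohorts of 160 animals — sizes at
which the binomial/χ² tolerances asserted in the tests are meaningful while
the whole suite runs in about a minute.

## Known limitations

- The duplicate key is a coordinate proxy; it cannot separate true PCR
  duplicates from coincidental siblings in low-complexity start
  distributions (see above).
- The slippage rate of long-range PCR at this locus is unknown; it is an
  exposed parameter, never asserted.
- Heteroplasmy phasing between the two sites, genome-wide SNV calling,
  realignment and consensus assembly are out of scope.
- The Spearman exact-permutation path enumerates n! permutations and is
  restricted to n ≤ 9 by design.
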