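# mthet

Repeat-length mitochondrial heteroplasmy calling at anchored homopolymers,
droplet-digital-PCR copy-number quantification, and cohort survival
statistics — the measurement-and-inference chain that links poly-A
repeat-length variation at the mouse mtDNA origin of light-strand replication
(OriL) to mtDNA copy number and lifespan.

## The problem

The mouse OriL contains a poly-A loop (reference 11 adenines starting at
nt 5172, anchored by the G at nt 5171) that is essential for priming
light-strand replication. Individual mtDNA molecules vary in the length of
this run: a sample is a mixture of 9 A–13 A alleles, and the fraction of
molecules carrying 12 adenines instead of 11 — the *12 A heteroplasmy*
`f_12` — differs between mouse strains and correlates with phenotype. Because
aligners place homopolymer indels wherever they like inside the run, naive
pileup counting misreads these alleles; `mthet` instead reconstructs each
read's sequence over the motif window from its CIGAR and counts the maximal
adenine run after the anchor, which is invariant to indel placement.

Around that core caller the package provides:

- **`mthet.sam_io`** — a minimal SAM text reader/writer (Phred+33) with CIGAR
  arithmetic; unmapped/secondary records are skipped and counted.
- **`mthet.calling`** — read filtering (mean quality ≥ 30, length ≥ 30 bp,
  both mates present), coordinate duplicate marking, window reconstruction,
  motif extraction (mean motif quality ≥ 20, spanning reads only),
  repeat-length spectra `f_L = n_L / Σ n_L`, pileup allele frequencies
  (base quality ≥ 30), and the point-allele classification
  (alt > 90% homoplasmic, 40–90% heteroplasmic, otherwise low-level).
- **`mthet.ddpcr`** — Poisson inversion of droplet counts,
  `λ = −ln(n_neg/n_tot)` copies per droplet, delta-method SEs and log-normal
  95% CIs on ratios such as mt-Co1/Vdac1.
- **`mthet.stats`** — Spearman rank correlation (exact permutation p for
  n ≤ 9), Kaplan–Meier curves with median and log(−log) 95% CI, log-rank and
  Gehan–Breslow tests, Mann–Whitney U, and two-sample t-test sample-size
  calculation via the noncentral-t power function.
- **`mthet.simulate`** — ground-truth generators: reads over the homopolymer
  with a ±1-unit geometric-tail slippage model, ddPCR droplets, and
  two-strain lifespan cohorts with a negative heteroplasmy effect and right
  censoring.

## Worked example

`examples/simulate_and_call.py` simulates 5,000 reads from a 75/25 mixture of
11 A and 12 A alleles with slippage (0.005) and substitution (0.002) noise,
then calls the spectrum back:

```
reads simulated: 5000, retained: 5000, motif observations: 4991
  11 A: 0.7351
  12 A: 0.2418
12A heteroplasmy (true 0.25):  0.2418
>11A heteroplasmy:             0.2436
```

The called `f_12` sits within sampling error of the simulated truth; the
trace fractions at short lengths are substitution errors truncating the run.
`examples/survival_analysis.py` runs the cohort layer on a simulated
two-strain cohort (80 females per strain):

```
Spearman het vs lifespan:   rho = -0.2506, p = 0.0014
       B6: median lifespan 877 d (95% CI 853-919), 8 censored
 B6-mtAKR: median lifespan 805 d (95% CI 751-849), 2 censored
log-rank: chi2 = 8.857, p = 0.0029
```

Higher 12 A heteroplasmy goes with shorter lifespan, and the
high-heteroplasmy strain's median is ~70 days shorter. The other examples
cover the ddPCR ratio (`ddpcr_ratio.py`) and the sample-size calculation
(`power_analysis.py`: d = 0.5 at α = 0.05, power 0.8 → 64 per group).

There is also a thin CLI over the same functions:

```bash
mthet simulate --out-dir sim --seed 1
mthet call-heteroplasmy --sam sim/reads.sam --out-dir calls --no-dedup
mthet copy-number --droplets sim/droplets.tsv --out ratios.tsv
mthet analyze --cohort sim/cohort.tsv --out-dir stats
```

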