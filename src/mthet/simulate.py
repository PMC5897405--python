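"""Synthetic data with ground truth: aligned reads over a homopolymer site
with a slippage error model, ddPCR droplet counts, and lifespan cohorts with
a heteroplasmy effect.

The read simulator emulates a 2x150 bp amplicon sequencing experiment over an
anchored poly-A run: each read draws a true repeat-length allele from a
mixture, polymerase slippage perturbs the observed run length by +-1 repeat
unit (geometric tail for larger shifts), per-base substitution errors and a
normal Phred-quality profile are applied, and the CIGAR carries the length
difference as a left-aligned indel at the run start, mimicking aligner
left-shifting.  Every read gets a truth-table row for parameter-recovery
tests.

The cohort simulator draws per-animal heteroplasmy from a truncated normal
(strain-specific mean), lifespan from a skew-normal plus a linear
heteroplasmy effect, and right-censors at a fixed rate.  Defaults emulate the
study conditions of a two-strain female mouse cohort: ~10% vs ~22% mean
expanded-allele heteroplasmy, a left-skewed lifespan distribution centred
near 800 days, and a negative heteroplasmy-lifespan slope producing a ~50-day
strain gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calling import ORIL_5172, MotifSite
from .ddpcr import DropletCounts
from .sam_io import (
    FLAG_FIRST,
    FLAG_LAST,
    FLAG_MATE_REVERSE,
    FLAG_PAIRED,
    FLAG_PROPER,
    FLAG_REVERSE,
    AlignedRead,
    CigarOp,
    default_header,
)

__all__ = [
    "ReadSimParams",
    "CohortSimParams",
    "make_reference",
    "simulate_polyA_reads",
    "simulate_droplets",
    "simulate_cohort",
]

_BASES = np.array(list("ACGT"))
REFERENCE_NAME = "chrM"


@dataclass(frozen=True)
class ReadSimParams:
    """Parameters of the poly-A read simulator."""

    site: MotifSite = ORIL_5172
    allele_fractions: dict[int, float] = field(default_factory=lambda: {11: 0.75, 12: 0.25})
    n_reads: int = 5000
    read_length: int = 150
    substitution_rate: float = 0.002
    slippage_rate: float = 0.005
    quality_mean: float = 35.0
    quality_sd: float = 4.0
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.allele_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele fractions sum to {total}, need 1")
        for rate in (self.substitution_rate, self.slippage_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("rates must be in [0, 1)")


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of the lifespan-cohort simulator (days)."""

    n_per_strain: int = 80
    strains: tuple[str, str] = ("B6", "B6-mtAKR")
    sex: str = "F"
    lifespan_location: float = 1000.0
    lifespan_scale: float = 240.0
    lifespan_skew: float = -4.0
    het_means: dict[str, float] = field(default_factory=lambda: {"B6": 0.10, "B6-mtAKR": 0.22})
    het_sd: float = 0.05
    lifespan_slope: float = -400.0
    copy_ratio_mean: float = 100.0
    copy_ratio_sd: float = 15.0
    copy_ratio_slope: float = -90.0
    censor_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.lifespan_scale <= 0:
            raise ValueError("lifespan_scale must be > 0")


def make_reference(site: MotifSite, flank: int) -> str:
    """Build a linear reference with the anchored run at its stated
    coordinates (string index 0 = position 1) and ``flank`` bases past the
    run's terminator.  Flank bases are a fixed pseudo-random sequence; the
    terminator is forced to differ from the repeat base."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    length = site.run_end + 1 + flank
    rng = np.random.default_rng(20180412)  # fixed: the reference is a constant
    seq = rng.choice(_BASES, size=length)
    seq[site.anchor_position - 1] = site.anchor_base
    seq[site.run_start - 1 : site.run_end - 1] = site.repeat_base
    terminator = next(b for b in "CTGA" if b not in (site.repeat_base, site.anchor_base))
    seq[site.run_end - 1] = terminator
    # the base before the anchor must neither extend the repeat run backwards
    # nor extend the anchor run ("G+") leftwards
    if seq[site.anchor_position - 2] in (site.repeat_base, site.anchor_base):
        seq[site.anchor_position - 2] = terminator
    return "".join(seq)


def _slip(rng: np.random.Generator, length: int, rate: float) -> int:
    """Apply slippage: with probability ``rate`` shift the run length by a
    geometric(0.5) magnitude in a random direction (floor 0)."""
    if rng.random() >= rate:
        return length
    magnitude = rng.geometric(0.5)
    direction = 1 if rng.random() < 0.5 else -1
    return max(length + direction * magnitude, 0)


def _read_cigar_and_bases(
    reference: str,
    site: MotifSite,
    start: int,
    read_length: int,
    run_obs: int,
) -> tuple[tuple[CigarOp, ...], str]:
    """Assemble a spanning read's CIGAR and bases.

    The observed run replaces the reference run; any length difference is a
    left-aligned insertion/deletion at the run start.  ``start`` is 1-based.
    """
    ref_run = site.reference_run_length
    diff = run_obs - ref_run
    pre = site.run_start - start  # reference bases before the run
    ref_len = read_length - max(diff, 0) + max(-diff, 0)
    bases = (
        reference[start - 1 : site.run_start - 1]
        + site.repeat_base * run_obs
        + reference[site.run_end - 1 : start - 1 + ref_len]
    )
    bases = bases[:read_length]
    if diff == 0:
        cigar: tuple[CigarOp, ...] = (CigarOp("M", read_length),)
    elif diff > 0:
        cigar = (CigarOp("M", pre), CigarOp("I", diff), CigarOp("M", read_length - pre - diff))
    else:
        cigar = (CigarOp("M", pre), CigarOp("D", -diff), CigarOp("M", read_length - pre))
    return cigar, bases


def simulate_polyA_reads(
    params: ReadSimParams, reference: str | None = None
) -> tuple[list[AlignedRead], pd.DataFrame, str]:
    """Simulate aligned reads over the homopolymer site.

    Returns (reads, truth table, reference sequence).  Every simulated
    fragment spans the full motif window (anchor-1 through run end + slack),
    so each contributes one informative motif observation; truth rows record
    the drawn allele, the post-slippage run length and the substitution
    count.  With ``paired`` a second, non-overlapping mate is emitted
    downstream so pair-completeness filters pass.
    """
    site = params.site
    rng = np.random.default_rng(params.seed)
    if reference is None:
        reference = make_reference(site, flank=params.read_length + 100)
    win_start, win_end = site.window()
    if params.read_length < (win_end - win_start) + 8:
        raise ValueError("read_length too short to span anchor, run and terminator")
    alleles = np.array(sorted(params.allele_fractions))
    probs = np.array([params.allele_fractions[a] for a in alleles], dtype=float)

    qual_header = default_header(REFERENCE_NAME, len(reference))
    reads: list[AlignedRead] = []
    truth_rows = []
    mate_gap = 20
    for i in range(params.n_reads):
        true_allele = int(rng.choice(alleles, p=probs))
        run_obs = _slip(rng, true_allele, params.slippage_rate)
        diff = run_obs - site.reference_run_length
        ref_len = params.read_length - max(diff, 0) + max(-diff, 0)
        # uniform start among positions where the read covers the full window
        lo = win_end - ref_len
        hi = win_start
        if lo > hi:
            raise ValueError("read cannot span the motif window at this allele length")
        start = int(rng.integers(lo, hi + 1))
        cigar, bases = _read_cigar_and_bases(reference, site, start, params.read_length, run_obs)
        # substitution errors
        n_sub = 0
        if params.substitution_rate > 0:
            hits = np.flatnonzero(rng.random(len(bases)) < params.substitution_rate)
            if hits.size:
                arr = np.array(list(bases))
                for h in hits:
                    choices = [b for b in "ACGT" if b != arr[h]]
                    arr[h] = choices[int(rng.integers(3))]
                bases = "".join(arr)
                n_sub = int(hits.size)
        quals = np.clip(
            np.rint(rng.normal(params.quality_mean, params.quality_sd, len(bases))), 2, 41
        ).astype(int)
        name = f"sim{i:06d}"
        flag1 = (FLAG_PAIRED | FLAG_PROPER | FLAG_MATE_REVERSE | FLAG_FIRST) if params.paired else 0
        reads.append(
            AlignedRead(
                name=name,
                reference_name=REFERENCE_NAME,
                position=start,
                cigar=cigar,
                bases=bases,
                qualities=tuple(int(q) for q in quals),
                flag=flag1,
            )
        )
        if params.paired:
            m_start = win_end + mate_gap
            m_bases = reference[m_start - 1 : m_start - 1 + params.read_length]
            m_quals = np.clip(
                np.rint(rng.normal(params.quality_mean, params.quality_sd, len(m_bases))), 2, 41
            ).astype(int)
            reads.append(
                AlignedRead(
                    name=name,
                    reference_name=REFERENCE_NAME,
                    position=m_start,
                    cigar=(CigarOp("M", len(m_bases)),),
                    bases=m_bases,
                    qualities=tuple(int(q) for q in m_quals),
                    flag=FLAG_PAIRED | FLAG_PROPER | FLAG_REVERSE | FLAG_LAST,
                )
            )
        truth_rows.append(
            {
                "read_name": name,
                "true_allele": true_allele,
                "observed_run": run_obs,
                "n_substitutions": n_sub,
                "start": start,
                "spanning": True,
            }
        )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["header"] = qual_header
    return reads, truth, reference


def simulate_droplets(
    lambda_true: float, n_total: int, seed: int | np.random.Generator = 0, assay: str = "assay"
) -> DropletCounts:
    """Simulate one ddPCR assay: each droplet is negative with probability
    e^(-lambda)."""
    if lambda_true < 0:
        raise ValueError("lambda must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_negative = int(rng.binomial(n_total, float(np.exp(-lambda_true))))
    return DropletCounts(assay=assay, n_total=n_total, n_negative=n_negative)


def simulate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Simulate a two-strain lifespan cohort.

    Columns: animal_id, strain, sex, lifespan_days, event, het_12A,
    copy_ratio.  Heteroplasmy is truncated-normal on [0, 1]; lifespan is a
    skew-normal draw plus ``lifespan_slope`` x (het - pooled mean het), so a
    strain with higher heteroplasmy lives shorter both between strains and
    along the within-strain het gradient; copy_ratio is normal plus
    ``copy_ratio_slope`` x (het - pooled mean); censoring is
    Bernoulli(censor_rate).
    """
    rng = np.random.default_rng(params.seed)
    pooled_mean = float(np.mean([params.het_means[s] for s in params.strains]))
    rows = []
    for strain in params.strains:
        mu = params.het_means[strain]
        a, b = (0.0 - mu) / params.het_sd, (1.0 - mu) / params.het_sd
        het = sps.truncnorm.rvs(a, b, loc=mu, scale=params.het_sd, size=params.n_per_strain, random_state=rng)
        base_life = sps.skewnorm.rvs(
            params.lifespan_skew,
            loc=params.lifespan_location,
            scale=params.lifespan_scale,
            size=params.n_per_strain,
            random_state=rng,
        )
        lifespan = np.maximum(base_life + params.lifespan_slope * (het - pooled_mean), 30.0)
        censored = rng.random(params.n_per_strain) < params.censor_rate
        ratio = (
            rng.normal(params.copy_ratio_mean, params.copy_ratio_sd, params.n_per_strain)
            + params.copy_ratio_slope * (het - pooled_mean)
        )
        for k in range(params.n_per_strain):
            rows.append(
                {
                    "animal_id": f"{strain}_{k:03d}",
                    "strain": strain,
                    "sex": params.sex,
                    "lifespan_days": float(lifespan[k]),
                    "event": bool(not censored[k]),
                    "het_12A": float(het[k]),
                    "copy_ratio": float(ratio[k]),
                }
            )
    return pd.DataFrame(rows)
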