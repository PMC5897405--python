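"""Droplet digital PCR quantification by Poisson inversion.

A ddPCR reaction partitions template molecules into droplets; with mean
occupancy lambda copies per droplet, the fraction of negative droplets is
e^(-lambda), so lambda = -ln(n_negative / n_total).  The mtDNA/nDNA copy
number ratio (mt-Co1/Vdac1 or mt-Nd5/Vdac1) is the ratio of two such
concentrations; reaction volume cancels, so ratios are unitless.  The 95% CI
uses the log-normal delta method with summed squared relative standard
errors, the standard ddPCR practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["DropletCounts", "CopyRatio", "droplet_concentration", "copy_ratio", "ratios_from_table"]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class DropletCounts:
    """Positive/negative droplet tallies for one assay."""

    assay: str
    n_total: int
    n_negative: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be > 0")
        if not 0 <= self.n_negative <= self.n_total:
            raise ValueError("n_negative must be in [0, n_total]")


@dataclass(frozen=True)
class CopyRatio:
    numerator_assay: str
    denominator_assay: str
    lambda_num: float
    lambda_den: float
    ratio: float
    ci_low: float
    ci_high: float


def droplet_concentration(counts: DropletCounts) -> tuple[float, float]:
    """Copies per droplet and its delta-method standard error.

    lambda = -ln(n_negative/n_total); SE = sqrt((n_total - n_negative) /
    (n_total * n_negative)).  A saturated assay (no negative droplets) cannot
    be inverted and raises; an all-negative assay gives lambda = 0.
    """
    if counts.n_negative == 0:
        raise ValueError(f"saturated assay {counts.assay!r}: no negative droplets")
    lam = -math.log(counts.n_negative / counts.n_total)
    se = math.sqrt((counts.n_total - counts.n_negative) / (counts.n_total * counts.n_negative))
    return lam, se


def copy_ratio(num: DropletCounts, den: DropletCounts) -> CopyRatio:
    """Ratio of two droplet concentrations with a log-scale 95% CI."""
    lam_n, se_n = droplet_concentration(num)
    lam_d, se_d = droplet_concentration(den)
    if lam_d == 0:
        raise ValueError(f"denominator assay {den.assay!r} has zero concentration")
    ratio = lam_n / lam_d
    if lam_n == 0:
        return CopyRatio(num.assay, den.assay, lam_n, lam_d, 0.0, math.nan, math.nan)
    rel_var = (se_n / lam_n) ** 2 + (se_d / lam_d) ** 2
    half = _Z95 * math.sqrt(rel_var)
    return CopyRatio(
        numerator_assay=num.assay,
        denominator_assay=den.assay,
        lambda_num=lam_n,
        lambda_den=lam_d,
        ratio=ratio,
        ci_low=ratio * math.exp(-half),
        ci_high=ratio * math.exp(half),
    )


def ratios_from_table(
    table: pd.DataFrame, numerator: str, denominator: str
) -> pd.DataFrame:
    """Compute per-sample copy ratios from a droplet-count table.

    ``table`` needs columns sample, assay, n_total, n_negative; one row per
    (sample, assay).  Returns one row per sample with ratio and CI.
    """
    required = {"sample", "assay", "n_total", "n_negative"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"droplet table missing columns: {sorted(missing)}")
    rows = []
    for sample, grp in table.groupby("sample", sort=True):
        by_assay = {r.assay: DropletCounts(r.assay, int(r.n_total), int(r.n_negative)) for r in grp.itertuples()}
        if numerator not in by_assay or denominator not in by_assay:
            raise ValueError(f"sample {sample!r}: missing assay {numerator!r} or {denominator!r}")
        cr = copy_ratio(by_assay[numerator], by_assay[denominator])
        rows.append(
            {
                "sample": sample,
                "numerator": numerator,
                "denominator": denominator,
                "lambda_num": cr.lambda_num,
                "lambda_den": cr.lambda_den,
                "ratio": cr.ratio,
                "ci_low": cr.ci_low,
                "ci_high": cr.ci_high,
            }
        )
    return pd.DataFrame(rows)
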