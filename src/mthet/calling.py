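"""Repeat-length heteroplasmy calling at anchored homopolymers.

The mouse mtDNA origin of light-strand replication (OriL) carries a poly-A
loop (reference 11 adenines starting at nt 5172, anchored by the G at
nt 5171) whose length varies between mtDNA molecules — repeat-length
heteroplasmy.  A second polymorphic run sits in the tRNA-Arg gene (8 A after
the anchor near nt 9821).  This module turns aligned reads into per-sample
repeat-length spectra: reads are quality/length/pair filtered, PCR duplicates
are collapsed, each read's sequence over the motif window is reconstructed
from its CIGAR (so the count is invariant to where the aligner placed the
indel within the run), and the maximal run of the repeated base after the
anchor is counted.  Pileup allele frequencies and the homoplasmy /
heteroplasmy classification of point alleles are computed alongside.

Thresholds default to: mean read quality >= 30, read length >= 30 bp, both
mates present, mean motif quality >= 20, pileup base quality >= 30,
heteroplasmy at alternate frequency 40-90% and homoplasmy above 90%.
Inequalities are strict on the discard side, so equality is retained.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .sam_io import AlignedRead, cigar_text, reference_span

__all__ = [
    "MotifSite",
    "MotifObservation",
    "LengthSpectrum",
    "SiteCall",
    "FilterReport",
    "ORIL_5172",
    "MT_TR_9821",
    "filter_reads",
    "mark_duplicates",
    "reconstruct_window",
    "extract_motif",
    "count_spectrum",
    "heteroplasmy_metrics",
    "pileup_frequencies",
    "classify_site",
    "verify_reference_motif",
]


@dataclass(frozen=True)
class MotifSite:
    """An anchored homopolymer locus.

    ``anchor_position`` is the 1-based coordinate where the anchor run starts;
    the repeat run starts immediately after the anchor base in the reference.
    """

    anchor_base: str
    anchor_position: int
    repeat_base: str
    reference_run_length: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.anchor_base == self.repeat_base:
            raise ValueError("anchor base must differ from repeat base")
        if self.reference_run_length < 1:
            raise ValueError("reference run length must be >= 1")

    @property
    def run_start(self) -> int:
        return self.anchor_position + 1

    @property
    def run_end(self) -> int:
        """Half-open end of the reference repeat run."""
        return self.run_start + self.reference_run_length

    def window(self, slack: int = 6) -> tuple[int, int]:
        """Half-open reference window: one base before the anchor through
        ``slack`` bases past the reference run (room for expanded alleles and
        the terminating non-repeat base)."""
        return self.anchor_position - 1, self.run_end + slack


# Shipped site definitions: OriL poly-A (G anchor at 5171, 11 A) and the
# tRNA-Arg DHU-loop poly-A (T anchor, 8 A near nt 9821).
ORIL_5172 = MotifSite("G", 5171, "A", 11, name="OriL-5172")
MT_TR_9821 = MotifSite("T", 9820, "A", 8, name="mt-Tr-9821")


@dataclass
class MotifObservation:
    read_name: str
    run_length: int
    mean_motif_quality: float
    spanning: bool = True


@dataclass
class LengthSpectrum:
    """Counts and fractions of observed repeat lengths at one site."""

    site: MotifSite
    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[int, float]:
        total = self.total
        if total == 0:
            return {}
        return {length: n / total for length, n in sorted(self.counts.items())}


@dataclass(frozen=True)
class SiteCall:
    position: int
    ref_base: str
    alt_base: str
    alt_frequency: float
    label: str


@dataclass
class FilterReport:
    n_input: int = 0
    n_removed_unpaired: int = 0
    n_removed_quality: int = 0
    n_removed_length: int = 0
    n_retained: int = 0


def filter_reads(
    reads: Sequence[AlignedRead],
    min_mean_quality: float = 30.0,
    min_length: int = 30,
    require_pair: bool = True,
) -> tuple[list[AlignedRead], FilterReport]:
    """Discard reads missing a mate, with mean quality < ``min_mean_quality``,
    or shorter than ``min_length`` bases.  Equality is retained (the discard
    rule is strict '<').  The report counts each violated criterion."""
    report = FilterReport(n_input=len(reads))
    kept: list[AlignedRead] = []
    for read in reads:
        ok = True
        if require_pair and not read.is_paired_complete:
            report.n_removed_unpaired += 1
            ok = False
        if read.mean_quality() < min_mean_quality:
            report.n_removed_quality += 1
            ok = False
        if len(read.bases) < min_length:
            report.n_removed_length += 1
            ok = False
        if ok:
            kept.append(read)
    report.n_retained = len(kept)
    return kept, report


def mark_duplicates(reads: Sequence[AlignedRead]) -> list[AlignedRead]:
    """Set the duplicate flag on all but the best read of each duplicate group.

    The duplicate key is (reference, position, CIGAR text, orientation) — a
    coordinate+structure proxy for PCR-duplicate marking.  Within a group the
    read with the highest summed base quality survives (ties: first seen).
    Returns the same read objects, flags updated in place.
    """
    groups: dict[tuple, list[AlignedRead]] = {}
    for read in reads:
        key = (read.reference_name, read.position, cigar_text(read.cigar), read.is_reverse)
        groups.setdefault(key, []).append(read)
    for members in groups.values():
        best = max(members, key=lambda r: sum(r.qualities))
        for read in members:
            read.is_duplicate = read is not best
    return list(reads)


def reconstruct_window(
    read: AlignedRead, window: tuple[int, int]
) -> tuple[str, tuple[int, ...]] | None:
    """Reconstruct the read's query sequence over a reference window.

    Walks the CIGAR op by op: M/=/X emit query bases at their reference
    coordinates, D emits nothing, I emits its query bases when the insertion
    point lies inside the window (left edge inclusive, right edge exclusive),
    soft/hard clips are excluded.  Returns (sequence, qualities), or None when
    the read does not span the full window.
    """
    start, end = window
    try:
        span = reference_span(read)
    except ValueError:
        return None
    if not (span[0] <= start and span[1] >= end):
        return None
    out_bases: list[str] = []
    out_quals: list[int] = []
    ref = read.position
    qi = 0
    for op in read.cigar:
        if op.op in "M=X":
            for k in range(op.length):
                if start <= ref + k < end:
                    out_bases.append(read.bases[qi + k])
                    out_quals.append(read.qualities[qi + k])
            ref += op.length
            qi += op.length
        elif op.op == "I":
            if start <= ref < end:
                out_bases.append(read.bases[qi : qi + op.length])
                out_quals.extend(read.qualities[qi : qi + op.length])
            qi += op.length
        elif op.op == "D":
            ref += op.length
        elif op.op == "S":
            qi += op.length
        # H consumes nothing
    return "".join(out_bases), tuple(out_quals)


def extract_motif(
    read: AlignedRead,
    site: MotifSite,
    min_motif_quality: float = 20.0,
    slack: int = 6,
) -> tuple[MotifObservation | None, str | None]:
    """Extract the anchored repeat run from one read.

    Reconstructs the window from one base before the anchor through ``slack``
    bases past the reference run, finds the first anchor base, tolerates a run
    of anchor bases ("G+ poly A"), counts the maximal run of the repeat base,
    and requires the terminating non-repeat base to be visible so partially
    spanning reads are censored rather than truncated.  Observations whose
    mean motif quality is below ``min_motif_quality`` are rejected.

    Returns (observation, None) when accepted, else (None, reason) with
    reason in {"not_spanning", "anchor_not_found", "low_quality"}.
    """
    rec = reconstruct_window(read, site.window(slack))
    if rec is None:
        return None, "not_spanning"
    seq, quals = rec
    i = seq.find(site.anchor_base)
    if i < 0:
        return None, "anchor_not_found"
    j = i
    while j < len(seq) and seq[j] == site.anchor_base:
        j += 1
    k = j
    while k < len(seq) and seq[k] == site.repeat_base:
        k += 1
    if k >= len(seq):
        # run reaches the window edge: terminator never observed
        return None, "not_spanning"
    run_length = k - j
    motif_quals = quals[i:k] if k > i else quals[i : i + 1]
    mean_q = sum(motif_quals) / len(motif_quals)
    if mean_q < min_motif_quality:
        return None, "low_quality"
    return MotifObservation(read.name, run_length, mean_q, spanning=True), None


def count_spectrum(
    observations: Iterable[MotifObservation], site: MotifSite
) -> LengthSpectrum:
    """Tally accepted observations into a repeat-length spectrum."""
    counts = Counter(obs.run_length for obs in observations)
    return LengthSpectrum(site=site, counts=dict(counts))


def heteroplasmy_metrics(spectrum: LengthSpectrum) -> dict[str, float]:
    """Per-length fractions plus the aggregate fraction above the reference
    run length (the '>11 A' statistic at OriL).  Keys: 'f_<L>' per observed
    length, 'gt_ref_fraction', and 'f_expanded' (= f at reference length + 1,
    the '12 A heteroplasmy' statistic; 0 when unobserved)."""
    if spectrum.total == 0:
        raise ValueError("empty spectrum")
    fractions = spectrum.fractions
    ref_len = spectrum.site.reference_run_length
    metrics: dict[str, float] = {f"f_{length}": f for length, f in fractions.items()}
    metrics["gt_ref_fraction"] = sum(f for length, f in fractions.items() if length > ref_len)
    metrics["f_expanded"] = fractions.get(ref_len + 1, 0.0)
    return metrics


@dataclass
class PileupResult:
    position: int
    counts: dict[str, int]
    n_below_quality: int
    n_deleted: int

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        depth = self.depth
        if depth == 0:
            return {}
        return {base: n / depth for base, n in sorted(self.counts.items())}


def pileup_frequencies(
    reads: Iterable[AlignedRead], position: int, min_base_quality: int = 30
) -> PileupResult:
    """Per-base counts and frequencies at one reference position.

    Only bases with Phred >= ``min_base_quality`` are counted; deletions
    covering the position are reported separately as depth loss; duplicate
    reads are ignored.
    """
    counts: Counter[str] = Counter()
    below = 0
    deleted = 0
    for read in reads:
        if read.is_duplicate:
            continue
        ref = read.position
        qi = 0
        for op in read.cigar:
            if op.op in "M=X":
                if ref <= position < ref + op.length:
                    off = position - ref
                    if read.qualities[qi + off] >= min_base_quality:
                        counts[read.bases[qi + off]] += 1
                    else:
                        below += 1
                    break
                ref += op.length
                qi += op.length
            elif op.op == "D":
                if ref <= position < ref + op.length:
                    deleted += 1
                    break
                ref += op.length
            elif op.op in "IS":
                qi += op.length
            if ref > position:
                break
    return PileupResult(position=position, counts=dict(counts), n_below_quality=below, n_deleted=deleted)


def classify_site(alt_frequency: float) -> str:
    """Classify a point allele by its alternate-allele frequency.

    > 90% homoplasmic, 40-90% (inclusive) heteroplasmic, below 40% low_level.
    """
    if not 0.0 <= alt_frequency <= 1.0:
        raise ValueError(f"alt frequency {alt_frequency} outside [0, 1]")
    if alt_frequency > 0.90:
        return "homoplasmic"
    if alt_frequency >= 0.40:
        return "heteroplasmic"
    return "low_level"


def verify_reference_motif(reference: str, site: MotifSite) -> int:
    """Measure the repeat run length at ``site`` in a reference sequence.

    ``reference`` is the full-length sequence with index 0 = position 1.
    Checks the anchor base at its stated coordinate and returns the maximal
    run length of the repeat base starting at ``site.run_start``.  Used to
    confirm a site definition (e.g. the 11 A after the G anchor at OriL)
    against a reference assembly.
    """
    if reference[site.anchor_position - 1] != site.anchor_base:
        raise ValueError(
            f"anchor {site.anchor_base!r} not found at position {site.anchor_position}"
        )
    i = site.run_start - 1
    n = 0
    while i + n < len(reference) and reference[i + n] == site.repeat_base:
        n += 1
    return n
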