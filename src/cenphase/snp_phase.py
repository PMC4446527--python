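"""Allele-specific enrichment classification and homolog phasing.

A heterozygous marker (SNP or microsatellite) inside a CENP-A peak carries
phasing information: if the domain sits on only one of the two homologous
chromosomes, immunoprecipitated chromatin is enriched for the allele that
homolog carries (monoallelic); if both homologs are bound at that position,
both alleles appear in the IP (biallelic).  Peaks plus classified markers
are then converted into per-homolog domain intervals.  A single broad peak
whose edge markers are monoallelic in opposite directions while its centre
markers are biallelic is deconvolved into two partially overlapping
domains, one per homolog — the left part of the peak on one homolog, the
right part on the other, overlapping across the biallelic centre.

Quantitative cutoffs (mono_floor, bi_ceiling, alpha) operationalise what a
reader of Sanger traces would call "clearly enriched for one nucleotide":
the band between bi_ceiling and mono_floor is deliberately uninformative to
avoid overcalling.  Sanger trace peak-height ratios can be supplied as
pseudo-counts scaled to a nominal depth.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .peakcall import Peak

__all__ = [
    "MarkerKind",
    "MarkerCall",
    "MarkerObservation",
    "MarkerClass",
    "HomologDomain",
    "PhasingResult",
    "classify_marker",
    "classify_markers",
    "smooth_calls",
    "phase_domains",
    "deconvolve_broad_peak",
    "DEFAULT_ALPHA",
    "DEFAULT_MONO_FLOOR",
    "DEFAULT_BI_CEILING",
]

DEFAULT_ALPHA = 0.01
DEFAULT_MONO_FLOOR = 0.80
DEFAULT_BI_CEILING = 0.65
HET_MINOR_FLOOR = 0.25  # input minor-allele fraction below this → not heterozygous


class MarkerKind(str, enum.Enum):
    SNP = "SNP"
    MICROSATELLITE = "microsatellite"


class MarkerCall(str, enum.Enum):
    MONO_A = "MONO_A"
    MONO_B = "MONO_B"
    BIALLELIC = "BIALLELIC"
    UNINFORMATIVE = "UNINFORMATIVE"

    @property
    def is_mono(self) -> bool:
        return self in (MarkerCall.MONO_A, MarkerCall.MONO_B)


@dataclass
class MarkerObservation:
    """A heterozygous marker with allele counts in input and IP samples.

    For microsatellites the two "alleles" are the two length variants and
    counts are over reads (or trace intensity) supporting each length.
    """

    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    input_a: int
    input_b: int
    ip_a: int
    ip_b: int
    marker_kind: MarkerKind = MarkerKind.SNP
    marker_id: str = ""

    def __post_init__(self) -> None:
        if self.input_a + self.input_b <= 0:
            raise ValueError(f"marker at {self.chrom}:{self.pos} has zero input depth")
        if min(self.input_a, self.input_b, self.ip_a, self.ip_b) < 0:
            raise ValueError("negative allele counts")

    @property
    def input_fraction_a(self) -> float:
        return self.input_a / (self.input_a + self.input_b)


@dataclass
class MarkerClass:
    """Classification of one marker's IP allele balance."""

    call: MarkerCall
    ip_major_fraction: float
    p_vs_balanced: float
    marker: MarkerObservation | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def pos(self) -> int:
        if self.marker is None:
            raise AttributeError("no marker attached")
        return self.marker.pos


@dataclass
class HomologDomain:
    """A CENP-A-bound interval assigned to homolog 1 or 2 of one individual.

    Homolog labels are a within-individual convention (homolog 1 =
    leftmost domain); true haplotype linkage across separated peaks is not
    assumed.
    """

    individual_id: str
    homolog: int
    chrom: str
    start: int
    end: int
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.homolog not in (1, 2):
            raise ValueError("homolog must be 1 or 2")
        if self.end <= self.start:
            raise ValueError("domain end must exceed start")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PhasingResult:
    """Outcome of converting peaks + markers into per-homolog domains."""

    domains: list[HomologDomain]
    structure_call: str
    overlap_interval: tuple[int, int] | None = None
    flags: list[str] = field(default_factory=list)


def classify_marker(
    m: MarkerObservation,
    alpha: float = DEFAULT_ALPHA,
    mono_floor: float = DEFAULT_MONO_FLOOR,
    bi_ceiling: float = DEFAULT_BI_CEILING,
) -> MarkerClass:
    """Classify one marker's IP allele balance.

    The marker must first look heterozygous in input: an exact two-sided
    binomial test of the input counts against 0.5 must not reject at
    ``alpha`` and the input minor-allele fraction must be at least 0.25.
    Then:

    * MONO_A / MONO_B — the IP major-allele fraction is >= ``mono_floor``
      and an exact two-sided binomial test of the IP counts against the
      input allele fraction rejects at ``alpha``;
    * BIALLELIC — the IP major fraction is strictly below ``bi_ceiling``;
    * UNINFORMATIVE — anything in between, failed heterozygosity, or zero
      IP depth (flagged, never an error).
    """
    n_in = m.input_a + m.input_b
    p_het = stats.binomtest(m.input_a, n_in, 0.5).pvalue
    minor_in = min(m.input_a, m.input_b) / n_in
    if p_het < alpha or minor_in < HET_MINOR_FLOOR:
        return MarkerClass(
            MarkerCall.UNINFORMATIVE, float("nan"), p_het, m, ["not_heterozygous"]
        )

    n_ip = m.ip_a + m.ip_b
    if n_ip == 0:
        return MarkerClass(
            MarkerCall.UNINFORMATIVE, float("nan"), 1.0, m, ["zero_ip_depth"]
        )

    frac_a = m.ip_a / n_ip
    major_fraction = max(frac_a, 1.0 - frac_a)
    p_skew = stats.binomtest(m.ip_a, n_ip, m.input_fraction_a).pvalue

    if major_fraction >= mono_floor and p_skew < alpha:
        call = MarkerCall.MONO_A if frac_a >= 0.5 else MarkerCall.MONO_B
        return MarkerClass(call, major_fraction, p_skew, m)
    # the band [bi_ceiling, mono_floor) is deliberately uninformative
    if major_fraction < bi_ceiling:
        return MarkerClass(MarkerCall.BIALLELIC, major_fraction, p_skew, m)
    return MarkerClass(MarkerCall.UNINFORMATIVE, major_fraction, p_skew, m)


def classify_markers(
    markers: list[MarkerObservation],
    alpha: float = DEFAULT_ALPHA,
    mono_floor: float = DEFAULT_MONO_FLOOR,
    bi_ceiling: float = DEFAULT_BI_CEILING,
) -> list[MarkerClass]:
    """Classify a list of markers, returned sorted by position."""
    out = [classify_marker(m, alpha, mono_floor, bi_ceiling) for m in markers]
    out.sort(key=lambda c: c.marker.pos)
    return out


def _symbol(call: MarkerCall) -> str:
    """Collapse a call to its phasing-relevant symbol: M (monoallelic,
    either direction — allele labels carry no haplotype information) or B
    (biallelic)."""
    return "M" if call.is_mono else "B"


def smooth_calls(calls: list[MarkerClass]) -> list[MarkerClass]:
    """Reclassify one isolated discordant monoallelic call surrounded by a
    biallelic consensus of at least three informative markers.

    Robustness against single-marker sequencing noise.  Smoothing is
    deliberately one-sided: allele dropout and preferential amplification
    create spurious *monoallelic* reads at a truly biallelic site, whereas
    a spurious *biallelic* read at a truly monoallelic site would require
    half the signal to come from the unbound homolog — so an isolated
    BIALLELIC call is kept (it may mark a minimal overlap centre).
    UNINFORMATIVE calls are ignored by (and never produced by) smoothing.
    """
    informative = [c for c in calls if c.call is not MarkerCall.UNINFORMATIVE]
    if len(informative) < 4:
        return calls
    seq = [_symbol(c.call) for c in informative]
    for i in range(1, len(seq) - 1):
        if seq[i] == "M" and seq[i - 1] == "B" and seq[i + 1] == "B":
            # neighbourhood consensus: require >=3 agreeing among the 4
            # nearest informative markers
            window = seq[max(0, i - 2) : i] + seq[i + 1 : i + 3]
            if len(window) >= 3 and all(s == "B" for s in window):
                old = informative[i]
                informative[i] = MarkerClass(
                    MarkerCall.BIALLELIC,
                    old.ip_major_fraction,
                    old.p_vs_balanced,
                    old.marker,
                    old.flags + ["smoothed"],
                )
                seq[i] = "B"
    smoothed_iter = iter(informative)
    return [
        c if c.call is MarkerCall.UNINFORMATIVE else next(smoothed_iter) for c in calls
    ]


def _peak_markers(peak: Peak, calls: list[MarkerClass]) -> list[MarkerClass]:
    return [c for c in calls if peak.start <= c.marker.pos < peak.end]


def _has_edge_centre_pattern(calls: list[MarkerClass]) -> bool:
    informative = [c for c in calls if c.call is not MarkerCall.UNINFORMATIVE]
    return _match_mono_bi_mono([c.call for c in informative]) is not None


def _match_mono_bi_mono(kinds: list[MarkerCall]) -> tuple[int, int] | None:
    """If the symbol sequence is MONO+ BIALLELIC+ MONO+ return the index
    range [i, j) of the biallelic block; else None.

    Mono direction is ignored: which nucleotide is enriched at each marker
    depends on arbitrary allele labelling, not on the homolog, so only the
    monoallelic/biallelic dichotomy is positional evidence.
    """
    symbols = "".join(_symbol(k) for k in kinds)
    n = len(symbols)
    i = symbols.find("B")
    if i <= 0:
        return None
    j = i
    while j < n and symbols[j] == "B":
        j += 1
    if j == n or "B" in symbols[j:]:
        return None
    return (i, j)


def deconvolve_broad_peak(
    peak: Peak,
    ordered_calls: list[MarkerClass],
    individual_id: str = "sample",
) -> tuple[HomologDomain, HomologDomain, tuple[int, int]]:
    """Split a single broad peak into two partially overlapping per-homolog
    domains using the edge-mono / centre-biallelic marker pattern.

    The biallelic segment boundaries are the midpoints between the
    outermost BIALLELIC markers and their flanking MONO markers.  The
    homolog-1 domain runs from the peak start to the biallelic segment end,
    the homolog-2 domain from the biallelic segment start to the peak end;
    the overlap is the biallelic segment itself.
    """
    calls = smooth_calls(sorted(ordered_calls, key=lambda c: c.marker.pos))
    informative = [c for c in calls if c.call is not MarkerCall.UNINFORMATIVE]
    kinds = [c.call for c in informative]
    span = _match_mono_bi_mono(kinds)
    if span is None:
        raise ValueError(
            "marker pattern is not MONO+ BIALLELIC+ MONO+ with opposite edges; "
            "fall back to phase_domains"
        )
    i, j = span
    left_mono = informative[i - 1]
    first_bi = informative[i]
    last_bi = informative[j - 1]
    right_mono = informative[j]
    ov_start = int(round((left_mono.marker.pos + first_bi.marker.pos) / 2))
    ov_end = int(round((last_bi.marker.pos + right_mono.marker.pos) / 2))

    evidence = {
        "peak": (peak.start, peak.end),
        "markers": [c.marker.marker_id or c.marker.pos for c in informative],
    }
    d1 = HomologDomain(individual_id, 1, peak.chrom, peak.start, ov_end, dict(evidence))
    d2 = HomologDomain(individual_id, 2, peak.chrom, ov_start, peak.end, dict(evidence))
    return d1, d2, (ov_start, ov_end)


def phase_domains(
    peaks: list[Peak],
    marker_classes: list[MarkerClass],
    individual_id: str = "sample",
) -> PhasingResult:
    """Convert peaks plus classified markers into per-homolog domains.

    Decision cases (every marker must lie within a peak; mono direction is
    never compared across markers since allele labels carry no haplotype
    information):

    * two peaks, each with monoallelic markers only → one domain per peak
      on different homologs, homolog 1 = leftmost
      (``one_domain_per_homolog``);
    * two peaks, biallelic markers in both → both peaks present on both
      homologs (``shared_multidomain``, four domain records);
    * one peak, all markers monoallelic → a single domain on one homolog
      (``single_domain_one_homolog``);
    * one peak, edge-mono/centre-biallelic pattern → broad-peak
      deconvolution (``one_domain_per_homolog`` with an overlap interval);
    * anything else (evidence matching no recognised structure) →
      ``inconsistent``, no domains.
    """
    peaks = sorted(peaks, key=lambda p: p.start)
    calls = classify_ready = sorted(marker_classes, key=lambda c: c.marker.pos)
    for c in calls:
        if not any(p.start <= c.marker.pos < p.end for p in peaks):
            raise ValueError(
                f"marker at {c.marker.pos} lies outside every peak"
            )
    calls = smooth_calls(classify_ready)

    if len(peaks) == 2:
        per_peak = [_peak_markers(p, calls) for p in peaks]
        informative = [
            [c for c in pm if c.call is not MarkerCall.UNINFORMATIVE]
            for pm in per_peak
        ]
        if any(len(pm) == 0 for pm in informative):
            return PhasingResult([], "inconsistent", None, ["peak_without_markers"])
        all_mono = all(all(c.call.is_mono for c in pm) for pm in informative)
        if all_mono:
            domains = [
                HomologDomain(
                    individual_id,
                    h,
                    p.chrom,
                    p.start,
                    p.end,
                    {"peak": (p.start, p.end), "n_mono_markers": len(pm)},
                )
                for h, (p, pm) in enumerate(zip(peaks, informative), start=1)
            ]
            return PhasingResult(domains, "one_domain_per_homolog")
        all_bi = all(
            all(c.call is MarkerCall.BIALLELIC for c in pm) for pm in informative
        )
        if all_bi:
            domains = [
                HomologDomain(
                    individual_id, h, p.chrom, p.start, p.end, {"peak": (p.start, p.end)}
                )
                for p in peaks
                for h in (1, 2)
            ]
            return PhasingResult(domains, "shared_multidomain")
        return PhasingResult([], "inconsistent", None, ["mixed_evidence_two_peaks"])

    if len(peaks) == 1:
        peak = peaks[0]
        pm = [c for c in calls if c.call is not MarkerCall.UNINFORMATIVE]
        if not pm:
            return PhasingResult([], "inconsistent", None, ["no_informative_markers"])
        if all(c.call.is_mono for c in pm):
            d = HomologDomain(
                individual_id,
                1,
                peak.chrom,
                peak.start,
                peak.end,
                {"peak": (peak.start, peak.end), "n_mono_markers": len(pm)},
            )
            return PhasingResult([d], "single_domain_one_homolog")
        if _has_edge_centre_pattern(pm):
            d1, d2, ov = deconvolve_broad_peak(peak, pm, individual_id)
            return PhasingResult([d1, d2], "one_domain_per_homolog", ov)
        if all(c.call is MarkerCall.BIALLELIC for c in pm):
            domains = [
                HomologDomain(
                    individual_id, h, peak.chrom, peak.start, peak.end,
                    {"peak": (peak.start, peak.end)},
                )
                for h in (1, 2)
            ]
            return PhasingResult(domains, "shared_multidomain")
        return PhasingResult([], "inconsistent", None, ["mixed_evidence_one_peak"])

    if len(peaks) == 0:
        return PhasingResult([], "no_peaks")
    return PhasingResult([], "unresolved", None, ["more_than_two_peaks"])
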