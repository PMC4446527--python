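"""Epiallele cataloguing and fibre-FISH pattern cross-validation.

Per-homolog CENP-A domains pooled across individuals are clustered into
positional "epialleles" — equivalence classes of domains occupying the
same genomic position — by single-linkage clustering under the relation
"reciprocal overlap >= threshold".  Labels follow the convention of
naming each domain by its individual's letter plus ``a``/``b`` for the
two homologs, joining shared entries ("Da/Eb").  Single-linkage lets a
chain of near-identical alleles collapse into one entry, so the reported
count is a lower bound on the number of distinct epialleles.

Fibre observations — intervals of CENP-A immunostaining (CREST) and of a
BAC FISH probe on single stretched chromatin fibres — are classified as
SUPERIMPOSED (staining inside the BAC), FLANKING (staining beside the
BAC), PARTIAL (partial overlap) or UNSCORABLE, and the two per-homolog
patterns are tallied against a balanced 50/50 expectation with an exact
binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .intervals import overlap_length, reciprocal_overlap
from .simulate import FibreObservation
from .snp_phase import HomologDomain

__all__ = [
    "EpialleleEntry",
    "EpialleleCatalog",
    "FibreTally",
    "match_domains",
    "domain_label",
    "classify_fibre",
    "classify_fibres",
    "tally_fibres",
    "DEFAULT_MIN_RECIPROCAL_OVERLAP",
    "DEFAULT_COVER_FLOOR",
    "DEFAULT_GAP_TOLERANCE",
]

DEFAULT_MIN_RECIPROCAL_OVERLAP = 0.7
DEFAULT_COVER_FLOOR = 0.8
DEFAULT_GAP_TOLERANCE = 10_000  # fibre-local bp, post stretch-normalisation

FLANKING = "FLANKING"
SUPERIMPOSED = "SUPERIMPOSED"
PARTIAL = "PARTIAL"
UNSCORABLE = "UNSCORABLE"


@dataclass
class EpialleleEntry:
    label: str
    representative: tuple[int, int]
    members: list[HomologDomain]


@dataclass
class EpialleleCatalog:
    entries: list[EpialleleEntry]
    min_reciprocal_overlap: float

    @property
    def n_distinct(self) -> int:
        return len(self.entries)

    def labels(self) -> list[str]:
        return [e.label for e in self.entries]


def domain_label(d: HomologDomain) -> str:
    """Individual letter + a/b homolog suffix (e.g. ``HSF-D`` homolog 2 →
    ``Db``)."""
    letter = d.individual_id.split("-")[-1][:1] or d.individual_id
    return f"{letter}{'a' if d.homolog == 1 else 'b'}"


def match_domains(
    domains: list[HomologDomain],
    min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
) -> EpialleleCatalog:
    """Cluster per-homolog domains into an epiallele catalogue.

    Single-linkage: two domains join the same entry if connected by a
    chain of pairs each with reciprocal overlap >= the threshold.  Entries
    are labelled by their members (sorted by start, joined with ``/``) and
    the catalogue is ordered by representative start, so output is
    deterministic and permutation-invariant.
    """
    if not 0 < min_reciprocal_overlap <= 1:
        raise ValueError("min_reciprocal_overlap must be in (0, 1]")
    if not domains:
        return EpialleleCatalog([], min_reciprocal_overlap)
    chroms = {d.chrom for d in domains}
    if len(chroms) > 1:
        raise ValueError(f"domains span multiple chromosomes: {sorted(chroms)}")

    order = sorted(range(len(domains)), key=lambda i: (domains[i].start, domains[i].end))
    parent = list(range(len(domains)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for ai in range(len(order)):
        for bi in range(ai + 1, len(order)):
            i, j = order[ai], order[bi]
            if domains[j].start >= domains[i].end:
                break  # sorted by start: no later domain can overlap i
            if (
                reciprocal_overlap(domains[i].interval, domains[j].interval)
                >= min_reciprocal_overlap
            ):
                union(i, j)

    clusters: dict[int, list[HomologDomain]] = {}
    for i, d in enumerate(domains):
        clusters.setdefault(find(i), []).append(d)

    entries = []
    for members in clusters.values():
        members = sorted(members, key=lambda d: (d.start, d.end, d.individual_id))
        rep = (min(d.start for d in members), max(d.end for d in members))
        # labels list members in cohort order (individual letter, homolog),
        # the convention the published catalogue uses (e.g. "Da/Eb")
        label = "/".join(
            domain_label(d)
            for d in sorted(members, key=lambda d: (d.individual_id, d.homolog))
        )
        entries.append(EpialleleEntry(label, rep, members))
    entries.sort(key=lambda e: e.representative)
    return EpialleleCatalog(entries, min_reciprocal_overlap)


def classify_fibre(
    crest_intervals: list[tuple[float, float]],
    bac_interval: tuple[float, float],
    gap_tolerance: float = DEFAULT_GAP_TOLERANCE,
    cover_floor: float = DEFAULT_COVER_FLOOR,
) -> str:
    """Classify one fibre's CENP-A staining against the BAC FISH signal.

    SUPERIMPOSED — at least ``cover_floor`` of the staining length falls
    inside the BAC; FLANKING — at most ``1 - cover_floor`` overlaps and
    the nearest edges are within ``gap_tolerance``; PARTIAL — anything in
    between; UNSCORABLE — disjoint signals farther apart than
    ``gap_tolerance``.
    """
    if not crest_intervals:
        raise ValueError("at least one CREST interval required")
    total = sum(e - s for s, e in crest_intervals)
    inside = sum(overlap_length(iv, bac_interval) for iv in crest_intervals)
    frac = inside / total if total > 0 else 0.0

    if frac >= cover_floor:
        return SUPERIMPOSED
    gap = min(
        max(bac_interval[0] - e, s - bac_interval[1], 0.0)
        for s, e in crest_intervals
    )
    if frac <= 1 - cover_floor:
        if inside == 0 and gap > gap_tolerance:
            return UNSCORABLE
        if gap <= gap_tolerance:
            return FLANKING
        return UNSCORABLE
    return PARTIAL


def classify_fibres(
    observations: list[FibreObservation],
    gap_tolerance: float = DEFAULT_GAP_TOLERANCE,
    cover_floor: float = DEFAULT_COVER_FLOOR,
) -> list[FibreObservation]:
    """Assign a pattern to each observation (in place) and return them."""
    for obs in observations:
        obs.pattern = classify_fibre(
            obs.crest_intervals, obs.bac_interval, gap_tolerance, cover_floor
        )
    return observations


@dataclass
class FibreTally:
    pattern_a: str
    pattern_b: str
    count_a: int
    count_b: int
    proportion: float
    p_vs_balanced: float
    n_scorable: int = 0


def tally_fibres(observations: list[FibreObservation]) -> FibreTally:
    """Tally the two epiallele patterns across fibres of one individual.

    Counts the two most frequent scorable pattern classes and tests the
    split against a balanced 50/50 sampling of the two homologs with an
    exact two-sided binomial test.
    """
    scorable = [o for o in observations if o.pattern and o.pattern != UNSCORABLE]
    if not scorable:
        raise ValueError("no scorable fibre observations")
    counts: dict[str, int] = {}
    for o in scorable:
        counts[o.pattern] = counts.get(o.pattern, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    pat_a, n_a = ranked[0]
    pat_b, n_b = ranked[1] if len(ranked) > 1 else ("(none)", 0)
    n = n_a + n_b
    p = stats.binomtest(n_a, n, 0.5).pvalue if n > 0 else 1.0
    return FibreTally(pat_a, pat_b, n_a, n_b, n_a / n, min(p, 1.0), len(scorable))
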