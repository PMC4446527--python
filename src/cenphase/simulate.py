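"""Synthetic diploid cohorts with planted per-homolog CENP-A domains.

The generator emulates the observable data of a ChIP-on-chip study of a
satellite-free centromere in a diploid organism: a ~3.2 Mb tiling-array
region at ~100 bp probe resolution, within which each individual carries
one CENP-A binding domain of ~80-160 kb per homologous chromosome, both
placed inside a ~500 kb placement window.  From a planted ground truth it
derives every downstream observable:

* probe-level log2(IP/input) tracks with Gaussian noise,
* heterozygous-marker allele depths in input (~50/50) and IP (skewed
  toward the allele of whichever homolog is bound at that position),
* qPCR Ct panels with triplicates and standard dilution curves,
* fibre-FISH interval observations (CENP-A immunostaining vs BAC probe)
  with multiplicative stretch noise.

Occupancy model: a probe's expected ratio is 0 where no homolog is bound,
``enrichment_amplitude`` where exactly one is, and ``amplitude + 1`` log2
units where both are (twice the bound DNA, since IP yield is proportional
to bound-copy count — not 2x the amplitude).  The IP fraction of the bound
homolog's allele at a marker inside exactly one homolog's domain defaults
to 0.95 rather than 1.0, modelling antibody background.

All randomness descends from one root seed through named child streams
(individual → probes / markers / fibres / qPCR), so sub-experiments are
individually reproducible.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, overlap_length, reciprocal_overlap
from .peakcall import ProbeTrack
from .snp_phase import MarkerKind, MarkerObservation

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CohortGroundTruth",
    "QpcrExperiment",
    "FibreObservation",
    "simulate_individual",
    "simulate_cohort",
    "simulate_qpcr",
    "simulate_fibres",
    "DEFAULT_CHROM",
]

DEFAULT_CHROM = "chr11"

# Stylised seven-epiallele layout reproducing the observed cohort's sharing
# and overlap structure (synthetic coordinates, not measured positions):
# with the assignment B:{a,b} C:{c,d} D:{e,f} E:{a,e} G:{f,g}, individuals
# B, C and G carry well-separated domain pairs (two array peaks) while D
# (e+f) and E (a+e) carry partially overlapping pairs (one broad peak each),
# and all seven members stay pairwise below the 0.7 identity overlap.
PUBLISHED_EPIALLELE_LAYOUT: list[tuple[int, int]] = [
    (27_480_000, 27_600_000),  # a
    (27_780_000, 27_900_000),  # b
    (27_415_000, 27_530_000),  # c
    (27_700_000, 27_820_000),  # d
    (27_560_000, 27_680_000),  # e (overlaps a by 40 kb)
    (27_635_000, 27_755_000),  # f (overlaps e by 45 kb)
    (27_850_000, 27_970_000),  # g
]
PUBLISHED_ASSIGNMENT: list[tuple[int, int]] = [(0, 1), (2, 3), (4, 5), (0, 4), (5, 6)]

# array region ECA11:25,566,599-28,305,611 (1-based inclusive) → 0-based
_REGION_START = 25_566_598
_REGION_END = 28_305_611
# domains scatter across a ~500 kb window inside the ~750 kb centromeric
# segment chr11:27,400,000-28,150,000
_WINDOW_START = 27_400_000
_WINDOW_END = 27_900_000


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the emulated experiment.

    Defaults reproduce the published study conditions: a 3.2 Mb tiling
    region at 100 bp resolution, 80-160 kb domains inside a 500 kb window,
    and an anti-CENP-A enrichment of 1.5 log2 units.  Probe noise (0.3 log2
    units) and marker depths (200) are generator choices, not measured
    array properties.
    """

    region_start: int = _REGION_START
    region_end: int = _REGION_END
    probe_spacing: int = 100
    domain_width_range: tuple[int, int] = (80_000, 160_000)
    placement_window: tuple[int, int] = (_WINDOW_START, _WINDOW_END)
    enrichment_amplitude: float = 1.5
    noise_sd: float = 0.3
    snp_density: float = 1.0 / 10_000
    input_depth: int = 200
    ip_depth: int = 200
    n_fibres: int = 10
    mono_ip_fraction: float = 0.95  # antibody background leaves ~5% of the other allele
    boundary_jitter: int = 5_000
    # the two homolog domains are either clearly separated or partially
    # overlapping with a resolvable shared centre, the two configurations
    # the cohort design emulates; sub-resolution gaps/overlaps are excluded.
    # margins are pre-jitter, so they exceed marker resolution (10 kb) plus
    # the worst-case boundary jitter (2 x 5 kb)
    min_domain_separation: int = 30_000
    min_overlap_centre: int = 20_000
    max_within_individual_overlap: float = 0.30  # reciprocal overlap cap
    chrom: str = DEFAULT_CHROM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_end <= self.region_start:
            raise ValueError("region_end must exceed region_start")
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be positive")
        lo, hi = self.domain_width_range
        w_start, w_end = self.placement_window
        if not 0 < lo <= hi:
            raise ValueError("invalid domain_width_range")
        if hi > w_end - w_start:
            raise ValueError(
                "placement_window too small for requested domain width"
            )
        if not (self.region_start <= w_start < w_end <= self.region_end):
            raise ValueError("placement_window must lie within the region")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.input_depth <= 0 or self.ip_depth <= 0:
            raise ValueError("depths must be positive")
        if not 0.5 < self.mono_ip_fraction <= 1.0:
            raise ValueError("mono_ip_fraction must be in (0.5, 1]")


@dataclass
class GroundTruth:
    """Planted truth for one individual: one domain per homolog plus the
    phase (homolog of origin) of each marker allele."""

    individual_id: str
    domains: list[tuple[int, int, int]]  # (homolog, start, end)
    snp_phase: dict[int, int] = field(default_factory=dict)  # pos → homolog of allele a
    pool_membership: dict[int, int] = field(default_factory=dict)  # homolog → pool index

    def domain_of(self, homolog: int) -> tuple[int, int]:
        for h, s, e in self.domains:
            if h == homolog:
                return (s, e)
        raise KeyError(f"no domain for homolog {homolog}")

    def occupancy(self, pos: float) -> int:
        """Number of homologs (0, 1 or 2) bound at this position."""
        return sum(1 for _, s, e in self.domains if s <= pos < e)

    def bound_homologs(self, pos: float) -> list[int]:
        return [h for h, s, e in self.domains if s <= pos < e]


@dataclass
class CohortGroundTruth:
    pool: list[tuple[int, int]]
    individuals: list[GroundTruth]


@dataclass
class QpcrExperiment:
    """Ct measurements for a primer panel, IP vs input, with triplicates
    and per-amplicon standard dilution curves."""

    measurements: list[tuple[tuple[int, int], str, int, float]]  # (amplicon, sample, rep, Ct)
    control_amplicon: tuple[int, int]
    standard_curves: dict[tuple[int, int], list[tuple[float, float]]] = field(
        default_factory=dict
    )


@dataclass
class FibreObservation:
    """Intervals measured on one stretched chromatin fibre, in fibre-local
    bp: CENP-A immunostaining segment(s) and the BAC FISH signal."""

    fibre_id: str
    crest_intervals: list[tuple[float, float]]
    bac_interval: tuple[float, float]
    true_homolog: int = 0
    pattern: str = ""


def _streams(seed: int, *keys: int) -> np.random.Generator:
    """Child generator derived from a root seed and a path of stream keys."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(keys)))


def _draw_domain(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[int, int]:
    lo, hi = config.domain_width_range
    width = int(rng.integers(lo, hi + 1))
    w_start, w_end = config.placement_window
    start = int(rng.integers(w_start, w_end - width + 1))
    return start, start + width


def _jitter_domain(
    rng: np.random.Generator, domain: tuple[int, int], config: SimulationConfig
) -> tuple[int, int]:
    j = config.boundary_jitter
    if j <= 0:
        return domain
    s = domain[0] + int(rng.integers(-j, j + 1))
    e = domain[1] + int(rng.integers(-j, j + 1))
    s = max(config.region_start, s)
    e = min(config.region_end, e)
    if e - s < 1000:  # degenerate after clipping; keep the original
        return domain
    return s, e


def _acceptable_pair(
    d1: tuple[int, int], d2: tuple[int, int], config: SimulationConfig
) -> bool:
    """Whether two homolog domains form one of the emulated configurations:
    clearly separated, or partially overlapping with a resolvable centre."""
    a, b = sorted((d1, d2))
    gap = b[0] - a[1]
    if gap >= config.min_domain_separation:
        return True
    ov = overlap_length(a, b)
    return (
        ov >= config.min_overlap_centre
        and reciprocal_overlap(a, b) <= config.max_within_individual_overlap
    )


def simulate_individual(
    config: SimulationConfig,
    epiallele_pool: list[tuple[int, int]] | None = None,
    individual_id: str = "sim",
    pool_choice: tuple[int, int] | None = None,
    individual_index: int = 0,
) -> tuple[ProbeTrack, list[MarkerObservation], GroundTruth]:
    """Simulate one diploid individual.

    Plants one domain per homolog — drawn fresh, or from ``epiallele_pool``
    (jittered by ``config.boundary_jitter``) when a pool is given — then
    derives the probe track and marker allele depths.
    """
    rng_place = _streams(config.seed, individual_index, 0)
    rng_probe = _streams(config.seed, individual_index, 1)
    rng_marker = _streams(config.seed, individual_index, 2)

    if epiallele_pool is not None:
        if pool_choice is None:
            for _ in range(1000):
                idx = rng_place.choice(len(epiallele_pool), size=2, replace=False)
                pool_choice = (int(idx[0]), int(idx[1]))
                if _acceptable_pair(
                    epiallele_pool[pool_choice[0]], epiallele_pool[pool_choice[1]], config
                ):
                    break
        tagged = [
            (_jitter_domain(rng_place, epiallele_pool[i], config), i)
            for i in pool_choice
        ]
    else:
        for _ in range(1000):
            tagged = [(_draw_domain(rng_place, config), -1) for _ in range(2)]
            if _acceptable_pair(tagged[0][0], tagged[1][0], config):
                break
        else:
            raise ValueError("could not place an acceptable domain pair")
    # homolog 1 = leftmost domain, matching the phasing labelling convention
    tagged.sort(key=lambda t: t[0])
    doms = [t[0] for t in tagged]
    membership = {
        h: t[1] for h, t in enumerate(tagged, start=1) if t[1] >= 0
    }
    truth = GroundTruth(
        individual_id,
        [(1, doms[0][0], doms[0][1]), (2, doms[1][0], doms[1][1])],
        pool_membership=membership,
    )

    positions = np.arange(config.region_start, config.region_end, config.probe_spacing)
    expected = np.zeros(positions.size)
    for _, s, e in truth.domains:
        expected[(positions >= s) & (positions < e)] += 1.0
    # occupancy → log2 ratio: 0 → 0; 1 → amplitude; 2 → amplitude + 1
    ratios = np.where(
        expected == 0,
        0.0,
        config.enrichment_amplitude + np.log2(np.maximum(expected, 1.0)),
    )
    if config.noise_sd > 0:
        ratios = ratios + rng_probe.normal(0.0, config.noise_sd, size=ratios.size)
    track = ProbeTrack(config.chrom, positions, ratios, individual_id)

    # markers sit on a regular grid (random offset): the study design seeks
    # informative heterozygous positions spanning the whole region, so
    # marker coverage is deliberate, not a random scatter
    spacing = int(round(1.0 / config.snp_density))
    offset = int(rng_marker.integers(0, spacing))
    marker_pos = np.arange(
        config.region_start + offset, config.region_end, spacing
    )
    markers: list[MarkerObservation] = []
    for k, pos in enumerate(marker_pos.tolist()):
        phase_a = int(rng_marker.integers(1, 3))  # homolog carrying allele a
        truth.snp_phase[pos] = phase_a
        bound = truth.bound_homologs(pos)
        if len(bound) == 1:
            p_ip_a = (
                config.mono_ip_fraction
                if bound[0] == phase_a
                else 1.0 - config.mono_ip_fraction
            )
        else:  # neither or both homologs bound → balanced IP
            p_ip_a = 0.5
        input_a = int(rng_marker.binomial(config.input_depth, 0.5))
        ip_a = int(rng_marker.binomial(config.ip_depth, p_ip_a))
        markers.append(
            MarkerObservation(
                chrom=config.chrom,
                pos=int(pos),
                allele_a="A",
                allele_b="B",
                input_a=input_a,
                input_b=config.input_depth - input_a,
                ip_a=ip_a,
                ip_b=config.ip_depth - ip_a,
                marker_kind=MarkerKind.SNP,
                marker_id=f"{individual_id}_m{k}",
            )
        )
    return track, markers, truth


_POOL_MAX_RO = 0.55  # distinct pool members must stay well below the 0.7
# reciprocal-overlap identity threshold even after jitter


def _generate_pool(
    rng: np.random.Generator, pool_size: int, config: SimulationConfig
) -> list[tuple[int, int]]:
    """Distinct epiallele intervals tiled across the placement window.

    Pool members are anchored on an even grid with random widths and
    positional jitter — the observed cohort's alleles likewise spread
    across the whole window — and must stay pairwise distinguishable
    (reciprocal overlap <= 0.55).  For large pools crowding the window,
    neighbouring members necessarily overlap partially, exactly as the
    observed partially-overlapping alleles do.
    """
    w_start, w_end = config.placement_window
    span = w_end - w_start
    lo, hi = config.domain_width_range
    best: list[tuple[int, int]] | None = None
    best_ro = np.inf
    for _ in range(300):
        widths = rng.integers(lo, hi + 1, size=pool_size)
        pool = []
        for i, w in enumerate(widths.tolist()):
            if pool_size == 1:
                anchor = w_start + (span - w) // 2
            else:
                anchor = w_start + round(i * (span - w) / (pool_size - 1))
            jit = int(rng.integers(-span // (3 * pool_size), span // (3 * pool_size) + 1))
            s = min(max(w_start, anchor + jit), w_end - w)
            pool.append((int(s), int(s + w)))
        max_ro = max(
            (
                reciprocal_overlap(pool[i], pool[j])
                for i in range(pool_size)
                for j in range(i + 1, pool_size)
            ),
            default=0.0,
        )
        if max_ro < best_ro:
            best, best_ro = pool, max_ro
        if max_ro <= _POOL_MAX_RO:
            return pool
    assert best is not None
    return best


def _draw_assignment(
    rng: np.random.Generator,
    pool: list[tuple[int, int]],
    n_individuals: int,
    allow_hom: bool,
    config: SimulationConfig,
) -> list[tuple[int, int]]:
    """Deal pool indices into per-individual pairs so that every pool
    member is carried by at least one individual and every pair forms an
    acceptable configuration (see ``_acceptable_pair``)."""
    k = len(pool)
    best: list[tuple[int, int]] | None = None

    def ok(pairs: list[tuple[int, int]]) -> bool:
        if not allow_hom and any(a == b for a, b in pairs):
            return False
        return all(
            _acceptable_pair(pool[a], pool[b], config) for a, b in pairs if a != b
        )

    for _ in range(500):
        slots = list(range(k)) + [int(rng.integers(0, k)) for _ in range(2 * n_individuals - k)]
        rng.shuffle(slots)
        pairs = [(slots[2 * i], slots[2 * i + 1]) for i in range(n_individuals)]
        if allow_hom or all(a != b for a, b in pairs):
            best = pairs
        if ok(pairs):
            return pairs
    # deterministic fallback: pair each member with the one roughly half the
    # pool away — for pools tiling the window, distant members are always
    # acceptably separated — then fill remaining slots the same way
    for h in range(max(2, k // 2), k):
        pairs = [((2 * i) % k, (2 * i + h) % k) for i in range(n_individuals)]
        covered = {x for p in pairs for x in p}
        if len(covered) == k and ok(pairs):
            return pairs
    if best is None:
        raise ValueError("could not assign pool members to individuals")
    return best


def simulate_cohort(
    config: SimulationConfig,
    n_individuals: int = 5,
    pool_size: int = 7,
    sharing: str = "heterozygous",
    assignment: list[tuple[int, int]] | None = None,
    pool: list[tuple[int, int]] | None = None,
) -> tuple[list[tuple[ProbeTrack, list[MarkerObservation], GroundTruth]], CohortGroundTruth]:
    """Simulate a cohort sharing epialleles from a common pool.

    A pool of ``pool_size`` distinct intervals is generated once; each
    individual's two homolog domains are drawn from the pool — with
    replacement across individuals, without replacement within an
    individual unless ``sharing == "allow_homozygous"``.  ``assignment``
    fixes each individual's (pool index, pool index) pair and ``pool``
    supplies explicit intervals; together they reproduce a prescribed
    cohort structure such as ``PUBLISHED_EPIALLELE_LAYOUT`` with
    ``PUBLISHED_ASSIGNMENT``.  Individual ids are letters B, C, D, E,
    G, ... mirroring the study's naming.
    """
    if pool_size > 2 * n_individuals:
        raise ValueError("pool_size must be at most 2 * n_individuals")
    allow_hom = sharing == "allow_homozygous"
    if pool_size < 2 and not allow_hom:
        raise ValueError("pool_size < 2 requires allow_homozygous sharing")

    if pool is None:
        rng_pool = _streams(config.seed, 10_000)
        pool = _generate_pool(rng_pool, pool_size, config)
    elif len(pool) != pool_size:
        raise ValueError("explicit pool must have pool_size members")

    labels = [c for c in string.ascii_uppercase if c not in "AF"]  # B, C, D, E, G, ...
    rng_assign = _streams(config.seed, 10_001)
    if assignment is None:
        assignment = _draw_assignment(
            rng_assign, pool, n_individuals, allow_hom, config
        )

    results = []
    truths = []
    for i in range(n_individuals):
        ind_id = f"HSF-{labels[i]}" if i < len(labels) else f"HSF-{i}"
        trip = simulate_individual(
            config,
            epiallele_pool=pool,
            individual_id=ind_id,
            pool_choice=tuple(assignment[i]),
            individual_index=i,
        )
        results.append(trip)
        truths.append(trip[2])
    cohort = CohortGroundTruth(pool=pool, individuals=truths)
    return results, cohort


def simulate_qpcr(
    truth: GroundTruth,
    primer_panel: list[tuple[int, int]],
    control_amplicon: tuple[int, int],
    ct_noise_sd: float = 0.0,
    fold_single: float = 8.0,
    config: SimulationConfig | None = None,
    base_ct: float = 24.0,
    ip_offset: float = 5.0,
    n_replicates: int = 3,
) -> QpcrExperiment:
    """Simulate a qPCR enrichment panel over the planted domains.

    Occupancy at an amplicon's midpoint sets its fold enrichment: 1 where
    no homolog is bound, ``fold_single`` where one is, ``2 * fold_single``
    where both are (twice the bound copies).  The IP Ct at an amplicon
    drops by log2(fold) relative to the unbound baseline, so
    ΔΔCt = -log2(fold) against the control.  Perfect-efficiency standard
    dilution curves (1:1, 1:10, 1:100) are attached per amplicon, with the
    same Ct noise.
    """
    if not primer_panel:
        raise ValueError("empty primer panel")
    if truth.occupancy(GenomicInterval("x", *control_amplicon).midpoint) != 0:
        raise ValueError("control amplicon must lie outside all planted domains")
    seed = config.seed if config is not None else 0
    rng = _streams(seed, 20_000)

    def fold_at(amp: tuple[int, int]) -> float:
        occ = truth.occupancy((amp[0] + amp[1]) / 2)
        return 1.0 if occ == 0 else fold_single * occ

    measurements: list[tuple[tuple[int, int], str, int, float]] = []
    curves: dict[tuple[int, int], list[tuple[float, float]]] = {}
    slope = -1.0 / np.log10(2.0)  # perfect doubling chemistry
    for amp in list(primer_panel) + [control_amplicon]:
        fold = fold_at(amp)
        for rep in range(n_replicates):
            ct_in = base_ct + (rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
            ct_ip = (
                base_ct
                + ip_offset
                - np.log2(fold)
                + (rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
            )
            measurements.append((amp, "input", rep, float(ct_in)))
            measurements.append((amp, "IP", rep, float(ct_ip)))
        curves[amp] = [
            (
                dil,
                float(
                    base_ct
                    + slope * np.log10(dil)
                    + (rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                ),
            )
            for dil in (1.0, 0.1, 0.01)
        ]
    return QpcrExperiment(measurements, control_amplicon, curves)


def simulate_fibres(
    truth: GroundTruth,
    bac_interval: tuple[int, int],
    n_fibres: int = 10,
    stretch_noise: float = 0.0,
    config: SimulationConfig | None = None,
) -> list[FibreObservation]:
    """Simulate stretched-chromatin fibre observations.

    Each fibre samples one homolog uniformly at random and reports the
    CENP-A (CREST immunostaining) interval of that homolog's domain and the
    BAC FISH interval, both in fibre-local coordinates after a shared
    multiplicative stretch factor of (1 + Normal(0, stretch_noise)).
    """
    if n_fibres <= 0:
        raise ValueError("n_fibres must be positive")
    window = (
        min(d[1] for d in truth.domains),
        max(d[2] for d in truth.domains),
    )
    if overlap_length(bac_interval, (window[0] - 500_000, window[1] + 500_000)) <= 0:
        raise ValueError("BAC interval must lie near the placement window")
    seed = config.seed if config is not None else 0
    rng = _streams(seed, 30_000)
    origin = min(window[0], bac_interval[0]) - 10_000

    fibres: list[FibreObservation] = []
    for i in range(n_fibres):
        homolog = int(rng.integers(1, 3))
        stretch = 1.0 + (rng.normal(0, stretch_noise) if stretch_noise > 0 else 0.0)
        stretch = max(stretch, 0.1)
        dom = truth.domain_of(homolog)
        crest = ((dom[0] - origin) * stretch, (dom[1] - origin) * stretch)
        bac = (
            (bac_interval[0] - origin) * stretch,
            (bac_interval[1] - origin) * stretch,
        )
        fibres.append(
            FibreObservation(
                fibre_id=f"{truth.individual_id}_f{i}",
                crest_intervals=[crest],
                bac_interval=bac,
                true_homolog=homolog,
            )
        )
    return fibres
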