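"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cenphase.peakcall import Peak, ProbeTrack
from cenphase.snp_phase import MarkerCall, MarkerClass, MarkerObservation


def make_marker(
    pos: int,
    ip_a: int,
    ip_b: int,
    input_a: int = 100,
    input_b: int = 100,
    chrom: str = "chr11",
) -> MarkerObservation:
    return MarkerObservation(
        chrom=chrom,
        pos=pos,
        allele_a="A",
        allele_b="G",
        input_a=input_a,
        input_b=input_b,
        ip_a=ip_a,
        ip_b=ip_b,
        marker_id=f"m{pos}",
    )


def make_class(call: MarkerCall, pos: int) -> MarkerClass:
    """A MarkerClass with counts consistent with the requested call."""
    if call is MarkerCall.MONO_A:
        m = make_marker(pos, 190, 10)
    elif call is MarkerCall.MONO_B:
        m = make_marker(pos, 10, 190)
    elif call is MarkerCall.BIALLELIC:
        m = make_marker(pos, 101, 99)
    else:
        m = make_marker(pos, 0, 0)
    frac = max(m.ip_a, m.ip_b) / max(m.ip_a + m.ip_b, 1)
    return MarkerClass(call, frac, 1e-12 if call.is_mono else 0.9, m)


def make_peak(start: int, end: int, chrom: str = "chr11") -> Peak:
    return Peak(
        chrom=chrom,
        start=start,
        end=end,
        n_probes=max(3, (end - start) // 100),
        mean_ratio=1.5,
        max_ratio=2.0,
        threshold_used=0.6,
        run_p=8e-6,
    )


def flat_track(
    n: int = 1000, value: float = 0.0, spacing: int = 100, chrom: str = "chr11"
) -> ProbeTrack:
    pos = np.arange(0, n * spacing, spacing)
    return ProbeTrack(chrom, pos, np.full(n, value))


@pytest.fixture(scope="session")
def default_individual():
    """One seeded default-condition individual (track, markers, truth)."""
    from cenphase.simulate import SimulationConfig, simulate_individual

    return simulate_individual(SimulationConfig(seed=11), individual_id="HSF-T")
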