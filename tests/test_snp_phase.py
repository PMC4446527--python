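import numpy as np
import pytest
from scipy.stats import binom

from cenphase.snp_phase import (
    DEFAULT_ALPHA,
    DEFAULT_BI_CEILING,
    DEFAULT_MONO_FLOOR,
    MarkerCall,
    classify_marker,
    classify_markers,
    deconvolve_broad_peak,
    phase_domains,
    smooth_calls,
)

from .conftest import make_class, make_marker, make_peak


class TestClassifyMarker:
    def test_strong_skew_is_monoallelic(self):
        cls = classify_marker(make_marker(0, 190, 10))
        assert cls.call is MarkerCall.MONO_A
        assert cls.ip_major_fraction == pytest.approx(0.95)
        assert cls.p_vs_balanced < 1e-10

    def test_balanced_ip_is_biallelic(self):
        assert classify_marker(make_marker(0, 101, 99)).call is MarkerCall.BIALLELIC

    def test_intermediate_band_is_uninformative(self):
        # fraction 0.65 sits in the deliberate dead band between bi_ceiling
        # and mono_floor
        assert classify_marker(make_marker(0, 130, 70)).call is MarkerCall.UNINFORMATIVE

    def test_mono_direction_follows_major_allele(self):
        assert classify_marker(make_marker(0, 10, 190)).call is MarkerCall.MONO_B

    def test_zero_ip_depth_flagged_not_error(self):
        cls = classify_marker(make_marker(0, 0, 0))
        assert cls.call is MarkerCall.UNINFORMATIVE
        assert "zero_ip_depth" in cls.flags

    def test_non_heterozygous_input_uninformative(self):
        cls = classify_marker(make_marker(0, 190, 10, input_a=160, input_b=40))
        assert cls.call is MarkerCall.UNINFORMATIVE
        assert "not_heterozygous" in cls.flags

    def test_agrees_with_exhaustive_binomial_oracle(self):
        """The classifier must reproduce an exhaustive-summation exact
        binomial test on every IP count pair with depth <= 50."""

        def oracle_p(k: int, n: int, p0: float) -> float:
            pmf = binom.pmf(np.arange(n + 1), n, p0)
            return float(pmf[pmf <= pmf[k] * (1 + 1e-9)].sum())

        for n in range(1, 51):
            for a in range(n + 1):
                m = make_marker(0, a, n - a)
                cls = classify_marker(m)
                frac = max(a, n - a) / n
                p = oracle_p(a, n, 0.5)
                if frac >= DEFAULT_MONO_FLOOR and p < DEFAULT_ALPHA:
                    expected = MarkerCall.MONO_A if a >= n - a else MarkerCall.MONO_B
                elif frac < DEFAULT_BI_CEILING:
                    expected = MarkerCall.BIALLELIC
                else:
                    expected = MarkerCall.UNINFORMATIVE
                assert cls.call is expected, (a, n, frac, p, cls.call)
                if cls.call is not MarkerCall.UNINFORMATIVE or frac > 0:
                    assert cls.p_vs_balanced == pytest.approx(p, abs=1e-12)


class TestSmoothing:
    def test_isolated_mono_in_biallelic_consensus_reclassified(self):
        calls = [
            make_class(c, p)
            for c, p in [
                (MarkerCall.BIALLELIC, 10),
                (MarkerCall.BIALLELIC, 20),
                (MarkerCall.MONO_A, 30),
                (MarkerCall.BIALLELIC, 40),
                (MarkerCall.BIALLELIC, 50),
            ]
        ]
        out = smooth_calls(calls)
        assert out[2].call is MarkerCall.BIALLELIC
        assert "smoothed" in out[2].flags

    def test_isolated_biallelic_is_preserved(self):
        # a lone biallelic marker may mark a minimal overlap centre and
        # cannot arise from allele dropout; it must survive smoothing
        calls = [
            make_class(c, p)
            for c, p in [
                (MarkerCall.MONO_A, 10),
                (MarkerCall.MONO_A, 20),
                (MarkerCall.BIALLELIC, 30),
                (MarkerCall.MONO_B, 40),
                (MarkerCall.MONO_B, 50),
            ]
        ]
        out = smooth_calls(calls)
        assert out[2].call is MarkerCall.BIALLELIC


class TestDeconvolveBroadPeak:
    def test_midpoint_arithmetic(self):
        peak = make_peak(0, 200_000)
        calls = [
            make_class(c, p)
            for c, p in [
                (MarkerCall.MONO_A, 20_000),
                (MarkerCall.MONO_A, 40_000),
                (MarkerCall.BIALLELIC, 90_000),
                (MarkerCall.BIALLELIC, 110_000),
                (MarkerCall.MONO_B, 160_000),
                (MarkerCall.MONO_B, 180_000),
            ]
        ]
        d1, d2, overlap = deconvolve_broad_peak(peak, calls, "HSF-D")
        assert (d1.start, d1.end) == (0, 135_000)
        assert (d2.start, d2.end) == (65_000, 200_000)
        assert overlap == (65_000, 135_000)

    def test_single_central_biallelic_marker(self):
        peak = make_peak(0, 200_000)
        calls = [
            make_class(c, p)
            for c, p in [
                (MarkerCall.MONO_A, 50_000),
                (MarkerCall.BIALLELIC, 100_000),
                (MarkerCall.MONO_B, 150_000),
            ]
        ]
        d1, d2, overlap = deconvolve_broad_peak(peak, calls)
        assert overlap == (75_000, 125_000)
        assert d1.start < d2.start and d1.end < d2.end
        assert d2.start < d1.end  # domains still overlap

    def test_unmatched_pattern_raises(self):
        peak = make_peak(0, 100_000)
        calls = [
            make_class(MarkerCall.MONO_A, 20_000),
            make_class(MarkerCall.MONO_A, 80_000),
        ]
        with pytest.raises(ValueError, match="phase_domains"):
            deconvolve_broad_peak(peak, calls)


class TestPhaseDomains:
    def test_two_mono_peaks_one_domain_per_homolog(self):
        p1, p2 = make_peak(0, 100_000), make_peak(300_000, 420_000)
        calls = [
            make_class(MarkerCall.MONO_A, 50_000),
            make_class(MarkerCall.MONO_B, 350_000),
        ]
        res = phase_domains([p1, p2], calls, "HSF-C")
        assert res.structure_call == "one_domain_per_homolog"
        assert len(res.domains) == 2
        by_homolog = {d.homolog: d for d in res.domains}
        assert (by_homolog[1].start, by_homolog[1].end) == (0, 100_000)
        assert (by_homolog[2].start, by_homolog[2].end) == (300_000, 420_000)

    def test_two_biallelic_peaks_shared_multidomain(self):
        p1, p2 = make_peak(0, 100_000), make_peak(300_000, 420_000)
        calls = [
            make_class(MarkerCall.BIALLELIC, 50_000),
            make_class(MarkerCall.BIALLELIC, 350_000),
        ]
        res = phase_domains([p1, p2], calls)
        assert res.structure_call == "shared_multidomain"
        assert len(res.domains) == 4
        assert sorted(d.homolog for d in res.domains) == [1, 1, 2, 2]

    def test_single_mono_peak_single_domain(self):
        res = phase_domains(
            [make_peak(0, 100_000)],
            [make_class(MarkerCall.MONO_A, 30_000), make_class(MarkerCall.MONO_B, 60_000)],
        )
        assert res.structure_call == "single_domain_one_homolog"
        assert len(res.domains) == 1

    def test_broad_peak_delegates_to_deconvolution(self):
        calls = [
            make_class(c, p)
            for c, p in [
                (MarkerCall.MONO_A, 20_000),
                (MarkerCall.BIALLELIC, 100_000),
                (MarkerCall.MONO_B, 180_000),
            ]
        ]
        res = phase_domains([make_peak(0, 200_000)], calls, "HSF-E")
        assert res.structure_call == "one_domain_per_homolog"
        assert res.overlap_interval is not None
        assert len(res.domains) == 2

    def test_contradictory_evidence_flagged_inconsistent(self):
        # biallelic at the edges with a mono centre matches no recognised
        # domain structure
        calls = [
            make_class(c, p)
            for c, p in [
                (MarkerCall.BIALLELIC, 10_000),
                (MarkerCall.MONO_A, 50_000),
                (MarkerCall.BIALLELIC, 90_000),
            ]
        ]
        res = phase_domains([make_peak(0, 100_000)], calls)
        assert res.structure_call == "inconsistent"
        assert res.domains == []

    def test_marker_outside_peaks_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            phase_domains([make_peak(0, 100_000)], [make_class(MarkerCall.MONO_A, 500_000)])

    def test_domains_lie_within_peaks_and_one_per_homolog(self):
        p1, p2 = make_peak(0, 100_000), make_peak(300_000, 420_000)
        calls = [
            make_class(MarkerCall.MONO_A, 50_000),
            make_class(MarkerCall.MONO_A, 350_000),
        ]
        res = phase_domains([p1, p2], calls)
        homologs = [d.homolog for d in res.domains]
        assert len(homologs) == len(set(homologs))
        for d in res.domains:
            assert any(p.start <= d.start and d.end <= p.end for p in (p1, p2))


class TestStructureRecovery:
    def test_default_conditions_recover_one_domain_per_homolog(self):
        """Across seeded default-condition individuals the pipeline must
        recover the true one-domain-per-homolog structure in >= 95%."""
        from cenphase.config import PipelineConfig
        from cenphase.pipeline import phase_individual
        from cenphase.simulate import SimulationConfig, simulate_individual

        n, ok = 200, 0
        for s in range(n):
            cfg = SimulationConfig(seed=40_000 + s)
            track, markers, _ = simulate_individual(cfg, individual_id=f"I{s}")
            res = phase_individual(track, markers, PipelineConfig())
            ok += res.phasing.structure_call == "one_domain_per_homolog"
        assert ok / n >= 0.95
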