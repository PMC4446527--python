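import numpy as np
import pytest
from scipy import stats

from cenphase.intervals import overlap_length
from cenphase.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_fibres,
    simulate_individual,
    simulate_qpcr,
)

CONTROL_AMPLICON = (28_227_838, 28_227_938)


class TestConfigValidation:
    def test_window_too_small_for_domain_width(self):
        with pytest.raises(ValueError, match="placement_window"):
            SimulationConfig(
                placement_window=(27_400_000, 27_450_000),
                domain_width_range=(80_000, 160_000),
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"probe_spacing": 0},
            {"noise_sd": -0.1},
            {"input_depth": 0},
            {"region_start": 5, "region_end": 5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestSimulateIndividual:
    def test_zero_noise_ratios_are_exact_occupancy_levels(self):
        cfg = SimulationConfig(seed=2, noise_sd=0.0, boundary_jitter=0)
        pool = [(27_500_000, 27_620_000), (27_700_000, 27_800_000)]
        track, _, truth = simulate_individual(cfg, epiallele_pool=pool, pool_choice=(0, 1))
        assert truth.domains == [(1, *pool[0]), (2, *pool[1])]
        inside = (track.positions >= pool[0][0]) & (track.positions < pool[0][1])
        outside = (track.positions < 27_400_000)
        assert np.all(track.ratios[inside] == cfg.enrichment_amplitude)
        assert np.all(track.ratios[outside] == 0.0)
        levels = {0.0, cfg.enrichment_amplitude, cfg.enrichment_amplitude + 1.0}
        assert set(np.unique(track.ratios)) <= levels

    def test_overlap_region_gains_one_log2_unit(self):
        # both homologs bound -> twice the bound DNA -> amplitude + 1, not 2x
        cfg = SimulationConfig(seed=2, noise_sd=0.0, boundary_jitter=0)
        pool = [(27_500_000, 27_620_000), (27_580_000, 27_700_000)]
        track, _, _ = simulate_individual(cfg, epiallele_pool=pool, pool_choice=(0, 1))
        centre = (track.positions >= 27_580_000) & (track.positions < 27_620_000)
        assert np.all(track.ratios[centre] == cfg.enrichment_amplitude + 1.0)

    def test_sole_bound_homolog_full_ip_fraction(self):
        # without antibody background the bound homolog's allele takes the
        # whole IP signal at a marker inside exactly one domain
        cfg = SimulationConfig(seed=3, mono_ip_fraction=1.0, ip_depth=500)
        track, markers, truth = simulate_individual(cfg)
        checked = 0
        for m in markers:
            bound = truth.bound_homologs(m.pos)
            if len(bound) == 1:
                frac_bound = (
                    m.ip_a if truth.snp_phase[m.pos] == bound[0] else m.ip_b
                ) / (m.ip_a + m.ip_b)
                assert frac_bound == 1.0
                checked += 1
        assert checked > 0

    def test_monte_carlo_matches_configured_distributions(self):
        fracs, widths = [], []
        for s in range(500):
            cfg = SimulationConfig(seed=60_000 + s)
            _, markers, truth = simulate_individual(cfg)
            fracs.extend(
                m.input_a / (m.input_a + m.input_b) for m in markers
            )
            widths.extend(e - s0 for _, s0, e in truth.domains)
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.01)
        lo, hi = SimulationConfig().domain_width_range
        # planted widths honour the configured range up to boundary jitter
        j = SimulationConfig().boundary_jitter
        assert min(widths) >= lo - 2 * j and max(widths) <= hi + 2 * j

    def test_input_fractions_binomial_about_half(self):
        # input chromatin is diploid: allele depths ~ Binomial(depth, 0.5).
        # KS applied after the randomised probability integral transform,
        # which maps a discrete sample to exact Uniform(0,1) under the null
        # (naive KS against a discrete CDF is invalid at the atoms)
        cfg = SimulationConfig(seed=7)
        counts = []
        for s in range(50):
            _, markers, _ = simulate_individual(
                SimulationConfig(seed=61_000 + s)
            )
            counts.extend(m.input_a for m in markers)
        counts = np.asarray(counts)
        assert counts.size >= 10_000
        dist = stats.binom(cfg.input_depth, 0.5)
        u = np.random.default_rng(0).uniform(size=counts.size)
        pit = dist.cdf(counts - 1) + u * dist.pmf(counts)
        ks = stats.kstest(pit, "uniform")
        assert ks.pvalue > 0.01

    def test_same_seed_identical_different_seed_differs(self):
        a1 = simulate_individual(SimulationConfig(seed=5))
        a2 = simulate_individual(SimulationConfig(seed=5))
        b = simulate_individual(SimulationConfig(seed=6))
        assert np.array_equal(a1[0].ratios, a2[0].ratios)
        assert a1[2].domains == a2[2].domains
        assert [m.ip_a for m in a1[1]] == [m.ip_a for m in a2[1]]
        assert a1[2].domains != b[2].domains


class TestSimulateCohort:
    def test_published_sharing_pattern_yields_seven_pool_members(self):
        # B:{a,b} C:{c,d} D:{e,f} E:{a,e} G:{f,g} -> 7 distinct epialleles
        from cenphase.simulate import PUBLISHED_ASSIGNMENT, PUBLISHED_EPIALLELE_LAYOUT

        cfg = SimulationConfig(seed=8)
        triples, cohort = simulate_cohort(
            cfg,
            n_individuals=5,
            pool_size=7,
            assignment=PUBLISHED_ASSIGNMENT,
            pool=PUBLISHED_EPIALLELE_LAYOUT,
        )
        assert len(cohort.pool) == 7
        used = {i for t in cohort.individuals for i in t.pool_membership.values()}
        assert used == set(range(7))
        # B, C and G carry separated pairs; D and E carry overlapping pairs
        for ind, expect_overlap in zip(
            cohort.individuals, (False, False, True, True, False)
        ):
            ov = overlap_length(ind.domain_of(1), ind.domain_of(2))
            assert (ov > 0) is expect_overlap, ind.individual_id

    def test_degenerate_pool_of_one_with_homozygosity(self):
        cfg = SimulationConfig(seed=9)
        triples, cohort = simulate_cohort(
            cfg, n_individuals=1, pool_size=1, sharing="allow_homozygous"
        )
        truth = cohort.individuals[0]
        d1, d2 = truth.domain_of(1), truth.domain_of(2)
        # same pool member on both homologs (positions may differ by jitter)
        assert truth.pool_membership == {1: 0, 2: 0}
        assert overlap_length(d1, d2) > 0

    def test_pool_without_homozygosity_needs_two_members(self):
        with pytest.raises(ValueError):
            simulate_cohort(SimulationConfig(seed=1), n_individuals=1, pool_size=1)

    def test_pool_size_bounded_by_slots(self):
        with pytest.raises(ValueError):
            simulate_cohort(SimulationConfig(seed=1), n_individuals=2, pool_size=5)

    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(seed=10)
        t1, c1 = simulate_cohort(cfg, 3, 4)
        t2, c2 = simulate_cohort(cfg, 3, 4)
        assert c1.pool == c2.pool
        for (tr1, m1, g1), (tr2, m2, g2) in zip(t1, t2):
            assert np.array_equal(tr1.ratios, tr2.ratios)
            assert g1.domains == g2.domains

    def test_every_pool_member_is_carried(self):
        for seed in range(5):
            _, cohort = simulate_cohort(SimulationConfig(seed=seed), 5, 9)
            used = {
                i for t in cohort.individuals for i in t.pool_membership.values()
            }
            assert used == set(range(9))


class TestSimulateQpcr:
    def make_truth(self, seed=3):
        cfg = SimulationConfig(seed=seed, noise_sd=0.0, boundary_jitter=0)
        pool = [(27_500_000, 27_620_000), (27_700_000, 27_800_000)]
        _, _, truth = simulate_individual(cfg, epiallele_pool=pool, pool_choice=(0, 1))
        return cfg, truth

    def test_interior_amplicon_ddct_is_minus_log2_fold(self):
        cfg, truth = self.make_truth()
        exp = simulate_qpcr(
            truth, [(27_550_000, 27_550_100)], CONTROL_AMPLICON,
            ct_noise_sd=0.0, fold_single=8.0, config=cfg,
        )
        from cenphase.qpcr import enrichment_profile

        pts = {p.amplicon: p for p in enrichment_profile(exp)}
        assert pts[(27_550_000, 27_550_100)].ddct == pytest.approx(-3.0)

    def test_outside_amplicon_matches_control(self):
        cfg, truth = self.make_truth()
        exp = simulate_qpcr(
            truth, [(27_450_000, 27_450_100)], CONTROL_AMPLICON,
            ct_noise_sd=0.0, config=cfg,
        )
        from cenphase.qpcr import enrichment_profile

        pts = {p.amplicon: p for p in enrichment_profile(exp)}
        assert pts[(27_450_000, 27_450_100)].ddct == pytest.approx(0.0)

    def test_empty_panel_rejected(self):
        cfg, truth = self.make_truth()
        with pytest.raises(ValueError):
            simulate_qpcr(truth, [], CONTROL_AMPLICON)

    def test_control_inside_domain_rejected(self):
        cfg, truth = self.make_truth()
        with pytest.raises(ValueError, match="control"):
            simulate_qpcr(truth, [(27_450_000, 27_450_100)], (27_550_000, 27_550_100))

    def test_ddct_noise_propagation(self):
        # ddct combines two replicate-mean dCt differences; with triplicates
        # its sd is sigma*2/sqrt(3), inside the sqrt(2)*sigma +/- 20% band
        cfg, truth = self.make_truth()
        vals = []
        for r in range(4000):
            exp = simulate_qpcr(
                truth, [(27_550_000, 27_550_100)], CONTROL_AMPLICON,
                ct_noise_sd=0.1, config=SimulationConfig(seed=70_000 + r),
            )
            from cenphase.qpcr import enrichment_profile

            pts = {p.amplicon: p for p in enrichment_profile(exp)}
            vals.append(pts[(27_550_000, 27_550_100)].ddct)
        sd = float(np.std(vals, ddof=1))
        assert 0.1 * np.sqrt(2) * 0.8 <= sd <= 0.1 * np.sqrt(2) * 1.2


class TestSimulateFibres:
    def make_truth(self):
        cfg = SimulationConfig(seed=4, noise_sd=0.0, boundary_jitter=0)
        pool = [(27_500_000, 27_620_000), (27_700_000, 27_800_000)]
        _, _, truth = simulate_individual(cfg, epiallele_pool=pool, pool_choice=(0, 1))
        return cfg, truth

    def test_disjoint_domain_and_bac_never_overlap_on_fibre(self):
        cfg, truth = self.make_truth()
        bac = (27_640_000, 27_690_000)  # between the two domains
        fibres = simulate_fibres(truth, bac, n_fibres=20, stretch_noise=0.0, config=cfg)
        for f in fibres:
            if f.true_homolog == 1:
                assert overlap_length(f.crest_intervals[0], f.bac_interval) == 0

    def test_domain_equal_to_bac_is_superimposed(self):
        cfg, truth = self.make_truth()
        bac = truth.domain_of(1)
        fibres = simulate_fibres(truth, bac, n_fibres=10, stretch_noise=0.0, config=cfg)
        for f in fibres:
            if f.true_homolog == 1:
                assert f.crest_intervals[0] == pytest.approx(f.bac_interval)

    def test_homolog_sampling_is_balanced(self):
        cfg, truth = self.make_truth()
        fibres = simulate_fibres(
            truth, (27_500_000, 27_620_000), n_fibres=1000, config=cfg
        )
        frac1 = np.mean([f.true_homolog == 1 for f in fibres])
        assert abs(frac1 - 0.5) <= 0.05

    def test_nonpositive_fibre_count_rejected(self):
        cfg, truth = self.make_truth()
        with pytest.raises(ValueError):
            simulate_fibres(truth, (27_500_000, 27_600_000), n_fibres=0)
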