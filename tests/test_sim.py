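"""Generative model: count distributions, gamete classes, sampling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ftl_chiasma.sim import (
    MarkerInterval,
    MeiosisModel,
    StudyDesign,
    bivalent_count_pmf,
    collapse_three_marker,
    crossover_count_distribution,
    default_intervals,
    default_models,
    gamete_class_probs,
    lambda_for_recombinant_probability,
    records_to_frame,
    recombinant_probability,
    simulate_cross,
    simulate_crossover_positions,
    simulate_study,
    simulate_three_marker_cross,
)

from conftest import stationary_renewal_counts_oracle


def haldane(lam: float) -> float:
    return (1.0 - np.exp(-2.0 * lam)) / 2.0


class TestCrossoverCountDistribution:
    def test_zero_rate_means_no_crossovers(self):
        model = MeiosisModel(lambda_m=0.0, lambda_f=0.0, nu_m=3, nu_f=3)
        pmf = crossover_count_distribution(model, "male", 40)
        assert pmf.tolist() == [1.0]

    def test_no_interference_is_poisson(self):
        model = MeiosisModel(lambda_m=0.25, lambda_f=0.25)
        pmf = crossover_count_distribution(model, "male", 40)
        expected = stats.poisson.pmf(np.arange(len(pmf)), 0.25)
        assert np.abs(pmf - expected).max() < 1e-9
        assert pmf[0] == pytest.approx(np.exp(-0.25), abs=1e-9)

    @pytest.mark.parametrize("nu", [1, 2, 4])
    @pytest.mark.parametrize("lam", [0.1, 0.3, 0.8])
    def test_mean_equals_lambda(self, lam, nu):
        model = MeiosisModel(lambda_m=lam, lambda_f=lam, nu_m=nu, nu_f=nu)
        pmf = crossover_count_distribution(model, "female", 40)
        mean = (np.arange(len(pmf)) * pmf).sum()
        assert mean == pytest.approx(lam, abs=1e-6)

    def test_age_effect_scales_mean(self):
        model = MeiosisModel(lambda_m=0.2, lambda_f=0.2, age_effect_m={55: 1.5})
        pmf = crossover_count_distribution(model, "male", 55)
        assert (np.arange(len(pmf)) * pmf).sum() == pytest.approx(0.3, abs=1e-6)

    def test_interference_thins_multi_crossover_tail(self):
        """At equal mean, nu=5 concentrates counts: P(>=2) drops below Poisson."""
        poisson = MeiosisModel(lambda_m=0.25, lambda_f=0.25)
        interfered = MeiosisModel(lambda_m=0.25, lambda_f=0.25, nu_m=5, nu_f=5)
        p_pois = crossover_count_distribution(poisson, "male", 40)
        p_int = crossover_count_distribution(interfered, "male", 40)
        assert 1 - p_int[:2].sum() < 1 - p_pois[:2].sum()

    @pytest.mark.parametrize("nu,mean", [(2, 0.5), (5, 0.5), (3, 1.6)])
    def test_bivalent_pmf_matches_independent_renewal_oracle(self, nu, mean):
        """Exact pmf vs direct simulation of the stationary renewal process."""
        n = 1_000_000
        counts = stationary_renewal_counts_oracle(mean, nu, n, seed=12345)
        pmf = bivalent_count_pmf(mean, nu)
        emp = np.bincount(counts, minlength=len(pmf))[: len(pmf)] / n
        se = np.sqrt(pmf * (1 - pmf) / n)
        assert np.all(np.abs(emp - pmf) <= 3 * se + 1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MeiosisModel(lambda_m=-0.1, lambda_f=0.1)
        with pytest.raises(ValueError):
            MeiosisModel(lambda_m=0.1, lambda_f=0.1, nu_m=0)
        with pytest.raises(ValueError):
            MeiosisModel(lambda_m=0.1, lambda_f=0.1, nu_m=1.5)
        with pytest.raises(ValueError):
            MeiosisModel(lambda_m=0.1, lambda_f=0.1, age_effect_f={40: 0.0})
        model = MeiosisModel(lambda_m=0.1, lambda_f=0.1)
        with pytest.raises(ValueError):
            crossover_count_distribution(model, "hermaphrodite", 40)


class TestGameteClassProbs:
    @settings(max_examples=60, deadline=None)
    @given(
        lam=st.floats(min_value=0.0, max_value=3.0),
        nu=st.integers(min_value=1, max_value=5),
    )
    def test_sum_one_and_coupling_symmetry(self, lam, nu):
        model = MeiosisModel(lambda_m=lam, lambda_f=lam, nu_m=nu, nu_f=nu)
        p = gamete_class_probs(model, "male", 40)
        total = p.p_both + p.p_none + p.p_r_only + p.p_g_only
        assert total == pytest.approx(1.0, abs=1e-12)
        assert p.p_r_only == p.p_g_only
        assert p.p_both == p.p_none

    def test_zero_lambda_all_parental(self):
        p = gamete_class_probs(MeiosisModel(0.0, 0.0), "female", 40)
        assert (p.p_both, p.p_none, p.p_r_only, p.p_g_only) == (0.5, 0.5, 0.0, 0.0)

    def test_haldane_closed_form_no_interference(self):
        for lam in [0.01, 0.1, 0.25, 0.5, 1.0, 2.0]:
            model = MeiosisModel(lambda_m=lam, lambda_f=lam)
            p = gamete_class_probs(model, "male", 40)
            assert p.p_recombinant == pytest.approx(haldane(lam), abs=1e-9)

    def test_linkage_equilibrium_limit(self):
        p = gamete_class_probs(MeiosisModel(8.0, 8.0), "male", 40)
        for v in (p.p_both, p.p_none, p.p_r_only, p.p_g_only):
            assert v == pytest.approx(0.25, abs=1e-6)

    @pytest.mark.parametrize("nu", [1, 2, 3])
    def test_brute_force_chromatid_enumeration(self, nu):
        """Class probabilities vs explicit enumeration of chromatid outcomes.

        For every bivalent count n (tail beyond n=6 negligible at this
        rate), enumerate all 2^n crossover-to-chromatid assignments; odd
        parity means the gamete is recombinant.
        """
        lam = 0.15
        biv = bivalent_count_pmf(2 * lam, nu)
        assert len(biv) <= 12  # enumeration stays tiny
        p_rec_brute = 0.0
        for n, pn in enumerate(biv):
            odd = sum(
                1 for bits in itertools.product([0, 1], repeat=n) if sum(bits) % 2 == 1
            )
            p_rec_brute += pn * odd / 2**n
        model = MeiosisModel(lambda_m=lam, lambda_f=lam, nu_m=nu, nu_f=nu)
        p = gamete_class_probs(model, "male", 40)
        assert p.p_recombinant == pytest.approx(p_rec_brute, abs=1e-9)

    def test_rf_bounded_by_mean_count_and_gap_monotone(self):
        """p_rec <= lambda, with the shortfall growing as lambda grows."""
        lams = np.linspace(0.05, 1.5, 20)
        gaps = []
        for lam in lams:
            model = MeiosisModel(lambda_m=lam, lambda_f=lam, nu_m=2, nu_f=2)
            p = recombinant_probability(model, "male", 40)
            assert p <= lam + 1e-12
            gaps.append(lam - p)
        assert np.all(np.diff(gaps) > 0)

    def test_inverse_recombinant_probability_roundtrip(self):
        for nu in (1, 3):
            lam = lambda_for_recombinant_probability(0.2, nu)
            model = MeiosisModel(lambda_m=lam, lambda_f=lam, nu_m=nu, nu_f=nu)
            assert recombinant_probability(model, "male", 40) == pytest.approx(0.2, abs=1e-9)


class TestSimulateCross:
    def test_zero_lambda_only_parental_classes(self, interval):
        rec = simulate_cross(MeiosisModel(0.0, 0.0), interval, "male_detector", 40, 100, 0)
        assert rec.seeds.n_r == rec.seeds.n_g == 0
        assert rec.seeds.n_rg + rec.seeds.n_nfs == 100

    def test_fixed_seed_reproducible(self, interval, no_interference_model):
        a = simulate_cross(no_interference_model, interval, "female_detector", 45, 500, 42)
        b = simulate_cross(no_interference_model, interval, "female_detector", 45, 500, 42)
        assert a == b

    def test_total_equals_n_seeds_and_bad_input(self, interval, no_interference_model):
        rec = simulate_cross(no_interference_model, interval, "male_detector", 40, 777, 1)
        assert rec.seeds.total == 777
        with pytest.raises(ValueError):
            simulate_cross(no_interference_model, interval, "male_detector", 40, 0, 1)
        with pytest.raises(ValueError):
            simulate_cross(no_interference_model, interval, "pollen", 40, 10, 1)

    def test_recombinant_fraction_is_unbiased(self, interval):
        """Mean observed RF over many replicates sits on the generating p."""
        p = 0.2
        lam = lambda_for_recombinant_probability(p)
        model = MeiosisModel(lambda_m=lam, lambda_f=lam)
        rng = np.random.default_rng(7)
        n_rep, n_seeds = 400, 2200
        fracs = [
            simulate_cross(model, interval, "male_detector", 40, n_seeds, rng).seeds.n_recombinant
            / n_seeds
            for _ in range(n_rep)
        ]
        se = np.sqrt(p * (1 - p) / (n_rep * n_seeds))
        assert abs(np.mean(fracs) - p) < 3 * se


class TestSimulateStudy:
    def test_cardinality_and_determinism(self, small_design):
        models = default_models()
        intervals = default_intervals()
        recs1, truth = simulate_study(models, intervals, small_design, 11)
        recs2, _ = simulate_study(models, intervals, small_design, 11)
        assert len(recs1) == 8 * 2 * 4 * 3
        assert recs1 == recs2
        assert len(truth) == 8 * 2 * 4
        assert {"line", "role", "age_das", "lambda_gamete", "p_recombinant"} <= set(truth.columns)

    def test_duplicate_design_cells_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(ages=(40, 40, 50, 55))

    def test_missing_interval_rejected(self, small_design):
        models = default_models()
        with pytest.raises(ValueError, match="without interval"):
            simulate_study(models, {}, small_design, 0)

    def test_seed_budget_split_across_replicates(self):
        design = StudyDesign(n_replicates=3, seeds_per_cell=2200)
        per_rep = design.replicate_seed_counts()
        assert sum(per_rep) == 2200 and max(per_rep) - min(per_rep) <= 1

    def test_default_models_hit_printed_rate_regime(self):
        """Generating probabilities reproduce the observed male:female regime
        (ratios mostly 1.2-3.2, averaging near the canonical ~1.8-2)."""
        models = default_models()
        ratios = []
        for model in models.values():
            pm = recombinant_probability(model, "male", 40)
            pf = recombinant_probability(model, "female", 40)
            ratios.append(pm / pf)
        assert 1.5 < np.mean(ratios) < 2.5
        assert min(ratios) > 1.0


class TestThreeMarker:
    @pytest.fixture
    def tri_interval(self):
        return MarkerInterval("TRI", 2, 1_000_000, 5_000_000, pos_mid=2_600_000)

    def test_requires_mid_marker(self, interval, no_interference_model):
        with pytest.raises(ValueError, match="pos_mid"):
            simulate_three_marker_cross(no_interference_model, interval, "male_detector", 40, 100, 0)

    def test_zero_lambda_all_parental(self, tri_interval):
        counts = simulate_three_marker_cross(MeiosisModel(0, 0), tri_interval, "male_detector", 40, 1000, 3)
        assert counts["+/+/+"] + counts["-/-/-"] == 1000

    def test_collapse_matches_two_marker_distribution(self, tri_interval):
        """Marginalizing the 8 classes recovers the exact 4-class probabilities."""
        model = MeiosisModel(lambda_m=0.2, lambda_f=0.2, nu_m=2, nu_f=2)
        n = 100_000
        counts8 = simulate_three_marker_cross(model, tri_interval, "male_detector", 40, n, 5)
        seeds = collapse_three_marker(counts8)
        assert seeds.total == n
        p = gamete_class_probs(model, "male", 40)
        for observed, expected in [
            (seeds.n_r, p.p_r_only),
            (seeds.n_g, p.p_g_only),
            (seeds.n_rg, p.p_both),
            (seeds.n_nfs, p.p_none),
        ]:
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed / n - expected) < 4 * se

    def test_double_recombinants_independent_without_interference(self, tri_interval):
        """Under nu=1 sub-interval recombination events are independent, so the
        double-recombinant fraction is the product of the sub-interval
        Haldane probabilities."""
        lam_total = 0.2
        model = MeiosisModel(lambda_m=lam_total, lambda_f=lam_total)
        frac_mid = (tri_interval.pos_mid - tri_interval.start) / (
            tri_interval.end - tri_interval.start
        )
        p1 = haldane(lam_total * frac_mid)
        p2 = haldane(lam_total * (1 - frac_mid))
        n = 200_000
        counts8 = simulate_three_marker_cross(model, tri_interval, "male_detector", 40, n, 9)
        # recombinant in both sub-intervals: marker state flips at mid and again at the end
        double = counts8["+/-/+"] + counts8["-/+/-"]
        expected = p1 * p2
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(double / n - expected) < 4 * se


class TestCrossoverPositions:
    def test_counts_match_exact_pmf(self):
        counts, pos, valid = simulate_crossover_positions(0.8, 3, 300_000, 21)
        pmf = bivalent_count_pmf(0.8, 3)
        emp = np.bincount(counts, minlength=len(pmf))[: len(pmf)] / len(counts)
        se = np.sqrt(pmf * (1 - pmf) / len(counts))
        assert np.all(np.abs(emp - pmf) <= 4 * se + 1e-12)
        assert (valid.sum(axis=1) == counts).all()
        assert not np.isnan(pos[valid]).any()

    def test_records_frame_schema(self, interval, no_interference_model):
        rec = simulate_cross(no_interference_model, interval, "male_detector", 40, 50, 0)
        df = records_to_frame([rec])
        assert list(df.columns) == ["line", "role", "age_das", "replicate", "n_r", "n_g", "n_rg", "n_nfs"]
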