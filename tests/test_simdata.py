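"""Generative-model checks: genotypes, treatment, event/censoring times,
recruitment, and the four observation scenarios."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from survpower import (
    SimulationConfig,
    apply_scenario,
    inverse_transform_time,
    simulate_censoring_times,
    simulate_dataset,
    simulate_event_times,
    simulate_genotypes,
    simulate_recruitment,
    simulate_treatment,
)

N_BIG = 100_000


def _sim(scenario=1, **kw):
    base = dict(
        n_subjects=100,
        maf=0.3,
        shape_a=1.0,
        baseline_scale_d0=0.1,
        beta_snp=0.4,
        scenario=scenario,
        end_of_study_Z=5.0,
        seed=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenotypes:
    def test_mean_matches_binomial_moment(self, rng):
        g = simulate_genotypes(N_BIG, 0.2, rng)
        se = np.sqrt(2 * 0.2 * 0.8 / N_BIG)
        assert abs(g.mean() - 0.4) < 3 * se

    def test_hwe_proportions_chi_square(self, rng):
        q = 0.3
        g = simulate_genotypes(N_BIG, q, rng)
        observed = np.bincount(g, minlength=3)
        expected = N_BIG * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 0.001  # non-rejection of HWE

    def test_near_zero_maf_is_monomorphic(self, rng):
        assert np.all(simulate_genotypes(10, 1e-9, rng) == 0)

    @pytest.mark.parametrize("maf", [0.0, -0.1, 0.6, 1.0])
    def test_maf_out_of_range_rejected(self, maf, rng):
        with pytest.raises(ValueError):
            simulate_genotypes(10, maf, rng)


class TestTreatment:
    @pytest.mark.parametrize("p,expected", [(0.0, 0), (1.0, 1)])
    def test_degenerate_probabilities(self, p, expected, rng):
        assert np.all(simulate_treatment(5, p, rng) == expected)

    def test_mean_matches_bernoulli_moment(self, rng):
        x = simulate_treatment(N_BIG, 0.5, rng)
        assert abs(x.mean() - 0.5) < 3 * np.sqrt(0.25 / N_BIG)

    def test_probability_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_treatment(5, 1.5, rng)


class TestEventTimes:
    @pytest.mark.parametrize(
        "a,b,u,expected",
        [
            (1.0, 0.5, np.exp(-1.0), 2.0),
            (2.0, 1.0, np.exp(-1.0), 1.0),
        ],
    )
    def test_inverse_transform_closed_form(self, a, b, u, expected):
        assert inverse_transform_time(a, b, u) == pytest.approx(expected)

    def test_exponential_mean_under_log_hazard_effect(self, rng):
        # all BB homozygotes: rate = d0 * exp(2*beta), mean = 1/rate at a=1
        cfg = _sim(n_subjects=N_BIG, baseline_scale_d0=0.1, beta_snp=0.4)
        genotype = np.full(N_BIG, 2)
        t = simulate_event_times(cfg, genotype, None, rng)
        mean_true = 1.0 / (0.1 * np.exp(0.8))
        se = mean_true / np.sqrt(N_BIG)  # exponential: sd == mean
        assert abs(t.mean() - mean_true) < 3 * se

    def test_nonpositive_shape_or_scale_rejected(self, rng):
        g = np.zeros(5, dtype=int)
        with pytest.raises(ValueError):
            simulate_event_times(_sim(shape_a=0.0), g, None, rng)
        with pytest.raises(ValueError):
            simulate_event_times(_sim(baseline_scale_d0=-1.0), g, None, rng)


class TestCensoringTimes:
    def test_exponential_mean(self, rng):
        c = simulate_censoring_times(N_BIG, 2.0, rng)
        assert abs(c.mean() - 2.0) < 3 * (2.0 / np.sqrt(N_BIG))

    def test_inverse_transform_gives_scale_at_u_exp_minus_one(self):
        # exponential is the shape-1 Weibull: rate = 1/scale
        s = 3.7
        assert inverse_transform_time(1.0, 1.0 / s, np.exp(-1.0)) == pytest.approx(s)

    def test_smaller_scale_censors_more(self):
        # mean-scale convention: early drop-out at small scales
        fractions = {}
        for scale in (0.5, 5.0):
            cfg = _sim(scenario=2, n_subjects=20_000, censor_scale=scale, seed=3)
            ds = simulate_dataset(cfg)
            fractions[scale] = 1.0 - ds.n_events / ds.n
        assert fractions[0.5] > fractions[5.0]

    def test_nonpositive_scale_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_censoring_times(5, 0.0, rng)


class TestRecruitment:
    def test_r_zero_means_simultaneous_entry(self, rng):
        assert np.all(simulate_recruitment(100, 0.0, rng) == 0.0)

    def test_discrete_uniform_frequencies(self, rng):
        r = simulate_recruitment(N_BIG, 4.0, rng)
        assert set(np.unique(r)) <= {0.0, 1.0, 2.0, 3.0, 4.0}
        freqs = np.bincount(r.astype(int), minlength=5) / N_BIG
        se = np.sqrt(0.2 * 0.8 / N_BIG)
        assert np.all(np.abs(freqs - 0.2) < 3 * se)

    def test_continuous_option_spans_interval(self, rng):
        r = simulate_recruitment(N_BIG, 4.0, rng, continuous=True)
        assert r.min() >= 0.0 and r.max() <= 4.0
        assert len(np.unique(r)) > 100  # genuinely continuous

    def test_followup_always_positive_when_r_below_z(self, rng):
        r = simulate_recruitment(1000, 4.0, rng)
        assert np.all(5.0 - r >= 1.0)


class TestApplyScenario:
    @pytest.mark.parametrize(
        "t,expected",
        [(3.0, (3.0, 1)), (7.0, (5.0, 0)), (5.0, (5.0, 1))],  # t == Z: event at Z
    )
    def test_scenario1_end_of_study(self, t, expected):
        cfg = _sim(scenario=1, end_of_study_Z=5.0)
        obs, ev = apply_scenario(cfg, np.array([t]))
        assert (obs[0], ev[0]) == expected

    def test_scenario2_dropout_before_event(self):
        cfg = _sim(scenario=2, end_of_study_Z=5.0, censor_scale=1.0)
        obs, ev = apply_scenario(cfg, np.array([3.0]), censor_times=np.array([1.0]))
        assert (obs[0], ev[0]) == (1.0, 0)

    def test_scenario4_administrative_censoring_wins(self):
        # entry at r=2 leaves a 3-unit horizon that precedes both the
        # latent event (10) and drop-out (7)
        cfg = _sim(scenario=4, end_of_study_Z=5.0, censor_scale=1.0, recruit_end_R=4.0)
        obs, ev = apply_scenario(
            cfg,
            np.array([10.0]),
            censor_times=np.array([7.0]),
            recruit_times=np.array([2.0]),
        )
        assert (obs[0], ev[0]) == (3.0, 0)

    def test_scenario3_boundary_r_equals_R(self):
        cfg = _sim(scenario=3, end_of_study_Z=5.0, recruit_end_R=4.0)
        obs, ev = apply_scenario(
            cfg, np.array([2.0, 2.0]), recruit_times=np.array([4.0, 4.0])
        )
        # horizon Z - r = 1 < t: administratively censored at 1
        assert np.all(obs == 1.0) and np.all(ev == 0)

    def test_missing_required_inputs_rejected(self):
        with pytest.raises(ValueError):
            apply_scenario(_sim(scenario=2, censor_scale=1.0), np.array([1.0]))
        with pytest.raises(ValueError):
            apply_scenario(_sim(scenario=3, recruit_end_R=2.0), np.array([1.0]))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            apply_scenario(_sim(scenario=1), np.array([-1.0]))

    @given(
        scenario=st.sampled_from([1, 2, 3, 4]),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_min_rule_brute_force(self, scenario, data):
        """(observed, event) always equals the subject-by-subject min rule."""
        Z = 5.0
        n = data.draw(st.integers(1, 8))
        pos = st.floats(0.01, 12.0, allow_nan=False)
        t = np.array(data.draw(st.lists(pos, min_size=n, max_size=n)))
        c = np.array(data.draw(st.lists(pos, min_size=n, max_size=n)))
        r = np.array(
            data.draw(st.lists(st.floats(0.0, 4.0), min_size=n, max_size=n))
        )
        kw = dict(
            censor_scale=1.0 if scenario in (2, 4) else None,
            recruit_end_R=4.0 if scenario in (3, 4) else None,
        )
        cfg = _sim(scenario=scenario, end_of_study_Z=Z, **kw)
        obs, ev = apply_scenario(
            cfg,
            t,
            censor_times=c if scenario in (2, 4) else None,
            recruit_times=r if scenario in (3, 4) else None,
        )
        for i in range(n):
            ci = c[i] if scenario in (2, 4) else np.inf
            hi = Z - r[i] if scenario in (3, 4) else Z
            assert obs[i] == pytest.approx(min(t[i], ci, hi))
            assert ev[i] == int(t[i] <= min(ci, hi))
            assert obs[i] <= hi


class TestDatasetLevel:
    def test_determinism_for_fixed_seed(self, basic_sim):
        d1 = simulate_dataset(basic_sim)
        d2 = simulate_dataset(basic_sim)
        assert np.array_equal(d1.genotype, d2.genotype)
        assert np.array_equal(d1.observed_time, d2.observed_time)
        assert np.array_equal(d1.event, d2.event)

    def test_censoring_monotone_in_horizon(self):
        fracs = []
        for Z in (1.0, 3.0, 9.0):
            cfg = _sim(scenario=1, n_subjects=20_000, end_of_study_Z=Z, seed=3)
            ds = simulate_dataset(cfg)
            fracs.append(1.0 - ds.n_events / ds.n)
        assert fracs[0] > fracs[1] > fracs[2]

    def test_null_model_exchangeable_across_genotypes(self):
        # beta = 0, a = 1: observed times carry no genotype signal
        cfg = _sim(n_subjects=60_000, beta_snp=0.0, scenario=1, seed=8)
        ds = simulate_dataset(cfg)
        means = [ds.observed_time[ds.genotype == g].mean() for g in (0, 1, 2)]
        sds = [
            ds.observed_time[ds.genotype == g].std() / np.sqrt((ds.genotype == g).sum())
            for g in (0, 1, 2)
        ]
        for g in (1, 2):
            assert abs(means[g] - means[0]) < 4 * np.hypot(sds[g], sds[0])

    def test_frame_columns_and_roundtrip(self, treatment_dataset):
        df = treatment_dataset.to_frame()
        assert list(df.columns) == ["id", "time", "event", "snp", "treatment"]
        back = type(treatment_dataset).from_frame(df)
        assert np.array_equal(back.genotype, treatment_dataset.genotype)
        assert np.array_equal(back.treatment, treatment_dataset.treatment)
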