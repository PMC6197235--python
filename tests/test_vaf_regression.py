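"""Two-step VAF regression: eligibility, least squares vs oracle, shuffled
null, run-length correction."""

import numpy as np
import pandas as pd
import pytest

from attnaxes.vaf_regression import (StimulusResponseSeries,
                                     compute_response_series,
                                     compute_session_vaf,
                                     fit_stimulus_response_axis,
                                     max_run_length,
                                     runlength_threshold,
                                     select_eligible_flashes,
                                     session_predictors, shuffled_null_vaf,
                                     significance_mask, two_step_vaf)


def flash_table(patterns):
    """Build a flash frame from trial patterns like 'sst' (sample/sample/
    target) or 'ss'; 'c' prefix marks a cue trial."""
    rows = []
    for tr, pat in enumerate(patterns, start=1):
        cue_trial = pat.startswith("c")
        pat = pat.lstrip("c")
        for i, ch in enumerate(pat, start=1):
            is_tgt = ch == "t"
            rows.append(("F", tr, i, 400 + (i - 1) * 800, cue_trial, "RF",
                         "RF-only" if cue_trial else "bilateral", 45.0,
                         is_tgt, "RF" if is_tgt else "none",
                         3.0 if is_tgt else 0.0, "hit" if is_tgt else "none",
                         250.0 if is_tgt else np.nan))
    return pd.DataFrame(rows, columns=[
        "session_id", "trial_id", "flash_index", "onset_ms", "is_cue_trial",
        "cue_location", "stimulus_locations", "orientation_RF", "is_target",
        "target_location", "delta_orientation", "outcome",
        "response_time_ms"])


class TestEligibility:
    def test_sample_sample_target(self):
        fl = flash_table(["sst"])
        rows = select_eligible_flashes(fl)
        assert list(fl.iloc[rows]["flash_index"]) == [2]

    def test_sample_target_has_none(self):
        assert len(select_eligible_flashes(flash_table(["st"]))) == 0

    def test_five_samples_no_target(self):
        fl = flash_table(["sssss"])
        rows = select_eligible_flashes(fl)
        assert list(fl.iloc[rows]["flash_index"]) == [2, 3, 4, 5]

    def test_cue_trials_excluded(self):
        fl = flash_table(["csss", "sss"])
        rows = select_eligible_flashes(fl)
        assert set(fl.iloc[rows]["trial_id"]) == {2}


def toy_series(r, time_ms=None):
    r = np.asarray(r, dtype=float)
    t = np.arange(r.shape[0]) if time_ms is None else time_ms
    return StimulusResponseSeries(t, r - r.mean(axis=1, keepdims=True),
                                  np.array([1.0]), 0.0,
                                  np.arange(r.shape[1]))


class TestTwoStep:
    def test_response_proportional_to_post_predictor(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=40)
        r = np.outer(np.ones(30), 2 * a)
        v = two_step_vaf(toy_series(r), a, rng.normal(size=40))
        np.testing.assert_allclose(v.vaf_post, 1.0)
        np.testing.assert_allclose(v.vaf_pre, 0.0, atol=1e-9)

    def test_response_along_orthogonal_pre_predictor(self):
        rng = np.random.default_rng(1)
        a_post = rng.normal(size=50)
        a_pre = rng.normal(size=50)
        a_post -= a_post.mean()
        a_pre -= a_pre.mean()
        a_pre -= (a_pre @ a_post) / (a_post @ a_post) * a_post  # sample-orth.
        r = np.outer(np.ones(10), a_pre)
        v = two_step_vaf(toy_series(r), a_post, a_pre)
        np.testing.assert_allclose(v.vaf_post, 0.0, atol=1e-12)
        np.testing.assert_allclose(v.vaf_pre, 1.0)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(2)
        r = rng.normal(size=(7, 50))
        r -= r.mean(axis=1, keepdims=True)
        a_post = rng.normal(size=50)
        a_pre = rng.normal(size=50)
        v = two_step_vaf(toy_series(r), a_post, a_pre)
        ac = a_post - a_post.mean()
        pc = a_pre - a_pre.mean()
        for t in range(7):
            beta, *_ = np.linalg.lstsq(ac[:, None], r[t], rcond=None)
            assert abs(v.beta_post[t] - beta[0]) < 1e-10
            resid = r[t] - ac * beta[0]
            vaf = 1 - resid @ resid / (r[t] @ r[t])
            assert abs(v.vaf_post[t] - vaf) < 1e-10
            beta2, *_ = np.linalg.lstsq(pc[:, None], resid, rcond=None)
            assert abs(v.beta_pre[t] - beta2[0]) < 1e-10

    def test_vaf_bounded_zero_one(self):
        rng = np.random.default_rng(3)
        r = rng.normal(size=(100, 20))
        v = two_step_vaf(toy_series(r), rng.normal(size=20),
                         rng.normal(size=20))
        assert np.all((v.vaf_post >= 0) & (v.vaf_post <= 1))
        assert np.all((v.vaf_pre >= 0) & (v.vaf_pre <= 1))

    def test_sequential_equals_joint_for_orthogonal_predictors(self):
        rng = np.random.default_rng(4)
        a_post = rng.normal(size=60)
        a_pre = rng.normal(size=60)
        a_post -= a_post.mean()
        a_pre -= a_pre.mean()
        a_pre -= (a_pre @ a_post) / (a_post @ a_post) * a_post
        r = rng.normal(size=(5, 60))
        r -= r.mean(axis=1, keepdims=True)
        v = two_step_vaf(toy_series(r), a_post, a_pre)
        X = np.column_stack([a_post, a_pre])
        for t in range(5):
            beta, *_ = np.linalg.lstsq(X, r[t], rcond=None)
            resid = r[t] - X @ beta
            joint_vaf = 1 - resid @ resid / (r[t] @ r[t])
            seq_total = v.vaf_post[t] + (1 - v.vaf_post[t]) * v.vaf_pre[t]
            assert abs(joint_vaf - seq_total) < 1e-10

    def test_zero_variance_predictor_rejected(self):
        r = np.random.default_rng(5).normal(size=(3, 10))
        with pytest.raises(ValueError):
            two_step_vaf(toy_series(r), np.ones(10), np.arange(10.0))


class TestShuffledNull:
    def test_null_matches_inverse_n_minus_one(self):
        rng = np.random.default_rng(6)
        n = 201
        r = rng.normal(size=(20, n))
        series = toy_series(r)
        null, theory = shuffled_null_vaf(series, rng.normal(size=n),
                                         rng.normal(size=n),
                                         n_shuffles=150, rng=rng)
        assert np.isclose(theory, 1 / (n - 1))
        # SE of the mean over 20 time points x 150 shuffles
        assert abs(null - theory) < 3 * theory / np.sqrt(150)

    def test_n_two_degenerate_rejected(self):
        r = np.random.default_rng(7).normal(size=(3, 2))
        with pytest.raises(ValueError):
            shuffled_null_vaf(toy_series(r), np.array([0.0, 1.0]),
                              np.array([1.0, 0.0]))


class TestRunLength:
    def test_max_run(self):
        assert max_run_length([0, 1, 1, 1, 0, 1]) == 3
        assert max_run_length([0, 0]) == 0
        assert max_run_length([1, 1]) == 2

    def test_white_noise_threshold_small(self):
        rng = np.random.default_rng(8)
        vaf = rng.normal(size=(47, 700)) * 1e-3
        out = runlength_threshold(vaf, n_sims=300, rng=rng)
        # for independent per-ms tests P(max run >= L) ~ 1 - exp(-T alpha^L):
        # ~8% at L = 3 and ~0.4% at L = 4, so the 5% familywise threshold is 4
        assert out["threshold"] <= 4
        assert abs(out["ar_coefficients"][0]) < 0.1

    def test_threshold_nondecreasing_in_autocorrelation(self):
        rng = np.random.default_rng(9)
        thresholds = []
        for phi in (0.0, 0.6, 0.95):
            x = np.zeros((6, 500))
            eps = rng.normal(size=(6, 500))
            for t in range(1, 500):
                x[:, t] = phi * x[:, t - 1] + eps[:, t]
            out = runlength_threshold(x, n_sims=300, rng=rng)
            thresholds.append(out["threshold"])
        assert thresholds[0] <= thresholds[1] <= thresholds[2]

    def test_mask_empty_at_null_level(self):
        rng = np.random.default_rng(10)
        vaf = 0.001 + 1e-4 * rng.normal(size=(10, 300))
        out = significance_mask(vaf, 0.001, run_threshold=5)
        assert out["mask"].mean() < 0.02

    def test_isolated_point_erased(self):
        vaf = np.zeros((8, 50))
        vaf[:, 25] = 1.0  # one hugely significant ms
        out = significance_mask(vaf + 1e-6 * np.random.default_rng(11)
                                .normal(size=(8, 50)), 0.0, run_threshold=20)
        assert not out["mask"].any()
        assert out["peak_index"] == 25

    def test_sustained_run_survives(self):
        rng = np.random.default_rng(12)
        vaf = 1e-4 * rng.normal(size=(8, 100))
        vaf[:, 30:80] += 0.05
        out = significance_mask(vaf, 0.0, run_threshold=20)
        assert out["mask"][35:75].all()


class TestStimulusResponseAxis:
    def test_single_responding_unit_gives_coordinate_axis(self):
        t = np.arange(-100, 600)
        win = np.zeros((20, 4, len(t)))
        resp = np.exp(-0.5 * ((t - 80) / 30.0) ** 2)
        win[:, 2, :] = 1.0 + resp  # only unit 2 responds
        axis, peak = fit_stimulus_response_axis(win, t)
        np.testing.assert_allclose(np.abs(axis), [0, 0, 1, 0], atol=1e-12)
        assert peak == 80

    def test_scale_invariance(self):
        rng = np.random.default_rng(13)
        t = np.arange(-100, 600)
        win = rng.random((10, 5, len(t))) + np.linspace(0, 1, len(t))
        a1, p1 = fit_stimulus_response_axis(win, t)
        a2, p2 = fit_stimulus_response_axis(2 * win, t)
        np.testing.assert_allclose(a1, a2, atol=1e-12)
        assert p1 == p2

    def test_degenerate_flat_trajectory(self):
        t = np.arange(-100, 600)
        win = np.ones((5, 3, len(t)))
        with pytest.raises(ValueError):
            fit_stimulus_response_axis(win, t)

    def test_peak_near_template_transient(self, synth_session,
                                          synth_projections):
        """The empirical peak of the population departure from baseline lands
        at the generator's transient peak plus the causal-kernel lag."""
        session, _ = synth_session
        _, records = synth_projections
        rows, a_post, a_pre = session_predictors(session, records)
        series = compute_response_series(session, rows)
        assert 50 <= series.peak_time_ms <= 95


class TestSessionVaf:
    def test_end_to_end_on_synthetic_session(self, synth_session,
                                             synth_projections):
        session, _ = synth_session
        _, records = synth_projections
        v = compute_session_vaf(session, records)
        assert v.time_ms[0] == -100 and v.time_ms[-1] == 599
        assert np.all((v.vaf_post >= 0) & (v.vaf_post <= 1))
        # the sustained stimulus response is where the post attention state
        # explains the most variance
        t = v.time_ms
        sustained = v.vaf_post[(t >= 200) & (t < 400)].mean()
        pre_onset = v.vaf_post[(t >= -100) & (t < 0)].mean()
        assert sustained > pre_onset
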