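"""Bayesian decoder: smoothing, factorized posteriors, LOOCV, overlap."""

import numpy as np
import pandas as pd
import pytest

import cardiopupil as cp
from cardiopupil.decoder import (discretize, fit_decoder, laplace_smooth,
                                 loocv_evaluate, overlap_metrics,
                                 posterior_response, predict_map,
                                 decoder_vs_criterion)
from cardiopupil.synth import ChannelMix, SessionConfig, TaskConfig


# --------------------------------------------------------------------------
# independent brute-force oracle: explicit loop/dict counting of the same
# factorization, kept free of the model's vectorized tables
# --------------------------------------------------------------------------

def brute_posterior(bins, responded, query, n_bins):
    """P(respond|query bins) by direct counting with add-one smoothing.

    bins: (n_trials, n_pred) ints; query: tuple of bin indices. The first
    predictor is the factorization target, the rest condition it.
    """
    target_q, cond_q = query[0], tuple(query[1:])
    num = {}
    for r in (0, 1):
        d_cond_r = 0
        d_cond_r_target = 0
        d_cond = 0
        for row, resp in zip(bins, responded):
            if tuple(row[1:]) == cond_q:
                d_cond += 1
                if int(resp) == r:
                    d_cond_r += 1
                    if row[0] == target_q:
                        d_cond_r_target += 1
        like = (d_cond_r_target + 1) / (d_cond_r + n_bins)
        prior = (d_cond_r + 1) / (d_cond + 2)
        num[r] = like * prior
    return num[1] / (num[0] + num[1])


class TestDiscretize:
    def test_extremes_map_to_extreme_bins(self):
        idx, edges = discretize([2.0, 5.0, 8.0], n_bins=15)
        assert idx[0] == 0 and idx[2] == 14

    def test_uniform_grid_fills_evenly(self):
        k = 4
        v = np.arange(15 * k) + 0.5  # k values per unit-width bin
        idx, _ = discretize(v, n_bins=15, edges=np.linspace(0, 15 * k, 16))
        assert all(np.sum(idx == b) == k for b in range(15))

    def test_clamping_with_supplied_edges(self):
        idx, _ = discretize([-10.0, 100.0], edges=np.linspace(0, 1, 16))
        assert idx[0] == 0 and idx[1] == 14

    def test_matches_edge_comparison_oracle(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(-5, 5, 200)
        idx, edges = discretize(v, n_bins=15)
        for val, b in zip(v, idx):
            assert edges[b] <= val or np.isclose(edges[b], val)
            if b < 14:
                assert val < edges[b + 1] or np.isclose(val, edges[b + 1])

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            discretize([1.0, 1.0])


class TestLaplaceSmooth:
    def test_printed_examples(self):
        assert laplace_smooth(0, 0, 2) == 0.5
        assert np.isclose(laplace_smooth(3, 9, 2), 4.0 / 11.0)

    def test_sums_to_one_over_categories(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 20, size=15)
        probs = laplace_smooth(counts, counts.sum(), 15)
        assert np.isclose(probs.sum(), 1.0, atol=1e-12)


class TestFitDecoder:
    def test_toy_hand_computation(self):
        """4 trials, PA bins {1,1,2,2}, responded {1,1,0,0}."""
        bl = {"pa": np.array([1.0, 1.0, 2.0, 2.0])}
        edges = {"pa": np.linspace(0.5, 15.5, 16)}  # value v lands in bin v-1
        model = fit_decoder(bl, [True, True, False, False], ("pa",), edges=edges)
        assert np.isclose(model.smoothed_prior(), 0.5)          # (2+1)/(4+2)
        tabs = model.conditional_tables()
        p_pa1_given_resp = tabs["p_target_given_cond_resp"][1, 0]
        assert np.isclose(p_pa1_given_resp, 3.0 / 17.0)          # (2+1)/(2+15)

    def test_all_responded_prior_below_one(self):
        bl = {"pa": np.arange(10.0)}
        model = fit_decoder(bl, np.ones(10, bool), ("pa",))
        assert np.isclose(model.smoothed_prior(), 11.0 / 12.0)

    def test_conditionals_sum_to_one(self):
        rng = np.random.default_rng(2)
        bl = {"pa": rng.uniform(0, 1, 100), "hr": rng.uniform(0, 1, 100)}
        model = fit_decoder(bl, rng.random(100) > 0.4, ("pa", "hr"))
        tabs = model.conditional_tables()
        np.testing.assert_allclose(
            tabs["p_target_given_cond_resp"].sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(
            tabs["p_resp_given_cond"].sum(axis=0), 1.0, atol=1e-12)

    def test_frequencies_recovered_at_large_n(self):
        rng = np.random.default_rng(3)
        n = 10_000
        resp = rng.random(n) < 0.6
        pa = np.where(resp, rng.normal(1, 1, n), rng.normal(-1, 1, n))
        model = fit_decoder({"pa": pa}, resp, ("pa",))
        tabs = model.conditional_tables()
        idx, _ = discretize(pa, 15, model.edges["pa"])
        for b in range(15):
            emp = np.mean(idx[resp] == b)
            assert abs(tabs["p_target_given_cond_resp"][1, b] - emp) < 10.0 / n + 3e-2 * emp + 1e-3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit_decoder({"pa": np.array([])}, np.array([], bool), ("pa",))


class TestPosterior:
    def test_equal_counts_cancel_to_prior(self):
        # identical PA distribution for both classes → posterior = prior
        pa = np.tile(np.arange(15.0), 2)
        resp = np.array([True] * 15 + [False] * 15)
        model = fit_decoder({"pa": pa}, resp, ("pa",))
        for b in range(15):
            assert np.isclose(posterior_response(model, (b,)),
                              model.smoothed_prior(), atol=1e-12)

    def test_normalization(self):
        rng = np.random.default_rng(4)
        model = fit_decoder({"pa": rng.uniform(0, 1, 40)}, rng.random(40) > 0.5, ("pa",))
        for b in range(15):
            p = posterior_response(model, (b,))
            assert 0.0 < p < 1.0

    @pytest.mark.parametrize("n_pred", [1, 2, 3])
    def test_factorized_equals_brute_force(self, n_pred):
        """Exhaustive oracle equivalence on toy sessions (≤4 bins, ≤50 trials)."""
        rng = np.random.default_rng(5)
        preds = ("pa", "hr", "hrv")[:n_pred]
        for trial in range(6):
            n_bins = int(rng.integers(2, 5))
            n = int(rng.integers(5, 51))
            data = {p: rng.uniform(0, 1, n) for p in preds}
            edges = {p: np.linspace(0, 1, n_bins + 1) for p in preds}
            resp = rng.random(n) > 0.5
            model = fit_decoder(data, resp, preds, edges=edges, n_bins=n_bins)
            bins = np.column_stack([
                discretize(data[p], n_bins, edges[p])[0] for p in preds])
            from itertools import product
            for query in product(range(n_bins), repeat=n_pred):
                expect = brute_posterior(bins, resp, query, n_bins)
                got = posterior_response(model, query)
                assert abs(got - expect) < 1e-12


class TestPredictMap:
    def test_clear_cases(self):
        assert predict_map(0.7) is True
        assert predict_map(0.3) is False

    def test_tie_uses_prior(self):
        assert predict_map(0.5, smoothed_prior=0.3) is False
        assert predict_map(0.5, smoothed_prior=0.7) is True
        assert predict_map(0.5, smoothed_prior=0.5) is True  # respond on full tie


class TestLoocv:
    def test_separable_toy(self):
        """Bin-separable labels decode perfectly; chance stays near 0.5."""
        n_resp, n_with = 16, 15
        pa = np.array([0.0] * n_resp + [1.0] * n_with)
        resp = np.array([True] * n_resp + [False] * n_with)
        res = loocv_evaluate({"pa": pa}, resp, ("pa",))
        assert res.accuracy == 1.0
        assert 0.4 <= res.above_chance <= 0.6
        assert len(res.posterior) == len(pa)

    def test_null_calibration_small(self):
        """Shuffled labels → above-chance centered on zero."""
        rng = np.random.default_rng(6)
        vals = []
        for _ in range(40):
            n = 120
            pa = rng.uniform(0, 1, n)
            resp = rng.random(n) < 0.58
            if resp.all() or not resp.any():
                continue
            vals.append(loocv_evaluate({"pa": pa}, resp, ("pa",)).above_chance)
        vals = np.array(vals)
        assert abs(vals.mean()) < 3 * vals.std(ddof=1) / np.sqrt(len(vals))

    def test_noise_predictor_harmless(self):
        """A pure-noise second predictor leaves expected accuracy unchanged."""
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(100):
            n = 200
            resp = rng.random(n) < 0.55
            pa = rng.uniform(0, 1, n)  # null: independent of the outcome
            noise = rng.uniform(0, 1, n)
            acc1 = loocv_evaluate({"pa": pa}, resp, ("pa",)).accuracy
            acc2 = loocv_evaluate({"pa": pa, "hrv": noise}, resp, ("pa", "hrv")).accuracy
            diffs.append(acc2 - acc1)
        assert abs(np.mean(diffs)) < 0.02

    def test_edges_per_fold_agrees_on_easy_data(self):
        rng = np.random.default_rng(8)
        n = 60
        resp = rng.random(n) < 0.5
        pa = resp * 2.0 + rng.normal(0, 0.3, n)
        a = loocv_evaluate({"pa": pa}, resp, ("pa",))
        b = loocv_evaluate({"pa": pa}, resp, ("pa",), edges_per_fold=True)
        assert abs(a.accuracy - b.accuracy) < 0.1

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            loocv_evaluate({"pa": np.array([1.0, 2.0])}, np.array([True, False]), ("pa",))


class TestOverlap:
    def test_identical_sets(self):
        m = overlap_metrics([0, 1, 2], [0, 1, 2])
        assert m.pct_overlap == 100.0

    def test_disjoint_sets(self):
        assert overlap_metrics([0, 1], [2, 3]).pct_overlap == 0.0

    def test_printed_formula(self):
        a = list(range(60))
        b = list(range(30)) + list(range(100, 110))
        m = overlap_metrics(a, b)
        assert np.isclose(m.pct_overlap, 60.0)

    def test_normalization(self):
        m = overlap_metrics([0, 1, 2, 3], [2, 3, 4, 5], accuracy_a=0.5, accuracy_b=0.5)
        assert np.isclose(m.normalized_overlap, m.pct_overlap / 50.0)

    def test_empty_sets_warn(self):
        with pytest.warns(UserWarning):
            m = overlap_metrics([], [])
        assert m.pct_overlap == 0.0


class TestDecoderStudy:
    def _session_frames(self, c0_values, seed0=0, n_trials=160):
        sessions = []
        for i, c0 in enumerate(c0_values):
            task = TaskConfig(n_trials=n_trials,
                              criterion_coeffs=(c0, -1.4, 0.2))
            cfg = SessionConfig(task=task)
            s = cp.simulate_session(cfg, seed=seed0 + i, with_ecg=False)
            cardiac = cp.cardiac_series(cp.BeatSeries(s.beats_truth.beat_times))
            pupil = cp.smooth_pupil(cp.interpolate_blinks(s.pupil))
            bl = cp.extract_baselines(s.trials[20:], cardiac, pupil)
            hit, fa = cp.response_rates(s.trials[20:])
            n_go = sum(t.stimulus == "go" for t in s.trials[20:])
            m = cp.loglinear_sdt(sum(t.outcome == "hit" for t in s.trials[20:]), n_go,
                                 sum(t.outcome == "fa" for t in s.trials[20:]),
                                 len(s.trials[20:]) - n_go)
            sessions.append({"session": i, "baselines": bl,
                             "responded": bl["responded"].to_numpy(),
                             "criterion": m.criterion})
        return sessions

    def test_table_shape(self):
        sessions = self._session_frames([-0.5, 0.0, 0.5])
        table = decoder_vs_criterion(sessions)
        assert len(table) == 3
        assert {"criterion", "accuracy_pa", "pct_overlap"} <= set(table.columns)

    def test_overlap_u_shape_with_criterion(self):
        """Extreme criteria force near-total overlap → positive curvature."""
        wins = 0
        n_rep = 8
        for rep in range(n_rep):
            sessions = self._session_frames(
                [-1.6, -1.0, -0.4, 0.0, 0.4, 1.0, 1.6], seed0=500 + 10 * rep)
            table = decoder_vs_criterion(sessions)
            fit = cp.quadratic_regression(table["criterion"], table["pct_overlap"])
            wins += fit.beta2 > 0
        assert wins >= 0.75 * n_rep

    def test_redundant_channels_raise_normalized_overlap(self):
        """Private per-channel signal lowers PA/HR overlap versus a single
        shared latent."""
        def mean_norm_overlap(lam, seed0):
            vals = []
            for i in range(10):
                cfg = SessionConfig(mix=ChannelMix(lambda_hr=lam, lambda_pa=lam),
                                    task=TaskConfig(n_trials=200))
                s = cp.simulate_session(cfg, seed=seed0 + i, with_ecg=False)
                cardiac = cp.cardiac_series(cp.BeatSeries(s.beats_truth.beat_times))
                pupil = cp.smooth_pupil(cp.interpolate_blinks(s.pupil))
                bl = cp.extract_baselines(s.trials[20:], cardiac, pupil)
                resp = bl["responded"].to_numpy()
                r_pa = loocv_evaluate(bl, resp, ("pa",))
                r_hr = loocv_evaluate(bl, resp, ("hr",))
                m = overlap_metrics(r_pa.correct_idx, r_hr.correct_idx,
                                    r_pa.accuracy, r_hr.accuracy)
                vals.append(m.normalized_overlap)
            return np.mean(vals)

        assert mean_norm_overlap(0.0, 900) > mean_norm_overlap(1.4, 900)
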