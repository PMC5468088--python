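"""Chunk construction and logistic PreMO/PostMO decoding."""

import numpy as np
import pytest

from betapop.population_decoder import (
    make_chunks,
    mo_distance,
    onoff_beta_distance_comparison,
    select_chosen_units,
    select_threshold,
    train_mo_classifier,
)


def _chunks_from(counts, mot, rng=None, beta=None, fast=None, **kw):
    n_trials, n_bins, _ = counts.shape
    if beta is None:
        beta = np.zeros((n_trials, n_bins), bool)
    if fast is None:
        fast = np.zeros((n_trials, n_bins), bool)
    return make_chunks(counts, mot, beta, fast, **kw)


def _separable_data(rng, n_trials=30, n_bins=100, n_units=6, delta=3.0):
    """Poisson counts with a clean rate step at each trial's MOT."""
    mot = rng.uniform(0.1, 0.6, n_trials)
    t_end = -1.5 + 0.025 * (np.arange(n_bins) + 1)
    counts = np.empty((n_trials, n_bins, n_units))
    for i in range(n_trials):
        post = t_end >= mot[i]
        lam = 0.5 + delta * post
        counts[i] = rng.poisson(lam, (n_units, n_bins)).T
    return counts, mot


class TestMakeChunks:
    def test_100_bins_give_98_chunks_per_trial(self, rng):
        counts, mot = _separable_data(rng, n_trials=4)
        chunks = _chunks_from(counts, mot)
        assert len(chunks) == 4 * 98
        assert chunks.X.shape == (4 * 98, 3 * 6)

    def test_majority_beta_label(self, rng):
        counts, mot = _separable_data(rng, n_trials=1)
        beta = np.zeros((1, 100), bool)
        beta[0, :2] = True  # chunk 0 spans bins (0,1,2): 2-of-3 majority on
        beta[0, 3] = False
        chunks = _chunks_from(counts, mot, beta=beta)
        assert chunks.on_beta[0]
        assert not chunks.on_beta[2]

    def test_mot_before_window_makes_all_postmo(self, rng):
        counts, _ = _separable_data(rng, n_trials=2)
        chunks = _chunks_from(counts, np.array([-2.0, -2.0]))
        assert chunks.post_mo.all()

    def test_infinite_mot_makes_all_premo(self, rng):
        counts, _ = _separable_data(rng, n_trials=2)
        chunks = _chunks_from(counts, np.array([np.inf, np.inf]))
        assert not chunks.post_mo.any()

    def test_zero_variance_unit_excluded_and_reported(self, rng):
        counts, mot = _separable_data(rng, n_trials=3)
        counts[..., 4] = 0.0
        chunks = _chunks_from(counts, mot)
        assert chunks.excluded_units == [4]
        assert chunks.X.shape[1] == 3 * 5


class TestClassifier:
    def test_separable_classes_high_heldout_accuracy(self, rng):
        counts, mot = _separable_data(rng, n_trials=40)
        chunks = _chunks_from(counts, mot)
        train = chunks.subset(chunks.trial_index < 26)
        held = chunks.subset(chunks.trial_index >= 26)
        clf = train_mo_classifier(train)
        acc = np.mean((clf.prob_post_mo(held.X) > 0.5) == held.post_mo)
        assert acc > 0.95

    def test_probabilities_sum_to_one(self, rng):
        counts, mot = _separable_data(rng, n_trials=10)
        chunks = _chunks_from(counts, mot)
        clf = train_mo_classifier(chunks)
        p_post = clf.prob_post_mo(chunks.X)
        p_pre = clf.model.predict_proba(chunks.X)[:, 0]
        np.testing.assert_allclose(p_post + p_pre, 1.0, atol=1e-12)

    def test_label_shuffled_training_near_chance(self, rng):
        counts, mot = _separable_data(rng, n_trials=40)
        chunks = _chunks_from(counts, mot)
        shuffled = chunks.subset(np.ones(len(chunks), bool))
        shuffled.post_mo = rng.permutation(shuffled.post_mo)
        train = shuffled.subset(shuffled.trial_index < 26)
        held = shuffled.subset(shuffled.trial_index >= 26)
        clf = train_mo_classifier(train)
        acc = np.mean((clf.prob_post_mo(held.X) > 0.5) == held.post_mo)
        n = len(held)
        assert abs(acc - max(held.post_mo.mean(), 1 - held.post_mo.mean())) < 0.1

    def test_single_class_training_raises(self, rng):
        counts, _ = _separable_data(rng, n_trials=4)
        chunks = _chunks_from(counts, np.full(4, np.inf))
        with pytest.raises(ValueError, match="single class"):
            train_mo_classifier(chunks)

    def test_distance_matches_logistic_formula_oracle(self, rng):
        counts, mot = _separable_data(rng, n_trials=20)
        chunks = _chunks_from(counts, mot)
        clf = train_mo_classifier(chunks, threshold=0.3)
        dist = mo_distance(clf, chunks)
        # independent re-implementation of the standard logistic
        eta = clf.intercept + chunks.X @ clf.weights
        oracle = 1.0 / (1.0 + np.exp(-eta)) - 0.3
        np.testing.assert_allclose(dist, oracle, atol=1e-10)

    def test_distance_sign_convention(self, rng):
        counts, mot = _separable_data(rng, n_trials=30)
        chunks = _chunks_from(counts, mot)
        clf = train_mo_classifier(chunks)
        dist = mo_distance(clf, chunks)
        assert dist[chunks.post_mo].mean() > dist[~chunks.post_mo].mean()


class TestSelectThreshold:
    def test_balanced_symmetric_classes_near_half(self, rng):
        counts, mot = _separable_data(rng, n_trials=40, delta=1.0)
        chunks = _chunks_from(counts, np.full(40, 0.0))  # ~60/40 split by bins
        clf = train_mo_classifier(chunks)
        thr = select_threshold(clf, chunks)
        assert 0.2 <= thr <= 0.8

    def test_matches_exhaustive_sweep_oracle(self, rng):
        counts, mot = _separable_data(rng, n_trials=30, delta=0.8)
        chunks = _chunks_from(counts, mot)
        clf = train_mo_classifier(chunks)
        thr = select_threshold(clf, chunks)
        p = clf.prob_post_mo(chunks.X)
        grid = np.round(np.arange(0.005, 1.0, 0.005), 10)
        accs = np.array([np.mean((p > g) == chunks.post_mo) for g in grid])
        assert np.mean((p > thr) == chunks.post_mo) == pytest.approx(accs.max())

    def test_degenerate_predictor_returns_half(self, rng):
        counts, mot = _separable_data(rng, n_trials=10, delta=0.0)
        chunks = _chunks_from(counts, mot)
        clf = train_mo_classifier(chunks, C=1e-6)  # crushed weights
        thr = select_threshold(clf, chunks)
        assert thr == pytest.approx(0.5, abs=0.2)


class TestOnOffComparison:
    def test_identical_states_give_t_zero(self):
        days = []
        for d in range(4):
            dist = np.tile([0.1, -0.2, -0.3, 0.4], 25)
            on = np.tile([True, False], 50)
            days.append(
                {
                    "distances": np.concatenate([dist[on], dist[on]]),
                    "post_mo": np.zeros(100, bool),
                    "fast": np.zeros(100, bool),
                    "on_beta": np.arange(100) < 50,
                }
            )
        df, test = onoff_beta_distance_comparison(days)
        assert test["t"] == pytest.approx(0.0, abs=1e-12)

    def test_day_missing_state_dropped(self):
        day_ok = {
            "distances": np.array([0.1, -0.1]),
            "post_mo": np.zeros(2, bool),
            "fast": np.zeros(2, bool),
            "on_beta": np.array([True, False]),
        }
        day_bad = {
            "distances": np.array([0.1, -0.1]),
            "post_mo": np.zeros(2, bool),
            "fast": np.zeros(2, bool),
            "on_beta": np.array([True, True]),  # no off-beta
        }
        df, test = onoff_beta_distance_comparison([day_ok, day_bad, day_ok])
        assert test["dropped"] == [1]
        assert test["n_days"] == 2


class TestSelectChosenUnits:
    def test_constructed_partition(self, rng):
        # unit 0: strong MO step and on-beta suppression -> chosen
        # unit 1: flat -> unchosen
        n_trials, n_bins = 40, 100
        mot = rng.uniform(0.1, 0.6, n_trials)
        t_end = -1.5 + 0.025 * (np.arange(n_bins) + 1)
        beta = rng.uniform(size=(n_trials, n_bins)) < 0.3
        counts = np.empty((n_trials, n_bins, 2))
        for i in range(n_trials):
            post = t_end >= mot[i]
            lam0 = 0.5 + 3.0 * post - 0.4 * beta[i] * (~post)
            counts[i, :, 0] = rng.poisson(np.maximum(lam0, 0.01))
            counts[i, :, 1] = rng.poisson(0.5, n_bins)
        chunks = make_chunks(counts, mot, beta, np.zeros((n_trials, n_bins), bool))
        chosen, details, comps = select_chosen_units(
            {"CO": chunks, "NR": chunks},
            metrics={"mean_rate": np.array([1.0, 0.5])},
        )
        assert chosen[0] and not chosen[1]
        assert len(comps) == 1
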