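import numpy as np
import pytest

from csrep import (
    ClassifierModel,
    SampleGroup,
    StateMap,
    argmax_state_map,
    base_count_summary,
    fit_classifier,
    one_hot_features,
    predict_probabilities,
    sample_training_positions,
    summarize_group,
)
from csrep.genome import GenomeIndex, StateScheme

from oracles import per_bin_mode, softmax_penalized_fit, softmax_probs, tally_base_count


class TestTrainingPositions:
    def test_ten_percent_of_genome(self, make_group):
        index = GenomeIndex(chromosomes=(("chr1", 200_000),), bin_size=200)
        ti = sample_training_positions(index, 0.1, seed=4)
        assert ti.positions.size == 100  # floor(0.1 * 1000)
        assert np.unique(ti.positions).size == 100

    def test_full_fraction_selects_every_bin(self):
        index = GenomeIndex(chromosomes=(("chr1", 10_000),), bin_size=200)
        ti = sample_training_positions(index, 1.0, seed=0)
        assert np.array_equal(np.sort(ti.positions), np.arange(50))

    def test_deterministic_given_seed(self):
        index = GenomeIndex(chromosomes=(("chr1", 100_000),), bin_size=200)
        a = sample_training_positions(index, 0.1, seed=7)
        b = sample_training_positions(index, 0.1, seed=7)
        c = sample_training_positions(index, 0.1, seed=8)
        assert np.array_equal(a.positions, b.positions)
        assert not np.array_equal(a.positions, c.positions)

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_rejects_bad_fraction(self, fraction):
        index = GenomeIndex(chromosomes=(("chr1", 10_000),), bin_size=200)
        with pytest.raises(ValueError):
            sample_training_positions(index, fraction, seed=0)

    def test_rejects_empty_selection(self):
        index = GenomeIndex(chromosomes=(("chr1", 1000),), bin_size=200)
        with pytest.raises(ValueError):
            sample_training_positions(index, 0.01, seed=0)  # floor(0.05) = 0


class TestOneHotFeatures:
    def test_worked_row(self):
        """N=3, S=2, non-target states (1, 2) -> [1,0, 0,1, 1]."""
        index = GenomeIndex(chromosomes=(("chr1", 200),), bin_size=200)
        scheme = StateScheme.from_n_states(2)
        members = [
            StateMap("a", [1], index, scheme),
            StateMap("b", [1], index, scheme),
            StateMap("c", [2], index, scheme),
        ]
        group = SampleGroup("g", members)
        X = one_hot_features(group, "a", [0])
        assert X.tolist() == [[1, 0, 0, 1, 1]]

    def test_one_hot_structure(self, make_group):
        group = make_group(N=4, S=3, G=30, seed=1)
        X = one_hot_features(group, "s2", np.arange(30))
        assert X.shape == (30, 3 * 3 + 1)
        assert np.all(X[:, -1] == 1)
        # exactly one indicator per non-target sample block
        for k in range(3):
            assert np.all(X[:, k * 3:(k + 1) * 3].sum(axis=1) == 1)

    def test_smallest_ensemble_width(self, make_group):
        group = make_group(N=2, S=4, G=10)
        X = one_hot_features(group, "s0", np.arange(10))
        assert X.shape[1] == 4 + 1

    def test_unknown_target_rejected(self, make_group):
        with pytest.raises(KeyError):
            one_hot_features(make_group(), "nope", [0])


class TestFitClassifier:
    def test_no_signal_predicts_class_frequencies(self):
        """With features carrying no information, the fitted probabilities
        reproduce the training class frequencies (intercept-only fit)."""
        n, S = 300, 3
        X = np.zeros((n, 4))
        X[:, 0] = 1.0  # constant one-hot feature
        X[:, -1] = 1.0
        y = np.concatenate([np.full(100, 1), np.full(100, 2), np.full(100, 3)])
        model = fit_classifier(X, y, n_states=S)
        probs = model.predict_proba(X[:1])
        assert np.allclose(probs, 1 / 3, atol=1e-3)

    def test_zero_coefficients_give_uniform(self):
        model = ClassifierModel(target_sample="t", coefficients=np.zeros((4, 9)),
                                classes=np.arange(1, 5), n_states=4)
        X = np.zeros((5, 9))
        X[:, -1] = 1
        assert np.allclose(model.predict_proba(X), 0.25)

    def test_matches_penalized_likelihood_oracle(self):
        """Tiny fixed instance: sklearn fit agrees with an independent
        full-batch gradient-descent optimizer of the same penalized
        likelihood to 1e-4 in predicted probabilities."""
        rng = np.random.default_rng(42)
        n, S = 20, 3
        width = 2 * S + 1  # N=3 ensemble geometry
        states = rng.integers(1, S + 1, size=(n, 2))
        X = np.zeros((n, width))
        for k in range(2):
            X[np.arange(n), k * S + states[:, k] - 1] = 1
        X[:, -1] = 1
        y = rng.integers(1, S + 1, size=n)
        model = fit_classifier(X, y, l2_strength=1.0, n_states=S)
        W = softmax_penalized_fit(X, y, S, C=1.0)
        assert np.abs(model.predict_proba(X) - softmax_probs(W, X)).max() < 1e-4

    def test_single_class_training_falls_back_to_constant(self):
        X = np.ones((5, 3))
        y = np.full(5, 2)
        with pytest.warns(RuntimeWarning):
            model = fit_classifier(X, y, n_states=3)
        probs = model.predict_proba(X)
        assert np.allclose(probs[:, 1], 1.0)

    def test_rejects_labels_out_of_range(self):
        X = np.ones((4, 3))
        with pytest.raises(ValueError):
            fit_classifier(X, np.array([1, 2, 3, 9]), n_states=3)


class TestPredictProbabilities:
    def test_rows_sum_to_one_and_identical_inputs_match(self, make_group):
        group = make_group(N=3, S=4, G=200, seed=3)
        X = one_hot_features(group, "s0", np.arange(200))
        model = fit_classifier(X, group.member("s0").states, n_states=4,
                               target_sample="s0")
        P = predict_probabilities(model, group)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
        others = np.stack([group.member("s1").states, group.member("s2").states], axis=1)
        i, j = 0, int(np.flatnonzero((others == others[0]).all(axis=1))[1])
        assert np.allclose(P[i], P[j])

    def test_zero_coefficient_model_uniform(self, make_group):
        group = make_group(N=3, S=4, G=20)
        model = ClassifierModel(target_sample="s0",
                                coefficients=np.zeros((4, 2 * 4 + 1)),
                                classes=np.arange(1, 5), n_states=4)
        assert np.allclose(predict_probabilities(model, group), 0.25)

    def test_width_mismatch_rejected(self, make_group):
        group = make_group(N=4, S=4, G=20)
        model = ClassifierModel(target_sample="s0",
                                coefficients=np.zeros((4, 2 * 4 + 1)),
                                classes=np.arange(1, 5), n_states=4)
        with pytest.raises(ValueError):
            predict_probabilities(model, group)


class TestSummarizeGroup:
    def test_rows_sum_to_one(self, make_group):
        group = make_group(N=3, S=4, G=400, seed=5)
        summary = summarize_group(group, fraction=0.5, seed=1)
        assert np.max(np.abs(summary.probs.sum(axis=1) - 1.0)) < 1e-6
        assert summary.method == "csrep"
        assert summary.probs.min() >= 0 and summary.probs.max() <= 1

    def test_consensus_limit(self):
        """Identical members: the argmax summary equals the shared map."""
        rng = np.random.default_rng(0)
        index = GenomeIndex(chromosomes=(("chr1", 400 * 200),), bin_size=200)
        scheme = StateScheme.from_n_states(4)
        shared = rng.integers(1, 5, size=400)
        group = SampleGroup("g", [StateMap(f"s{n}", shared.copy(), index, scheme)
                                  for n in range(3)])
        summary = summarize_group(group, fraction=0.5, seed=1)
        assert np.array_equal(argmax_state_map(summary), shared)

    def test_member_order_invariance(self, make_group):
        group = make_group(N=4, S=3, G=300, seed=9)
        perm = SampleGroup("g", [group.members[i] for i in (2, 0, 3, 1)])
        a = summarize_group(group, fraction=0.5, seed=6)
        b = summarize_group(perm, fraction=0.5, seed=6)
        assert np.max(np.abs(a.probs - b.probs)) < 1e-6

    def test_needs_at_least_two_members(self, make_group):
        group = make_group(N=3)
        solo = SampleGroup("solo", group.members[:1])
        with pytest.raises(ValueError):
            summarize_group(solo, seed=0)


class TestBaseCount:
    def test_counting_definition(self):
        index = GenomeIndex(chromosomes=(("chr1", 200),), bin_size=200)
        scheme = StateScheme.from_n_states(2)
        group = SampleGroup("g", [StateMap(f"s{n}", [s], index, scheme)
                                  for n, s in enumerate((1, 1, 2))])
        summary = base_count_summary(group)
        assert summary.probs.tolist() == [[2 / 3, 1 / 3]]
        assert summary.method == "base_count"

    def test_rows_sum_exactly_to_one(self, make_group):
        group = make_group(N=4, S=5, G=100, seed=2)
        summary = base_count_summary(group)
        assert np.all(summary.probs.sum(axis=1) == 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_tally(self, make_group, seed):
        group = make_group(N=5, S=3, G=40, seed=seed)
        assert np.array_equal(base_count_summary(group).probs, tally_base_count(group))


class TestArgmax:
    def test_max_probability_wins(self, make_group):
        group = make_group(N=3, S=3, G=1)
        summary = base_count_summary(group)
        summary.probs = np.array([[0.1, 0.7, 0.2]])
        assert argmax_state_map(summary).tolist() == [2]

    def test_tie_goes_to_lowest_state(self, make_group):
        group = make_group(N=2, S=2, G=1)
        summary = base_count_summary(group)
        summary.probs = np.array([[0.5, 0.5]])
        assert argmax_state_map(summary).tolist() == [1]

    @pytest.mark.parametrize("seed", [3, 4])
    def test_base_count_argmax_is_per_bin_mode(self, make_group, seed):
        group = make_group(N=5, S=4, G=60, seed=seed)
        assert np.array_equal(argmax_state_map(base_count_summary(group)),
                              per_bin_mode(group))
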