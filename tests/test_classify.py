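"""Classification tests: tree, PI threshold, frame rules, DP validation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleotrace.classify import (
    CLASS1_LARGE_UNIFORM,
    CLASS2_CONDENSED,
    FEASIBLE_TRANSITIONS,
    TrainedClassifier,
    calibrate_pi_threshold,
    classify_frame,
    train_tree,
    validate_sequence,
    validate_sequence_two_pass,
)
from nucleotrace.types import CellState

from conftest import make_detection

V, A, N = CellState.VIABLE, CellState.APOPTOTIC, CellState.NECROTIC


def brute_force_validate(raw, allowed=FEASIBLE_TRANSITIONS):
    """Enumerate every feasible 3-state sequence and apply the stated
    tie-break: minimum disagreement count, then per frame (forward) prefer
    matching the raw label, then the earliest state."""
    n = len(raw)
    best_key, best_seq, best_cost = None, None, None
    for seq in itertools.product((0, 1, 2), repeat=n):
        if any(not allowed[a, b] for a, b in zip(seq, seq[1:])):
            continue
        cost = sum(1 for t, s in enumerate(seq)
                   if raw[t] is not None and int(raw[t]) != s)
        key = (cost, tuple(
            (0 if (raw[t] is not None and int(raw[t]) == s) else 1, s)
            for t, s in enumerate(seq)))
        if best_key is None or key < best_key:
            best_key, best_seq, best_cost = key, seq, cost
    return [CellState(s) for s in best_seq], best_cost


def separable_training_set():
    """Class 2 iff h_mean > 500; 20 rows, 1-D separable."""
    feats, labels = [], []
    for k in range(10):
        feats.append([150, 300 + k, 50, 900, 100])
        labels.append(CLASS1_LARGE_UNIFORM)
        feats.append([150, 700 + k, 50, 900, 100])
        labels.append(CLASS2_CONDENSED)
    return np.array(feats, float), np.array(labels)


class TestTrainTree:
    def test_separable_toy_depth_one_split_on_mean(self):
        feats, labels = separable_training_set()
        model = train_tree(feats, labels)
        assert model.depth == 1
        assert model.feature[0] == 1  # h_mean column
        pred = np.array([model.predict_class(f) for f in feats])
        assert np.array_equal(pred, labels)

    def test_contradictory_duplicates_majority_vote(self):
        feats = np.tile([100.0, 500.0, 50.0, 900.0, 100.0], (15, 1))
        labels = np.array([CLASS1_LARGE_UNIFORM] * 10
                          + [CLASS2_CONDENSED] * 5)
        model = train_tree(feats, labels)
        assert model.predict_class(feats[0]) == CLASS1_LARGE_UNIFORM

    def test_single_class_rejected(self):
        feats = np.tile([100.0, 500.0, 50.0, 900.0, 100.0], (10, 1))
        with pytest.raises(ValueError):
            train_tree(feats, np.ones(10, dtype=int))

    def test_too_few_rows_per_class_rejected(self):
        feats, labels = separable_training_set()
        with pytest.raises(ValueError):
            train_tree(feats[:7], labels[:7])

    def test_training_deterministic(self):
        feats, labels = separable_training_set()
        m1, m2 = train_tree(feats, labels), train_tree(feats, labels)
        assert m1.to_json() == m2.to_json()

    def test_json_round_trip(self):
        feats, labels = separable_training_set()
        model = train_tree(feats, labels)
        model.pi_threshold = 123.4
        clone = TrainedClassifier.from_json(model.to_json())
        assert clone.to_json() == model.to_json()
        assert clone.predict_class(feats[0]) == model.predict_class(feats[0])

    def test_heldout_accuracy_on_generator_features(self, default_model):
        from nucleotrace.pipeline import make_training_data
        from nucleotrace.synthetic import SceneConfig

        feats, labels, _ = make_training_data(SceneConfig(rng_seed=30_303))
        pred = np.array([default_model.predict_class(f) for f in feats])
        assert (pred == labels).mean() >= 0.9


class TestCalibratePiThreshold:
    def test_bimodal_threshold_between_populations(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(100, 5, 200),
                               rng.normal(2000, 50, 100)])
        dets = [make_detection(0, 0, 0, pi_mean=v) for v in vals]
        cal = calibrate_pi_threshold(dets)
        assert cal.method == "otsu"
        assert 115 < cal.threshold < 1850

    def test_all_negative_fallback_formula(self):
        # unimodal controls around 100 with sd 10 -> mean + 5*sd ~ 150
        rng = np.random.default_rng(2)
        vals = rng.normal(100.0, 10.0, 300)
        dets = [make_detection(0, 0, 0, pi_mean=v) for v in vals]
        cal = calibrate_pi_threshold(dets, k=5.0)
        assert cal.method == "mean_plus_k_sd"
        assert cal.threshold == pytest.approx(vals.mean() + 5 * vals.std())
        assert cal.threshold == pytest.approx(150.0, rel=0.05)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            calibrate_pi_threshold([])

    def test_separates_necrotic_frames_on_synthetic_scene(self, default_model):
        from nucleotrace.pipeline import make_training_data, match_detections
        from nucleotrace.synthetic import SceneConfig, sample_scene
        from nucleotrace.pipeline import segment_scene

        cfg = SceneConfig(rng_seed=909, necrotic_fraction=0.5,
                          apoptotic_fraction=0.2)
        cells, _ = sample_scene(cfg)
        frames = [12, 20, 24]
        dets_by = segment_scene(cells, cfg, frames)
        thr = default_model.pi_threshold
        hits = total = 0
        for k, t in enumerate(frames):
            match = match_detections(dets_by[k], cells, t)
            for j, d in enumerate(dets_by[k]):
                if j in match and cells[match[j]].state_at(t) == N:
                    total += 1
                    hits += int(d.pi_mean > thr)
        assert total > 20
        assert hits / total >= 0.95


class TestClassifyFrame:
    def _model(self, pi_threshold=200.0):
        feats, labels = separable_training_set()
        model = train_tree(feats, labels)
        model.pi_threshold = pi_threshold
        return model

    def test_class1_low_pi_is_viable(self):
        det = make_detection(0, 0, 0, h_mean=300, pi_mean=50)
        assert classify_frame(det, self._model()) == V

    def test_class1_high_pi_is_necrotic(self):
        det = make_detection(0, 0, 0, h_mean=300, pi_mean=900)
        assert classify_frame(det, self._model()) == N

    def test_class2_is_apoptotic_at_any_pi(self):
        for pi in (0.0, 5000.0):
            det = make_detection(0, 0, 0, h_mean=800, pi_mean=pi)
            assert classify_frame(det, self._model()) == A

    def test_missing_detection_is_unknown(self):
        assert classify_frame(None, self._model()) is None


class TestValidateSequence:
    def test_constant_viable_unchanged(self):
        validated, n = validate_sequence([V] * 10)
        assert validated == [V] * 10 and n == 0

    def test_necrotic_flicker_erased(self):
        validated, n = validate_sequence([V, V, N, V, V])
        assert validated == [V] * 5
        assert n == 1

    def test_apoptotic_relapse_filled(self):
        validated, n = validate_sequence([V, A, V, A, N])
        assert validated == [V, A, A, A, N]
        assert n == 1

    def test_output_never_contains_forbidden_transition(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            raw = [None if rng.uniform() < 0.2
                   else CellState(int(rng.integers(3)))
                   for _ in range(int(rng.integers(1, 12)))]
            validated, _ = validate_sequence(raw)
            for a, b in zip(validated, validated[1:]):
                assert FEASIBLE_TRANSITIONS[int(a), int(b)]

    def test_unknown_frames_inherit_optimal_path(self):
        validated, n = validate_sequence([None, V, None, N, None])
        assert validated == [V, V, V, N, N]
        assert n == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            validate_sequence([])

    @pytest.mark.parametrize("seed", range(30))
    def test_dp_equals_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 9))
        raw = [None if rng.uniform() < 0.15
               else CellState(int(rng.integers(3))) for _ in range(n)]
        got_seq, got_n = validate_sequence(raw)
        want_seq, want_n = brute_force_validate(raw)
        assert got_n == want_n
        assert got_seq == want_seq

    @pytest.mark.parametrize("seed", range(10))
    def test_no_single_edit_improves_discrepancy(self, seed):
        rng = np.random.default_rng(100 + seed)
        raw = [CellState(int(rng.integers(3))) for _ in range(8)]
        validated, n = validate_sequence(raw)
        seq = [int(s) for s in validated]

        def feasible(s):
            return all(FEASIBLE_TRANSITIONS[a, b]
                       for a, b in zip(s, s[1:]))

        def cost(s):
            return sum(1 for t, x in enumerate(s) if int(raw[t]) != x)

        assert cost(seq) == n
        for t in range(8):
            for alt in (0, 1, 2):
                if alt == seq[t]:
                    continue
                edited = seq[:t] + [alt] + seq[t + 1:]
                if feasible(edited):
                    assert cost(edited) >= n

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(st.lists(st.sampled_from([None, V, A, N]), min_size=1,
                    max_size=10))
    def test_validated_sequence_properties(self, raw):
        """For any raw labelling: output is feasible, same length, the
        reported correction count is exact, and it never exceeds the
        number of known labels."""
        validated, n = validate_sequence(raw)
        assert len(validated) == len(raw)
        for a, b in zip(validated, validated[1:]):
            assert FEASIBLE_TRANSITIONS[int(a), int(b)]
        mismatches = sum(1 for r, v in zip(raw, validated)
                         if r is not None and r != v)
        assert n == mismatches
        assert n <= sum(1 for r in raw if r is not None)

    def test_two_pass_feasible_and_not_better_than_dp(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            raw = [None if rng.uniform() < 0.2
                   else CellState(int(rng.integers(3)))
                   for _ in range(int(rng.integers(1, 10)))]
            seq, n2 = validate_sequence_two_pass(raw)
            for a, b in zip(seq, seq[1:]):
                assert FEASIBLE_TRANSITIONS[int(a), int(b)]
            _, ndp = validate_sequence(raw)
            assert n2 >= ndp
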