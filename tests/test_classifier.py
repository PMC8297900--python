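"""Window classification, majority vote, model persistence."""

import numpy as np
import pytest

import attachmon as am
from attachmon._rnn import GRUClassifier
from attachmon.classifier import majority_vote, predict_windows, save_model, load_model, train
from attachmon.errors import DegenerateInputError, SchemaError
from attachmon.labels import BinaryLabel

from conftest import make_feature_windows


def _accuracy(preds, windows):
    return np.mean(
        [
            (p.hard_label is BinaryLabel.INSECURE) == (not w.label.secure)
            for p, w in zip(preds, windows)
        ]
    )


@pytest.mark.parametrize("backend", ["summary-logistic", "recurrent-sequence"])
def test_separable_classes_learned(backend, separable_windows):
    spec = am.ModelSpec(backend=backend, seed=7, epochs=30)
    model = train(separable_windows, spec)
    preds = predict_windows(model, separable_windows)
    assert _accuracy(preds, separable_windows) >= 0.95
    held_out = make_feature_windows(10, seed=99)
    held_preds = predict_windows(model, held_out)
    assert _accuracy(held_preds, held_out) >= 0.9
    assert all(0.0 <= p.p_insecure <= 1.0 for p in held_preds)


def test_recurrent_training_loss_decreases(separable_windows):
    model = train(
        separable_windows[:40] + separable_windows[40:60],
        am.ModelSpec(backend="recurrent-sequence", seed=3, epochs=15),
    )
    hist = model.backend.loss_history_
    assert hist[-1] < hist[0]


def test_seeded_training_is_deterministic(separable_windows):
    held_out = make_feature_windows(5, seed=31)
    p1 = predict_windows(
        train(separable_windows, am.ModelSpec(backend="recurrent-sequence", seed=7, epochs=5)),
        held_out,
    )
    p2 = predict_windows(
        train(separable_windows, am.ModelSpec(backend="recurrent-sequence", seed=7, epochs=5)),
        held_out,
    )
    assert [p.p_insecure for p in p1] == [p.p_insecure for p in p2]


def test_prediction_is_pure(separable_windows):
    model = train(separable_windows, am.ModelSpec(seed=0))
    a = predict_windows(model, separable_windows[:10])
    b = predict_windows(model, separable_windows[:10])
    assert a == b


def test_empty_window_list_gives_empty_predictions(separable_windows):
    model = train(separable_windows, am.ModelSpec(seed=0))
    assert predict_windows(model, []) == []


def test_single_class_training_rejected(separable_windows):
    secure_only = [w for w in separable_windows if w.label.secure]
    with pytest.raises(DegenerateInputError):
        train(secure_only, am.ModelSpec(seed=0))


def test_inconsistent_window_lengths_rejected(separable_windows):
    short = make_feature_windows(2, window_size=64, seed=1)
    with pytest.raises(SchemaError):
        train(list(separable_windows) + short, am.ModelSpec(seed=0))


def test_model_round_trips_through_json(tmp_path, separable_windows):
    for backend in ("summary-logistic", "recurrent-sequence"):
        spec = am.ModelSpec(backend=backend, seed=2, epochs=5)
        model = train(separable_windows, spec)
        path = tmp_path / f"{backend}.json"
        save_model(model, path)
        back = load_model(path)
        held = make_feature_windows(5, seed=8)
        assert [p.p_insecure for p in predict_windows(model, held)] == pytest.approx(
            [p.p_insecure for p in predict_windows(back, held)]
        )


def test_schema_mismatch_refused(separable_windows):
    model = train(separable_windows, am.ModelSpec(seed=0))
    bad = make_feature_windows(1, seed=0)[0]
    bad.columns = tuple(c + "_v2" for c in bad.columns)
    with pytest.raises(SchemaError):
        predict_windows(model, [bad])


def test_distance_family_alone_carries_signal(small_cohort):
    # restricting the deterministic backend to the inter-hand distance
    # channels must still beat chance on the synthetic cohort
    _, _, windows = small_cohort
    flat = [w for ws in windows.values() for w in ws]
    model = train(
        flat, am.ModelSpec(backend="summary-logistic", seed=0),
        feature_mask=("dist", "dist_valid"),
    )
    acc = _accuracy(predict_windows(model, flat), flat)
    assert acc > 0.6


class TestMajorityVote:
    def _preds(self, child, labels):
        return [
            am.WindowPrediction(child, i, 1.0 if lab else 0.0,
                                BinaryLabel.INSECURE if lab else BinaryLabel.SECURE)
            for i, lab in enumerate(labels)
        ]

    def test_unanimous(self):
        r = majority_vote(self._preds("c", [1] * 10))
        assert r.label is BinaryLabel.INSECURE
        assert r.vote_fraction == 1.0 and r.n_windows == 10

    def test_majority_with_cap(self):
        # 260 secure then 240 insecure within the 500-window cap
        r = majority_vote(self._preds("c", [0] * 260 + [1] * 240), cap=500)
        assert r.label is BinaryLabel.SECURE
        assert r.vote_fraction == pytest.approx(0.52)
        assert r.n_windows == 500

    def test_cap_limits_counted_windows(self):
        # windows beyond the cap (temporal order) do not vote
        r = majority_vote(self._preds("c", [1] * 300 + [0] * 400), cap=500)
        assert r.n_windows == 500
        assert r.label is BinaryLabel.INSECURE  # 300 vs 200 within the cap

    def test_exact_tie_resolves_insecure(self):
        r = majority_vote(self._preds("c", [0] * 250 + [1] * 250), cap=500)
        assert r.label is BinaryLabel.INSECURE
        assert r.vote_fraction == 0.5

    def test_flip_property_and_vote_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            labs = rng.integers(0, 2, size=rng.integers(1, 30)).tolist()
            r = majority_vote(self._preds("c", labs))
            assert 0.5 <= r.vote_fraction <= 1.0
            flipped = majority_vote(self._preds("c", [1 - l for l in labs]))
            if sum(labs) * 2 != len(labs):  # not a tie
                assert flipped.label is not r.label
            else:
                assert r.label is BinaryLabel.INSECURE
                assert flipped.label is BinaryLabel.INSECURE

    def test_permutation_invariant_below_cap(self):
        rng = np.random.default_rng(4)
        labs = rng.integers(0, 2, size=21).tolist()
        preds = self._preds("c", labs)
        shuffled = list(preds)
        rng.shuffle(shuffled)
        assert majority_vote(preds) == majority_vote(shuffled)

    def test_mixed_children_rejected(self):
        preds = self._preds("a", [1]) + self._preds("b", [1])
        with pytest.raises(ValueError, match="mix"):
            majority_vote(preds)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


def test_gru_gradients_match_numerical():
    """BPTT gradients agree with central finite differences on a tiny net."""
    rng = np.random.default_rng(0)
    net = GRUClassifier(n_features=2, hidden_size=3, seed=1)
    net._init_params(np.random.default_rng(1))
    X = rng.standard_normal((4, 5, 2))
    y = np.array([0.0, 1.0, 1.0, 0.0])
    sw = np.array([1.0, 2.0, 1.0, 0.5])
    prob, cache = net._forward(X)
    grads = net._backward(X, y, sw, prob, cache)
    eps = 1e-6
    for name, g in grads.items():
        p = net.params[name]
        it = np.nditer(p, flags=["multi_index"])
        for _ in range(min(p.size, 6)):  # spot-check a few entries per tensor
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + eps
            lp = net._loss(net._forward(X)[0], y, sw)
            p[idx] = orig - eps
            lm = net._loss(net._forward(X)[0], y, sw)
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(num, abs=1e-6, rel=1e-4)
            it.iternext()
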