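"""Unit tests for the subject split, label binarization and voting logic.

Voting tests stub the five columns with deterministic fakes, so the
ensemble combination rule is exercised as a pure function of the column
decisions, independent of any training.
"""

import numpy as np
import pytest

from affecteeg.ensemble import (
    ColumnConfig,
    EnsembleModel,
    N_COLUMNS,
    binarize_labels,
    evaluate,
    predict_trial,
    split_subjects,
    train_ensemble,
    windows_from_corpus,
    load_model,
    save_model,
)
from affecteeg.preprocess import TrialWindowSet
from affecteeg.synthetic import GeneratorParams, generate_deap_like


class TestSplit:
    def test_canonical_22_5_5_trial_counts(self):
        ids = [f"s{i:02d}" for i in range(1, 33)]
        spec = split_subjects(ids, 22, 5, 5, seed=1)
        assert (len(spec.train), len(spec.val), len(spec.test)) == (22, 5, 5)
        assert 40 * len(spec.train) == 880
        assert 40 * len(spec.val) == 200
        assert 40 * len(spec.test) == 200

    def test_small_split_counts(self):
        spec = split_subjects(["a", "b", "c", "d"], 2, 1, 1, seed=0)
        assert 40 * len(spec.train) == 80
        assert 40 * len(spec.val) == 40 * len(spec.test) == 40

    def test_partitions_disjoint_and_exhaustive(self):
        ids = [f"s{i}" for i in range(10)]
        spec = split_subjects(ids, 6, 2, 2, seed=3)
        assert set(spec.train) | set(spec.val) | set(spec.test) == set(ids)
        assert not set(spec.train) & set(spec.val)
        assert not set(spec.val) & set(spec.test)

    def test_deterministic_given_seed(self):
        ids = [f"s{i}" for i in range(8)]
        assert split_subjects(ids, 4, 2, 2, seed=9) == split_subjects(ids, 4, 2, 2, seed=9)

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            split_subjects(["a", "b", "c"], 2, 2, 2, seed=0)


class TestBinarize:
    @pytest.mark.parametrize("label,cls", [
        (7.2, 1), (5.0, 1), (1.0, 0), (4.999, 0), (9.0, 1),
    ])
    def test_threshold_at_midpoint(self, label, cls):
        assert binarize_labels(label) == cls

    @pytest.mark.parametrize("bad", [0.5, 9.5, float("nan")])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            binarize_labels(bad)


class _StubColumn:
    """Fake column emitting fixed per-window classes for both heads."""

    def __init__(self, val_classes, aro_classes=None):
        self.v = np.asarray(val_classes)
        self.a = np.asarray(aro_classes if aro_classes is not None else val_classes)

    def predict_classes(self, windows, batch=2048):
        n = windows.shape[0]
        return self.v[:n], self.a[:n]


def _stub_model(columns):
    return EnsembleModel(columns=list(columns), config=ColumnConfig())


def _trial(n_windows=4, v=None, a=None):
    return TrialWindowSet(np.zeros((n_windows, 32, 32)),
                          trial_id="t", valence_class=v, arousal_class=a)


class TestVoting:
    def test_unanimous_high_gives_score_one(self):
        model = _stub_model([_StubColumn([1, 1, 1, 1])] * N_COLUMNS)
        cv, ca, sv, sa = predict_trial(model, _trial())
        assert (cv, ca) == (1, 1)
        assert (sv, sa) == (1.0, 1.0)

    def test_unanimous_low_gives_score_minus_one(self):
        model = _stub_model([_StubColumn([0, 0, 0, 0])] * N_COLUMNS)
        cv, _, sv, _ = predict_trial(model, _trial())
        assert cv == 0
        assert sv == -1.0

    def test_two_high_three_low_majority_is_low(self):
        cols = ([_StubColumn([1, 1, 1, 1])] * 2 + [_StubColumn([0, 0, 0, 0])] * 3)
        cv, _, _, _ = predict_trial(_stub_model(cols), _trial())
        assert cv == 0

    def test_column_order_invariance(self):
        cols = [_StubColumn([1, 1, 0, 0]), _StubColumn([1, 0, 0, 0]),
                _StubColumn([1, 1, 1, 0]), _StubColumn([0, 0, 0, 0]),
                _StubColumn([1, 1, 1, 1])]
        base = predict_trial(_stub_model(cols), _trial())
        for perm in ([4, 3, 2, 1, 0], [2, 0, 4, 1, 3]):
            assert predict_trial(_stub_model([cols[i] for i in perm]), _trial()) == base

    def test_window_tie_within_column_breaks_low(self):
        # 2 of 4 windows high -> not a strict majority -> column votes low
        model = _stub_model([_StubColumn([1, 1, 0, 0])] * N_COLUMNS)
        cv, _, _, _ = predict_trial(model, _trial())
        assert cv == 0

    def test_column_vote_score_quantization(self):
        cols = ([_StubColumn([1, 1, 1, 1])] * 3 + [_StubColumn([0, 0, 0, 0])] * 2)
        _, _, sv, _ = predict_trial(_stub_model(cols), _trial(), score_mode="column_vote")
        assert sv == pytest.approx(2 * 3 / 5 - 1)  # 0.2
        for k in range(6):
            cols = ([_StubColumn([1] * 4)] * k + [_StubColumn([0] * 4)] * (5 - k))
            _, _, s, _ = predict_trial(_stub_model(cols), _trial(), score_mode="column_vote")
            assert s == pytest.approx(2 * k / 5 - 1)

    def test_window_fraction_score_bounds(self):
        cols = [_StubColumn([1, 0, 0, 0]), _StubColumn([1, 1, 0, 0]),
                _StubColumn([0, 0, 0, 0]), _StubColumn([1, 1, 1, 0]),
                _StubColumn([1, 1, 1, 1])]
        _, _, sv, _ = predict_trial(_stub_model(cols), _trial())
        assert -1.0 < sv < 1.0
        assert sv == pytest.approx(2 * 10 / 20 - 1)

    def test_wrong_window_shape_rejected(self):
        model = _stub_model([_StubColumn([1])] * N_COLUMNS)
        with pytest.raises(ValueError, match="32x32"):
            predict_trial(model, TrialWindowSet(np.zeros((1, 16, 16))))

    def test_ensemble_size_enforced(self):
        with pytest.raises(ValueError, match="5"):
            _stub_model([_StubColumn([1])] * 3)


class TestEvaluate:
    def test_perfect_and_complement_predictions(self):
        trials = [_trial(v=1, a=0), _trial(v=1, a=0)]
        right = _stub_model([_StubColumn([1, 1, 1, 1], [0, 0, 0, 0])] * N_COLUMNS)
        wrong = _stub_model([_StubColumn([0, 0, 0, 0], [1, 1, 1, 1])] * N_COLUMNS)
        assert evaluate(right, trials) == {"valence": 1.0, "arousal": 1.0}
        assert evaluate(wrong, trials) == {"valence": 0.0, "arousal": 0.0}

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_stub_model([_StubColumn([1])] * N_COLUMNS), [])


@pytest.fixture(scope="module")
def tiny_corpus():
    # 2 subjects x 40 one-second trials: enough to exercise training end to end
    return generate_deap_like(2, GeneratorParams(trial_seconds=1.0), seed=5)


TINY_CONFIG = ColumnConfig(conv_channels=(4, 8, 8, 8), max_epochs=2, patience=2,
                           batch_size=64, train_windows_per_trial=4,
                           val_windows_per_trial=4, seed=17)


class TestTrainEnsemble:
    def test_retraining_is_bit_reproducible(self, tiny_corpus):
        tr = windows_from_corpus(tiny_corpus, ["s01"])
        va = windows_from_corpus(tiny_corpus, ["s02"])
        m1 = train_ensemble(tr, va, TINY_CONFIG)
        m2 = train_ensemble(tr, va, TINY_CONFIG)
        for c1, c2 in zip(m1.columns, m2.columns):
            for k in c1.params:
                assert np.array_equal(c1.params[k], c2.params[k])
        assert predict_trial(m1, tr[0]) == predict_trial(m2, tr[0])

    def test_manifest_records_seeds_and_epochs(self, tiny_corpus):
        tr = windows_from_corpus(tiny_corpus, ["s01"])
        va = windows_from_corpus(tiny_corpus, ["s02"])
        m = train_ensemble(tr, va, TINY_CONFIG)
        assert len(m.manifest["column_seeds"]) == N_COLUMNS
        assert len(set(m.manifest["column_seeds"])) == N_COLUMNS  # distinct inits
        assert len(m.manifest["epochs_run"]) == N_COLUMNS
        assert m.manifest["train_data_hash"]

    def test_save_load_round_trip(self, tiny_corpus, tmp_path):
        tr = windows_from_corpus(tiny_corpus, ["s01"])
        va = windows_from_corpus(tiny_corpus, ["s02"])
        m = train_ensemble(tr, va, TINY_CONFIG)
        save_model(m, tmp_path / "model")
        m2 = load_model(tmp_path / "model")
        assert predict_trial(m, tr[3]) == predict_trial(m2, tr[3])

    def test_empty_partition_rejected(self, tiny_corpus):
        tr = windows_from_corpus(tiny_corpus, ["s01"])
        with pytest.raises(ValueError):
            train_ensemble(tr, [], TINY_CONFIG)
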