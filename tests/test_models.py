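import numpy as np
import pytest

from berbp import (
    LabeledDataset,
    VoteForest,
    cross_predict,
    feature_importance,
    oob_scores,
    predict,
    train_general,
    train_specific,
)
from berbp.features import FEATURE_NAMES, FeatureVector
from berbp.models import NotFittedError, StandardizationError


def toy_dataset(seed=0, n=40, signal=2.0, pwm_id="toy"):
    """Separable 40-feature dataset without any sequence machinery."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n, 40))
    y = np.concatenate([np.ones(n, int), np.zeros(n, int)])
    X[:n, :5] += signal
    return LabeledDataset(X=X, y=y, ids=[f"r{i}" for i in range(2 * n)], pwm_id=pwm_id)


class TestVoteForest:
    def test_determinism(self):
        data = toy_dataset()
        a = VoteForest(n_trees=50, seed=3).fit(data.X, data.y)
        b = VoteForest(n_trees=50, seed=3).fit(data.X, data.y)
        np.testing.assert_array_equal(
            a.vote_fractions(data.X), b.vote_fractions(data.X)
        )
        np.testing.assert_array_equal(a.oob_vote_fractions(), b.oob_vote_fractions())

    def test_votes_in_unit_interval(self):
        data = toy_dataset()
        f = VoteForest(n_trees=30, seed=0).fit(data.X, data.y)
        v = f.vote_fractions(data.X)
        assert ((v >= 0) & (v <= 1)).all()

    def test_single_class_error(self):
        X = np.zeros((20, 40))
        with pytest.raises(ValueError, match="both classes"):
            VoteForest(n_trees=5, seed=0).fit(X, np.ones(20, int))

    def test_unfitted_error(self):
        with pytest.raises(NotFittedError):
            VoteForest().vote_fractions(np.zeros((1, 40)))

    def test_one_tree_oob_fraction(self):
        """~37% of rows are out of a single bootstrap (1-1/n)^n -> e^-1."""
        data = toy_dataset(n=150)
        fracs = []
        for seed in range(10):
            f = VoteForest(n_trees=1, seed=seed).fit(data.X, data.y)
            scores = f.oob_vote_fractions()
            fracs.append(np.isfinite(scores).mean())
        assert 0.30 < np.mean(fracs) < 0.44

    def test_many_trees_all_rows_oob(self):
        data = toy_dataset(n=100)
        f = VoteForest(n_trees=500, seed=1).fit(data.X, data.y)
        assert np.isfinite(f.oob_vote_fractions()).all()


class TestTrainSpecific:
    def test_planted_motif_recovery(self, planted_dataset):
        data, _ = planted_dataset
        model = train_specific(data, n_trees=200, seed=11)
        assert model.oob_auc >= 0.85
        assert model.kind == "specific"
        assert not model.standardized

    def test_permuted_labels_no_signal(self, planted_dataset):
        data, pwm = planted_dataset
        rng = np.random.default_rng(11)
        shuffled = LabeledDataset(
            X=data.X, y=rng.permutation(data.y), ids=data.ids, pwm_id=pwm.id
        )
        model = train_specific(shuffled, n_trees=200, seed=11)
        assert 0.4 <= model.oob_auc <= 0.6

    def test_same_seed_identical_oob(self, planted_dataset):
        data, _ = planted_dataset
        a = train_specific(data, n_trees=60, seed=5)
        b = train_specific(data, n_trees=60, seed=5)
        np.testing.assert_array_equal(oob_scores(a), oob_scores(b))

    def test_single_class_error(self):
        X = np.random.default_rng(0).normal(size=(30, 40))
        data = LabeledDataset(X=X, y=np.ones(30, int), ids=[f"r{i}" for i in range(30)],
                              pwm_id="p")
        with pytest.raises(ValueError):
            train_specific(data)

    def test_min_rows_per_class(self):
        data = toy_dataset(n=5)
        with pytest.raises(ValueError, match=">= 10"):
            train_specific(data)

    def test_metadata_recorded(self, planted_model, planted_dataset):
        data, pwm = planted_dataset
        assert planted_model.pwm_ids == (pwm.id,)
        assert planted_model.n_pos == data.n_pos
        assert planted_model.n_neg == data.n_neg
        assert planted_model.n_trees == 200
        assert planted_model.mtry == 6


class TestOobScores:
    def test_values_in_unit_interval(self, planted_model):
        s = oob_scores(planted_model)
        finite = s[np.isfinite(s)]
        assert ((finite >= 0) & (finite <= 1)).all()

    def test_forest_without_bookkeeping_error(self, planted_model):
        import copy

        stripped = copy.copy(planted_model)
        stripped.forest = VoteForest()
        with pytest.raises(ValueError):
            oob_scores(stripped)


class TestTrainGeneral:
    def test_neg_ratio_arithmetic(self, standardized_rbps):
        datasets, stats = standardized_rbps
        model = train_general(datasets[:3], stats, neg_ratio=2.0, n_trees=30, seed=0)
        assert model.n_pos == sum(d.n_pos for d in datasets[:3])
        assert model.n_neg == 2 * model.n_pos
        assert model.standardized
        assert model.kind == "general"

    def test_unstandardized_input_error(self, standardized_rbps):
        datasets, stats = standardized_rbps
        raw = LabeledDataset(
            X=datasets[0].X, y=datasets[0].y, ids=datasets[0].ids,
            pwm_id=datasets[0].pwm_id,
        )
        with pytest.raises(StandardizationError):
            train_general([raw, datasets[1]], stats, n_trees=10)

    def test_mismatched_stats_error(self, standardized_rbps):
        datasets, stats = standardized_rbps
        tampered = LabeledDataset(
            X=datasets[0].X, y=datasets[0].y, ids=datasets[0].ids,
            pwm_id=datasets[0].pwm_id, standardized=True,
            stats_fingerprint="deadbeef00000000",
        )
        with pytest.raises(StandardizationError, match="different"):
            train_general([tampered, datasets[1]], stats, n_trees=10)

    def test_needs_two_pwms(self, standardized_rbps):
        datasets, stats = standardized_rbps
        with pytest.raises(ValueError, match="2 distinct"):
            train_general([datasets[0]], stats, n_trees=10)

    def test_bad_ratio_error(self, standardized_rbps):
        datasets, stats = standardized_rbps
        with pytest.raises(ValueError, match="ratio"):
            train_general(datasets[:2], stats, neg_ratio=0)

    def test_determinism(self, standardized_rbps):
        datasets, stats = standardized_rbps
        a = train_general(datasets[:2], stats, n_trees=40, seed=9)
        b = train_general(datasets[:2], stats, n_trees=40, seed=9)
        np.testing.assert_array_equal(
            a.forest.vote_fractions(datasets[2].X),
            b.forest.vote_fractions(datasets[2].X),
        )


def _fvs_from(data, n=None, standardized=False, fingerprint=None):
    rows = range(len(data.y) if n is None else n)
    return [
        FeatureVector(
            seq_id=data.ids[i], pwm_id=data.pwm_id, values=data.X[i],
            best_site_start=0, best_site_score=float(data.X[i, 0]),
            standardized=standardized, stats_fingerprint=fingerprint,
        )
        for i in rows
    ]


class TestPredict:
    def test_positive_median_vote(self, planted_model, planted_dataset):
        data, _ = planted_dataset
        fvs = [fv for fv, y in zip(_fvs_from(data), data.y) if y == 1]
        records = predict(planted_model, fvs)
        votes = [r.vote_fraction for r in records]
        assert np.median(votes) > 0.5

    def test_threshold_semantics(self, planted_model, planted_dataset):
        data, _ = planted_dataset
        records = predict(planted_model, _fvs_from(data, 20), call_threshold=1.01)
        assert not any(r.binding_call for r in records)
        records = predict(planted_model, _fvs_from(data, 20), call_threshold=0.0)
        assert all(r.binding_call for r in records)

    def test_call_iff_threshold(self, planted_model, planted_dataset):
        data, _ = planted_dataset
        for r in predict(planted_model, _fvs_from(data), call_threshold=0.5):
            assert r.binding_call == (r.vote_fraction >= 0.5)

    def test_untrained_model_error(self, planted_model):
        import copy

        stub = copy.copy(planted_model)
        stub.forest = VoteForest()
        fv = FeatureVector(seq_id="s", pwm_id="p", values=np.zeros(40),
                           best_site_start=0, best_site_score=0.0)
        with pytest.raises(NotFittedError):
            predict(stub, [fv])

    def test_standardization_mismatch_error(self, planted_model, planted_dataset):
        data, _ = planted_dataset
        fvs = _fvs_from(data, 3, standardized=True)
        with pytest.raises(StandardizationError):
            predict(planted_model, fvs)

    def test_empty_input(self, planted_model):
        assert predict(planted_model, []) == []


class TestFeatureImportance:
    def test_sequence_features_dominate(self, planted_dataset):
        """Only MS/CS carry planted signal (no tracks, random structure)."""
        data, _ = planted_dataset
        model = train_specific(data, n_trees=200, seed=11)
        ranking = feature_importance(model, seed=0)
        assert ranking[0][0].startswith(("MS", "CS"))

    def test_pure_noise_importances_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 40))
        y = np.concatenate([np.ones(30, int), np.zeros(30, int)])
        data = LabeledDataset(X=X, y=y, ids=[f"r{i}" for i in range(60)], pwm_id="p")
        model = train_specific(data, n_trees=100, seed=0)
        vals = np.array([v for _, v in feature_importance(model, seed=1)])
        assert abs(vals.mean()) < 0.02

    def test_deterministic_ranking(self, planted_model):
        assert feature_importance(planted_model, seed=4) == feature_importance(
            planted_model, seed=4
        )

    def test_returns_all_40_ranked(self, planted_model):
        ranking = feature_importance(planted_model, seed=0)
        assert len(ranking) == 40
        assert {name for name, _ in ranking} == set(FEATURE_NAMES)
        vals = [v for _, v in ranking]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestCrossPredict:
    def test_transfer_between_synthetic_rbps(self, standardized_rbps):
        datasets, stats = standardized_rbps
        model = train_general(datasets[:1] + datasets[1:2], stats, n_trees=100, seed=2)
        auc = cross_predict(model, datasets[2])
        assert auc > 0.6

    def test_raw_dataset_error(self, standardized_rbps, planted_dataset):
        datasets, stats = standardized_rbps
        model = train_general(datasets[:2], stats, n_trees=20, seed=0)
        raw, _ = planted_dataset
        with pytest.raises(StandardizationError):
            cross_predict(model, raw)

    def test_self_prediction_beats_oob(self, standardized_rbps):
        datasets, stats = standardized_rbps
        model = train_general(datasets[:2], stats, n_trees=100, seed=3)
        train_X = np.vstack([datasets[0].X, datasets[1].X])
        train_y = np.concatenate([datasets[0].y, datasets[1].y])
        ds = LabeledDataset(
            X=train_X, y=train_y, ids=datasets[0].ids + datasets[1].ids,
            pwm_id=datasets[0].pwm_id, standardized=True,
            stats_fingerprint=datasets[0].stats_fingerprint,
        )
        assert cross_predict(model, ds) >= model.oob_auc - 1e-9

    def test_label_flip_symmetry(self, standardized_rbps):
        datasets, stats = standardized_rbps
        model = train_general(datasets[:2], stats, n_trees=100, seed=4)
        ds = datasets[2]
        auc = cross_predict(model, ds)
        flipped = LabeledDataset(
            X=ds.X, y=1 - ds.y, ids=ds.ids, pwm_id=ds.pwm_id,
            standardized=True, stats_fingerprint=ds.stats_fingerprint,
        )
        # 0.5 tie credit makes the flip identity exact even with tied votes
        assert cross_predict(model, flipped) == pytest.approx(1 - auc)
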