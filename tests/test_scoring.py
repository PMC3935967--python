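import numpy as np
import pytest

from meftop.scoring import (
    FEATURE_GROUPS,
    FEATURE_NAMES,
    DecoySet,
    ScorerConfig,
    TrainedScorer,
    assemble_features,
    cost_F,
    feature_matrix,
    m_score,
    p_score,
    rank_models,
    select_mscore_weight,
    train,
    z_score,
)
from meftop.synthetic_fixtures import make_target
from meftop.target_profile import ProfileNoise, profile_from_structure


@pytest.fixture(scope="module")
def target():
    return make_target("t0", ["H10", "E6", "E6", "H10", "H8"], seed=11,
                       decoys_per_target=30)


@pytest.fixture(scope="module")
def scorer(target):
    X = feature_matrix(target.profile, target.decoys)
    return train(X, target.tm_labels)


class TestAssembleFeatures:
    def test_vector_length_and_grouping(self, mixed_native):
        prof = profile_from_structure(mixed_native, seed=0)
        vec = assemble_features(prof, mixed_native)
        assert vec.shape == (37,)
        assert len(FEATURE_NAMES) == 37
        sizes = [len(v) for v in FEATURE_GROUPS.values()]
        assert sizes == [14, 10, 6, 7]

    def test_deterministic(self, mixed_native):
        prof = profile_from_structure(mixed_native, seed=0)
        a = assemble_features(prof, mixed_native)
        b = assemble_features(prof, mixed_native)
        assert np.array_equal(a, b)

    def test_length_mismatch_errors(self, mixed_native, helical_native):
        prof = profile_from_structure(mixed_native, seed=0)
        with pytest.raises(ValueError, match="length"):
            assemble_features(prof, helical_native)

    def test_all_finite(self, target):
        X = feature_matrix(target.profile, target.decoys)
        assert np.isfinite(X).all()


class TestZScore:
    def test_plug_in_values(self):
        z = z_score([10.0, 8.0, 6.0])
        assert np.allclose(z, [1.2247, 0.0, -1.2247], atol=1e-4)

    def test_constant_scores_all_zero(self):
        assert np.array_equal(z_score([5.0, 5.0, 5.0]), np.zeros(3))

    def test_mean_zero_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        s = rng.normal(3, 2, 20)
        z = z_score(s)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(z_score(4.0 * s + 7.0), z)

    def test_too_few_scores_errors(self):
        with pytest.raises(ValueError):
            z_score([1.0])


class TestTrainPredict:
    def test_training_fit_quality(self, target, scorer):
        X = feature_matrix(target.profile, target.decoys)
        pred = scorer.predict(X)
        r = np.corrcoef(pred, target.tm_labels)[0, 1]
        assert r > 0.7

    def test_sample_weight_defaults_to_label(self, target):
        # default per-instance weight is the TM label itself (weight of a
        # TM 0.8 model is twice that of a TM 0.4 model)
        X = feature_matrix(target.profile, target.decoys)
        y = target.tm_labels
        default = train(X, y).predict(X)
        explicit = train(X, y, sample_weight=y).predict(X)
        assert np.array_equal(default, explicit)
        # weights are honoured: suppressing the low-quality half changes the fit
        lopsided = train(X, y, sample_weight=(y > 0.4).astype(float) + 1e-6).predict(X)
        assert not np.array_equal(default, lopsided)

    def test_save_load_bit_identical(self, tmp_path, target, scorer):
        X = feature_matrix(target.profile, target.decoys[:5])
        before = scorer.predict(X)
        path = tmp_path / "scorer.joblib"
        scorer.save(path)
        after = TrainedScorer.load(path).predict(X)
        assert np.array_equal(before, after)

    def test_too_few_vectors_errors(self):
        with pytest.raises(ValueError, match="20"):
            train(np.zeros((5, 37)), np.linspace(0.2, 0.8, 5))

    def test_degenerate_labels_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            train(np.random.default_rng(0).random((25, 37)), np.full(25, 0.5))

    def test_p_score_clipped_and_deterministic(self, target, scorer):
        x = assemble_features(target.profile, target.decoys[0])
        p1 = p_score(scorer, x)
        p2 = p_score(scorer, x)
        assert p1 == p2
        assert 0.0 <= p1 <= 1.0


class TestMScore:
    def test_zero_weight_reduces_to_z(self):
        assert m_score(1.3, 0.9, 0.0) == 1.3

    def test_plug_in(self):
        assert m_score(0.0, 0.7, 1.0) == pytest.approx(0.7)

    def test_monotone_in_p(self):
        assert m_score(0.5, 0.8, 2.0) > m_score(0.5, 0.6, 2.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            m_score(0.0, 0.5, -1.0)


class TestCostF:
    def test_all_first_substitution(self):
        zs = [1.5, 2.0, 2.5]
        f = cost_F([1, 1, 1], zs, n_weight=2.0)
        assert f == pytest.approx(1.0 - 2.0 * np.mean(zs))

    def test_missed_increases_cost_linearly(self):
        base = cost_F([1, 1], [0.0, 0.0], missed=0, lam=1.0)
        assert cost_F([1, 1], [0.0, 0.0], missed=1, lam=1.0) == base + 1.0

    def test_lower_missed_wins_at_equal_terms(self):
        a = cost_F([2, 2], [1.0, 1.0], missed=0)
        b = cost_F([2, 2], [1.0, 1.0], missed=2)
        assert a < b

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cost_F([], [])


class TestSelectMScoreWeight:
    def test_picks_weight_that_rescues_selection(self):
        # Z alone picks a bad model; any n >= 0.5 rescues it
        z = [np.array([1.0, 0.0])]
        p = [np.array([0.1, 0.9])]
        tm = [np.array([0.2, 0.8])]
        n = select_mscore_weight(z, p, tm, grid=[0.5, 1.0, 5.0])
        sel = int(np.argmax(z[0] + n * p[0]))
        assert tm[0][sel] > 0.4

    def test_tie_takes_smaller_weight(self):
        z = [np.array([0.0, 1.0])]
        p = [np.array([0.0, 1.0])]
        tm = [np.array([0.2, 0.9])]
        assert select_mscore_weight(z, p, tm, grid=[0.5, 1.0]) == 0.5


class TestRankModels:
    def test_z_metric_ordering(self, target, scorer):
        ds = DecoySet("t", target.decoys[:3], raw_scores=np.array([10.0, 8.0, 6.0]),
                      profile=target.profile)
        ranked = rank_models(ds, scorer=scorer, metric="z")
        assert [s.model_id for s in ranked] == [m.model_id for m in target.decoys[:3]]

    def test_metric_m_with_zero_weight_equals_z(self, target, scorer):
        rng = np.random.default_rng(0)
        raw = rng.normal(0, 1, len(target.decoys))
        ds = DecoySet("t", target.decoys, raw_scores=raw, profile=target.profile)
        scorer.config.mscore_weight = 0.0
        try:
            rz = [s.model_id for s in rank_models(ds, scorer=scorer, metric="z")]
            rm = [s.model_id for s in rank_models(ds, scorer=scorer, metric="m")]
            assert rz == rm
        finally:
            scorer.config.mscore_weight = 1.0

    def test_ranking_is_permutation(self, target, scorer):
        ds = DecoySet("t", target.decoys, raw_scores=target.raw_scores, profile=target.profile)
        ranked = rank_models(ds, scorer=scorer, metric="m")
        assert sorted(s.model_id for s in ranked) == sorted(m.model_id for m in target.decoys)

    def test_tie_breaks_by_model_id(self, target, scorer):
        ds = DecoySet("t", target.decoys[:4], raw_scores=np.zeros(4))
        ranked = rank_models(ds, metric="z")
        assert [s.model_id for s in ranked] == sorted(m.model_id for m in target.decoys[:4])

    def test_missing_raw_scores_errors(self, target, scorer):
        ds = DecoySet("t", target.decoys[:3], profile=target.profile)
        with pytest.raises(ValueError, match="raw"):
            rank_models(ds, scorer=scorer, metric="z")
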