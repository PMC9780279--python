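"""Standardization, SVM phase decoding, f1 and permutation importances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import retinacuity as ra
from retinacuity.decoding import (
    DecoderConfig,
    DecodingDataset,
    cross_validated_decode,
    f1_from_confusion,
    feature_importance,
    fraction_contributing_units,
    standardize,
)
from retinacuity.stimulus import ConfigurationError

from conftest import decode_dataset


class TestStandardize:
    def test_self_application_gives_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3, 5, (40, 6))
        _, Z = standardize(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-12)  # population SD

    def test_constant_column_maps_to_zero(self):
        X = np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]])
        params, Z = standardize(X)
        assert params.zero_variance[1]
        assert np.all(Z[:, 1] == 0)

    def test_two_by_two_toy(self):
        params, Z = standardize(np.array([[0.0, 10.0], [2.0, 10.0]]))
        np.testing.assert_allclose(params.mean, [1.0, 10.0])
        np.testing.assert_allclose(params.std, [1.0, 0.0])

    def test_no_leakage_from_apply_set(self):
        """An extreme outlier in the apply set cannot move the scaler."""
        rng = np.random.default_rng(1)
        X_train = rng.normal(size=(30, 4))
        X_test = rng.normal(size=(10, 4))
        p_clean, _ = standardize(X_train, X_test)
        X_test_out = X_test.copy()
        X_test_out[0] = 1e6
        p_dirty, _ = standardize(X_train, X_test_out)
        np.testing.assert_array_equal(p_clean.mean, p_dirty.mean)
        np.testing.assert_array_equal(p_clean.std, p_dirty.std)


class TestF1:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected", [(8, 2, 2, 0.8), (5, 0, 0, 1.0), (3, 3, 3, 0.5)]
    )
    def test_known_values(self, tp, fp, fn, expected):
        assert f1_from_confusion(tp, fp, fn) == pytest.approx(expected)

    def test_degenerate_zero(self):
        assert f1_from_confusion(0, 0, 0) == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(
        tp=st.integers(0, 500), fp=st.integers(0, 500), fn=st.integers(0, 500)
    )
    def test_both_algebraic_forms_agree(self, tp, fp, fn):
        """2PR/(P+R) == TP/(TP + (FP+FN)/2) on arbitrary confusion counts."""
        if tp + fp + fn == 0:
            return
        direct = tp / (tp + 0.5 * (fp + fn))
        assert f1_from_confusion(tp, fp, fn) == pytest.approx(direct, abs=1e-12)


class TestCrossValidatedDecode:
    def test_separable_gaussians_reach_perfect_f1(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (60, 5)), rng.normal(8, 1, (60, 5))])
        y = np.repeat([1, 0], 60)
        res = cross_validated_decode(DecodingDataset(X, y), DecoderConfig(seed=0))
        assert res.f1_mean == 1.0
        assert res.confusion["FP"] == res.confusion["FN"] == 0

    def test_permuted_labels_are_at_chance(self):
        """Label permutation null: mean f1 across seeds within [0.4, 0.6]."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 10))
        means = []
        for seed in range(30):
            y = np.random.default_rng(seed).permutation(np.repeat([1, 0], 40))
            res = cross_validated_decode(
                DecodingDataset(X, y), DecoderConfig(n_folds=5, seed=seed)
            )
            means.append(res.f1_mean)
        assert 0.4 < np.mean(means) < 0.6

    def test_duplicating_samples_leaves_f1_unchanged(self):
        ds, _, _ = decode_dataset(n_units=20, r=0.5, n_repetitions=30, seed=4)
        base = cross_validated_decode(ds, DecoderConfig(seed=1)).f1_mean
        dup = DecodingDataset(np.vstack([ds.X, ds.X]), np.concatenate([ds.y, ds.y]))
        doubled = cross_validated_decode(dup, DecoderConfig(seed=1)).f1_mean
        assert doubled == pytest.approx(base, abs=0.05)

    def test_single_class_raises(self):
        with pytest.raises(ConfigurationError):
            cross_validated_decode(DecodingDataset(np.zeros((10, 2)), np.ones(10)))

    def test_fold_count_reduced_with_warning(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (6, 3)), rng.normal(5, 1, (6, 3))])
        y = np.repeat([1, 0], 6)
        with pytest.warns(UserWarning, match="reducing folds"):
            res = cross_validated_decode(DecodingDataset(X, y), DecoderConfig(n_folds=10))
        assert len(res.f1_per_fold) == 6

    def test_deterministic_for_fixed_seed(self):
        ds, _, _ = decode_dataset(n_units=15, r=0.3, n_repetitions=30, seed=6)
        a = cross_validated_decode(ds, DecoderConfig(seed=9))
        b = cross_validated_decode(ds, DecoderConfig(seed=9))
        assert a.f1_per_fold == b.f1_per_fold
        assert a.confusion == b.confusion

    def test_holdout_mode(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 1, (50, 4)), rng.normal(6, 1, (50, 4))])
        y = np.repeat([1, 0], 50)
        res = cross_validated_decode(
            DecodingDataset(X, y), DecoderConfig(seed=0, holdout_fraction=0.2)
        )
        assert len(res.f1_per_fold) == 1
        assert sum(res.confusion.values()) == 20  # 20% of 100 samples

    def test_confusion_sums_to_test_samples(self):
        ds, _, _ = decode_dataset(n_units=10, r=0.2, n_repetitions=30, seed=8)
        res = cross_validated_decode(ds, DecoderConfig(seed=0))
        assert sum(res.confusion.values()) == len(ds.y)


@pytest.fixture(scope="module")
def bimodal_importances():
    """Importances on ~60%-selective populations decoded below ceiling.

    Moderate selectivity (r = 0.3) keeps mean f1 off 1.0, so permuting a
    single unit's column measurably degrades the prediction.
    """
    out = []
    for seed in range(5):
        ds, units, _ = decode_dataset(
            n_units=40, r=0.3, n_repetitions=150, seed=seed, weights=(0.4, 0.3, 0.3)
        )
        imp = feature_importance(ds, DecoderConfig(seed=seed, importance_repeats=8))
        out.append((imp, np.array([abs(u.true_rfr) for u in units])))
    return out


class TestImportance:
    def test_single_informative_unit_ranks_first(self):
        rng = np.random.default_rng(0)
        y = np.tile([1, 0], 60)
        X = rng.poisson(5.0, (120, 10)).astype(float)
        X[:, 3] += 10.0 * y
        imp = feature_importance(DecodingDataset(X, y), DecoderConfig(seed=0))
        assert np.argmax(imp) == 3

    def test_uninformative_population_has_null_importances(self):
        ds, _, _ = decode_dataset(n_units=12, r=0.0, n_repetitions=40, seed=1)
        imp = feature_importance(ds, DecoderConfig(seed=0))
        assert np.abs(imp).max() < 0.3  # no unit stands out beyond fold noise

    def test_stronger_separation_ranks_higher(self):
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            y = np.tile([1, 0], 60)
            X = rng.poisson(5.0, (120, 8)).astype(float)
            X[:, 2] += 3.0 * y   # weaker unit
            X[:, 5] += 6.0 * y   # stronger unit
            imp = feature_importance(DecodingDataset(X, y), DecoderConfig(seed=seed))
            wins += imp[5] > imp[2]
        assert wins >= 0.9 * n_seeds

    def test_importance_tracks_true_selectivity(self, bimodal_importances):
        """|true RFR| and permutation importance are rank-correlated."""
        from scipy.stats import spearmanr

        rhos = [
            spearmanr(true_sel, imp).statistic
            for imp, true_sel in bimodal_importances
        ]
        assert all(r > 0.5 for r in rhos)

    def test_too_few_units_raises(self):
        with pytest.raises(ConfigurationError):
            feature_importance(DecodingDataset(np.zeros((10, 1)), np.tile([0, 1], 5)))


class TestFractionContributing:
    def test_single_contributor_among_fifty(self):
        imp = np.zeros(50)
        imp[17] = 0.4
        out = fraction_contributing_units(imp)
        assert out["fraction"] == pytest.approx(0.02)

    def test_all_equal_gives_one(self):
        assert fraction_contributing_units(np.full(20, 0.3))["fraction"] == 1.0

    def test_no_positive_importance_gives_zero(self):
        assert fraction_contributing_units(np.zeros(10))["fraction"] == 0.0

    def test_bimodal_population_fraction(self, bimodal_importances):
        """~60% selective units -> mean contributing fraction in [0.4, 0.8]."""
        fracs = [
            fraction_contributing_units(imp)["fraction"]
            for imp, _ in bimodal_importances
        ]
        assert 0.4 <= np.mean(fracs) <= 0.8
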