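"""Mean-centring, SVM training, nested C selection, CV decoding, searchlight."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexdecode import (
    DecodingConfig,
    EffectSpec,
    decode_meanings,
    decode_relatedness,
    gaussian_smooth,
    mean_center_trials,
    searchlight_map,
    select_C_nested,
    sphere_offsets,
    train_linear_classifier,
)
from lexdecode.decoding import DecodingError, cross_validated_decode
from lexdecode.simulate import PatternSet

FAST = DecodingConfig(nested_cv=False)


def pattern_set(X, conditions, runs, meanings=None):
    meta = pd.DataFrame(
        {
            "run": runs,
            "target": ["w"] * len(runs),
            "condition": conditions,
            "meaning": meanings if meanings is not None else [None] * len(runs),
            "task": ["semantic"] * len(runs),
        }
    )
    return PatternSet(np.asarray(X, dtype=float), meta)


class TestMeanCentring:
    def test_examples(self):
        ps = pattern_set([[1, 2, 3], [5, 5, 5]], ["related-ambiguous"] * 2, [1, 1])
        out = mean_center_trials(ps)
        assert np.array_equal(out.patterns[0], [-1, 0, 1])
        assert np.array_equal(out.patterns[1], [0, 0, 0])

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-1e6, 1e6), st.integers(0, 2**31 - 1))
    def test_row_shift_invariance(self, shift, seed):
        """Adding any constant to a whole trial row leaves the centred
        patterns bit-identical (up to float cancellation)."""
        X = np.random.default_rng(seed).standard_normal((4, 6))
        ps = pattern_set(X, ["related-ambiguous"] * 4, [1, 1, 2, 2])
        shifted = X.copy()
        shifted[2] += shift
        ps2 = pattern_set(shifted, ["related-ambiguous"] * 4, [1, 1, 2, 2])
        a, b = mean_center_trials(ps), mean_center_trials(ps2)
        assert np.allclose(a.patterns, b.patterns, atol=1e-6 * max(1.0, abs(shift)))

    def test_output_row_means_zero(self):
        X = np.random.default_rng(0).standard_normal((10, 7)) + 100
        out = mean_center_trials(pattern_set(X, ["related-ambiguous"] * 10, [1] * 10))
        assert np.allclose(out.patterns.mean(axis=1), 0.0, atol=1e-12)


class TestLinearClassifier:
    def test_separable_two_points(self):
        X = np.array([[0.0, 1.0], [1.0, 0.0]])
        y = np.array(["a", "b"])
        clf = train_linear_classifier(X, y, C=1.0)
        assert list(clf.predict(X)) == ["a", "b"]

    def test_single_class_rejected(self):
        with pytest.raises(DecodingError, match="single class"):
            train_linear_classifier(np.zeros((3, 2)), np.array(["a"] * 3), 1.0)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 5))
        y = np.array(["a"] * 10 + ["b"] * 10)
        y_flip = np.where(y == "a", "b", "a")
        Xte = rng.standard_normal((15, 5))
        a = train_linear_classifier(X, y, 1.0)
        b = train_linear_classifier(X, y_flip, 1.0)
        assert np.allclose(a.coef_, -b.coef_, atol=1e-4)
        assert np.array_equal(a.predict(Xte) == "a", b.predict(Xte) == "b")

    def test_hard_margin_limit_separates_training_data(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-3, 0.3, (10, 4)), rng.normal(3, 0.3, (10, 4))])
        y = np.array(["a"] * 10 + ["b"] * 10)
        clf = train_linear_classifier(X, y, C=1e6)
        assert (clf.predict(X) == y).all()

    def test_deterministic_refit(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 8))
        y = np.array(["a", "b"] * 15)
        w1 = train_linear_classifier(X, y, 0.5).coef_
        w2 = train_linear_classifier(X, y, 0.5).coef_
        assert np.array_equal(w1, w2)


class TestNestedCSelection:
    def test_singleton_grid(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 4))
        y = np.array(["a", "b"] * 10)
        runs = np.repeat([1, 2], 10)
        assert select_C_nested(X, y, runs, [0.5]) == 0.5

    def test_ties_take_smallest_C(self):
        # constant features: every C predicts identically, so all tie
        X = np.ones((20, 3))
        y = np.array(["a", "b"] * 10)
        runs = np.repeat([1, 2], 10)
        grid = [1e-4, 1e-2, 1.0, 100.0]
        assert select_C_nested(X, y, runs, grid) == 1e-4

    def test_chosen_C_maximises_inner_accuracy(self):
        rng = np.random.default_rng(3)
        mu = rng.standard_normal(6) * 2
        X = np.vstack([mu + rng.standard_normal((15, 6)), -mu + rng.standard_normal((15, 6))])
        y = np.array(["a"] * 15 + ["b"] * 15)
        runs = np.tile(np.repeat([1, 2, 3], 5), 2)
        grid = (1e-4, 1e-2, 1.0, 100.0)
        chosen = select_C_nested(X, y, runs, grid)
        accs = {}
        for C in grid:
            correct = 0
            for r in (1, 2, 3):
                val = runs == r
                clf = train_linear_classifier(X[~val], y[~val], C)
                correct += (clf.predict(X[val]) == y[val]).sum()
            accs[C] = correct
        assert accs[chosen] == max(accs.values())

    def test_requires_two_runs(self):
        with pytest.raises(DecodingError, match="2 training runs"):
            select_C_nested(np.zeros((4, 2)), np.array(["a", "b"] * 2), np.ones(4), [1.0])


class TestRelatednessDecoding:
    def test_chance_on_null_data(self, make_task_patterns):
        ps = make_task_patterns(EffectSpec(participant_pattern_seed=0), seed=1)
        acc = decode_relatedness(ps, FAST).accuracy
        # 95% binomial CI around 0.5 at n=120
        assert abs(acc - 0.5) < 1.96 * np.sqrt(0.25 / 120)

    def test_high_accuracy_with_strong_pattern_signal(self, make_task_patterns):
        spec = EffectSpec(relatedness_amplitude=3.0, participant_pattern_seed=1)
        ps = make_task_patterns(spec, seed=2)
        assert decode_relatedness(ps, FAST).accuracy > 0.9

    def test_centring_removes_pure_univariate_signal(self, make_task_patterns):
        spec = EffectSpec(univariate_offsets={"related": 1.0}, participant_pattern_seed=2)
        ps = make_task_patterns(spec, seed=3)
        uncentred = decode_relatedness(ps, DecodingConfig(nested_cv=False, center_trials=False))
        centred = decode_relatedness(ps, DecodingConfig(nested_cv=False, center_trials=True))
        assert uncentred.accuracy > 0.9
        assert abs(centred.accuracy - 0.5) < 1.96 * np.sqrt(0.25 / 120)

    def test_accuracy_is_fold_size_weighted_mean(self, make_task_patterns):
        ps = make_task_patterns(EffectSpec(relatedness_amplitude=1.0), seed=4)
        res = decode_relatedness(ps, FAST)
        assert np.isclose(
            res.accuracy, np.dot(res.fold_accuracies, res.fold_sizes) / sum(res.fold_sizes)
        )
        assert res.n_trials == 120

    def test_missing_run_column_rejected(self):
        ps = pattern_set(np.zeros((4, 3)), ["related-ambiguous"] * 4, [1] * 4)
        ps.metadata = ps.metadata.drop(columns=["run"])
        with pytest.raises(DecodingError, match="run"):
            decode_relatedness(ps, FAST)

    def test_held_out_run_never_influences_training(self, make_task_patterns):
        """Corrupting the test run's labels leaves that fold's trained rule,
        hence its predictions, unchanged."""
        ps = make_task_patterns(EffectSpec(relatedness_amplitude=1.5), seed=5)
        X = ps.patterns - ps.patterns.mean(1, keepdims=True)
        y = ps.metadata["condition"].str.split("-").str[0].to_numpy()
        runs = ps.metadata["run"].to_numpy()
        test = runs == 1
        y_poisoned = y.copy()
        y_poisoned[test] = np.roll(y[test], 7)
        for labels in (y, y_poisoned):
            C = select_C_nested(X[~test], labels[~test], runs[~test], (0.01, 1.0))
            clf = train_linear_classifier(X[~test], labels[~test], C)
            pred = clf.predict(X[test])
            if labels is y:
                ref = pred
        assert np.array_equal(ref, pred)


class TestMeaningDecoding:
    def test_chance_on_null_data(self, make_task_patterns):
        # single-participant accuracy is noisy (n=40 test trials), so
        # average a few simulated participants and use a 3-sigma band
        accs = [
            decode_meanings(
                make_task_patterns(EffectSpec(participant_pattern_seed=s), seed=6 + s), FAST
            ).accuracy
            for s in range(5)
        ]
        assert abs(np.mean(accs) - 0.5) < 3 * np.sqrt(0.25 / 40) / np.sqrt(5)

    def test_high_accuracy_with_strong_meaning_signal(self, make_task_patterns):
        spec = EffectSpec(meaning_amplitude=4.0, participant_pattern_seed=6)
        ps = make_task_patterns(spec, seed=7)
        res = decode_meanings(ps, FAST)
        assert res.accuracy > 0.9
        assert len(res.per_homonym) == 5

    def test_accuracy_is_unweighted_homonym_mean(self, make_task_patterns):
        ps = make_task_patterns(EffectSpec(meaning_amplitude=1.0), seed=8)
        res = decode_meanings(ps, FAST)
        assert np.isclose(res.accuracy, np.mean(list(res.per_homonym.values())))

    def test_missing_meaning_in_a_run_rejected(self, make_task_patterns):
        ps = make_task_patterns(EffectSpec(), seed=9)
        meta = ps.metadata
        hom = (meta["condition"] == "related-ambiguous") & (meta["target"] == "bark")
        idx = meta.index[hom & (meta["run"] == 1)][0]
        meta.loc[idx, "meaning"] = meta.loc[meta.index[hom][1], "meaning"]
        with pytest.raises(DecodingError, match="bark"):
            decode_meanings(ps, FAST)


class TestSphereOffsets:
    def test_radius_zero_is_centre_only(self):
        assert len(sphere_offsets(0.0, 2.4)) == 1

    def test_radius_one_voxel_gives_faces(self):
        assert len(sphere_offsets(2.4, 2.4)) == 7

    def test_matches_brute_force_enumeration(self):
        radius, vox = 12.0, 2.4
        got = {tuple(o) for o in sphere_offsets(radius, vox)}
        expect = set()
        r = int(np.ceil(radius / vox))
        for i in range(-r, r + 1):
            for j in range(-r, r + 1):
                for k in range(-r, r + 1):
                    if vox * np.sqrt(i * i + j * j + k * k) <= radius + 1e-9:
                        expect.add((i, j, k))
        assert got == expect


class TestSearchlight:
    def _volumes(self, signal_region=None, seed=0):
        rng = np.random.default_rng(seed)
        n_trials = 40
        vols = rng.standard_normal((n_trials, 6, 6, 6))
        labels = np.tile(["a"] * 5 + ["b"] * 5, 4)
        runs = np.repeat([1, 2, 3, 4], 10)
        if signal_region is not None:
            sig = (labels == "a").astype(float) * 3.0
            sl = signal_region
            pattern = rng.standard_normal((1, *vols[0][sl].shape))
            vols[:, sl[0], sl[1], sl[2]] += sig[:, None, None, None] * pattern
        return vols, labels, runs

    def test_chance_level_on_noise(self):
        vols, labels, runs = self._volumes()
        mask = np.zeros((6, 6, 6), bool)
        mask[2:4, 2:4, 2:4] = True  # keep it small
        acc = searchlight_map(vols, mask, labels, runs, FAST, voxel_size_mm=2.4)
        vals = acc[np.isfinite(acc)]
        assert len(vals) == 8
        assert abs(vals.mean() - 0.5) < 0.15

    def test_signal_localises_to_planted_region(self):
        region = (slice(0, 2), slice(0, 2), slice(0, 2))
        vols, labels, runs = self._volumes(signal_region=region, seed=1)
        mask = np.ones((6, 6, 6), bool)
        cfg = DecodingConfig(nested_cv=False, searchlight_radius_mm=2.4)
        acc = searchlight_map(vols, mask, labels, runs, cfg, voxel_size_mm=2.4, center=False)
        flat = acc.ravel()
        top = np.argsort(flat)[-21:]  # top decile of 216 voxels
        planted = np.zeros((6, 6, 6), bool)
        planted[region] = True
        near = np.flatnonzero(planted.ravel())
        overlap = np.isin(top, near).mean()
        assert overlap > 0.3

    def test_single_voxel_mask_radius_zero(self):
        vols, labels, runs = self._volumes(seed=2)
        mask = np.zeros((6, 6, 6), bool)
        mask[3, 3, 3] = True
        cfg = DecodingConfig(nested_cv=False, searchlight_radius_mm=0.0)
        acc = searchlight_map(vols, mask, labels, runs, cfg)
        assert np.isfinite(acc).sum() == 1


class TestGaussianSmooth:
    def test_fwhm_zero_is_identity(self):
        vol = np.random.default_rng(0).standard_normal((5, 5, 5))
        assert np.array_equal(gaussian_smooth(vol, 0.0), vol)

    def test_delta_becomes_kernel_peaked_at_delta(self):
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        out = gaussian_smooth(vol, fwhm_mm=4.0, voxel_size_mm=2.4)
        assert np.unravel_index(np.argmax(out), out.shape) == (7, 7, 7)
        assert np.isclose(out.sum(), 1.0, atol=1e-6)

    def test_profile_matches_analytic_gaussian(self):
        vol = np.zeros((31, 31, 31))
        vol[15, 15, 15] = 1.0
        fwhm, vox = 4.0, 1.0
        out = gaussian_smooth(vol, fwhm, vox)
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        x = np.arange(31) - 15.0
        expect = np.exp(-(x**2) / (2 * sigma**2))
        expect /= expect.sum()
        line = out[:, 15, 15] / out[:, 15, 15].sum()
        assert np.allclose(line, expect, atol=1e-4)
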