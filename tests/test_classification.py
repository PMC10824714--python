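"""Feature extraction, stratified splitting and the centroid classifier."""

import numpy as np
import pytest

from holopol import classification as clf
from holopol.errors import EmptyRegionError, InsufficientDataError
from holopol.polarimetry import dolp_map, ssd_map, stokes_maps
from holopol.scene import render_uniform_retarder


def maps_for(delta, theta=0.3, shape=(24, 24)):
    st = render_uniform_retarder(delta, theta, shape)
    s = stokes_maps(st)
    return ssd_map(st), dolp_map(s)


class TestExtractFeatures:
    def test_glass_like_region_is_dark(self):
        ssd, dolp = maps_for(0.0)
        mask = np.zeros((24, 24), dtype=bool)
        mask[8:16, 8:16] = True
        v = clf.extract_features(mask, ssd, dolp)
        assert v[0] <= 1e-3 and v[2] <= 1e-3

    def test_quarter_wave_region_is_fully_polarized(self):
        ssd, dolp = maps_for(np.pi / 2)
        mask = np.zeros((24, 24), dtype=bool)
        mask[4:20, 4:20] = True
        v = clf.extract_features(mask, ssd, dolp)
        assert v[2] == pytest.approx(1.0, abs=1e-3)
        assert v[0] == pytest.approx(1 / (2 * np.sqrt(2)), abs=1e-3)

    def test_empty_overlap_rejected(self):
        ssd, dolp = maps_for(0.5)
        with pytest.raises(EmptyRegionError):
            clf.extract_features(np.zeros((24, 24), dtype=bool), ssd, dolp)

    def test_transmittance_feature(self):
        ssd, dolp = maps_for(0.5)
        mask = np.zeros((24, 24), dtype=bool)
        mask[10:14, 10:14] = True
        v = clf.extract_features(mask, ssd, dolp, transmittance=np.full((24, 24), 0.8))
        assert v[3] == pytest.approx(0.8)


class TestSplitDataset:
    def test_thousand_records_split_800_100_100(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["a", "b", "c", "d"], size=1000, p=[0.4, 0.3, 0.2, 0.1])
        tr, va, te = clf.split_dataset(labels, clf.SplitSpec(seed=1))
        assert (len(tr), len(va), len(te)) == (800, 100, 100)

    def test_ten_of_one_class(self):
        tr, va, te = clf.split_dataset(["x"] * 10, clf.SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (8, 1, 1)

    def test_same_seed_identical_split(self):
        labels = list("aabbbcccc") * 7
        a = clf.split_dataset(labels, clf.SplitSpec(seed=3))
        b = clf.split_dataset(labels, clf.SplitSpec(seed=3))
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_partition_is_exhaustive_and_disjoint(self):
        labels = np.repeat(["u", "v", "w"], [17, 23, 9])
        tr, va, te = clf.split_dataset(labels, clf.SplitSpec(seed=5))
        combined = np.concatenate([tr, va, te])
        assert sorted(combined) == list(range(len(labels)))

    def test_stratification_within_one_of_exact(self):
        labels = np.repeat(["u", "v"], [40, 20])
        tr, va, te = clf.split_dataset(labels, clf.SplitSpec(seed=2))
        labels = np.asarray(labels)
        for cls, n in (("u", 40), ("v", 20)):
            got = sum(labels[tr] == cls)
            assert abs(got - 0.8 * n) <= 1


class TestCentroidModel:
    def test_single_class_centroid_at_origin(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 2, size=(30, 4))
        model = clf.train_centroids(X, ["only"] * 30)
        assert np.allclose(model.centroids[0], 0.0, atol=1e-12)

    def test_symmetric_classes_opposite_centroids(self):
        X = np.array([[1.0, 2.0], [-1.0, -2.0], [1.0, 2.0], [-1.0, -2.0]])
        model = clf.train_centroids(X, ["p", "n", "p", "n"], feature_names=("f1", "f2"))
        assert np.allclose(model.centroids[0], -model.centroids[1])

    def test_zero_variance_feature_dropped(self):
        X = np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]])
        model = clf.train_centroids(X, ["a", "a", "b"], feature_names=("f1", "f2"))
        assert model.kept.tolist() == [True, False]

    def test_well_separated_gaussians_recovered(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(0, 1, (200, 3)), rng.normal(4, 1, (200, 3))])
        y = ["lo"] * 200 + ["hi"] * 200
        model = clf.train_centroids(X, y)
        pred, _ = clf.predict(model, X)
        assert np.mean(np.asarray(pred) == np.asarray(y)) >= 0.99

    def test_training_centroid_predicts_its_class(self):
        rng = np.random.default_rng(2)
        X = np.concatenate([rng.normal(0, 1, (50, 2)), rng.normal(3, 1, (50, 2))])
        y = ["a"] * 50 + ["b"] * 50
        model = clf.train_centroids(X, y)
        raw_centroids = model.centroids * model.sd + model.mean
        pred, margins = clf.predict(model, raw_centroids)
        assert pred == ["a", "b"]
        assert np.all(margins > 0)

    def test_equidistant_tie_goes_to_first_class(self):
        X = np.array([[-1.0, 0.0], [1.0, 0.0]] * 5)
        y = ["a", "b"] * 5
        model = clf.train_centroids(X, y, feature_names=("f1", "f2"))
        pred, _ = clf.predict(model, np.array([[0.0, 0.0]]))
        assert pred == ["a"]

    def test_prediction_invariant_to_affine_feature_rescaling(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 4)) + np.repeat([[0.0], [2.0]], 30, axis=0)
        y = ["a"] * 30 + ["b"] * 30
        model1 = clf.train_centroids(X, y)
        p1, _ = clf.predict(model1, X)
        X2 = X * np.array([3.0, 0.5, 10.0, 1.0]) + np.array([5.0, -2.0, 0.0, 100.0])
        model2 = clf.train_centroids(X2, y)
        p2, _ = clf.predict(model2, X2)
        assert p1 == p2

    def test_json_round_trip(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 4))
        model = clf.train_centroids(X, ["a", "b"] * 10)
        model2 = clf.CentroidModel.from_json(model.to_json())
        p1, _ = clf.predict(model, X)
        p2, _ = clf.predict(model2, X)
        assert p1 == p2

    def test_empty_training_rejected(self):
        with pytest.raises(InsufficientDataError):
            clf.train_centroids(np.zeros((0, 4)), [])


class TestEvaluate:
    def test_perfect_predictions(self):
        X = np.array([[0.0, 0], [10, 10]] * 20)
        y = ["a", "b"] * 20
        model = clf.train_centroids(X, y, feature_names=("f1", "f2"))
        acc, conf = clf.evaluate(model, X, y)
        assert acc == 1.0
        assert conf.loc["a", "a"] == 20 and conf.loc["a", "b"] == 0

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(0)
        k = 4
        n = 10**4
        X = rng.normal(size=(n, 3))  # features carry no class signal
        y = rng.choice([f"c{i}" for i in range(k)], size=n)
        model = clf.train_centroids(X[:400], y[:400])
        acc, conf = clf.evaluate(model, X, y)
        se = np.sqrt((1 / k) * (1 - 1 / k) / n)
        assert abs(acc - 1 / k) < 3 * se + 0.01
        assert conf.sum(axis=1).tolist() == [int(np.sum(y == c)) for c in model.class_order]

    def test_accuracy_monotone_in_class_separation(self):
        seps = [0.2, 0.8, 2.0, 5.0]
        mean_acc = []
        for sep in seps:
            accs = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                X = np.concatenate([rng.normal(0, 1, (40, 2)), rng.normal(sep, 1, (40, 2))])
                y = ["a"] * 40 + ["b"] * 40
                model = clf.train_centroids(X, y)
                acc, _ = clf.evaluate(model, X, y)
                accs.append(acc)
            mean_acc.append(np.mean(accs))
        assert all(b >= a - 0.01 for a, b in zip(mean_acc, mean_acc[1:]))

    def test_glass_separable_from_birefringent_plastic(self):
        """Zero-retardance controls split from delta >= 0.3 rad plastics."""
        rng = np.random.default_rng(6)
        rows, labels = [], []
        for name, d_mean in (("glass", 0.0), ("PS", 0.35)):
            for _ in range(50):
                d = float(np.clip(rng.normal(d_mean, 0.05), 0, np.pi))
                ssd, dolp = maps_for(d, theta=float(rng.uniform(0, np.pi)), shape=(12, 12))
                mask = np.ones((12, 12), dtype=bool)
                rows.append(clf.extract_features(mask, ssd, dolp))
                labels.append(name)
        X = np.stack(rows)
        model = clf.train_centroids(X, labels)
        acc, _ = clf.evaluate(model, X, labels)
        assert acc >= 0.99
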