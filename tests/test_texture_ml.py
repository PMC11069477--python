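"""GLCM features, dataset construction, SVM training and metrics."""

import math

import numpy as np
import pandas as pd
import pytest

import polartissue as pt
from polartissue.texture_ml import GLCM_LEVELS, quantize


def brute_force_features(p):
    """Independent double-loop evaluation of all 20 texture statistics."""
    n = len(p)
    px = [sum(p[i][j] for j in range(n)) for i in range(n)]
    py = [sum(p[i][j] for i in range(n)) for j in range(n)]
    mu_i = sum(i * p[i][j] for i in range(n) for j in range(n))
    mu_j = sum(j * p[i][j] for i in range(n) for j in range(n))
    var_i = sum((i - mu_i) ** 2 * p[i][j] for i in range(n) for j in range(n))
    var_j = sum((j - mu_j) ** 2 * p[i][j] for i in range(n) for j in range(n))

    def l2(x):
        return math.log2(x) if x > 0 else 0.0

    psum = [0.0] * (2 * n - 1)
    pdiff = [0.0] * n
    for i in range(n):
        for j in range(n):
            psum[i + j] += p[i][j]
            pdiff[abs(i - j)] += p[i][j]
    sa = sum(k * psum[k] for k in range(2 * n - 1))
    da = sum(k * pdiff[k] for k in range(n))
    entropy = -sum(p[i][j] * l2(p[i][j]) for i in range(n) for j in range(n))
    hx = -sum(v * l2(v) for v in px)
    hy = -sum(v * l2(v) for v in py)
    hxy1 = -sum(p[i][j] * l2(px[i] * py[j]) for i in range(n) for j in range(n))
    hxy2 = -sum(px[i] * py[j] * l2(px[i] * py[j]) for i in range(n) for j in range(n))
    denom = max(hx, hy)
    corr = (sum((i - mu_i) * (j - mu_j) * p[i][j] for i in range(n) for j in range(n))
            / math.sqrt(var_i * var_j)) if var_i > 0 and var_j > 0 else 0.0
    return {
        "contrast": sum((i - j) ** 2 * p[i][j] for i in range(n) for j in range(n)),
        "dissimilarity": sum(abs(i - j) * p[i][j] for i in range(n) for j in range(n)),
        "homogeneity": sum(p[i][j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n)),
        "energy": sum(p[i][j] ** 2 for i in range(n) for j in range(n)),
        "correlation": corr,
        "entropy": entropy,
        "variance": var_i,
        "sum_average": sa,
        "sum_variance": sum((k - sa) ** 2 * psum[k] for k in range(2 * n - 1)),
        "sum_entropy": -sum(v * l2(v) for v in psum),
        "difference_variance": sum((k - da) ** 2 * pdiff[k] for k in range(n)),
        "difference_entropy": -sum(v * l2(v) for v in pdiff),
        "imc1": (entropy - hxy1) / denom if denom > 0 else 0.0,
        "imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy)))),
        "autocorrelation": sum(i * j * p[i][j] for i in range(n) for j in range(n)),
        "cluster_shade": sum((i + j - mu_i - mu_j) ** 3 * p[i][j]
                             for i in range(n) for j in range(n)),
        "cluster_prominence": sum((i + j - mu_i - mu_j) ** 4 * p[i][j]
                                  for i in range(n) for j in range(n)),
        "maximum_probability": max(p[i][j] for i in range(n) for j in range(n)),
        "inverse_difference": sum(p[i][j] / (1 + abs(i - j) / n)
                                  for i in range(n) for j in range(n)),
        "inverse_difference_moment": sum(p[i][j] / (1 + (i - j) ** 2 / n**2)
                                         for i in range(n) for j in range(n)),
    }


class TestAugment:
    def test_three_versions(self, rng):
        imgs = pt.augment(rng.uniform(size=(8, 8)))
        assert len(imgs) == 3

    def test_hflip_involution(self, rng):
        img = rng.uniform(size=(6, 6))
        _, h, _ = pt.augment(img)
        np.testing.assert_array_equal(h[:, ::-1], img)

    def test_symmetric_image_hflip_is_identity(self):
        img = np.zeros((4, 4))
        img[:, 1:3] = 1.0
        _, h, _ = pt.augment(img)
        np.testing.assert_array_equal(h, img)


class TestPatch16:
    def test_256_gives_16_patches_of_64(self):
        patches = pt.patch16(np.zeros((256, 256)))
        assert len(patches) == 16
        assert all(p.shape == (64, 64) for p in patches)

    def test_row_major_reconstruction(self, rng):
        img = rng.uniform(size=(16, 16))
        patches = pt.patch16(img)
        rows = [np.hstack(patches[i * 4:(i + 1) * 4]) for i in range(4)]
        np.testing.assert_array_equal(np.vstack(rows), img)

    def test_center_crop_odd_size(self):
        patches = pt.patch16(np.zeros((255, 255)))
        assert all(p.shape == (63, 63) for p in patches)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            pt.patch16(np.zeros((3, 5)))


class TestGlcm:
    def test_constant_patch_single_diagonal_entry(self):
        g = pt.glcm(np.full((8, 8), 0.3), value_range=(0, 1))
        assert g.sum() == pytest.approx(1.0)
        nz = np.nonzero(g)
        assert len(nz[0]) == 1
        assert nz[0][0] == nz[1][0]  # on the diagonal

    def test_normalized_and_symmetric(self, rng):
        for _ in range(10):
            g = pt.glcm(rng.uniform(size=(12, 12)), value_range=(0, 1))
            assert g.shape == (GLCM_LEVELS, GLCM_LEVELS)
            assert g.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(g, g.T, atol=1e-12)

    def test_hand_counted_two_by_two(self):
        """Patch quantizing to levels [[0,1],[0,1]] at the 0-degree offset:
        2 horizontal pairs (0,1), symmetrized -> P[0,1] = P[1,0] = 1/2."""
        patch = np.array([[0.0, 0.15], [0.0, 0.15]])
        g = pt.glcm(patch, value_range=(0, 1), angles=(0.0,))
        expected = np.zeros((8, 8))
        expected[0, 1] = expected[1, 0] = 0.5
        np.testing.assert_allclose(g, expected)

    def test_quantize_uses_physical_range(self):
        q = quantize(np.array([[-0.5, 1.0]]), value_range=(-0.5, 1.0))
        assert q[0, 0] == 0
        assert q[0, 1] == GLCM_LEVELS - 1


class TestFeatures20:
    def test_uniform_glcm_closed_forms(self):
        g = np.full((8, 8), 1 / 64)
        f = pt.features20(g)
        assert f["energy"] == pytest.approx(1 / 64)
        assert f["maximum_probability"] == pytest.approx(1 / 64)

    def test_single_entry_glcm(self):
        g = np.zeros((8, 8)); g[3, 3] = 1.0
        f = pt.features20(g)
        assert f["entropy"] == pytest.approx(0.0)
        assert f["energy"] == pytest.approx(1.0)
        assert f["correlation"] == 0.0  # degenerate: defined as 0

    def test_matches_brute_force_oracle(self, rng):
        """Each feature equals an independent direct-summation evaluation on
        100 random normalized symmetric GLCMs."""
        for _ in range(100):
            g = rng.uniform(size=(8, 8))
            g = (g + g.T) / 2
            g /= g.sum()
            ours = pt.features20(g)
            oracle = brute_force_features(g.tolist())
            for name in pt.FEATURE_NAMES:
                assert ours[name] == pytest.approx(oracle[name], abs=1e-10), name

    def test_all_features_finite_and_distinct_names(self, rng):
        g = rng.uniform(size=(8, 8)); g /= g.sum()
        f = pt.features20(g)
        assert len(f) == 20
        assert all(np.isfinite(v) for v in f.values())


def _fake_regions(rng, n_per_class=4, size=32):
    regions = []
    for c, label in enumerate(("normal", "tumour")):
        for k in range(n_per_class):
            img = rng.uniform(0, 0.4, (size, size)) + 0.5 * c
            regions.append((f"{label}_{k:02d}", label, np.clip(img, 0, 1)))
    return regions


class TestBuildDataset:
    def test_384_records_for_8_regions(self, rng):
        table = pt.build_dataset(_fake_regions(rng), "dop", "H")
        assert len(table) == 8 * 3 * 16 == 384

    def test_class_balance(self, rng):
        table = pt.build_dataset(_fake_regions(rng), "dop", "H")
        counts = table["class_label"].value_counts()
        assert counts["normal"] == counts["tumour"] == 192

    def test_mueller_element_mode_6144(self, default_dataset, default_analyses):
        from polartissue.cli_io import build_features
        table = build_features(default_dataset, default_analyses, "mueller", "H")
        assert len(table) == 6144

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            pt.build_dataset([], "dop", "H")


class TestMetricsFromConfusion:
    def test_perfect(self):
        m = pt.metrics_from_confusion(10, 0, 0, 10)
        assert (m.sensitivity, m.precision, m.specificity, m.accuracy, m.f1) == \
            (100, 100, 100, 100, 100)

    def test_all_missed(self):
        m = pt.metrics_from_confusion(0, 10, 0, 10)
        assert m.sensitivity == 0
        assert m.specificity == 100
        assert "undefined-precision" in m.flags

    def test_table_row_counts(self):
        """Counts (35,3,7,31) reproduce the printed anisotropy-at-0° test
        metrics."""
        m = pt.metrics_from_confusion(35, 3, 7, 31)
        assert m.sensitivity == pytest.approx(92.11, abs=5e-3)
        assert m.precision == pytest.approx(83.33, abs=5e-3)
        assert m.specificity == pytest.approx(81.58, abs=5e-3)
        assert m.accuracy == pytest.approx(86.84, abs=5e-3)
        assert m.f1 == pytest.approx(87.50, abs=5e-3)

    def test_accuracy_identity(self, rng):
        """accuracy = (sens*P + spec*N)/(P+N) for class sizes P, N."""
        for _ in range(20):
            tp, fn, fp, tn = rng.integers(1, 50, 4)
            m = pt.metrics_from_confusion(int(tp), int(fn), int(fp), int(tn))
            p_, n_ = tp + fn, tn + fp
            assert m.accuracy == pytest.approx(
                (m.sensitivity * p_ + m.specificity * n_) / (p_ + n_))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pt.metrics_from_confusion(-1, 0, 0, 1)


class TestTrainEval:
    def _table(self, rng, separation):
        rows = []
        for c, label in enumerate(("normal", "tumour")):
            for r in range(4):
                for k in range(48):
                    feats = {name: rng.normal(c * separation, 1.0)
                             for name in pt.FEATURE_NAMES}
                    rows.append({"region_id": f"{label}_{r}", "class_label": label,
                                 "augmentation": "orig", "patch_index": k,
                                 "parameter": "dop", "state": "H", **feats})
        return pd.DataFrame(rows)

    def test_separable_features_perfect(self, rng):
        res = pt.train_eval(self._table(rng, separation=20.0), seed=0)
        assert res["test"].accuracy == 100.0
        assert res["validation"].accuracy == 100.0

    def test_label_permutation_near_chance(self, rng):
        """With labels shuffled, held-out accuracy sits at chance within
        binomial noise."""
        table = self._table(rng, separation=20.0)
        table["class_label"] = rng.permutation(table["class_label"].to_numpy())
        res = pt.train_eval(table, seed=0, split="patch")
        assert 30.0 <= res["test"].accuracy <= 70.0

    def test_single_class_rejected(self, rng):
        table = self._table(rng, 1.0)
        table = table[table["class_label"] == "normal"]
        with pytest.raises(ValueError):
            pt.train_eval(table, seed=0)

    def test_region_split_holds_out_whole_regions(self, rng):
        table = self._table(rng, separation=5.0)
        res = pt.train_eval(table, seed=0, split="region")
        # 8 regions, 20% -> 2 held-out regions = 96 patches
        total = res["test"].tp + res["test"].fn + res["test"].fp + res["test"].tn
        assert total == 96

    def test_determinism(self, rng):
        table = self._table(rng, separation=2.0)
        r1 = pt.train_eval(table, seed=3)
        r2 = pt.train_eval(table, seed=3)
        assert r1["test"].to_dict() == r2["test"].to_dict()
        assert r1["validation"].to_dict() == r2["validation"].to_dict()

    def test_phantom_dop_classifier_above_chance(self, default_dataset,
                                                 default_analyses):
        """DOP maps at the 0° probe separate the phantom classes well above
        chance (>=80% held-out accuracy, region-level split)."""
        from polartissue.cli_io import build_features
        table = build_features(default_dataset, default_analyses, "dop", "H")
        res = pt.train_eval(table, seed=1, split="region")
        assert res["test"].accuracy >= 80.0
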