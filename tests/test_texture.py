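"""Texture features vs independent brute-force enumeration oracles."""
import numpy as np
import pandas as pd
import pytest

from apexfa.texture import (ANGLES, EmptyPairsError, GLCM_STATS, GLRLM_STATS,
                            extract_all, feature_schema, glcm, glcm_features,
                            glrlm_features, histogram_features, quantize)

# ---------------------------------------------------------------------------
# brute-force oracles: plain double loops, no shared code with the package
# ---------------------------------------------------------------------------

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def oracle_glcm(levels, mask, d, theta, G):
    dr, dc = OFFSETS[theta][0] * d, OFFSETS[theta][1] * d
    P = np.zeros((G, G), dtype=float)
    h, w = levels.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                P[levels[r, c], levels[r2, c2]] += 1
                P[levels[r2, c2], levels[r, c]] += 1
    return P


def oracle_glcm_features(P):
    G = P.shape[0]
    out = {}
    asm = con = idm = ent = 0.0
    for i in range(G):
        for j in range(G):
            p = P[i, j]
            asm += p * p
            con += (i - j) ** 2 * p
            idm += p / (1 + (i - j) ** 2)
            if p > 0:
                ent -= p * np.log(p)
    px = P.sum(axis=1)
    mu = sum(i * px[i] for i in range(G))
    var = sum((i - mu) ** 2 * px[i] for i in range(G))
    corr = 0.0
    if var > 0:
        corr = sum((i - mu) * (j - mu) * P[i, j]
                   for i in range(G) for j in range(G)) / var
    psum = np.zeros(2 * G - 1)
    pdif = np.zeros(G)
    for i in range(G):
        for j in range(G):
            psum[i + j] += P[i, j]
            pdif[abs(i - j)] += P[i, j]
    savg = sum(k * psum[k] for k in range(2 * G - 1))
    svar = sum((k - savg) ** 2 * psum[k] for k in range(2 * G - 1))
    sent = -sum(p * np.log(p) for p in psum if p > 0)
    davg = sum(k * pdif[k] for k in range(G))
    dvar = sum((k - davg) ** 2 * pdif[k] for k in range(G))
    dent = -sum(p * np.log(p) for p in pdif if p > 0)
    return {"AngScMom": asm, "Contrast": con, "Correlat": corr,
            "SumOfSqs": var, "InvDfMom": idm, "SumAverg": savg,
            "SumVarnc": svar, "SumEntrp": sent, "Entropy": ent,
            "DifVarnc": dvar, "DifEntrp": dent}


def oracle_runs(levels, mask, theta):
    """Independent run enumeration: walk each line pixel by pixel."""
    h, w = levels.shape
    if theta == 0:
        lines = [[(r, c) for c in range(w)] for r in range(h)]
    elif theta == 90:
        lines = [[(r, c) for r in range(h)] for c in range(w)]
    elif theta == 45:
        lines = [[(r, s - r) for r in range(h) if 0 <= s - r < w]
                 for s in range(h + w - 1)]
    else:
        lines = [[(s + c, c) for c in range(w) if 0 <= s + c < h]
                 for s in range(-(w - 1), h)]
    runs = []
    for line in lines:
        prev, length = None, 0
        for r, c in line:
            if mask[r, c] and prev == levels[r, c]:
                length += 1
            else:
                if prev is not None:
                    runs.append((prev, length))
                prev, length = (levels[r, c], 1) if mask[r, c] else (None, 0)
        if prev is not None:
            runs.append((prev, length))
    return runs


def oracle_glrlm_features(levels, mask, G, theta):
    runs = oracle_runs(levels, mask, theta)
    N = len(runs)
    lens = np.array([l for _, l in runs], float)
    sre = np.mean(1.0 / lens**2) if False else (1.0 / lens**2).sum() / N
    lre = (lens**2).sum() / N
    gl = np.zeros(G)
    rl = np.zeros(int(lens.max()) + 1)
    for g, l in runs:
        gl[g] += 1
        rl[int(l)] += 1
    return {"ShrtREmph": sre, "LngREmph": lre,
            "GLevNonUni": (gl**2).sum() / N, "RLNonUni": (rl**2).sum() / N,
            "Fraction": N / mask.sum()}


def random_roi(rng, shape=(16, 16), G=16):
    img = rng.uniform(0, 255, shape)
    mask = rng.random(shape) < 0.8
    mask[rng.integers(0, shape[0]), rng.integers(0, shape[1])] = True
    return img, mask, quantize(img, mask, G=G)


# ---------------------------------------------------------------------------


class TestQuantize:
    def test_exact_bins_identity(self):
        img = np.array([[0.0, 1.0], [2.0, 3.0]])
        q = quantize(img, np.ones((2, 2), bool), G=4, clip_k=None)
        assert np.array_equal(q.levels, [[0, 1], [2, 3]])

    def test_constant_roi_maps_to_middle_level(self):
        q = quantize(np.full((4, 4), 7.0), np.ones((4, 4), bool), G=64)
        assert np.all(q.levels == 32)

    def test_occupancy_matches_independent_rebinning(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 30, (20, 20))
        mask = rng.random((20, 20)) < 0.7
        q = quantize(img, mask, G=32, clip_k=3.0)
        v = img[mask]
        mu, sd = v.mean(), v.std()
        clipped = np.clip(v, mu - 3 * sd, mu + 3 * sd)
        lo, hi = mu - 3 * sd, mu + 3 * sd
        expected = np.minimum((np.floor((clipped - lo) / (hi - lo) * 32)
                               ).astype(int), 31)
        assert np.array_equal(np.sort(q.levels[mask]), np.sort(expected))

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            quantize(np.ones((2, 2)), np.zeros((2, 2), bool), G=8)
        with pytest.raises(ValueError):
            quantize(np.ones((2, 2)), np.ones((2, 2), bool), G=1)


class TestGlcm:
    def test_normalized_and_symmetric(self):
        rng = np.random.default_rng(1)
        _, _, q = random_roi(rng)
        P = glcm(q, 2, 45)
        assert P.sum() == pytest.approx(1.0)
        assert np.allclose(P, P.T)

    def test_alternating_columns_hand_enumeration(self):
        """4x4 image with alternating 0/1 columns: the 24 horizontal pairs
        all couple levels 0 and 1, so P(0,1) = P(1,0) = 0.5."""
        img = np.tile([0.0, 1.0, 0.0, 1.0], (4, 1))
        q = quantize(img, np.ones((4, 4), bool), G=2, clip_k=None)
        P = glcm(q, 1, 0)
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == P[1, 1] == 0.0

    def test_constant_roi_single_diagonal_entry(self):
        q = quantize(np.full((6, 6), 5.0), np.ones((6, 6), bool), G=8)
        P = glcm(q, 1, 0)
        assert P[4, 4] == pytest.approx(1.0)

    def test_too_thin_roi_raises(self):
        mask = np.zeros((8, 8), bool)
        mask[:, 0] = True
        q = quantize(np.random.default_rng(0).uniform(0, 9, (8, 8)), mask, G=4)
        with pytest.raises(EmptyPairsError):
            glcm(q, 3, 0)

    def test_matrix_matches_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            img, mask, q = random_roi(rng)
            for d in (1, 3):
                for theta in ANGLES:
                    ours = glcm(q, d, theta)
                    ref = oracle_glcm(q.levels, mask, d, theta, q.G)
                    assert np.allclose(ours, ref / ref.sum(), atol=1e-12)


class TestGlcmFeatures:
    def test_constant_roi_closed_forms(self):
        q = quantize(np.full((6, 6), 5.0), np.ones((6, 6), bool), G=8)
        f = glcm_features(glcm(q, 1, 0))
        assert f["Contrast"] == 0.0
        assert f["AngScMom"] == pytest.approx(1.0)
        assert f["Entropy"] == pytest.approx(0.0)

    def test_alternating_pattern_contrast_one(self):
        img = np.tile([0.0, 1.0] * 4, (8, 1))
        q = quantize(img, np.ones((8, 8), bool), G=2, clip_k=None)
        f = glcm_features(glcm(q, 1, 0))
        assert f["Contrast"] == pytest.approx(1.0)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError):
            glcm_features(np.ones((4, 4)))

    def test_features_match_direct_summation_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            _, _, q = random_roi(rng)
            P = glcm(q, 1, 0)
            ours = glcm_features(P)
            ref = oracle_glcm_features(P)
            for k in GLCM_STATS:
                assert ours[k] == pytest.approx(ref[k], abs=1e-12), k


class TestGlrlm:
    def test_single_row_single_run(self):
        img = np.full((1, 8), 3.0)
        q = quantize(img, np.ones((1, 8), bool), G=8)
        f = glrlm_features(q, 0)
        assert f["Fraction"] == pytest.approx(1.0 / 8.0)
        assert f["LngREmph"] == pytest.approx(64.0)

    def test_alternating_row_unit_runs(self):
        img = np.tile([0.0, 1.0] * 4, (1, 1))
        q = quantize(img, np.ones((1, 8), bool), G=2, clip_k=None)
        f = glrlm_features(q, 0)
        assert f["ShrtREmph"] == pytest.approx(1.0)
        assert f["Fraction"] == pytest.approx(1.0)

    def test_features_match_run_scanner_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            img, mask, q = random_roi(rng, G=8)
            for theta in ANGLES:
                ours = glrlm_features(q, theta)
                ref = oracle_glrlm_features(q.levels, mask, 8, theta)
                for k in GLRLM_STATS:
                    assert ours[k] == pytest.approx(ref[k], abs=1e-12), (theta, k)

    def test_empty_roi_rejected(self):
        q = quantize(np.ones((2, 2)), np.ones((2, 2), bool), G=4)
        q.mask = np.zeros((2, 2), bool)
        with pytest.raises(ValueError):
            glrlm_features(q, 0)


class TestHistogram:
    def test_constant_roi(self):
        f = histogram_features(np.full((5, 5), 9.0), np.ones((5, 5), bool))
        assert f["Mean"] == 9.0
        assert f["Variance"] == 0.0
        assert f["Skewness"] == 0.0

    def test_symmetric_values_zero_skewness(self):
        img = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        f = histogram_features(img, np.ones((1, 5), bool))
        assert f["Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_moment_formulas(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 255, (12, 12))
        mask = rng.random((12, 12)) < 0.6
        f = histogram_features(img, mask)
        v = img[mask]
        m = v.mean()
        assert f["Mean"] == pytest.approx(m, abs=1e-12)
        assert f["Variance"] == pytest.approx(((v - m) ** 2).mean(), abs=1e-9)
        sk = ((v - m) ** 3).mean() / ((v - m) ** 2).mean() ** 1.5
        assert f["Skewness"] == pytest.approx(sk, abs=1e-10)
        ku = ((v - m) ** 4).mean() / ((v - m) ** 2).mean() ** 2 - 3.0
        assert f["Kurtosis"] == pytest.approx(ku, abs=1e-10)
        assert f["Perc50"] == pytest.approx(np.percentile(v, 50), abs=1e-12)


class TestExtractAll:
    def test_s5_0_contrast_present_per_roi(self, segmented_phantom, noisy_phantom):
        image, contour, rois = segmented_phantom
        from apexfa.fragments import fragment_pipeline

        _, _, s4 = fragment_pipeline(image, contour)
        row = extract_all(image, rois, s4)
        for roi in ("S1", "S2", "S3", "S4"):
            assert f"{roi}_S(5,0)Contrast" in row.index
        assert row.notna().all()

    def test_identical_inputs_identical_rows(self, segmented_phantom):
        image, contour, rois = segmented_phantom
        from apexfa.fragments import fragment_pipeline

        _, _, s4 = fragment_pipeline(image, contour)
        a = extract_all(image, rois, s4)
        b = extract_all(image, rois, s4)
        pd.testing.assert_series_equal(a, b)

    def test_constant_shift_invariance_of_second_order_features(self):
        rng = np.random.default_rng(6)
        img = rng.uniform(40, 200, (24, 24))
        mask = np.ones((24, 24), bool)
        qa = quantize(img, mask, G=16)
        qb = quantize(img + 25.0, mask, G=16)
        assert np.array_equal(qa.levels, qb.levels)

    def test_schema_covers_every_feature(self, segmented_phantom):
        image, contour, rois = segmented_phantom
        from apexfa.fragments import fragment_pipeline

        _, _, s4 = fragment_pipeline(image, contour)
        row = extract_all(image, rois, s4)
        names = {e["name"] for e in feature_schema()}
        assert set(row.index) == names
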