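"""Texture-matrix features against brute-force enumeration oracles."""

import numpy as np
import pytest

from crsrad.features._grid import DIRECTIONS_13, runs_along_direction
from crsrad.features.firstorder import LOG_EPS
from crsrad.features.glcm import compute_glcm_features, glcm_matrices
from crsrad.features.gldm import compute_gldm_features, gldm_matrix
from crsrad.features.glrlm import compute_glrlm_features, glrlm_matrix
from crsrad.features.glszm import compute_glszm_features, glszm_matrix
from crsrad.features.ngtdm import compute_ngtdm_features, ngtdm_table

from oracles import (
    brute_dependence,
    brute_glcm,
    brute_ngtdm,
    brute_runs,
    brute_zones,
)


class TestGLCM:
    def test_matrices_match_pair_enumeration(self, toy_grid):
        levels, mask, ng = toy_grid
        mats = glcm_matrices(levels, mask, ng)
        assert len(mats) == 13
        for mat, direction in zip(mats, DIRECTIONS_13):
            expected = brute_glcm(levels, mask, ng, direction)
            np.testing.assert_allclose(mat, expected, atol=1e-12)

    def test_matrices_sum_to_one(self, toy_grid_masked):
        levels, mask, ng = toy_grid_masked
        for mat in glcm_matrices(levels, mask, ng):
            assert mat.sum() == pytest.approx(1.0, abs=1e-12)
            assert (mat >= 0).all()

    def test_hand_enumerated_features_on_toy_grid(self):
        """4x4x1 grid: contrast / IDMN / difference entropy from first principles."""
        levels = np.array([[[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]]],
                          dtype=np.int32).reshape(1, 4, 4)
        mask = np.ones_like(levels, dtype=bool)
        ng = 4
        feats = compute_glcm_features(levels, mask, ng)
        contrasts, idmns, diffents = [], [], []
        for direction in DIRECTIONS_13:
            p = brute_glcm(levels, mask, ng, direction)
            if p.sum() == 0:
                continue
            contrast = idmn = 0.0
            pdiff = np.zeros(ng)
            for i in range(ng):
                for j in range(ng):
                    contrast += p[i, j] * (i - j) ** 2
                    idmn += p[i, j] / (1 + (i - j) ** 2 / ng**2)
                    pdiff[abs(i - j)] += p[i, j]
            diffent = -sum(pk * np.log2(pk + LOG_EPS) for pk in pdiff)
            contrasts.append(contrast)
            idmns.append(idmn)
            diffents.append(diffent)
        assert feats["glcm_Contrast"] == pytest.approx(np.mean(contrasts), abs=1e-10)
        assert feats["glcm_Idmn"] == pytest.approx(np.mean(idmns), abs=1e-10)
        assert feats["glcm_DifferenceEntropy"] == pytest.approx(np.mean(diffents), abs=1e-10)

    def test_constant_image_conventions(self):
        levels = np.ones((3, 3, 3), dtype=np.int32)
        mask = np.ones((3, 3, 3), dtype=bool)
        feats = compute_glcm_features(levels, mask, 1)
        assert feats["glcm_Idmn"] == pytest.approx(1.0)
        assert feats["glcm_DifferenceEntropy"] == pytest.approx(0.0, abs=1e-9)
        assert feats["glcm_JointEnergy"] == pytest.approx(1.0)


class TestGLRLM:
    @pytest.mark.parametrize("fixture", ["toy_grid", "toy_grid_masked"])
    def test_runs_match_line_walk_oracle(self, fixture, request):
        levels, mask, ng = request.getfixturevalue(fixture)
        for direction in DIRECTIONS_13:
            gray, lengths = runs_along_direction(levels, mask, direction)
            got = sorted(zip(gray.tolist(), lengths.tolist()))
            expected = sorted(brute_runs(levels, mask, direction))
            assert got == expected, direction

    def test_constant_cube_runs(self):
        """A constant 2x2x2 lesion: each direction yields runs of its max extent."""
        levels = np.ones((2, 2, 2), dtype=np.int32)
        mask = np.ones((2, 2, 2), dtype=bool)
        for direction in DIRECTIONS_13:
            gray, lengths = runs_along_direction(levels, mask, direction)
            expected = sorted(brute_runs(levels, mask, direction))
            assert sorted(zip(gray.tolist(), lengths.tolist())) == expected
        # axis-aligned direction: 4 runs of length 2
        gray, lengths = runs_along_direction(levels, mask, (0, 0, 1))
        assert list(lengths) == [2, 2, 2, 2]

    def test_features_from_oracle_matrix(self, toy_grid):
        levels, mask, ng = toy_grid
        feats = compute_glrlm_features(levels, mask, ng)
        sre_per_dir = []
        for direction in DIRECTIONS_13:
            runs = brute_runs(levels, mask, direction)
            nr = len(runs)
            sre_per_dir.append(sum(1.0 / l**2 for _, l in runs) / nr)
        assert feats["glrlm_ShortRunEmphasis"] == pytest.approx(
            np.mean(sre_per_dir), abs=1e-10
        )


class TestGLSZM:
    def test_zones_match_flood_fill(self, toy_grid_masked):
        levels, mask, ng = toy_grid_masked
        mat = glszm_matrix(levels, mask, ng)
        expected = brute_zones(levels, mask)
        got = [
            (g + 1, s + 1)
            for g in range(mat.shape[0])
            for s in range(mat.shape[1])
            for _ in range(int(mat[g, s]))
        ]
        assert sorted(got) == sorted(expected)

    def test_constant_lesion_single_zone(self):
        levels = np.ones((3, 3, 3), dtype=np.int32)
        mask = np.ones((3, 3, 3), dtype=bool)
        mat = glszm_matrix(levels, mask, 1)
        assert mat.sum() == 1
        assert mat[0, 26] == 1  # one zone of size 27
        feats = compute_glszm_features(levels, mask, 1)
        assert feats["glszm_ZonePercentage"] == pytest.approx(1 / 27)


class TestGLDM:
    def test_dependences_match_neighbor_count_oracle(self, toy_grid):
        levels, mask, ng = toy_grid
        mat = gldm_matrix(levels, mask, ng)
        expected = brute_dependence(levels, mask)
        got = [
            (g + 1, d + 1)
            for g in range(mat.shape[0])
            for d in range(mat.shape[1])
            for _ in range(int(mat[g, d]))
        ]
        assert sorted(got) == sorted(expected)
        assert mat.sum() == mask.sum()

    def test_large_dependence_emphasis_from_oracle(self, toy_grid_masked):
        levels, mask, ng = toy_grid_masked
        feats = compute_gldm_features(levels, mask, ng)
        deps = brute_dependence(levels, mask)
        lde = sum(d**2 for _, d in deps) / len(deps)
        assert feats["gldm_LargeDependenceEmphasis"] == pytest.approx(lde, abs=1e-10)


class TestNGTDM:
    def test_checkerboard_hand_oracle(self):
        """3x3x1 two-level checkerboard: coarseness/contrast by hand enumeration."""
        levels = np.array([[1, 2, 1], [2, 1, 2], [1, 2, 1]], dtype=np.int32).reshape(1, 3, 3)
        mask = np.ones_like(levels, dtype=bool)
        n_i, s_i = ngtdm_table(levels, mask, 2)
        en, es = brute_ngtdm(levels, mask, 2)
        np.testing.assert_allclose(n_i, en)
        np.testing.assert_allclose(s_i, es, atol=1e-12)
        feats = compute_ngtdm_features(levels, mask, 2)
        nvp = 9
        p = en / nvp
        coarse = 1.0 / float((p * es).sum())
        contrast = (
            p[0] * p[1] * (1 - 2) ** 2 + p[1] * p[0] * (2 - 1) ** 2
        ) / (2 * 1) * es.sum() / nvp
        assert feats["ngtdm_Coarseness"] == pytest.approx(coarse, abs=1e-10)
        assert feats["ngtdm_Contrast"] == pytest.approx(contrast, abs=1e-10)

    def test_table_matches_oracle_on_random_grid(self, toy_grid):
        levels, mask, ng = toy_grid
        n_i, s_i = ngtdm_table(levels, mask, ng)
        en, es = brute_ngtdm(levels, mask, ng)
        np.testing.assert_allclose(n_i, en)
        np.testing.assert_allclose(s_i, es, atol=1e-10)
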