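"""Texture core: discretization, GLCM/GLRLM builders and their features.

The builders are checked against independent brute-force pair/run
enumerators on random small volumes, and against hand-worked
micro-examples on a 1x1x4 line.
"""

import numpy as np
import pytest

from radsig.texture import (
    DIRECTIONS_13,
    discretize,
    glcm,
    glcm_features,
    glrlm,
    glrlm_features,
    texture_features,
)

LINE = np.array([0.0, 0.0, 10.0, 10.0]).reshape(1, 1, 4)
LINE_MASK = np.ones((1, 1, 4), dtype=bool)


def brute_glcm_counts(levels, mask, directions, distance, ng):
    """Independent pair enumerator: loop over every voxel and direction, both ways."""
    counts = np.zeros((ng, ng))
    for idx in np.argwhere(mask):
        for d in directions:
            for sign in (1, -1):
                nb = idx + sign * distance * np.asarray(d)
                if np.all(nb >= 0) and np.all(nb < mask.shape) and mask[tuple(nb)]:
                    counts[levels[tuple(idx)] - 1, levels[tuple(nb)] - 1] += 1
    return counts


def brute_glrlm_counts(levels, mask, direction, ng):
    """Independent run enumerator: walk every line voxel by voxel."""
    d = np.asarray(direction)
    runs = {}
    for idx in np.argwhere(mask):
        prev = idx - d
        inside = np.all(prev >= 0) and np.all(prev < mask.shape)
        if inside and mask[tuple(prev)] and levels[tuple(prev)] == levels[tuple(idx)]:
            continue  # not a run start
        length = 1
        cur = idx + d
        while (
            np.all(cur >= 0)
            and np.all(cur < mask.shape)
            and mask[tuple(cur)]
            and levels[tuple(cur)] == levels[tuple(idx)]
        ):
            length += 1
            cur = cur + d
        runs[(levels[tuple(idx)], length)] = runs.get((levels[tuple(idx)], length), 0) + 1
    max_len = max((l for (_, l) in runs), default=1)
    counts = np.zeros((ng, max_len))
    for (g, l), c in runs.items():
        counts[g - 1, l - 1] = c
    return counts


class TestDiscretize:
    def test_one_value_per_bin(self):
        vol = np.arange(32, dtype=float).reshape(2, 4, 4)
        d = discretize(vol, np.ones_like(vol, bool), 32)
        assert sorted(np.unique(d.levels[d.mask])) == list(range(1, 33))
        assert not d.degenerate

    def test_constant_region_is_degenerate(self):
        vol = np.full((3, 3, 3), 7.0)
        d = discretize(vol, np.ones_like(vol, bool), 32)
        assert d.degenerate
        assert np.all(d.levels[d.mask] == 1)

    def test_max_value_closed_into_last_bin(self):
        vol = np.array([0.0, 10.0, 0.0, 10.0]).reshape(1, 1, 4)
        d = discretize(vol, np.ones((1, 1, 4), bool), 2)
        assert sorted(np.unique(d.levels[d.mask])) == [1, 2]
        assert d.levels[0, 0, 1] == 2  # max maps to level 2, not 3

    def test_in_mask_levels_within_range(self):
        rng = np.random.default_rng(5)
        vol = rng.normal(size=(6, 6, 6))
        mask = rng.random((6, 6, 6)) < 0.5
        mask[0, 0, 0] = True
        d = discretize(vol, mask, 8)
        lv = d.levels[mask]
        assert lv.min() >= 1 and lv.max() == 8
        assert np.all(d.levels[~mask] == 0)
        assert len(d.bin_edges) == 9 and np.all(np.diff(d.bin_edges) > 0)

    def test_rejects_single_bin(self):
        with pytest.raises(ValueError):
            discretize(LINE, LINE_MASK, 1)


class TestGLCM:
    def test_hand_enumerated_line(self):
        d = discretize(LINE, LINE_MASK, 2)
        m = glcm(d, [(0, 0, 1)], 1)
        expected = np.array([[2, 1], [1, 2]]) / 6.0
        np.testing.assert_allclose(m.probabilities, expected)

    def test_probabilities_sum_to_one_and_symmetric(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.7
        m = glcm(discretize(vol, mask, 4))
        assert m.probabilities.sum() == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(m.probabilities, m.probabilities.T)

    def test_single_level_collapses_to_one_cell(self):
        d = discretize(np.full((2, 2, 2), 3.0), np.ones((2, 2, 2), bool), 4)
        m = glcm(d, [(0, 0, 1)], 1)
        assert m.probabilities[0, 0] == 1.0

    def test_direction_sign_irrelevant(self):
        d = discretize(LINE, LINE_MASK, 2)
        np.testing.assert_allclose(
            glcm(d, [(0, 0, 1)]).probabilities, glcm(d, [(0, 0, -1)]).probabilities
        )

    def test_no_pairs_raises(self):
        vol = np.zeros((3, 3, 3))
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        with pytest.raises(ValueError, match="no co-occurrences"):
            glcm(discretize(vol, mask, 2), [(0, 0, 1)], 1)


class TestGLRLM:
    def test_hand_enumerated_line(self):
        d = discretize(LINE, LINE_MASK, 2)
        m = glrlm(d, (0, 0, 1))
        assert m.n_runs == 2
        assert m.counts[0, 1] == 1 and m.counts[1, 1] == 1  # two runs of length 2
        assert m.counts.sum() == 2

    def test_uniform_line_single_run(self):
        vol = np.zeros((1, 1, 6))
        d = discretize(vol, np.ones((1, 1, 6), bool), 4)
        m = glrlm(d, (0, 0, 1))
        assert m.n_runs == 1
        assert m.counts[0, 5] == 1

    def test_voxel_conservation(self):
        d = discretize(LINE, LINE_MASK, 2)
        m = glrlm(d, (0, 0, 1))
        lengths = np.arange(1, m.counts.shape[1] + 1)
        assert (m.counts * lengths).sum() == 4

    def test_conservation_random_masks(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            vol = rng.normal(size=(5, 5, 5))
            mask = rng.random((5, 5, 5)) < 0.6
            if not mask.any():
                continue
            d = discretize(vol, mask, 3)
            for direction in DIRECTIONS_13:
                m = glrlm(d, direction)
                lengths = np.arange(1, m.counts.shape[1] + 1)
                assert (m.counts * lengths).sum() == mask.sum()
                assert m.counts.sum() == m.n_runs


class TestBruteForceOracle:
    def test_glcm_matches_enumerator(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            mask = rng.random((4, 4, 4)) < 0.6
            if mask.sum() < 2:
                continue
            vol = rng.integers(0, 4, size=(4, 4, 4)).astype(float)
            d = discretize(vol, mask, 4)
            expected = brute_glcm_counts(d.levels, mask, DIRECTIONS_13, 1, 4)
            if expected.sum() == 0:
                continue
            np.testing.assert_allclose(
                glcm(d).probabilities, expected / expected.sum(), atol=1e-12
            )

    def test_glrlm_matches_enumerator(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            mask = rng.random((4, 4, 4)) < 0.6
            if not mask.any():
                continue
            vol = rng.integers(0, 4, size=(4, 4, 4)).astype(float)
            d = discretize(vol, mask, 4)
            for direction in [(0, 0, 1), (1, 0, 0), (1, 1, 0), (1, -1, 1)]:
                got = glrlm(d, direction).counts
                want = brute_glrlm_counts(d.levels, mask, direction, 4)
                w = max(got.shape[1], want.shape[1])
                np.testing.assert_array_equal(
                    np.pad(got, ((0, 0), (0, w - got.shape[1]))),
                    np.pad(want, ((0, 0), (0, w - want.shape[1]))),
                )


class TestGLCMFeatures:
    def test_hand_sum_average(self):
        d = discretize(LINE, LINE_MASK, 2)
        f = glcm_features(glcm(d, [(0, 0, 1)], 1))
        assert f["sum_average"] == pytest.approx(3.0)

    def test_degenerate_conventions(self):
        d = discretize(np.full((2, 2, 2), 1.0), np.ones((2, 2, 2), bool), 4)
        f = glcm_features(glcm(d, [(0, 0, 1)], 1))
        assert f["correlation"] == 1.0
        assert f["entropy"] == 0.0
        assert f["IMC1"] == 0.0
        assert f["MCC"] == 1.0

    def test_uniform_matrix_max_probability(self):
        from radsig.texture import GLCMatrix

        ng = 4
        m = GLCMatrix(np.full((ng, ng), 1.0 / ng**2), ((0, 0, 1),), 1)
        f = glcm_features(m)
        assert f["max_probability"] == pytest.approx(1.0 / ng**2)
        assert f["energy"] == pytest.approx(1.0 / ng**2)

    def test_roster_size_and_finiteness(self):
        rng = np.random.default_rng(2)
        vol = rng.normal(size=(6, 6, 6))
        f = glcm_features(glcm(discretize(vol, np.ones((6, 6, 6), bool), 8)))
        assert len(f) == 25
        assert all(np.isfinite(v) for v in f.values())


class TestGLRLMFeatures:
    def test_hand_rp_and_sre(self):
        d = discretize(LINE, LINE_MASK, 2)
        f = glrlm_features(glrlm(d, (0, 0, 1)))
        assert f["RP"] == pytest.approx(0.5)
        assert f["SRE"] == pytest.approx(0.25)

    def test_all_unit_runs_limit(self):
        vol = np.array([0.0, 10.0, 0.0, 10.0]).reshape(1, 1, 4)
        d = discretize(vol, np.ones((1, 1, 4), bool), 2)
        f = glrlm_features(glrlm(d, (0, 0, 1)))
        assert f["SRE"] == pytest.approx(1.0)
        assert f["RP"] == pytest.approx(1.0)

    def test_roster_size(self):
        d = discretize(LINE, LINE_MASK, 2)
        f = glrlm_features(glrlm(d, (0, 0, 1)))
        assert len(f) == 11


def test_direction_order_irrelevant():
    rng = np.random.default_rng(9)
    vol = rng.normal(size=(6, 6, 6))
    mask = rng.random((6, 6, 6)) < 0.8
    d = discretize(vol, mask, 6)
    f1 = texture_features(d, DIRECTIONS_13)
    f2 = texture_features(d, tuple(reversed(DIRECTIONS_13)))
    assert f1.keys() == f2.keys()
    for k in f1:
        assert f1[k] == pytest.approx(f2[k], rel=1e-12)


def test_texture_feature_count():
    rng = np.random.default_rng(1)
    vol = rng.normal(size=(6, 6, 6))
    f = texture_features(discretize(vol, np.ones((6, 6, 6), bool), 8))
    assert len(f) == 36
    assert sum(k.startswith("GLCM_") for k in f) == 25
    assert sum(k.startswith("GLRLM_") for k in f) == 11
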