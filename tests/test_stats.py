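"""Pseudo-t maps, TFCE enhancement, and permutation FWE control."""

import numpy as np
import pytest
from scipy import stats as sps

from speechtrack.forward import make_grid
from speechtrack.simulate import synth_null_maps
from speechtrack.stats import (TfceParams, interaction_contrast, peak_voxel,
                               permutation_fwe, pseudo_t_map, sphere_mask, tfce)


@pytest.fixture(scope="module")
def grid():
    return make_grid(0.015, 0.08)


def subj_maps(grid, n, seed, effect=0.0, where=None):
    m = synth_null_maps(grid, n, seed=seed)
    if effect:
        m[:, where] += effect
    return m


class TestPseudoT:
    def test_identical_groups_zero_t(self, grid):
        a = subj_maps(grid, 6, 0)
        t = pseudo_t_map(a, a.copy(), design="dependent", grid=grid)
        np.testing.assert_allclose(t.t_values, 0.0, atol=1e-12)

    def test_no_smoothing_matches_textbook_t(self, grid):
        a, b = subj_maps(grid, 8, 1), subj_maps(grid, 9, 2)
        t = pseudo_t_map(a, b, design="independent", fwhm_mm=0.0, grid=grid)
        ref = sps.ttest_ind(a, b, axis=0).statistic
        np.testing.assert_allclose(t.t_values, ref, atol=1e-10)

    def test_paired_no_smoothing_matches_textbook_t(self, grid):
        a, b = subj_maps(grid, 8, 3), subj_maps(grid, 8, 4)
        t = pseudo_t_map(a, b, design="dependent", fwhm_mm=0.0, grid=grid)
        ref = sps.ttest_rel(a, b, axis=0).statistic
        np.testing.assert_allclose(t.t_values, ref, atol=1e-10)

    def test_default_smoothing_fwhm(self, grid):
        a, b = subj_maps(grid, 4, 5), subj_maps(grid, 4, 6)
        t = pseudo_t_map(a, b, design="independent", grid=grid)
        assert t.smoothing_fwhm_mm == 15.0

    def test_single_subject_rejected(self, grid):
        a, b = subj_maps(grid, 1, 7), subj_maps(grid, 4, 8)
        with pytest.raises(ValueError):
            pseudo_t_map(a, b, design="independent", grid=grid)


class TestTfce:
    def test_zero_map_zero_output(self, grid):
        out = tfce(np.zeros(grid.n_inside), grid=grid)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_plateau_beats_isolated_voxel(self, grid):
        vals = np.zeros(grid.n_inside)
        pts = grid.masked_points
        center = pts[np.argmin(np.linalg.norm(pts - [0.03, 0, 0.03], axis=1))]
        plateau = np.linalg.norm(pts - center, axis=1) <= 0.022  # ~10 voxels
        vals[plateau] = 2.0
        isolated = int(np.argmin(np.linalg.norm(pts - [-0.04, 0, -0.04], axis=1)))
        vals[isolated] = 2.0
        out = tfce(vals, TfceParams(dh=0.1), grid=grid)
        i_plateau = int(np.flatnonzero(plateau)[0])
        assert out.values[i_plateau] > out.values[isolated]

    def test_single_voxel_closed_form(self, grid):
        # e = 1 throughout: TFCE -> t^(H+1)/(H+1) as dh -> 0
        h = 3.0
        vals = np.zeros(grid.n_inside)
        vals[37] = h
        out = tfce(vals, TfceParams(dh=h / 1000), grid=grid)
        assert out.values[37] == pytest.approx(h ** 3 / 3, rel=0.01)

    def test_monotonicity(self, grid, rng):
        m1 = np.abs(rng.standard_normal(grid.n_inside))
        m2 = m1 + np.abs(rng.standard_normal(grid.n_inside))
        p = TfceParams(dh=0.05)
        t1, t2 = tfce(m1, p, grid=grid), tfce(m2, p, grid=grid)
        assert np.all(t2.values >= t1.values - 1e-12)

    def test_scaling_increases_enhancement(self, grid, rng):
        m = np.abs(rng.standard_normal(grid.n_inside)) + 0.1
        p = TfceParams(dh=0.02)
        t1, t2 = tfce(m, p, grid=grid), tfce(3.0 * m, p, grid=grid)
        assert np.all(t2.values[m > 0] > t1.values[m > 0])

    def test_negative_values_enhanced_symmetrically(self, grid):
        vals = np.zeros(grid.n_inside)
        vals[10], vals[200] = 2.0, -2.0
        out = tfce(vals, TfceParams(dh=0.1), grid=grid)
        assert out.values[200] == pytest.approx(-out.values[10], rel=1e-12)


class TestPermutationFwe:
    def test_constant_map_high_p(self, grid):
        rng = np.random.default_rng(0)
        base = synth_null_maps(grid, 8, seed=1)
        # permutation-invariant observed statistic: both groups identical
        res = permutation_fwe(base, base.copy(), design="dependent",
                              params=TfceParams(n_steps=20),
                              n_perms=100, seed=2, grid=grid)
        assert np.all(res.fwe_p > 0.9)

    def test_small_n_enumerates_all_permutations(self, grid):
        a = synth_null_maps(grid, 3, seed=3)
        b = synth_null_maps(grid, 3, seed=4)
        with pytest.warns(UserWarning, match="distinct"):
            res = permutation_fwe(a, b, design="independent",
                                  params=TfceParams(n_steps=20),
                                  n_perms=100, seed=5, grid=grid)
        from math import comb
        assert res.n_perms == comb(6, 3)

    def test_planted_effect_detected_and_localized(self, grid):
        where = sphere_mask(grid, [[0.03, 0.0, 0.03]], 0.02)
        a = subj_maps(grid, 8, 6, effect=2.5, where=where)
        b = subj_maps(grid, 8, 7)
        res = permutation_fwe(a, b, design="independent",
                              params=TfceParams(n_steps=25),
                              n_perms=200, seed=8, grid=grid)
        v = grid.masked_points[peak_voxel(res)]
        assert np.linalg.norm(v - [0.03, 0.0, 0.03]) <= 2 * 0.015 + 1e-9
        assert res.fwe_p.min() < 0.05

    def test_deterministic_given_seed(self, grid):
        a = synth_null_maps(grid, 6, seed=9)
        b = synth_null_maps(grid, 6, seed=10)
        kw = dict(design="independent", params=TfceParams(n_steps=20),
                  n_perms=120, seed=11, grid=grid)
        r1 = permutation_fwe(a, b, **kw)
        r2 = permutation_fwe(a, b, **kw)
        np.testing.assert_array_equal(r1.fwe_p, r2.fwe_p)
        np.testing.assert_array_equal(r1.max_stat_null, r2.max_stat_null)

    def test_mask_changes_only_max_statistic(self, grid):
        a = synth_null_maps(grid, 6, seed=12)
        b = synth_null_maps(grid, 6, seed=13)
        mask = sphere_mask(grid, [[0.02, 0.0, 0.02]], 0.03)
        kw = dict(design="independent", params=TfceParams(n_steps=20),
                  n_perms=120, seed=14, grid=grid)
        full = permutation_fwe(a, b, **kw)
        small = permutation_fwe(a, b, mask=mask, **kw)
        np.testing.assert_array_equal(full.observed_t, small.observed_t)
        # restricting the search volume can only make p smaller or equal
        assert np.all(small.fwe_p[mask] <= full.fwe_p[mask] + 1e-12)

    def test_null_p_values_super_uniform(self, grid):
        # desk-scale validity: min-p over replicates should not be
        # stochastically smaller than uniform at the voxel level
        ps = []
        for rep in range(25):
            a = synth_null_maps(grid, 6, seed=100 + 2 * rep)
            b = synth_null_maps(grid, 6, seed=101 + 2 * rep)
            res = permutation_fwe(a, b, design="independent",
                                  params=TfceParams(n_steps=15),
                                  n_perms=100, seed=rep, grid=grid)
            ps.append(res.fwe_p.min())
        ps = np.array(ps)
        # FWE-corrected minimum p: P(min p <= a) <= a  => counts bounded
        for alpha in (0.1, 0.25, 0.5):
            assert (ps <= alpha).mean() <= alpha + 2.5 * np.sqrt(alpha / 25)


class TestInteraction:
    def test_equal_conditions_give_zero(self, grid):
        nat = synth_null_maps(grid, 5, seed=20)
        da, db = interaction_contrast(nat, nat.copy(),
                                      synth_null_maps(grid, 4, seed=21),
                                      synth_null_maps(grid, 4, seed=21))
        np.testing.assert_allclose(da, 0.0, atol=1e-12)
        np.testing.assert_allclose(db, 0.0, atol=1e-12)

    def test_contrast_linearity(self, grid):
        na, ca = synth_null_maps(grid, 4, seed=22), synth_null_maps(grid, 4, seed=23)
        nb, cb = synth_null_maps(grid, 4, seed=24), synth_null_maps(grid, 4, seed=25)
        da1, db1 = interaction_contrast(na, ca, nb, cb)
        da2, db2 = interaction_contrast(3 * na, 3 * ca, 3 * nb, 3 * cb)
        np.testing.assert_allclose(da2, 3 * da1, atol=1e-12)
        np.testing.assert_allclose(db2, 3 * db1, atol=1e-12)
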