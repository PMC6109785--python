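"""GLM t-maps, TFCE and permutation FWE against independent oracles."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from fcmech.inference import (
    GLMSpec,
    TFCEParams,
    fit_glm_tmap,
    permutation_fwe,
    tfce_enhance,
)


def tfce_sweep_oracle(m, params: TFCEParams):
    """Brute-force threshold sweep with scipy labeling over the same
    discrete threshold grid."""
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[
        params.connectivity])
    out = np.zeros_like(m, dtype=float)
    for sign in (1, -1):
        mm = np.where(sign * m > 0, sign * np.asarray(m, float), 0.0)
        mx = mm.max()
        if mx <= 0:
            continue
        dh = mx / params.n_steps if params.dh == "auto" else params.dh
        n_steps = params.n_steps if params.dh == "auto" else int(np.ceil(mx / dh))
        acc = np.zeros_like(mm)
        for s in range(1, n_steps + 1):
            h = s * dh
            lab, nl = ndimage.label(mm >= h - 1e-12, structure=structure)
            if nl == 0:
                continue
            sizes = np.bincount(lab.ravel()).astype(float)
            sizes[0] = 0
            acc += np.where(lab > 0, sizes[lab] ** params.E * h**params.H * dh, 0.0)
        out += sign * acc
    return out


def two_group_design(n1, n0):
    x = np.array([1.0] * n1 + [0.0] * n0)
    X = np.column_stack([x, np.ones(n1 + n0)])
    return GLMSpec(design=X, contrast=np.array([1.0, 0.0]), ev_of_interest=0,
                   nuisance_idx=(1,))


class TestGLM:
    def test_identical_groups_give_zero_t(self):
        Y = np.vstack([np.arange(5.0)[:, None]] * 2)
        t = fit_glm_tmap(Y, two_group_design(5, 5))
        assert t[0] == pytest.approx(0.0, abs=1e-12)

    def test_textbook_two_sample_t(self):
        """4 vs 4 with {10..13} vs {0..3} equals the pooled-variance
        two-sample t computed from the hand formula."""
        a = np.array([10.0, 11.0, 12.0, 13.0])
        b = np.array([0.0, 1.0, 2.0, 3.0])
        Y = np.concatenate([a, b])[:, None]
        t = fit_glm_tmap(Y, two_group_design(4, 4))[0]
        sp2 = (a.var(ddof=1) * 3 + b.var(ddof=1) * 3) / 6
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        assert t == pytest.approx(t_hand, abs=1e-10)

    def test_orthogonal_nuisance_leaves_t_unchanged(self, rng):
        n = 12
        x = np.array([1.0] * 6 + [0.0] * 6)
        Y = rng.standard_normal((n, 20))
        base = GLMSpec(np.column_stack([x, np.ones(n)]), np.array([1.0, 0]),
                       0, (1,))
        t0 = fit_glm_tmap(Y, base)
        # nuisance orthogonal to both contrast column and data
        z = np.tile([1.0, -1.0], 6)
        z -= z @ x / (x @ x) * x
        Yo = Y - np.outer(z, z @ Y / (z @ z))
        t0 = fit_glm_tmap(Yo, base)
        withz = GLMSpec(np.column_stack([x, np.ones(n), z]),
                        np.array([1.0, 0, 0]), 0, (1, 2))
        t1 = fit_glm_tmap(Yo, withz)
        # same contrast estimate; dof changes the scale by a known factor
        assert np.abs(t1 / t0 - t1[0] / t0[0]).max() < 1e-8

    def test_singular_design_lists_columns(self):
        x = np.array([1.0] * 4 + [0.0] * 4)
        X = np.column_stack([x, np.ones(8), 2 * x])
        with pytest.raises(ValueError, match="rank deficient"):
            GLMSpec(X, np.array([1.0, 0, 0]), 0, (1, 2))


class TestTFCE:
    def test_zero_map(self):
        assert np.all(tfce_enhance(np.zeros((5, 5, 5))) == 0)

    def test_single_voxel_closed_form(self):
        """Isolated voxel of height 3 with E=0.5, H=2: the threshold sum
        approximates the closed-form integral 3^3/3 = 9 within 2%."""
        m = np.zeros((7, 7, 7))
        m[3, 3, 3] = 3.0
        v = tfce_enhance(m, TFCEParams(E=0.5, H=2.0))[3, 3, 3]
        assert abs(v - 9.0) / 9.0 < 0.02

    def test_ridge_matches_sweep_oracle(self):
        m = np.zeros((5, 1, 1))
        m[:, 0, 0] = [1.0, 2.0, 3.0, 2.0, 1.0]
        params = TFCEParams()
        got = tfce_enhance(m, params)
        want = tfce_sweep_oracle(m, params)
        assert np.abs(got - want).max() <= 0.01 * np.abs(want).max()

    @pytest.mark.parametrize("conn", [6, 18, 26])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_maps_match_sweep_oracle(self, conn, seed):
        rng = np.random.default_rng(seed)
        m = rng.standard_normal((9, 8, 7))
        params = TFCEParams(connectivity=conn)
        got = tfce_enhance(m, params)
        want = tfce_sweep_oracle(m, params)
        assert np.abs(got - want).max() <= 0.01 * np.abs(want).max()

    def test_explicit_dh(self):
        m = np.zeros((3, 3, 3))
        m[1, 1, 1] = 3.0
        v = tfce_enhance(m, TFCEParams(dh=0.03))[1, 1, 1]
        # sum_{i=1..100} (0.03 i)^2 * 0.03
        want = sum((0.03 * i) ** 2 * 0.03 for i in range(1, 101))
        assert v == pytest.approx(want, rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(0, 63), st.floats(0.1, 2.0))
    def test_monotone_in_voxel_height(self, seed, vox, bump):
        """Raising any voxel never decreases any enhanced value."""
        rng = np.random.default_rng(seed)
        m = rng.standard_normal((4, 4, 4)).clip(0, None)
        m2 = m.copy()
        m2[np.unravel_index(vox, m.shape)] += bump
        params = TFCEParams(dh=0.05)  # shared grid so maps are comparable
        e1 = tfce_enhance(m, params)
        e2 = tfce_enhance(m2, params)
        assert (e2 - e1).min() > -1e-9


def exhaustive_oracle(Y, n1, mask_shape, params):
    """Independent relabeling enumeration: direct OLS t + sweep-oracle TFCE."""
    n = Y.shape[0]
    maxima, obs = [], None
    for S in combinations(range(n), n1):
        x = np.zeros(n)
        x[list(S)] = 1.0
        X = np.column_stack([x, np.ones(n)])
        XtX_inv = np.linalg.inv(X.T @ X)
        b = XtX_inv @ X.T @ Y
        res = Y - X @ b
        s2 = (res**2).sum(0) / (n - 2)
        t = b[0] / np.sqrt(np.maximum(s2 * XtX_inv[0, 0], 1e-300))
        grid = t.reshape(mask_shape)
        enh = np.clip(tfce_sweep_oracle(grid, params), 0, None)
        maxima.append(enh.max())
        if S == tuple(range(n1)):
            obs = enh
    maxima = np.array(maxima)
    p = (maxima[:, None] >= obs.ravel()[None, :] - 1e-12).mean(axis=0)
    return p.reshape(mask_shape)


class TestPermutationFWE:
    def test_exhaustive_matches_relabeling_oracle(self, rng):
        params = TFCEParams()
        Y = rng.standard_normal((9, 24))
        Y[:4, :8] += 1.2
        spec = two_group_design(4, 5)
        stat = permutation_fwe(Y, spec, params, n_perm=500,
                               mask=np.ones((4, 3, 2), bool), seed=0)
        assert stat.exhaustive and stat.n_perm == 126
        oracle = exhaustive_oracle(Y, 4, (4, 3, 2), params)
        assert np.abs(stat.p_fwe - oracle).max() < 1e-12

    def test_classic_4v4_single_voxel(self):
        Y = np.array([10.0, 11, 12, 13, 0, 1, 2, 3])[:, None]
        stat = permutation_fwe(Y, two_group_design(4, 4), TFCEParams(), 500,
                               np.ones((1, 1, 1), bool), seed=3)
        assert stat.p_fwe[0, 0, 0] == pytest.approx(1 / 70)

    def test_alpha_one_makes_everything_significant(self, rng):
        Y = rng.standard_normal((10, 27))
        stat = permutation_fwe(Y, two_group_design(5, 5), TFCEParams(), 200,
                               np.ones((3, 3, 3), bool), seed=1)
        assert stat.sig_mask(alpha=1.0).sum() == 27

    def test_sampled_p_has_floor(self, rng):
        Y = rng.standard_normal((30, 8))
        Y[:15] += 5.0
        x = np.array([1.0] * 15 + [0.0] * 15)
        spec = GLMSpec(np.column_stack([x, np.ones(30)]), np.array([1.0, 0]),
                       0, (1,))
        stat = permutation_fwe(Y, spec, TFCEParams(), 99,
                               np.ones((2, 2, 2), bool), seed=2)
        assert not stat.exhaustive
        assert stat.p_fwe.min() >= 1 / 100

    def test_freedman_lane_nuisance_does_not_bias_null(self, rng):
        """Small null check with a group-correlated nuisance covariate: the
        corrected p of the max voxel is not systematically tiny."""
        hits = 0
        for c in range(30):
            r = np.random.default_rng(c)
            Y = r.standard_normal((12, 64))
            x = np.array([1.0] * 6 + [0.0] * 6)
            z = 0.7 * x + r.standard_normal(12)
            spec = GLMSpec(np.column_stack([x, np.ones(12), z]),
                           np.array([1.0, 0, 0]), 0, (1, 2))
            stat = permutation_fwe(Y, spec, TFCEParams(), 200,
                                   np.ones((4, 4, 4), bool), seed=c)
            hits += int((stat.p_fwe <= 0.05).any())
        assert hits <= 6  # ~binomial(30, 0.05) upper tail

    def test_empty_mask_rejected(self, rng):
        Y = rng.standard_normal((8, 0))
        with pytest.raises(ValueError, match="mask"):
            permutation_fwe(Y, two_group_design(4, 4), TFCEParams(), 10,
                            np.zeros((2, 2, 2), bool), seed=0)

    def test_both_signs_negates_t(self, rng):
        Y = rng.standard_normal((10, 27))
        pos, neg = permutation_fwe(Y, two_group_design(5, 5), TFCEParams(), 100,
                                   np.ones((3, 3, 3), bool), seed=1,
                                   both_signs=True)
        assert np.allclose(pos.t, -neg.t)
        assert pos.contrast_name != neg.contrast_name
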