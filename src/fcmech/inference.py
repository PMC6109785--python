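"""Voxelwise GLM group inference with TFCE and permutation FWE correction.

The engine behind every statistic map in the pipeline: ordinary
least-squares voxelwise GLM, threshold-free cluster enhancement (TFCE) of
the t map, and family-wise error control through the permutation
distribution of the image-wide maximum TFCE statistic under a
Freedman-Lane scheme (residualize against nuisance regressors, permute
residuals, refit the full model).

Exchangeability is exploited exactly where possible: when the regressor of
interest is a two-level indicator and all nuisance regressors are constant,
the distinct relabelings are enumerated exhaustively whenever their number
does not exceed ``n_perm``, yielding exact p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb, factorial

import numpy as np
from numba import njit

from .containers import StatMap

__all__ = [
    "GLMSpec",
    "TFCEParams",
    "fit_glm_tmap",
    "tfce_enhance",
    "permutation_fwe",
]


@dataclass
class GLMSpec:
    """Design matrix, single-EV contrast and nuisance bookkeeping."""

    design: np.ndarray
    contrast: np.ndarray
    ev_of_interest: int
    nuisance_idx: tuple = ()

    def __post_init__(self):
        self.design = np.asarray(self.design, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.design.ndim != 2:
            raise ValueError("design must be 2D (subjects x regressors)")
        n, r = self.design.shape
        if self.contrast.shape != (r,):
            raise ValueError("contrast length must match the number of regressors")
        nz = np.nonzero(self.contrast)[0]
        if len(nz) != 1 or nz[0] != self.ev_of_interest:
            raise ValueError("contrast must be nonzero only on ev_of_interest")
        _check_full_rank(self.design)

    @property
    def n_subjects(self) -> int:
        return self.design.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.design.shape[1]


def _check_full_rank(X: np.ndarray) -> None:
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    if s[-1] < 1e-10 * s[0]:
        null = vt[-1]
        cols = sorted(np.nonzero(np.abs(null) > 1e-8)[0].tolist())
        raise ValueError(f"design is rank deficient; dependent columns: {cols}")


@dataclass
class TFCEParams:
    """TFCE parameterization: extent exponent E, height exponent H,
    integration step and cluster connectivity."""

    E: float = 0.5
    H: float = 2.0
    dh: float | str = "auto"  # "auto" -> max statistic / n_steps
    connectivity: int = 26
    n_steps: int = 100

    def __post_init__(self):
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be positive")
        if self.dh != "auto" and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


def _neighbor_offsets(connectivity: int) -> np.ndarray:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return np.array(offs, dtype=np.int64)


@njit(cache=True)
def _uf_find(parent, w, x):  # pragma: no cover
    """Find with path compression, preserving per-node value offsets.

    value(v) = sum of w along the path from v to its root; compression
    rewrites each path node's offset so the sum is unchanged.
    """
    root = x
    total = 0.0
    while parent[root] != root:
        total += w[root]
        root = parent[root]
    # second pass: re-point path nodes at the root, fixing offsets
    cur = x
    remaining = total
    while parent[cur] != root:
        nxt = parent[cur]
        w_cur = w[cur]
        parent[cur] = root
        w[cur] = remaining
        remaining -= w_cur
        cur = nxt
    return root


@njit(cache=True)
def _tfce_uf(smax, order_desc, s0, s1, s2, offs, E, H, dh, n_steps, out):  # pragma: no cover
    """Union-find threshold sweep computing the full TFCE map.

    ``smax[v]`` is the highest threshold step at which voxel v is
    suprathreshold (0 = never); ``order_desc`` lists active voxels by
    descending smax.  Equivalent to summing ``e(h,p)^E h^H dh`` over the
    discrete thresholds, but clusters are grown once, from the top down.
    """
    n = smax.size
    s12 = s1 * s2
    parent = np.full(n, -1, np.int64)
    w = np.zeros(n)
    size = np.zeros(n, np.int64)
    since = np.zeros(n, np.int64)
    prefix = np.zeros(n_steps + 1)
    for t in range(1, n_steps + 1):
        prefix[t] = prefix[t - 1] + (t * dh) ** H * dh
    for oi in range(order_desc.size):
        v = order_desc[oi]
        s = smax[v]
        parent[v] = v
        w[v] = 0.0
        size[v] = 1
        since[v] = s
        x = v // s12
        rem = v - x * s12
        y = rem // s2
        z = rem - y * s2
        for o in range(offs.shape[0]):
            xx = x + offs[o, 0]
            yy = y + offs[o, 1]
            zz = z + offs[o, 2]
            if 0 <= xx < s0 and 0 <= yy < s1 and 0 <= zz < s2:
                nb = xx * s12 + yy * s2 + zz
                if parent[nb] != -1:
                    ra = _uf_find(parent, w, v)
                    rb = _uf_find(parent, w, nb)
                    if ra != rb:
                        # flush both clusters' pending gains down to step s
                        w[ra] += size[ra] ** E * (prefix[since[ra]] - prefix[s])
                        since[ra] = s
                        w[rb] += size[rb] ** E * (prefix[since[rb]] - prefix[s])
                        since[rb] = s
                        if size[ra] < size[rb]:
                            ra, rb = rb, ra
                        parent[rb] = ra
                        w[rb] -= w[ra]
                        size[ra] += size[rb]
    # final flush down to step 0 and read out values
    for oi in range(order_desc.size):
        v = order_desc[oi]
        r = _uf_find(parent, w, v)
        if since[r] > 0:
            w[r] += size[r] ** E * prefix[since[r]]
            since[r] = 0
    for oi in range(order_desc.size):
        v = order_desc[oi]
        r = _uf_find(parent, w, v)
        out[v] = w[v] + (w[r] if r != v else 0.0)
    return out


def _tfce_one_sign(pos: np.ndarray, params: TFCEParams, offs: np.ndarray) -> np.ndarray:
    """Enhance the non-negative map ``pos`` (values <= 0 are background)."""
    out = np.zeros_like(pos)
    mx = float(pos.max(initial=0.0))
    if mx <= 0:
        return out
    if params.dh == "auto":
        n_steps = params.n_steps
        dh = mx / n_steps
    else:
        dh = float(params.dh)
        n_steps = int(np.ceil(mx / dh - 1e-12))
        if n_steps > 100000:
            raise ValueError("dh too small for the map's range")
    # crop to the support's bounding box: clusters cannot cross zeros
    nz = np.nonzero(pos > 0)
    lo = [int(a.min()) for a in nz]
    hi = [int(a.max()) + 1 for a in nz]
    sub = np.ascontiguousarray(pos[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]])
    flat = sub.ravel()
    smax = np.minimum(np.floor(flat / dh + 1e-9), n_steps).astype(np.int64)
    active = np.nonzero(smax > 0)[0]
    order_desc = active[np.argsort(-smax[active], kind="stable")]
    sub_out = np.zeros(flat.size)
    _tfce_uf(
        smax, order_desc, sub.shape[0], sub.shape[1], sub.shape[2],
        offs, params.E, params.H, dh, n_steps, sub_out,
    )
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub_out.reshape(sub.shape)
    return out


def tfce_enhance(t_map: np.ndarray, params: TFCEParams | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed 3D statistic map.

    ``TFCE(p) = sum_h e(h, p)^E h^H dh`` over thresholds ``h = dh, 2dh, ...``
    up to the voxel's own height, where ``e(h, p)`` is the voxel count of
    the suprathreshold cluster containing ``p``.  Negative values are
    enhanced on the negated map and returned with negative sign.
    """
    params = params or TFCEParams()
    m = np.asarray(t_map, dtype=float)
    if m.ndim != 3:
        raise ValueError("t_map must be 3D")
    if not np.isfinite(m).all():
        raise ValueError("t_map must be finite")
    offs = _neighbor_offsets(params.connectivity)
    pos = _tfce_one_sign(np.where(m > 0, m, 0.0), params, offs)
    neg = _tfce_one_sign(np.where(m < 0, -m, 0.0), params, offs)
    return pos - neg


class _GLMEngine:
    """Precomputed pieces for fast repeated t-map evaluation on one design."""

    def __init__(self, spec: GLMSpec):
        X = spec.design
        n, r = X.shape
        if n < r + 2:
            raise ValueError("need at least regressors + 2 subjects")
        XtX_inv = np.linalg.inv(X.T @ X)
        self.a = spec.contrast @ XtX_inv @ X.T  # (n,): c'beta = a @ Y
        self.g = float(spec.contrast @ XtX_inv @ spec.contrast)
        self.Q, _ = np.linalg.qr(X)
        self.df = n - r

    def t(self, Y: np.ndarray) -> np.ndarray:
        eff = self.a @ Y
        rss = np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", self.Q.T @ Y, self.Q.T @ Y)
        rss = np.clip(rss, 0.0, None)
        se = np.sqrt(np.maximum(rss / self.df * self.g, 1e-300))
        return eff / se


def fit_glm_tmap(subject_maps: np.ndarray, spec: GLMSpec) -> np.ndarray:
    """Voxelwise OLS t statistics for ``contrast' beta`` on a
    ``subjects x voxels`` matrix."""
    Y = np.asarray(subject_maps, dtype=float)
    if Y.shape[0] != spec.n_subjects:
        raise ValueError("subject_maps rows must match the design")
    return _GLMEngine(spec).t(Y)


def _permutation_index_sets(spec: GLMSpec, n_perm: int, rng: np.random.Generator):
    """Permutations of residual rows; exhaustive when feasible.

    Returns ``(perms, exhaustive)`` where ``perms`` is an array of row
    indices, the first row being the identity when exhaustive.
    """
    n = spec.n_subjects
    x = spec.design[:, spec.ev_of_interest]
    Z = spec.design[:, list(spec.nuisance_idx)] if spec.nuisance_idx else None
    z_const = Z is None or all(np.ptp(Z[:, j]) == 0 for j in range(Z.shape[1]))
    levels = np.unique(x)
    if len(levels) == 2 and z_const:
        hi = np.nonzero(x == levels[1])[0]
        lo = np.nonzero(x == levels[0])[0]
        n_distinct = comb(n, len(hi))
        if n_distinct <= n_perm:
            perms = np.empty((n_distinct, n), dtype=np.intp)
            all_idx = np.arange(n)
            for p_i, subset in enumerate(combinations(range(n), len(hi))):
                subset = np.array(subset, dtype=np.intp)
                rest = np.setdiff1d(all_idx, subset, assume_unique=True)
                perm = np.empty(n, dtype=np.intp)
                perm[hi] = subset
                perm[lo] = rest
                perms[p_i] = perm
            return perms, True
    if n <= 9 and factorial(n) <= n_perm:
        perms = np.array(list(permutations(range(n))), dtype=np.intp)
        return perms, True
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    return perms, False


def permutation_fwe(
    subject_maps: np.ndarray,
    spec: GLMSpec,
    params: TFCEParams,
    n_perm: int,
    mask: np.ndarray,
    seed: int,
    both_signs: bool = False,
    joint_correction: bool = False,
    stage: str = "tstatFC",
    component: str = "",
    contrast_name: str = "",
    neg_contrast_name: str = "",
):
    """Freedman-Lane permutation test with max-TFCE FWE correction.

    ``subject_maps`` is ``subjects x voxels`` over the in-``mask`` voxels
    (C-order raveling of the 3D mask).  Returns a :class:`StatMap`, or a
    ``(positive, negative)`` pair of StatMaps sharing one permutation pass
    when ``both_signs`` is set.  With ``joint_correction`` the two signs
    form a single FWE family (null distribution = image-wide max over
    either side); otherwise each one-sided contrast is its own family.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    Y = np.asarray(subject_maps, dtype=float)
    if Y.shape != (spec.n_subjects, int(mask.sum())):
        raise ValueError("subject_maps shape must be (subjects, n_mask_voxels)")
    engine = _GLMEngine(spec)
    offs = _neighbor_offsets(params.connectivity)

    # crop the mask bounding box once; all 3D work happens on the crop
    nzm = np.nonzero(mask)
    lo = [int(a.min()) for a in nzm]
    hi = [int(a.max()) + 1 for a in nzm]
    cmask = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]

    def tfce_sides(tvec: np.ndarray):
        grid = np.zeros(cmask.shape)
        grid[cmask] = tvec
        pos = _tfce_one_sign(np.where(grid > 0, grid, 0.0), params, offs)
        neg = _tfce_one_sign(np.where(grid < 0, -grid, 0.0), params, offs)
        return pos, neg

    t_obs = engine.t(Y)
    tfce_pos, tfce_neg = tfce_sides(t_obs)

    # Freedman-Lane: residualize against nuisance, permute, refit full model
    if spec.nuisance_idx:
        Z = spec.design[:, list(spec.nuisance_idx)]
        gamma, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        fitted = Z @ gamma
        resid = Y - fitted
    else:
        fitted = np.zeros_like(Y)
        resid = Y

    rng = np.random.default_rng(seed)
    perms, exhaustive = _permutation_index_sets(spec, n_perm, rng)
    max_pos = np.empty(len(perms))
    max_neg = np.empty(len(perms))
    for i, perm in enumerate(perms):
        t_star = engine.t(fitted + resid[perm])
        p_side, n_side = tfce_sides(t_star)
        max_pos[i] = p_side.max(initial=0.0)
        max_neg[i] = n_side.max(initial=0.0)
    if joint_correction:
        # one family over both signs: null = image-wide max of either side
        max_pos = max_neg = np.maximum(max_pos, max_neg)

    def pvals(obs_c: np.ndarray, maxima: np.ndarray) -> np.ndarray:
        obs = obs_c[cmask]
        exceed = (maxima[:, None] >= obs[None, :]).sum(axis=0)
        if exhaustive:
            p = exceed / len(maxima)
        else:
            p = (1.0 + exceed) / (1.0 + len(maxima))
        out = np.ones(mask.shape)
        grid = np.ones(cmask.shape)
        grid[cmask] = p
        out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = grid
        return out

    def embed(vals_c: np.ndarray, fill: float = 0.0) -> np.ndarray:
        out = np.full(mask.shape, fill)
        out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = vals_c
        out[~mask] = fill
        return out

    t3d_vals = np.zeros(cmask.shape)
    t3d_vals[cmask] = t_obs
    t3d = embed(t3d_vals)

    pos_map = StatMap(
        stage=stage, component=component,
        contrast_name=contrast_name or "positive",
        t=t3d, tfce=embed(tfce_pos), p_fwe=pvals(tfce_pos, max_pos),
        mask=mask, n_perm=len(perms), seed=seed, exhaustive=exhaustive,
    )
    if not both_signs:
        return pos_map
    neg_map = StatMap(
        stage=stage, component=component,
        contrast_name=neg_contrast_name or "negative",
        t=-t3d, tfce=embed(tfce_neg), p_fwe=pvals(tfce_neg, max_neg),
        mask=mask, n_perm=len(perms), seed=seed, exhaustive=exhaustive,
    )
    return pos_map, neg_map
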