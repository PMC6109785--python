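"""Dual regression: subject-specific time courses and spatial maps.

Stage 1 regresses every timepoint's in-mask values on all group component
maps simultaneously, giving one time course per component.  Stage 2
regresses every voxel's time series on all stage-1 time courses, giving
subject-specific parameter-estimate (PE) maps and standardized Z maps.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .containers import GroupICAResult, SubjectMaps, Volume4D

__all__ = ["stage1_timecourses", "stage2_subject_maps", "dual_regress"]


def _require_full_rank(M: np.ndarray, what: str) -> None:
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    if s[-1] < 1e-10 * s[0]:
        null = vt[-1]
        cols = sorted(np.nonzero(np.abs(null) > 1e-8)[0].tolist())
        raise ValueError(f"{what} are collinear (columns {cols})")


def stage1_timecourses(vol: Volume4D, group_maps: np.ndarray) -> np.ndarray:
    """OLS of each timepoint's in-mask values on all group maps at once.

    ``group_maps`` is ``(n_components, n_mask_voxels)``; returns a
    ``(T, n_components)`` coefficient series.
    """
    G = np.asarray(group_maps, dtype=float).T  # (voxels, components)
    _require_full_rank(G, "group maps")
    Y = vol.timeseries().T  # (voxels, T)
    tc, *_ = np.linalg.lstsq(G, Y, rcond=None)
    return tc.T


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t statistics to standard normal deviates, preserving sign."""
    sf = stats.t.sf(np.abs(t), df)
    z = stats.norm.isf(np.clip(sf, 1e-300, None))
    return np.sign(t) * z


def stage2_subject_maps(
    vol: Volume4D, timecourses: np.ndarray, variance_normalize_tc: bool = True
) -> SubjectMaps:
    """Per-voxel OLS of the time series on all stage-1 time courses.

    PE maps are the coefficients; Z maps divide each coefficient by its
    standard error and convert the resulting t (``T - k`` degrees of
    freedom) to a standard normal deviate.  With
    ``variance_normalize_tc`` each time course is scaled to unit sample
    variance first, so PE maps carry both amplitude and shape information.
    """
    X = np.asarray(timecourses, dtype=float)
    T, k = X.shape
    if T != vol.n_timepoints:
        raise ValueError("timecourses length must match the volume")
    if T <= k:
        raise ValueError("need more timepoints than components")
    if variance_normalize_tc:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("constant time course cannot be variance-normalized")
        X = X / sd
    _require_full_rank(X, "time courses")
    Y = vol.timeseries()  # (T, voxels)
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # (k, voxels)
    resid = Y - X @ B
    df = T - k
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tmap = np.where(se > 0, B / np.maximum(se, 1e-300), 0.0)
    zmap = t_to_z(tmap, df)
    return SubjectMaps(pe_maps=B, z_maps=zmap, timecourses=X, mask=vol.mask.copy())


def dual_regress(
    vol: Volume4D, group: GroupICAResult, variance_normalize_tc: bool = True
) -> SubjectMaps:
    """Convenience wrapper: stage 1 then stage 2 against a group ICA result."""
    tc = stage1_timecourses(vol, group.spatial_maps)
    return stage2_subject_maps(vol, tc, variance_normalize_tc=variance_normalize_tc)
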