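"""Sequential masked covariate analysis: FC -> T2LL -> MSSS.

Starting from the voxels where the group FC contrast survived FWE
correction, a second permutation analysis tests the association of
subject FC maps with lesion load (T2LL) inside that mask; its surviving
voxels mask a third analysis against the MS severity score (MSSS).  The
significant sets are nested by construction
(``tstatFC`` superset of ``tstatFC_T2LL`` superset of ``tstatFC_T2LL_MSSS``).
Per-subject mean Z values over each stage's mask feed Pearson
correlations with the corresponding covariate, Bonferroni-corrected over
the number of tests actually run.

Only MS subjects enter the covariate stages (controls carry no T2LL or
MSSS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import StatMap
from .inference import GLMSpec, TFCEParams, permutation_fwe

__all__ = [
    "build_stage_mask",
    "masked_covariate_inference",
    "extract_mean_z",
    "pearson_with_bonferroni",
    "CascadeResult",
    "run_cascade",
]


def build_stage_mask(stat: StatMap, alpha: float = 0.05) -> np.ndarray:
    """Voxels surviving the FWE-corrected threshold."""
    return stat.sig_mask(alpha)


def masked_covariate_inference(
    subject_maps: np.ndarray,
    covariate: np.ndarray,
    stage_mask: np.ndarray,
    n_perm: int,
    seed: int,
    analysis_mask: np.ndarray,
    nuisance: np.ndarray | None = None,
    params: TFCEParams | None = None,
    stage: str = "tstatFC_T2LL",
    component: str = "",
    covariate_name: str = "covariate",
) -> StatMap:
    """Permutation GLM with the covariate as the explanatory variable of
    interest, restricted to ``stage_mask``; both signs tested.

    ``subject_maps`` is ``subjects x voxels`` over ``analysis_mask``.  The
    returned StatMap carries the per-voxel covariate t; ``p_fwe`` at each
    voxel is the corrected p of the sign matching the voxel's t, with both
    signs corrected as a single FWE family (the null distribution is the
    image-wide maximum over either direction).
    """
    stage_mask = np.asarray(stage_mask, dtype=bool)
    if not stage_mask.any():
        raise ValueError("stage_mask is empty")
    if (stage_mask & ~analysis_mask).any():
        raise ValueError("stage_mask must lie within the analysis mask")
    cov = np.asarray(covariate, dtype=float)
    if np.isnan(cov).any():
        raise ValueError("covariate undefined for an included subject")
    if np.ptp(cov) == 0:
        raise ValueError("covariate is constant")
    n = len(cov)
    cols = [np.ones(n), cov - cov.mean()]
    nuis_idx = [0]
    if nuisance is not None and nuisance.size:
        nuisance = np.asarray(nuisance, dtype=float)
        for j in range(nuisance.shape[1]):
            col = nuisance[:, j]
            cols.append(col - col.mean())
            nuis_idx.append(2 + j)
    design = np.column_stack(cols)
    contrast = np.zeros(design.shape[1])
    contrast[1] = 1.0
    spec = GLMSpec(design=design, contrast=contrast, ev_of_interest=1,
                   nuisance_idx=tuple(nuis_idx))
    keep = stage_mask[analysis_mask]
    Y = np.asarray(subject_maps, dtype=float)[:, keep]
    pos, neg = permutation_fwe(
        Y, spec, params or TFCEParams(), n_perm, stage_mask, seed,
        both_signs=True, joint_correction=True, stage=stage, component=component,
        contrast_name=f"{covariate_name}+", neg_contrast_name=f"{covariate_name}-",
    )
    t = pos.t
    p = np.where(t >= 0, pos.p_fwe, neg.p_fwe)
    p[~stage_mask] = 1.0
    tfce = np.where(t >= 0, pos.tfce, -neg.tfce)
    return StatMap(
        stage=stage, component=component, contrast_name=covariate_name,
        t=t, tfce=tfce, p_fwe=p, mask=stage_mask,
        n_perm=pos.n_perm, seed=seed, exhaustive=pos.exhaustive,
    )


def extract_mean_z(subject_z_maps: np.ndarray, mask_cols: np.ndarray) -> np.ndarray:
    """Per-subject mean of the Z map over the mask voxels.

    ``subject_z_maps`` is ``subjects x voxels``; ``mask_cols`` a boolean
    column selector of the same voxel space.
    """
    mask_cols = np.asarray(mask_cols, dtype=bool)
    if not mask_cols.any():
        raise ValueError("mask is empty")
    return np.asarray(subject_z_maps, dtype=float)[:, mask_cols].mean(axis=1)


def pearson_with_bonferroni(
    x: np.ndarray, y: np.ndarray, m_tests: int
) -> tuple[float, float, float]:
    """Sample Pearson r, two-sided p (t transform, n-2 df) and the
    Bonferroni-corrected p over ``m_tests`` comparisons."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length series with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input series")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), float(min(1.0, m_tests * p))


@dataclass
class CascadeResult:
    """Outputs of one FC -> T2LL -> MSSS cascade."""

    component: str
    contrast_name: str
    masks: dict = field(default_factory=dict)  # stage -> 3D bool
    statmaps: dict = field(default_factory=dict)  # stage -> StatMap
    pearson: pd.DataFrame | None = None

    def nested(self) -> bool:
        """Check the strict nesting of the stage masks."""
        order = ["tstatFC", "tstatFC_T2LL", "tstatFC_T2LL_MSSS"]
        present = [s for s in order if s in self.masks]
        for a, b in zip(present, present[1:]):
            if (self.masks[b] & ~self.masks[a]).any():
                return False
        return True


def run_cascade(
    ms_pe_maps: np.ndarray,
    ms_z_maps: np.ndarray,
    ms_design: pd.DataFrame,
    fc_stat: StatMap,
    analysis_mask: np.ndarray,
    n_perm: int,
    seed: int,
    alpha: float = 0.05,
    nuisance: np.ndarray | None = None,
    params: TFCEParams | None = None,
) -> CascadeResult:
    """Run the full cascade for one (component, group-contrast) pair.

    ``ms_pe_maps``/``ms_z_maps`` are MS subjects only, ``subjects x voxels``
    over ``analysis_mask``.  Pearson rows are appended for each covariate
    stage with a nonempty significant set; ``m_tests`` (Bonferroni) is the
    number of Pearson tests actually run in this cascade.
    """
    res = CascadeResult(component=fc_stat.component, contrast_name=fc_stat.contrast_name)
    res.statmaps["tstatFC"] = fc_stat
    mask_fc = build_stage_mask(fc_stat, alpha)
    res.masks["tstatFC"] = mask_fc
    rows = []
    if mask_fc.any():
        t2ll = masked_covariate_inference(
            ms_pe_maps, ms_design["t2ll"].to_numpy(), mask_fc, n_perm, seed,
            analysis_mask, nuisance=nuisance, params=params,
            stage="tstatFC_T2LL", component=fc_stat.component, covariate_name="T2LL",
        )
        res.statmaps["tstatFC_T2LL"] = t2ll
        mask_t2 = build_stage_mask(t2ll, alpha)
        res.masks["tstatFC_T2LL"] = mask_t2
        if mask_t2.any():
            mean_z = extract_mean_z(ms_z_maps, mask_t2[analysis_mask])
            rows.append(("tstatFC_T2LL", "T2LL", mean_z, ms_design["t2ll"].to_numpy()))
            msss = masked_covariate_inference(
                ms_pe_maps, ms_design["msss"].to_numpy(), mask_t2, n_perm, seed + 1,
                analysis_mask, nuisance=nuisance, params=params,
                stage="tstatFC_T2LL_MSSS", component=fc_stat.component,
                covariate_name="MSSS",
            )
            res.statmaps["tstatFC_T2LL_MSSS"] = msss
            mask_ms = build_stage_mask(msss, alpha)
            res.masks["tstatFC_T2LL_MSSS"] = mask_ms
            if mask_ms.any():
                mean_z3 = extract_mean_z(ms_z_maps, mask_ms[analysis_mask])
                rows.append(
                    ("tstatFC_T2LL_MSSS", "MSSS", mean_z3, ms_design["msss"].to_numpy())
                )
    m_tests = len(rows)
    out = []
    for stage, covname, zvals, cov in rows:
        r, p, pb = pearson_with_bonferroni(zvals, cov, m_tests)
        out.append(
            {
                "component": fc_stat.component,
                "contrast": fc_stat.contrast_name,
                "stage": stage,
                "covariate": covname,
                "r": r,
                "p_two_sided": p,
                "p_bonferroni": pb,
                "n": len(cov),
                "m_tests": m_tests,
            }
        )
    res.pearson = pd.DataFrame(out)
    return res
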