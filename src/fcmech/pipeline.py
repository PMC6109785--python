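"""End-to-end orchestration: simulate/ingest -> preprocess -> group ICA ->
dual regression -> group contrasts -> gFC ranking -> covariate cascade ->
scenario report.

Two entry points:

* :func:`analyze_cohort` — in-memory pipeline on a list of volumes plus a
  design table; returns an :class:`AnalysisResult`.
* :func:`run_pipeline` — file-based runner driven by a config mapping (or
  YAML file), writing every artifact with provenance into a run directory.
  Completed stages are skipped on rerun when their config hash matches.

A single master seed is fanned out to per-stage seeds through a counter
scheme, so each stage is locally reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .cascade import CascadeResult, run_cascade
from .containers import (
    GroupICAResult,
    NetworkTemplate,
    ScenarioLabelMap,
    StatMap,
    Volume4D,
)
from .dualreg import dual_regress
from .ica import classify_components, estimate_model_order, group_decompose
from .inference import GLMSpec, TFCEParams, permutation_fwe
from .preprocess import highpass_filter, spatial_smooth, variance_normalize
from .ranking import plot_gfc, rank_networks
from .scenarios import classify_scenarios, scenario_report
from .synthetic import CohortConfig, simulate_cohort

__all__ = ["AnalysisParams", "AnalysisResult", "analyze_cohort", "run_pipeline"]

log = logging.getLogger(__name__)

CONTRAST_POS = "MS>HC"
CONTRAST_NEG = "MS<HC"
SUBGROUP_POS = "MS_short>MS_long"
SUBGROUP_NEG = "MS_short<MS_long"


def stage_seed(master: int, counter: int) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return int(np.random.default_rng([int(master), int(counter)]).integers(2**31))


@dataclass
class AnalysisParams:
    """Tunable parameters of the analysis stages (defaults follow the
    emulated protocol: 150 s high-pass, 5 mm FWHM, nuisance covariates
    age/gender/education/GM ratio, 5000 permutations, FWE p <= 0.05)."""

    highpass_sec: float = 150.0
    fwhm_mm: float = 5.0
    ica_order: int | str = "auto"
    max_order: int = 40
    r_min: float = 0.4
    p_min: float = 0.5
    covariates: tuple = ("age", "gender", "education", "gm_ratio")
    n_perm: int = 5000
    alpha: float = 0.05
    alpha_strict: float = 0.01
    tfce: TFCEParams = field(default_factory=TFCEParams)
    rsn_z_threshold: float = 3.0
    methods_convention: bool = False
    subgroup_contrasts: bool = True
    cascade_nuisance: bool = True
    variance_normalize_tc: bool = True


@dataclass
class AnalysisResult:
    design: pd.DataFrame
    ica: GroupICAResult
    subject_maps: list
    fc_stats: dict  # (component, contrast) -> StatMap
    subgroup_stats: dict
    atlas: dict  # component -> 3D bool extent
    gfc_table: pd.DataFrame
    cascades: list
    pearson: pd.DataFrame
    scenario_map: ScenarioLabelMap
    report: dict
    estimated_order: int = 0


def preprocess_volume(vol: Volume4D, params: AnalysisParams) -> Volume4D:
    out = highpass_filter(vol, params.highpass_sec)
    return spatial_smooth(out, params.fwhm_mm)


def nuisance_matrix(design: pd.DataFrame, covariates: tuple) -> np.ndarray:
    """Mean-centered nuisance columns; gender coded as an indicator.

    Columns that are constant in the (sub)sample carry no information and
    would make the design singular, so they are dropped.
    """
    cols = []
    for name in covariates:
        if name == "gender":
            col = (design["gender"] == "M").to_numpy(float)
        else:
            col = design[name].to_numpy(float)
        if np.ptp(col) == 0:
            log.info("nuisance covariate %s constant in this sample; dropped", name)
            continue
        cols.append(col - col.mean())
    return np.column_stack(cols) if cols else np.empty((len(design), 0))


def _estimate_order(subjects: list[Volume4D], params: AnalysisParams) -> int:
    """Model order from a decimated concatenation.

    The evidence criterion assumes exchangeable voxel observations, which
    spatial smoothing violates; voxels are therefore decimated to roughly
    one smoothing FWHM apart, and timepoints subsampled to keep the
    eigenproblem desk-sized.
    """
    mask = subjects[0].mask
    stride = max(1, int(np.ceil(params.fwhm_mm / subjects[0].voxel_sizes().min())))
    sub = np.zeros_like(mask)
    sub[::stride, ::stride, ::stride] = True
    while (mask & sub).sum() < 40 and stride > 1:
        stride -= 1
        sub[:] = False
        sub[::stride, ::stride, ::stride] = True
    m2 = mask & sub
    X = np.vstack([s.data[m2].T for s in subjects])
    n_vox = X.shape[1]
    cap = min(150, max(12, n_vox // 2))
    if X.shape[0] > cap:
        X = X[np.linspace(0, X.shape[0] - 1, cap).astype(int)]
    return max(2, estimate_model_order(X, max_order=params.max_order))


def group_contrast_stats(
    pe_stack: np.ndarray,
    design: pd.DataFrame,
    params: AnalysisParams,
    mask: np.ndarray,
    component: str,
    seed: int,
    ev_values: np.ndarray,
    contrast_names: tuple,
) -> tuple[StatMap, StatMap]:
    """Both one-sided contrasts of a two-group comparison for one component."""
    nuis = nuisance_matrix(design, params.covariates)
    n = len(design)
    design_mat = np.column_stack([ev_values - ev_values.mean(), np.ones(n), nuis])
    contrast = np.zeros(design_mat.shape[1])
    contrast[0] = 1.0
    spec = GLMSpec(
        design=design_mat, contrast=contrast, ev_of_interest=0,
        nuisance_idx=tuple(range(1, design_mat.shape[1])),
    )
    return permutation_fwe(
        pe_stack, spec, params.tfce, params.n_perm, mask, seed,
        both_signs=True, stage="tstatFC", component=component,
        contrast_name=contrast_names[0], neg_contrast_name=contrast_names[1],
    )


def _merge_labels(base: np.ndarray, add: np.ndarray) -> np.ndarray:
    """First-come merge of per-component scenario labels."""
    out = base.copy()
    new = (out == 0) & (add != 0)
    out[new] = add[new]
    return out


def analyze_cohort(
    volumes: list[Volume4D],
    design: pd.DataFrame,
    templates: list,
    params: AnalysisParams,
    seed: int,
    preprocessed: bool = False,
) -> AnalysisResult:
    """Run the full analysis in memory and return all stage outputs."""
    if not preprocessed:
        volumes = [preprocess_volume(v, params) for v in volumes]
    mask = volumes[0].mask

    # variance normalization conditions the ICA only; dual regression runs
    # on the filtered+smoothed data so PE maps keep amplitude information
    ica_volumes = [variance_normalize(v) for v in volumes]
    if params.ica_order == "auto":
        order = _estimate_order(ica_volumes, params)
    else:
        order = int(params.ica_order)
    log.info("group ICA at order %d", order)
    ica = group_decompose(ica_volumes, order, stage_seed(seed, 0))
    ica = classify_components(ica, templates, r_min=params.r_min, p_min=params.p_min)

    subject_maps = [
        dual_regress(v, ica, variance_normalize_tc=params.variance_normalize_tc)
        for v in volumes
    ]

    rsn_idx = ica.rsn_indices()
    atlas = {
        ica.labels[k]: np.abs(ica.map_3d(k)) >= params.rsn_z_threshold for k in rsn_idx
    }
    is_ms = (design["group"] == "MS").to_numpy()
    ms_design = design.loc[is_ms].reset_index(drop=True)
    ms_nuis = (
        nuisance_matrix(ms_design, params.covariates) if params.cascade_nuisance else None
    )

    fc_stats: dict = {}
    subgroup_stats: dict = {}
    cascades: list[CascadeResult] = []
    all_stats = []
    labels_grid = np.zeros(mask.shape, dtype=np.int32)

    for j, k in enumerate(rsn_idx):
        comp = ica.labels[k]
        # analysis restricted to the network's own spatial extent
        comp_mask = atlas[comp]
        if not comp_mask.any():
            comp_mask = mask
        keep = comp_mask[mask]
        pe_stack = np.stack([sm.pe_maps[k] for sm in subject_maps])[:, keep]
        pos, neg = group_contrast_stats(
            pe_stack, design, params, comp_mask, comp, stage_seed(seed, 10 + j),
            is_ms.astype(float), (CONTRAST_POS, CONTRAST_NEG),
        )
        fc_stats[(comp, CONTRAST_POS)] = pos
        fc_stats[(comp, CONTRAST_NEG)] = neg
        all_stats += [pos, neg]

        ms_pe = pe_stack[is_ms]
        ms_z = np.stack([sm.z_maps[k] for sm in subject_maps])[is_ms][:, keep]
        comp_sign_fc = np.zeros(mask.shape, dtype=np.int8)
        comp_sign_t2 = np.zeros(mask.shape, dtype=np.int8)
        comp_sign_ms = np.zeros(mask.shape, dtype=np.int8)
        for sgn, stat in ((+1, pos), (-1, neg)):
            casc = run_cascade(
                ms_pe, ms_z, ms_design, stat, comp_mask,
                params.n_perm, stage_seed(seed, 200 + 10 * j + (0 if sgn > 0 else 5)),
                alpha=params.alpha, nuisance=ms_nuis, params=params.tfce,
            )
            cascades.append(casc)
            fcm = casc.masks["tstatFC"]
            comp_sign_fc[fcm] = sgn
            t2 = casc.statmaps.get("tstatFC_T2LL")
            if t2 is not None:
                sig2 = casc.masks["tstatFC_T2LL"]
                comp_sign_t2[sig2] = np.sign(t2.t[sig2]).astype(np.int8)
            ms3 = casc.statmaps.get("tstatFC_T2LL_MSSS")
            if ms3 is not None:
                sig3 = casc.masks["tstatFC_T2LL_MSSS"]
                comp_sign_ms[sig3] = np.sign(ms3.t[sig3]).astype(np.int8)
        comp_labels = classify_scenarios(
            comp_sign_fc, comp_sign_t2, comp_sign_ms,
            methods_convention=params.methods_convention,
        )
        labels_grid = _merge_labels(labels_grid, comp_labels.labels)

        if params.subgroup_contrasts and ms_design["subgroup"].nunique() > 1:
            short = (ms_design["subgroup"] == "MS_short").to_numpy(float)
            spos, sneg = group_contrast_stats(
                ms_pe, ms_design, params, comp_mask, comp, stage_seed(seed, 100 + j),
                short, (SUBGROUP_POS, SUBGROUP_NEG),
            )
            subgroup_stats[(comp, SUBGROUP_POS)] = spos
            subgroup_stats[(comp, SUBGROUP_NEG)] = sneg

    gfc_table = rank_networks(all_stats, atlas, alpha=params.alpha)
    if subgroup_stats:
        gfc_table = pd.concat(
            [gfc_table, rank_networks(list(subgroup_stats.values()), atlas,
                                      alpha=params.alpha)],
            ignore_index=True,
        )

    pearson = (
        pd.concat([c.pearson for c in cascades if c.pearson is not None],
                  ignore_index=True)
        if cascades else pd.DataFrame()
    )
    if len(pearson):
        m = len(pearson)
        pearson["m_tests"] = m
        pearson["p_bonferroni"] = np.minimum(1.0, m * pearson["p_two_sided"])

    scenario_map = ScenarioLabelMap(labels=labels_grid)
    query_masks = {}
    for con in (SUBGROUP_POS, SUBGROUP_NEG):
        stats_c = [s for (c, cn), s in subgroup_stats.items() if cn == con]
        if stats_c:
            union = np.zeros(mask.shape, dtype=bool)
            for s in stats_c:
                union |= s.sig_mask(params.alpha_strict)
            query_masks[con] = union
    report = scenario_report(scenario_map, network_maps=atlas, query_masks=query_masks)

    return AnalysisResult(
        design=design, ica=ica, subject_maps=subject_maps, fc_stats=fc_stats,
        subgroup_stats=subgroup_stats, atlas=atlas, gfc_table=gfc_table,
        cascades=cascades, pearson=pearson, scenario_map=scenario_map,
        report=report, estimated_order=order,
    )


# ---------------------------------------------------------------------------
# file-based runner


def _hash_config(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage_done(rundir: Path, stage: str, confhash: str) -> bool:
    marker = rundir / f"{stage}.done.json"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text())["hash"] == confhash
    except Exception:
        return False


def _mark_done(rundir: Path, stage: str, confhash: str, extra: dict | None = None):
    payload = {"stage": stage, "hash": confhash}
    payload.update(extra or {})
    (rundir / f"{stage}.done.json").write_text(json.dumps(payload, indent=2))


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    return dict(config)


def _cohort_config(cfg: dict) -> CohortConfig:
    sim = dict(cfg.get("simulate", {}))
    fields = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(sim) - fields
    if unknown:
        raise ValueError(f"unknown simulate config keys: {sorted(unknown)}")
    cc = CohortConfig(**sim)
    cc.grid = tuple(cc.grid)
    return cc


def _analysis_params(cfg: dict) -> AnalysisParams:
    pdict = dict(cfg.get("analysis", {}))
    tfce = pdict.pop("tfce", None)
    fields = {f.name for f in dataclasses.fields(AnalysisParams)}
    unknown = set(pdict) - fields
    if unknown:
        raise ValueError(f"unknown analysis config keys: {sorted(unknown)}")
    params = AnalysisParams(**pdict)
    if tfce:
        params.tfce = TFCEParams(**tfce)
    if isinstance(params.covariates, list):
        params.covariates = tuple(params.covariates)
    return params


def run_pipeline(config, out_dir: str | Path | None = None) -> Path:
    """Execute the full pipeline from a config mapping or YAML file.

    The config has top-level keys ``simulate`` (cohort generation block),
    ``analysis`` (stage parameters), ``seed`` and ``out_dir``.  Returns the
    run directory.  Rerunning with an identical config and seed skips
    completed stages and reproduces identical outputs.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    rundir = Path(out_dir or cfg.get("out_dir", "fcmech_run"))
    rundir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(rundir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("fcmech")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_pipeline_inner(cfg, seed, rundir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_pipeline_inner(cfg: dict, seed: int, rundir: Path) -> Path:
    cohort_cfg = _cohort_config(cfg)
    params = _analysis_params(cfg)
    if params.n_perm <= 100:
        log.warning(
            "n_perm=%d limits attainable FWE p to >= %.4f",
            params.n_perm, 1.0 / (params.n_perm + 1),
        )
    (rundir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    # --- simulate -----------------------------------------------------
    sim_hash = _hash_config({"simulate": dataclasses.asdict(cohort_cfg), "seed": seed})
    simdir = rundir / "simulate"
    if not _stage_done(rundir, "simulate", sim_hash):
        log.info("stage simulate: generating %d subjects", cohort_cfg.n_subjects)
        simdir.mkdir(exist_ok=True)
        volumes, design, truth = simulate_cohort(cohort_cfg, seed)
        fio.save_design(design, simdir / "design.tsv")
        for vol, sid in zip(volumes, design["subject_id"]):
            fio.save_volume(vol, simdir / f"{sid}_bold.nii.gz")
        fio.save_scenario_map(
            truth.scenario_map, volumes[0].affine, simdir / "truth_scenarios.nii.gz"
        )
        truth.couplings.to_csv(simdir / "truth_couplings.tsv", sep="\t", index=False)
        tmpl_flat = np.stack([t.map[volumes[0].mask] for t in truth.templates])
        fio.save_map_stack(
            tmpl_flat, volumes[0].mask, volumes[0].affine, simdir / "templates.nii.gz"
        )
        (simdir / "templates.json").write_text(
            json.dumps({"names": [t.name for t in truth.templates]}, indent=2)
        )
        _mark_done(rundir, "simulate", sim_hash, {"n_subjects": cohort_cfg.n_subjects})
    else:
        log.info("stage simulate: up to date, skipping")
        design = fio.load_design(simdir / "design.tsv")
        volumes = [
            fio.load_volume(simdir / f"{sid}_bold.nii.gz") for sid in design["subject_id"]
        ]
        truth = None

    if truth is not None:
        templates = truth.templates
    else:
        names = json.loads((simdir / "templates.json").read_text())["names"]
        flat = fio.load_map_stack(simdir / "templates.nii.gz", volumes[0].mask)
        templates = []
        for n, f in zip(names, flat):
            m = np.zeros(volumes[0].mask.shape)
            m[volumes[0].mask] = f
            peak = [tuple(int(c) for c in np.unravel_index(np.argmax(m), m.shape))]
            templates.append(NetworkTemplate(name=n, map=m, peak_coords=peak))

    # --- analysis (preprocess .. scenarios in memory, artifacts per stage)
    ana_hash = _hash_config(
        {"analysis": dataclasses.asdict(params), "seed": seed, "upstream": sim_hash}
    )
    if _stage_done(rundir, "analysis", ana_hash):
        log.info("stage analysis: up to date, skipping")
        return rundir

    result = analyze_cohort(volumes, design, templates, params, seed)
    affine = volumes[0].affine

    icadir = rundir / "ica"
    icadir.mkdir(exist_ok=True)
    fio.save_map_stack(result.ica.spatial_maps, result.ica.mask, affine,
                       icadir / "group_maps.nii.gz")
    pd.DataFrame(
        {
            "component": range(result.ica.order),
            "label": result.ica.labels,
            "power_low_ratio": result.ica.power_low_ratio,
        }
    ).to_csv(icadir / "labels.tsv", sep="\t", index=False)
    np.savetxt(icadir / "timecourses.tsv", result.ica.timecourses, delimiter="\t")

    drdir = rundir / "dualreg"
    drdir.mkdir(exist_ok=True)
    for sm, sid in zip(result.subject_maps, design["subject_id"]):
        fio.save_map_stack(sm.pe_maps, sm.mask, affine, drdir / f"{sid}_pe.nii.gz")
        fio.save_map_stack(sm.z_maps, sm.mask, affine, drdir / f"{sid}_z.nii.gz")

    infdir = rundir / "infer"
    infdir.mkdir(exist_ok=True)
    for (comp, con), stat in {**result.fc_stats, **result.subgroup_stats}.items():
        safe = con.replace(">", "_gt_").replace("<", "_lt_")
        fio.save_statmap(stat, infdir / f"{comp}_{safe}", affine)

    rankdir = rundir / "rank"
    rankdir.mkdir(exist_ok=True)
    result.gfc_table.to_csv(rankdir / "gfc.tsv", sep="\t", index=False)
    try:
        plot_gfc(result.gfc_table, str(rankdir / "gfc.png"))
    except Exception as err:  # plotting is best-effort
        log.warning("gfc plot failed: %s", err)

    cadir = rundir / "cascade"
    cadir.mkdir(exist_ok=True)
    for casc in result.cascades:
        safe = casc.contrast_name.replace(">", "_gt_").replace("<", "_lt_")
        for stage, stat in casc.statmaps.items():
            if stage == "tstatFC":
                continue
            fio.save_statmap(stat, cadir / f"{casc.component}_{safe}_{stage}", affine)
    result.pearson.to_csv(cadir / "pearson.tsv", sep="\t", index=False)

    scdir = rundir / "scenarios"
    scdir.mkdir(exist_ok=True)
    fio.save_scenario_map(result.scenario_map, affine, scdir / "scenario_map.nii.gz")
    result.report["presence"].to_csv(scdir / "presence.tsv", sep="\t", index=False)
    result.report["overlap"].to_csv(scdir / "overlap.tsv", sep="\t", index=False)
    lines = ["Scenario support:"]
    for _, row in result.report["presence"].iterrows():
        lines.append(
            f"  {row['scenario']:>2} {row['mechanism']:<35} "
            f"{'present' if row['present'] else 'absent':>8} ({row['n_voxels']} voxels)"
        )
    (scdir / "report.txt").write_text("\n".join(lines) + "\n")

    provenance = {
        "seed": seed,
        "estimated_order": result.estimated_order,
        "n_perm": params.n_perm,
        "alpha": params.alpha,
        "stages": ["simulate", "analysis"],
    }
    (rundir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    _mark_done(rundir, "analysis", ana_hash, {"order": result.estimated_order})
    return rundir
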