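"""Synthetic resting-state cohorts with planted ground truth.

Generates desk-scale two-group cohorts (healthy controls vs relapsing
remitting MS) of network-structured 4D BOLD-like time series.  Each network
is a smooth Gaussian spatial template driven by a band-limited (0.01-0.1 Hz)
time course; per-subject network coupling carries the planted effects:

* a group FC shift (``fc_effect``) inside compact scenario regions,
* a linear dependence on T2 lesion load (``t2ll_slope``, per mL) and on the
  MS severity score (``msss_slope``, per unit), centered at the configured
  population means so the group-mean shift equals ``fc_effect`` exactly.

Every cohort is reproducible from ``(config, seed)`` and ships a
:class:`~fcmech.containers.GroundTruth` with the scenario label map and the
true per-subject couplings, so downstream inference can be validated in a
closed loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    SCENARIO_CODES,
    SCENARIO_SIGNS,
    GroundTruth,
    NetworkTemplate,
    ScenarioLabelMap,
    ScenarioRegionSpec,
    Volume4D,
    validate_design,
)

__all__ = [
    "CohortConfig",
    "ScenarioEffect",
    "make_rsn_templates",
    "bandlimited_timecourse",
    "simulate_subject",
    "simulate_cohort",
    "default_scenario_effects",
    "t2ll_distribution_sd",
    "jitter_for_target_correlation",
]

#: RSN names assigned to generated templates, in order.
RSN_NAMES = [
    "DMNa", "PNsup", "SMNm1", "MVN", "LVN", "ECN", "TPN", "CBLN",
    "PN", "AN", "SN", "FCN", "LNa", "LNp", "LVAN", "RVAN", "DMN", "SMNs2",
]

_HALF_MAX_RADIUS = np.sqrt(2.0 * np.log(2.0))  # radius of the 0.5 level set, in sigmas


class PlacementError(ValueError):
    """Raised when a grid is too small to place non-overlapping templates."""


def make_rsn_templates(
    grid_dims: tuple,
    n_networks: int,
    seed: int,
    sigma_vox: float | None = None,
    max_tries: int = 5000,
) -> list[NetworkTemplate]:
    """Place ``n_networks`` smooth Gaussian blobs at distinct centers.

    Each template is ``exp(-r^2 / (2 sigma^2))`` around its center, so the
    maximum weight is exactly 1.  Centers are drawn (deterministically from
    ``seed``) with enough separation that the suprathreshold (>0.5) masks of
    distinct networks are disjoint.
    """
    grid_dims = tuple(int(g) for g in grid_dims)
    if n_networks < 2:
        raise ValueError("need at least two networks")
    if any(g < 8 for g in grid_dims):
        bad = "xyz"[min(range(3), key=lambda i: grid_dims[i])]
        raise PlacementError(f"grid dimension {bad} too small (each must be >= 8)")
    if sigma_vox is None:
        sigma_vox = max(1.2, min(grid_dims) / 7.0)
    rng = np.random.default_rng(seed)
    margin = _HALF_MAX_RADIUS * sigma_vox + 1.0
    min_sep = 2.0 * _HALF_MAX_RADIUS * sigma_vox + 1.5
    if any(g - 1 - margin <= margin for g in grid_dims):
        bad = "xyz"[int(np.argmin(grid_dims))]
        raise PlacementError(
            f"grid dimension {bad} ({min(grid_dims)} voxels) too small for "
            f"sigma={sigma_vox:.2f} templates"
        )
    centers: list[np.ndarray] = []
    # rejection sampling with full restarts: an unlucky early center can
    # make the remaining placements infeasible
    for _ in range(max(1, max_tries // 50)):
        centers = []
        for _ in range(50 * n_networks):
            if len(centers) == n_networks:
                break
            cand = np.array([rng.uniform(margin, g - 1 - margin) for g in grid_dims])
            if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
                centers.append(cand)
        if len(centers) == n_networks:
            break
    if len(centers) < n_networks:
        bad = "xyz"[int(np.argmin(grid_dims))]
        raise PlacementError(
            f"could not place {n_networks} separated templates; smallest grid "
            f"dimension is {bad} ({min(grid_dims)} voxels)"
        )
    grids = np.meshgrid(*[np.arange(g, dtype=float) for g in grid_dims], indexing="ij")
    templates = []
    for k, center in enumerate(centers):
        r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        w = np.exp(-r2 / (2.0 * sigma_vox**2))
        w[w < 1e-8] = 0.0
        w /= w.max()  # guarantee an exact 1 at the peak voxel
        name = RSN_NAMES[k % len(RSN_NAMES)] if k < len(RSN_NAMES) else f"RSN{k}"
        peak = [tuple(int(round(c)) for c in center)]
        templates.append(NetworkTemplate(name=name, map=w, peak_coords=peak))
    return templates


def bandlimited_timecourse(
    T: int, tr: float, rng: np.random.Generator, band: tuple = (0.01, 0.1)
) -> np.ndarray:
    """White noise band-pass filtered to ``band`` (Hz), zero mean, unit sd."""
    freqs = np.fft.rfftfreq(T, d=tr)
    spec = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():  # degenerate short series: keep the lowest non-DC bin
        keep = np.zeros_like(keep)
        keep[1] = True
    spec[~keep] = 0.0
    x = np.fft.irfft(spec, n=T)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _subject_couplings(
    row: pd.Series,
    templates: list[NetworkTemplate],
    scenarios: list[ScenarioRegionSpec],
    rng: np.random.Generator,
    baseline: float,
    network_jitter_sd: float,
    coupling_jitter_sd: float,
    t2ll_center: float,
    msss_center: float,
) -> tuple[np.ndarray, dict]:
    """Per-network baseline couplings and per-region effective couplings.

    Returns ``(base_k, region_coupling)`` where ``base_k[k]`` is the
    subject's coupling for network ``k`` outside scenario regions and
    ``region_coupling[scenario_id]`` the coupling inside each region.
    Region couplings equal the baseline for HC subjects.
    """
    base = baseline + network_jitter_sd * rng.standard_normal(len(templates))
    region = []
    is_ms = row["group"] == "MS"
    for spec in scenarios:
        k = _template_index(templates, spec)
        c = base[k]
        if is_ms:
            if pd.isna(row["t2ll"]) or pd.isna(row["msss"]):
                raise ValueError(
                    f"MS subject {row['subject_id']} missing t2ll/msss metadata"
                )
            c = (
                c
                + spec.fc_effect
                + spec.t2ll_slope * (row["t2ll"] - t2ll_center)
                + spec.msss_slope * (row["msss"] - msss_center)
            )
            if coupling_jitter_sd > 0:
                c += coupling_jitter_sd * rng.standard_normal()
        region.append(c)
    return base, region


def _template_index(templates: list[NetworkTemplate], spec: ScenarioRegionSpec) -> int:
    if spec.network:
        for k, t in enumerate(templates):
            if t.name == spec.network:
                return k
        raise ValueError(f"scenario {spec.scenario_id}: unknown network {spec.network!r}")
    # fall back to the template whose suprathreshold extent contains the region
    hits = [
        k for k, t in enumerate(templates) if (spec.region_mask & t.suprathreshold()).any()
    ]
    if len(hits) != 1:
        raise ValueError(
            f"scenario {spec.scenario_id}: region must lie inside exactly one "
            f"template (found {len(hits)})"
        )
    return hits[0]


def _validate_region(spec: ScenarioRegionSpec, templates: list[NetworkTemplate]) -> None:
    k = _template_index(templates, spec)
    inside = templates[k].suprathreshold()
    if not spec.region_mask[~inside].sum() == 0:
        raise ValueError(
            f"scenario {spec.scenario_id}: region extends outside the "
            f"suprathreshold extent of network {templates[k].name}"
        )
    for j, t in enumerate(templates):
        if j != k and (spec.region_mask & t.suprathreshold()).any():
            raise ValueError(
                f"scenario {spec.scenario_id}: region overlaps two templates "
                f"({templates[k].name} and {t.name})"
            )


def default_affine(voxel_mm: tuple = (3.75, 3.75, 4.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_mm
    return aff


def simulate_subject(
    templates: list[NetworkTemplate],
    design_row: pd.Series,
    scenarios: list[ScenarioRegionSpec],
    T: int,
    TR: float,
    noise_sd: float,
    seed: int,
    baseline: float = 1.0,
    network_jitter_sd: float = 0.0,
    coupling_jitter_sd: float = 0.0,
    t2ll_center: float = 0.0,
    msss_center: float = 0.0,
    voxel_mm: tuple = (3.75, 3.75, 4.0),
) -> Volume4D:
    """Render one subject's 4D volume from templates, couplings and noise.

    Each voxel's series is ``sum_k c_k(voxel) * w_k(voxel) * s_k(t)`` plus
    Gaussian noise, with ``s_k`` band-limited to 0.01-0.1 Hz.
    """
    if T < 40:
        raise ValueError("need at least 40 timepoints")
    if TR <= 0:
        raise ValueError("TR must be positive")
    rng = np.random.default_rng(seed)
    shape = templates[0].map.shape
    base, region_c = _subject_couplings(
        design_row, templates, scenarios, rng, baseline,
        network_jitter_sd, coupling_jitter_sd, t2ll_center, msss_center,
    )
    data = np.zeros(shape + (T,))
    for k, tmpl in enumerate(templates):
        c_map = np.full(shape, base[k])
        for i, spec in enumerate(scenarios):
            if _template_index(templates, spec) == k:
                c_map[spec.region_mask] = region_c[i]
        s = bandlimited_timecourse(T, TR, rng)
        data += (c_map * tmpl.map)[..., None] * s
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal(data.shape)
    mask = np.ones(shape, dtype=bool)
    return Volume4D(data=data, affine=default_affine(voxel_mm), tr=TR, mask=mask)


@dataclass
class ScenarioEffect:
    """Effect sizes for one planted scenario region (before geometry)."""

    scenario_id: str
    network: str
    fc_effect: float
    t2ll_slope: float
    msss_slope: float


#: default planted effect magnitudes.  The FC shift is a 60% change of the
#: baseline coupling (reduced FC attenuates the network signal without
#: inverting it); the covariate slopes put the lesion-load and severity
#: contributions (sd ~0.4 coupling units each across the cohort) on the
#: same footing as the group shift.
DEFAULT_FC_EFFECT = 0.6
DEFAULT_T2LL_SLOPE = 0.025
DEFAULT_MSSS_SLOPE = 0.25


def default_scenario_effects(networks: list[str]) -> list[ScenarioEffect]:
    """Default planted mechanisms: the four scenario classes the default
    cohort exhibits, one per network."""
    ids = ["1", "2", "3b", "4b"]
    effects = []
    for sid, net in zip(ids, networks):
        fc, t2, ms = SCENARIO_SIGNS[sid]
        effects.append(
            ScenarioEffect(
                scenario_id=sid,
                network=net,
                fc_effect=DEFAULT_FC_EFFECT * fc,
                t2ll_slope=DEFAULT_T2LL_SLOPE * t2,
                msss_slope=DEFAULT_MSSS_SLOPE * ms,
            )
        )
    return effects


def all_scenario_effects(networks: list[str]) -> list[ScenarioEffect]:
    """One region per scenario class (requires >= 6 networks)."""
    ids = list(SCENARIO_CODES)
    if len(networks) < len(ids):
        raise ValueError("need at least six networks to plant all six scenarios")
    return [
        ScenarioEffect(sid, net, DEFAULT_FC_EFFECT * SCENARIO_SIGNS[sid][0],
                       DEFAULT_T2LL_SLOPE * SCENARIO_SIGNS[sid][1],
                       DEFAULT_MSSS_SLOPE * SCENARIO_SIGNS[sid][2])
        for sid, net in zip(ids, networks)
    ]


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the emulated study: 29 HC and 62 MS subjects (36 with
    short and 26 with long disease duration), TR 2.5 s, lesion load
    lognormal with mean near 16.63 mL, MSSS uniform on 0-6.
    """

    n_hc: int = 29
    n_ms_short: int = 36
    n_ms_long: int = 26
    grid: tuple = (20, 20, 12)
    T: int = 120
    tr: float = 2.5
    voxel_mm: tuple = (3.75, 3.75, 4.0)
    n_networks: int = 4
    template_sigma_vox: float | None = None
    region_radius_vox: float = 2.0
    noise_sd: float = 0.4
    baseline_coupling: float = 1.0
    network_jitter_sd: float = 0.05
    coupling_jitter_sd: float = 0.1
    scenario_effects: list = None  # None -> default_scenario_effects
    # covariate distributions (means/sds follow the emulated cohort table)
    age_hc: tuple = (34.45, 10.17)
    age_ms: tuple = (38.58, 8.25)
    p_female_hc: float = 21 / 29
    p_female_ms: float = 47 / 62
    education: tuple = (13.2, 2.4)
    gm_ratio: tuple = (0.45, 0.03)
    t2ll_mean: float = 16.63
    t2ll_sd: float = 22.23
    t2ll_cap: float = 80.0
    msss_range: tuple = (0.0, 6.0)
    duration_short: tuple = (0.5, 5.0)
    duration_long: tuple = (5.0, 15.0)

    @property
    def n_ms(self) -> int:
        return self.n_ms_short + self.n_ms_long

    @property
    def n_subjects(self) -> int:
        return self.n_hc + self.n_ms


def _lognormal_params(mean: float, sd: float) -> tuple:
    s2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    return mu, np.sqrt(s2)


def _draw_t2ll(rng: np.random.Generator, n: int, cfg: CohortConfig) -> np.ndarray:
    mu, sig = _lognormal_params(cfg.t2ll_mean, cfg.t2ll_sd)
    out = rng.lognormal(mu, sig, size=n)
    for _ in range(100):
        over = out > cfg.t2ll_cap
        if not over.any():
            break
        out[over] = rng.lognormal(mu, sig, size=int(over.sum()))
    return np.minimum(out, cfg.t2ll_cap)


def t2ll_distribution_sd(cfg: CohortConfig) -> float:
    """Analytic sd of the capped lognormal lesion-load distribution."""
    mu, sig = _lognormal_params(cfg.t2ll_mean, cfg.t2ll_sd)
    dist = stats.lognorm(s=sig, scale=np.exp(mu))
    b = dist.cdf(cfg.t2ll_cap)
    # moments of the truncated-at-cap distribution via numerical integration
    from scipy.integrate import quad

    m1 = quad(lambda x: x * dist.pdf(x), 0, cfg.t2ll_cap)[0] / b
    m2 = quad(lambda x: x * x * dist.pdf(x), 0, cfg.t2ll_cap)[0] / b
    return float(np.sqrt(m2 - m1**2))


def jitter_for_target_correlation(slope: float, target_r: float, cov_sd: float) -> float:
    """Coupling-jitter sd so that corr(coupling, covariate) ~= target_r.

    With coupling = slope * covariate + jitter, r = slope*sd_cov /
    sqrt(slope^2 sd_cov^2 + jitter^2); invert for jitter.
    """
    if not 0 < abs(target_r) < 1:
        raise ValueError("target_r must lie strictly between 0 and 1 in magnitude")
    signal = abs(slope) * cov_sd
    return signal * np.sqrt(1.0 / target_r**2 - 1.0)


def draw_design(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Draw the cohort design table (covariates only, no imaging)."""
    rng = np.random.default_rng(seed)
    rows = []
    groups = (
        [("HC", "none")] * config.n_hc
        + [("MS", "MS_short")] * config.n_ms_short
        + [("MS", "MS_long")] * config.n_ms_long
    )
    t2ll = _draw_t2ll(rng, config.n_ms, config)
    i_ms = 0
    for i, (grp, sub) in enumerate(groups):
        age_mu, age_sd = config.age_hc if grp == "HC" else config.age_ms
        p_f = config.p_female_hc if grp == "HC" else config.p_female_ms
        row = {
            "subject_id": f"sub-{i:03d}",
            "group": grp,
            "subgroup": sub,
            "age": float(np.clip(rng.normal(age_mu, age_sd), 18, 75)),
            "gender": "F" if rng.random() < p_f else "M",
            "education": float(np.clip(rng.normal(*config.education), 6, 22)),
            "gm_ratio": float(np.clip(rng.normal(*config.gm_ratio), 0.3, 0.6)),
            "t2ll": np.nan,
            "msss": np.nan,
            "disease_duration": np.nan,
        }
        if grp == "MS":
            row["t2ll"] = float(t2ll[i_ms])
            row["msss"] = float(rng.uniform(*config.msss_range))
            lo, hi = config.duration_short if sub == "MS_short" else config.duration_long
            # open lower bound for MS_long (duration strictly greater than 5)
            row["disease_duration"] = float(rng.uniform(lo + 1e-6, hi))
            i_ms += 1
        rows.append(row)
    return validate_design(pd.DataFrame(rows))


def build_scenario_regions(
    templates: list[NetworkTemplate],
    effects: list[ScenarioEffect],
    radius_vox: float,
) -> list[ScenarioRegionSpec]:
    """Materialize spherical region masks at each target network's peak."""
    shape = templates[0].map.shape
    grids = np.meshgrid(*[np.arange(g, dtype=float) for g in shape], indexing="ij")
    specs = []
    for eff in effects:
        k = next((i for i, t in enumerate(templates) if t.name == eff.network), None)
        if k is None:
            raise ValueError(f"scenario {eff.scenario_id}: unknown network {eff.network!r}")
        center = templates[k].peak_coords[0]
        r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        # clip to the template's half-max extent so the region stays inside
        mask = (r2 <= radius_vox**2) & (templates[k].map > 0.5 + 1e-9)
        spec = ScenarioRegionSpec(
            scenario_id=eff.scenario_id,
            region_mask=mask,
            fc_effect=eff.fc_effect,
            t2ll_slope=eff.t2ll_slope,
            msss_slope=eff.msss_slope,
            network=eff.network,
        )
        _validate_region(spec, templates)
        specs.append(spec)
    return specs


def simulate_cohort(
    config: CohortConfig, seed: int, make_volumes: bool = True
) -> tuple[list, pd.DataFrame, GroundTruth]:
    """Generate a full cohort: volumes, design table and ground truth.

    With ``make_volumes=False`` only the design and truth couplings are
    produced (cheap; used for calibration studies over many seeds).
    """
    rng = np.random.default_rng(seed)
    seed_templates = int(rng.integers(2**31))
    seed_design = int(rng.integers(2**31))
    subject_seeds = rng.integers(2**31, size=config.n_subjects)

    templates = make_rsn_templates(
        config.grid, config.n_networks, seed_templates, sigma_vox=config.template_sigma_vox
    )
    names = [t.name for t in templates]
    effects = (
        default_scenario_effects(names)
        if config.scenario_effects is None
        else config.scenario_effects
    )
    scenarios = build_scenario_regions(templates, effects, config.region_radius_vox)
    design = draw_design(config, seed_design)

    labels = np.zeros(config.grid, dtype=np.int32)
    for spec in scenarios:
        labels[spec.region_mask] = spec.code
    scenario_map = ScenarioLabelMap(labels=labels)

    t2ll_center = float(design["t2ll"].mean())
    msss_center = float(design["msss"].mean())

    volumes = []
    coupling_rows = []
    for i, (_, row) in enumerate(design.iterrows()):
        sub_seed = int(subject_seeds[i])
        # couplings recorded with the same rng stream the renderer uses
        crng = np.random.default_rng(sub_seed)
        base, region_c = _subject_couplings(
            row, templates, scenarios, crng, config.baseline_coupling,
            config.network_jitter_sd, config.coupling_jitter_sd,
            t2ll_center, msss_center,
        )
        rec = {"subject_id": row["subject_id"]}
        rec.update({f"base_{n}": b for n, b in zip(names, base)})
        rec.update(
            {
                f"region{i}_{spec.scenario_id}_{spec.network}": c
                for i, (spec, c) in enumerate(zip(scenarios, region_c))
            }
        )
        coupling_rows.append(rec)
        if make_volumes:
            volumes.append(
                simulate_subject(
                    templates, row, scenarios, config.T, config.tr,
                    config.noise_sd, sub_seed,
                    baseline=config.baseline_coupling,
                    network_jitter_sd=config.network_jitter_sd,
                    coupling_jitter_sd=config.coupling_jitter_sd,
                    t2ll_center=t2ll_center, msss_center=msss_center,
                    voxel_mm=config.voxel_mm,
                )
            )
    couplings = pd.DataFrame(coupling_rows)
    truth = GroundTruth(
        scenario_map=scenario_map,
        couplings=couplings,
        templates=templates,
        region_specs=scenarios,
    )
    return volumes, design, truth
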