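"""Core in-memory containers shared across the pipeline.

The containers are deliberately thin: plain :class:`dataclasses.dataclass`
wrappers around numpy arrays plus the minimal metadata (affine, TR, masks,
stage tags) the analysis stages need to talk to each other.  Tabular data
(cohort designs, gFC tables, Pearson tables) lives in pandas DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SCENARIO_CODES",
    "SCENARIO_NAMES",
    "SCENARIO_SIGNS",
    "Volume4D",
    "NetworkTemplate",
    "ScenarioRegionSpec",
    "GroundTruth",
    "GroupICAResult",
    "SubjectMaps",
    "StatMap",
    "ScenarioLabelMap",
    "validate_design",
]

#: scenario id -> integer code used in label maps
SCENARIO_CODES = {"1": 1, "2": 2, "3a": 31, "3b": 32, "4a": 41, "4b": 42}

#: integer code -> mechanism name
SCENARIO_NAMES = {
    1: "FC reduction driven by lesions",
    2: "True functional compensation",
    31: "Functional compensation attempt",
    32: "False functional compensation",
    41: "Neurodegeneration",
    42: "Pre-symptomatic condition",
}

#: scenario id -> required signs of (group FC change, FC~T2LL assoc, FC~MSSS assoc).
#: A 0 means the MSSS stage is not part of the scenario's definition.
SCENARIO_SIGNS = {
    "1": (-1, -1, 0),
    "2": (+1, -1, 0),
    "3a": (+1, +1, -1),
    "3b": (+1, +1, +1),
    "4a": (-1, +1, -1),
    "4b": (-1, +1, +1),
}

#: columns of a cohort design table
DESIGN_COLUMNS = [
    "subject_id",
    "group",
    "subgroup",
    "age",
    "gender",
    "education",
    "gm_ratio",
    "t2ll",
    "msss",
    "disease_duration",
]


@dataclass
class Volume4D:
    """One subject's 4D BOLD grid.

    Parameters
    ----------
    data
        ``(X, Y, Z, T)`` float array.
    affine
        4x4 voxel-to-world transform (RAS).
    tr
        Repetition time in seconds.
    mask
        ``(X, Y, Z)`` boolean brain mask.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float
    mask: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-dimensional (X, Y, Z, T)")
        if self.data.shape[3] < 2:
            raise ValueError("need at least two timepoints")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial dims")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not np.isfinite(self.data[self.mask]).all():
            raise ValueError("non-finite values inside the brain mask")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple:
        return self.data.shape[:3]

    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def timeseries(self) -> np.ndarray:
        """In-mask data as a ``(T, n_voxels)`` matrix (mask raveled in C order)."""
        return self.data[self.mask].T

    def with_data(self, data: np.ndarray) -> "Volume4D":
        return Volume4D(data=data, affine=self.affine.copy(), tr=self.tr, mask=self.mask.copy())


@dataclass
class NetworkTemplate:
    """Spatial pattern of one resting-state network: a smooth non-negative
    weight map peaking at 1."""

    name: str
    map: np.ndarray
    peak_coords: list

    def __post_init__(self):
        self.map = np.asarray(self.map, dtype=float)
        if self.map.min() < 0 or self.map.max() > 1 + 1e-12:
            raise ValueError("template weights must lie in [0, 1]")

    def suprathreshold(self, threshold: float = 0.5) -> np.ndarray:
        return self.map > threshold


@dataclass
class ScenarioRegionSpec:
    """A compact region planted with a mechanism-scenario effect.

    ``fc_effect`` is the MS-vs-HC coupling shift; ``t2ll_slope`` and
    ``msss_slope`` are coupling change per mL of lesion load and per MSSS
    unit.  Signs must jointly satisfy the scenario's row in
    :data:`SCENARIO_SIGNS`.
    """

    scenario_id: str
    region_mask: np.ndarray
    fc_effect: float
    t2ll_slope: float
    msss_slope: float
    network: str = ""

    def __post_init__(self):
        if self.scenario_id not in SCENARIO_CODES:
            raise ValueError(f"unknown scenario id {self.scenario_id!r}")
        self.region_mask = np.asarray(self.region_mask, dtype=bool)
        self.validate_signs()

    def validate_signs(self):
        want_fc, want_t2, want_ms = SCENARIO_SIGNS[self.scenario_id]
        checks = [
            ("fc_effect", self.fc_effect, want_fc),
            ("t2ll_slope", self.t2ll_slope, want_t2),
            ("msss_slope", self.msss_slope, want_ms),
        ]
        for name, value, want in checks:
            if want == 0 or value == 0:  # zero = no effect planted (null cohorts)
                continue
            if np.sign(value) != want:
                raise ValueError(
                    f"scenario {self.scenario_id}: {name}={value} must have sign {want:+d}"
                )

    @property
    def code(self) -> int:
        return SCENARIO_CODES[self.scenario_id]


@dataclass
class ScenarioLabelMap:
    """Voxelwise categorical map over the six mechanism scenarios."""

    labels: np.ndarray
    legend: dict = field(default_factory=lambda: dict(SCENARIO_NAMES))

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int32)
        bad = set(np.unique(self.labels)) - ({0} | set(self.legend))
        if bad:
            raise ValueError(f"labels contain codes outside the legend: {sorted(bad)}")

    def support(self, code: int) -> np.ndarray:
        return self.labels == code

    def present_codes(self) -> list:
        return sorted(c for c in np.unique(self.labels) if c != 0)


@dataclass
class GroundTruth:
    """Planted truth emitted next to a synthetic cohort."""

    scenario_map: ScenarioLabelMap
    couplings: pd.DataFrame  # one row per subject, one column per region/network
    templates: list
    region_specs: list = field(default_factory=list)


@dataclass
class GroupICAResult:
    """Group spatial ICA decomposition over the concatenated cohort."""

    spatial_maps: np.ndarray  # (order, n_mask_voxels), Z-scaled
    timecourses: np.ndarray  # (total_T, order)
    order: int
    mask: np.ndarray  # 3D boolean
    tr: float
    labels: list = field(default_factory=list)  # per-component RSN name or "artifact"
    power_low_ratio: np.ndarray | None = None
    subject_lengths: list = field(default_factory=list)

    def map_3d(self, k: int) -> np.ndarray:
        out = np.zeros(self.mask.shape)
        out[self.mask] = self.spatial_maps[k]
        return out

    def rsn_indices(self) -> list:
        return [i for i, lab in enumerate(self.labels) if lab != "artifact"]


@dataclass
class SubjectMaps:
    """Per-subject dual-regression outputs."""

    pe_maps: np.ndarray  # (order, n_mask_voxels)
    z_maps: np.ndarray  # (order, n_mask_voxels)
    timecourses: np.ndarray  # (T, order)
    mask: np.ndarray


@dataclass
class StatMap:
    """Voxelwise statistic map from one permutation analysis.

    ``t``, ``tfce`` and ``p_fwe`` are full 3D grids; values outside ``mask``
    are 0 for t/tfce and 1 for p_fwe.
    """

    stage: str  # tstatFC | tstatFC_T2LL | tstatFC_T2LL_MSSS
    component: str
    contrast_name: str
    t: np.ndarray
    tfce: np.ndarray
    p_fwe: np.ndarray
    mask: np.ndarray
    n_perm: int = 0
    seed: int | None = None
    exhaustive: bool = False

    def __post_init__(self):
        inside = self.p_fwe[self.mask]
        if inside.size and ((inside < 0).any() or (inside > 1).any()):
            raise ValueError("p_fwe must lie in [0, 1] inside the mask")

    def sig_mask(self, alpha: float = 0.05) -> np.ndarray:
        return self.mask & (self.p_fwe <= alpha)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort design table against the schema and its invariants."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    if not design["group"].isin(["HC", "MS"]).all():
        raise ValueError("group must be HC or MS")
    if not design["subgroup"].isin(["none", "MS_short", "MS_long"]).all():
        raise ValueError("subgroup must be none, MS_short or MS_long")
    hc = design["group"] == "HC"
    if (design.loc[hc, "subgroup"] != "none").any():
        raise ValueError("HC subjects cannot carry an MS subgroup")
    ms = design.loc[~hc]
    for col in ("t2ll", "msss", "disease_duration"):
        if ms[col].isna().any():
            raise ValueError(f"MS subject missing {col}")
    if (ms["t2ll"] < 0).any():
        raise ValueError("t2ll must be non-negative")
    short = ms["subgroup"] == "MS_short"
    if (ms.loc[short, "disease_duration"] > 5).any():
        raise ValueError("MS_short requires disease_duration <= 5 years")
    lng = ms["subgroup"] == "MS_long"
    dd = ms.loc[lng, "disease_duration"]
    if ((dd <= 5) | (dd > 15)).any():
        raise ValueError("MS_long requires 5 < disease_duration <= 15 years")
    gm = design["gm_ratio"]
    if ((gm <= 0) | (gm >= 1)).any():
        raise ValueError("gm_ratio must lie in (0, 1)")
    return design
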