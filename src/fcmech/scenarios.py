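"""Mechanism-scenario classification of cascade outputs.

Each voxel that survived the full cascade is classified by the sign
pattern of (group FC change, FC~T2LL association, FC~MSSS association)
into one of six mechanistic scenarios:

====  ====  =====  =====  =======================================
code  FC    T2LL   MSSS   mechanism
====  ====  =====  =====  =======================================
1     -     -             FC reduction driven by lesions
2     +     -             True functional compensation
3a    +     +      -      Functional compensation attempt
3b    +     +      +      False functional compensation
4a    -     +      -      Neurodegeneration
4b    -     +      +      Pre-symptomatic condition
====  ====  =====  =====  =======================================

Signs are of the voxel's covariate t statistic (positive t: FC increases
with the covariate; so scenario 1 is reduced FC whose residual FC
correlates negatively with lesion load, i.e. low FC goes with high T2LL).
Scenarios 1 and 2 are decided at the T2LL stage; 3a/3b/4a/4b additionally
require MSSS-stage significance.  An alternative reading of the 4a/4b
naming swaps those two labels; ``methods_convention=True`` applies it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import SCENARIO_CODES, SCENARIO_NAMES, ScenarioLabelMap

__all__ = ["classify_scenarios", "overlap_percent", "scenario_report"]


def classify_scenarios(
    fc_dir: np.ndarray,
    t2ll_sig_sign: np.ndarray,
    msss_sig_sign: np.ndarray,
    methods_convention: bool = False,
) -> ScenarioLabelMap:
    """Apply the scenario decision table to three per-voxel sign maps.

    ``fc_dir`` is -1/+1 on the FC-significant voxels of the originating
    contrast (0 elsewhere); ``t2ll_sig_sign`` and ``msss_sig_sign`` are
    -1/0/+1 maps of the covariate-stage significant signs, nonzero only
    inside the previous stage's significant set.
    """
    fc = np.asarray(fc_dir)
    t2 = np.asarray(t2ll_sig_sign)
    ms = np.asarray(msss_sig_sign)
    if not (fc.shape == t2.shape == ms.shape):
        raise ValueError("sign maps must share the grid")
    bad_t2 = int(((t2 != 0) & (fc == 0)).sum())
    if bad_t2:
        raise ValueError(
            f"{bad_t2} voxels have T2LL significance outside the FC-significant mask"
        )
    bad_ms = int(((ms != 0) & (t2 == 0)).sum())
    if bad_ms:
        raise ValueError(
            f"{bad_ms} voxels have MSSS significance outside the T2LL-significant mask"
        )
    labels = np.zeros(fc.shape, dtype=np.int32)
    labels[(fc == -1) & (t2 == -1)] = 1
    labels[(fc == +1) & (t2 == -1)] = 2
    labels[(fc == +1) & (t2 == +1) & (ms == -1)] = 31
    labels[(fc == +1) & (t2 == +1) & (ms == +1)] = 32
    labels[(fc == -1) & (t2 == +1) & (ms == -1)] = 41
    labels[(fc == -1) & (t2 == +1) & (ms == +1)] = 42
    if methods_convention:
        a, b = labels == 41, labels == 42
        labels[a], labels[b] = 42, 41
    return ScenarioLabelMap(labels=labels)


def overlap_percent(
    query_mask: np.ndarray, scenario_map: ScenarioLabelMap, code: int
) -> float:
    """Percentage of ``query_mask`` voxels carrying scenario ``code``."""
    if code not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario code {code}")
    query_mask = np.asarray(query_mask, dtype=bool)
    if query_mask.shape != scenario_map.labels.shape:
        raise ValueError("query mask and scenario map must share the grid")
    n = int(query_mask.sum())
    if n == 0:
        warnings.warn("empty query mask; overlap defined as 0", stacklevel=2)
        return 0.0
    hit = int((scenario_map.labels[query_mask] == code).sum())
    return 100.0 * hit / n


def scenario_report(
    scenario_map: ScenarioLabelMap,
    network_maps: dict | None = None,
    query_masks: dict | None = None,
) -> dict:
    """Summarize scenario support: presence, per-network voxel counts and
    overlap percentages against any query masks (e.g. subgroup-difference
    significant sets).

    Returns ``{"presence": DataFrame, "overlap": DataFrame}``.
    """
    rows = []
    for sid, code in SCENARIO_CODES.items():
        support = scenario_map.support(code)
        row = {
            "scenario": sid,
            "mechanism": SCENARIO_NAMES[code],
            "present": bool(support.any()),
            "n_voxels": int(support.sum()),
        }
        if network_maps:
            for name, netmask in network_maps.items():
                row[f"n_{name}"] = int((support & netmask).sum())
        rows.append(row)
    presence = pd.DataFrame(rows)
    overlaps = []
    for qname, qmask in (query_masks or {}).items():
        for sid, code in SCENARIO_CODES.items():
            if not np.asarray(qmask, dtype=bool).any():
                pct = 0.0
            else:
                pct = overlap_percent(qmask, scenario_map, code)
            overlaps.append(
                {
                    "query": qname,
                    "scenario": sid,
                    "mechanism": SCENARIO_NAMES[code],
                    "overlap_pct": pct,
                }
            )
    return {"presence": presence, "overlap": pd.DataFrame(overlaps)}
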