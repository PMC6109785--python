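"""NIfTI-1 / TSV / JSON serialization of the pipeline's artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import ScenarioLabelMap, StatMap, Volume4D, validate_design

__all__ = [
    "save_volume",
    "load_volume",
    "save_map_stack",
    "load_map_stack",
    "save_design",
    "load_design",
    "save_statmap",
    "load_statmap",
    "save_scenario_map",
    "load_scenario_map",
]


def save_volume(vol: Volume4D, path: str | Path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(vol.data.astype(dtype), vol.affine)
    img.header.set_zooms((*vol.voxel_sizes(), vol.tr))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    mask_img = nib.Nifti1Image(vol.mask.astype(np.uint8), vol.affine)
    nib.save(mask_img, str(_mask_path(path)))


def _mask_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return p.with_name(name[: -len(suf)] + "_mask" + suf)
    return p.with_name(name + "_mask.nii")


def load_volume(path: str | Path) -> Volume4D:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    mask_file = _mask_path(path)
    if mask_file.exists():
        mask = np.asarray(nib.load(str(mask_file)).dataobj) > 0
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return Volume4D(data=data, affine=img.affine, tr=tr, mask=mask)


def save_map_stack(maps: np.ndarray, mask: np.ndarray, affine: np.ndarray,
                   path: str | Path) -> None:
    """Stack of flat maps (k x n_mask_voxels) as a 4D NIfTI (k on dim 4)."""
    out = np.zeros(mask.shape + (maps.shape[0],), dtype=np.float32)
    for k in range(maps.shape[0]):
        vol = np.zeros(mask.shape, dtype=np.float32)
        vol[mask] = maps[k]
        out[..., k] = vol
    nib.save(nib.Nifti1Image(out, affine), str(path))


def load_map_stack(path: str | Path, mask: np.ndarray) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return np.stack([data[..., k][mask] for k in range(data.shape[-1])])


def save_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def load_design(path: str | Path) -> pd.DataFrame:
    return validate_design(pd.read_csv(path, sep="\t"))


def save_statmap(stat: StatMap, prefix: str | Path, affine: np.ndarray) -> None:
    """t / tfce / p_fwe triplet plus a JSON sidecar."""
    prefix = Path(prefix)
    for name, arr in (("t", stat.t), ("tfce", stat.tfce), ("p_fwe", stat.p_fwe)):
        nib.save(
            nib.Nifti1Image(arr.astype(np.float32), affine),
            str(prefix.parent / f"{prefix.name}_{name}.nii.gz"),
        )
    nib.save(
        nib.Nifti1Image(stat.mask.astype(np.uint8), affine),
        str(prefix.parent / f"{prefix.name}_mask.nii.gz"),
    )
    sidecar = {
        "stage": stat.stage,
        "component": stat.component,
        "contrast": stat.contrast_name,
        "n_perm": stat.n_perm,
        "seed": stat.seed,
        "exhaustive": stat.exhaustive,
    }
    (prefix.parent / f"{prefix.name}.json").write_text(json.dumps(sidecar, indent=2))


def load_statmap(prefix: str | Path) -> StatMap:
    prefix = Path(prefix)
    meta = json.loads((prefix.parent / f"{prefix.name}.json").read_text())
    arrs = {}
    for name in ("t", "tfce", "p_fwe", "mask"):
        img = nib.load(str(prefix.parent / f"{prefix.name}_{name}.nii.gz"))
        arrs[name] = np.asarray(img.dataobj, dtype=float)
    return StatMap(
        stage=meta["stage"], component=meta["component"],
        contrast_name=meta["contrast"], t=arrs["t"], tfce=arrs["tfce"],
        p_fwe=arrs["p_fwe"], mask=arrs["mask"] > 0,
        n_perm=meta["n_perm"], seed=meta["seed"], exhaustive=meta["exhaustive"],
    )


def save_scenario_map(
    scen: ScenarioLabelMap, affine: np.ndarray, path: str | Path
) -> None:
    nib.save(nib.Nifti1Image(scen.labels.astype(np.int16), affine), str(path))
    legend = {str(k): v for k, v in scen.legend.items()}
    Path(str(path).split(".nii")[0] + "_legend.json").write_text(
        json.dumps(legend, indent=2)
    )


def load_scenario_map(path: str | Path) -> ScenarioLabelMap:
    labels = np.asarray(nib.load(str(path)).dataobj).astype(np.int32)
    legend_file = Path(str(path).split(".nii")[0] + "_legend.json")
    legend = {int(k): v for k, v in json.loads(legend_file.read_text()).items()}
    return ScenarioLabelMap(labels=labels, legend=legend)
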