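"""Persistence: NIfTI volumes, TSV tables, JSON sidecars.

Volumes are written as NIfTI-1 with a diagonal voxel-size affine.  Default is
uncompressed ``.nii`` so that repeated runs produce byte-identical files
(gzip embeds a timestamp); pass ``compress=True`` for ``.nii.gz``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import GridSpec
from .templates import AnalysisMask, NormativeTemplate

__all__ = [
    "save_volume", "load_volume", "save_template", "load_template",
    "save_mask", "load_mask", "write_json", "read_json",
    "write_records_tsv", "read_records_tsv",
]


def save_volume(volume: np.ndarray, grid: GridSpec, path: str | Path,
                *, compress: bool = False) -> Path:
    path = Path(path)
    if path.suffix not in (".nii", ".gz"):
        path = path.with_suffix(".nii.gz" if compress else ".nii")
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), grid.affine())
    img.header.set_zooms(grid.voxel_size)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, GridSpec(shape=data.shape, voxel_size=zooms)


def save_template(template: NormativeTemplate, grid: GridSpec, prefix: str | Path,
                  *, compress: bool = False) -> dict[str, Path]:
    """Write mean/sd NIfTI pair plus a JSON sidecar describing the stratum."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    suffix = ".nii.gz" if compress else ".nii"
    paths = {
        "mean": save_volume(template.mean_map, grid, Path(str(prefix) + "_mean" + suffix)),
        "sd": save_volume(template.sd_map, grid, Path(str(prefix) + "_sd" + suffix)),
        "json": Path(str(prefix) + ".json"),
    }
    write_json(paths["json"], {
        "sex": template.sex,
        "target_age": template.target_age,
        "window": template.window,
        "n_ref": template.n_ref,
    })
    return paths


def load_template(prefix: str | Path) -> NormativeTemplate:
    prefix = Path(prefix)
    meta = read_json(Path(str(prefix) + ".json"))
    suffix = ".nii" if Path(str(prefix) + "_mean.nii").exists() else ".nii.gz"
    mean, _ = load_volume(Path(str(prefix) + "_mean" + suffix))
    sd, _ = load_volume(Path(str(prefix) + "_sd" + suffix))
    return NormativeTemplate(mean_map=mean, sd_map=sd, sex=meta["sex"],
                             target_age=meta["target_age"], window=meta["window"],
                             n_ref=meta["n_ref"])


def save_mask(mask: AnalysisMask, grid: GridSpec, prefix: str | Path,
              *, compress: bool = False) -> dict[str, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    suffix = ".nii.gz" if compress else ".nii"
    paths = {
        "mask": save_volume(mask.mask.astype(np.float64), grid,
                            Path(str(prefix) + "_mask" + suffix)),
        "json": Path(str(prefix) + "_mask.json"),
    }
    write_json(paths["json"], {"n_voxels": mask.n_voxels,
                               "provenance": mask.provenance})
    return paths


def load_mask(prefix: str | Path) -> AnalysisMask:
    prefix = Path(prefix)
    suffix = ".nii" if Path(str(prefix) + "_mask.nii").exists() else ".nii.gz"
    data, _ = load_volume(Path(str(prefix) + "_mask" + suffix))
    meta = read_json(Path(str(prefix) + "_mask.json"))
    return AnalysisMask(mask=data > 0.5, provenance=meta.get("provenance", {}))


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_records_tsv(records, path: str | Path) -> Path:
    """Impact records as TSV: subject_id, condition_a, condition_b, rmse, status."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [{"subject_id": r.subject_id, "condition_a": r.condition_a,
          "condition_b": r.condition_b,
          "rmse": "" if r.rmse is None else repr(float(r.rmse)),
          "status": r.status}
         for r in records],
        columns=["subject_id", "condition_a", "condition_b", "rmse", "status"],
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_records_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"rmse": float})
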