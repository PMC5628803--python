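"""Readers and writers for the formats the pipeline touches.

NIfTI-1 (via nibabel) for images, TSV for tables (tab-separated, UTF-8,
'.' decimal, 'NA' for missing), YAML/JSON for configuration, JSON for run
manifests.  TR and voxel sizes ride in the NIfTI header pixdims.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, InvalidInputError
from .types import AlffMap, BoldSeries, MotionTrace, StatMap

NA_REP = "NA"


def write_nifti(
    path: str | Path,
    data: np.ndarray,
    voxel_size: tuple[float, float, float],
    tr: float | None = None,
    affine: np.ndarray | None = None,
) -> None:
    if affine is None:
        affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    zooms = list(voxel_size)
    if data.ndim == 4:
        zooms.append(tr if tr is not None else 1.0)
        img.header.set_xyzt_units("mm", "sec")
    img.header.set_zooms(zooms)
    img.to_filename(str(path))


def read_nifti_series(path: str | Path) -> BoldSeries:
    """Read a 4D NIfTI file as a BOLD series (TR from the time pixdim)."""
    img = _load(path)
    if img.ndim != 4:
        raise FormatError(f"{path}: expected a 4D series, got shape {img.shape}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    return BoldSeries(
        data=data,
        tr=tr,
        voxel_size=tuple(float(z) for z in zooms[:3]),
        affine=np.asarray(img.affine),
    )


def read_nifti_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D NIfTI file; returns (data, affine)."""
    img = _load(path)
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {img.shape}")
    return np.asarray(img.get_fdata(), dtype=np.float64), np.asarray(img.affine)


def read_mask(path: str | Path) -> np.ndarray:
    data, _ = read_nifti_volume(path)
    return data > 0.5


def _load(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    # unset slope/intercept are stored as nan and mean identity scaling;
    # infinities can only come from a corrupt header
    for field in ("scl_slope", "scl_inter"):
        value = float(img.header[field]) if field in img.header else 0.0
        if np.isinf(value):
            raise FormatError(f"{path}: infinite {field} in header")
    return img


def write_alff_map(path: str | Path, amap: AlffMap) -> None:
    write_nifti(path, amap.data, amap.voxel_size, affine=amap.affine)


def write_stat_map(path: str | Path, stat: StatMap) -> None:
    data = np.where(np.isfinite(stat.data), stat.data, 0.0)
    write_nifti(path, data, stat.voxel_size, affine=stat.affine)


def write_motion_tsv(path: str | Path, trace: MotionTrace) -> None:
    """6-column parameter TSV plus a 12-column affine TSV alongside."""
    path = Path(path)
    pd.DataFrame(trace.params, columns=["tx", "ty", "tz", "rx", "ry", "rz"]).to_csv(
        path, sep="\t", index=False, na_rep=NA_REP
    )
    aff = trace.affines[:, :3, :].reshape(len(trace.affines), 12)
    cols = [f"m{r}{c}" for r in range(3) for c in range(4)]
    pd.DataFrame(aff, columns=cols).to_csv(
        path.with_name(path.stem + "_affines.tsv"), sep="\t", index=False, na_rep=NA_REP
    )


def read_motion_tsv(path: str | Path) -> MotionTrace:
    """Read motion parameters; rebuild affines from the companion file
    when present, otherwise from the 6 parameters."""
    from .synthetic import rigid_affine

    path = Path(path)
    params = pd.read_csv(path, sep="\t").to_numpy(float)
    if params.shape[1] != 6:
        raise FormatError(f"{path}: expected 6 motion columns, got {params.shape[1]}")
    aff_path = path.with_name(path.stem + "_affines.tsv")
    if aff_path.exists():
        flat = pd.read_csv(aff_path, sep="\t").to_numpy(float)
        affines = np.tile(np.eye(4), (len(flat), 1, 1))
        affines[:, :3, :] = flat.reshape(len(flat), 3, 4)
    else:
        affines = np.stack([rigid_affine(p) for p in params])
    return MotionTrace(params=params, affines=affines)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t", na_values=[NA_REP])


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    table = read_table(path)
    required = {"subject_id", "group", "age", "wmh_count"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: cohort table missing columns {sorted(missing)}")
    if table["subject_id"].duplicated().any():
        raise InvalidInputError(f"{path}: duplicate subject ids")
    return table


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
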