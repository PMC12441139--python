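"""File formats and reproducibility plumbing.

Subject tables are TSV, images NIfTI (4-D gray-matter stack + 3-D mask,
float32 on disk, float64 in memory), reports CSV, configs YAML; every
written artifact gets a JSON provenance sidecar (config hash, package
version, seeds, timestamps, subject order).
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .datasets import VoxelDataset

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "subject_id",
    "cohort",
    "scanner_group",
    "age",
    "sex",
    "TIV",
    "diagnosis",
)
CTQ_COLUMNS = ("EA", "PA", "SA", "EN", "PN", "CTQ_SUM")
SEX_TOKENS = {"female", "male"}
DIAGNOSIS_TOKENS = {"HC", "MDD"}


class TableFormatError(ValueError):
    pass


def read_subject_table(path: str | Path, drop_missing_ctq: bool = True) -> pd.DataFrame:
    """Read and validate a subject TSV.

    Rows with missing CTQ data are dropped (the exclusion count is logged
    and stored in ``df.attrs['n_excluded_ctq']``), mirroring the exclusion
    of CTQ-incomplete participants.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS + CTQ_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")

    bad_sex = set(df["sex"].dropna().unique()) - SEX_TOKENS
    if bad_sex:
        raise TableFormatError(f"{path}: unknown sex tokens {sorted(bad_sex)}")
    bad_dx = set(df["diagnosis"].dropna().unique()) - DIAGNOSIS_TOKENS
    if bad_dx:
        raise TableFormatError(f"{path}: unknown diagnosis tokens {sorted(bad_dx)}")

    n_excluded = 0
    if drop_missing_ctq:
        complete = df[list(CTQ_COLUMNS)].notna().all(axis=1)
        n_excluded = int((~complete).sum())
        if n_excluded:
            logger.info(
                "%s: excluding %d rows with missing CTQ data", path, n_excluded
            )
        df = df[complete].reset_index(drop=True)

    bad_rows = df[list(REQUIRED_COLUMNS)].isna().any(axis=1)
    if bad_rows.any():
        lines = (df.index[bad_rows] + 2).tolist()  # 1-based + header
        raise TableFormatError(f"{path}: unparseable/missing values at lines {lines}")

    df.attrs["n_excluded_ctq"] = n_excluded
    return df


def write_subject_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def write_voxel_dataset(
    dataset: VoxelDataset, prefix: str | Path, provenance: dict | None = None
) -> dict[str, Path]:
    """Write a dataset as ``<prefix>_gm.nii.gz`` + mask + JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    data_path = prefix.with_name(prefix.name + "_gm.nii.gz")
    mask_path = prefix.with_name(prefix.name + "_mask.nii.gz")
    sidecar_path = prefix.with_name(prefix.name + "_gm.json")

    stack = dataset.to_4d().astype(np.float32)
    nib.save(nib.Nifti1Image(stack, dataset.affine), data_path)
    nib.save(
        nib.Nifti1Image(dataset.mask.astype(np.uint8), dataset.affine), mask_path
    )
    sidecar = {
        "subject_ids": list(dataset.subject_ids),
        "voxel_size": dataset.voxel_size,
        "meta": _jsonable(dataset.meta),
        "provenance": provenance or {},
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return {"data": data_path, "mask": mask_path, "sidecar": sidecar_path}


def read_voxel_dataset(prefix: str | Path) -> VoxelDataset:
    """Read a dataset written by :func:`write_voxel_dataset`."""
    prefix = Path(prefix)
    data_img = nib.load(prefix.with_name(prefix.name + "_gm.nii.gz"))
    mask_img = nib.load(prefix.with_name(prefix.name + "_mask.nii.gz"))
    mask = np.asarray(mask_img.dataobj).astype(bool)
    stack = np.asarray(data_img.dataobj, dtype=np.float64)
    if stack.shape[:3] != mask.shape:
        raise ValueError(
            f"data grid {stack.shape[:3]} does not match mask grid {mask.shape}"
        )
    sidecar = json.loads(
        prefix.with_name(prefix.name + "_gm.json").read_text()
    )
    return VoxelDataset(
        data=stack[mask, :].T,
        mask=mask,
        affine=data_img.affine,
        subject_ids=sidecar["subject_ids"],
        voxel_size=float(sidecar.get("voxel_size", 1.0)),
        meta=sidecar.get("meta", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(_jsonable(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def provenance_record(config: dict, seeds: dict | None = None, **extra) -> dict:
    """Provenance for an artifact: config hash, version, seeds, timestamp."""
    from . import __version__

    return {
        "config_hash": config_hash(config),
        "software": f"vbmrep {__version__}",
        "seeds": _jsonable(seeds or {}),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        **_jsonable(extra),
    }


def read_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
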