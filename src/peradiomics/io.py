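"""Plain-text and NIfTI input/output for cohorts and run artifacts."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .prep import CTSlice, ROIMask
from .synthetic import Cohort, CohortConfig


def write_slice_nifti(ct: CTSlice, path: str | Path) -> None:
    """Write a 2D slice as NIfTI with the pixel spacing in the header."""
    affine = np.diag([ct.spacing[0], ct.spacing[1], 1.0, 1.0])
    img = nib.Nifti1Image(ct.values.astype(np.float32), affine)
    img.header.set_zooms((ct.spacing[0], ct.spacing[1]))
    nib.save(img, str(path))


def read_slice_nifti(path: str | Path, patient_id: str = "") -> CTSlice:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    zooms = img.header.get_zooms()[:2]
    return CTSlice(values=data, spacing=(float(zooms[0]), float(zooms[1])),
                   patient_id=patient_id or Path(path).stem.split(".")[0])


def write_mask_nifti(roi: ROIMask, spacing: tuple[float, float], path: str | Path) -> None:
    affine = np.diag([spacing[0], spacing[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(roi.mask.astype(np.uint8), affine), str(path))


def read_mask_nifti(path: str | Path, tissue: str = "SM_IMAT",
                    window: tuple[float, float] = (-190.0, 150.0)) -> ROIMask:
    data = np.asarray(nib.load(str(path)).dataobj)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    return ROIMask(mask=data > 0, tissue=tissue, window=window)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write slices/masks as NIfTI, the clinical table as CSV and the
    generator configuration as YAML."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(exist_ok=True)
    for ct, roi, rec in cohort:
        write_slice_nifti(ct, outdir / "images" / f"{rec.patient_id}.nii.gz")
        write_mask_nifti(roi, ct.spacing, outdir / "masks" / f"{rec.patient_id}.nii.gz")
    cohort.clinical.to_csv(outdir / "clinical.csv")
    save_config(cohort.config, outdir / "cohort_config.yaml")
    return outdir


def save_config(config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def load_cohort_config(path: str | Path) -> CohortConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return CohortConfig(**raw)


def write_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path)
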