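"""NIfTI / CSV / JSON file handling with round-trip and schema guarantees."""

from __future__ import annotations

import hashlib
import json
import os

import nibabel as nib
import numpy as np
import pandas as pd

from .histogram import COLUMN_DICTIONARY

__all__ = ["save_nifti", "load_nifti", "validate_columns",
           "METRICS_COLUMNS", "COHORT_COLUMNS", "file_sha256", "write_json"]

#: required columns of the wide metrics table (36 metric columns)
METRICS_COLUMNS = tuple(COLUMN_DICTIONARY)

#: required columns of the cohort table
COHORT_COLUMNS = (
    "er_status", "pr_status", "her2_status", "ki67_status", "lnm_status",
    "subtype", "shape_label", "margin_label", "signal_label", "max_diameter",
)


def save_nifti(path, array, affine=None) -> None:
    """Write an array as NIfTI; default affine is identity."""
    if affine is None:
        affine = np.eye(4)
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, affine), os.fspath(path))


def load_nifti(path):
    """Read a NIfTI file; returns ``(array, affine)``."""
    img = nib.load(os.fspath(path))
    return np.asarray(img.get_fdata()), img.affine


def validate_columns(frame: pd.DataFrame, required, name: str) -> None:
    """Raise naming every missing required column of a table."""
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{name} is missing required column(s): {missing}")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
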