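"""NIfTI and config I/O for the pipeline.

All volumes in one run share a single voxel grid and affine; no resampling
happens inside the pipeline, so grid mismatches are configuration errors
and are rejected at load time.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .echoes import MultiEchoSeries


def write_nifti(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), img.affine


def read_multiecho(
    echo_paths,
    te_ms,
    tr_s: float,
    label_parity: str = "even-control",
) -> MultiEchoSeries:
    """Load one 4-D NIfTI per echo into a MultiEchoSeries.

    All echoes must share shape and affine; mismatches raise with the
    offending file named.
    """
    vols, affines = [], []
    for p in echo_paths:
        d, a = read_nifti(p)
        if d.ndim != 4:
            raise ValueError(f"{p}: expected a 4-D series, got shape {d.shape}")
        vols.append(d)
        affines.append(a)
    ref_shape, ref_aff = vols[0].shape, affines[0]
    for p, d, a in zip(echo_paths, vols, affines):
        if d.shape != ref_shape:
            raise ValueError(f"{p}: grid {d.shape} != {ref_shape} of {echo_paths[0]}")
        if not np.allclose(a, ref_aff):
            raise ValueError(f"{p}: affine differs from {echo_paths[0]}")
    return MultiEchoSeries(
        data=np.stack(vols), te_ms=np.asarray(te_ms, float), tr_s=tr_s,
        label_parity=label_parity,
    )


def read_mask(path, reference_affine: np.ndarray | None = None) -> np.ndarray:
    data, affine = read_nifti(path)
    if reference_affine is not None and not np.allclose(affine, reference_affine):
        raise ValueError(f"{path}: mask affine does not match the series affine")
    return data > 0.5


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def save_table(path, rows: list[dict]) -> None:
    """Write a list of records as a tab-delimited table."""
    import pandas as pd

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
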