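"""NIfTI and CSV round-trip helpers with provenance headers.

Volumes and masks travel as NIfTI (.nii or .nii.gz) with the voxel
spacing carried in the affine; tables travel as CSV whose leading
``#`` comment lines record tool version, seed and config hash so every
output is traceable to the run that produced it.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import CTVolume, LabelMask


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def _descrip(provenance: dict | None) -> bytes:
    if not provenance:
        return b""
    text = ";".join(f"{k}={v}" for k, v in provenance.items())
    return text.encode()[:79]


def write_volume(volume: CTVolume, path: str | Path, provenance: dict | None = None) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.spacing))
    img.header["descrip"] = _descrip(provenance)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> CTVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(np.asanyarray(img.dataobj, dtype=np.float32), spacing)


def write_mask(mask: LabelMask, path: str | Path, provenance: dict | None = None) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing))
    img.header["descrip"] = _descrip(provenance)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> LabelMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMask(np.asanyarray(img.dataobj) > 0, spacing)


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    provenance: dict | None = None,
    float_format: str | None = None,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, index=False, float_format=float_format)


def read_table(path: str | Path, required_columns: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
    return df
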