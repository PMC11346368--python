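"""File formats: NIfTI volumes, CSV tables, JSON/YAML sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import Centerline, ImageVolume, LabelVolume


def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def write_image_nifti(image: ImageVolume, path: str | Path) -> None:
    """HU volume as signed 16-bit NIfTI, spacing/origin in the affine."""
    data = np.clip(np.rint(image.data), -32768, 32767).astype(np.int16)
    nib.save(nib.Nifti1Image(data, _affine(image.spacing, image.origin)), str(path))


def write_labels_nifti(labels: LabelVolume, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(labels.data.astype(np.uint8), _affine(labels.spacing, labels.origin)),
        str(path),
    )


def _load(path: str | Path):
    img = nib.load(str(path))
    aff = img.affine
    spacing = np.abs(np.diag(aff)[:3])
    origin = aff[:3, 3]
    return np.asarray(img.dataobj), spacing, origin


def read_image_nifti(path: str | Path) -> ImageVolume:
    data, spacing, origin = _load(path)
    return ImageVolume(data=data.astype(np.float32), spacing=spacing, origin=origin)


def read_labels_nifti(path: str | Path) -> LabelVolume:
    data, spacing, origin = _load(path)
    return LabelVolume(data=data, spacing=spacing, origin=origin)


def write_centerline_csv(cl: Centerline, path: str | Path) -> None:
    cl.to_frame().to_csv(path, index=False)


def read_centerline_csv(path: str | Path) -> Centerline:
    return Centerline.from_frame(pd.read_csv(path))


def write_anchors_json(anchors: list, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([{"position_mm": float(p), "kind": k} for p, k in anchors], indent=1)
    )


def read_anchors_json(path: str | Path) -> list:
    return [(a["position_mm"], a["kind"]) for a in json.loads(Path(path).read_text())]
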