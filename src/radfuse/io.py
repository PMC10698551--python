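"""File interfaces: NIfTI volumes, CSV feature tables, JSON manifests."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import CohortSpec, LesionImageSet


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_image_set(image_set: LesionImageSet, out_dir) -> list[Path]:
    """One ``.nii.gz`` per channel plus the mask, under ``out_dir/<lesion_id>/``."""
    out = Path(out_dir) / image_set.lesion_id
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(image_set.voxel_spacing)
    written = []
    for name, vol in image_set.channels.items():
        p = out / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), p)
        written.append(p)
    p = out / "mask.nii.gz"
    nib.save(nib.Nifti1Image(image_set.mask.astype(np.uint8), aff), p)
    written.append(p)
    return written


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def write_feature_tables(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for ch, df in tables.items():
        p = out / f"features_{ch}.csv"
        df.to_csv(p)
        paths.append(p)
    return paths


def read_feature_tables(in_dir) -> dict[str, pd.DataFrame]:
    tables = {}
    for p in sorted(Path(in_dir).glob("features_*.csv")):
        ch = p.stem.removeprefix("features_")
        tables[ch] = pd.read_csv(p, index_col="lesion_id")
    if not tables:
        raise FileNotFoundError(f"no features_*.csv under {in_dir}")
    return tables


def write_manifest(spec: CohortSpec, out_path, extra: dict | None = None) -> None:
    doc = {
        "n_per_class": spec.n_per_class,
        "class_names": list(spec.class_names),
        "size_median_mm": spec.size_median_mm,
        "shape_irregularity": spec.shape_irregularity,
        "channels": list(spec.channels),
        "channel_effects": {f"{c}/{ch}": asdict(e)
                            for (c, ch), e in spec.channel_effects.items()},
        "test_size": spec.test_size,
        "seed": spec.seed,
    }
    if extra:
        doc.update(extra)
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        json.dump(doc, fh, indent=2)
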