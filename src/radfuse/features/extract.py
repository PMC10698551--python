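"""Per-lesion, per-channel feature extraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..preprocess import PreprocessConfig, discretize, preprocess
from .firstorder import firstorder_features
from .registry import FeatureRegistry, default_registry
from .shape import shape_features
from .texture import (
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)


@dataclass
class FeatureVector:
    """One lesion x one channel feature vector, aligned to a registry."""

    lesion_id: str
    channel: str
    values: np.ndarray
    registry: FeatureRegistry

    def __post_init__(self) -> None:
        if len(self.values) != len(self.registry):
            raise ValueError("vector length must match registry size")


def extract_channel(volume: np.ndarray, mask: np.ndarray,
                    registry: FeatureRegistry | None = None,
                    config: PreprocessConfig | None = None,
                    shape_values: dict[str, float] | None = None,
                    spacing=(1.0, 1.0, 1.0),
                    preprocessed: bool = False,
                    lesion_id: str = "?") -> dict[str, float]:
    """Extract the full registry feature set for one channel volume.

    ``shape_values`` lets callers reuse the (channel-independent) morphology
    block across channels; when omitted it is computed from the mask. With
    ``preprocessed=True`` the volume/mask are taken as already resampled and
    normalized and ``spacing`` is interpreted on the current grid.
    """
    registry = registry or default_registry()
    config = config or PreprocessConfig()
    if not preprocessed:
        volume, mask = preprocess(volume, mask, config, spacing=spacing, lesion_id=lesion_id)
        spacing = config.target_spacing
    mask = mask.astype(bool)
    if mask.sum() < 2:
        raise ValueError(f"mask of lesion {lesion_id!r} smaller than 2 voxels")

    voxel_volume = float(np.prod(spacing))
    in_mask = volume[mask]

    out: dict[str, float] = {}
    fo = firstorder_features(in_mask, voxel_volume, n_bins=config.n_bins)
    out.update({f"firstorder_{k}": v for k, v in fo.items()})

    if shape_values is None:
        shape_values = shape_features(mask, spacing)
    out.update({f"shape_{k}": v for k, v in shape_values.items()})

    disc = np.zeros(volume.shape, dtype=np.int64)
    disc[mask] = discretize(in_mask, config.n_bins)

    glcm_mean, glcm_dirvar = glcm_features(disc)
    out.update({f"glcm_{k}": v for k, v in glcm_mean.items()})
    out.update({f"glcm_{k}_DirectionVariance": v for k, v in glcm_dirvar.items()})
    out.update({f"glrlm_{k}": v for k, v in glrlm_features(disc).items()})
    out.update({f"glszm_{k}": v for k, v in glszm_features(disc).items()})
    out.update({f"ngtdm_{k}": v for k, v in ngtdm_features(disc).items()})

    missing = [n for n in registry.names if n not in out]
    if missing:
        raise ValueError(f"registry names not computed: {missing[:5]} ...")
    vec = {n: float(out[n]) for n in registry.names}
    bad = [n for n, v in vec.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values for lesion {lesion_id!r}: {bad}")
    return vec


def extract_features(image_set, registry: FeatureRegistry | None = None,
                     config: PreprocessConfig | None = None) -> dict[str, FeatureVector]:
    """Extract one feature vector per channel of a :class:`LesionImageSet`.

    Morphology is computed once from the (shared) mask and repeated per
    channel; intensity/texture are channel-specific.
    """
    registry = registry or default_registry()
    config = config or PreprocessConfig()
    if image_set.mask.sum() < 2:
        raise ValueError(f"mask of lesion {image_set.lesion_id!r} smaller than 2 voxels")

    # preprocess the mask once so geometry is shared across channels
    first_channel = next(iter(image_set.channels.values()))
    _, mask_pp = preprocess(first_channel, image_set.mask, config,
                            spacing=image_set.voxel_spacing, lesion_id=image_set.lesion_id)
    shape_vals = shape_features(mask_pp, config.target_spacing)

    vectors: dict[str, FeatureVector] = {}
    for channel, volume in image_set.channels.items():
        vol_pp, _ = preprocess(volume, image_set.mask, config,
                               spacing=image_set.voxel_spacing, lesion_id=image_set.lesion_id)
        vals = extract_channel(vol_pp, mask_pp, registry, config,
                               shape_values=shape_vals,
                               spacing=config.target_spacing, preprocessed=True,
                               lesion_id=image_set.lesion_id)
        vectors[channel] = FeatureVector(
            lesion_id=image_set.lesion_id, channel=channel,
            values=np.array([vals[n] for n in registry.names]), registry=registry,
        )
    return vectors


def table_from_vectors(vectors: list[FeatureVector], labels: dict[str, str]) -> pd.DataFrame:
    """Assemble FeatureVectors (one channel) into a lesions x features table.

    Rows are sorted by lesion id; a ``class`` column is attached first.
    """
    if not vectors:
        reg = default_registry()
        return pd.DataFrame(columns=["class", *reg.names]).rename_axis("lesion_id")
    reg = vectors[0].registry
    ids = [v.lesion_id for v in vectors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate lesion_id in vectors")
    for v in vectors:
        if v.registry.names != reg.names:
            raise ValueError("inconsistent registries across vectors")
    missing = [i for i in ids if i not in labels]
    if missing:
        raise ValueError(f"missing class label for lesions: {missing}")
    rows = sorted(vectors, key=lambda v: v.lesion_id)
    df = pd.DataFrame([v.values for v in rows],
                      index=pd.Index([v.lesion_id for v in rows], name="lesion_id"),
                      columns=list(reg.names))
    df.insert(0, "class", [labels[v.lesion_id] for v in rows])
    return df
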