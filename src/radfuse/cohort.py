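"""Synthetic breast-lesion cohort generation.

Emulates the class structure of a 466-lesion breast mpMRI cohort — 336
hormone-receptor positive (HR+), 76 HER-2-enriched (HEBC) and 54 triple
negative (TNBC) lesions — across up to ten co-registered sequence channels
(T2WI, DWI600, DWI800, ADC, DCE1..DCE6). Two generation modes are offered:

* ``features`` — draw per-channel radiomics feature tables directly from a
  latent factor model (fast; used by the model-bank and fusion pipeline);
* ``images`` — build voxel phantoms (superellipsoid masks with radial
  boundary noise, Gaussian-random-field channel textures) to exercise the
  full extraction path.

Class-conditional signal follows the clinical picture the pipeline is built
around: HR+ lesions are smaller with more irregular margins; TNBC lesions
are smoother-textured and lower-intensity on the ADC-like channel (lower
intensity entropy and mean absolute deviation than non-TNBC); and the
discriminative signal is deliberately split across several channels so that
multi-sequence fusion has something to gain over any single sequence.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._seeds import substream
from .features.registry import FeatureRegistry, default_registry
from .features.shape import _boundary_coords, _max_pairwise

CLASSES = ("HR+", "HEBC", "TNBC")
CHANNELS = ("T2WI", "DWI600", "DWI800", "ADC", "DCE1", "DCE2", "DCE3", "DCE4", "DCE5", "DCE6")

DEFAULT_SPACING = (1.096, 1.096, 1.2)


@dataclass(frozen=True)
class ChannelEffect:
    """Class-conditional effect profile of one (class, channel) pair.

    Expressed in latent units (standard deviations of the per-lesion
    channel latents): ``level`` shifts overall intensity, ``spread`` the
    intensity dispersion, ``smoothness`` the texture correlation length
    (higher = smoother = lower entropy).
    """

    level: float = 0.0
    spread: float = 0.0
    smoothness: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.level, self.spread, self.smoothness])


def default_channel_effects() -> dict[tuple[str, str], ChannelEffect]:
    """Default class/channel effect layout.

    ADC carries the strongest TNBC signal (smoother, narrower, darker than
    non-TNBC); T2WI and DWI600 carry complementary TNBC signal; DWI600/
    DWI800/DCE5 separate HR- from HR+; DCE2 adds TNBC-vs-HEBC contrast.
    """
    e = ChannelEffect
    return {
        ("TNBC", "ADC"): e(level=-0.6, spread=-0.7, smoothness=0.8),
        ("HEBC", "ADC"): e(level=0.25, spread=0.25, smoothness=-0.25),
        ("TNBC", "T2WI"): e(level=-0.55, spread=-0.4, smoothness=0.5),
        ("TNBC", "DWI600"): e(level=-0.5, spread=-0.5, smoothness=0.5),
        ("HEBC", "DWI600"): e(level=0.0, spread=0.3, smoothness=0.5),
        ("TNBC", "DWI800"): e(level=0.2, spread=0.0, smoothness=0.4),
        ("HEBC", "DWI800"): e(level=0.4, spread=0.2, smoothness=0.3),
        ("TNBC", "DCE2"): e(level=0.3, spread=0.3, smoothness=-0.3),
        ("HEBC", "DCE2"): e(level=-0.2, spread=0.0, smoothness=0.0),
        ("TNBC", "DCE5"): e(level=0.3, spread=0.0, smoothness=0.3),
        ("HEBC", "DCE5"): e(level=0.3, spread=0.0, smoothness=0.3),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Generator configuration for one synthetic cohort."""

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"HR+": 336, "HEBC": 76, "TNBC": 54})
    class_names: tuple[str, ...] = CLASSES
    size_median_mm: dict[str, float] = field(
        default_factory=lambda: {"HR+": 21.0, "HEBC": 27.0, "TNBC": 26.0})
    size_log_sigma: dict[str, float] = field(
        default_factory=lambda: {"HR+": 0.466, "HEBC": 0.631, "TNBC": 0.509})
    shape_irregularity: dict[str, float] = field(
        default_factory=lambda: {"HR+": 0.45, "HEBC": 0.33, "TNBC": 0.30})
    channel_effects: dict[tuple[str, str], ChannelEffect] = field(
        default_factory=default_channel_effects)
    channels: tuple[str, ...] = CHANNELS
    test_size: int = 129
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValueError("class counts must be >= 0")
        if unknown := set(self.n_per_class) - set(self.class_names):
            raise ValueError(f"unknown classes: {unknown}")
        if unknown := set(self.channels) - set(CHANNELS):
            raise ValueError(f"unknown channels: {unknown}")
        total = sum(self.n_per_class.values())
        if total == 0:
            raise ValueError("cohort is empty")
        if not 0 <= self.test_size < total:
            raise ValueError("test_size must be < total lesions")
        if any(not 0 <= q <= 1 for q in self.shape_irregularity.values()):
            raise ValueError("shape_irregularity must lie in [0, 1]")

    @property
    def total(self) -> int:
        return sum(self.n_per_class.values())

    def lesion_list(self) -> list[tuple[str, str]]:
        """Ordered (lesion_id, class) pairs; ids are stable per class."""
        out = []
        for cls in self.class_names:
            for i in range(self.n_per_class.get(cls, 0)):
                out.append((f"{cls}_{i:04d}", cls))
        return out


@dataclass
class LesionImageSet:
    """Co-registered voxel volumes plus mask for one lesion."""

    lesion_id: str
    class_label: str
    channels: dict[str, np.ndarray]
    mask: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.mask.sum() == 0:
            raise ValueError("mask must be nonempty")
        for name, vol in self.channels.items():
            if name not in CHANNELS:
                raise ValueError(f"unknown channel {name!r}")
            if vol.shape != self.mask.shape:
                raise ValueError("all channels must share the mask grid")


@dataclass
class RaterPair:
    mask_a: np.ndarray
    mask_b: np.ndarray
    perturbation_mm: float


# ---------------------------------------------------------------------------
# latent-factor feature model
# ---------------------------------------------------------------------------

_LEVEL_POS = ("Mean", "Median", "RootMeanSquared", "90Percentile", "10Percentile",
              "Minimum", "Maximum", "Energy", "TotalEnergy", "JointAverage",
              "SumAverage", "Autocorrelation", "HighGrayLevel")
_LEVEL_NEG = ("LowGrayLevel",)
_SPREAD_POS = ("Variance", "StandardDeviation", "MeanAbsoluteDeviation",
               "InterquartileRange", "Range", "SumSquares", "ClusterTendency",
               "ClusterProminence", "Contrast", "DifferenceAverage")
_SMOOTH_POS = ("Uniformity", "JointEnergy", "MaximumProbability", "Id", "Idm",
               "Idn", "Idmn", "InverseVariance", "Imc2", "Correlation", "MCC",
               "LongRun", "LargeArea", "Coarseness")
_SMOOTH_NEG = ("Entropy", "ShortRun", "SmallArea", "Busyness", "Complexity",
               "ZonePercentage", "RunPercentage")


def _feature_loadings(registry: FeatureRegistry) -> np.ndarray:
    """p x 3 loading matrix (level, spread, smoothness) from feature names.

    Morphology features get zero loadings (they are driven by the shape
    latents instead); each loading is scaled by a deterministic per-feature
    factor in [0.8, 1.2] so duplicated columns do not occur.
    """
    rows = []
    for name, family in registry.entries:
        if family == "morphology":
            rows.append((0.0, 0.0, 0.0))
            continue
        short = name.split("_", 1)[1]
        level = spread = smooth = 0.0
        if any(k in short for k in _LEVEL_POS):
            level = 0.9
        if any(k in short for k in _LEVEL_NEG):
            level = -0.7
        if any(k in short for k in _SPREAD_POS):
            spread = 0.8
        # word-boundary-ish matching: "Id" would match inside other names
        if short in ("Id", "Idm", "Idn", "Idmn") or any(
                k in short for k in _SMOOTH_POS if len(k) > 3):
            smooth = 0.8
        if any(k in short for k in _SMOOTH_NEG):
            smooth = -0.8
        u = 0.8 + 0.4 * (zlib.crc32(name.encode()) % 1000) / 999.0
        rows.append((level * u, spread * u, smooth * u))
    return np.array(rows)


def _shape_row(d_mm: float, q: float, rng: np.random.Generator) -> dict[str, float]:
    """Synthesize a self-consistent morphology feature block.

    ``d_mm`` is the lesion's major diameter, ``q`` its boundary
    irregularity in [0, 1]. Identities (Sphericity x SphericalDisproportion
    = 1, Compactness2 = Sphericity^3) hold exactly.
    """
    e = rng.normal(size=6) * 0.04
    major = d_mm * (1.0 + e[0])
    minor = major * np.clip(0.72 - 0.12 * q + e[1], 0.3, 0.95)
    least = major * np.clip(0.55 - 0.10 * q + e[2], 0.2, 0.9)
    sph = float(np.clip(0.90 - 0.45 * q + e[3], 0.25, 0.98))
    volume = np.pi / 6.0 * major * minor * least * (1.0 - 0.15 * q + e[4])
    volume = max(volume, 1.0)
    area = (36.0 * np.pi * volume**2) ** (1.0 / 3.0) / sph
    return {
        "shape_VoxelVolume": volume,
        "shape_SurfaceArea": area,
        "shape_SurfaceVolumeRatio": area / volume,
        "shape_Sphericity": sph,
        "shape_SphericalDisproportion": 1.0 / sph,
        "shape_Compactness2": sph**3,
        "shape_Maximum3DDiameter": major * (1.0 + 0.05 * abs(e[5])),
        "shape_Maximum2DDiameterSlice": major * (0.97 + e[0] * 0.5),
        "shape_Maximum2DDiameterColumn": float(np.hypot(major, least) * 0.72),
        "shape_Maximum2DDiameterRow": float(np.hypot(minor, least) * 0.80),
        "shape_MajorAxisLength": major,
        "shape_MinorAxisLength": minor,
        "shape_LeastAxisLength": least,
        "shape_Elongation": minor / major,
        "shape_Flatness": least / major,
    }


def _lesion_geometry(spec: CohortSpec, cls: str, i: int) -> tuple[float, float, np.random.Generator]:
    rng = substream(spec.seed, "lesion", cls, i)
    d = float(np.exp(np.log(spec.size_median_mm[cls]) + spec.size_log_sigma[cls] * rng.normal()))
    d = float(np.clip(d, 6.0, 90.0))
    q = float(np.clip(rng.normal(spec.shape_irregularity[cls], 0.15), 0.0, 1.0))
    return d, q, rng


def generate_feature_tables(spec: CohortSpec,
                            registry: FeatureRegistry | None = None) -> dict[str, pd.DataFrame]:
    """Draw per-channel feature tables directly from the latent model."""
    registry = registry or default_registry()
    loadings = _feature_loadings(registry)
    lesions = spec.lesion_list()
    n = len(lesions)
    names = registry.names

    shape_rows = []
    for lid, cls in lesions:
        i = int(lid.rsplit("_", 1)[1])
        d, q, rng = _lesion_geometry(spec, cls, i)
        shape_rows.append(_shape_row(d, q, rng))
    shape_df = pd.DataFrame(shape_rows)

    tables: dict[str, pd.DataFrame] = {}
    idio = 0.6
    for ch in spec.channels:
        rng = substream(spec.seed, "features", ch)
        effects = np.zeros((n, 3))
        for row, (_, cls) in enumerate(lesions):
            eff = spec.channel_effects.get((cls, ch))
            if eff is not None:
                effects[row] = eff.as_array()
        latents = effects + rng.normal(size=(n, 3))
        X = latents @ loadings.T + idio * rng.normal(size=(n, len(names)))
        df = pd.DataFrame(X, columns=list(names),
                          index=pd.Index([lid for lid, _ in lesions], name="lesion_id"))
        for col in shape_df.columns:
            df[col] = shape_df[col].to_numpy()
        df.insert(0, "class", [cls for _, cls in lesions])
        tables[ch] = df
    return tables


# ---------------------------------------------------------------------------
# voxel phantoms
# ---------------------------------------------------------------------------

def _smooth_field(shape, sigma_vox, rng) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma_vox)
    sd = field.std()
    return field / sd if sd > 0 else field


def _make_mask(d_mm: float, q: float, spacing, rng) -> np.ndarray:
    half_extent = 0.7 * d_mm + 5.0
    shape = tuple(int(min(np.ceil(2 * half_extent / s), 80)) for s in spacing)
    axes = [(np.arange(m) - (m - 1) / 2.0) * s for m, s in zip(shape, spacing)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    a, b, c = d_mm / 2.0, d_mm / 2.0 * 0.8, d_mm / 2.0 * 0.65
    p = 2.5  # superellipsoid exponent: slightly boxier than an ellipsoid
    r = (np.abs(X / a) ** p + np.abs(Y / b) ** p + np.abs(Z / c) ** p) ** (1.0 / p)
    noise = _smooth_field(shape, sigma_vox=max(d_mm / 4.0 / spacing[0], 1.0), rng=rng)
    mask = r <= 1.0 + 0.35 * q * noise
    if not mask.any():
        mask = r <= 1.0
    return mask


def _make_channel(mask: np.ndarray, effect: ChannelEffect, spacing, rng) -> np.ndarray:
    corr_mm = 2.5 * (1.0 + 0.6 * effect.smoothness)
    sigma_vox = tuple(max(corr_mm / s, 0.5) for s in spacing)
    texture = _smooth_field(mask.shape, sigma_vox, rng)
    # smoothness also sharpens the histogram: stretching the tails of the
    # field makes the binned in-mask distribution more peaked relative to
    # its range, lowering discretized entropy (and vice versa)
    gamma = max(1.0 + 0.8 * effect.smoothness, 0.3)
    texture = np.sign(texture) * np.abs(texture) ** gamma
    tsd = texture.std()
    if tsd > 0:
        texture = texture / tsd
    sd = 20.0 * max(1.0 + 0.4 * effect.spread, 0.2)
    contrast = 60.0 * (1.0 + 0.4 * effect.level)
    return 100.0 + sd * texture + mask * contrast


def generate_image_cohort(spec: CohortSpec) -> list[LesionImageSet]:
    """Generate voxel phantoms for every lesion of the spec."""
    out = []
    for lid, cls in spec.lesion_list():
        i = int(lid.rsplit("_", 1)[1])
        d, q, rng = _lesion_geometry(spec, cls, i)
        mask = _make_mask(d, q, DEFAULT_SPACING, rng)
        channels = {}
        for ch in spec.channels:
            eff = spec.channel_effects.get((cls, ch), ChannelEffect())
            channels[ch] = _make_channel(mask, eff, DEFAULT_SPACING,
                                         substream(spec.seed, "texture", cls, i, ch))
        out.append(LesionImageSet(lesion_id=lid, class_label=cls, channels=channels,
                                  mask=mask, voxel_spacing=DEFAULT_SPACING))
    return out


def generate_cohort(spec: CohortSpec, mode: str = "features"):
    """Generate a synthetic cohort in ``features`` or ``images`` mode."""
    if mode == "features":
        return generate_feature_tables(spec)
    if mode == "images":
        return generate_image_cohort(spec)
    raise ValueError(f"invalid mode {mode!r}; expected 'features' or 'images'")


def lesion_max_diameter(mask: np.ndarray, spacing=DEFAULT_SPACING) -> float:
    """Maximum 3D boundary diameter of a mask, in mm."""
    return _max_pairwise(_boundary_coords(mask.astype(bool), spacing))


# ---------------------------------------------------------------------------
# rater perturbation and cohort splitting
# ---------------------------------------------------------------------------

def make_rater_pair(mask: np.ndarray, perturbation_mm: float, seed: int,
                    spacing=DEFAULT_SPACING) -> RaterPair:
    """Derive a second-rater mask by smooth boundary jitter of the first.

    The signed distance to the boundary is perturbed by a smooth random
    field scaled to ``perturbation_mm`` (unit-variance field, so boundary
    displacements are of that order). Zero perturbation returns the mask
    unchanged.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if perturbation_mm < 0:
        raise ValueError("perturbation must be >= 0")
    if perturbation_mm == 0:
        return RaterPair(mask_a=mask, mask_b=mask.copy(), perturbation_mm=0.0)
    rng = substream(seed, "rater")
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    # a jitter comparable to the lesion's inradius is no longer a plausible
    # second-rater delineation and can erase the lesion entirely
    if perturbation_mm >= 2.0 * float(inside.max()):
        raise ValueError("perturbation too large relative to lesion size")
    signed = inside - outside
    fieldsig = tuple(max(2.0 / s, 0.5) for s in spacing)
    field = _smooth_field(mask.shape, fieldsig, rng)
    mask_b = signed + perturbation_mm * field > 0
    if not mask_b.any():
        raise ValueError("perturbation too large: second-rater mask is empty")
    return RaterPair(mask_a=mask, mask_b=mask_b, perturbation_mm=float(perturbation_mm))


def split_cohort(labels, test_size: int, seed: int,
                 allow_empty_test: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split with an exact held-out count.

    Per-class test counts follow largest-remainder proportional allocation,
    so each class's test fraction is within one lesion of the global
    fraction and the split is exhaustive and disjoint. Returns positional
    index arrays (train, test).
    """
    labels = np.asarray(labels)
    n = len(labels)
    if test_size <= 0 and not allow_empty_test:
        raise ValueError("test_size must be > 0")
    if test_size >= n:
        raise ValueError("test_size must be < number of lesions")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to stratify")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members")
    quota = counts * test_size / n
    base = np.floor(quota).astype(int)
    rem = test_size - base.sum()
    order = np.lexsort((classes, -counts, -(quota - base)))  # largest remainder first
    take = base.copy()
    for idx in order[:rem]:
        take[idx] += 1
    rng = substream(seed, "split")
    test_idx: list[int] = []
    for cls, k in zip(classes, take):
        members = np.flatnonzero(labels == cls)
        perm = rng.permutation(len(members))
        test_idx.extend(members[perm[:k]])
    test = np.sort(np.array(test_idx, dtype=int))
    train = np.setdiff1d(np.arange(n), test)
    return train, test
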