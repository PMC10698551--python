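"""The feature registry: the ordered 109-feature vocabulary.

The default registry partitions into 19 intensity, 15 morphology and 75
texture features (24 direction-averaged GLCM + 14 GLCM direction-variance
variants + 16 GLRLM + 16 GLSZM + 5 NGTDM). Composition is configurable; the
default is what the rest of the package (including the synthetic cohort
generator) assumes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .firstorder import FIRSTORDER_NAMES
from .shape import SHAPE_NAMES
from .texture import (
    GLCM_DIRVAR_NAMES,
    GLCM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
)

INTENSITY = "intensity"
MORPHOLOGY = "morphology"
TEXTURE = "texture"


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered list of (name, family) pairs defining the feature vector."""

    entries: tuple[tuple[str, str], ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries)

    @property
    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, fam in self.entries:
            counts[fam] = counts.get(fam, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.entries)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")


def default_registry() -> FeatureRegistry:
    """The canonical 109-feature registry (19 intensity / 15 morphology / 75 texture)."""
    entries: list[tuple[str, str]] = []
    entries += [(f"firstorder_{n}", INTENSITY) for n in FIRSTORDER_NAMES]
    entries += [(f"shape_{n}", MORPHOLOGY) for n in SHAPE_NAMES]
    entries += [(f"glcm_{n}", TEXTURE) for n in GLCM_NAMES]
    entries += [(f"glcm_{n}_DirectionVariance", TEXTURE) for n in GLCM_DIRVAR_NAMES]
    entries += [(f"glrlm_{n}", TEXTURE) for n in GLRLM_NAMES]
    entries += [(f"glszm_{n}", TEXTURE) for n in GLSZM_NAMES]
    entries += [(f"ngtdm_{n}", TEXTURE) for n in NGTDM_NAMES]
    return FeatureRegistry(entries=tuple(entries))
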