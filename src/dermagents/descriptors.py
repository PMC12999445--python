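"""Rule-based textual lesion descriptors.

A deterministic stand-in for a prompt-based visual-language model: it maps
clinically meaningful lesion cues (asymmetry, border irregularity, color
heterogeneity, dermoscopic structures) to a short token sequence over a
fixed vocabulary. For generated images the cues come from the generator's
ground-truth feature record; for real images they can be measured from the
pixels and mask with :func:`measure_features`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .synthetic import (
    LesionImage,
    border_irregularity,
    mask_asymmetry,
)

VOCABULARY: tuple[str, ...] = (
    "<pad>",
    "lesion",
    "regular",
    "asymmetric",
    "shape",
    "irregular",
    "border",
    "heterogeneous",
    "colors",
    "structures",
    "present",
)

_INDEX = {word: i for i, word in enumerate(VOCABULARY)}


@dataclass(frozen=True)
class DescriptorConfig:
    """Cue thresholds on the ground-truth feature record."""

    asymmetry_threshold: float = 0.10
    border_threshold: float = 0.08
    color_count_threshold: int = 3


DEFAULT_DESCRIPTOR = DescriptorConfig()


@dataclass(frozen=True)
class TextDescriptor:
    tokens: tuple[int, ...]
    vocab_size: int
    source_features: dict

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(VOCABULARY[i] for i in self.tokens)


def describe(
    image: LesionImage,
    config: DescriptorConfig = DEFAULT_DESCRIPTOR,
) -> TextDescriptor:
    """Tokenize the lesion's diagnostic cues.

    Each cue whose ground-truth score exceeds its threshold contributes its
    phrase; a lesion with no flagged cue gets the fixed "regular lesion"
    template. Deterministic in the feature record.
    """
    feats = image.features
    if feats is None:
        raise DomainError("image carries no ground-truth feature record")
    words: list[str] = []
    if feats["asymmetry"] >= config.asymmetry_threshold:
        words += ["asymmetric", "shape"]
    if feats["border_irregularity"] >= config.border_threshold:
        words += ["irregular", "border"]
    if feats["n_colors"] >= config.color_count_threshold:
        words += ["heterogeneous", "colors"]
    if feats.get("structures"):
        words += ["structures", "present"]
    words = ["regular", "lesion"] if not words else ["lesion"] + words
    return TextDescriptor(
        tokens=tuple(_INDEX[w] for w in words),
        vocab_size=len(VOCABULARY),
        source_features=dict(feats),
    )


def measure_features(image: LesionImage) -> dict:
    """Measure descriptor cues from pixels and mask (for real images).

    Color heterogeneity is the number of coarse color bins each covering at
    least 5% of the lesion interior; structures are flagged when >2% of
    interior pixels are very dark.
    """
    mask = image.lesion_mask
    if not mask.any():
        raise DomainError("empty lesion mask")
    interior = image.pixels[mask]
    bins = np.floor(interior * 6).astype(int)
    codes = bins[:, 0] * 49 + bins[:, 1] * 7 + bins[:, 2]
    _, counts = np.unique(codes, return_counts=True)
    n_colors = int((counts / counts.sum() >= 0.05).sum())
    return {
        "asymmetry": mask_asymmetry(mask),
        "border_irregularity": max(border_irregularity(mask), 0.0) / 4.0,
        "n_colors": n_colors,
        "structures": bool((interior.mean(axis=1) < 0.15).mean() > 0.02),
    }


def describe_measured(
    image: LesionImage,
    config: DescriptorConfig = DEFAULT_DESCRIPTOR,
) -> TextDescriptor:
    """Describe an image without generator ground truth (measures cues first)."""
    measured = LesionImage(
        pixels=image.pixels,
        label=image.label,
        lesion_mask=image.lesion_mask,
        seed=image.seed,
        features=measure_features(image),
    )
    return describe(measured, config)
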