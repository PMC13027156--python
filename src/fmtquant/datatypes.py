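"""Shared containers for microscopy fields, segmentation masks and per-image measurements.

Intensities live on a float [0, ``intensity_scale``] domain (default 0-255).
The absolute background floor used by the PLA pipeline (intensity 80) only has
meaning on such an 8-bit-like scale, so every generator and reader normalises
to it; the scale is configurable but never implicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


class DegenerateImageError(ValueError):
    """Raised when a channel is constant and thresholding is undefined."""


class NoNucleiError(ValueError):
    """Raised when an operation requires a non-empty nuclear mask."""


@dataclass(frozen=True)
class FieldMeta:
    """Nesting labels of one field of view.

    group: treatment label (fixed effect); specimen: coverslip/well id;
    image: field-of-view id within the specimen; experiment: independent
    replicate id. These labels drive the random-effect structure downstream.
    """

    group: str = "control"
    specimen: str = "s1"
    image: str = "i1"
    experiment: str = "e1"

    def as_dict(self) -> dict:
        return {
            "group": self.group,
            "specimen": self.specimen,
            "image": self.image,
            "experiment": self.experiment,
        }


@dataclass
class FieldImage:
    """One multi-channel field of view.

    ``nuclear_channel`` is the DNA counterstain (Hoechst-like), ``target_channel``
    the protein of interest (e.g. MRTFA immunofluorescence), ``puncta_channel``
    the PLA spot channel. All present channels share one shape and are
    non-negative.
    """

    nuclear_channel: np.ndarray
    target_channel: Optional[np.ndarray] = None
    puncta_channel: Optional[np.ndarray] = None
    meta: FieldMeta = field(default_factory=FieldMeta)

    def __post_init__(self) -> None:
        self.nuclear_channel = np.asarray(self.nuclear_channel, dtype=float)
        if self.nuclear_channel.ndim != 2:
            raise ValueError("channels must be 2-D")
        for name in ("target_channel", "puncta_channel"):
            ch = getattr(self, name)
            if ch is None:
                continue
            ch = np.asarray(ch, dtype=float)
            if ch.shape != self.nuclear_channel.shape:
                raise ValueError(
                    f"{name} shape {ch.shape} != nuclear channel "
                    f"shape {self.nuclear_channel.shape}"
                )
            setattr(self, name, ch)
        for name in ("nuclear_channel", "target_channel", "puncta_channel"):
            ch = getattr(self, name)
            if ch is not None and np.any(ch < 0):
                raise ValueError(f"{name} has negative intensities")

    @property
    def shape(self) -> tuple:
        return self.nuclear_channel.shape


@dataclass
class NuclearMask:
    """Labeled nuclear segmentation.

    ``labels`` uses 0 for background and consecutive positive integers for
    retained components; ``component_areas[i]`` is the pixel area of label
    ``i + 1``. ``threshold_used`` records the global threshold applied.
    """

    labels: np.ndarray
    component_areas: np.ndarray
    threshold_used: float

    @property
    def n_components(self) -> int:
        return int(len(self.component_areas))

    @property
    def mask_area(self) -> int:
        return int(self.component_areas.sum()) if self.n_components else 0

    @property
    def is_empty(self) -> bool:
        return self.n_components == 0

    def boolean(self) -> np.ndarray:
        return self.labels > 0


@dataclass(frozen=True)
class MeasurementRecord:
    """One per-image quantification value with its nesting labels."""

    value: float
    group: str
    specimen: str
    image: str
    experiment: str

    @classmethod
    def from_meta(cls, value: float, meta: FieldMeta) -> "MeasurementRecord":
        return cls(value=float(value), **meta.as_dict())


def relabel_by_area(labels: np.ndarray, min_area: int) -> tuple[np.ndarray, np.ndarray]:
    """Drop components with area strictly below ``min_area`` and relabel 1..K.

    The strict-< exclusion is the boundary rule shared by all three
    segmentation stages (nuclei < 700 px, puncta < 25 px, PLA nuclei
    < 3000 px): an object of exactly ``min_area`` pixels survives.
    Components are renumbered in ascending order of their original label.
    """
    labels = np.asarray(labels)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= min_area]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    new_labels = lut[labels]
    areas = counts[counts >= min_area].astype(np.int64)
    return new_labels, areas


__all__ = [
    "DegenerateImageError",
    "NoNucleiError",
    "FieldMeta",
    "FieldImage",
    "NuclearMask",
    "MeasurementRecord",
    "relabel_by_area",
    "replace",
]
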