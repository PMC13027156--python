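"""Proximity ligation assay (PLA) puncta detection and the per-field PLA index.

PLA produces discrete fluorescent puncta where two proteins (here MRTFA and
G-actin) are within ligation distance; the per-field index is the total
punctum count divided by the total nucleus count. The detection pipeline:

1. floor: pixels with raw intensity < 80 (on the 0-255 domain) are zeroed;
2. blur: Gaussian smoothing, sigma = 1.5 (floor first, then blur — the
   reverse order changes results and is exposed via ``order`` for
   sensitivity analysis);
3. Li threshold, binarize (>=), 8-connected labeling;
4. size exclusion: components < 25 px (strict) removed as non-specific noise;
5. watershed: merged puncta split on the inverted smoothed intensity, seeded
   at regional maxima with minimum seed separation 2*sigma. Splitting happens
   after size exclusion and fragments are not re-filtered.

Nuclei in PLA fields are segmented with the same pipeline shape as the
translocation analysis but with blur sigma = 1.5 and a 3000 px size floor
(PLA imaging uses higher magnification, so nuclei are larger in pixels).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_maxima
from skimage.segmentation import watershed

from .datatypes import (
    FieldImage,
    FieldMeta,
    MeasurementRecord,
    NoNucleiError,
    NuclearMask,
    relabel_by_area,
)
from .nuclear import label_components, li_threshold, segment_nuclei, smooth

logger = logging.getLogger(__name__)

#: absolute background floor on the 0-255 intensity domain (strict <)
DEFAULT_FLOOR = 80.0
#: Gaussian blur applied to the puncta channel, in pixels
DEFAULT_PLA_SIGMA = 1.5
#: puncta below this pixel area are discarded (strict <)
DEFAULT_MIN_PUNCTUM = 25
#: PLA-field nuclei below this pixel area are discarded (strict <)
DEFAULT_MIN_PLA_NUCLEUS = 3000


def preprocess_pla(
    channel: np.ndarray,
    floor: float = DEFAULT_FLOOR,
    sigma: float = DEFAULT_PLA_SIGMA,
    order: str = "floor_then_blur",
) -> np.ndarray:
    """Background suppression and smoothing of a raw puncta channel.

    Pixels strictly below ``floor`` are set to zero first, then the Gaussian
    blur is applied. ``order="blur_then_floor"`` swaps the two steps for
    sensitivity analysis.
    """
    channel = np.asarray(channel, dtype=float)
    if np.any(channel < 0):
        raise ValueError("puncta channel has negative intensities")
    if order == "floor_then_blur":
        floored = np.where(channel < floor, 0.0, channel)
        return smooth(floored, sigma)
    if order == "blur_then_floor":
        blurred = smooth(channel, sigma)
        return np.where(blurred < floor, 0.0, blurred)
    raise ValueError(f"unknown order {order!r}")


@dataclass
class PunctaSet:
    """Detected puncta: labels, count, centroids and per-punctum areas."""

    labels: np.ndarray
    count: int
    centroids: np.ndarray  # (count, 2) array of (row, col)
    areas: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return self.labels > 0


def _watershed_split(
    labels: np.ndarray, intensity: np.ndarray, min_distance: float
) -> np.ndarray:
    """Split merged components by watershed on the inverted intensity.

    Seeds are regional intensity maxima (plateau-aware: one seed per
    connected maximal region) thinned so that no two seeds within one
    component are closer than ``min_distance`` (brighter seed wins). The
    foreground support is preserved exactly — only labels change.
    """
    support = labels > 0
    maxima = local_maxima(intensity, connectivity=2) & support
    max_regions = label_components(maxima)
    seeds = []  # (intensity, row, col, component)
    for k in range(1, int(max_regions.max()) + 1):
        rows, cols = np.nonzero(max_regions == k)
        i = len(rows) // 2  # representative pixel of the (flat) maximal region
        seeds.append((float(intensity[rows[i], cols[i]]), int(rows[i]), int(cols[i]),
                      int(labels[rows[i], cols[i]])))
    seeds.sort(key=lambda s: (-s[0], s[1], s[2]))
    kept: list[tuple] = []
    for s in seeds:
        if all(
            s[3] != k[3] or np.hypot(s[1] - k[1], s[2] - k[2]) >= min_distance
            for k in kept
        ):
            kept.append(s)
    markers = np.zeros(labels.shape, dtype=np.int32)
    for i, (_, r, c, _) in enumerate(kept, start=1):
        markers[r, c] = i
    # a component whose maxima were all thinned away cannot occur (the
    # brightest seed of each component is always kept first)
    return watershed(-intensity, markers=markers, mask=support)


def detect_puncta(
    channel: np.ndarray,
    min_area: int = DEFAULT_MIN_PUNCTUM,
    sigma: float = DEFAULT_PLA_SIGMA,
    split_merged: bool = True,
) -> PunctaSet:
    """Detect PLA puncta in a *preprocessed* channel.

    Li threshold -> binarize (>=) -> remove components < ``min_area`` (strict)
    -> watershed-split merged puncta seeded at regional maxima (minimum
    separation ``2*sigma``). An all-zero channel yields an empty PunctaSet.
    ``sigma`` is only used to set the seed separation; the channel is assumed
    already blurred.
    """
    channel = np.asarray(channel, dtype=float)
    if not np.any(channel > 0):
        return PunctaSet(
            labels=np.zeros(channel.shape, dtype=np.int32),
            count=0,
            centroids=np.empty((0, 2)),
            areas=np.empty(0, dtype=np.int64),
        )
    threshold = li_threshold(channel)
    binary = channel >= threshold
    labels = label_components(binary)
    labels, _ = relabel_by_area(labels, min_area)
    if split_merged and labels.max() > 0:
        labels = _watershed_split(labels, channel, min_distance=max(1, math.ceil(2 * sigma)))
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    # relabel consecutively (watershed can skip marker ids)
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1)
    labels = lut[labels]
    centroids = (
        np.asarray(ndi.center_of_mass(labels > 0, labels, np.arange(1, len(ids) + 1)))
        if len(ids)
        else np.empty((0, 2))
    )
    return PunctaSet(
        labels=labels, count=int(len(ids)), centroids=centroids,
        areas=counts.astype(np.int64),
    )


def segment_pla_nuclei(
    channel: np.ndarray | FieldImage,
    sigma: float = DEFAULT_PLA_SIGMA,
    min_area: int = DEFAULT_MIN_PLA_NUCLEUS,
) -> NuclearMask:
    """Segment nuclei in a PLA field (blur sigma 1.5, size floor 3000 px).

    Same pipeline shape as the translocation nuclear segmentation; Li
    thresholding is used here too for consistency (the choice is
    configurable upstream through the shared segmentation surface).
    """
    return segment_nuclei(channel, sigma=sigma, min_area=min_area)


@dataclass
class PLAResult:
    """Per-field PLA quantification: puncta count / nuclei count."""

    puncta_count: int
    nuclei_count: int
    pla_index: float
    meta: FieldMeta


def pla_index(puncta: PunctaSet, nuclei: NuclearMask, meta: FieldMeta | None = None) -> PLAResult:
    """Total puncta divided by total nuclei in one field.

    A field without nuclei has an undefined index and raises
    :class:`NoNucleiError` (callers exclude and log it; never index = inf).
    """
    if nuclei.n_components == 0:
        raise NoNucleiError("no nuclei in field; PLA index undefined")
    return PLAResult(
        puncta_count=puncta.count,
        nuclei_count=nuclei.n_components,
        pla_index=puncta.count / nuclei.n_components,
        meta=meta or FieldMeta(),
    )


def quantify_pla_field(
    field: FieldImage,
    floor: float = DEFAULT_FLOOR,
    sigma: float = DEFAULT_PLA_SIGMA,
    min_punctum: int = DEFAULT_MIN_PUNCTUM,
    min_nucleus: int = DEFAULT_MIN_PLA_NUCLEUS,
) -> PLAResult:
    """Full PLA quantification of one field (puncta channel + nuclear channel)."""
    if field.puncta_channel is None:
        raise ValueError("field has no puncta channel")
    preprocessed = preprocess_pla(field.puncta_channel, floor=floor, sigma=sigma)
    puncta = detect_puncta(preprocessed, min_area=min_punctum, sigma=sigma)
    nuclei = segment_pla_nuclei(field.nuclear_channel, sigma=sigma, min_area=min_nucleus)
    return pla_index(puncta, nuclei, meta=field.meta)


def quantify_pla_batch(
    fields: Iterable[FieldImage],
    floor: float = DEFAULT_FLOOR,
    sigma: float = DEFAULT_PLA_SIGMA,
    min_punctum: int = DEFAULT_MIN_PUNCTUM,
    min_nucleus: int = DEFAULT_MIN_PLA_NUCLEUS,
) -> list[MeasurementRecord]:
    """Quantify a batch of PLA fields; failing fields are logged and excluded."""
    fields = list(fields)
    if not fields:
        raise ValueError("empty batch")
    records: list[MeasurementRecord] = []
    failures = 0
    for field in fields:
        try:
            result = quantify_pla_field(
                field, floor=floor, sigma=sigma,
                min_punctum=min_punctum, min_nucleus=min_nucleus,
            )
        except (NoNucleiError, ValueError) as exc:
            failures += 1
            logger.warning(
                "PLA field %s/%s/%s/%s failed: %s",
                field.meta.group, field.meta.specimen, field.meta.image,
                field.meta.experiment, exc,
            )
            continue
        records.append(MeasurementRecord.from_meta(result.pla_index, field.meta))
    if not records:
        raise RuntimeError(f"all {failures} PLA fields failed quantification")
    return records
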