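"""Nuclear segmentation and the per-image Nuclear Enrichment Index.

The index quantifies nuclear translocation of a target protein (e.g. MRTFA)
as the ratio of mean target-channel fluorescence to mean nuclear-marker
(Hoechst) fluorescence inside the segmented nuclear area of a whole field of
view. Segmentation is global: Gaussian smoothing (sigma = 3.0) of the nuclear
channel, Li minimum-cross-entropy thresholding, connected-component labeling,
and removal of small objects (< 700 px, strict) likely to be debris.

Conventions this module fixes (the pipeline is insensitive to none of them):

* binarization keeps pixels ``>= threshold`` (boundary pixel included);
* components are labeled with 8-connectivity;
* intensity means for the index are taken from the *raw* channels — smoothing
  is for segmentation only, not measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_li

from .datatypes import (
    DegenerateImageError,
    FieldImage,
    FieldMeta,
    MeasurementRecord,
    NoNucleiError,
    NuclearMask,
    relabel_by_area,
)

logger = logging.getLogger(__name__)

#: default smoothing for the nuclear-marker channel, in pixels
DEFAULT_SIGMA = 3.0
#: components below this pixel area are discarded as noise (strict <)
DEFAULT_MIN_AREA = 700

# 8-connectivity structuring element for 2-D component labeling
_STRUCT8 = np.ones((3, 3), dtype=bool)


def li_threshold(values: np.ndarray) -> float:
    """Li's minimum-cross-entropy threshold of an intensity array.

    Iterative fixed point started from the array mean. Raises
    :class:`DegenerateImageError` on a constant array, where no threshold
    separates anything.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0 or np.ptp(values) == 0:
        raise DegenerateImageError("degenerate histogram: constant intensity array")
    return float(threshold_li(values))


def smooth(channel: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing preserving the intensity range (no rescale)."""
    channel = np.asarray(channel, dtype=float)
    if sigma <= 0:
        return channel
    return gaussian(channel, sigma=sigma, preserve_range=True)


def label_components(binary: np.ndarray) -> np.ndarray:
    """8-connected component labeling of a boolean image."""
    labels, _ = ndi.label(np.asarray(binary, dtype=bool), structure=_STRUCT8)
    return labels


def segment_nuclei(
    field: FieldImage | np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    min_area: int = DEFAULT_MIN_AREA,
) -> NuclearMask:
    """Segment all nuclei in a field with the global pipeline.

    Order: smooth -> global Li threshold -> binarize (>= threshold) ->
    label connected components -> drop components with area < ``min_area``.
    A field in which no component survives yields an empty (but valid)
    mask, logged as a warning; a constant nuclear channel raises
    :class:`DegenerateImageError`.
    """
    channel = field.nuclear_channel if isinstance(field, FieldImage) else np.asarray(field, float)
    smoothed = smooth(channel, sigma)
    threshold = li_threshold(smoothed)
    binary = smoothed >= threshold
    labels = label_components(binary)
    labels, areas = relabel_by_area(labels, min_area)
    if len(areas) == 0:
        logger.warning("segment_nuclei: no component of area >= %d survived", min_area)
    return NuclearMask(labels=labels, component_areas=areas, threshold_used=threshold)


@dataclass
class EnrichmentResult:
    """Per-image Nuclear Enrichment Index and its ingredients.

    ``index = mean_target_in_mask / mean_marker_in_mask`` with both means
    pooled over every retained nuclear pixel of the image (one value per
    image, not per nucleus).
    """

    index: float
    mean_target_in_mask: float
    mean_marker_in_mask: float
    mask_area: int
    meta: FieldMeta


def enrichment_index(
    field: FieldImage,
    mask: NuclearMask,
    per_nucleus: bool = False,
) -> EnrichmentResult | tuple[EnrichmentResult, np.ndarray]:
    """Nuclear Enrichment Index of one field.

    Means are computed on the raw channels over the pooled nuclear area.
    With ``per_nucleus=True`` additionally returns the per-component
    target/marker ratios as a diagnostic; the headline index remains the
    pooled one.
    """
    if field.target_channel is None:
        raise ValueError("field has no target channel")
    if mask.is_empty:
        raise NoNucleiError("no nuclei in mask; cannot form enrichment index")
    inside = mask.boolean()
    mean_target = float(field.target_channel[inside].mean())
    mean_marker = float(field.nuclear_channel[inside].mean())
    if mean_marker <= 0:
        raise ValueError("zero mean nuclear-marker intensity inside mask")
    result = EnrichmentResult(
        index=mean_target / mean_marker,
        mean_target_in_mask=mean_target,
        mean_marker_in_mask=mean_marker,
        mask_area=mask.mask_area,
        meta=field.meta,
    )
    if not per_nucleus:
        return result
    ratios = np.empty(mask.n_components)
    for k in range(mask.n_components):
        sel = mask.labels == k + 1
        ratios[k] = field.target_channel[sel].mean() / field.nuclear_channel[sel].mean()
    return result, ratios


def quantify_nuclear_batch(
    fields: Iterable[FieldImage],
    sigma: float = DEFAULT_SIGMA,
    min_area: int = DEFAULT_MIN_AREA,
) -> list[MeasurementRecord]:
    """Quantify a batch of fields; failures are logged, never silently dropped.

    Returns one :class:`MeasurementRecord` per successfully quantified field.
    Raises ``RuntimeError`` when every field fails.
    """
    fields = list(fields)
    if not fields:
        raise ValueError("empty batch")
    records: list[MeasurementRecord] = []
    failures = 0
    for field in fields:
        try:
            mask = segment_nuclei(field, sigma=sigma, min_area=min_area)
            result = enrichment_index(field, mask)
        except (DegenerateImageError, NoNucleiError, ValueError) as exc:
            failures += 1
            logger.warning(
                "field %s/%s/%s/%s failed quantification: %s",
                field.meta.group, field.meta.specimen, field.meta.image,
                field.meta.experiment, exc,
            )
            continue
        records.append(MeasurementRecord.from_meta(result.index, field.meta))
    if not records:
        raise RuntimeError(f"all {failures} fields failed quantification")
    return records


def records_to_frame(records: Sequence[MeasurementRecord]):
    """Tidy DataFrame (value, group, specimen, image, experiment) from records."""
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in records])


def read_records_csv(path) -> list[MeasurementRecord]:
    """Read a quantification CSV back into records (exact float round-trip)."""
    import pandas as pd

    return frame_to_records(pd.read_csv(path, float_precision="round_trip"))


def frame_to_records(frame) -> list[MeasurementRecord]:
    """Inverse of :func:`records_to_frame`."""
    return [
        MeasurementRecord(
            value=float(row.value), group=str(row.group), specimen=str(row.specimen),
            image=str(row.image), experiment=str(row.experiment),
        )
        for row in frame.itertuples(index=False)
    ]
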