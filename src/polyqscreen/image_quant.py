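"""Two-channel field quantification: nuclei counts, aggregate counts,
percent aggregates per cell averaged over the fields of a well.

The recipe mirrors a standard batch macro. Nuclei channel: Gaussian
smoothing, Otsu threshold, hole filling, distance-transform watershed to
split touching nuclei, area filter. GFP channel: white top-hat to isolate
compact bright spots, threshold at a configurable multiple of the estimated
diffuse-GFP amplitude, area filter. All thresholds are relative to image
statistics, so counts are invariant under positive intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature, filters, measure, morphology, segmentation

from .config import QuantParams


@dataclass
class FieldImage:
    """One field: co-registered nuclei and GFP intensity grids."""

    nuclei_channel: np.ndarray
    gfp_channel: np.ndarray
    field_id: str = ""
    well_id: str = ""

    def __post_init__(self) -> None:
        if self.nuclei_channel.shape != self.gfp_channel.shape:
            raise ValueError("channel shapes differ")
        if (self.nuclei_channel < 0).any() or (self.gfp_channel < 0).any():
            raise ValueError("intensities must be non-negative")


@dataclass
class FieldQuant:
    field_id: str
    n_cells: int
    n_aggregates: int
    pct: float | None  # None when n_cells == 0 (undefined, excluded from mean)
    blank: bool = False


@dataclass
class WellQuant:
    """Per-well aggregation measurement: field records and their mean."""

    well_id: str
    fields: list[FieldQuant] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_fields(self) -> int:
        return len(self.fields)

    @property
    def well_pct(self) -> float | None:
        vals = [f.pct for f in self.fields if f.pct is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def all_blank(self) -> bool:
        return all(f.blank or f.n_cells == 0 for f in self.fields)


def _is_blank(img: np.ndarray) -> bool:
    return float(img.max() - img.min()) == 0.0


def _foreground_mask(img: np.ndarray, params: QuantParams) -> np.ndarray | None:
    """Otsu foreground, rejected when fore/background contrast is below the
    noise floor (keeps pure-noise fields at zero objects)."""
    smooth = ndimage.gaussian_filter(img, params.smooth_sigma)
    thresh = filters.threshold_otsu(smooth)
    mask = smooth > thresh
    if not mask.any() or mask.all():
        return None
    bg = smooth[~mask]
    contrast = smooth[mask].mean() - bg.mean()
    if contrast < params.contrast_snr * max(bg.std(), 1e-12):
        return None
    return mask


def count_nuclei(
    nuclei_channel: np.ndarray, params: QuantParams | None = None
) -> tuple[int, list[tuple[float, float]], bool]:
    """Count nuclei; returns (count, centroids, blank_flag).

    Touching nuclei are separated by watershed on the smoothed distance
    transform seeded at local maxima at least ``separation_min_distance``
    apart.
    """
    params = params or QuantParams()
    if _is_blank(nuclei_channel):
        return 0, [], True
    mask = _foreground_mask(nuclei_channel, params)
    if mask is None:
        return 0, [], False
    mask = ndimage.binary_fill_holes(mask)
    mask = morphology.remove_small_objects(mask, max_size=params.nucleus_min_area - 1)
    if not mask.any():
        return 0, [], False

    distance = ndimage.gaussian_filter(ndimage.distance_transform_edt(mask), 1.0)
    peaks = feature.peak_local_max(
        distance, min_distance=params.separation_min_distance,
        labels=mask, exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=int)
    for k, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = k
    if markers.max() == 0:
        labels = measure.label(mask)
    else:
        labels = segmentation.watershed(-distance, markers, mask=mask)

    centroids = []
    for region in measure.regionprops(labels):
        if params.nucleus_min_area <= region.area <= params.nucleus_max_area:
            centroids.append(tuple(region.centroid))
    return len(centroids), centroids, False


def _diffuse_amplitude(gfp: np.ndarray, params: QuantParams) -> float | None:
    """Median above-background amplitude of the diffuse-GFP foreground."""
    mask = _foreground_mask(gfp, params)
    if mask is None:
        return None
    background = float(np.median(gfp[~mask]))
    return float(np.median(gfp[mask]) - background)


def detect_aggregates(
    gfp_channel: np.ndarray,
    params: QuantParams | None = None,
    threshold_abs: float | None = None,
) -> tuple[int, list[tuple[float, float]], bool]:
    """Count bright compact aggregates; returns (count, centroids, blank).

    A white top-hat with a structuring element larger than an aggregate but
    smaller than a cell isolates compact spots; spots must exceed
    ``aggregate_min_contrast`` times the estimated diffuse-GFP amplitude
    (or ``threshold_abs`` when given) and pass the area filter. Fields with
    diffuse signal only therefore yield zero.
    """
    params = params or QuantParams()
    if _is_blank(gfp_channel):
        return 0, [], True
    if threshold_abs is None:
        diffuse = _diffuse_amplitude(gfp_channel, params)
        if diffuse is None or diffuse <= 0:
            return 0, [], False
        threshold_abs = params.aggregate_min_contrast * diffuse

    smooth = ndimage.gaussian_filter(gfp_channel, params.smooth_sigma)
    tophat = morphology.white_tophat(
        smooth, morphology.disk(params.aggregate_tophat_radius)
    )
    mask = tophat > threshold_abs
    mask = morphology.remove_small_objects(mask, max_size=params.aggregate_min_area - 1)
    labels = measure.label(mask)
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for region in measure.regionprops(labels):
        keep[region.label] = (
            params.aggregate_min_area <= region.area <= params.aggregate_max_area
        )
    labels[~keep[labels]] = 0
    if labels.max() == 0:
        return 0, [], False
    # spots close enough to share a thresholded blob are split on their maxima
    peaks = feature.peak_local_max(
        tophat, min_distance=params.aggregate_peak_min_distance,
        labels=labels, exclude_border=False,
    )
    centroids = [(float(y), float(x)) for y, x in peaks]
    return len(centroids), centroids, False


def quantify_field(img: FieldImage, params: QuantParams | None = None) -> FieldQuant:
    params = params or QuantParams()
    n_cells, _, blank_n = count_nuclei(img.nuclei_channel, params)
    n_agg, _, blank_g = detect_aggregates(img.gfp_channel, params)
    pct = 100.0 * n_agg / n_cells if n_cells > 0 else None
    return FieldQuant(img.field_id, n_cells, n_agg, pct, blank=blank_n and blank_g)


def quantify_well(
    fields: list[FieldImage], params: QuantParams | None = None
) -> WellQuant:
    """Quantify every field of a well and average the per-field percentages.

    Fields with zero detected cells have an undefined percentage and are
    excluded from the mean. A warning is recorded when the number of fields
    differs from the expected count (default 5) or when the whole well is
    blank.
    """
    params = params or QuantParams()
    if not fields:
        raise ValueError("a well needs at least one field")
    well_id = fields[0].well_id
    wq = WellQuant(well_id=well_id)
    for img in fields:
        wq.fields.append(quantify_field(img, params))
    if wq.n_fields != params.expected_fields_per_well:
        wq.warnings.append(
            f"{well_id}: {wq.n_fields} fields, expected "
            f"{params.expected_fields_per_well}"
        )
    if wq.all_blank:
        wq.warnings.append(f"{well_id}: all fields blank or cell-free; excluded")
    return wq
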