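"""Synaptic immunopuncta quantification and object-based colocalization.

Each two-channel field (presynaptic and postsynaptic markers) is reduced
to: per-channel punctum count and area fraction (protein expression
level), the number of co-labeled puncta from the pixelwise AND of the two
binary masks (excitatory-synapse proxy), synapse density per µm³ of
optical section, and the percentage of each channel's puncta that belong
to co-labeled sites.  Direction verdicts on count and area changes map to
a biological label: concordant changes read as true expression changes,
area-only changes as growth/shrinkage of pre-existing clusters, and
count-only changes as dispersion or aggregation of a fixed protein pool.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology, segmentation
import tifffile

__all__ = [
    "ImageField",
    "PunctaSet",
    "ColocalizationResult",
    "ExpressionChangeLabel",
    "preprocess_channel",
    "segment_puncta",
    "colocalize",
    "synapse_density",
    "percent_participation",
    "classify_expression_change",
    "quantify_field",
    "write_image_field",
    "read_image_field",
]


@dataclass
class ImageField:
    """One two-channel optical section with its acquisition geometry."""

    channels: np.ndarray  # (2, H, W); index 0 presynaptic, 1 postsynaptic
    pixel_size_um: float
    optical_thickness_um: float
    field_id: str = "field"
    channel_labels: tuple[str, str] = ("presynaptic", "postsynaptic")

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3 or self.channels.shape[0] != 2:
            raise ValueError("channels must be a (2, H, W) array")
        if self.pixel_size_um <= 0 or self.optical_thickness_um <= 0:
            raise ValueError("pixel size and optical thickness must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    @property
    def area_um2(self) -> float:
        h, w = self.shape
        return h * w * self.pixel_size_um**2


@dataclass
class PunctaSet:
    """Segmented puncta of one channel."""

    mask: np.ndarray  # bool, size-filtered
    labels: np.ndarray  # int32 labels matching mask
    puncta: list[tuple[int, tuple[float, float], int]]  # (label, centroid, area px)
    count: int
    area_fraction_pct: float
    saturated: bool = False


def preprocess_channel(
    image: np.ndarray, background_radius_px: int = 15, median_size_px: int = 3
) -> np.ndarray:
    """Background subtraction (rolling-ball equivalent) plus median filtering.

    The background is a grayscale morphological opening with a disk wider
    than any punctum, so spots are removed from the background estimate but
    smooth shading survives and is subtracted.  The median filter then
    knocks out single-pixel noise.  Output is non-negative float.
    """
    img = np.asarray(image, dtype=float)
    if median_size_px % 2 != 1:
        raise ValueError("median_size_px must be odd")
    if min(img.shape) <= 2 * background_radius_px:
        raise ValueError("background kernel larger than the image")
    bg = morphology.opening(img, morphology.disk(background_radius_px))
    out = np.clip(img - bg, 0.0, None)
    out = ndi.median_filter(out, size=median_size_px)
    return out


def segment_puncta(
    image: np.ndarray,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
    min_area_px: int = 4,
    max_area_px: int | None = None,
    split_touching: bool = True,
) -> PunctaSet:
    """Threshold a preprocessed channel and label discrete puncta.

    Otsu by default (a fixed value via ``threshold_method='fixed'`` keeps
    thresholds comparable across fields); touching blobs are separated by a
    watershed seeded at intensity peaks; components outside
    ``[min_area_px, max_area_px]`` are discarded.  An empty mask is a valid
    zero-count result, not an error.
    """
    img = np.asarray(image, dtype=float)
    saturated = False
    if img.max() == img.min():
        warnings.warn("flat (all-equal) channel; returning empty puncta set")
        mask = np.zeros(img.shape, bool)
    else:
        if threshold_method == "otsu":
            thr = filters.threshold_otsu(img)
        elif threshold_method == "fixed":
            if threshold_value is None:
                raise ValueError("fixed thresholding needs threshold_value")
            thr = threshold_value
        else:
            raise ValueError(f"unknown threshold method: {threshold_method!r}")
        mask = img > thr
        if np.mean(img >= img.max()) > 0.05:
            saturated = True
            warnings.warn("channel looks saturated; counts may be unreliable")

    if split_touching and mask.any():
        peaks = feature.peak_local_max(
            img, min_distance=3, labels=measure.label(mask), exclude_border=False
        )
        markers = np.zeros(img.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = segmentation.watershed(-img, markers, mask=mask)
    else:
        labels = measure.label(mask)

    keep = np.zeros(labels.max() + 1, dtype=bool)
    puncta = []
    for rp in measure.regionprops(labels):
        if rp.area < min_area_px:
            continue
        if max_area_px is not None and rp.area > max_area_px:
            continue
        keep[rp.label] = True
        puncta.append((rp.label, (rp.centroid[0], rp.centroid[1]), int(rp.area)))
    filtered = np.where(keep[labels], labels, 0)
    fmask = filtered > 0
    return PunctaSet(
        mask=fmask,
        labels=filtered,
        puncta=puncta,
        count=len(puncta),
        area_fraction_pct=100.0 * float(fmask.mean()),
        saturated=saturated,
    )


@dataclass
class ColocalizationResult:
    """Co-labeled puncta from the AND of two channel masks."""

    and_mask: np.ndarray
    co_labeled_count: int
    synapse_density_per_um3: float = float("nan")
    percent_participation_pre: float = float("nan")
    percent_participation_post: float = float("nan")


def colocalize(
    pre: PunctaSet, post: PunctaSet, min_overlap_px: int = 1
) -> ColocalizationResult:
    """Count connected components of the pixelwise AND of the two masks.

    Components smaller than ``min_overlap_px`` pixels are ignored (the
    plain AND operation corresponds to the default of 1).
    """
    if pre.mask.shape != post.mask.shape:
        raise ValueError("channel masks have different dimensions")
    and_mask = pre.mask & post.mask
    lab, n = measure.label(and_mask, return_num=True)
    if min_overlap_px > 1 and n:
        areas = np.bincount(lab.ravel())[1:]
        n = int(np.sum(areas >= min_overlap_px))
        small = np.flatnonzero(np.bincount(lab.ravel()) < min_overlap_px)
        and_mask = and_mask & ~np.isin(lab, small[small > 0])
    return ColocalizationResult(and_mask=and_mask, co_labeled_count=int(n))


def synapse_density(co_labeled_count: int, field: ImageField) -> float:
    """Synapses per µm³: count over field area times optical-section thickness."""
    volume = field.area_um2 * field.optical_thickness_um
    if volume <= 0:
        raise ValueError("field geometry metadata missing or invalid")
    return co_labeled_count / volume


def percent_participation(co_labeled_count: int, channel_count: int) -> float:
    """Share of a channel's puncta that sit in co-labeled (synaptic) sites.

    Undefined (NaN) when the channel detected no puncta.
    """
    if channel_count < 0:
        raise ValueError("channel_count must be non-negative")
    if channel_count == 0:
        warnings.warn("channel has zero puncta; participation undefined")
        return float("nan")
    return 100.0 * co_labeled_count / channel_count


class ExpressionChangeLabel(str, enum.Enum):
    EXPRESSION_INCREASE = "expression_increase"
    EXPRESSION_DECREASE = "expression_decrease"
    INCREASE_WITHIN_EXISTING_CLUSTERS = "increase_within_existing_clusters"
    DECREASE_WITHIN_EXISTING_CLUSTERS = "decrease_within_existing_clusters"
    DISPERSION = "dispersion"
    AGGREGATION = "aggregation"
    NO_CHANGE = "no_change"
    INDETERMINATE = "indeterminate"


_EXPRESSION_MAP = {
    ("up", "up"): ExpressionChangeLabel.EXPRESSION_INCREASE,
    ("down", "down"): ExpressionChangeLabel.EXPRESSION_DECREASE,
    ("ns", "up"): ExpressionChangeLabel.INCREASE_WITHIN_EXISTING_CLUSTERS,
    ("ns", "down"): ExpressionChangeLabel.DECREASE_WITHIN_EXISTING_CLUSTERS,
    ("up", "ns"): ExpressionChangeLabel.DISPERSION,
    ("down", "ns"): ExpressionChangeLabel.AGGREGATION,
    ("ns", "ns"): ExpressionChangeLabel.NO_CHANGE,
    ("up", "down"): ExpressionChangeLabel.INDETERMINATE,
    ("down", "up"): ExpressionChangeLabel.INDETERMINATE,
}


def classify_expression_change(
    count_direction: str, area_direction: str
) -> ExpressionChangeLabel:
    """Map (immunopunctum-count change, area change) to a biological reading.

    Concordant significant changes confirm a change in expression level; an
    area-only change means the level changed inside pre-existing clusters;
    more puncta over the same area means dispersion of the protein pool,
    fewer puncta aggregation; opposing significant directions are
    indeterminate.
    """
    key = (count_direction, area_direction)
    if key not in _EXPRESSION_MAP:
        raise ValueError(f"directions must be 'up'/'down'/'ns', got {key}")
    return _EXPRESSION_MAP[key]


@dataclass
class FieldQuantification:
    """Flat per-field record combining both channels and the colocalization."""

    field_id: str
    count_pre: int
    count_post: int
    area_fraction_pre_pct: float
    area_fraction_post_pct: float
    co_labeled_count: int
    density_per_um3: float
    participation_pre_pct: float
    participation_post_pct: float


def quantify_field(
    field: ImageField,
    background_radius_px: int = 15,
    median_size_px: int = 3,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
    min_area_px: int = 4,
    max_area_px: int | None = None,
    min_overlap_px: int = 1,
    split_touching: bool = True,
) -> FieldQuantification:
    """Run the full per-field chain: preprocess, segment, colocalize, convert."""
    sets = []
    for ch in field.channels:
        pp = preprocess_channel(ch, background_radius_px, median_size_px)
        sets.append(
            segment_puncta(
                pp, threshold_method, threshold_value, min_area_px, max_area_px,
                split_touching,
            )
        )
    pre, post = sets
    coloc = colocalize(pre, post, min_overlap_px)
    n = coloc.co_labeled_count
    return FieldQuantification(
        field_id=field.field_id,
        count_pre=pre.count,
        count_post=post.count,
        area_fraction_pre_pct=pre.area_fraction_pct,
        area_fraction_post_pct=post.area_fraction_pct,
        co_labeled_count=n,
        density_per_um3=synapse_density(n, field),
        participation_pre_pct=percent_participation(n, pre.count),
        participation_post_pct=percent_participation(n, post.count),
    )


# ---------------------------------------------------------------------------
# file I/O: multi-channel TIFF + YAML sidecar
# ---------------------------------------------------------------------------

def write_image_field(field: ImageField, path: str | Path) -> None:
    """Write a (2, H, W) TIFF plus a YAML sidecar with the geometry."""
    path = Path(path)
    tifffile.imwrite(path, field.channels.astype(np.float32))
    sidecar = {
        "pixel_size_um": field.pixel_size_um,
        "optical_thickness_um": field.optical_thickness_um,
        "channel_labels": list(field.channel_labels),
        "field_id": field.field_id,
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)


def read_image_field(path: str | Path) -> ImageField:
    path = Path(path)
    channels = tifffile.imread(path)
    with open(path.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    return ImageField(
        channels=channels,
        pixel_size_um=float(meta["pixel_size_um"]),
        optical_thickness_um=float(meta["optical_thickness_um"]),
        field_id=str(meta.get("field_id", path.stem)),
        channel_labels=tuple(meta.get("channel_labels", ("presynaptic", "postsynaptic"))),
    )
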