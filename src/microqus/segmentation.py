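"""Digital segmentation of the mucosa/submucosa ROI from a B-scan.

The algorithm: detect the envelope, express it in dB relative to the
brightest pixel of the whole scan, keep everything above an empirical
-26 dB threshold, clean the binary mask with a morphological closing, keep
the largest connected echo region, and zero the RF outside it. A variable
thickness sub-segmentation retains only the top ``thickness`` mm of the ROI
on each A-line, which is how impedance-versus-thickness curves are built.

Conventions (all configurable): the threshold comparison is inclusive
(>= threshold); components are labelled with 8-connectivity; the closing
uses an elliptical structuring element of radius 3 samples (axial) by
2 lines (lateral); depth is sample_index * c_assumed / (2 fs) from the
image top, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_closing
from scipy.signal import hilbert
from skimage.measure import label as _label

from .synth.bscan import BScan

DEFAULT_THRESHOLD_DB = -26.0
DEFAULT_CLOSING_RADIUS = (2, 3)  # (lateral lines, axial samples)


@dataclass(frozen=True)
class EnvelopeImage:
    """Log-compressed envelope of a B-scan, 0 dB at the brightest pixel."""

    db: np.ndarray = field(repr=False)
    sampling_rate: float
    line_pitch: float
    sound_speed_assumed: float
    depth_origin: float

    def __post_init__(self) -> None:
        db = np.asarray(self.db, dtype=float)
        if db.ndim != 2:
            raise ValueError("db must be 2-D")
        if not np.isclose(np.nanmax(db[np.isfinite(db)]), 0.0):
            raise ValueError("db must be normalized to a 0 dB maximum")
        object.__setattr__(self, "db", db)


@dataclass(frozen=True)
class ROIMask:
    """Single connected echo region with its depth bookkeeping.

    ``d1``/``d2`` are the minimum and maximum depths (mm) of the region over
    the whole mask; ``per_line_depths`` holds (top, bottom) mm per A-line,
    NaN pairs where the line has no ROI.
    """

    mask: np.ndarray = field(repr=False)
    region_count_before_selection: int
    d1: float
    d2: float
    per_line_depths: np.ndarray = field(repr=False)  # (n_lines, 2) mm
    sampling_rate: float
    line_pitch: float
    sound_speed_assumed: float
    depth_origin: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if self.d1 > self.d2:
            raise ValueError("d1 must be <= d2")

    @property
    def n_lines(self) -> int:
        return self.mask.shape[0]


@dataclass(frozen=True)
class SegmentedScan:
    """RF with everything outside the ROI zeroed."""

    rf_masked: np.ndarray = field(repr=False)
    mask: ROIMask
    source: BScan

    def __post_init__(self) -> None:
        if self.rf_masked.shape != self.source.rf.shape:
            raise ValueError("rf_masked and source shapes differ")


def compute_envelope(scan: BScan) -> EnvelopeImage:
    """Per-line analytic-signal magnitude in dB relative to the global max.

    Raises
    ------
    ValueError
        If the scan is all zero (no brightest echo exists).
    """
    env = np.abs(hilbert(scan.rf, axis=1))
    peak = env.max()
    if peak == 0:
        raise ValueError("all-zero scan: no brightest echo to normalize against")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / peak)
    return EnvelopeImage(
        db=db,
        sampling_rate=scan.sampling_rate,
        line_pitch=scan.line_pitch,
        sound_speed_assumed=scan.sound_speed_assumed,
        depth_origin=scan.depth_origin,
    )


def threshold_mask(env: EnvelopeImage, threshold_db: float = DEFAULT_THRESHOLD_DB) -> np.ndarray:
    """Boolean mask of pixels at or above ``threshold_db`` (inclusive)."""
    if threshold_db >= 0:
        raise ValueError("threshold_db must be negative (relative to the brightest echo)")
    return env.db >= threshold_db


def _elliptical_footprint(radius_lines: int, radius_samples: int) -> np.ndarray:
    ry, rx = radius_lines, radius_samples
    y, x = np.ogrid[-ry : ry + 1, -rx : rx + 1]
    return (y / max(ry, 1)) ** 2 + (x / max(rx, 1)) ** 2 <= 1.0


def clean_mask(mask: np.ndarray, closing_radius=DEFAULT_CLOSING_RADIUS) -> np.ndarray:
    """Morphological closing with an elliptical structuring element.

    ``closing_radius`` is (lateral lines, axial samples); radius (0, 0) is
    the identity. The input is padded before closing so the operation stays
    extensive (output is a superset of the input) at the image borders.
    """
    mask = np.asarray(mask, dtype=bool)
    ry, rx = closing_radius
    if ry < 0 or rx < 0:
        raise ValueError("closing radii must be >= 0")
    if ry == 0 and rx == 0:
        return mask.copy()
    fp = _elliptical_footprint(ry, rx)
    padded = np.pad(mask, ((ry, ry), (rx, rx)), mode="constant", constant_values=False)
    closed = binary_closing(padded, structure=fp)
    out = closed[ry : ry + mask.shape[0], rx : rx + mask.shape[1]]
    # closing is extensive; keep that guarantee explicit
    return out | mask


def select_largest_region(
    mask: np.ndarray,
    *,
    sampling_rate: float,
    line_pitch: float,
    sound_speed_assumed: float = 1540.0,
    depth_origin: float = 0.0,
    connectivity: int = 2,
) -> ROIMask:
    """Keep the largest connected component and record depth geometry.

    Connectivity 2 (8-neighbour) by default. Ties are broken toward the
    lowest label, which scanning order makes deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no echo region to select")
    labels, n_regions = _label(mask, connectivity=connectivity, return_num=True)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = int(np.argmax(sizes))
    selected = labels == keep

    dz = sound_speed_assumed / (2.0 * sampling_rate) * 1e3  # mm per sample
    rows, cols = np.nonzero(selected)
    d1 = depth_origin + cols.min() * dz
    d2 = depth_origin + cols.max() * dz
    per_line = np.full((mask.shape[0], 2), np.nan)
    for j in np.unique(rows):
        c = cols[rows == j]
        per_line[j] = (depth_origin + c.min() * dz, depth_origin + c.max() * dz)

    return ROIMask(
        mask=selected,
        region_count_before_selection=int(n_regions),
        d1=float(d1),
        d2=float(d2),
        per_line_depths=per_line,
        sampling_rate=sampling_rate,
        line_pitch=line_pitch,
        sound_speed_assumed=sound_speed_assumed,
        depth_origin=depth_origin,
    )


def apply_mask(scan: BScan, roi: ROIMask) -> SegmentedScan:
    """Zero the RF outside the ROI; inside values are untouched."""
    if roi.mask.shape != scan.rf.shape:
        raise ValueError(
            f"mask shape {roi.mask.shape} does not match scan shape {scan.rf.shape}"
        )
    rf_masked = np.where(roi.mask, scan.rf, 0.0)
    return SegmentedScan(rf_masked=rf_masked, mask=roi, source=scan)


def segment_roi(
    scan: BScan,
    threshold_db: float = DEFAULT_THRESHOLD_DB,
    closing_radius=DEFAULT_CLOSING_RADIUS,
    connectivity: int = 2,
) -> SegmentedScan:
    """Full segmentation: envelope -> threshold -> closing -> largest region -> mask."""
    env = compute_envelope(scan)
    raw = threshold_mask(env, threshold_db)
    cleaned = clean_mask(raw, closing_radius)
    roi = select_largest_region(
        cleaned,
        sampling_rate=scan.sampling_rate,
        line_pitch=scan.line_pitch,
        sound_speed_assumed=scan.sound_speed_assumed,
        depth_origin=scan.depth_origin,
        connectivity=connectivity,
    )
    return apply_mask(scan, roi)


def sub_segment_by_thickness(segmented: SegmentedScan, thickness: float) -> SegmentedScan:
    """Retain, per line, the ROI from its top surface down to ``thickness`` mm.

    Lines whose ROI is thinner than ``thickness`` keep their full ROI. The
    top surface sample is always retained (the thickness -> 0 limit).
    """
    if thickness <= 0:
        raise ValueError("thickness must be > 0")
    roi = segmented.mask
    scan = segmented.source
    dz = roi.sound_speed_assumed / (2.0 * roi.sampling_rate) * 1e3
    n_keep = max(int(np.floor(thickness / dz)) + 1, 1)  # samples from the top surface

    new_mask = np.zeros_like(roi.mask)
    for j in range(roi.mask.shape[0]):
        cols = np.nonzero(roi.mask[j])[0]
        if cols.size == 0:
            continue
        top = cols.min()
        keep = cols[cols < top + n_keep]
        new_mask[j, keep] = True

    dz_origin = roi.depth_origin
    rows, cols = np.nonzero(new_mask)
    per_line = np.full_like(roi.per_line_depths, np.nan)
    for j in np.unique(rows):
        c = cols[rows == j]
        per_line[j] = (dz_origin + c.min() * dz, dz_origin + c.max() * dz)
    new_roi = ROIMask(
        mask=new_mask,
        region_count_before_selection=roi.region_count_before_selection,
        d1=float(dz_origin + cols.min() * dz),
        d2=float(dz_origin + cols.max() * dz),
        per_line_depths=per_line,
        sampling_rate=roi.sampling_rate,
        line_pitch=roi.line_pitch,
        sound_speed_assumed=roi.sound_speed_assumed,
        depth_origin=roi.depth_origin,
    )
    return apply_mask(scan, new_roi)
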