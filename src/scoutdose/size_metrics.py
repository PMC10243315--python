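"""Patient-size surrogates from axial slices and localizer radiographs.

The gold-standard water-equivalent area of an axial slice is

    A_W = (mean CT / 1000 + 1) · A_ROI,        WED = 2·sqrt(A_W / π),

with CT in Hounsfield units and A_ROI the area of the region of interest.
Air contributes exactly zero (CT = −1000), so a full-image ROI and a tight
body mask agree on noiseless data — the default ROI is the full image with
the couch removed.  Geometric surrogates (AP, LAT extents and the effective
diameter ED = sqrt(AP·LAT)) come from a thresholded body mask on axial data,
or from the thresholded object width on the localizer after divergent-beam
demagnification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .dicom_io import AxialSeries, AxialSlice, LocalizerImage

__all__ = [
    "RegionMask",
    "WaterEquivalentResult",
    "SizeProfile",
    "LocalizerProfile",
    "water_equivalent_area",
    "wed_from_area",
    "body_mask",
    "scan_size_profile",
    "localizer_profile",
    "ed_from_localizer",
    "mask_to_png",
]


@dataclass
class RegionMask:
    """Binary ROI aligned to an axial slice."""

    mask: np.ndarray
    pixel_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.pixel_spacing[0] * self.pixel_spacing[1]


@dataclass(frozen=True)
class WaterEquivalentResult:
    a_w_mm2: float
    wed_mm: float
    z_mm: float


def wed_from_area(a_w_mm2: float) -> float:
    """Water-equivalent diameter of a disk with area ``a_w_mm2``."""
    if a_w_mm2 < 0:
        raise ValueError("water-equivalent area must be non-negative")
    return 2.0 * math.sqrt(a_w_mm2 / math.pi)


def water_equivalent_area(
    slice_: AxialSlice, mask: RegionMask | None = None
) -> WaterEquivalentResult:
    """A_W of one slice over a ROI (full image when ``mask`` is None).

    Whether automatic exposure control was on cannot change this contract:
    only the HU values and the ROI area enter.  Tiny negative areas from
    noise in an all-air ROI clamp to zero.
    """
    if mask is None:
        roi = np.ones(slice_.hu.shape, dtype=bool)
    else:
        if mask.mask.shape != slice_.hu.shape:
            raise ValueError("mask is not aligned with the slice")
        roi = mask.mask
    if not roi.any():
        raise ValueError("empty ROI mask")
    mean_ct = float(slice_.hu[roi].mean())
    a_roi = float(roi.sum()) * slice_.pixel_area_mm2
    a_w = max((mean_ct / 1000.0 + 1.0) * a_roi, 0.0)
    return WaterEquivalentResult(a_w, wed_from_area(a_w), slice_.z_mm)


def body_mask(
    slice_: AxialSlice,
    threshold_hu: float = -300.0,
    remove_couch: bool = True,
) -> RegionMask:
    """Threshold foreground; with couch removal keep the largest component.

    −300 HU sits between lung and soft tissue, so lungs stay inside the body
    component while the air gap isolates any couch structure.
    """
    fg = slice_.hu >= threshold_hu
    if not fg.any():
        raise ValueError(f"no pixel at or above {threshold_hu} HU")
    if remove_couch:
        labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
        if n > 1:
            sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
            fg = labels == (1 + int(np.argmax(sizes)))
    # lungs are below threshold: fill holes so AP/LAT extents see the body outline
    fg = ndimage.binary_fill_holes(fg)
    return RegionMask(fg, slice_.pixel_spacing)


@dataclass
class SizeProfile:
    """Per-z size surrogates plus their scan means.

    Entries may be NaN where a surrogate is undefined for the source (e.g. no
    WED for a purely geometric localizer profile); scan means are arithmetic
    means over the defined entries.
    """

    z_mm: np.ndarray
    wed_mm: np.ndarray
    ed_mm: np.ndarray
    ap_mm: np.ndarray
    lat_mm: np.ndarray
    source: str  # "axial" | "localizer"
    extrapolated: np.ndarray | None = None
    clamped: np.ndarray | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        self.z_mm = np.asarray(self.z_mm, dtype=np.float64)
        for name in ("wed_mm", "ed_mm", "ap_mm", "lat_mm"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != self.z_mm.shape:
                raise ValueError(f"{name} does not match z")
            setattr(self, name, arr)

    @property
    def mean_wed_mm(self) -> float:
        return float(np.nanmean(self.wed_mm))

    @property
    def mean_ed_mm(self) -> float:
        return float(np.nanmean(self.ed_mm))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "z_mm": self.z_mm,
                "wed_mm": self.wed_mm,
                "ed_mm": self.ed_mm,
                "ap_mm": self.ap_mm,
                "lat_mm": self.lat_mm,
            }
        )
        df["source"] = self.source
        if self.extrapolated is not None:
            df["extrapolated"] = self.extrapolated
        if self.clamped is not None:
            df["clamped"] = self.clamped
        return df


def _mask_extents(mask: RegionMask) -> tuple[float, float]:
    rows = np.flatnonzero(mask.mask.any(axis=1))
    cols = np.flatnonzero(mask.mask.any(axis=0))
    ap = (rows[-1] - rows[0] + 1) * mask.pixel_spacing[0]
    lat = (cols[-1] - cols[0] + 1) * mask.pixel_spacing[1]
    return float(ap), float(lat)


def scan_size_profile(
    series: AxialSeries,
    roi_policy: str = "full",
    threshold_hu: float = -300.0,
    remove_couch: bool = True,
) -> SizeProfile:
    """Per-slice WED, AP, LAT, ED over a series, plus scan means.

    ``roi_policy`` selects the A_W region: ``"full"`` uses the whole
    reconstructed image (air contributes ~0), ``"body"`` the thresholded body
    mask.  AP/LAT are the body-mask extents along image rows/columns either
    way, and ED = sqrt(AP·LAT).
    """
    if roi_policy not in ("full", "body"):
        raise ValueError(f"unknown ROI policy {roi_policy!r}")
    z, wed, ed, ap, lat = [], [], [], [], []
    for sl in series:
        bm = body_mask(sl, threshold_hu, remove_couch)
        if roi_policy == "body":
            res = water_equivalent_area(sl, bm)
        elif remove_couch:
            # full-image ROI, couch pixels blanked to air so they do not count
            keep = sl.hu.copy()
            fg = sl.hu >= threshold_hu
            couch_px = fg & ~bm.mask
            if couch_px.any():
                keep[couch_px] = -1000
                res = water_equivalent_area(
                    AxialSlice(keep, sl.pixel_spacing, sl.z_mm, sl.kv, sl.scanner_model)
                )
            else:
                res = water_equivalent_area(sl)
        else:
            res = water_equivalent_area(sl)
        a, l = _mask_extents(bm)
        z.append(sl.z_mm)
        wed.append(res.wed_mm)
        ap.append(a)
        lat.append(l)
        ed.append(math.sqrt(a * l))
    return SizeProfile(
        z_mm=np.array(z),
        wed_mm=np.array(wed),
        ed_mm=np.array(ed),
        ap_mm=np.array(ap),
        lat_mm=np.array(lat),
        source="axial",
    )


@dataclass
class LocalizerProfile:
    """Row-mean pixel values (PPV̄) of a localizer with their z coordinates."""

    ppv: np.ndarray
    z_mm: np.ndarray

    def __post_init__(self) -> None:
        self.ppv = np.asarray(self.ppv, dtype=np.float64)
        self.z_mm = np.asarray(self.z_mm, dtype=np.float64)
        if self.ppv.shape != self.z_mm.shape:
            raise ValueError("ppv and z must match")


def localizer_profile(
    localizer: LocalizerImage, rows: Sequence[int] | None = None
) -> LocalizerProfile:
    """Arithmetic mean of each full localizer row (air included; a linear
    calibration's intercept absorbs the constant offset)."""
    if rows is None:
        idx = np.arange(localizer.n_rows)
    else:
        idx = np.asarray(list(rows), dtype=int)
        if idx.size == 0:
            raise ValueError("empty row range")
        if idx.min() < 0 or idx.max() >= localizer.n_rows:
            raise ValueError("row range outside the localizer image")
    ppv = localizer.pixels[idx].astype(np.float64).mean(axis=1)
    z = localizer.top_z_mm - idx * localizer.row_spacing_mm
    return LocalizerProfile(ppv=ppv, z_mm=z)


def ed_from_localizer(
    localizer: LocalizerImage,
    geometry,
    aspect_ratio: float = 0.75,
    rel_threshold: float = 0.05,
    rows: Sequence[int] | None = None,
) -> SizeProfile:
    """Geometric size surrogates from the localizer object width.

    Per row, LAT is the thresholded object width at the detector scaled by
    SAD/SID (divergent-beam demagnification; unity for parallel geometry);
    AP = aspect_ratio · LAT stands in for the unavailable lateral view, and
    ED = sqrt(AP·LAT).  The threshold sits ``rel_threshold`` of the image
    dynamic range above background.  Rows whose object touches the edge of
    the field of view mark the profile as truncated.
    """
    if not 0 < rel_threshold < 1:
        raise ValueError("relative threshold must be in (0, 1)")
    if aspect_ratio <= 0:
        raise ValueError("aspect ratio must be positive")
    img = localizer.pixels.astype(np.float64)
    background, peak = float(img.min()), float(img.max())
    if peak <= background:
        raise ValueError("localizer contains no object above background")
    threshold = background + rel_threshold * (peak - background)
    idx = np.arange(localizer.n_rows) if rows is None else np.asarray(list(rows), dtype=int)
    if idx.size == 0:
        raise ValueError("empty row range")
    demag = geometry.sad_mm / geometry.sid_mm if geometry.beam == "fan" else 1.0
    lat = np.full(idx.shape, np.nan)
    truncated = bool(localizer.truncated)
    for k, r in enumerate(idx):
        above = np.flatnonzero(img[r] >= threshold)
        if above.size == 0:
            continue
        width_det = (above[-1] - above[0] + 1) * localizer.col_spacing_mm
        lat[k] = width_det * demag
        if above[0] == 0 or above[-1] == localizer.n_cols - 1:
            truncated = True
    ap = aspect_ratio * lat
    return SizeProfile(
        z_mm=localizer.top_z_mm - idx * localizer.row_spacing_mm,
        wed_mm=np.full(idx.shape, np.nan),
        ed_mm=np.sqrt(ap * lat),
        ap_mm=ap,
        lat_mm=lat,
        source="localizer",
        truncated=truncated,
    )


def mask_to_png(mask: RegionMask, path) -> None:
    """Export a mask as an 8-bit PNG for visual QA (requires pillow)."""
    from PIL import Image

    Image.fromarray((mask.mask * 255).astype(np.uint8)).save(path)
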