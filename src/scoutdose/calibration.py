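"""Per-scanner, per-kV calibration between localizer profiles and A_W.

A localizer row at position z is a projection of the same anatomy the axial
slice at z reconstructs.  The product of the row-mean pixel value (PPV̄) and
the field-of-view width FOV_X tracks the total object attenuation, i.e. the
axial water-equivalent area A_W at that z (Toth's relation).  Because
localizer pixel values are scanner- and kV-specific rather than absolute,
the link is established empirically: phantoms of several sizes are scanned
both ways, per-slice pairs

    (PPV̄,  R = A_W / FOV_X)

are pooled across phantoms, and an ordinary least-squares line
R = slope·PPV̄ + intercept is fitted per (scanner model, localizer kV,
axial kV).  Applying the line to a patient localizer yields per-row A_W and
hence the water-equivalent diameter before the axial scan is acquired.  The
fit inverts any affine pixel response exactly: a change of offset moves only
the intercept, a change of gain scales the slope by 1/gain.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dicom_io import AxialSeries, LocalizerImage, map_z_to_row
from .size_metrics import (
    LocalizerProfile,
    SizeProfile,
    localizer_profile,
    scan_size_profile,
    water_equivalent_area,
    body_mask,
)

log = logging.getLogger(__name__)

__all__ = [
    "CalibrationPoint",
    "CalibrationModel",
    "CalibrationStore",
    "collect_calibration_points",
    "fit_calibration",
    "apply_calibration",
    "localizer_wed",
    "compare_localizer_to_axial",
    "save_calibration",
    "load_calibration",
    "points_to_frame",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One paired observation: PPV̄ at a localizer row and R = A_W/FOV_X of
    the axial slice mapped to that row."""

    ppv: float
    r_mm: float
    phantom_label: str
    z_mm: float

    def __post_init__(self) -> None:
        if self.r_mm < 0:
            raise ValueError("R = A_W/FOV_X must be non-negative")


@dataclass(frozen=True)
class CalibrationModel:
    """Line of best fit R = slope·PPV̄ + intercept for one scanner and kV pair."""

    scanner_model: str
    localizer_kv: float
    axial_kv: float
    slope: float  # mm per localizer unit
    intercept: float  # mm
    r_squared: float
    ppv_range: tuple[float, float]
    n_points: int
    phantom_labels: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, float, float]:
        return (self.scanner_model, self.localizer_kv, self.axial_kv)

    def predict_area(self, ppv, fov_x_mm: float):
        """Predicted A_W (mm²) for profile values ``ppv`` at a given FOV_X."""
        return (self.slope * np.asarray(ppv, dtype=np.float64) + self.intercept) * fov_x_mm

    def to_dict(self) -> dict:
        return {
            "scanner_model": self.scanner_model,
            "localizer_kv": self.localizer_kv,
            "axial_kv": self.axial_kv,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "ppv_range": list(self.ppv_range),
            "n_points": self.n_points,
            "phantom_labels": list(self.phantom_labels),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            scanner_model=d["scanner_model"],
            localizer_kv=float(d["localizer_kv"]),
            axial_kv=float(d["axial_kv"]),
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            r_squared=float(d["r_squared"]),
            ppv_range=(float(d["ppv_range"][0]), float(d["ppv_range"][1])),
            n_points=int(d["n_points"]),
            phantom_labels=tuple(d.get("phantom_labels", ())),
            metadata=dict(d.get("metadata", {})),
        )


def collect_calibration_points(
    series: AxialSeries,
    localizer: LocalizerImage,
    phantom_label: str,
    roi_policy: str = "full",
    threshold_hu: float = -300.0,
    remove_couch: bool = True,
) -> list[CalibrationPoint]:
    """Pair each axial slice with the localizer row at the same z.

    For every slice whose z falls inside the localizer extent the pair
    (PPV̄ at the mapped row, A_W/FOV_X) becomes one calibration point.
    Slices with no overlapping z are skipped; none at all is an error, as is
    a scanner-model mismatch between the two acquisitions.
    """
    if series.scanner_model != localizer.scanner_model:
        raise ValueError(
            f"scanner mismatch: axial {series.scanner_model!r} "
            f"vs localizer {localizer.scanner_model!r}"
        )
    fov = localizer.fov_x_mm
    points: list[CalibrationPoint] = []
    for sl in series:
        try:
            row = map_z_to_row(localizer, sl.z_mm)
        except ValueError:
            continue
        if roi_policy == "body":
            res = water_equivalent_area(sl, body_mask(sl, threshold_hu, remove_couch))
        else:
            res = water_equivalent_area(sl)
        ppv = float(localizer.pixels[row].astype(np.float64).mean())
        points.append(CalibrationPoint(ppv, res.a_w_mm2 / fov, phantom_label, sl.z_mm))
    if not points:
        raise ValueError(
            "no overlapping z between axial series "
            f"[{series.z_min_mm}, {series.z_max_mm}] mm and localizer"
        )
    return points


def fit_calibration(
    points: Sequence[CalibrationPoint],
    scanner_model: str,
    localizer_kv: float,
    axial_kv: float = 120.0,
) -> CalibrationModel:
    """Ordinary least-squares line R = slope·PPV̄ + intercept.

    Requires at least 3 points spanning at least 2 distinct phantoms and a
    non-degenerate spread in PPV̄.  The valid range is the observed PPV̄
    span; applying the model outside it is flagged, not forbidden.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 calibration points")
    labels = {p.phantom_label for p in points}
    if len(labels) < 2:
        raise ValueError("need points from at least 2 distinct phantom sizes")
    x = np.array([p.ppv for p in points], dtype=np.float64)
    y = np.array([p.r_mm for p in points], dtype=np.float64)
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration set: all PPV̄ values are equal")
    slope, intercept = np.polyfit(x, y, 1)
    predicted = slope * x + intercept
    ss_res = float(np.sum((y - predicted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0:
        r_squared = 1.0 - ss_res / ss_tot
    else:
        r_squared = 1.0 if ss_res < 1e-12 else 0.0
    return CalibrationModel(
        scanner_model=scanner_model,
        localizer_kv=localizer_kv,
        axial_kv=axial_kv,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r_squared,
        ppv_range=(float(x.min()), float(x.max())),
        n_points=len(points),
        phantom_labels=tuple(sorted(labels)),
        metadata={"package_version": __version__},
    )


def apply_calibration(
    model: CalibrationModel,
    profile: LocalizerProfile,
    fov_x_mm: float,
    localizer_kv: float | None = None,
) -> SizeProfile:
    """Convert a localizer profile to per-row A_W and WED.

    Per row, A_W = (slope·PPV̄ + intercept)·FOV_X and WED = 2·sqrt(A_W/π).
    Rows outside the fitted PPV̄ range are flagged as extrapolated; negative
    predicted areas (air-only rows) clamp to zero with a warning record
    rather than failing a batch run.
    """
    if localizer_kv is not None and not math.isclose(localizer_kv, model.localizer_kv):
        raise ValueError(
            f"localizer kV {localizer_kv} does not match the calibration's "
            f"{model.localizer_kv} (scanner {model.scanner_model!r})"
        )
    a_w = model.predict_area(profile.ppv, fov_x_mm)
    clamped = a_w < 0
    if clamped.any():
        log.warning(
            "%d rows predicted negative A_W; clamped to zero", int(clamped.sum())
        )
        a_w = np.clip(a_w, 0.0, None)
    lo, hi = model.ppv_range
    extrapolated = (profile.ppv < lo) | (profile.ppv > hi)
    wed = 2.0 * np.sqrt(a_w / np.pi)
    nan = np.full(wed.shape, np.nan)
    return SizeProfile(
        z_mm=profile.z_mm,
        wed_mm=wed,
        ed_mm=nan,
        ap_mm=nan.copy(),
        lat_mm=nan.copy(),
        source="localizer",
        extrapolated=extrapolated,
        clamped=clamped,
    )


def localizer_wed(
    model: CalibrationModel,
    localizer: LocalizerImage,
    rows: Sequence[int] | None = None,
) -> SizeProfile:
    """Convenience: profile a localizer and apply a calibration in one step."""
    profile = localizer_profile(localizer, rows)
    return apply_calibration(model, profile, localizer.fov_x_mm, localizer.kv)


def compare_localizer_to_axial(
    model: CalibrationModel,
    localizer: LocalizerImage,
    series: AxialSeries,
    roi_policy: str = "full",
) -> pd.DataFrame:
    """Per-slice localizer-vs-axial WED at matched z, with % differences.

    The localizer is profiled only at the rows mapped from the axial slice
    z-locations (the scan range), so the two scan means average the same
    anatomy.  The axial value is the reference in the percentage difference.
    """
    # AxialSeries is z-sorted, so rows, loc and axial share one slice order
    rows = [map_z_to_row(localizer, sl.z_mm) for sl in series]
    loc = localizer_wed(model, localizer, rows)
    axial = scan_size_profile(series, roi_policy=roi_policy)
    df = pd.DataFrame(
        {
            "z_mm": axial.z_mm,
            "wed_axial_mm": axial.wed_mm,
            "wed_localizer_mm": loc.wed_mm,
            "ed_axial_mm": axial.ed_mm,
        }
    )
    df["pct_diff_wed"] = (
        (df["wed_localizer_mm"] - df["wed_axial_mm"]).abs() / df["wed_axial_mm"] * 100.0
    )
    return df


def points_to_frame(points: Iterable[CalibrationPoint]) -> pd.DataFrame:
    """Calibration points as a table (for export / replotting the curves)."""
    return pd.DataFrame(
        [
            {"ppv": p.ppv, "r_mm": p.r_mm, "phantom": p.phantom_label, "z_mm": p.z_mm}
            for p in points
        ]
    )


class CalibrationStore:
    """Keyed collection of calibration models with JSON persistence.

    Keys are (scanner model, localizer kV, axial kV); calibrations never
    transfer across scanners because localizer pixel values are not absolute.
    """

    FORMAT = "scoutdose-calibration-v1"

    def __init__(self, models: Iterable[CalibrationModel] = ()) -> None:
        self._models: dict[tuple[str, float, float], CalibrationModel] = {}
        for m in models:
            self.add(m)

    def __len__(self) -> int:
        return len(self._models)

    def __iter__(self):
        return iter(self._models.values())

    @property
    def keys(self) -> list[tuple[str, float, float]]:
        return sorted(self._models)

    def add(self, model: CalibrationModel, overwrite: bool = False) -> None:
        if model.key in self._models and not overwrite:
            raise ValueError(f"duplicate calibration key {model.key}")
        self._models[model.key] = model

    def get(
        self, scanner_model: str, localizer_kv: float, axial_kv: float = 120.0
    ) -> CalibrationModel:
        key = (scanner_model, float(localizer_kv), float(axial_kv))
        if key not in self._models:
            raise KeyError(
                f"no calibration for {key}; available keys: {self.keys}"
            )
        return self._models[key]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "format": self.FORMAT,
            "package_version": __version__,
            "models": [m.to_dict() for m in self._models.values()],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationStore":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != cls.FORMAT:
            raise ValueError(f"{path} is not a {cls.FORMAT} file")
        return cls(CalibrationModel.from_dict(d) for d in payload["models"])


def save_calibration(
    models: CalibrationStore | Iterable[CalibrationModel], path: str | Path
) -> Path:
    store = models if isinstance(models, CalibrationStore) else CalibrationStore(models)
    return store.save(path)


def load_calibration(path: str | Path) -> CalibrationStore:
    return CalibrationStore.load(path)
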