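"""Synthetic CT phantoms with paired axial / localizer renders.

Digital stand-ins for the objects used to calibrate localizer-based size
estimation: CTDI-style cylinders (the ~1 cm acrylic rod, 16 cm and 32 cm
PMMA phantoms), an ACR-like oval, and elliptical "patients" with optional
low-density lung inserts.  Attenuation is stored relative to water
(water = 1, air = 0, lung ≈ 0.25, PMMA ≈ 1.15) on a 2-D voxel cross-section
that is constant along the body axis.

Renders produce the in-memory containers from :mod:`scoutdose.dicom_io`:

* axial slices in HU (HU = 1000·(attenuation − 1), rounded to integers like
  real reconstructions), and
* a localizer radiograph whose pixel value is an affine, per-kV function of
  the water-equivalent path length of each ray — localizer pixel values are
  not absolute on real scanners, which is exactly why the downstream
  calibration exists.  Parallel-beam rays integrate straight columns; fan
  beam rays diverge from a source at distance SAD and magnify a centred
  object by SID/SAD at the detector.

A cohort generator produces synthetic patients with a known linear link
between the true SSDE and a per-patient risk index, so that the regression
stage can be checked against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .dicom_io import AxialSeries, AxialSlice, LocalizerImage
from .dose_risk import NdcModel, TG204_32CM, ndc

__all__ = [
    "WATER",
    "AIR",
    "LUNG",
    "PMMA",
    "GridSpec",
    "DigitalPhantom",
    "AcquisitionGeometry",
    "PixelResponse",
    "SyntheticPatientRecord",
    "RiskCohort",
    "make_cylinder_phantom",
    "make_ellipse_phantom",
    "make_elliptical_patient",
    "add_couch",
    "render_axial_series",
    "render_localizer",
    "standard_phantom_set",
    "size_sweep_records",
    "make_risk_cohort",
]

WATER = 1.0
AIR = 0.0
LUNG = 0.25  # representative lung attenuation relative to water (≈ −750 HU)
PMMA = 1.15


@dataclass(frozen=True)
class GridSpec:
    """Reconstruction grid: physical size, voxel pitch, and z extent (mm)."""

    size_mm: tuple[float, float] = (360.0, 360.0)  # (y/AP, x/LAT)
    voxel_mm: tuple[float, float] = (1.0, 1.0)
    z_extent_mm: float = 30.0
    z_top_mm: float = 0.0

    def __post_init__(self) -> None:
        if min(self.size_mm) <= 0 or min(self.voxel_mm) <= 0:
            raise ValueError("grid size and voxel pitch must be positive")
        if self.z_extent_mm <= 0:
            raise ValueError("z extent must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (
            int(round(self.size_mm[0] / self.voxel_mm[0])),
            int(round(self.size_mm[1] / self.voxel_mm[1])),
        )


@dataclass
class DigitalPhantom:
    """Voxelized cross-section of relative water attenuation, constant in z."""

    attenuation: np.ndarray  # (ny, nx), 1.0 = water, 0.0 = air
    voxel_mm: tuple[float, float]
    z_extent_mm: float
    z_top_mm: float = 0.0
    label: str = "phantom"

    def __post_init__(self) -> None:
        self.attenuation = np.asarray(self.attenuation, dtype=np.float64)
        if self.attenuation.ndim != 2 or self.attenuation.size == 0:
            raise ValueError("attenuation grid must be a non-empty 2-D array")
        if np.any(self.attenuation < 0):
            raise ValueError("attenuation values must be non-negative")
        if min(self.voxel_mm) <= 0 or self.z_extent_mm <= 0:
            raise ValueError("voxel pitch and z extent must be positive")

    @property
    def voxel_area_mm2(self) -> float:
        return self.voxel_mm[0] * self.voxel_mm[1]

    @property
    def y_centers_mm(self) -> np.ndarray:
        ny = self.attenuation.shape[0]
        return (np.arange(ny) - (ny - 1) / 2) * self.voxel_mm[0]

    @property
    def x_centers_mm(self) -> np.ndarray:
        nx = self.attenuation.shape[1]
        return (np.arange(nx) - (nx - 1) / 2) * self.voxel_mm[1]

    def water_equivalent_area_mm2(self) -> float:
        """Voxel-sum A_W of the cross-section (the brute-force ground truth)."""
        return float(self.attenuation.sum() * self.voxel_area_mm2)

    def lateral_halfwidth_mm(self) -> float:
        """Half-extent of non-air voxels along x, measured from isocenter."""
        cols = self.attenuation.any(axis=0)
        if not cols.any():
            return 0.0
        x = self.x_centers_mm[cols]
        return float(max(abs(x[0]), abs(x[-1])) + self.voxel_mm[1] / 2)


def _grids(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = grid.shape
    y = (np.arange(ny) - (ny - 1) / 2)[:, None] * grid.voxel_mm[0]
    x = (np.arange(nx) - (nx - 1) / 2)[None, :] * grid.voxel_mm[1]
    return y, x


def make_cylinder_phantom(
    diameter_mm: float,
    attenuation: float = WATER,
    grid: GridSpec = GridSpec(),
    label: str | None = None,
) -> DigitalPhantom:
    """Circular cylinder of uniform material centred on the grid."""
    if diameter_mm <= 0:
        raise ValueError("cylinder diameter must be positive")
    if diameter_mm > min(grid.size_mm):
        raise ValueError(
            f"cylinder diameter {diameter_mm} mm exceeds grid size {grid.size_mm} mm"
        )
    y, x = _grids(grid)
    mask = (x**2 + y**2) <= (diameter_mm / 2) ** 2
    return DigitalPhantom(
        attenuation=np.where(mask, attenuation, AIR),
        voxel_mm=grid.voxel_mm,
        z_extent_mm=grid.z_extent_mm,
        z_top_mm=grid.z_top_mm,
        label=label or f"cylinder-{diameter_mm:g}mm",
    )


# Lung-insert layout: two ellipses with semi-axes (s·KA·AP/2, s·KB·LAT/2)
# centred at x = ±KC·LAT/2, scaled so their combined area is the requested
# fraction of the body area.
_LUNG_KA, _LUNG_KB, _LUNG_KC = 0.55, 0.30, 0.45


def make_ellipse_phantom(
    ap_mm: float,
    lat_mm: float,
    attenuation: float = WATER,
    lung_fraction: float = 0.0,
    lung_attenuation: float = LUNG,
    grid: GridSpec = GridSpec(),
    label: str | None = None,
) -> DigitalPhantom:
    """Elliptical body (semi-axes AP/2, LAT/2), optionally with lung inserts.

    ``lung_fraction`` is the fraction of the body cross-section occupied by
    the two lung ellipses; the analytic water-equivalent area is then
    π·(AP/2)·(LAT/2)·(1 − f·(1 − lung_attenuation)).
    """
    if ap_mm <= 0 or lat_mm <= 0:
        raise ValueError("AP and LAT must be positive")
    if ap_mm > grid.size_mm[0] or lat_mm > grid.size_mm[1]:
        raise ValueError(
            f"body {ap_mm} x {lat_mm} mm exceeds grid size {grid.size_mm} mm"
        )
    if not 0 <= lung_fraction < 1:
        raise ValueError("lung fraction must be in [0, 1)")
    a, b = ap_mm / 2, lat_mm / 2
    y, x = _grids(grid)
    body = (x / b) ** 2 + (y / a) ** 2 <= 1.0
    att = np.where(body, attenuation, AIR)
    if lung_fraction > 0:
        s = math.sqrt(lung_fraction / (2 * _LUNG_KA * _LUNG_KB))
        if (
            s * _LUNG_KB + _LUNG_KC > 0.97  # lungs poke through the lateral wall
            or s * _LUNG_KA > 0.97  # through the AP wall
            or _LUNG_KC - s * _LUNG_KB < 0.02  # left/right lungs merge
        ):
            raise ValueError(
                f"lung fraction {lung_fraction} is geometrically impossible "
                "for the two-insert layout"
            )
        for sign in (-1.0, 1.0):
            lung = ((x - sign * _LUNG_KC * b) / (s * _LUNG_KB * b)) ** 2 + (
                y / (s * _LUNG_KA * a)
            ) ** 2 <= 1.0
            att[lung & body] = lung_attenuation
    return DigitalPhantom(
        attenuation=att,
        voxel_mm=grid.voxel_mm,
        z_extent_mm=grid.z_extent_mm,
        z_top_mm=grid.z_top_mm,
        label=label or f"ellipse-{ap_mm:g}x{lat_mm:g}mm",
    )


@dataclass(frozen=True)
class SyntheticPatientRecord:
    """One synthetic patient: geometry, scan region, and true risk index.

    ``risk_index`` is in expected cancers per 1000 patients per 100 mGy; it
    stands in for the output of an external organ-dose / lifetime-risk chain
    and is treated as an input by the regression stage.
    """

    patient_id: str
    sex: str
    age_years: float
    ap_mm: float
    lat_mm: float
    lung_fraction: float
    region: str  # "chest" | "abdominopelvis"
    risk_index: float
    lung_attenuation: float = LUNG

    def __post_init__(self) -> None:
        if self.ap_mm <= 0 or self.lat_mm <= 0:
            raise ValueError("AP and LAT must be positive")
        if not 0 <= self.lung_fraction < 1:
            raise ValueError("lung fraction must be in [0, 1)")
        if self.risk_index < 0:
            raise ValueError("risk index must be non-negative")
        if self.region not in ("chest", "abdominopelvis"):
            raise ValueError(f"unknown region {self.region!r}")

    @property
    def ed_mm(self) -> float:
        """Geometric effective diameter sqrt(AP × LAT)."""
        return math.sqrt(self.ap_mm * self.lat_mm)

    @property
    def wed_mm(self) -> float:
        """Analytic water-equivalent diameter of the elliptical body."""
        factor = 1.0 - self.lung_fraction * (1.0 - self.lung_attenuation)
        return math.sqrt(self.ap_mm * self.lat_mm * factor)


def make_elliptical_patient(
    record: SyntheticPatientRecord, grid: GridSpec = GridSpec()
) -> DigitalPhantom:
    """Voxelize a synthetic patient record as a water body with lung inserts."""
    return make_ellipse_phantom(
        ap_mm=record.ap_mm,
        lat_mm=record.lat_mm,
        attenuation=WATER,
        lung_fraction=record.lung_fraction,
        lung_attenuation=record.lung_attenuation,
        grid=grid,
        label=f"patient-{record.patient_id}",
    )


def add_couch(
    phantom: DigitalPhantom,
    gap_mm: float = 8.0,
    thickness_mm: float = 12.0,
    attenuation: float = PMMA,
    half_angle_deg: float = 55.0,
) -> DigitalPhantom:
    """Add a PMMA half-pipe couch beneath the body (posterior = +y).

    The couch is an arc of a circular annulus concentric with the grid,
    separated from the body by ``gap_mm`` of air so that couch-removal logic
    (largest connected component) can be exercised.
    """
    ny, nx = phantom.attenuation.shape
    y = phantom.y_centers_mm[:, None]
    x = phantom.x_centers_mm[None, :]
    r = np.hypot(x, y)
    occupied = phantom.attenuation > 0
    if not occupied.any():
        raise ValueError("phantom is empty; nothing to place a couch under")
    r_inner = float(r[occupied].max()) + gap_mm
    r_outer = r_inner + thickness_mm
    half_extent = min(
        ny * phantom.voxel_mm[0], nx * phantom.voxel_mm[1]
    ) / 2
    if r_outer > half_extent:
        raise ValueError("couch does not fit inside the grid")
    angle = np.arctan2(x, y)  # 0 along +y (posterior)
    couch = (
        (r >= r_inner)
        & (r <= r_outer)
        & (np.abs(angle) <= math.radians(half_angle_deg))
    )
    att = phantom.attenuation.copy()
    att[couch] = attenuation
    return replace(phantom, attenuation=att, label=phantom.label + "+couch")


# ---------------------------------------------------------------------------
# Acquisition models


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Localizer acquisition geometry.

    The parallel model integrates straight columns and is the idealization
    under which row-mean x FOV_X reproduces the axial A_W exactly; the fan
    model traces diverging rays from a source at distance SAD, magnifying a
    centred object by SID/SAD at the detector.
    """

    sad_mm: float = 600.0  # source to isocenter
    sid_mm: float = 1100.0  # source to detector
    pixel_pitch_mm: float = 1.0  # detector column pitch
    beam: str = "parallel"  # "parallel" | "fan"
    fov_x_mm: float = 500.0

    def __post_init__(self) -> None:
        if not self.sid_mm >= self.sad_mm > 0:
            raise ValueError("require source-to-detector >= source-to-axis > 0")
        if self.fov_x_mm <= 0 or self.pixel_pitch_mm <= 0:
            raise ValueError("FOV_X and pixel pitch must be positive")
        if self.beam not in ("parallel", "fan"):
            raise ValueError(f"unknown beam model {self.beam!r}")

    @property
    def n_cols(self) -> int:
        return int(round(self.fov_x_mm / self.pixel_pitch_mm))

    @property
    def magnification(self) -> float:
        return self.sid_mm / self.sad_mm if self.beam == "fan" else 1.0


@dataclass(frozen=True)
class PixelResponse:
    """Affine per-kV localizer pixel response: gain·path + offset + noise.

    ``gain`` is in localizer pixel units per mm of water-equivalent path.
    The affine form is the minimal model a linear calibration can invert;
    real responses are scanner- and kV-specific, hence the kv label.
    """

    kv: float = 120.0
    gain: float = 10.0
    offset: float = 50.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


def render_axial_series(
    phantom: DigitalPhantom,
    slice_thickness_mm: float = 2.5,
    hu_noise_sigma: float = 0.0,
    seed: int = 0,
    axial_kv: float = 120.0,
    scanner_model: str = "SIMCT-1",
    software: str = "scoutdose-sim",
) -> AxialSeries:
    """Render per-slice HU images; HU = 1000·(attenuation − 1), integer-valued.

    SliceLocations descend from the phantom's top-z in steps of the slice
    thickness (slice centres).  Gaussian HU noise is reproducible under
    ``seed``; pixels are rounded to integers as real reconstructions are.
    """
    if slice_thickness_mm <= 0:
        raise ValueError("slice thickness must be positive")
    n = max(1, int(phantom.z_extent_mm / slice_thickness_mm + 1e-9))
    hu0 = 1000.0 * (phantom.attenuation - 1.0)
    rng = np.random.default_rng(seed)
    slices = []
    for i in range(n):
        z = phantom.z_top_mm - (i + 0.5) * slice_thickness_mm
        hu = hu0 if hu_noise_sigma == 0 else hu0 + rng.normal(0.0, hu_noise_sigma, hu0.shape)
        hu = np.clip(np.rint(hu), -1024, 32767).astype(np.int16)
        slices.append(
            AxialSlice(
                hu=hu,
                pixel_spacing=phantom.voxel_mm,
                z_mm=z,
                kv=axial_kv,
                scanner_model=scanner_model,
                software=software,
            )
        )
    return AxialSeries(slices)


def _parallel_paths(phantom: DigitalPhantom, xs_mm: np.ndarray) -> np.ndarray:
    column_paths = phantom.attenuation.sum(axis=0) * phantom.voxel_mm[0]
    return np.interp(xs_mm, phantom.x_centers_mm, column_paths, left=0.0, right=0.0)


def _fan_paths(
    phantom: DigitalPhantom,
    xs_det_mm: np.ndarray,
    sad_mm: float,
    sid_mm: float,
    step_mm: float = 0.5,
) -> np.ndarray:
    """Water-equivalent path of each fan ray through the voxel cross-section.

    Rays run from the source at (0, −SAD) to detector columns at y = SID−SAD;
    the attenuation map is sampled bilinearly at ``step_mm`` increments over
    the y-range of the grid (air outside contributes nothing).
    """
    dy, dx = phantom.voxel_mm
    yc = phantom.y_centers_mm
    xc = phantom.x_centers_mm
    y_min, y_max = yc[0] - dy / 2, yc[-1] + dy / 2
    t0 = (y_min + sad_mm) / sid_mm
    t1 = (y_max + sad_mm) / sid_mm
    k = max(4, int(math.ceil((y_max - y_min) / step_mm)))
    tc = t0 + (np.arange(k) + 0.5) * (t1 - t0) / k
    ys = -sad_mm + tc * sid_mm
    rows = (ys - yc[0]) / dy  # (k,)
    cols = (tc[:, None] * xs_det_mm[None, :] - xc[0]) / dx  # (k, ncols)
    coords = np.broadcast_arrays(rows[:, None], cols)
    values = map_coordinates(
        phantom.attenuation, np.array(coords), order=1, mode="constant", cval=0.0
    )
    segment = np.sqrt(xs_det_mm**2 + sid_mm**2) * (t1 - t0) / k  # per-sample length
    return values.sum(axis=0) * segment


def render_localizer(
    phantom: DigitalPhantom,
    geometry: AcquisitionGeometry = AcquisitionGeometry(),
    response: PixelResponse = PixelResponse(),
    row_spacing_mm: float = 1.0,
    scanner_model: str = "SIMCT-1",
    quantize: bool = True,
) -> LocalizerImage:
    """Render the scout radiograph: one row per z position, columns along x.

    Pixel value = gain · (water-equivalent ray path) + offset + noise.  With
    ``quantize`` (the default, matching what a scanner stores) pixels are
    rounded to unsigned integers.  An object wider than the field of view is
    flagged as truncated rather than rejected.
    """
    if row_spacing_mm <= 0:
        raise ValueError("row spacing must be positive")
    ncols = geometry.n_cols
    fov = ncols * geometry.pixel_pitch_mm
    xs = (np.arange(ncols) - (ncols - 1) / 2) * geometry.pixel_pitch_mm
    if geometry.beam == "parallel":
        paths = _parallel_paths(phantom, xs)
    else:
        paths = _fan_paths(phantom, xs, geometry.sad_mm, geometry.sid_mm)
    truncated = phantom.lateral_halfwidth_mm() * geometry.magnification > fov / 2

    n_rows = max(1, int(round(phantom.z_extent_mm / row_spacing_mm)))
    profile = response.gain * paths + response.offset
    img = np.tile(profile, (n_rows, 1))
    if response.noise_sigma > 0:
        rng = np.random.default_rng(response.seed)
        img = img + rng.normal(0.0, response.noise_sigma, img.shape)
    if quantize:
        img = np.clip(np.rint(img), 0, 0xFFFF).astype(np.uint16)
    return LocalizerImage(
        pixels=img,
        row_spacing_mm=row_spacing_mm,
        col_spacing_mm=geometry.pixel_pitch_mm,
        top_z_mm=phantom.z_top_mm - row_spacing_mm / 2,
        kv=response.kv,
        scanner_model=scanner_model,
        truncated=truncated,
    )


def standard_phantom_set(grid: GridSpec = GridSpec()) -> list[DigitalPhantom]:
    """The calibration phantom family: acrylic rod, 16 cm and 32 cm PMMA
    cylinders, and an ACR-like water oval.  The rod anchors the calibration
    line near the origin; the others span the phantom sizes available in a
    CT department."""
    return [
        make_cylinder_phantom(10.0, PMMA, grid, label="rod"),
        make_cylinder_phantom(160.0, PMMA, grid, label="ctdi16"),
        make_cylinder_phantom(320.0, PMMA, grid, label="ctdi32"),
        make_ellipse_phantom(200.0, 250.0, WATER, grid=grid, label="acr-oval"),
    ]


def size_sweep_records(
    n: int = 14,
    wed_range_mm: tuple[float, float] = (80.0, 400.0),
    aspect_ratio: float = 0.75,
    lung_fraction: float = 0.3,
    lung_attenuation: float = LUNG,
) -> list[SyntheticPatientRecord]:
    """Deterministic validation sweep: true WED evenly spaced over the range,
    alternating abdominopelvis (all-water) and chest (lung-insert) bodies.

    Used to check localizer-derived against axial-derived WED across the
    clinically relevant size range.
    """
    if n < 2:
        raise ValueError("a sweep needs at least 2 sizes")
    records = []
    for i, wed in enumerate(np.linspace(*wed_range_mm, n)):
        region = "chest" if i % 2 else "abdominopelvis"
        f = lung_fraction if region == "chest" else 0.0
        factor = 1.0 - f * (1.0 - lung_attenuation)
        lat = float(wed) / math.sqrt(aspect_ratio * factor)
        records.append(
            SyntheticPatientRecord(
                patient_id=f"SWEEP{i:02d}",
                sex="F" if i % 2 else "M",
                age_years=40.0,
                ap_mm=aspect_ratio * lat,
                lat_mm=lat,
                lung_fraction=f,
                region=region,
                risk_index=0.0,
                lung_attenuation=lung_attenuation,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Risk cohort generator


@dataclass
class RiskCohort:
    """Synthetic cohort with known ground-truth risk model RI = α + β·SSDE + ε."""

    records: list[SyntheticPatientRecord]
    ctdivol_mgy: np.ndarray
    alpha: float
    beta: float
    sigma: float
    seed: int
    ndc_model: NdcModel = TG204_32CM

    def __len__(self) -> int:
        return len(self.records)

    def frame(self) -> pd.DataFrame:
        """Cohort table with the columns the risk-assessment stage consumes."""
        rows = []
        for rec, cv in zip(self.records, self.ctdivol_mgy):
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "sex": rec.sex,
                    "age_years": rec.age_years,
                    "region": rec.region,
                    "ap_mm": rec.ap_mm,
                    "lat_mm": rec.lat_mm,
                    "lung_fraction": rec.lung_fraction,
                    "wed_mm": rec.wed_mm,
                    "ed_mm": rec.ed_mm,
                    "ctdivol_mgy": float(cv),
                    "ssde_true_mgy": ndc(rec.wed_mm / 10.0, self.ndc_model) * float(cv),
                    "ri": rec.risk_index,
                }
            )
        return pd.DataFrame(rows)


def make_risk_cohort(
    n: int,
    alpha: float = 0.0,
    beta: float = 0.5,
    sigma: float = 0.1,
    seed: int = 0,
    region: str = "mixed",
    wed_range_mm: tuple[float, float] = (80.0, 400.0),
    aspect_ratio: float = 0.75,
    lung_fraction_range: tuple[float, float] = (0.15, 0.40),
    lung_attenuation: float = LUNG,
    ctdivol_range_mgy: tuple[float, float] = (4.0, 30.0),
    ndc_model: NdcModel = TG204_32CM,
) -> RiskCohort:
    """Draw a synthetic cohort with RI = α + β·SSDE_true + N(0, σ²).

    Body sizes are drawn so the true WED is uniform over ``wed_range_mm``
    (NDC then varies materially across the cohort); chest patients get a lung
    fraction from ``lung_fraction_range``, abdominopelvis patients none.  The
    generating α, β, σ are stored on the returned cohort for recovery checks.
    The draw is fully reproducible under ``seed``.
    """
    if n < 3:
        raise ValueError("need at least 3 patients (regression undefined below that)")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if region not in ("chest", "abdominopelvis", "mixed"):
        raise ValueError(f"unknown region {region!r}")
    rng = np.random.default_rng(seed)
    records: list[SyntheticPatientRecord] = []
    ctdivol = np.empty(n)
    for i in range(n):
        reg = region if region != "mixed" else ("chest" if i % 2 == 0 else "abdominopelvis")
        f = float(rng.uniform(*lung_fraction_range)) if reg == "chest" else 0.0
        wed = float(rng.uniform(*wed_range_mm))
        factor = 1.0 - f * (1.0 - lung_attenuation)
        lat = wed / math.sqrt(aspect_ratio * factor)
        ap = aspect_ratio * lat
        cv = float(rng.uniform(*ctdivol_range_mgy))
        record = SyntheticPatientRecord(
            patient_id=f"SYN{i:04d}",
            sex="F" if rng.uniform() < 0.5 else "M",
            age_years=float(rng.uniform(1.0, 80.0)),
            ap_mm=ap,
            lat_mm=lat,
            lung_fraction=f,
            region=reg,
            risk_index=0.0,
            lung_attenuation=lung_attenuation,
        )
        # SSDE from the record's own (AP, LAT)-derived WED so that stored
        # tables and the generating model agree to the last bit
        ssde_true = ndc(record.wed_mm / 10.0, ndc_model) * cv
        ri = alpha + beta * ssde_true
        if sigma > 0:
            ri += float(rng.normal(0.0, sigma))
        records.append(replace(record, risk_index=max(ri, 0.0)))
        ctdivol[i] = cv
    return RiskCohort(records, ctdivol, alpha, beta, sigma, seed, ndc_model)
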