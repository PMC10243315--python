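"""Shared study conditions for the test suite.

One scanner, one kV pair, the standard calibration phantom family, and a
deterministic patient size sweep; noise levels for the "clean" and
"realistic" conditions are fixed here so every test sees the same study.
"""

from __future__ import annotations

from scoutdose.calibration import (
    collect_calibration_points,
    compare_localizer_to_axial,
    fit_calibration,
)
from scoutdose.phantom_sim import (
    AcquisitionGeometry,
    GridSpec,
    PixelResponse,
    make_elliptical_patient,
    render_axial_series,
    render_localizer,
    size_sweep_records,
    standard_phantom_set,
)

SCANNER = "SIMCT-1"
LOCALIZER_KV = 120.0
AXIAL_KV = 120.0
GAIN = 10.0  # localizer units per mm water
OFFSET = 50.0
NOISY_SIGMA = GAIN / 50.0  # gain-SNR 50: the "realistic" localizer noise
CLEAN_SIGMA = GAIN / 100.0  # gain-SNR 100: the "clean" condition
HU_SIGMA = 10.0
SLICE_THICKNESS = 5.0

PHANTOM_GRID = GridSpec((360.0, 360.0), (1.0, 1.0), 30.0)
PATIENT_GRID = GridSpec((560.0, 560.0), (1.0, 1.0), 30.0)
GEOMETRY = AcquisitionGeometry(fov_x_mm=600.0)


def response(sigma: float, seed: int) -> PixelResponse:
    return PixelResponse(LOCALIZER_KV, GAIN, OFFSET, sigma, seed=seed)


def build_calibration(loc_sigma: float, hu_sigma: float, base_seed: int = 0):
    """Render the standard phantom family and fit the pooled calibration."""
    points = []
    for i, phantom in enumerate(standard_phantom_set(PHANTOM_GRID)):
        series = render_axial_series(
            phantom, SLICE_THICKNESS, hu_sigma, seed=base_seed + 2 * i,
            axial_kv=AXIAL_KV, scanner_model=SCANNER,
        )
        localizer = render_localizer(
            phantom, GEOMETRY, response(loc_sigma, base_seed + 2 * i + 1),
            scanner_model=SCANNER,
        )
        points.extend(collect_calibration_points(series, localizer, phantom.label))
    model = fit_calibration(points, SCANNER, LOCALIZER_KV, AXIAL_KV)
    return model, points


def sweep_max_pct_diff(
    model, loc_sigma: float, hu_sigma: float, base_seed: int, n: int = 14
) -> float:
    """Max per-exam |WED_localizer − WED_axial| / WED_axial × 100 over the
    deterministic size sweep (scan-mean WED per exam)."""
    worst = 0.0
    for i, record in enumerate(size_sweep_records(n)):
        phantom = make_elliptical_patient(record, PATIENT_GRID)
        series = render_axial_series(
            phantom, SLICE_THICKNESS, hu_sigma, seed=base_seed + 2 * i,
            axial_kv=AXIAL_KV, scanner_model=SCANNER,
        )
        localizer = render_localizer(
            phantom, GEOMETRY, response(loc_sigma, base_seed + 2 * i + 1),
            scanner_model=SCANNER,
        )
        df = compare_localizer_to_axial(model, localizer, series)
        wed_loc = df["wed_localizer_mm"].mean()
        wed_ax = df["wed_axial_mm"].mean()
        worst = max(worst, abs(wed_loc - wed_ax) / wed_ax * 100.0)
    return worst
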