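"""Read, write and align CT axial series and localizer radiographs.

The localizer (scout / topogram) is the planar radiograph acquired before the
axial scan.  Unlike calibrated CT numbers, its pixel values are scanner- and
kV-specific, so downstream size estimation needs a per-scanner calibration;
this module only moves pixels and geometry in and out of DICOM and maps axial
slice z-locations onto localizer rows.

Geometry conventions
--------------------
* Axial slice z comes from SliceLocation (0020,1041), falling back to the
  third component of ImagePositionPatient (0020,0032) when absent.
* The localizer's top-corner z is the third component of ImagePositionPatient,
  i.e. the centre of the first row of pixels; rows advance toward smaller z.
* FOV_X of a localizer is (number of columns) x (column pixel spacing).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

log = logging.getLogger(__name__)

__all__ = [
    "AxialSlice",
    "AxialSeries",
    "LocalizerImage",
    "read_axial_series",
    "write_axial_series",
    "read_localizer",
    "write_localizer",
    "map_z_to_row",
    "geometry_summary",
    "write_geometry_summary",
]


@dataclass
class AxialSlice:
    """One calibrated axial CT image: pixels in HU with its z-location."""

    hu: np.ndarray
    pixel_spacing: tuple[float, float]  # (row, col) mm
    z_mm: float
    kv: float = 120.0
    scanner_model: str = "SIMCT-1"
    software: str = ""

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 2 or self.hu.size == 0:
            raise ValueError("axial pixel data must be a non-empty 2-D array")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.hu.shape  # type: ignore[return-value]


@dataclass
class AxialSeries:
    """Axial slices of one series, sorted by z (strictly monotonic)."""

    slices: list[AxialSlice]

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("series is empty")
        self.slices = sorted(self.slices, key=lambda s: s.z_mm)
        zs = [s.z_mm for s in self.slices]
        if len(set(zs)) != len(zs):
            raise ValueError("duplicate SliceLocation values in series")
        spacings = {s.pixel_spacing for s in self.slices}
        if len(spacings) != 1:
            raise ValueError("non-uniform PixelSpacing across series")

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self) -> Iterator[AxialSlice]:
        return iter(self.slices)

    def __getitem__(self, i: int) -> AxialSlice:
        return self.slices[i]

    @property
    def z_min_mm(self) -> float:
        return self.slices[0].z_mm

    @property
    def z_max_mm(self) -> float:
        return self.slices[-1].z_mm

    @property
    def pixel_spacing(self) -> tuple[float, float]:
        return self.slices[0].pixel_spacing

    @property
    def kv(self) -> float:
        return self.slices[0].kv

    @property
    def scanner_model(self) -> str:
        return self.slices[0].scanner_model


@dataclass
class LocalizerImage:
    """Scout radiograph: scanner-specific pixel units on a z-by-x grid."""

    pixels: np.ndarray
    row_spacing_mm: float  # z per row
    col_spacing_mm: float  # x per column
    top_z_mm: float  # z of the centre of row 0 (ImagePositionPatient[2])
    kv: float = 120.0
    scanner_model: str = "SIMCT-1"
    truncated: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("localizer pixel data must be a non-empty 2-D array")
        if self.row_spacing_mm <= 0 or self.col_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def fov_x_mm(self) -> float:
        """Field-of-view width along x: columns x column pixel spacing."""
        return self.n_cols * self.col_spacing_mm

    def z_of_row(self, row: int) -> float:
        return self.top_z_mm - row * self.row_spacing_mm


def map_z_to_row(localizer: LocalizerImage, z_mm: float) -> int:
    """Map an axial slice z-location to the nearest localizer row.

    row = round((top-corner z - z) / row pixel spacing), with ties broken
    toward the smaller row index, clamped to valid rows.  z more than half a
    row pitch outside the localizer extent is an error.
    """
    v = (localizer.top_z_mm - z_mm) / localizer.row_spacing_mm
    if v < -0.5 or v > localizer.n_rows - 0.5:
        raise ValueError(
            f"z = {z_mm} mm lies outside the localizer z-extent "
            f"[{localizer.z_of_row(localizer.n_rows - 1)}, {localizer.top_z_mm}] mm "
            f"(overhang of {min(abs(v), abs(v - localizer.n_rows + 1)) * localizer.row_spacing_mm:.1f} mm)"
        )
    row = math.ceil(v - 0.5)  # nearest; ties toward the smaller index
    return min(max(row, 0), localizer.n_rows - 1)


# ---------------------------------------------------------------------------
# DICOM writing


def _file_meta(sop_instance_uid: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = sop_instance_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _base_dataset(entropy: Sequence[str]) -> Dataset:
    ds = Dataset()
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = generate_uid(entropy_srcs=list(entropy))
    ds.Modality = "CT"
    ds.PatientName = "SYNTHETIC^PHANTOM"
    ds.PatientID = "SYN000"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    return ds


def _set_pixels_u16(ds: Dataset, stored: np.ndarray) -> None:
    if stored.min() < 0 or stored.max() > 0xFFFF:
        raise ValueError("stored pixel values out of unsigned 16-bit range")
    arr = stored.astype(np.uint16)
    ds.Rows, ds.Columns = arr.shape
    ds.PixelData = arr.tobytes()


def write_axial_series(
    series: AxialSeries, directory: str | Path, uid_entropy: str | None = None
) -> list[Path]:
    """Write one DICOM file per slice (CT, explicit VR little endian).

    HU are stored with RescaleSlope 1 / RescaleIntercept -1024.  UIDs are
    derived deterministically from the series content (or ``uid_entropy``) so
    that deterministic pipelines reproduce files byte-identically.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entropy = uid_entropy or (
        f"{series.scanner_model}/{series.kv}/{len(series)}/"
        f"{series.z_min_mm}/{series.z_max_mm}"
    )
    series_uid = generate_uid(entropy_srcs=[entropy, "series"])
    study_uid = generate_uid(entropy_srcs=[entropy, "study"])
    frame_uid = generate_uid(entropy_srcs=[entropy, "frame"])
    paths: list[Path] = []
    for i, sl in enumerate(series):
        stored = np.rint(np.asarray(sl.hu, dtype=np.float64)).astype(np.int64) + 1024
        ds = _base_dataset([entropy, f"slice{i}"])
        ds.file_meta = _file_meta(ds.SOPInstanceUID)
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = i + 1
        ds.ImageType = ["ORIGINAL", "PRIMARY", "AXIAL"]
        ds.PixelSpacing = [sl.pixel_spacing[0], sl.pixel_spacing[1]]
        ds.SliceLocation = sl.z_mm
        ds.ImagePositionPatient = [0.0, 0.0, sl.z_mm]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.KVP = sl.kv
        ds.ManufacturerModelName = sl.scanner_model
        if sl.software:
            ds.SoftwareVersions = sl.software
        ds.RescaleSlope = 1
        ds.RescaleIntercept = -1024
        ds.RescaleType = "HU"
        _set_pixels_u16(ds, stored)
        path = directory / f"slice_{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def write_localizer(
    localizer: LocalizerImage, path: str | Path, uid_entropy: str | None = None
) -> Path:
    """Write a single-frame localizer radiograph as DICOM."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    entropy = uid_entropy or (
        f"{localizer.scanner_model}/{localizer.kv}/localizer/"
        f"{localizer.n_rows}x{localizer.n_cols}/{localizer.top_z_mm}"
    )
    stored = np.rint(np.asarray(localizer.pixels, dtype=np.float64)).astype(np.int64)
    ds = _base_dataset([entropy, "frame0"])
    ds.file_meta = _file_meta(ds.SOPInstanceUID)
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=[entropy, "series"])
    ds.StudyInstanceUID = generate_uid(entropy_srcs=[entropy, "study"])
    ds.ImageType = ["DERIVED", "PRIMARY", "LOCALIZER"]
    ds.PixelSpacing = [localizer.row_spacing_mm, localizer.col_spacing_mm]
    ds.ImagePositionPatient = [
        -(localizer.n_cols - 1) / 2 * localizer.col_spacing_mm,
        0.0,
        localizer.top_z_mm,
    ]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 0, -1]
    ds.KVP = localizer.kv
    ds.ManufacturerModelName = localizer.scanner_model
    _set_pixels_u16(ds, stored)
    ds.save_as(path, enforce_file_format=True)
    return path


# ---------------------------------------------------------------------------
# DICOM reading


def _require(ds: Dataset, keyword: str, tag: str, path: Path) -> None:
    if keyword not in ds:
        raise KeyError(f"{keyword} {tag} missing from {path}")


def _hu_array(ds: Dataset) -> np.ndarray:
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = ds.pixel_array.astype(np.float64) * slope + intercept
    rounded = np.rint(arr)
    if np.array_equal(arr, rounded) and arr.min() >= -(2**15) and arr.max() < 2**15:
        return rounded.astype(np.int16)
    return arr


def read_axial_series(source: str | Path | Iterable[str | Path]) -> AxialSeries:
    """Read a directory (or explicit file list) of axial CT DICOM files.

    Slices are sorted by z regardless of file order; mixed SeriesInstanceUIDs
    are rejected.  When SliceLocation (0020,1041) is absent the z-component of
    ImagePositionPatient (0020,0032) is used and the fallback is logged.
    """
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        paths = sorted(Path(source).glob("*.dcm"))
    elif isinstance(source, (str, Path)):
        paths = [Path(source)]
    else:
        paths = [Path(p) for p in source]
    if not paths:
        raise ValueError("no DICOM files found")

    slices: list[AxialSlice] = []
    uids: set[str] = set()
    for path in paths:
        ds = pydicom.dcmread(path)
        uids.add(str(getattr(ds, "SeriesInstanceUID", "")))
        _require(ds, "PixelSpacing", "(0028,0030)", path)
        if "SliceLocation" in ds:
            z = float(ds.SliceLocation)
        elif "ImagePositionPatient" in ds:
            z = float(ds.ImagePositionPatient[2])
            log.warning(
                "SliceLocation (0020,1041) missing from %s; "
                "falling back to ImagePositionPatient[2]",
                path,
            )
        else:
            raise KeyError(f"SliceLocation (0020,1041) missing from {path}")
        slices.append(
            AxialSlice(
                hu=_hu_array(ds),
                pixel_spacing=(float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])),
                z_mm=z,
                kv=float(ds.KVP) if "KVP" in ds else float("nan"),
                scanner_model=str(getattr(ds, "ManufacturerModelName", "")),
                software=str(getattr(ds, "SoftwareVersions", "")),
            )
        )
    if len(uids) > 1:
        raise ValueError(f"mixed SeriesInstanceUID values in input: {sorted(uids)}")
    return AxialSeries(slices)


def read_localizer(path: str | Path) -> LocalizerImage:
    """Read a single-frame localizer radiograph from DICOM."""
    path = Path(path)
    ds = pydicom.dcmread(path)
    if int(getattr(ds, "NumberOfFrames", 1)) > 1:
        raise ValueError(f"{path} is multi-frame; expected a single-frame localizer")
    _require(ds, "ImagePositionPatient", "(0020,0032)", path)
    _require(ds, "PixelSpacing", "(0028,0030)", path)
    return LocalizerImage(
        pixels=ds.pixel_array,
        row_spacing_mm=float(ds.PixelSpacing[0]),
        col_spacing_mm=float(ds.PixelSpacing[1]),
        top_z_mm=float(ds.ImagePositionPatient[2]),
        kv=float(ds.KVP) if "KVP" in ds else float("nan"),
        scanner_model=str(getattr(ds, "ManufacturerModelName", "")),
    )


# ---------------------------------------------------------------------------
# Audit output


def geometry_summary(obj: AxialSeries | LocalizerImage) -> dict:
    """Geometry of a series or localizer as a flat dict for audit trails."""
    if isinstance(obj, AxialSeries):
        return {
            "class": "AxialSeries",
            "n_slices": len(obj),
            "rows": obj[0].shape[0],
            "cols": obj[0].shape[1],
            "pixel_spacing_mm": list(obj.pixel_spacing),
            "z_min_mm": obj.z_min_mm,
            "z_max_mm": obj.z_max_mm,
            "kv": obj.kv,
            "scanner_model": obj.scanner_model,
        }
    return {
        "class": "LocalizerImage",
        "rows": obj.n_rows,
        "cols": obj.n_cols,
        "row_spacing_mm": obj.row_spacing_mm,
        "col_spacing_mm": obj.col_spacing_mm,
        "top_z_mm": obj.top_z_mm,
        "fov_x_mm": obj.fov_x_mm,
        "kv": obj.kv,
        "scanner_model": obj.scanner_model,
        "truncated": obj.truncated,
    }


def write_geometry_summary(obj: AxialSeries | LocalizerImage, path: str | Path) -> Path:
    path = Path(path)
    summary = geometry_summary(obj)
    if path.suffix.lower() == ".csv":
        import pandas as pd

        pd.DataFrame([summary]).to_csv(path, index=False)
    else:
        path.write_text(json.dumps(summary, indent=2) + "\n")
    return path
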