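"""File I/O: native plan containers, tables, configs and DICOM-RT.

The native plan container is an ``.npz`` array archive (dose plus one
boolean mask per structure) with a JSON sidecar carrying the geometry
(spacing, origin), the structure metadata (names, roles, prescriptions,
RPI weights) and the generator provenance.  Round trips are loss-free.

DICOM support covers standard-conformant RT Dose (read and a minimal
writer, doses quantized at 1e-4 Gy) and RT Structure Set ingestion with
planar contours rasterized by the voxel-center-in-polygon rule.  All
doses are Gy, lengths mm, volumes cm3.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DoseGrid, Structure
from .synthetic import LesionSpec, SyntheticPatientSpec

logger = logging.getLogger(__name__)

__all__ = [
    "write_plan",
    "read_plan",
    "write_metrics_csv",
    "read_metrics_csv",
    "write_comparison_json",
    "read_comparison_json",
    "write_cohort_json",
    "read_cohort_json",
    "read_rpi_config",
    "read_rtdose",
    "write_rtdose",
    "read_rtstruct",
    "write_rtstruct",
]

DOSE_QUANTUM_GY = 1e-4

#: Leading columns of every metrics CSV, in fixed order; any further
#: columns (per-OAR statistics) follow in sorted order.
METRIC_COLUMN_ORDER = [
    "plan_id", "technique", "d98_pct", "hi", "pci", "gi",
    "v90_pct", "v100_pct", "v110_pct",
    "brain_mean_gy", "brain_v12_cc", "brain_v4_cc",
    "brain_v12_pct", "brain_v4_pct",
    "target_volume_cc", "piv_cc", "sdev_pct",
    "rpi_all", "rpi_targets_brain",
]


# ---------------------------------------------------------------------------
# native containers

def write_plan(
    prefix: str | Path,
    grid: DoseGrid,
    structures: list[Structure],
    provenance: dict | None = None,
) -> None:
    """Write ``<prefix>.npz`` (arrays) and ``<prefix>.json`` (sidecar)."""
    prefix = Path(prefix)
    arrays = {"dose": grid.values}
    meta_structures = []
    for i, s in enumerate(structures):
        key = f"mask_{i}"
        arrays[key] = s.mask
        meta_structures.append(
            {
                "name": s.name,
                "role": s.role,
                "prescription_dose": s.prescription_dose,
                "weight": s.weight,
                "array_key": key,
            }
        )
    np.savez(prefix.with_suffix(".npz"), **arrays)
    sidecar = {
        "spacing": list(grid.spacing),
        "origin": list(grid.origin),
        "shape": list(grid.shape),
        "structures": meta_structures,
        "provenance": provenance or {},
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_plan(prefix: str | Path) -> tuple[DoseGrid, list[Structure], dict]:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    for key in ("spacing", "origin", "structures"):
        if key not in sidecar:
            raise ValueError(f"sidecar {prefix}.json is missing {key!r}")
    with np.load(prefix.with_suffix(".npz")) as arrays:
        dose = arrays["dose"]
        if list(dose.shape) != list(sidecar.get("shape", dose.shape)):
            raise ValueError("sidecar shape does not match the dose array")
        grid = DoseGrid(dose, tuple(sidecar["spacing"]), tuple(sidecar["origin"]))
        structures = []
        for meta in sidecar["structures"]:
            mask = arrays[meta["array_key"]]
            if mask.shape != grid.shape:
                raise ValueError(
                    f"mask {meta['name']!r} shape {mask.shape} does not match "
                    f"the dose grid {grid.shape}"
                )
            structures.append(
                Structure(
                    name=meta["name"],
                    role=meta["role"],
                    mask=mask,
                    prescription_dose=meta.get("prescription_dose"),
                    weight=meta.get("weight", 1.0),
                )
            )
    return grid, structures, sidecar.get("provenance", {})


# ---------------------------------------------------------------------------
# tables and configs

def write_metrics_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Metrics CSV with a stable, documented column order."""
    lead = [c for c in METRIC_COLUMN_ORDER if c in table.columns]
    rest = sorted(c for c in table.columns if c not in METRIC_COLUMN_ORDER)
    table[lead + rest].to_csv(path, index=False)


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_comparison_json(results: list, path: str | Path) -> None:
    payload = [r.to_dict() for r in results]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_comparison_json(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())


def write_cohort_json(cohort: list[SyntheticPatientSpec], path: str | Path) -> None:
    payload = [dataclasses.asdict(spec) for spec in cohort]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_cohort_json(path: str | Path) -> list[SyntheticPatientSpec]:
    payload = json.loads(Path(path).read_text())
    cohort = []
    for entry in payload:
        lesions = [LesionSpec(tuple(l["center"]), l["radius"], l["prescription"])
                   for l in entry["lesions"]]
        oars = {
            name: {k: tuple(v) if isinstance(v, list) else v for k, v in p.items()}
            for name, p in entry["oars"].items()
        }
        cohort.append(
            SyntheticPatientSpec(
                patient_id=entry["patient_id"],
                lesions=lesions,
                brain_center=tuple(entry["brain_center"]),
                brain_semiaxes=tuple(entry["brain_semiaxes"]),
                oars=oars,
                grid_spacing=entry["grid_spacing"],
                seed=entry["seed"],
            )
        )
    return cohort


def read_rpi_config(path: str | Path) -> tuple[dict[str, float], str]:
    """Per-structure RPI weights and formula variant from a JSON config."""
    cfg = json.loads(Path(path).read_text())
    weights = {str(k): float(v) for k, v in cfg.get("weights", {}).items()}
    for name, w in weights.items():
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"weight for {name!r} must lie in [0, 1], got {w}")
    variant = cfg.get("variant", "printed")
    if variant not in ("printed", "per_structure"):
        raise ValueError(f"unknown RPI variant {variant!r}")
    return weights, variant


# ---------------------------------------------------------------------------
# DICOM RT Dose

_RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
_RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"


def _require(ds, attr: str):
    if not hasattr(ds, attr):
        raise ValueError(f"RT Dose is missing required attribute {attr}")
    return getattr(ds, attr)


def read_rtdose(path: str | Path, reference_grid: DoseGrid | None = None) -> DoseGrid:
    """Read a standard-conformant DICOM RT Dose into a :class:`DoseGrid`.

    Doses are scaled to Gy via DoseGridScaling; geometry comes from
    ImagePositionPatient, PixelSpacing and GridFrameOffsetVector, with the
    axes reordered to the native (z, y, x) convention.  Only axial
    identity orientation is supported.  If ``reference_grid`` is given and
    its lattice differs, the dose is trilinearly resampled onto it.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    scaling = float(_require(ds, "DoseGridScaling"))
    if scaling <= 0:
        raise ValueError("RT Dose attribute DoseGridScaling must be > 0")
    ipp = [float(v) for v in _require(ds, "ImagePositionPatient")]
    iop = [float(v) for v in _require(ds, "ImageOrientationPatient")]
    if not np.allclose(iop, [1, 0, 0, 0, 1, 0]):
        raise ValueError(
            "only axial identity ImageOrientationPatient is supported, "
            f"got {iop}"
        )
    row_sp, col_sp = (float(v) for v in _require(ds, "PixelSpacing"))
    offsets = np.asarray([float(v) for v in _require(ds, "GridFrameOffsetVector")])
    if offsets.size > 1:
        dz_all = np.diff(offsets)
        if not np.allclose(dz_all, dz_all[0]):
            raise ValueError("non-uniform GridFrameOffsetVector is not supported")
        dz = float(dz_all[0])
    else:
        dz = 1.0
    values = ds.pixel_array.astype(np.float64) * scaling  # (frames, rows, cols)
    grid = DoseGrid(
        values,
        spacing=(dz, row_sp, col_sp),
        origin=(ipp[2] + float(offsets[0]), ipp[1], ipp[0]),
    )
    if reference_grid is not None and (
        grid.shape != reference_grid.shape
        or not np.allclose(grid.spacing, reference_grid.spacing)
        or not np.allclose(grid.origin, reference_grid.origin)
    ):
        grid = _resample_to(grid, reference_grid)
    return grid


def _resample_to(grid: DoseGrid, reference: DoseGrid) -> DoseGrid:
    """Trilinear resampling of ``grid`` onto the reference lattice."""
    from scipy import ndimage

    logger.info("resampling RT Dose grid %s onto reference lattice %s",
                grid.shape, reference.shape)
    coords = []
    for ax in range(3):
        ref_pos = reference.origin[ax] + np.arange(reference.shape[ax]) * reference.spacing[ax]
        coords.append((ref_pos - grid.origin[ax]) / grid.spacing[ax])
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    values = ndimage.map_coordinates(
        grid.values, [zz, yy, xx], order=1, mode="constant", cval=0.0
    )
    return DoseGrid(np.clip(values, 0, None), reference.spacing, reference.origin)


def write_rtdose(path: str | Path, grid: DoseGrid) -> None:
    """Write a minimal standard-conformant RT Dose (doses quantized at 1e-4 Gy)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    ints = np.round(grid.values / DOSE_QUANTUM_GY).astype(np.uint32)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID(_RTDOSE_SOP)
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    nz, ny, nx = grid.shape
    ds.Rows, ds.Columns, ds.NumberOfFrames = ny, nx, nz
    ds.PixelSpacing = [grid.spacing[1], grid.spacing[2]]
    ds.ImagePositionPatient = [grid.origin[2], grid.origin[1], grid.origin[0]]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [i * grid.spacing[0] for i in range(nz)]
    ds.FrameIncrementPointer = (0x3004, 0x000C)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseGridScaling = DOSE_QUANTUM_GY
    ds.PixelData = ints.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# DICOM RT Structure Set

def read_rtstruct(
    path: str | Path,
    reference_grid: DoseGrid,
    roles: dict[str, str] | None = None,
) -> list[Structure]:
    """Rasterize RT Structure Set planar contours onto the reference grid.

    A voxel belongs to an ROI iff its center lies inside a contour polygon
    on the slice nearest to the contour's plane (within half a slice
    spacing; contours farther away are skipped with a warning).  ``roles``
    optionally maps ROI names to structure roles (default ``oar``).
    """
    import pydicom
    from matplotlib.path import Path as MplPath

    ds = pydicom.dcmread(str(path))
    roles = roles or {}
    names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in ds.StructureSetROISequence
    }
    nz, ny, nx = reference_grid.shape
    oz, oy, ox = reference_grid.origin
    dz, dy, dx = reference_grid.spacing
    xs = ox + np.arange(nx) * dx
    ys = oy + np.arange(ny) * dy
    xx, yy = np.meshgrid(xs, ys)  # (ny, nx)
    points = np.column_stack([xx.ravel(), yy.ravel()])

    structures = []
    for roi_contour in ds.ROIContourSequence:
        number = int(roi_contour.ReferencedROINumber)
        name = names.get(number, f"roi_{number}")
        mask = np.zeros(reference_grid.shape, dtype=bool)
        for contour in getattr(roi_contour, "ContourSequence", []):
            if contour.ContourGeometricType != "CLOSED_PLANAR":
                warnings.warn(
                    f"{name}: skipping non-planar contour "
                    f"({contour.ContourGeometricType})", stacklevel=2,
                )
                continue
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            z = float(pts[:, 2].mean())
            k = int(np.round((z - oz) / dz))
            if not 0 <= k < nz or abs(z - (oz + k * dz)) > dz / 2 + 1e-9:
                warnings.warn(
                    f"{name}: contour at z={z:.2f} mm lies outside the grid; "
                    "skipped", stacklevel=2,
                )
                continue
            inside = MplPath(pts[:, :2]).contains_points(points)
            mask[k] |= inside.reshape(ny, nx)
        s = Structure(name=name, role=roles.get(name, "oar"), mask=mask)
        if not mask.any():
            s.flags["empty_after_rasterization"] = True
            warnings.warn(f"ROI {name!r} rasterized to an empty mask", stacklevel=2)
        structures.append(s)
    return structures


def write_rtstruct(
    path: str | Path,
    contours: dict[str, list[np.ndarray]],
) -> None:
    """Write a minimal RT Structure Set from named planar contours.

    ``contours`` maps ROI name -> list of (N, 3) arrays of (x, y, z) mm
    vertices, one array per closed planar contour.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID(_RTSTRUCT_SOP)
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "synthetic"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    frame_uid = generate_uid()
    for number, (name, rings) in enumerate(contours.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        for ring in rings:
            ring = np.asarray(ring, dtype=float).reshape(-1, 3)
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = ring.shape[0]
            c.ContourData = [float(v) for v in ring.ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    ds.save_as(str(path), enforce_file_format=True)
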