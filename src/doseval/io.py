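"""Standard-format I/O: portable .npz + JSON sidecars, DICOM RT files, NIfTI.

The portable format is the test-suite and pipeline default: a ``.npz``
holding the array plus a JSON sidecar (same stem, ``.json``) with
``{name, shape, spacing, origin, ...}``.  DICOM RT Structure Set and RT
Dose readers/writers are provided so clinical exports can be consumed;
the writers emit minimal but standard-conformant datasets, which also lets
the test suite exercise the readers without clinical files.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .grid import ContourSlice, ContourStack, DoseGrid, Grid3D, StructureMask

__all__ = [
    "save_mask",
    "load_mask",
    "save_dose",
    "load_dose",
    "save_mask_nifti",
    "write_rtstruct",
    "read_rtstruct",
    "write_rtdose",
    "read_rtdose",
    "write_cohort",
    "read_manifest",
]

RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"


# ---------------------------------------------------------------------------
# portable .npz + JSON sidecar
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_sidecar(path: Path, grid: Grid3D, **extra) -> None:
    meta = {
        "shape": list(grid.shape),
        "spacing": list(grid.spacing),
        "origin": list(grid.origin),
        **extra,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path: Path) -> dict:
    return json.loads(_sidecar_path(path).read_text())


def save_mask(path: str | Path, mask: StructureMask) -> Path:
    """Write a mask as ``.npz`` (uint8 voxels) with a JSON sidecar."""
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(path, voxels=mask.voxels.astype(np.uint8))
    _write_sidecar(path, mask.grid, name=mask.name, kind="mask")
    return path


def load_mask(path: str | Path) -> StructureMask:
    path = Path(path)
    meta = _read_sidecar(path)
    grid = Grid3D(tuple(meta["shape"]), tuple(meta["spacing"]), tuple(meta["origin"]))
    with np.load(path) as z:
        voxels = z["voxels"].astype(bool)
    return StructureMask(meta.get("name", path.stem), grid, voxels)


def save_dose(path: str | Path, dose: DoseGrid) -> Path:
    """Write a dose grid as ``.npz`` (float32 Gy) with a JSON sidecar."""
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(path, dose=dose.dose.astype(np.float32))
    _write_sidecar(path, dose.grid, prescription=dose.prescription, kind="dose")
    return path


def load_dose(path: str | Path) -> DoseGrid:
    path = Path(path)
    meta = _read_sidecar(path)
    grid = Grid3D(tuple(meta["shape"]), tuple(meta["spacing"]), tuple(meta["origin"]))
    with np.load(path) as z:
        dose = z["dose"].astype(float)
    return DoseGrid(grid, dose, float(meta["prescription"]))


def save_mask_nifti(path: str | Path, mask: StructureMask) -> Path:
    """Write a mask as NIfTI (array reordered to (x, y, z); LPS affine).

    NIfTI convention is RAS+; the affine flips x and y accordingly.  The
    JSON sidecar remains the loss-free geometry record.
    """
    import nibabel as nib

    path = Path(path)
    dz, dy, dx = mask.grid.spacing
    oz, oy, ox = mask.grid.origin
    affine = np.array(
        [
            [-dx, 0, 0, -ox],
            [0, -dy, 0, -oy],
            [0, 0, dz, oz],
            [0, 0, 0, 1],
        ]
    )
    img = nib.Nifti1Image(
        np.ascontiguousarray(mask.voxels.transpose(2, 1, 0).astype(np.uint8)), affine
    )
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# DICOM RT Structure Set
# ---------------------------------------------------------------------------


def _file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    fm = FileMetaDataset()
    fm.MediaStorageSOPClassUID = sop_class
    fm.MediaStorageSOPInstanceUID = sop_instance
    fm.TransferSyntaxUID = ExplicitVRLittleEndian
    return fm


def write_rtstruct(
    path: str | Path,
    stacks: dict[str, ContourStack],
    frame_of_reference_uid: str | None = None,
) -> Path:
    """Write named contour stacks as a DICOM RT Structure Set."""
    path = Path(path)
    for_uid = frame_of_reference_uid or generate_uid()
    sop_instance = generate_uid()
    ds = Dataset()
    ds.SOPClassUID = RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = sop_instance
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "doseval"
    ds.PatientName = "phantom"
    ds.PatientID = "phantom"

    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for num, (name, stack) in enumerate(stacks.items(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = for_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for sl in stack.slices:
            for poly in sl.polygons:
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.NumberOfContourPoints = len(poly)
                data = []
                for yv, xv in poly:  # ContourData is x, y, z triplets
                    data += [float(xv), float(yv), float(sl.z_mm)]
                c.ContourData = data
                rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)

    ds.file_meta = _file_meta(RTSTRUCT_SOP_CLASS, sop_instance)
    ds.save_as(str(path), enforce_file_format=True)
    return path


def read_rtstruct(
    path: str | Path, expected_frame_of_reference: str | None = None
) -> dict[str, ContourStack]:
    """Read a DICOM RT Structure Set into named contour stacks (mm coordinates).

    Raises
    ------
    ValueError
        If the file is not an RT Structure Set or lacks contour sequences.
    """
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "SOPClassUID", None) != RTSTRUCT_SOP_CLASS:
        raise ValueError(f"{path} is not a DICOM RT Structure Set")
    if "ROIContourSequence" not in ds or "StructureSetROISequence" not in ds:
        raise ValueError(f"{path} has no ROI contour sequence")
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    if expected_frame_of_reference is not None:
        fors = {
            str(getattr(r, "ReferencedFrameOfReferenceUID", ""))
            for r in ds.StructureSetROISequence
        }
        if fors - {expected_frame_of_reference}:
            warnings.warn(
                f"frame-of-reference mismatch in {path}: {fors}", stacklevel=2
            )
    out: dict[str, ContourStack] = {}
    for rc in ds.ROIContourSequence:
        name = names[int(rc.ReferencedROINumber)]
        by_z: dict[float, list[np.ndarray]] = {}
        for c in getattr(rc, "ContourSequence", []):
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            z = float(pts[0, 2])
            by_z.setdefault(z, []).append(pts[:, [1, 0]])  # (y, x)
        slices = [ContourSlice(z, polys) for z, polys in sorted(by_z.items())]
        out[name] = ContourStack(name, slices)
    return out


# ---------------------------------------------------------------------------
# DICOM RT Dose
# ---------------------------------------------------------------------------

_PRIVATE_CREATOR = "doseval"


def write_rtdose(path: str | Path, dose: DoseGrid) -> Path:
    """Write a dose grid as a DICOM RT Dose (uint32 pixels x DoseGridScaling).

    The prescription is stored in a private block so round trips are
    self-contained.
    """
    path = Path(path)
    sop_instance = generate_uid()
    ds = Dataset()
    ds.SOPClassUID = RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = sop_instance
    ds.Modality = "RTDOSE"
    ds.PatientName = "phantom"
    ds.PatientID = "phantom"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"

    nz, ny, nx = dose.grid.shape
    dz, dy, dx = dose.grid.spacing
    oz, oy, ox = dose.grid.origin
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [dy, dx]  # row spacing, column spacing
    ds.ImagePositionPatient = [ox, oy, oz]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [k * dz for k in range(nz)]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0

    dmax = float(dose.dose.max())
    scaling = dmax / (2**32 - 1) if dmax > 0 else 1.0
    ds.DoseGridScaling = scaling
    pixels = np.rint(dose.dose / scaling).astype(np.uint32) if dmax > 0 else np.zeros(
        dose.grid.shape, dtype=np.uint32
    )
    ds.PixelData = pixels.tobytes()

    block = ds.private_block(0x7771, _PRIVATE_CREATOR, create=True)
    block.add_new(0x01, "DS", str(dose.prescription))

    ds.file_meta = _file_meta(RTDOSE_SOP_CLASS, sop_instance)
    ds.save_as(str(path), enforce_file_format=True)
    return path


def read_rtdose(path: str | Path, prescription: float | None = None) -> DoseGrid:
    """Read a DICOM RT Dose into Gy on its native grid.

    ``prescription`` overrides the private-block value written by
    :func:`write_rtdose`; one of the two must be available.

    Raises
    ------
    ValueError
        If the file is not an RT Dose, lacks DoseGridScaling, has
        non-uniform slice spacing (unsupported), or no prescription is
        available.
    """
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "SOPClassUID", None) != RTDOSE_SOP_CLASS:
        raise ValueError(f"{path} is not a DICOM RT Dose")
    if "DoseGridScaling" not in ds:
        raise ValueError(f"{path} lacks DoseGridScaling")
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    if len(offsets) > 1:
        steps = np.diff(offsets)
        if not np.allclose(steps, steps[0], atol=1e-6):
            raise ValueError(f"{path} has non-uniform slice spacing (unsupported)")
        dz = float(steps[0])
    else:
        dz = 1.0
    dy, dx = (float(v) for v in ds.PixelSpacing)
    ox, oy, oz = (float(v) for v in ds.ImagePositionPatient)
    nz = int(ds.NumberOfFrames)
    ny, nx = int(ds.Rows), int(ds.Columns)
    grid = Grid3D((nz, ny, nx), (dz, dy, dx), (oz, oy, ox))
    arr = ds.pixel_array.reshape(nz, ny, nx).astype(float) * float(ds.DoseGridScaling)

    if prescription is None:
        try:
            block = ds.private_block(0x7771, _PRIVATE_CREATOR)
            prescription = float(block[0x01].value)
        except KeyError:
            raise ValueError(
                f"{path} carries no prescription; pass prescription= explicitly"
            ) from None
    return DoseGrid(grid, arr, prescription)


# ---------------------------------------------------------------------------
# cohort manifests
# ---------------------------------------------------------------------------


def write_cohort(cases, out_dir: str | Path) -> Path:
    """Write a cohort (masks, PTVs, doses as portable files) plus manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"format": "doseval-cohort-v1", "cases": []}
    for case in cases:
        cdir = out_dir / case.case_id
        cdir.mkdir(exist_ok=True)
        entry: dict = {
            "id": case.case_id,
            "prescription": case.prescription,
            "technique": case.technique,
            "sets": {},
        }
        for cs in case.contour_sets:
            sdir = cdir / cs
            sdir.mkdir(exist_ok=True)
            sets: dict = {"structures": {}}
            for organ, m in case.structures[cs].items():
                p = save_mask(sdir / f"{organ}.npz", m)
                sets["structures"][organ] = str(p.relative_to(out_dir))
            p = save_mask(sdir / "PTV.npz", case.ptv[cs])
            sets["ptv"] = str(p.relative_to(out_dir))
            if cs in case.dose:
                p = save_dose(sdir / "dose.npz", case.dose[cs])
                sets["dose"] = str(p.relative_to(out_dir))
            entry["sets"][cs] = sets
        manifest["cases"].append(entry)
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_manifest(manifest_path: str | Path) -> list[dict]:
    """Load a cohort manifest; returns the case entries with absolute paths."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format") != "doseval-cohort-v1":
        raise ValueError(f"{manifest_path} is not a doseval cohort manifest")
    cases = []
    for entry in manifest["cases"]:
        e = {
            "id": entry["id"],
            "prescription": entry["prescription"],
            "technique": entry["technique"],
            "sets": {},
        }
        for cs, sets in entry["sets"].items():
            e["sets"][cs] = {
                "structures": {
                    organ: root / p for organ, p in sets["structures"].items()
                },
                "ptv": root / sets["ptv"],
                "dose": root / sets["dose"] if "dose" in sets else None,
            }
        cases.append(e)
    return cases
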