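"""Reading and writing DWI series, ROI masks and parametric maps.

Supported external formats
--------------------------
* DICOM: a directory of single-frame ``.dcm`` files, one file per slice per
  acquisition.  The b-value is taken from the standard diffusion tag
  (0018,9087), with the Siemens private tag (0019,100C) as fallback; the
  diffusion direction from the gradient-orientation tag (0018,9089), absent
  or zero meaning a trace/combined frame.
* NIfTI-1 (``.nii``/``.nii.gz``): a 4-D volume accompanied by a JSON sidecar
  ``{"bvalues": [...], "directions": [...]}`` next to the image file.
* ROI masks: NIfTI volumes, nonzero = inside.
* Parametric maps: NIfTI float32 with the map kind recorded in the header
  ``descrip`` field and mirrored in a JSON sidecar.

Conventions: 0-based voxel indices; masks and maps share a grid (nearest-
neighbour mask resampling is opt-in); invalid voxels are NaN, never
sentinel values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

log = logging.getLogger(__name__)

#: Valid parametric-map kinds and their units.
MAP_KINDS = {
    "ADC": "mm^2/s",
    "IVIM-D": "mm^2/s",
    "IVIM-Dstar": "mm^2/s",
    "IVIM-f": "dimensionless",
    "S0": "a.u.",
}

# DICOM tags used for diffusion metadata.
_TAG_BVALUE = (0x0018, 0x9087)
_TAG_BVALUE_SIEMENS = (0x0019, 0x100C)
_TAG_GRADIENT = (0x0018, 0x9089)


@dataclass
class DWISeries:
    """A 4-D diffusion-weighted series: one 3-D frame per (b, direction).

    Parameters
    ----------
    signal
        Non-negative array indexed ``(x, y, z, acquisition)``.
    bvalues
        Diffusion weighting per acquisition, s/mm².
    direction_index
        Diffusion direction id per acquisition (0-2), or -1 for a
        trace/combined frame.
    spacing
        Voxel dimensions in mm.
    """

    signal: np.ndarray
    bvalues: list[float]
    direction_index: list[int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    series_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, acquisition)")
        n_acq = self.signal.shape[3]
        if len(self.bvalues) != n_acq or len(self.direction_index) != n_acq:
            raise ValueError(
                f"b-value count mismatch: {len(self.bvalues)} b-values / "
                f"{len(self.direction_index)} directions for {n_acq} frames"
            )
        if any(b < 0 for b in self.bvalues):
            raise ValueError("b-values must be non-negative")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")

    @property
    def n_acquisitions(self) -> int:
        return self.signal.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class ParametricMap:
    """A 3-D quantitative map (ADC, IVIM-D, IVIM-Dstar, IVIM-f or S0).

    NaN marks invalid voxels.  Diffusivities are stored in mm²/s; the
    perfusion fraction f is dimensionless in [0, 1].
    """

    values: np.ndarray
    kind: str
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("map values must be 3-D")
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}; expected one of {sorted(MAP_KINDS)}")
        if not self.units:
            self.units = MAP_KINDS[self.kind]
        finite = self.values[np.isfinite(self.values)]
        if self.kind == "IVIM-f" and finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("IVIM-f values must lie in [0, 1] or be NaN")
        if self.kind in ("ADC", "IVIM-D", "IVIM-Dstar") and finite.size and finite.min() < 0:
            raise ValueError(f"{self.kind} values must be non-negative or NaN")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ROIMask:
    """Binary region-of-interest mask on a parametric-map grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label: str = "roi"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# DWI series
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_dwi_series(path, format_hint: str | None = None) -> DWISeries:
    """Read a DWI series from a DICOM directory or NIfTI + JSON sidecar.

    Returns a :class:`DWISeries` with one 3-D frame per (b, direction)
    acquisition; acquisition order is preserved as stored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None:
        fmt = "dicom" if path.is_dir() else "nifti"
    if fmt == "dicom":
        return _read_dwi_dicom(path)
    if fmt == "nifti":
        return _read_dwi_nifti(path)
    raise ValueError(f"unknown format hint {fmt!r}")


def _read_dwi_nifti(path: Path) -> DWISeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing b-value sidecar {sidecar.name!r}: NIfTI DWI requires a JSON "
            'sidecar {"bvalues": [...], "directions": [...]}'
        )
    meta = json.loads(sidecar.read_text())
    if "bvalues" not in meta:
        raise ValueError(f"sidecar {sidecar.name!r} lacks a 'bvalues' entry")
    bvalues = [float(b) for b in meta["bvalues"]]
    directions = [int(d) for d in meta.get("directions", [-1] * len(bvalues))]
    if len(bvalues) != data.shape[3]:
        raise ValueError(
            f"b-value count mismatch: sidecar lists {len(bvalues)} b-values "
            f"but the volume has {data.shape[3]} frames"
        )
    zooms = img.header.get_zooms()[:3]
    return DWISeries(
        signal=data,
        bvalues=bvalues,
        direction_index=directions,
        spacing=tuple(float(z) for z in zooms),
        series_id=path.name,
    )


def _dicom_bvalue(ds: Dataset) -> float:
    if _TAG_BVALUE in ds:
        return float(ds[_TAG_BVALUE].value)
    if _TAG_BVALUE_SIEMENS in ds:
        return float(ds[_TAG_BVALUE_SIEMENS].value)
    raise ValueError(
        "missing b-value metadata: neither DiffusionBValue (0018,9087) nor the "
        "Siemens private tag (0019,100C) is present"
    )


def _dicom_direction(ds: Dataset) -> int:
    if _TAG_GRADIENT not in ds:
        return -1
    vec = np.asarray([float(v) for v in ds[_TAG_GRADIENT].value])
    if np.allclose(vec, 0):
        return -1
    return int(np.argmax(np.abs(vec)))


def _read_dwi_dicom(path: Path) -> DWISeries:
    files = sorted(path.glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files in {path}")
    slices = []
    for f in files:
        ds = pydicom.dcmread(str(f))
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        pos = getattr(ds, "ImagePositionPatient", (0.0, 0.0, 0.0))
        slices.append(
            {
                "acq": int(getattr(ds, "AcquisitionNumber", 0)),
                "instance": int(getattr(ds, "InstanceNumber", 0)),
                "z": float(pos[2]),
                "b": _dicom_bvalue(ds),
                "dir": _dicom_direction(ds),
                "pixels": arr,
                "spacing_xy": [float(v) for v in getattr(ds, "PixelSpacing", [1.0, 1.0])],
                "dz": float(getattr(ds, "SliceThickness", 1.0)),
            }
        )
    shapes = {s["pixels"].shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame geometry across DICOM files: {sorted(shapes)}")
    acqs = sorted({s["acq"] for s in slices})
    frames, bvalues, directions = [], [], []
    n_slices = None
    for acq in acqs:
        group = sorted((s for s in slices if s["acq"] == acq), key=lambda s: (s["z"], s["instance"]))
        if n_slices is None:
            n_slices = len(group)
        elif len(group) != n_slices:
            raise ValueError("inconsistent frame geometry: unequal slice counts per acquisition")
        if len({s["b"] for s in group}) != 1:
            raise ValueError(f"acquisition {acq} mixes b-values")
        # slices stack along z; pixel_array rows/cols map to y/x -> transpose
        vol = np.stack([s["pixels"].T for s in group], axis=2)
        frames.append(vol)
        bvalues.append(group[0]["b"])
        directions.append(group[0]["dir"])
    first = slices[0]
    spacing = (first["spacing_xy"][1], first["spacing_xy"][0], first["dz"])
    return DWISeries(
        signal=np.stack(frames, axis=3),
        bvalues=bvalues,
        direction_index=directions,
        spacing=spacing,
        series_id=path.name,
    )


def write_dwi_series(dwi: DWISeries, path, fmt: str = "nifti") -> None:
    """Write a DWI series as NIfTI + JSON sidecar or as a DICOM directory."""
    path = Path(path)
    if fmt == "nifti":
        _write_dwi_nifti(dwi, path)
    elif fmt == "dicom":
        _write_dwi_dicom(dwi, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _write_dwi_nifti(dwi: DWISeries, path: Path) -> None:
    affine = np.diag(list(dwi.spacing) + [1.0])
    img = nib.Nifti1Image(dwi.signal.astype(np.float32), affine)
    img.header.set_zooms(tuple(dwi.spacing) + (1.0,))
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps({"bvalues": list(map(float, dwi.bvalues)),
                    "directions": list(map(int, dwi.direction_index))})
    )


def _write_dwi_dicom(dwi: DWISeries, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    instance = 0
    peak = float(dwi.signal.max())
    slope = peak / 65535.0 if peak > 0 else 1.0
    directions_xyz = {0: [1.0, 0.0, 0.0], 1: [0.0, 1.0, 0.0], 2: [0.0, 0.0, 1.0]}
    for acq in range(dwi.n_acquisitions):
        for k in range(dwi.shape[2]):
            instance += 1
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
            meta.MediaStorageSOPInstanceUID = generate_uid()
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = Dataset()
            ds.file_meta = meta
            ds.SOPClassUID = meta.MediaStorageSOPClassUID
            ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
            ds.SeriesInstanceUID = series_uid
            ds.StudyInstanceUID = series_uid
            ds.Modality = "MR"
            ds.SeriesDescription = dwi.series_id or "synthetic DWI"
            ds.InstanceNumber = instance
            ds.AcquisitionNumber = acq
            ds.PixelSpacing = [dwi.spacing[1], dwi.spacing[0]]  # row, col
            ds.SliceThickness = dwi.spacing[2]
            ds.ImagePositionPatient = [0.0, 0.0, k * dwi.spacing[2]]
            ds.add_new(_TAG_BVALUE, "FD", float(dwi.bvalues[acq]))
            d = dwi.direction_index[acq]
            ds.add_new(_TAG_GRADIENT, "FD", directions_xyz.get(d, [0.0, 0.0, 0.0]))
            plane = dwi.signal[:, :, k, acq].T  # rows = y, cols = x
            stored = np.round(plane / slope).astype(np.uint16)
            ds.Rows, ds.Columns = stored.shape
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.RescaleSlope = slope
            ds.RescaleIntercept = 0.0
            ds.PixelData = stored.tobytes()
            pydicom.dcmwrite(str(path / f"{instance:05d}.dcm"), ds,
                             enforce_file_format=True)


# ---------------------------------------------------------------------------
# ROI masks
# ---------------------------------------------------------------------------

def read_roi_mask(path, reference: ParametricMap, allow_resample: bool = False,
                  label: str | None = None) -> ROIMask:
    """Read a binary ROI mask and align it with ``reference``.

    Nonzero voxels are inside.  If the mask grid differs from the reference
    grid, nearest-neighbour resampling is applied only when
    ``allow_resample`` is true; otherwise a grid mismatch is an error.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj) != 0
    if data.ndim != 3:
        raise ValueError("ROI mask must be 3-D")
    if data.shape != reference.shape:
        if not allow_resample:
            raise ValueError(
                f"mask grid {data.shape} does not match reference grid "
                f"{reference.shape} and resampling is not enabled"
            )
        data = resample_mask_nearest(data, reference.shape)
    if not data.any():
        raise ValueError("ROI contains no voxels")
    return ROIMask(mask=data, spacing=reference.spacing, label=label or path.name)


def resample_mask_nearest(mask: np.ndarray, out_shape: tuple[int, int, int]) -> np.ndarray:
    """Nearest-neighbour resampling of a binary mask onto ``out_shape``.

    Each output voxel takes the input voxel whose cell contains the output
    voxel centre (grids assumed to span the same physical extent).
    """
    mask = np.asarray(mask).astype(bool)
    idx = []
    for ax in range(3):
        n_in, n_out = mask.shape[ax], out_shape[ax]
        src = np.floor((np.arange(n_out) + 0.5) * n_in / n_out).astype(int)
        idx.append(np.clip(src, 0, n_in - 1))
    return mask[np.ix_(idx[0], idx[1], idx[2])]


def write_roi_mask(roi: ROIMask, path) -> None:
    affine = np.diag(list(roi.spacing) + [1.0])
    img = nib.Nifti1Image(roi.mask.astype(np.uint8), affine)
    img.header.set_zooms(roi.spacing)
    nib.save(img, str(Path(path)))


# ---------------------------------------------------------------------------
# Parametric maps
# ---------------------------------------------------------------------------

def write_parametric_map(pmap: ParametricMap, path) -> None:
    """Write a parametric map as NIfTI float32 with kind/units metadata.

    The kind is stored in the NIfTI ``descrip`` header field and mirrored in
    a JSON sidecar so either survives transport alone.
    """
    if pmap.kind not in MAP_KINDS:
        raise ValueError(f"unknown map kind {pmap.kind!r}")
    path = Path(path)
    affine = np.diag(list(pmap.spacing) + [1.0])
    img = nib.Nifti1Image(pmap.values.astype(np.float32), affine)
    img.header.set_zooms(pmap.spacing)
    img.header["descrip"] = f"kind={pmap.kind}".encode()
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps({"kind": pmap.kind, "units": pmap.units}))


def read_parametric_map(path) -> ParametricMap:
    """Read a parametric map written by :func:`write_parametric_map`."""
    path = Path(path)
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    kind = None
    descrip = img.header["descrip"].tobytes().decode(errors="ignore").rstrip("\x00")
    if descrip.startswith("kind="):
        kind = descrip[5:].strip()
    sidecar = _sidecar_path(path)
    units = ""
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        kind = kind or meta.get("kind")
        units = meta.get("units", "")
    if kind not in MAP_KINDS:
        raise ValueError(f"unknown or missing map kind {kind!r} in {path.name}")
    zooms = img.header.get_zooms()[:3]
    return ParametricMap(values=values, kind=kind,
                         spacing=tuple(float(z) for z in zooms), units=units)
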