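"""Reading and writing phase-contrast CMR exams.

A through-plane PC acquisition yields paired magnitude and phase image
stacks over the cardiac cycle (typically 20-30 frames).  Anatomy is visible
in the magnitude channel; through-plane velocity is encoded in the phase
pixel values.  This module defines the in-memory containers (:class:`PCSeries`,
:class:`SegmentationMap`) and round-trips them through DICOM directories, a
self-contained single-file fixture format (compressed ``.npz``), and NIfTI
mask stacks.

Vendors disagree about where velocity-encoding metadata lives in the DICOM
header, so :func:`read_dicom_series` resolves VENC and the reconstruction
scale through a configurable *dialect* mapping instead of hard-coding one
vendor's private block.
"""

from __future__ import annotations

import logging
import warnings
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

MM2_TO_CM2 = 0.01  # 1 mm^2 = 0.01 cm^2; applied exactly once, on header read

__all__ = [
    "PCSeries",
    "SegmentationMap",
    "PairingError",
    "MetadataError",
    "AlignmentError",
    "FixtureFormatError",
    "DEFAULT_DICOM_DIALECT",
    "read_dicom_series",
    "write_dicom_series",
    "read_fixture",
    "write_fixture",
    "read_mask_nifti",
    "write_mask_nifti",
]


class PairingError(ValueError):
    """Magnitude/phase series could not be unambiguously paired."""


class MetadataError(KeyError):
    """A required acquisition header field is missing."""


class AlignmentError(ValueError):
    """Frame counts or frame geometry disagree between aligned stacks."""


class FixtureFormatError(ValueError):
    """A fixture archive is malformed or truncated."""


@dataclass(frozen=True)
class PCSeries:
    """One exam's temporally ordered magnitude + phase frame pairs.

    Attributes
    ----------
    magnitude : ndarray, shape (n_frames, H, W)
        Non-negative raw magnitude pixel values.
    phase : ndarray, shape (n_frames, H, W)
        Signed raw phase pixel values (velocity-encoded).
    venc : float
        Velocity-encoding limit in cm/s; the maximum velocity representable
        without phase aliasing.
    recon_scale : float
        Dimensionless reconstruction scaling factor from the header.
    pixel_area : float
        In-plane pixel area in cm^2.
    frame_interval : float
        Time between consecutive temporal segments, in seconds.
    pixel_spacing_mm : tuple of float
        (row, column) spacing in mm, kept for surface-distance metrics.
    exam_id : str
        Identifier used for fold assignment and reporting.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    venc: float
    recon_scale: float
    pixel_area: float
    frame_interval: float
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    exam_id: str = "exam"

    def __post_init__(self) -> None:
        mag = np.asarray(self.magnitude)
        pha = np.asarray(self.phase)
        if mag.ndim != 3 or pha.ndim != 3:
            raise AlignmentError("magnitude and phase must be (n_frames, H, W) stacks")
        if mag.shape != pha.shape:
            raise AlignmentError(
                f"magnitude shape {mag.shape} != phase shape {pha.shape}"
            )
        if mag.shape[0] < 1:
            raise AlignmentError("series must contain at least one frame")
        for name in ("venc", "recon_scale", "pixel_area", "frame_interval"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        object.__setattr__(self, "magnitude", mag)
        object.__setattr__(self, "phase", pha)

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.magnitude.shape[1:]

    def with_frames(self, magnitude: np.ndarray, phase: np.ndarray) -> "PCSeries":
        return replace(self, magnitude=magnitude, phase=phase)


@dataclass(frozen=True)
class SegmentationMap:
    """Frame-aligned binary valve masks (1 = valve, 0 = non-valve)."""

    masks: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.masks)
        if m.ndim != 3:
            raise AlignmentError("masks must be a (n_frames, H, W) stack")
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be strictly binary, found {vals}")
        object.__setattr__(self, "masks", m.astype(np.uint8))

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.masks.shape

    def check_matches(self, series: PCSeries) -> None:
        if self.masks.shape != series.magnitude.shape:
            raise AlignmentError(
                f"mask shape {self.masks.shape} != series shape {series.magnitude.shape}"
            )


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

#: Default header dialect.  Standard public tags cover geometry and timing;
#: VENC and the reconstruction scale live in a package-owned private block
#: (creator "AORTAFLOW", group 0x0011) because classic 2D PC exports have no
#: public tag for them and each vendor uses a different private one.  Override
#: entries with ``(group, element)`` tuples or pydicom keywords for other
#: vendors.
DEFAULT_DICOM_DIALECT: dict[str, object] = {
    "venc": (0x0011, 0x1001),
    "recon_scale": (0x0011, 0x1002),
    "pixel_spacing": "PixelSpacing",
    "trigger_time": "TriggerTime",
    "series_number": "SeriesNumber",
    "magnitude_series_number": 1,
    "phase_series_number": 2,
    "private_creator": "AORTAFLOW",
}


def _header_value(ds, key, field_name: str):
    import pydicom

    if isinstance(key, tuple):
        tag = pydicom.tag.Tag(*key)
        if tag not in ds:
            raise MetadataError(f"required header field '{field_name}' (tag {tag}) missing")
        return ds[tag].value
    if not hasattr(ds, key) or getattr(ds, key) is None:
        raise MetadataError(f"required header field '{field_name}' ({key}) missing")
    return getattr(ds, key)


def read_dicom_series(
    directory: str | Path,
    dialect: Mapping[str, object] | None = None,
    exam_id: str | None = None,
) -> PCSeries:
    """Read one exam (one magnitude series + one phase series) from a directory.

    Frames are ordered by trigger time from the header, never by file name.
    The frame interval is the mean gap between consecutive trigger times
    (converted ms -> s); uneven gaps are tolerated with a logged warning
    because the downstream flow integral assumes a single scalar interval.
    """
    import pydicom

    cfg = dict(DEFAULT_DICOM_DIALECT)
    if dialect:
        cfg.update(dialect)
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise PairingError(f"no DICOM files found in {directory}")

    by_series: dict[int, list] = {}
    for f in files:
        ds = pydicom.dcmread(f)
        sn = int(_header_value(ds, cfg["series_number"], "series_number"))
        by_series.setdefault(sn, []).append(ds)

    mag_sn = int(cfg["magnitude_series_number"])
    pha_sn = int(cfg["phase_series_number"])
    if mag_sn not in by_series or pha_sn not in by_series:
        raise PairingError(
            f"expected magnitude series {mag_sn} and phase series {pha_sn}; "
            f"found series numbers {sorted(by_series)}"
        )
    if len(by_series) != 2:
        raise PairingError(
            f"directory holds {len(by_series)} series; exactly one magnitude "
            "and one phase series are required"
        )

    def ordered(stack):
        keyed = [
            (float(_header_value(ds, cfg["trigger_time"], "trigger_time")), ds)
            for ds in stack
        ]
        keyed.sort(key=lambda kv: kv[0])
        return [k for k, _ in keyed], [ds for _, ds in keyed]

    mag_t, mag_ds = ordered(by_series[mag_sn])
    pha_t, pha_ds = ordered(by_series[pha_sn])
    if len(mag_ds) != len(pha_ds):
        raise AlignmentError(
            f"{len(mag_ds)} magnitude frames but {len(pha_ds)} phase frames"
        )

    ref = mag_ds[0]
    venc = float(_header_value(ref, cfg["venc"], "venc"))
    recon_scale = float(_header_value(ref, cfg["recon_scale"], "recon_scale"))
    spacing = _header_value(ref, cfg["pixel_spacing"], "pixel_spacing")
    row_mm, col_mm = float(spacing[0]), float(spacing[1])
    pixel_area = row_mm * col_mm * MM2_TO_CM2

    if len(mag_t) > 1:
        gaps = np.diff(mag_t)
        frame_interval = float(np.mean(gaps)) / 1000.0  # TriggerTime is in ms
        if gaps.size and not np.allclose(gaps, gaps[0], rtol=1e-3):
            logger.warning(
                "uneven trigger-time gaps (min %.3f, max %.3f ms); using mean gap",
                gaps.min(),
                gaps.max(),
            )
    else:
        frame_interval = float(_header_value(ref, "RepetitionTime", "frame_interval")) / 1000.0

    magnitude = np.stack([ds.pixel_array.astype(np.float64) for ds in mag_ds])
    phase_frames = []
    for ds in pha_ds:
        arr = ds.pixel_array
        if int(getattr(ds, "PixelRepresentation", 0)) == 1:
            arr = arr.astype(np.int16)
        phase_frames.append(arr.astype(np.float64))
    phase = np.stack(phase_frames)

    return PCSeries(
        magnitude=magnitude,
        phase=phase,
        venc=venc,
        recon_scale=recon_scale,
        pixel_area=pixel_area,
        frame_interval=frame_interval,
        pixel_spacing_mm=(row_mm, col_mm),
        exam_id=exam_id or directory.name,
    )


def write_dicom_series(
    series: PCSeries,
    directory: str | Path,
    dialect: Mapping[str, object] | None = None,
) -> Path:
    """Write a PCSeries as a DICOM directory (magnitude + phase series).

    Used by the phantom module for round-trip tests.  Magnitude pixels are
    stored as unsigned 16-bit, phase pixels as signed 16-bit; both are rounded
    to integers, so velocities survive only to quantization of the integer
    encoding.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    cfg = dict(DEFAULT_DICOM_DIALECT)
    if dialect:
        cfg.update(dialect)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    row_mm, col_mm = series.pixel_spacing_mm
    study_uid = generate_uid(entropy_srcs=[series.exam_id, "study"])

    def write_frame(arr: np.ndarray, sn: int, frame: int, signed: bool) -> None:
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=[series.exam_id, str(sn), str(frame)]
        )
        ds.SOPClassUID = pydicom.uid.MRImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = generate_uid(entropy_srcs=[series.exam_id, str(sn)])
        ds.Modality = "MR"
        ds.SeriesNumber = sn
        ds.InstanceNumber = frame + 1
        ds.PatientID = series.exam_id
        ds.PatientName = series.exam_id
        ds.Rows, ds.Columns = arr.shape
        ds.PixelSpacing = [f"{row_mm:g}", f"{col_mm:g}"]
        ds.TriggerTime = f"{frame * series.frame_interval * 1000.0:g}"
        ds.RepetitionTime = f"{series.frame_interval * 1000.0:g}"
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1 if signed else 0
        block = ds.private_block(0x0011, str(cfg["private_creator"]), create=True)
        block.add_new(0x01, "DS", f"{series.venc:.10g}")
        block.add_new(0x02, "DS", f"{series.recon_scale:.10g}")
        if signed:
            ds.PixelData = np.round(arr).astype("<i2").tobytes()
        else:
            ds.PixelData = np.round(arr).clip(0, 65535).astype("<u2").tobytes()
        ds.save_as(directory / f"s{sn}_f{frame:03d}.dcm", enforce_file_format=True)

    for n in range(series.n_frames):
        write_frame(series.magnitude[n], int(cfg["magnitude_series_number"]), n, signed=False)
        write_frame(series.phase[n], int(cfg["phase_series_number"]), n, signed=True)
    return directory


# ---------------------------------------------------------------------------
# Fixture format
# ---------------------------------------------------------------------------

_FIXTURE_META_KEYS = ("venc", "recon_scale", "pixel_area", "frame_interval")


def write_fixture(
    series: PCSeries,
    path: str | Path,
    masks: SegmentationMap | None = None,
) -> Path:
    """Write a self-contained single-file exam archive (compressed ``.npz``).

    The archive holds the magnitude stack, phase stack, optional mask stack
    and a metadata record; writing the same series twice produces identical
    bytes (numpy's zip layout is deterministic for fixed arrays).
    """
    path = Path(path)
    payload: dict[str, np.ndarray] = {
        "magnitude": series.magnitude,
        "phase": series.phase,
        "meta": np.array(
            [series.venc, series.recon_scale, series.pixel_area, series.frame_interval],
            dtype=np.float64,
        ),
        "pixel_spacing_mm": np.array(series.pixel_spacing_mm, dtype=np.float64),
        "exam_id": np.array(series.exam_id),
    }
    if masks is not None:
        masks.check_matches(series)
        payload["masks"] = masks.masks
    with open(path, "wb") as fh:
        np.savez_compressed(fh, **payload)
    return path


def read_fixture(path: str | Path) -> tuple[PCSeries, SegmentationMap | None]:
    """Read an archive written by :func:`write_fixture` (lossless round trip)."""
    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as z:
            required = {"magnitude", "phase", "meta"}
            if not required <= set(z.files):
                raise FixtureFormatError(
                    f"{path} is missing keys {sorted(required - set(z.files))}"
                )
            meta = z["meta"]
            if meta.shape != (len(_FIXTURE_META_KEYS),):
                raise FixtureFormatError(f"{path}: malformed metadata record")
            spacing = tuple(z["pixel_spacing_mm"]) if "pixel_spacing_mm" in z.files else (1.0, 1.0)
            exam_id = str(z["exam_id"]) if "exam_id" in z.files else path.stem
            series = PCSeries(
                magnitude=z["magnitude"],
                phase=z["phase"],
                venc=float(meta[0]),
                recon_scale=float(meta[1]),
                pixel_area=float(meta[2]),
                frame_interval=float(meta[3]),
                pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
                exam_id=exam_id,
            )
            masks = SegmentationMap(z["masks"]) if "masks" in z.files else None
    except (OSError, ValueError, KeyError, zipfile.BadZipFile) as exc:
        if isinstance(exc, FixtureFormatError):
            raise
        raise FixtureFormatError(f"{path} is not a readable fixture archive: {exc}") from exc
    return series, masks


# ---------------------------------------------------------------------------
# NIfTI masks
# ---------------------------------------------------------------------------

def write_mask_nifti(masks: SegmentationMap, path: str | Path) -> Path:
    """Export a mask stack as a NIfTI volume (frames along the last axis)."""
    import nibabel as nib

    path = Path(path)
    vol = np.moveaxis(masks.masks, 0, -1).astype(np.uint8)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))
    return path


def read_mask_nifti(path: str | Path) -> SegmentationMap:
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj)
    if vol.ndim == 2:
        vol = vol[..., None]
    masks = np.moveaxis(vol, -1, 0)
    return SegmentationMap((masks > 0.5).astype(np.uint8))
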