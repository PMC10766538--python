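"""Discovery and assembly of raw DICOM series into oriented volumes.

Raw preclinical exports arrive as directory trees whose organisation
varies between sites: a *layout* descriptor (an ordered tuple of roles,
one per directory level under the root) tells the indexer where the
subject, session and series levels sit.  Files are grouped into
:class:`SeriesRecord` objects, which :func:`assemble_volume` turns into
:class:`VolumeStack` arrays indexed ``(x, y, z[, echo][, frame])`` with a
NIfTI-style RAS affine.  :func:`reorient` moves a stack to any axis-code
orientation (e.g. ``RSA`` → ``RPI``) and :func:`extract_diffusion_tables`
pulls FSL-style b-value/b-vector tables from diffusion series.

Both classic one-file-per-slice series and multi-frame files (one file
per time frame holding a full slice stack) assemble to identical arrays.
"""

from __future__ import annotations

import logging
import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pydicom
from nibabel.orientations import (
    aff2axcodes,
    apply_orientation,
    axcodes2ornt,
    inv_ornt_aff,
    io_orientation,
    ornt_transform,
)
from pydicom.errors import InvalidDicomError

logger = logging.getLogger(__name__)

#: Directory-level roles a layout descriptor may declare.
LAYOUT_ROLES = ("subject", "session", "series", "ignore")

#: Default layout: root/<subject>/<session>/<series>/files
DEFAULT_LAYOUT = ("subject", "session", "series")

#: Single-session layout: root/<subject>/<series>/files
SINGLE_SESSION_LAYOUT = ("subject", "series")


class DicomIngestError(RuntimeError):
    """Raised when a series cannot be assembled into a volume."""


@dataclass
class SeriesRecord:
    """One DICOM series: an ordered group of files plus light metadata.

    ``echo_times`` are in seconds (converted from the millisecond DICOM
    convention); ``frame_count`` counts distinct temporal positions.
    """

    series_id: str
    subject_label: str
    session_label: str | None
    modality_hint: str
    file_paths: list[Path]
    echo_times: list[float] = field(default_factory=list)
    frame_count: int = 1
    acquisition_year: int | None = None
    series_description: str = ""
    valid: bool = True
    invalid_reason: str | None = None

    def __post_init__(self) -> None:
        if not self.file_paths:
            raise ValueError("SeriesRecord requires at least one file")
        if len(self.echo_times) > 1:
            diffs = np.diff(self.echo_times)
            if not np.all(diffs > 0):
                raise ValueError("echo_times must be strictly increasing")
        if self.frame_count < 1:
            raise ValueError("frame_count must be >= 1")


@dataclass
class VolumeStack:
    """Multi-dimensional image volume with spatial orientation.

    ``voxels`` is indexed ``(x, y, z)`` plus an echo axis when the series
    sampled more than one echo time and a trailing frame axis when it is
    dynamic.  ``affine`` maps voxel indices to RAS world coordinates in
    millimetres; ``orientation_code`` is the corresponding 3-letter
    anatomical code (``RAS``, ``RPI``, ...).
    """

    voxels: np.ndarray
    spacing_mm: np.ndarray
    affine: np.ndarray
    orientation_code: str
    intensity_units: str = "arbitrary"
    echo_times: tuple[float, ...] = ()
    frame_times_s: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim < 3:
            raise ValueError("voxels must have at least 3 spatial dimensions")
        if self.spacing_mm.shape != (3,) or np.any(self.spacing_mm <= 0):
            raise ValueError("spacing_mm must be a positive 3-vector")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be 4x4 with an invertible spatial block")
        expected = 3 + int(self.has_echo_axis) + int(self.has_frame_axis)
        if self.voxels.ndim != expected:
            raise ValueError(
                f"voxel array is {self.voxels.ndim}-D but echo/frame metadata "
                f"implies {expected}-D"
            )
        if "".join(aff2axcodes(self.affine)) != self.orientation_code:
            raise ValueError("orientation_code inconsistent with affine axis signs")

    @property
    def has_echo_axis(self) -> bool:
        return len(self.echo_times) > 1

    @property
    def has_frame_axis(self) -> bool:
        return len(self.frame_times_s) > 1

    @property
    def n_echoes(self) -> int:
        return max(len(self.echo_times), 1)

    @property
    def n_frames(self) -> int:
        return max(len(self.frame_times_s), 1)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    def get_volume(self, echo: int = 0, frame: int = 0) -> np.ndarray:
        """Return the 3-D spatial volume at the given echo/frame index."""
        vol = self.voxels
        if self.has_frame_axis:
            vol = vol[..., frame]
        elif frame != 0:
            raise IndexError("stack has no frame axis")
        if self.has_echo_axis:
            vol = vol[..., echo]
        elif echo != 0:
            raise IndexError("stack has no echo axis")
        return vol

    def iter_volumes(self) -> Iterator[tuple[int, int, np.ndarray]]:
        """Yield ``(echo_index, frame_index, 3-D volume)`` in order."""
        for e in range(self.n_echoes):
            for f in range(self.n_frames):
                yield e, f, self.get_volume(e, f)


@dataclass
class DiffusionTables:
    """FSL-convention diffusion tables: one b-value and gradient unit
    vector per diffusion volume (zero vector for b=0 volumes)."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must be (n_volumes, 3) matching bvals")
        norms = np.linalg.norm(self.bvecs, axis=1)
        nonzero = norms > 0
        if np.any(np.abs(norms[nonzero] - 1.0) > 1e-3):
            raise ValueError("nonzero b-vectors must be unit norm")


# ---------------------------------------------------------------------------
# indexing


def _strip_prefix(label: str) -> str:
    for prefix in ("sub-", "ses-"):
        if label.startswith(prefix):
            return label[len(prefix):]
    return label


def _read_header(path: Path) -> pydicom.Dataset | None:
    try:
        return pydicom.dcmread(path, stop_before_pixels=True)
    except (InvalidDicomError, IsADirectoryError, OSError, struct.error):
        return None


def _year_of(ds: pydicom.Dataset) -> int | None:
    for tag in ("AcquisitionDate", "SeriesDate", "StudyDate"):
        value = getattr(ds, tag, None)
        if value:
            try:
                return int(str(value)[:4])
            except ValueError:
                continue
    return None


def index_dicom_tree(
    root: str | Path,
    layout: Sequence[str] = DEFAULT_LAYOUT,
) -> list[SeriesRecord]:
    """Discover and group every readable DICOM file under ``root``.

    Parameters
    ----------
    root
        Directory holding the raw export.
    layout
        Role of each directory level below the root, in order.  Roles are
        ``"subject"``, ``"session"``, ``"series"`` and ``"ignore"``.
        ``("subject", "series")`` describes a single-session study;
        session labels are then ``None``.

    Returns
    -------
    list of SeriesRecord
        One record per (subject, session, SeriesInstanceUID).  Series
        whose files disagree on image dimensions are flagged invalid
        rather than silently merged.  Non-DICOM files are skipped with a
        logged warning.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"raw DICOM root does not exist: {root}")
    for role in layout:
        if role not in LAYOUT_ROLES:
            raise ValueError(f"unknown layout role {role!r}; expected one of {LAYOUT_ROLES}")

    groups: dict[tuple, dict] = {}
    for path in sorted(root.rglob("*")):
        if not path.is_file():
            continue
        ds = _read_header(path)
        if ds is None:
            logger.warning("skipping non-DICOM file: %s", path)
            continue
        levels = path.relative_to(root).parts[:-1]
        subject = session = None
        for depth, role in enumerate(layout):
            if depth >= len(levels):
                break
            if role == "subject":
                subject = _strip_prefix(levels[depth])
            elif role == "session":
                session = _strip_prefix(levels[depth])
        if subject is None:
            subject = str(getattr(ds, "PatientID", "unknown"))
        uid = str(getattr(ds, "SeriesInstanceUID", path.parent))
        key = (subject, session, uid)
        info = groups.setdefault(
            key,
            {
                "paths": [],
                "echo_times": set(),
                "frames": set(),
                "dims": set(),
                "year": None,
                "modality": "",
                "description": "",
            },
        )
        info["paths"].append(path)
        te = getattr(ds, "EchoTime", None)
        if te is not None:
            info["echo_times"].add(float(te) / 1000.0)
        frame_id = getattr(ds, "TemporalPositionIdentifier", None)
        if frame_id is not None:
            info["frames"].add(int(frame_id))
        rows, cols = getattr(ds, "Rows", None), getattr(ds, "Columns", None)
        if rows is not None and cols is not None:
            info["dims"].add((int(rows), int(cols)))
        if info["year"] is None:
            info["year"] = _year_of(ds)
        info["modality"] = info["modality"] or str(getattr(ds, "Modality", ""))
        info["description"] = info["description"] or str(getattr(ds, "SeriesDescription", ""))

    records = []
    for (subject, session, uid), info in sorted(groups.items()):
        record = SeriesRecord(
            series_id=uid,
            subject_label=subject,
            session_label=session,
            modality_hint=info["modality"],
            file_paths=sorted(info["paths"]),
            echo_times=sorted(info["echo_times"]),
            frame_count=max(len(info["frames"]), 1),
            acquisition_year=info["year"],
            series_description=info["description"],
        )
        if len(info["dims"]) > 1:
            record.valid = False
            record.invalid_reason = (
                f"files disagree on image dimensions: {sorted(info['dims'])}"
            )
            logger.warning("series %s flagged invalid: %s", uid, record.invalid_reason)
        records.append(record)
    if not records:
        logger.warning("no DICOM files found under %s", root)
    return records


# ---------------------------------------------------------------------------
# volume assembly


@dataclass
class _Slice:
    echo_s: float
    frame_id: int
    position: np.ndarray | None
    instance: int | None
    pixels: np.ndarray  # (rows, cols), rescaled
    iop: np.ndarray | None
    spacing_rc: np.ndarray | None
    thickness: float | None


def _rescale(ds: pydicom.Dataset, frame: np.ndarray) -> np.ndarray:
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    if slope == 1.0 and intercept == 0.0:
        return frame
    return frame.astype(np.float64) * slope + intercept


def _explode_file(ds: pydicom.Dataset) -> list[_Slice]:
    """Turn one DICOM file into per-slice entries.

    Multi-frame files (NumberOfFrames > 1) are treated as a full slice
    stack for a single time frame, stacked along the slice normal with
    SpacingBetweenSlices.
    """
    iop = getattr(ds, "ImageOrientationPatient", None)
    iop = np.asarray([float(v) for v in iop]) if iop is not None else None
    ipp = getattr(ds, "ImagePositionPatient", None)
    ipp = np.asarray([float(v) for v in ipp]) if ipp is not None else None
    spacing = getattr(ds, "PixelSpacing", None)
    spacing = np.asarray([float(v) for v in spacing]) if spacing is not None else None
    thickness = getattr(ds, "SpacingBetweenSlices", None) or getattr(ds, "SliceThickness", None)
    thickness = float(thickness) if thickness is not None else None
    echo_s = float(getattr(ds, "EchoTime", 0.0) or 0.0) / 1000.0
    frame_id = int(getattr(ds, "TemporalPositionIdentifier", 1) or 1)
    instance = getattr(ds, "InstanceNumber", None)
    instance = int(instance) if instance is not None else None
    pixels = _rescale(ds, ds.pixel_array)

    n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if n_frames == 1:
        return [_Slice(echo_s, frame_id, ipp, instance, pixels, iop, spacing, thickness)]
    if pixels.ndim != 3 or pixels.shape[0] != n_frames:
        raise DicomIngestError("multi-frame pixel data inconsistent with NumberOfFrames")
    if iop is None or ipp is None or thickness is None:
        raise DicomIngestError(
            "multi-frame file requires ImageOrientationPatient, "
            "ImagePositionPatient and SpacingBetweenSlices"
        )
    normal = np.cross(iop[:3], iop[3:])
    out = []
    for k in range(n_frames):
        out.append(
            _Slice(
                echo_s,
                frame_id,
                ipp + k * thickness * normal,
                instance,
                pixels[k],
                iop,
                spacing,
                thickness,
            )
        )
    return out


def assemble_volume(record: SeriesRecord) -> VolumeStack:
    """Assemble a series into a ``(x, y, z[, echo][, frame])`` stack.

    Slices are ordered by ascending position along the slice normal,
    falling back to InstanceNumber when positions are absent.  The affine
    is built from the orientation/position/spacing tags and maps voxel
    indices to RAS world millimetres.

    Raises
    ------
    DicomIngestError
        If the series is flagged invalid, slices carry neither spatial
        position nor instance number, pixel spacing is inconsistent, or
        slice ordering is ambiguous (duplicate positions).
    """
    if not record.valid:
        raise DicomIngestError(
            f"series {record.series_id} is invalid: {record.invalid_reason}"
        )
    slices: list[_Slice] = []
    for path in record.file_paths:
        ds = pydicom.dcmread(path)
        slices.extend(_explode_file(ds))
    if not slices:
        raise DicomIngestError(f"series {record.series_id} contains no image data")

    iops = [s.iop for s in slices if s.iop is not None]
    if not iops:
        raise DicomIngestError(
            f"series {record.series_id}: ImageOrientationPatient missing on all slices"
        )
    iop = iops[0]
    if any(not np.allclose(other, iop, atol=1e-4) for other in iops[1:]):
        raise DicomIngestError(f"series {record.series_id}: inconsistent slice orientation")
    spacings = [s.spacing_rc for s in slices if s.spacing_rc is not None]
    if not spacings:
        raise DicomIngestError(f"series {record.series_id}: PixelSpacing missing")
    spacing_rc = spacings[0]
    if any(not np.allclose(other, spacing_rc, atol=1e-6) for other in spacings[1:]):
        raise DicomIngestError(f"series {record.series_id}: inconsistent pixel spacing")

    row_cos, col_cos = iop[:3], iop[3:]
    normal = np.cross(row_cos, col_cos)

    echoes = sorted({s.echo_s for s in slices})
    frames = sorted({s.frame_id for s in slices})
    groups: dict[tuple[float, int], list[_Slice]] = {}
    for s in slices:
        groups.setdefault((s.echo_s, s.frame_id), []).append(s)

    # establish the common slice ordering from the first group
    def sort_key(group: list[_Slice]) -> list[_Slice]:
        if all(s.position is not None for s in group):
            keyed = sorted(group, key=lambda s: float(np.dot(s.position, normal)))
            positions = [float(np.dot(s.position, normal)) for s in keyed]
            if len(positions) > 1 and np.min(np.diff(positions)) < 1e-9:
                raise DicomIngestError(
                    f"series {record.series_id}: duplicate slice positions; "
                    "ordering is ambiguous"
                )
            return keyed
        if all(s.instance is not None for s in group):
            keyed = sorted(group, key=lambda s: s.instance)
            if len({s.instance for s in keyed}) != len(keyed):
                raise DicomIngestError(
                    f"series {record.series_id}: duplicate instance numbers"
                )
            return keyed
        raise DicomIngestError(
            f"series {record.series_id}: slices carry neither spatial position "
            "nor instance number"
        )

    n_z = None
    sorted_groups: dict[tuple[float, int], list[_Slice]] = {}
    for key, group in groups.items():
        ordered = sort_key(group)
        if n_z is None:
            n_z = len(ordered)
        elif len(ordered) != n_z:
            raise DicomIngestError(
                f"series {record.series_id}: unequal slice counts across echo/frame groups"
            )
        sorted_groups[key] = ordered

    first = sorted_groups[(echoes[0], frames[0])]
    if n_z > 1 and first[0].position is not None:
        z_positions = [float(np.dot(s.position, normal)) for s in first]
        dz = float(np.median(np.diff(z_positions)))
    else:
        dz = first[0].thickness or 1.0

    rows, cols = first[0].pixels.shape
    dr, dc = float(spacing_rc[0]), float(spacing_rc[1])
    shape = [cols, rows, n_z]
    if len(echoes) > 1:
        shape.append(len(echoes))
    if len(frames) > 1:
        shape.append(len(frames))
    dtype = first[0].pixels.dtype
    voxels = np.empty(shape, dtype=dtype)
    for (echo_s, frame_id), ordered in sorted_groups.items():
        e, f = echoes.index(echo_s), frames.index(frame_id)
        plane = np.stack([s.pixels.T for s in ordered], axis=2)  # (cols, rows, z)
        if len(echoes) > 1 and len(frames) > 1:
            voxels[:, :, :, e, f] = plane
        elif len(echoes) > 1:
            voxels[:, :, :, e] = plane
        elif len(frames) > 1:
            voxels[:, :, :, f] = plane
        else:
            voxels[:, :, :] = plane

    origin = first[0].position if first[0].position is not None else np.zeros(3)
    affine_lps = np.eye(4)
    affine_lps[:3, 0] = row_cos * dc
    affine_lps[:3, 1] = col_cos * dr
    affine_lps[:3, 2] = normal * dz
    affine_lps[:3, 3] = origin
    affine = np.diag([-1.0, -1.0, 1.0, 1.0]) @ affine_lps

    return VolumeStack(
        voxels=voxels,
        spacing_mm=np.array([dc, dr, abs(dz)]),
        affine=affine,
        orientation_code="".join(aff2axcodes(affine)),
        echo_times=tuple(echoes),
        frame_times_s=tuple(float(f) for f in frames) if len(frames) > 1 else (),
    )


# ---------------------------------------------------------------------------
# reorientation


def obliquity_deg(affine: np.ndarray) -> float:
    """Maximal angular deviation (degrees) of the voxel axes from the
    nearest axis-aligned anatomical directions."""
    rot = np.asarray(affine, dtype=float)[:3, :3]
    cols = rot / np.linalg.norm(rot, axis=0, keepdims=True)
    best = np.max(np.abs(cols), axis=0)
    return float(np.degrees(np.max(np.arccos(np.clip(best, -1.0, 1.0)))))


def reorient(
    volume: VolumeStack,
    target: str,
    oblique_tolerance_deg: float = 20.0,
) -> VolumeStack:
    """Permute/flip a stack to the ``target`` 3-letter axis code.

    Only the spatial axes move; echo and frame axes are untouched, so the
    round trip ``reorient(reorient(v, X), v.orientation_code)``
    reproduces the voxel array exactly.  Affines more oblique than
    ``oblique_tolerance_deg`` are snapped to the nearest axis-aligned
    code with a warning flagging the series for manual review.
    """
    target = target.upper()
    try:
        target_ornt = axcodes2ornt(tuple(target))
    except ValueError as exc:
        raise ValueError(f"invalid orientation code {target!r}") from exc
    if np.any(np.isnan(target_ornt)):
        raise ValueError(f"invalid orientation code {target!r}")

    angle = obliquity_deg(volume.affine)
    if angle > oblique_tolerance_deg:
        warnings.warn(
            f"affine is oblique by {angle:.1f} deg (> {oblique_tolerance_deg} deg); "
            "snapping to the nearest axis-aligned code — review manually",
            stacklevel=2,
        )
    current = io_orientation(volume.affine)
    transform = ornt_transform(current, target_ornt)
    voxels = apply_orientation(volume.voxels, transform)
    affine = volume.affine @ inv_ornt_aff(transform, volume.spatial_shape)
    perm = transform[:, 0].astype(int)
    spacing = volume.spacing_mm[np.argsort(perm)]
    return replace(
        volume,
        voxels=voxels,
        affine=affine,
        spacing_mm=spacing,
        orientation_code="".join(aff2axcodes(affine)),
    )


# ---------------------------------------------------------------------------
# diffusion tables


def extract_diffusion_tables(record: SeriesRecord) -> DiffusionTables:
    """Read per-volume b-values and gradient vectors from a diffusion
    series, ordered as the frame axis of the assembled 4-D stack.

    b=0 volumes get zero vectors; nonzero gradients are normalised to
    unit length.  Gradient tags absent from the headers raise an error
    pointing at the sequence-overview config fallback mechanism.
    """
    per_frame: dict[int, tuple[float, np.ndarray]] = {}
    for path in record.file_paths:
        ds = pydicom.dcmread(path, stop_before_pixels=True)
        frame_id = int(getattr(ds, "TemporalPositionIdentifier", 1) or 1)
        if frame_id in per_frame:
            continue
        bval = getattr(ds, "DiffusionBValue", None)
        bvec = getattr(ds, "DiffusionGradientOrientation", None)
        if bval is None:
            raise DicomIngestError(
                f"series {record.series_id}: DiffusionBValue tag absent; "
                "provide b-values via the sequence-overview config fallback"
            )
        bval = float(bval)
        if bval == 0 or bvec is None:
            vec = np.zeros(3)
        else:
            vec = np.asarray([float(v) for v in bvec], dtype=float)
            norm = np.linalg.norm(vec)
            vec = vec / norm if norm > 0 else vec
        per_frame[frame_id] = (bval, vec)
    order = sorted(per_frame)
    bvals = np.array([per_frame[f][0] for f in order])
    bvecs = np.stack([per_frame[f][1] for f in order])
    return DiffusionTables(bvals=bvals, bvecs=bvecs)


def reorient_bvecs(tables: DiffusionTables, source: str, target: str) -> DiffusionTables:
    """Re-express gradient vectors after an axis-code reorientation.

    The transform is a signed permutation, so vector norms are preserved
    exactly.
    """
    transform = ornt_transform(axcodes2ornt(tuple(source.upper())), axcodes2ornt(tuple(target.upper())))
    mat = np.zeros((3, 3))
    for src_axis, (dst_axis, flip) in enumerate(transform):
        mat[int(dst_axis), src_axis] = flip
    return DiffusionTables(bvals=tables.bvals.copy(), bvecs=tables.bvecs @ mat.T)
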