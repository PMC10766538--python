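"""Ground-truthed synthetic PET/MR cohorts written as classic DICOM.

The generator emulates the raw material a preclinical hybrid PET/MR
study produces, at desk scale, so the whole curation loop — indexing,
assembly, BIDS conversion, quality metrics, cohort report — can be
exercised end to end with every planted truth known:

* **structural phantoms** — an ellipsoid of tissue mean ``μ`` over a
  zero-mean Gaussian background of standard deviation ``σ`` (magnitude-MR
  Rician tails are ignored at the SNR levels generated); multi-echo
  variants scale the tissue by ``exp(−TE/T2*)``;
* **dynamic PET** — per-frame tissue intensity follows a gamma-variate
  time–activity curve (the standard bolus stand-in) averaged over each
  frame, with per-frame prompts drawn Poisson from the curve integral
  plus a randoms floor (randoms ≤ prompts by construction);
* **tag dropout** — any listed DICOM tag is omitted from the written
  headers, emulating the missing metadata of retrospective exports;
  geometry-critical tags are only droppable with an explicit force flag;
* **cohorts** — a multi-subject tree (with test–retest sessions, planted
  missing acquisitions and a planted parameter-shifted outlier session)
  plus the three CSV configs and a JSON manifest that fully determines
  the tree given the seed.

All randomness flows through a single integer seed: identical seeds give
byte-identical trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from petmrbids.bids_builder import FrameSchedule, expand_frame_schedule
from petmrbids.dicom_ingest import VolumeStack
from petmrbids.quality_metrics import CountRateSeries

#: Tags whose dropout breaks volume assembly by design; refused without force.
GEOMETRY_CRITICAL_TAGS = frozenset(
    {"ImageOrientationPatient", "ImagePositionPatient", "PixelSpacing"}
)

#: Printed dynamic frame schedules of the two tracers (seconds).
H2O_SCHEDULE = FrameSchedule(blocks=[(8, 4), (4, 6), (6, 10), (8, 20)])
PK11195_SCHEDULE = FrameSchedule(blocks=[(6, 10), (6, 20), (6, 120), (8, 300)])


@dataclass
class PhantomSpec:
    """Ground-truth parameters of one synthetic acquisition.

    Defaults describe a desk-scale stand-in for a 3T head acquisition:
    a 64×64×32 grid at 2 mm isotropic with a centred ellipsoid of tissue.
    ``tissue_mean``/``background_sigma`` are in arbitrary scanner units;
    ``echo_times_s`` with ``t2star_s`` switch on multi-echo decay;
    ``tac`` (amplitude, t0 s, alpha, beta s) with ``frame_schedule``
    switch on dynamic PET.
    """

    grid: tuple[int, int, int] = (64, 64, 32)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    center_vox: tuple[float, float, float] | None = None
    semi_axes_vox: tuple[float, float, float] = (22.0, 18.0, 11.0)
    tissue_mean: float = 4000.0
    background_sigma: float = 200.0
    echo_times_s: tuple[float, ...] = ()
    t2star_s: float = 0.030
    tac: tuple[float, float, float, float] | None = None  # amplitude, t0, alpha, beta
    frame_schedule: FrameSchedule | None = None
    expected_counts_scale: float = 2.0e4  # prompts per unit TAC integral
    randoms_floor_cps: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue_mean <= 0 or self.background_sigma <= 0:
            raise ValueError("tissue_mean and background_sigma must be > 0")
        center = self.center_vox or tuple((g - 1) / 2.0 for g in self.grid)
        self.center_vox = center
        for c, a, g in zip(center, self.semi_axes_vox, self.grid):
            if c - a < -0.5 or c + a > g - 0.5:
                raise ValueError("ellipsoid semi-axes do not fit inside the grid")
        if self.tac is not None and self.tac[0] < 0:
            raise ValueError("TAC amplitude must be >= 0")


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.grid
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = spec.center_vox
    ax, ay, az = spec.semi_axes_vox
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _axial_affine(spec: PhantomSpec) -> np.ndarray:
    # standard axial LPS geometry, converted to RAS
    dx, dy, dz = spec.spacing_mm
    affine = np.diag([-dx, -dy, dz, 1.0])
    return affine


def _quantize(values: np.ndarray) -> np.ndarray:
    """Round to the signed 16-bit integers stored in the DICOM files, so
    the ground truth matches the written data bit-exactly."""
    return np.clip(np.rint(values), -32768, 32767).astype(np.int16)


def make_structural_phantom(spec: PhantomSpec, seed: int | None = None) -> tuple[VolumeStack, dict]:
    """Generate a structural (optionally multi-echo) ellipsoid phantom.

    Returns the stack plus a truth dict with the planted ``mu``/``sigma``,
    the tissue mask and the per-echo tissue means after T2* decay.  The
    voxel values are the exact 16-bit integers the DICOM writer stores.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mask = _ellipsoid_mask(spec)
    echoes = spec.echo_times_s or (0.0,)
    volumes = []
    tissue_means = []
    for te in echoes:
        decay = np.exp(-te / spec.t2star_s) if spec.echo_times_s else 1.0
        signal = np.where(mask, spec.tissue_mean * decay, 0.0)
        noise = rng.normal(0.0, spec.background_sigma, size=spec.grid)
        volumes.append(_quantize(signal + noise))
        tissue_means.append(spec.tissue_mean * decay)
    voxels = np.stack(volumes, axis=3) if len(echoes) > 1 else volumes[0]
    affine = _axial_affine(spec)
    import nibabel as nib

    stack = VolumeStack(
        voxels=voxels,
        spacing_mm=np.asarray(spec.spacing_mm),
        affine=affine,
        orientation_code="".join(nib.orientations.aff2axcodes(affine)),
        echo_times=tuple(spec.echo_times_s) if len(echoes) > 1 else (),
    )
    truth = {
        "mu": spec.tissue_mean,
        "sigma": spec.background_sigma,
        "tissue_mask": mask,
        "tissue_means_per_echo": tissue_means,
        "voi_voxels_analytic": 4.0 / 3.0 * np.pi * float(np.prod(spec.semi_axes_vox)),
    }
    return stack, truth


def gamma_variate(t: np.ndarray, amplitude: float, t0: float, alpha: float, beta: float) -> np.ndarray:
    """Gamma-variate bolus curve ``A·((t−t0)/(αβ))^α·exp(α−(t−t0)/β)``,
    normalised so its peak (at ``t0 + αβ``) equals ``A``; zero before
    ``t0``."""
    t = np.asarray(t, dtype=float)
    dt = np.clip(t - t0, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        curve = amplitude * (dt / (alpha * beta)) ** alpha * np.exp(alpha - dt / beta)
    return np.where(dt > 0, curve, 0.0)


def _frame_tac_means(spec: PhantomSpec, starts: Sequence[float], durations: Sequence[float]) -> np.ndarray:
    """Mean TAC value over each frame (midpoint-subsampled integral)."""
    amplitude, t0, alpha, beta = spec.tac
    means = []
    for s, d in zip(starts, durations):
        tt = np.linspace(s, s + d, 32)
        means.append(float(np.trapezoid(gamma_variate(tt, amplitude, t0, alpha, beta), tt)) / d)
    return np.asarray(means)


def make_dynamic_pet(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[VolumeStack, CountRateSeries, dict]:
    """Generate a dynamic PET phantom with matching counting statistics.

    Tissue intensity per frame follows the gamma-variate TAC averaged
    over the frame; prompts per frame are Poisson with mean proportional
    to the frame's TAC integral plus a Poisson randoms floor, and the
    randoms are a subset of the prompts so ``D ≤ P`` always holds.
    """
    if spec.frame_schedule is None or spec.tac is None:
        raise ValueError("dynamic phantom requires tac and frame_schedule")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    starts, durations = expand_frame_schedule(spec.frame_schedule)
    tac_means = _frame_tac_means(spec, starts, durations)

    mask = _ellipsoid_mask(spec)
    frames = []
    for mean_activity in tac_means:
        signal = np.where(mask, mean_activity, 0.0)
        noise = rng.normal(0.0, spec.background_sigma, size=spec.grid)
        frames.append(_quantize(signal + noise))
    voxels = np.stack(frames, axis=3)

    trues_mean = spec.expected_counts_scale * tac_means * np.asarray(durations)
    randoms_mean = spec.randoms_floor_cps * np.asarray(durations)
    trues = rng.poisson(trues_mean).astype(float)
    randoms = rng.poisson(randoms_mean).astype(float)
    prompts = trues + randoms

    affine = _axial_affine(spec)
    import nibabel as nib

    stack = VolumeStack(
        voxels=voxels,
        spacing_mm=np.asarray(spec.spacing_mm),
        affine=affine,
        orientation_code="".join(nib.orientations.aff2axcodes(affine)),
        frame_times_s=tuple(starts),
    )
    counts = CountRateSeries(
        frame_starts_s=np.asarray(starts),
        frame_durations_s=np.asarray(durations),
        prompts=prompts,
        randoms=randoms,
    )
    amplitude, t0, alpha, beta = spec.tac
    truth = {
        "tac_mode_s": t0 + alpha * beta,
        "tac_frame_means": tac_means,
        "peak_frame": int(np.argmax(tac_means)),
        "tissue_mask": mask,
        "trues_mean": trues_mean,
        "randoms_mean": randoms_mean,
    }
    return stack, counts, truth


# ---------------------------------------------------------------------------
# DICOM writing


def _base_dataset(
    uid_root: pydicom.uid.UID,
    modality: str,
    series_description: str,
    subject: str,
    instance: int,
) -> Dataset:
    file_meta = FileMetaDataset()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    file_meta.MediaStorageSOPClassUID = (
        "1.2.840.10008.5.1.4.1.1.4" if modality == "MR" else "1.2.840.10008.5.1.4.1.1.128"
    )
    file_meta.MediaStorageSOPInstanceUID = f"{uid_root}.{instance}"
    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = file_meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    ds.SeriesInstanceUID = str(uid_root)
    ds.SeriesDescription = series_description
    ds.PatientID = subject
    ds.PatientName = subject
    return ds


def write_synthetic_dicom(
    stack: VolumeStack,
    out_dir: str | Path,
    series_description: str,
    modality: str = "MR",
    subject: str = "sub",
    sidecar_truth: Mapping[str, Any] | None = None,
    dropout: Sequence[str] = (),
    multiframe: bool = False,
    force: bool = False,
    acquisition_date: str = "20170101",
    uid_seed: int = 0,
) -> list[Path]:
    """Write a stack as a classic DICOM series with controlled tag dropout.

    ``sidecar_truth`` supplies header values (RepetitionTime and FlipAngle
    in their DICOM conventions, diffusion tables, ...).  ``dropout`` lists
    tag keywords to omit from every header; dropping a geometry-critical
    tag breaks assembly by design and is refused without ``force``.
    ``multiframe=True`` writes one file per time frame holding the full
    slice stack (NumberOfFrames = n_z) instead of one file per slice —
    both variants assemble to identical arrays.
    """
    blocked = set(dropout) & GEOMETRY_CRITICAL_TAGS
    if blocked and not force:
        raise ValueError(
            f"refusing to drop geometry-critical tags {sorted(blocked)} "
            "without force=True (assembly will break, for negative tests only)"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = dict(sidecar_truth or {})

    # deterministic series UID derived from the seed
    uid_root = pydicom.uid.UID(f"1.2.826.0.1.3680043.9999.{uid_seed}")

    nx, ny, nz = stack.spatial_shape
    dx, dy, dz = stack.spacing_mm
    # invert the RAS affine back to DICOM LPS geometry tags
    lps = np.diag([-1.0, -1.0, 1.0, 1.0]) @ stack.affine
    row_cos = lps[:3, 0] / np.linalg.norm(lps[:3, 0])
    col_cos = lps[:3, 1] / np.linalg.norm(lps[:3, 1])
    normal = lps[:3, 2] / np.linalg.norm(lps[:3, 2])
    origin = lps[:3, 3]
    iop = [*row_cos, *col_cos]

    echoes = stack.echo_times or (0.0,)
    n_frames = stack.n_frames
    written: list[Path] = []
    instance = 0

    def finalize(ds: Dataset, pixels: np.ndarray) -> Path:
        nonlocal instance
        ds.Rows, ds.Columns = pixels.shape[-2], pixels.shape[-1]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed, so Gaussian noise keeps its tail
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "0"
        ds.PixelData = np.ascontiguousarray(pixels.astype(np.int16)).tobytes()
        for tag in dropout:
            if tag in ds:
                delattr(ds, tag)
        path = out_dir / f"{instance:05d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        written.append(path)
        instance += 1
        return path

    def common_tags(ds: Dataset, echo_s: float, frame_id: int) -> None:
        ds.AcquisitionDate = acquisition_date
        ds.SeriesDate = acquisition_date
        ds.PixelSpacing = [f"{dy:g}", f"{dx:g}"]  # row spacing, column spacing
        ds.SliceThickness = f"{dz:g}"
        ds.SpacingBetweenSlices = f"{dz:g}"
        ds.ImageOrientationPatient = [f"{v:.8f}" for v in iop]
        if len(echoes) > 1 or echo_s > 0:
            ds.EchoTime = f"{echo_s * 1000.0:g}"
        elif "EchoTime" in truth:
            ds.EchoTime = f"{float(truth['EchoTime']) * 1000.0:g}"
        if n_frames > 1:
            ds.TemporalPositionIdentifier = frame_id + 1
            ds.NumberOfTemporalPositions = n_frames
        for key, dicom_kw, scale in (
            ("RepetitionTime", "RepetitionTime", 1000.0),
            ("FlipAngle", "FlipAngle", 1.0),
            ("PixelBandwidth", "PixelBandwidth", 1.0),
        ):
            if key in truth:
                setattr(ds, dicom_kw, f"{float(truth[key]) * scale:g}")

    for f in range(n_frames):
        if multiframe:
            e = 0  # multi-frame variant is single-echo (PET-style export)
            vol = stack.get_volume(e, f)
            ds = _base_dataset(uid_root, modality, series_description, subject, instance)
            common_tags(ds, echoes[0] if stack.echo_times else 0.0, f)
            ds.InstanceNumber = instance + 1
            ds.NumberOfFrames = nz
            ds.ImagePositionPatient = [f"{v:.6f}" for v in origin]
            # pixels: (frames=z, rows, cols); voxels are (x, y, z) → transpose
            pixels = np.transpose(vol, (2, 1, 0))
            finalize(ds, pixels)
        else:
            for e, echo_s in enumerate(echoes):
                vol = stack.get_volume(e if stack.has_echo_axis else 0, f)
                for k in range(nz):
                    ds = _base_dataset(uid_root, modality, series_description, subject, instance)
                    common_tags(ds, echo_s if stack.echo_times else 0.0, f)
                    ds.InstanceNumber = instance + 1
                    pos = origin + k * dz * normal
                    ds.ImagePositionPatient = [f"{v:.6f}" for v in pos]
                    if "bvals" in truth:
                        ds.DiffusionBValue = float(truth["bvals"][f])
                        vec = truth["bvecs"][f]
                        ds.DiffusionGradientOrientation = [float(v) for v in vec]
                    finalize(ds, vol[:, :, k].T)  # (rows, cols)
    return written


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortManifest:
    """Planted ground truth of a generated cohort.

    Fully determines the generated tree given the seed: which sequences
    each session holds, the planted missing acquisitions and outlier
    sessions, dropped tags, dose values and true (μ, σ) per sequence.
    """

    seed: int
    subjects: list[str]
    sessions: dict[str, list[str]]
    sequences: list[str]
    missing: list[dict[str, str]] = field(default_factory=list)
    outliers: list[dict[str, Any]] = field(default_factory=list)
    dropped_tags: dict[str, list[str]] = field(default_factory=dict)
    doses: list[dict[str, Any]] = field(default_factory=list)
    truth: dict[str, dict[str, Any]] = field(default_factory=dict)
    participants: list[dict[str, Any]] = field(default_factory=list)

    def to_json(self) -> str:
        def _default(obj: Any) -> Any:
            if isinstance(obj, np.integer):
                return int(obj)
            if isinstance(obj, np.floating):
                return float(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            raise TypeError(f"not JSON serialisable: {type(obj)}")

        return json.dumps(asdict(self), indent=2, sort_keys=True, default=_default) + "\n"


#: Sequence menu of a generated session: description → (suffix, datatype,
#: entities, modality, kind).
COHORT_SEQUENCES: dict[str, dict[str, Any]] = {
    "t1_mprage": {"suffix": "T1w", "datatype": "anat", "entities": {}, "modality": "MR", "kind": "static"},
    "t2_spc": {"suffix": "T2w", "datatype": "anat", "entities": {}, "modality": "MR", "kind": "static"},
    "t2star_gre": {"suffix": "T2starw", "datatype": "anat", "entities": {}, "modality": "MR", "kind": "multiecho"},
    "ep2d_diff": {"suffix": "dwi", "datatype": "dwi", "entities": {}, "modality": "MR", "kind": "dwi"},
    "pet_h2o": {"suffix": "pet", "datatype": "pet", "entities": {"trc": "H2O"}, "modality": "PT", "kind": "pet"},
    "pet_pk11195": {"suffix": "pet", "datatype": "pet", "entities": {"trc": "PK11195"}, "modality": "PT", "kind": "pet"},
}

#: Injected-dose study conditions per tracer: mean/sd of InjectedRadioactivity
#: (MBq), plus molar activity (GBq/µmol) and injected mass (nmol) for the
#: carbon-11 tracer (oxygen-15 decays too fast for molar-activity assay).
DOSE_CONDITIONS = {
    "H2O": {"InjectedRadioactivity": (255.0, 15.0)},
    "PK11195": {
        "InjectedRadioactivity": (140.1, 21.4),
        "SpecificRadioactivity": (48.0, 24.5),
        "InjectedMass": (3.50, 1.7),
    },
}

TRACER_SCHEDULES = {"H2O": H2O_SCHEDULE, "PK11195": PK11195_SCHEDULE}


def _default_specs(rng: np.random.Generator) -> dict[str, PhantomSpec]:
    """Per-sequence phantom parameters for one session, with mild
    subject-to-subject variation in tissue intensity (±3%)."""
    jitter = rng.normal(1.0, 0.03)
    return {
        "t1_mprage": PhantomSpec(tissue_mean=4000.0 * jitter, background_sigma=160.0),
        "t2_spc": PhantomSpec(tissue_mean=3000.0 * jitter, background_sigma=150.0),
        "t2star_gre": PhantomSpec(
            tissue_mean=3500.0 * jitter,
            background_sigma=175.0,
            echo_times_s=(0.00445, 0.0120, 0.0200),
            t2star_s=0.030,
        ),
        "ep2d_diff": PhantomSpec(tissue_mean=2500.0 * jitter, background_sigma=250.0),
        "pet_h2o": PhantomSpec(
            tissue_mean=1.0,
            background_sigma=40.0,
            tac=(8000.0, 10.0, 3.0, 6.0),
            frame_schedule=H2O_SCHEDULE,
            expected_counts_scale=30.0,
            randoms_floor_cps=2000.0,
        ),
        "pet_pk11195": PhantomSpec(
            tissue_mean=1.0,
            background_sigma=30.0,
            tac=(6000.0, 30.0, 3.0, 20.0),
            frame_schedule=PK11195_SCHEDULE,
            expected_counts_scale=300.0,
            randoms_floor_cps=5000.0,
        ),
    }


_DWI_BVALS = [0.0] + [1000.0] * 6
_DWI_BVECS = [
    [0.0, 0.0, 0.0],
    [1.0, 0.0, 0.0],
    [0.0, 1.0, 0.0],
    [0.0, 0.0, 1.0],
    [0.7071067811865476, 0.7071067811865476, 0.0],
    [0.7071067811865476, 0.0, 0.7071067811865476],
    [0.0, 0.7071067811865476, 0.7071067811865476],
]


def _write_cohort_configs(out_dir: Path, doses: list[dict[str, Any]]) -> None:
    import pandas as pd

    overview_rows = []
    common_mr = "EchoTime;RepetitionTime;FlipAngle;PixelBandwidth"
    fallback_mr = "RepetitionTime=2.0;FlipAngle=9;PixelBandwidth=190;EchoTime=0.0042"
    for desc, info in COHORT_SEQUENCES.items():
        if info["kind"] == "pet":
            tracer = info["entities"]["trc"]
            overview_rows.append(
                {
                    "match_pattern": f"^{desc}$",
                    "bids_suffix": "pet",
                    "destination": "pet",
                    "bids_entities": f"trc={tracer}",
                    "required_keys": "TracerName;InjectedRadioactivity",
                    "fallback_values": "",
                }
            )
        else:
            overview_rows.append(
                {
                    "match_pattern": f"^{desc}$",
                    "bids_suffix": info["suffix"],
                    "destination": info["datatype"],
                    "bids_entities": "",
                    "required_keys": common_mr,
                    "fallback_values": fallback_mr,
                }
            )
    pd.DataFrame(overview_rows).to_csv(out_dir / "sequence_overview.csv", index=False)

    tagmap_rows = [
        {"bids_key": "EchoTime", "dicom_tag": "EchoTime"},
        {"bids_key": "RepetitionTime", "dicom_tag": "RepetitionTime"},
        {"bids_key": "FlipAngle", "dicom_tag": "FlipAngle"},
        {"bids_key": "PixelBandwidth", "dicom_tag": "PixelBandwidth"},
    ]
    pd.DataFrame(tagmap_rows).to_csv(out_dir / "tag_map.csv", index=False)
    dose_columns = [
        "subject_label", "session_label", "tracer",
        "InjectedRadioactivity", "InjectedMass", "SpecificRadioactivity",
    ]
    doses_df = pd.DataFrame(doses) if doses else pd.DataFrame(columns=dose_columns)
    doses_df.to_csv(out_dir / "pet_doses.csv", index=False)


def make_cohort(
    out_dir: str | Path,
    n_subjects: int = 20,
    retest_subjects: Sequence[int] = (4, 11),
    missingness_plan: Sequence[tuple[str, str, str]] = (),
    outlier_plan: Sequence[tuple[str, str, str, float]] = (),
    dropout_plan: Mapping[str, Sequence[str]] | None = None,
    sequences: Sequence[str] | None = None,
    seed: int = 0,
) -> CohortManifest:
    """Generate a raw multi-subject DICOM tree plus configs and manifest.

    Parameters
    ----------
    out_dir
        Destination; raw DICOM goes under ``out_dir/raw``, the three CSV
        configs and ``manifest.json`` at the top level.
    n_subjects, retest_subjects
        Cohort size and the (1-based) subjects acquiring a second
        test–retest session.
    missingness_plan
        ``(subject, session, sequence)`` acquisitions to omit, e.g.
        ``("07", "01", "pet_h2o")``.
    outlier_plan
        ``(subject, session, sequence, sigma_factor)`` sessions whose
        noise level is multiplied, emulating an acquisition-parameter
        shift in one session.
    dropout_plan
        sequence → list of DICOM tag keywords to drop from its headers.
    sequences
        Subset of :data:`COHORT_SEQUENCES` to generate (default: all).
    seed
        Master seed; the tree is byte-identical for identical seeds.
    """
    out_dir = Path(out_dir)
    raw = out_dir / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seq_names = list(sequences) if sequences is not None else list(COHORT_SEQUENCES)
    unknown = [s for s in seq_names if s not in COHORT_SEQUENCES]
    if unknown:
        raise ValueError(f"unknown sequences in plan: {unknown}")

    subjects = [f"{i:02d}" for i in range(1, n_subjects + 1)]
    for sub, ses, seq in missingness_plan:
        if sub not in subjects:
            raise ValueError(f"missingness plan references unknown subject {sub!r}")
        if seq not in seq_names:
            raise ValueError(f"missingness plan references unknown sequence {seq!r}")
    for sub, ses, seq, _factor in outlier_plan:
        if sub not in subjects:
            raise ValueError(f"outlier plan references unknown subject {sub!r}")
        if seq not in seq_names:
            raise ValueError(f"outlier plan references unknown sequence {seq!r}")
    retest = {f"{i:02d}" for i in retest_subjects}
    unknown_retest = retest - set(subjects)
    if unknown_retest:
        raise ValueError(f"retest plan references unknown subjects {sorted(unknown_retest)}")
    sessions = {s: (["01", "02"] if s in retest else ["01"]) for s in subjects}
    missing = {(sub, ses, seq) for sub, ses, seq in missingness_plan}
    outliers = {(sub, ses, seq): factor for sub, ses, seq, factor in outlier_plan}
    dropout_plan = dict(dropout_plan or {})

    # study-condition participant variables: ages 5/6/7 y at 20/60/20 %,
    # weights around 7.4 ± 1.1 kg
    ages = rng.choice([5, 6, 7], size=n_subjects, p=[0.2, 0.6, 0.2])
    weights = np.round(rng.normal(7.37, 1.11, size=n_subjects), 2)
    participants = [
        {
            "participant_id": f"sub-{s}",
            "species": "Macaca fascicularis",
            "age": int(a),
            "sex": "M",
            "weight": float(w),
        }
        for s, a, w in zip(subjects, ages, weights)
    ]

    manifest = CohortManifest(
        seed=seed,
        subjects=subjects,
        sessions=sessions,
        sequences=seq_names,
        missing=[{"subject": m[0], "session": m[1], "sequence": m[2]} for m in sorted(missing)],
        outliers=[
            {"subject": k[0], "session": k[1], "sequence": k[2], "sigma_factor": v}
            for k, v in sorted(outliers.items())
        ],
        dropped_tags={k: list(v) for k, v in dropout_plan.items()},
        participants=participants,
    )

    doses: list[dict[str, Any]] = []
    uid_counter = 0
    for si, sub in enumerate(subjects):
        for ses in sessions[sub]:
            year = int(rng.choice([2016, 2017, 2019]))
            date = f"{year}0{int(rng.integers(1, 10))}15"
            session_rng = np.random.default_rng([seed, si, int(ses)])
            specs = _default_specs(session_rng)
            for seq in seq_names:
                if (sub, ses, seq) in missing:
                    continue
                info = COHORT_SEQUENCES[seq]
                spec = specs[seq]
                if (sub, ses, seq) in outliers:
                    factor = outliers[(sub, ses, seq)]
                    spec = PhantomSpec(
                        **{
                            **{k: getattr(spec, k) for k in spec.__dataclass_fields__},
                            "background_sigma": spec.background_sigma * factor,
                            "center_vox": None,
                        }
                    )
                series_dir = raw / f"sub-{sub}" / f"ses-{ses}" / seq
                gen_seed = int(session_rng.integers(0, 2**31 - 1))
                truth_key = f"sub-{sub}_ses-{ses}_{seq}"
                sidecar_truth: dict[str, Any] = {
                    "RepetitionTime": 2.0,
                    "FlipAngle": 9,
                    "PixelBandwidth": 190,
                }
                if info["kind"] in ("static", "dwi"):
                    sidecar_truth["EchoTime"] = 0.0042
                if info["kind"] == "pet":
                    tracer = info["entities"]["trc"]
                    stack, counts, truth = make_dynamic_pet(spec, seed=gen_seed)
                    write_synthetic_dicom(
                        stack,
                        series_dir,
                        series_description=seq,
                        modality="PT",
                        subject=sub,
                        sidecar_truth=sidecar_truth,
                        dropout=dropout_plan.get(seq, ()),
                        multiframe=True,
                        acquisition_date=date,
                        uid_seed=uid_counter,
                    )
                    counts_table = np.column_stack(
                        [
                            np.arange(counts.n_frames),
                            counts.frame_starts_s,
                            counts.frame_durations_s,
                            counts.prompts,
                            counts.randoms,
                        ]
                    )
                    header = "frame_index,start_s,duration_s,prompts,randoms"
                    np.savetxt(
                        series_dir / "counts.csv",
                        counts_table,
                        delimiter=",",
                        header=header,
                        comments="",
                        fmt=["%d", "%.6g", "%.6g", "%d", "%d"],
                    )
                    dose_row: dict[str, Any] = {
                        "subject_label": sub,
                        "session_label": ses,
                        "tracer": tracer,
                    }
                    for key, (mean, sd) in DOSE_CONDITIONS[tracer].items():
                        dose_row[key] = round(float(max(session_rng.normal(mean, sd), 0.1)), 2)
                    doses.append(dose_row)
                    manifest.truth[truth_key] = {
                        "peak_frame": truth["peak_frame"],
                        "tac_mode_s": truth["tac_mode_s"],
                        "n_frames": counts.n_frames,
                        "year": year,
                    }
                else:
                    if info["kind"] == "dwi":
                        sidecar_truth["bvals"] = _DWI_BVALS
                        sidecar_truth["bvecs"] = _DWI_BVECS
                        frames = len(_DWI_BVALS)
                        stack, truth = make_structural_phantom(spec, seed=gen_seed)
                        vols = [stack.voxels]
                        sub_rng = np.random.default_rng([gen_seed, 1])
                        mask = truth["tissue_mask"]
                        for b, vec in zip(_DWI_BVALS[1:], _DWI_BVECS[1:]):
                            att = np.exp(-b * 0.0007)
                            signal = np.where(mask, spec.tissue_mean * att, 0.0)
                            noise = sub_rng.normal(0.0, spec.background_sigma, size=spec.grid)
                            vols.append(_quantize(signal + noise))
                        voxels = np.stack(vols, axis=3)
                        stack = VolumeStack(
                            voxels=voxels,
                            spacing_mm=stack.spacing_mm,
                            affine=stack.affine,
                            orientation_code=stack.orientation_code,
                            frame_times_s=tuple(range(frames)),
                        )
                    else:
                        stack, truth = make_structural_phantom(spec, seed=gen_seed)
                    write_synthetic_dicom(
                        stack,
                        series_dir,
                        series_description=seq,
                        modality="MR",
                        subject=sub,
                        sidecar_truth=sidecar_truth,
                        dropout=dropout_plan.get(seq, ()),
                        acquisition_date=date,
                        uid_seed=uid_counter,
                    )
                    manifest.truth[truth_key] = {
                        "mu": spec.tissue_mean,
                        "sigma": spec.background_sigma,
                        "snr_true": spec.tissue_mean / spec.background_sigma,
                        "year": year,
                    }
                uid_counter += 1

    manifest.doses = doses
    _write_cohort_configs(out_dir, doses)
    import pandas as pd

    pd.DataFrame(participants).to_csv(out_dir / "participants.csv", index=False)
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
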