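"""Config-driven BIDS dataset emission.

Three CSV configuration files drive the conversion:

* **sequence overview** — which series descriptions to convert, the BIDS
  suffix/entities/datatype they map to, the sidecar keys each sequence
  requires, and replacement values for tags missing from the headers;
* **PET doses** — per subject/session/tracer injected-radioactivity
  parameters (InjectedRadioactivity in MBq, InjectedMass in nmol,
  SpecificRadioactivity in GBq/µmol), required only when PET series are
  selected;
* **tag map** — the DICOM tag backing each BIDS sidecar key.

Every required sidecar key is resolved by a fixed precedence —
dose-config values first (they are study inputs, not scanner tags), then
the DICOM header via the tag map, then the overview fallback — and the
winning source is recorded per key, so a converted dataset is fully
auditable.  Times are stored in seconds per the BIDS convention; the
millisecond DICOM timing tags are converted on the way through.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import pydicom
import nibabel as nib

from petmrbids.dicom_ingest import (
    SeriesRecord,
    VolumeStack,
    assemble_volume,
    extract_diffusion_tables,
    reorient,
    reorient_bvecs,
)

logger = logging.getLogger(__name__)

#: BIDS entity ordering for filename construction.
ENTITY_ORDER = ("task", "acq", "ce", "trc", "rec", "dir", "run", "echo", "flip", "part")

#: Sidecar keys whose DICOM source is in milliseconds but whose BIDS
#: value is in seconds.
_MS_TO_S_KEYS = frozenset({"EchoTime", "RepetitionTime", "InversionTime"})

#: Dose keys owned by the PET-doses config.
DOSE_KEYS = ("TracerName", "InjectedRadioactivity", "InjectedMass", "SpecificRadioactivity")


class ConfigError(ValueError):
    """Raised for schema violations in the configuration files."""


class SidecarResolutionError(RuntimeError):
    """Raised when a required sidecar key cannot be filled from any source."""


@dataclass
class OverviewRow:
    match_pattern: str
    bids_suffix: str
    destination: str
    bids_entities: dict[str, str] = field(default_factory=dict)
    required_keys: list[str] = field(default_factory=list)
    fallback_values: dict[str, Any] = field(default_factory=dict)


@dataclass
class SequenceOverviewConfig:
    """Sequences to integrate, their BIDS naming and fallback values."""

    rows: list[OverviewRow]

    def match(self, series_description: str) -> OverviewRow | None:
        """Return the unique overview row whose pattern matches, None when
        no row matches; two matches are an ambiguity error."""
        hits = [r for r in self.rows if re.search(r.match_pattern, series_description)]
        if not hits:
            return None
        if len(hits) > 1:
            patterns = [r.match_pattern for r in hits]
            raise ConfigError(
                f"series description {series_description!r} matches several "
                f"overview patterns {patterns}; ambiguity is never auto-resolved"
            )
        return hits[0]


@dataclass
class PetDoseConfig:
    """Per subject/session/tracer injected-dose parameters."""

    table: pd.DataFrame

    def lookup(self, subject: str, session: str | None, tracer: str) -> dict[str, Any]:
        t = self.table
        mask = (t["subject_label"].astype(str) == str(subject)) & (
            t["tracer"].astype(str) == str(tracer)
        )
        if session is not None and "session_label" in t.columns:
            mask &= t["session_label"].astype(str) == str(session)
        hits = t[mask]
        if hits.empty:
            raise ConfigError(
                f"no dose row for subject {subject!r} session {session!r} tracer {tracer!r}"
            )
        row = hits.iloc[0]
        out = {"TracerName": str(row["tracer"])}
        for key in ("InjectedRadioactivity", "InjectedMass", "SpecificRadioactivity"):
            if key in row.index and pd.notna(row[key]):
                out[key] = float(row[key])
        return out


@dataclass
class TagMapConfig:
    """BIDS sidecar key → DICOM tag name (or ``(group,element)`` path)."""

    mapping: dict[str, str]


@dataclass
class SidecarMetadata:
    """Resolved BIDS sidecar payload plus per-key provenance.

    Provenance values are ``"dicom"``, ``"tagmap"`` (alias of dicom via
    the tag map), ``"fallback"`` or ``"dose_config"``.
    """

    payload: dict[str, Any]
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.payload) - set(self.provenance)
        if missing:
            raise ValueError(f"keys without provenance: {sorted(missing)}")
        starts = self.payload.get("FrameTimesStart")
        durations = self.payload.get("FrameDuration")
        if starts is not None:
            if np.any(np.diff(starts) <= 0):
                raise ValueError("FrameTimesStart must be strictly increasing")
            if durations is not None and len(starts) != len(durations):
                raise ValueError("FrameTimesStart and FrameDuration lengths differ")

    def to_json(self) -> str:
        return json.dumps(self.payload, indent=2, sort_keys=True) + "\n"


@dataclass
class FrameSchedule:
    """Dynamic-PET frame schedule as ordered ``repeat × duration`` blocks,
    e.g. ``[(8, 4), (4, 6), (6, 10), (8, 20)]`` for a 26-frame water scan."""

    blocks: list[tuple[int, float]]

    def __post_init__(self) -> None:
        for repeat, duration in self.blocks:
            if repeat < 1:
                raise ValueError("block repeat must be >= 1")
            if duration <= 0:
                raise ValueError("block duration must be > 0")

    @property
    def n_frames(self) -> int:
        return sum(repeat for repeat, _ in self.blocks)


def expand_frame_schedule(
    schedule: FrameSchedule,
    expected_frames: int | None = None,
) -> tuple[list[float], list[float]]:
    """Expand a block schedule into per-frame ``(FrameTimesStart,
    FrameDuration)`` lists in seconds.

    Start times are cumulative: frame *i+1* starts when frame *i* ends.
    When ``expected_frames`` is given (a frame count stated in a protocol
    document), a mismatch with the block arithmetic is surfaced as a
    warning rather than silently trusted either way.
    """
    if not schedule.blocks:
        raise ValueError("empty frame schedule")
    durations: list[float] = []
    for repeat, duration in schedule.blocks:
        durations.extend([float(duration)] * repeat)
    starts = [0.0]
    for d in durations[:-1]:
        starts.append(starts[-1] + d)
    if expected_frames is not None and expected_frames != len(durations):
        warnings.warn(
            f"frame schedule expands to {len(durations)} frames but the protocol "
            f"states {expected_frames}; trusting the block arithmetic",
            stacklevel=2,
        )
    return starts, durations


# ---------------------------------------------------------------------------
# config loading


def _split_kv(cell: str | float | None) -> dict[str, str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        return {}
    out = {}
    for item in str(cell).split(";"):
        if not item.strip():
            continue
        if "=" not in item:
            raise ConfigError(f"malformed key=value item {item!r}")
        key, value = item.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _split_list(cell: str | float | None) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        return []
    return [item.strip() for item in str(cell).split(";") if item.strip()]


def _coerce(value: str) -> Any:
    try:
        return json.loads(value)
    except (json.JSONDecodeError, ValueError):
        return value


def load_configs(
    overview_path: str | Path,
    tagmap_path: str | Path,
    doses_path: str | Path | None = None,
) -> tuple[SequenceOverviewConfig, TagMapConfig, PetDoseConfig | None]:
    """Load and validate the three CSV configuration files.

    The doses file may be omitted when no PET sequence is converted;
    selecting a PET series without it is an error raised at resolution
    time naming the subject.
    """
    overview_df = pd.read_csv(overview_path, dtype=str)
    required_cols = {"match_pattern", "bids_suffix", "destination"}
    if not required_cols.issubset(overview_df.columns):
        raise ConfigError(
            f"sequence overview must have columns {sorted(required_cols)}"
        )
    seen: dict[str, int] = {}
    rows = []
    for i, row in overview_df.iterrows():
        pattern = str(row["match_pattern"])
        if pattern in seen:
            raise ConfigError(
                f"duplicate match_pattern {pattern!r} (rows {seen[pattern]} and {i})"
            )
        seen[pattern] = i
        fallbacks = {k: _coerce(v) for k, v in _split_kv(row.get("fallback_values")).items()}
        rows.append(
            OverviewRow(
                match_pattern=pattern,
                bids_suffix=str(row["bids_suffix"]),
                destination=str(row["destination"]),
                bids_entities=_split_kv(row.get("bids_entities")),
                required_keys=_split_list(row.get("required_keys")),
                fallback_values=fallbacks,
            )
        )
    overview = SequenceOverviewConfig(rows=rows)

    tagmap_df = pd.read_csv(tagmap_path, dtype=str)
    if not {"bids_key", "dicom_tag"}.issubset(tagmap_df.columns):
        raise ConfigError("tag map must have columns bids_key, dicom_tag")
    if tagmap_df["bids_key"].duplicated().any():
        dupes = tagmap_df.loc[tagmap_df["bids_key"].duplicated(), "bids_key"].tolist()
        raise ConfigError(f"duplicate bids_key entries in tag map: {dupes}")
    tagmap = TagMapConfig(mapping=dict(zip(tagmap_df["bids_key"], tagmap_df["dicom_tag"])))

    doses = None
    if doses_path is not None:
        doses_df = pd.read_csv(
            doses_path, dtype={"subject_label": str, "session_label": str, "tracer": str}
        )
        if not {"subject_label", "tracer"}.issubset(doses_df.columns):
            raise ConfigError("doses file must have columns subject_label, tracer")
        for i, row in doses_df.iterrows():
            if not str(row["tracer"]).strip():
                raise ConfigError(f"doses row {i}: empty tracer")
            for key in ("InjectedRadioactivity", "InjectedMass", "SpecificRadioactivity"):
                if key in doses_df.columns and pd.notna(row[key]) and float(row[key]) <= 0:
                    raise ConfigError(f"doses row {i}: {key} must be > 0")
        doses = PetDoseConfig(table=doses_df.astype({"subject_label": str}))
    return overview, tagmap, doses


# ---------------------------------------------------------------------------
# sidecar resolution


def _read_dicom_value(meta: pydicom.Dataset | Mapping[str, Any], tag: str) -> Any:
    m = re.fullmatch(r"\(?\s*([0-9a-fA-F]{4})\s*,\s*([0-9a-fA-F]{4})\s*\)?", tag)
    if isinstance(meta, pydicom.Dataset):
        if m:
            key = (int(m.group(1), 16), int(m.group(2), 16))
            element = meta.get(key)
            return None if element is None else element.value
        value = getattr(meta, tag, None)
        return value
    return meta.get(tag)


def resolve_sidecar(
    dicom_meta: pydicom.Dataset | Mapping[str, Any],
    record: SeriesRecord,
    overview_row: OverviewRow,
    tagmap: TagMapConfig,
    doses: PetDoseConfig | None = None,
) -> SidecarMetadata:
    """Fill every required sidecar key of one acquisition, auditable.

    Precedence per key: dose-config (PET dose keys only) > DICOM header
    via the tag map > overview fallback.  Each resolved key records the
    source that supplied it; a required key no source can fill raises
    :class:`SidecarResolutionError`.
    """
    payload: dict[str, Any] = {}
    provenance: dict[str, str] = {}

    dose_values: dict[str, Any] = {}
    is_pet = overview_row.destination == "pet" or overview_row.bids_suffix == "pet"
    if is_pet:
        if doses is None:
            raise ConfigError(
                f"PET sequence selected for subject {record.subject_label!r} "
                "but no PET-doses configuration was provided"
            )
        tracer = overview_row.bids_entities.get("trc", "")
        dose_values = doses.lookup(record.subject_label, record.session_label, tracer)

    for key in overview_row.required_keys:
        if key in dose_values:
            payload[key] = dose_values[key]
            provenance[key] = "dose_config"
            continue
        tag = tagmap.mapping.get(key)
        value = _read_dicom_value(dicom_meta, tag) if tag else None
        if value is not None:
            if key in _MS_TO_S_KEYS:
                value = float(value) / 1000.0
            elif isinstance(value, (int, float)):
                value = float(value)
            else:
                value = str(value)
            payload[key] = value
            provenance[key] = "dicom"
            continue
        if key in overview_row.fallback_values:
            payload[key] = overview_row.fallback_values[key]
            provenance[key] = "fallback"
            continue
        raise SidecarResolutionError(
            f"required sidecar key {key!r} for series {record.series_id} "
            f"(subject {record.subject_label}) is absent from the dose config, "
            "the DICOM header and the overview fallbacks"
        )
    return SidecarMetadata(payload=payload, provenance=provenance)


# ---------------------------------------------------------------------------
# naming and writing


_LABEL_RE = re.compile(r"^[a-zA-Z0-9]+$")


def _clean_entity(value: str) -> str:
    return re.sub(r"[^a-zA-Z0-9]", "", str(value))


def bids_name(
    subject: str,
    session: str | None,
    entities: Mapping[str, str],
    suffix: str,
    extension: str,
    datatype: str | None = None,
) -> str:
    """Deterministic BIDS-relative path for one acquisition.

    ``session=None`` produces single-session naming with no ``ses-``
    entity anywhere.  Entity values are stripped to alphanumerics (the
    BIDS label grammar); illegal subject/session labels raise.
    """
    if not _LABEL_RE.fullmatch(subject):
        raise ValueError(f"illegal subject label {subject!r}")
    if session is not None and not _LABEL_RE.fullmatch(session):
        raise ValueError(f"illegal session label {session!r}")
    parts = [f"sub-{subject}"]
    if session is not None:
        parts.append(f"ses-{session}")
    for key in ENTITY_ORDER:
        if key in entities:
            parts.append(f"{key}-{_clean_entity(entities[key])}")
    unknown = set(entities) - set(ENTITY_ORDER)
    if unknown:
        raise ValueError(f"unknown BIDS entities: {sorted(unknown)}")
    stem = "_".join(parts + [suffix])
    folder = Path(f"sub-{subject}")
    if session is not None:
        folder = folder / f"ses-{session}"
    if datatype is None:
        datatype = {"dwi": "dwi", "pet": "pet"}.get(suffix, "anat")
    return str(folder / datatype / f"{stem}{extension}")


DATASET_DESCRIPTION_TEMPLATE = {
    "Name": "Converted PET/MR dataset",
    "BIDSVersion": "1.8.0",
    "DatasetType": "raw",
}

#: participants.tsv columns covering the variables a preclinical cohort
#: description reports.
PARTICIPANTS_COLUMNS = ("participant_id", "species", "age", "sex", "weight")


@dataclass
class ConversionItem:
    """One acquisition ready to be written: volume + naming + sidecar."""

    stack: VolumeStack
    subject: str
    session: str | None
    suffix: str
    datatype: str
    entities: dict[str, str]
    sidecar: SidecarMetadata
    diffusion: Any = None  # DiffusionTables for dwi items


def _nifti_dtype(arr: np.ndarray) -> np.dtype:
    if np.issubdtype(arr.dtype, np.integer):
        return arr.dtype
    return np.dtype(np.float32) if arr.dtype == np.float32 else np.dtype(np.float64)


def write_dataset(
    items: Sequence[ConversionItem],
    output_root: str | Path,
    participants: pd.DataFrame | None = None,
    dataset_name: str | None = None,
    overwrite: bool = False,
) -> list[Path]:
    """Write conversion items as a BIDS tree under ``output_root``.

    Emits gzipped NIfTI-1 images, JSON sidecars (keys serialised in fixed
    order, so re-runs are byte-identical), FSL-style ``.bval``/``.bvec``
    for diffusion items, a ``dataset_description.json`` template and a
    ``participants.tsv``.  Collisions with existing files raise unless
    ``overwrite`` is set.

    Returns the list of image paths written.
    """
    output_root = Path(output_root)
    output_root.mkdir(parents=True, exist_ok=True)

    description = dict(DATASET_DESCRIPTION_TEMPLATE)
    if dataset_name:
        description["Name"] = dataset_name
    (output_root / "dataset_description.json").write_text(
        json.dumps(description, indent=2, sort_keys=True) + "\n"
    )

    if participants is None:
        subjects = sorted({item.subject for item in items})
        participants = pd.DataFrame(
            {"participant_id": [f"sub-{s}" for s in subjects]}
        ).reindex(columns=PARTICIPANTS_COLUMNS, fill_value="n/a")
    participants.to_csv(output_root / "participants.tsv", sep="\t", index=False, na_rep="n/a")

    written: list[Path] = []
    for item in items:
        rel = bids_name(
            item.subject, item.session, item.entities, item.suffix, ".nii.gz", item.datatype
        )
        img_path = output_root / rel
        if img_path.exists() and not overwrite:
            raise FileExistsError(f"refusing to overwrite {img_path} (pass overwrite=True)")
        img_path.parent.mkdir(parents=True, exist_ok=True)

        arr = item.stack.voxels
        img = nib.Nifti1Image(arr.astype(_nifti_dtype(arr)), item.stack.affine)
        img.header.set_zooms(
            tuple(item.stack.spacing_mm) + (1.0,) * (arr.ndim - 3)
        )
        nib.save(img, img_path)
        written.append(img_path)

        sidecar_path = img_path.with_name(img_path.name.replace(".nii.gz", ".json"))
        sidecar_path.write_text(item.sidecar.to_json())

        if item.diffusion is not None:
            bval_path = img_path.with_name(img_path.name.replace(".nii.gz", ".bval"))
            bvec_path = img_path.with_name(img_path.name.replace(".nii.gz", ".bvec"))
            bvals = np.atleast_2d(item.diffusion.bvals)
            np.savetxt(bval_path, bvals, fmt="%g")
            np.savetxt(bvec_path, item.diffusion.bvecs.T, fmt="%.6f")
    return written


# ---------------------------------------------------------------------------
# end-to-end conversion


def convert_series(
    records: Sequence[SeriesRecord],
    overview: SequenceOverviewConfig,
    tagmap: TagMapConfig,
    doses: PetDoseConfig | None = None,
    orientation: str = "RPI",
    subjects: Sequence[str] | None = None,
    sessions: Sequence[str] | None = None,
    frame_schedules: Mapping[str, FrameSchedule] | None = None,
) -> list[ConversionItem]:
    """Match indexed series against the overview, assemble and reorient
    volumes, and resolve sidecars — the library core of the ``convert``
    command.

    ``frame_schedules`` maps tracer names to dynamic frame schedules;
    matched PET items get ``FrameTimesStart``/``FrameDuration`` expanded
    from them when those keys are not already resolved.  Series matching
    no overview row are skipped with a warning; an ambiguous match is an
    error.
    """
    items: list[ConversionItem] = []
    for record in records:
        if subjects is not None and record.subject_label not in subjects:
            continue
        if sessions is not None and record.session_label not in sessions:
            continue
        if not record.valid:
            logger.warning(
                "skipping invalid series %s: %s", record.series_id, record.invalid_reason
            )
            continue
        row = overview.match(record.series_description)
        if row is None:
            logger.warning(
                "series %s (%r) matches no overview row; skipped",
                record.series_id,
                record.series_description,
            )
            continue
        stack = assemble_volume(record)
        if stack.orientation_code != orientation.upper():
            source_code = stack.orientation_code
            stack = reorient(stack, orientation)
        else:
            source_code = stack.orientation_code

        header = pydicom.dcmread(record.file_paths[0], stop_before_pixels=True)
        sidecar = resolve_sidecar(header, record, row, tagmap, doses)
        if stack.has_echo_axis and "EchoTime" in sidecar.payload:
            # multi-echo stacks carry the full ascending echo-time list
            sidecar.payload["EchoTime"] = list(stack.echo_times)
        if record.acquisition_year is not None:
            sidecar.payload["AcquisitionYear"] = record.acquisition_year
            sidecar.provenance["AcquisitionYear"] = "dicom"

        is_pet = row.destination == "pet" or row.bids_suffix == "pet"
        if is_pet and frame_schedules:
            tracer = str(sidecar.payload.get("TracerName", row.bids_entities.get("trc", "")))
            schedule = frame_schedules.get(tracer)
            if schedule is not None and "FrameTimesStart" not in sidecar.payload:
                starts, durations = expand_frame_schedule(schedule)
                if stack.n_frames != len(durations):
                    raise ConfigError(
                        f"series {record.series_id}: {stack.n_frames} frames in data "
                        f"but schedule expands to {len(durations)}"
                    )
                sidecar.payload["FrameTimesStart"] = starts
                sidecar.payload["FrameDuration"] = durations
                sidecar.provenance["FrameTimesStart"] = "fallback"
                sidecar.provenance["FrameDuration"] = "fallback"

        diffusion = None
        if row.destination == "dwi" or row.bids_suffix == "dwi":
            diffusion = extract_diffusion_tables(record)
            if source_code != orientation.upper():
                diffusion = reorient_bvecs(diffusion, source_code, orientation)

        items.append(
            ConversionItem(
                stack=stack,
                subject=record.subject_label,
                session=record.session_label,
                suffix=row.bids_suffix,
                datatype=row.destination,
                entities=dict(row.bids_entities),
                sidecar=sidecar,
                diffusion=diffusion,
            )
        )
    return items
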