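"""Image-quality and PET counting-statistics metrics.

The image metrics work on a volume of interest (VOI) obtained by Otsu
thresholding the volume with the highest mean intensity in a stack:
voxels at or above the threshold are tissue signal, voxels below it are
background used for noise measurement.  With ``μ_VOI`` the mean tissue
intensity, ``σ_noise`` the sample standard deviation of the background,
and ``max/min/median_VOI`` order statistics over the tissue voxels:

    SNR = μ_VOI / σ_noise
    CNR = (max_VOI − min_VOI) / σ_noise
    median intensity = median_VOI

For dynamic acquisitions the metrics are averaged across frames; for
multi-echo acquisitions the median intensity is averaged across echoes
while SNR and CNR are computed on the first echo only, where SNR is
maximal.

The PET counting metric is the pseudo-noise-equivalent count rate
computed per frame from total prompts ``P`` and total randoms ``D``:

    PNECR = (P − D)² / P

expressed as a rate (divided by the frame duration) so that curves from
different frame schedules are comparable; the maximum over frames
summarises each scan.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from petmrbids.dicom_ingest import VolumeStack

logger = logging.getLogger(__name__)

#: Histogram resolution for Otsu thresholding on raw samples.
OTSU_BINS = 256


class DegenerateImageError(ValueError):
    """Raised when an image has no contrast to threshold or measure."""


# ---------------------------------------------------------------------------
# Otsu thresholding


def otsu_threshold(
    intensities: np.ndarray | None = None,
    *,
    histogram: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Otsu's threshold: maximise the between-class variance.

    Accepts either a raw intensity sample (histogrammed into
    :data:`OTSU_BINS` equal-width bins between the observed min and max)
    or a pre-computed ``(counts, bin_edges)`` histogram.  Candidate
    thresholds are the interior bin edges; bins are represented by their
    centres.  The between-class variance ``w0·w1·(μ0 − μ1)²`` is
    maximised; ties select the lowest threshold, so the result is
    deterministic for a fixed binning.
    """
    if (intensities is None) == (histogram is None):
        raise ValueError("provide exactly one of intensities or histogram")
    if histogram is not None:
        counts, edges = histogram
        counts = np.asarray(counts, dtype=float)
        edges = np.asarray(edges, dtype=float)
        if counts.size + 1 != edges.size:
            raise ValueError("histogram needs len(edges) == len(counts) + 1")
    else:
        sample = np.asarray(intensities, dtype=float).ravel()
        sample = sample[np.isfinite(sample)]
        if sample.size == 0 or np.ptp(sample) == 0:
            raise DegenerateImageError("degenerate image: fewer than 2 distinct values")
        counts, edges = np.histogram(sample, bins=OTSU_BINS)
        counts = counts.astype(float)

    if counts.sum() <= 0 or np.count_nonzero(counts) < 2:
        raise DegenerateImageError("degenerate image: fewer than 2 distinct values")

    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    prob = counts / total
    w0 = np.cumsum(prob)[:-1]               # weight of class below edge k+1
    w1 = 1.0 - w0
    cum_mean = np.cumsum(prob * centers)[:-1]
    grand_mean = float(np.sum(prob * centers))
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / w0
        mu1 = (grand_mean - cum_mean) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    # a split whose lower class ends in an empty bin partitions the data
    # identically to an earlier split: skip it so that plateaus across
    # empty bins resolve canonically to their lowest edge
    valid = (w0 > 0) & (w1 > 0) & (counts[:-1] > 0)
    between = np.where(valid, between, -np.inf)
    best = int(np.argmax(between))          # argmax takes the first (lowest) tie
    return float(edges[best + 1])


@dataclass
class VoiSegmentation:
    """Tissue/background split of a stack from one Otsu threshold.

    The threshold is computed on the *reference volume* — the (echo,
    frame) 3-D volume with the highest mean intensity — and the resulting
    masks are applied to every volume of the stack.
    """

    threshold: float
    voi_mask: np.ndarray
    background_mask: np.ndarray
    reference_volume_index: tuple[int, int]

    def __post_init__(self) -> None:
        if np.any(self.voi_mask & self.background_mask):
            raise ValueError("voi and background masks overlap")
        if not np.all(self.voi_mask | self.background_mask):
            raise ValueError("masks do not cover the volume")
        if not self.voi_mask.any() or not self.background_mask.any():
            raise DegenerateImageError("empty VOI or empty background after thresholding")


def segment_voi(stack: VolumeStack) -> VoiSegmentation:
    """Otsu-segment a stack on its highest-mean-intensity volume."""
    means = np.array(
        [[stack.get_volume(e, f).mean() for f in range(stack.n_frames)]
         for e in range(stack.n_echoes)]
    )
    e_ref, f_ref = np.unravel_index(int(np.argmax(means)), means.shape)
    reference = stack.get_volume(int(e_ref), int(f_ref))
    threshold = otsu_threshold(reference)
    voi = reference >= threshold
    return VoiSegmentation(
        threshold=threshold,
        voi_mask=voi,
        background_mask=~voi,
        reference_volume_index=(int(e_ref), int(f_ref)),
    )


# ---------------------------------------------------------------------------
# scalar metrics


def _sigma_noise(volume: np.ndarray, seg: VoiSegmentation) -> float:
    sigma = float(np.std(volume[seg.background_mask], ddof=1))
    if sigma == 0:
        raise DegenerateImageError("noiseless background: sigma_noise is zero")
    return sigma


def compute_snr(volume: np.ndarray, seg: VoiSegmentation) -> float:
    """Signal-to-noise ratio ``μ_VOI / σ_noise`` of one 3-D volume."""
    return float(np.mean(volume[seg.voi_mask])) / _sigma_noise(volume, seg)


def compute_cnr(volume: np.ndarray, seg: VoiSegmentation) -> float:
    """Contrast-to-noise ratio ``(max_VOI − min_VOI) / σ_noise``.

    Literal max and min over the VOI — no percentile clipping."""
    voi = volume[seg.voi_mask]
    return float(voi.max() - voi.min()) / _sigma_noise(volume, seg)


def compute_median_intensity(volume: np.ndarray, seg: VoiSegmentation) -> float:
    """Median intensity over the VOI (mean-of-middle for even counts)."""
    return float(np.median(volume[seg.voi_mask]))


# ---------------------------------------------------------------------------
# per-acquisition record


@dataclass
class QcRecord:
    """Per-acquisition quality summary."""

    subject: str
    session: str | None
    sequence: str
    acquisition_year: int | None
    snr: float
    cnr: float
    median_intensity: float
    voi_voxels: int
    background_voxels: int
    threshold: float = float("nan")
    reference_volume_index: tuple[int, int] = (0, 0)
    outlier: bool = False
    outlier_reason: str | None = None

    def __post_init__(self) -> None:
        if self.snr < 0 or self.cnr < 0:
            raise ValueError("snr and cnr must be non-negative")


def qc_acquisition(
    stack: VolumeStack,
    subject: str = "",
    session: str | None = None,
    sequence: str = "",
    acquisition_year: int | None = None,
) -> QcRecord:
    """Compute the quality metrics of one acquisition with the dynamic
    and multi-echo averaging rules.

    * dynamic (frame axis): per-frame metrics averaged over frames;
    * multi-echo: median intensity averaged across echoes, SNR and CNR
      from the first echo only;
    * static 3-D: plain single-volume metrics.
    """
    try:
        seg = segment_voi(stack)
    except DegenerateImageError as exc:
        raise DegenerateImageError(f"sequence {sequence!r} ({subject}): {exc}") from exc

    snr_frames = [
        compute_snr(stack.get_volume(0, f), seg) for f in range(stack.n_frames)
    ]
    cnr_frames = [
        compute_cnr(stack.get_volume(0, f), seg) for f in range(stack.n_frames)
    ]
    medians = [
        np.mean([
            compute_median_intensity(stack.get_volume(e, f), seg)
            for f in range(stack.n_frames)
        ])
        for e in range(stack.n_echoes)
    ]
    return QcRecord(
        subject=subject,
        session=session,
        sequence=sequence,
        acquisition_year=acquisition_year,
        snr=float(np.mean(snr_frames)),
        cnr=float(np.mean(cnr_frames)),
        median_intensity=float(np.mean(medians)),
        voi_voxels=int(seg.voi_mask.sum()),
        background_voxels=int(seg.background_mask.sum()),
        threshold=seg.threshold,
        reference_volume_index=seg.reference_volume_index,
    )


# ---------------------------------------------------------------------------
# PET counting statistics


def pnecr(prompts: float, randoms: float) -> float:
    """Pseudo-noise-equivalent counts ``(P − D)² / P`` of one frame.

    ``P`` is the total prompts and ``D`` the total randoms of the frame.
    An empty frame (``P = 0``) is defined as 0; more randoms than prompts
    is a counting impossibility and raises.
    """
    if randoms < 0:
        raise ValueError("randoms must be non-negative")
    if randoms > prompts:
        raise ValueError(f"randoms ({randoms}) exceed prompts ({prompts})")
    if prompts == 0:
        return 0.0
    return (prompts - randoms) ** 2 / prompts


@dataclass
class CountRateSeries:
    """Per-frame prompts/randoms counts with the derived PNECR curve.

    ``pnecr_rate`` holds the per-frame PNECR divided by the frame
    duration (counts/s) so curves across frame schedules are comparable;
    ``pnecr_total`` keeps the undivided per-frame value.  ``pnecr_max``
    is the maximum of the rate curve.
    """

    frame_starts_s: np.ndarray
    frame_durations_s: np.ndarray
    prompts: np.ndarray
    randoms: np.ndarray
    pnecr_total: np.ndarray | None = None
    pnecr_rate: np.ndarray | None = None
    pnecr_max: float | None = None

    def __post_init__(self) -> None:
        self.frame_starts_s = np.asarray(self.frame_starts_s, dtype=float)
        self.frame_durations_s = np.asarray(self.frame_durations_s, dtype=float)
        self.prompts = np.asarray(self.prompts, dtype=float)
        self.randoms = np.asarray(self.randoms, dtype=float)
        n = self.prompts.size
        if not (self.randoms.size == self.frame_starts_s.size == self.frame_durations_s.size == n):
            raise ValueError("frame timing and count arrays must have equal length")
        if np.any(self.randoms < 0) or np.any(self.randoms > self.prompts):
            raise ValueError("counts must satisfy 0 <= randoms <= prompts per frame")
        if np.any(self.frame_durations_s <= 0):
            raise ValueError("frame durations must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.prompts.size)


def pnecr_series(
    series: CountRateSeries,
    expected_frames: int | None = None,
) -> CountRateSeries:
    """Fill the PNECR curve of a count-rate series.

    Raises when the frame count disagrees with ``expected_frames`` (the
    frame schedule the counts should align with).
    """
    if expected_frames is not None and series.n_frames != expected_frames:
        raise ValueError(
            f"count table has {series.n_frames} frames but the schedule "
            f"expects {expected_frames}"
        )
    total = np.array([pnecr(p, d) for p, d in zip(series.prompts, series.randoms)])
    rate = total / series.frame_durations_s
    series.pnecr_total = total
    series.pnecr_rate = rate
    series.pnecr_max = float(rate.max())
    return series


def pnecr_log_curve(series: CountRateSeries) -> tuple[np.ndarray, np.ndarray, int]:
    """Frame mid-times and PNECR rates ready for a log-scale plot.

    Nonpositive values cannot be drawn on a logarithmic axis; they are
    dropped and their count is returned alongside.
    """
    if series.pnecr_rate is None:
        series = pnecr_series(series)
    mids = series.frame_starts_s + series.frame_durations_s / 2.0
    keep = series.pnecr_rate > 0
    return mids[keep], series.pnecr_rate[keep], int(np.sum(~keep))


# ---------------------------------------------------------------------------
# BIDS-tree entry points


def read_counts_csv(path) -> CountRateSeries:
    """Load a per-frame counts table (columns ``frame_index, start_s,
    duration_s, prompts, randoms``) into a :class:`CountRateSeries`."""
    import pandas as pd

    t = pd.read_csv(path)
    required = {"start_s", "duration_s", "prompts", "randoms"}
    if not required.issubset(t.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    return CountRateSeries(
        frame_starts_s=t["start_s"].to_numpy(float),
        frame_durations_s=t["duration_s"].to_numpy(float),
        prompts=t["prompts"].to_numpy(float),
        randoms=t["randoms"].to_numpy(float),
    )


def load_bids_stack(img_path) -> tuple[VolumeStack, dict]:
    """Read one BIDS NIfTI image plus its JSON sidecar as a stack.

    A 4th dimension is interpreted as a frame axis when the sidecar has
    ``FrameTimesStart`` or the suffix is ``dwi``, as an echo axis when
    ``EchoTime`` is a list, and as frames otherwise.
    """
    import json
    from pathlib import Path

    import nibabel as nib

    img_path = Path(img_path)
    img = nib.load(img_path)
    arr = np.asanyarray(img.dataobj)
    sidecar_path = Path(str(img_path).replace(".nii.gz", ".json").replace(".nii", ".json"))
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}

    echo_times: tuple = ()
    frame_times: tuple = ()
    if arr.ndim >= 4:
        n4 = arr.shape[3]
        te = sidecar.get("EchoTime")
        if isinstance(te, (list, tuple)) and len(te) == n4:
            echo_times = tuple(float(v) for v in te)
        elif "FrameTimesStart" in sidecar:
            frame_times = tuple(float(v) for v in sidecar["FrameTimesStart"])
        else:
            frame_times = tuple(float(i) for i in range(n4))
    code = "".join(nib.orientations.aff2axcodes(img.affine))
    stack = VolumeStack(
        voxels=arr,
        spacing_mm=np.asarray(img.header.get_zooms()[:3], dtype=float),
        affine=np.asarray(img.affine),
        orientation_code=code,
        echo_times=echo_times,
        frame_times_s=frame_times,
    )
    return stack, sidecar


def qc_bids_dataset(bids_root) -> list[QcRecord]:
    """Run :func:`qc_acquisition` over every image of a BIDS tree."""
    import re
    from pathlib import Path

    bids_root = Path(bids_root)
    name_re = re.compile(
        r"^sub-(?P<sub>[a-zA-Z0-9]+)(_ses-(?P<ses>[a-zA-Z0-9]+))?"
        r"(?P<entities>(_[a-z]+-[a-zA-Z0-9]+)*)_(?P<suffix>[a-zA-Z0-9]+)\.nii(\.gz)?$"
    )
    records: list[QcRecord] = []
    for img_path in sorted(bids_root.rglob("*.nii*")):
        m = name_re.match(img_path.name)
        if m is None:
            continue
        stack, sidecar = load_bids_stack(img_path)
        entities = [e for e in (m.group("entities") or "").strip("_").split("_") if e]
        sequence = " ".join(entities + [m.group("suffix")]) if entities else m.group("suffix")
        year = sidecar.get("AcquisitionYear")
        records.append(
            qc_acquisition(
                stack,
                subject=m.group("sub"),
                session=m.group("ses"),
                sequence=sequence,
                acquisition_year=int(year) if year is not None else None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# outlier flagging


def flag_outliers(
    records: Sequence[QcRecord],
    metric: str = "snr",
    n_mad: float = 3.0,
    min_group: int = 4,
) -> list[bool]:
    """Flag records whose metric departs from their sequence group.

    Within each sequence group a record is flagged when
    ``|value − group median| > n_mad × scaled MAD`` (MAD scaled by
    1.4826 to be consistent with a normal σ).  Groups smaller than
    ``min_group`` get no flags, with a warning.  Flags and reasons are
    also written back onto the records.
    """
    values = np.array([getattr(r, metric) for r in records], dtype=float)
    flags = [False] * len(records)
    sequences = sorted({r.sequence for r in records})
    for sequence in sequences:
        idx = [i for i, r in enumerate(records) if r.sequence == sequence]
        if len(idx) < min_group:
            warnings.warn(
                f"sequence group {sequence!r} has only {len(idx)} records; "
                "too small for outlier flagging",
                stacklevel=2,
            )
            continue
        group = values[idx]
        center = float(np.median(group))
        mad = float(stats.median_abs_deviation(group, scale="normal"))
        if mad == 0:
            deviants = [i for i in idx if values[i] != center]
        else:
            deviants = [i for i in idx if abs(values[i] - center) > n_mad * mad]
        for i in deviants:
            flags[i] = True
            records[i].outlier = True
            records[i].outlier_reason = (
                f"{metric}={values[i]:.4g} departs from {sequence} group median "
                f"{center:.4g} by more than {n_mad} scaled MAD ({mad:.4g})"
            )
    return flags
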