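"""Cohort-level aggregation: availability, participants summary, figures.

The availability matrix is the automated counter behind the classic
"which subject has which sequence" heatmap: one row per subject-session,
one column per sequence label, each cell the number of acquisitions
found in the BIDS tree (0 = missing; test–retest subjects contribute two
rows).  The participants summary reports mean, sample standard deviation
(n−1 denominator) and value→count/percentage distributions per numeric
variable.  Distribution exports render the per-sequence violin + strip
plots and the log-scale dynamic PNECR figure.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from petmrbids.quality_metrics import CountRateSeries, QcRecord, pnecr_log_curve

logger = logging.getLogger(__name__)

_BIDS_FILE_RE = re.compile(
    r"^sub-(?P<sub>[a-zA-Z0-9]+)(_ses-(?P<ses>[a-zA-Z0-9]+))?"
    r"(?P<entities>(_[a-z]+-[a-zA-Z0-9]+)*)_(?P<suffix>[a-zA-Z0-9]+)"
    r"\.(?P<ext>nii(\.gz)?)$"
)


def _sequence_label(entities: str, suffix: str) -> str:
    """Column label for the availability matrix: the suffix plus any
    distinguishing entities (e.g. ``trc-H2O pet``)."""
    parts = [e for e in entities.strip("_").split("_") if e]
    return " ".join(parts + [suffix]) if parts else suffix


@dataclass
class AvailabilityMatrix:
    """Acquisition counts per subject-session × sequence label."""

    table: pd.DataFrame

    @property
    def n_sessions(self) -> int:
        return len(self.table.index)

    @property
    def total(self) -> int:
        return int(self.table.to_numpy().sum())

    def missing_cells(self) -> list[tuple[str, str]]:
        """``(row, column)`` pairs with zero acquisitions."""
        zero = self.table == 0
        return [
            (str(idx), str(col))
            for idx in self.table.index
            for col in self.table.columns
            if zero.loc[idx, col]
        ]


def availability_matrix(bids_root: str | Path) -> AvailabilityMatrix:
    """Count each suffix/entity combination per subject-session.

    Scans the BIDS tree for image files; non-BIDS-named files are ignored
    with a warning.  An empty tree yields an empty matrix.
    """
    bids_root = Path(bids_root)
    counts: dict[tuple[str, str], int] = {}
    rows: set[str] = set()
    cols: set[str] = set()
    for path in sorted(bids_root.rglob("*.nii*")):
        m = _BIDS_FILE_RE.match(path.name)
        if m is None:
            logger.warning("ignoring non-BIDS image file: %s", path)
            continue
        row = f"sub-{m.group('sub')}"
        if m.group("ses"):
            row += f"_ses-{m.group('ses')}"
        col = _sequence_label(m.group("entities") or "", m.group("suffix"))
        rows.add(row)
        cols.add(col)
        counts[(row, col)] = counts.get((row, col), 0) + 1
    table = pd.DataFrame(0, index=sorted(rows), columns=sorted(cols), dtype=int)
    for (row, col), n in counts.items():
        table.loc[row, col] = n
    return AvailabilityMatrix(table=table)


@dataclass
class ParticipantsSummary:
    """Mean/SD/n plus value→(count, percent) tables per variable."""

    stats: dict[str, dict[str, float | int | None]]
    distributions: dict[str, pd.DataFrame]


def summarize_participants(
    table: pd.DataFrame,
    variables: Sequence[str] = ("age", "weight"),
    bins: dict[str, Sequence[float]] | None = None,
) -> ParticipantsSummary:
    """Summarise numeric cohort variables.

    Sample standard deviation uses the n−1 denominator; for a single
    subject the SD is reported as None.  ``bins`` maps a variable to bin
    edges for a binned distribution (half-open ``[lo; hi)`` intervals,
    last bin closed); unbinned variables get exact value counts.
    Percentages sum to 100 per variable.
    """
    bins = bins or {}
    stats: dict[str, dict] = {}
    distributions: dict[str, pd.DataFrame] = {}
    for var in variables:
        if var not in table.columns:
            raise KeyError(f"variable {var!r} not in participants table")
        values = pd.to_numeric(table[var], errors="coerce")
        bad = values.isna() & table[var].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric entries for {var!r} at rows {list(table.index[bad])}"
            )
        values = values.dropna()
        n = int(values.size)
        stats[var] = {
            "mean": float(values.mean()) if n else None,
            "sd": float(values.std(ddof=1)) if n > 1 else None,
            "n": n,
        }
        if var in bins:
            edges = list(bins[var])
            labels = [f"[{lo:g};{hi:g}]" for lo, hi in zip(edges[:-1], edges[1:])]
            binned = pd.cut(values, bins=edges, labels=labels, include_lowest=True)
            vc = binned.value_counts().reindex(labels).fillna(0).astype(int)
        else:
            vc = values.value_counts().sort_index()
        dist = pd.DataFrame({"count": vc})
        dist["percent"] = 100.0 * dist["count"] / max(n, 1)
        distributions[var] = dist
    return ParticipantsSummary(stats=stats, distributions=distributions)


def qc_records_table(records: Sequence[QcRecord]) -> pd.DataFrame:
    """Long-format table of QC metrics: one row per acquisition × metric."""
    rows = []
    for r in records:
        for metric in ("snr", "cnr", "median_intensity"):
            rows.append(
                {
                    "subject": r.subject,
                    "session": r.session,
                    "sequence": r.sequence,
                    "year": r.acquisition_year,
                    "metric": metric,
                    "value": getattr(r, metric),
                    "outlier": r.outlier,
                }
            )
    return pd.DataFrame(rows)


def export_distributions(
    records: Sequence[QcRecord],
    out_dir: str | Path,
    count_series: Sequence[tuple[str, CountRateSeries]] = (),
    figure_format: str = "png",
) -> dict[str, Path]:
    """Write plot-ready tables and the violin/strip and PNECR figures.

    One violin per sequence label with acquisition-level strip points,
    per metric; dynamic PNECR curves on a log scale (nonpositive frames
    dropped, with the dropped count recorded in the long table).

    Returns a name → path mapping of everything written.
    """
    if not records and not count_series:
        raise ValueError("nothing to export")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    table = qc_records_table(records)
    if records:
        table_path = out_dir / "qc_metrics_long.tsv"
        table.to_csv(table_path, sep="\t", index=False)
        written["qc_table"] = table_path

    for metric in ("snr", "cnr", "median_intensity") if records else ():
        sub = table[table["metric"] == metric]
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(1.2 * max(sub["sequence"].nunique(), 4) + 2, 4))
        order = sorted(sub["sequence"].unique())
        sns.violinplot(
            data=sub, x="sequence", y="value", order=order, inner=None,
            color="lightsteelblue", cut=0, ax=ax,
        )
        sns.stripplot(
            data=sub, x="sequence", y="value", order=order, hue="year",
            palette="viridis", size=4, ax=ax,
        )
        ax.set_ylabel(metric)
        fig.tight_layout()
        path = out_dir / f"{metric}_violin.{figure_format}"
        fig.savefig(path)
        plt.close(fig)
        written[f"{metric}_figure"] = path

    if count_series:
        pn_rows = []
        dropped_rows = []
        fig, ax = plt.subplots(figsize=(7, 4))
        for label, series in count_series:
            mids, rates, dropped = pnecr_log_curve(series)
            ax.plot(mids, rates, alpha=0.6, label=None)
            for t, v in zip(mids, rates):
                pn_rows.append({"label": label, "time_s": t, "pnecr_rate": v})
            if dropped:
                logger.info("%s: %d nonpositive PNECR frames dropped from log plot", label, dropped)
            dropped_rows.append({"label": label, "dropped_frames": dropped})
        ax.set_yscale("log")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("PNECR (counts/s)")
        fig.tight_layout()
        path = out_dir / f"pnecr_dynamics.{figure_format}"
        fig.savefig(path)
        plt.close(fig)
        written["pnecr_figure"] = path

        pn_table = pd.DataFrame(pn_rows)
        pn_path = out_dir / "pnecr_long.tsv"
        pn_table.to_csv(pn_path, sep="\t", index=False)
        written["pnecr_table"] = pn_path

        dropped_path = out_dir / "pnecr_dropped_frames.tsv"
        pd.DataFrame(dropped_rows).to_csv(dropped_path, sep="\t", index=False)
        written["pnecr_dropped"] = dropped_path
    return written
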