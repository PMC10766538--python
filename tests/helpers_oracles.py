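"""Independent test oracles, deliberately written without reusing the
package's implementation paths.

* a brute-force Otsu threshold search (explicit loops over candidate
  thresholds, direct two-class statistics);
* a rule-based BIDS structure validator (naming grammar + required
  dataset files), used to check written trees;
* a plain matrix-multiplication world-coordinate mapper for affine
  consistency checks.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np


def brute_force_otsu(counts: np.ndarray, edges: np.ndarray) -> float:
    """Exhaustive between-class-variance maximisation over all interior
    bin edges; ties resolved to the lowest threshold."""
    counts = np.asarray(counts, dtype=float)
    edges = np.asarray(edges, dtype=float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    best_score, best_threshold = -np.inf, None
    for k in range(1, len(counts)):
        n0, n1 = counts[:k].sum(), counts[k:].sum()
        # splits ending the lower class in an empty bin duplicate an
        # earlier partition; skip so plateau ties resolve to lowest edge
        if n0 == 0 or n1 == 0 or counts[k - 1] == 0:
            continue
        w0, w1 = n0 / total, n1 / total
        mu0 = float(np.dot(counts[:k], centers[:k]) / n0)
        mu1 = float(np.dot(counts[k:], centers[k:]) / n1)
        score = w0 * w1 * (mu0 - mu1) ** 2
        if score > best_score:
            best_score, best_threshold = score, float(edges[k])
    return best_threshold


# --------------------------------------------------------------------------
# BIDS structure validator

_ENTITY_ORDER = ["task", "acq", "ce", "trc", "rec", "dir", "run", "echo", "flip", "part"]
_NAME_RE = re.compile(
    r"^sub-(?P<sub>[a-zA-Z0-9]+)(?:_ses-(?P<ses>[a-zA-Z0-9]+))?"
    r"(?P<entities>(?:_[a-z]+-[a-zA-Z0-9]+)*)_(?P<suffix>[a-zA-Z0-9]+)"
    r"(?P<ext>\.nii(\.gz)?|\.json|\.bval|\.bvec)$"
)
_DATATYPES = {"anat", "dwi", "perf", "pet", "func", "fmap"}


def validate_bids_tree(root: str | Path) -> list[str]:
    """Return a list of BIDS-structure violations (empty = valid).

    Checks: required dataset-level files; datatype folder names; file
    naming grammar; filename labels consistent with the sub-/ses- folder
    they live in; entity ordering; every image has a JSON sidecar; every
    dwi image has .bval/.bvec.
    """
    root = Path(root)
    errors: list[str] = []
    if not (root / "dataset_description.json").is_file():
        errors.append("missing dataset_description.json")
    else:
        try:
            desc = json.loads((root / "dataset_description.json").read_text())
            for key in ("Name", "BIDSVersion"):
                if key not in desc:
                    errors.append(f"dataset_description.json lacks {key}")
        except json.JSONDecodeError:
            errors.append("dataset_description.json is not valid JSON")
    if not (root / "participants.tsv").is_file():
        errors.append("missing participants.tsv")

    for sub_dir in sorted(root.glob("sub-*")):
        if not sub_dir.is_dir():
            continue
        ses_dirs = sorted(sub_dir.glob("ses-*")) or [sub_dir]
        for ses_dir in ses_dirs:
            for dt_dir in sorted(p for p in ses_dir.iterdir() if p.is_dir()):
                if dt_dir.name.startswith("ses-"):
                    continue
                if dt_dir.name not in _DATATYPES:
                    errors.append(f"unknown datatype folder {dt_dir}")
                    continue
                for f in sorted(dt_dir.iterdir()):
                    m = _NAME_RE.match(f.name)
                    if m is None:
                        errors.append(f"non-BIDS filename {f}")
                        continue
                    if f"sub-{m.group('sub')}" != sub_dir.name:
                        errors.append(f"{f}: subject label mismatch with folder")
                    if ses_dir is not sub_dir:
                        if m.group("ses") is None or f"ses-{m.group('ses')}" != ses_dir.name:
                            errors.append(f"{f}: session label mismatch with folder")
                    elif m.group("ses") is not None:
                        errors.append(f"{f}: ses- entity in a single-session layout")
                    keys = [e.split("-")[0] for e in m.group("entities").strip("_").split("_") if e]
                    order = [_ENTITY_ORDER.index(k) for k in keys if k in _ENTITY_ORDER]
                    if order != sorted(order) or len(order) != len(keys):
                        errors.append(f"{f}: entity keys out of order or unknown: {keys}")
                    if m.group("ext").startswith(".nii"):
                        sidecar = f.name[: -len(m.group("ext"))] + ".json"
                        if not (dt_dir / sidecar).is_file():
                            errors.append(f"{f}: missing JSON sidecar")
                        if m.group("suffix") == "dwi":
                            for ext in (".bval", ".bvec"):
                                table = f.name[: -len(m.group("ext"))] + ext
                                if not (dt_dir / table).is_file():
                                    errors.append(f"{f}: missing {ext}")
    return errors


def world_coordinates(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map voxel indices to world coordinates by plain homogeneous
    matrix multiplication."""
    ijk = np.atleast_2d(ijk)
    homog = np.hstack([ijk, np.ones((len(ijk), 1))])
    return (np.asarray(affine) @ homog.T).T[:, :3]
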