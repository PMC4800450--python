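"""Reading and writing the package's plain-text data formats.

Subject tables are CSV (subject_id, gender, eyes_score, face_acc,
flower_acc, plus any appended measure columns). Pattern matrices are one
CSV per subject: rows are voxels; columns are ``<category>_run<j>`` betas
for every category and run, followed by ``contrast_z``. Volumes and ROI
masks round-trip through NIfTI via nibabel.
"""

from __future__ import annotations

import re
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .roi import PatternMatrix, ROIMask

__all__ = [
    "write_subject_table", "read_subject_table",
    "write_patterns", "read_patterns",
    "write_cohort_patterns", "read_cohort_patterns",
    "save_volume", "load_volume", "write_roi_mask",
]


def write_subject_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_subject_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing subject_id column")
    return df


def write_patterns(patterns: PatternMatrix, path) -> None:
    cols = {}
    for ic, cat in enumerate(patterns.categories):
        for r in range(patterns.n_runs):
            cols[f"{cat}_run{r + 1}"] = patterns.betas[ic, r]
    cols["contrast_z"] = patterns.contrast_z
    pd.DataFrame(cols).to_csv(path, index=False)


def read_patterns(path) -> PatternMatrix:
    df = pd.read_csv(path)
    if "contrast_z" not in df.columns:
        raise ValueError(f"{path}: missing contrast_z column")
    pat = re.compile(r"^(.*)_run(\d+)$")
    cats: list[str] = []
    runs: set[int] = set()
    for col in df.columns:
        m = pat.match(col)
        if m:
            if m.group(1) not in cats:
                cats.append(m.group(1))
            runs.add(int(m.group(2)))
    if not cats:
        raise ValueError(f"{path}: no <category>_run<j> beta columns found")
    n_runs = max(runs)
    if runs != set(range(1, n_runs + 1)):
        raise ValueError(f"{path}: run indices must be contiguous from 1")
    betas = np.stack(
        [
            np.stack([df[f"{c}_run{r + 1}"].to_numpy(float) for r in range(n_runs)])
            for c in cats
        ]
    )
    return PatternMatrix(categories=tuple(cats), betas=betas,
                         contrast_z=df["contrast_z"].to_numpy(float))


def write_cohort_patterns(subject_ids, patterns, directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for sid, pat in zip(subject_ids, patterns):
        p = directory / f"{sid}_patterns.csv"
        write_patterns(pat, p)
        paths.append(p)
    return paths


def read_cohort_patterns(subject_ids, directory) -> list[PatternMatrix]:
    directory = Path(directory)
    return [read_patterns(directory / f"{sid}_patterns.csv") for sid in subject_ids]


def save_volume(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_roi_mask(mask: ROIMask, path) -> None:
    """Binary NIfTI mask, or a voxel-index CSV when path ends in .csv."""
    path = Path(path)
    if path.suffix == ".csv":
        pd.DataFrame(mask.indices, columns=["i", "j", "k"]).to_csv(path, index=False)
    else:
        save_volume(mask.to_volume().astype(np.float32), path)
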