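"""Compound tables, duplicate removal, descriptor pre-filtering and the
Kennard-Stone train/test split.

The on-disk format is a UTF-8 comma-separated table with a header row and
required columns ``id``, ``smiles``, ``logkp`` (log10 of the permeability
coefficient in cm/h); optional columns ``name``, ``split`` and tabulated
descriptor values ``cos2_alogp``, ``x3v``, ``neoplastic80``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .descriptors import descriptor_vector
from .molgraph import parse_smiles

__all__ = [
    "QsarDataset",
    "SplitResult",
    "DatasetError",
    "MODEL_DESCRIPTORS",
    "read_table",
    "write_table",
    "deduplicate",
    "prefilter_descriptors",
    "kennard_stone_split",
    "assign_split",
]

REQUIRED_COLUMNS = ("id", "smiles", "logkp")
DESCRIPTOR_COLUMNS = ("cos2_alogp", "x3v", "neoplastic80")
MODEL_DESCRIPTORS = DESCRIPTOR_COLUMNS
SPLIT_LABELS = ("train", "test", "unassigned")


class DatasetError(ValueError):
    pass


@dataclass
class QsarDataset:
    """Compound records with endpoint, split labels and descriptors.

    ``descriptor_source`` records whether descriptor columns were read from
    the input table ("tabulated") or computed from SMILES ("computed").
    """

    frame: pd.DataFrame
    descriptor_source: str = "tabulated"
    removed_duplicates: list = field(default_factory=list)

    def __post_init__(self):
        f = self.frame
        for col in REQUIRED_COLUMNS:
            if col not in f.columns:
                raise DatasetError(f"missing required column {col!r}")
        if f["id"].duplicated().any():
            dupes = f.loc[f["id"].duplicated(), "id"].tolist()
            raise DatasetError(f"duplicate compound ids: {dupes}")
        if not np.isfinite(f["logkp"].to_numpy(dtype=float)).all():
            bad = f.index[~np.isfinite(f["logkp"].to_numpy(dtype=float))].tolist()
            raise DatasetError(f"non-finite logkp at rows {bad}")
        if "split" not in f.columns:
            f["split"] = "unassigned"
        unknown = set(f["split"]) - set(SPLIT_LABELS)
        if unknown:
            raise DatasetError(f"unknown split labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_descriptors(self) -> bool:
        return all(c in self.frame.columns for c in DESCRIPTOR_COLUMNS)

    def descriptor_matrix(self, columns: Sequence[str] = DESCRIPTOR_COLUMNS) -> np.ndarray:
        if not all(c in self.frame.columns for c in columns):
            raise DatasetError(f"descriptor columns {columns} not present; "
                               "call compute_descriptors() first")
        return self.frame.loc[:, list(columns)].to_numpy(dtype=float)

    def endpoint(self) -> np.ndarray:
        return self.frame["logkp"].to_numpy(dtype=float)

    def subset(self, split: str) -> "QsarDataset":
        sub = self.frame[self.frame["split"] == split].reset_index(drop=True)
        return QsarDataset(sub.copy(), descriptor_source=self.descriptor_source)

    def compute_descriptors(self) -> "QsarDataset":
        """Fill the descriptor columns from SMILES (overwrites tabulated values)."""
        rows = [descriptor_vector(s).as_dict() for s in self.frame["smiles"]]
        frame = self.frame.copy()
        for col in ("alogp", "cos2_alogp", "x3v", "neoplastic80", "mw", "mr", "n_atoms"):
            frame[col] = [r[col] for r in rows]
        return QsarDataset(frame, descriptor_source="computed",
                           removed_duplicates=list(self.removed_duplicates))


def read_table(path) -> QsarDataset:
    """Read and validate a compound table CSV."""
    frame = pd.read_csv(path, dtype={"id": str, "smiles": str})
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise DatasetError(f"{path}: missing required column {col!r}")
    try:
        frame["logkp"] = pd.to_numeric(frame["logkp"])
    except (ValueError, TypeError) as exc:
        bad = [
            i + 2  # header + 1-based
            for i, v in enumerate(frame["logkp"])
            if pd.isna(pd.to_numeric(v, errors="coerce"))
        ]
        raise DatasetError(f"{path}: non-numeric logkp in file rows {bad}") from exc
    source = "tabulated" if all(c in frame.columns for c in DESCRIPTOR_COLUMNS) else "computed"
    return QsarDataset(frame, descriptor_source=source)


def write_table(ds: QsarDataset, path) -> None:
    ds.frame.to_csv(path, index=False)


def deduplicate(ds: QsarDataset) -> QsarDataset:
    """Keep one record per canonical structure (first occurrence wins).

    Duplicate structures whose log Kp values disagree by more than 0.01 log
    units trigger a warning naming both records.  Removed ids are available
    on the returned dataset as ``removed_duplicates``.
    """
    seen: dict = {}
    keep = []
    removed = []
    for pos, row in ds.frame.iterrows():
        smi = row["smiles"]
        key = parse_smiles(smi).canonical_smiles if smi else f"__blank_{pos}"
        if key in seen:
            first = seen[key]
            removed.append((first["id"], row["id"]))
            if abs(first["logkp"] - row["logkp"]) > 0.01:
                warnings.warn(
                    f"duplicate structure {key!r}: kept {first['id']} "
                    f"(logkp={first['logkp']}), dropped {row['id']} "
                    f"(logkp={row['logkp']})",
                    stacklevel=2,
                )
        else:
            seen[key] = row
            keep.append(pos)
    frame = ds.frame.loc[keep].reset_index(drop=True)
    return QsarDataset(frame.copy(), descriptor_source=ds.descriptor_source,
                       removed_duplicates=removed)


def prefilter_descriptors(matrix: np.ndarray, r_max: float = 0.90) -> list:
    """Indices of descriptor columns surviving the constant/collinearity filter.

    Constant columns are dropped first; the remaining columns are scanned in
    order, dropping any whose absolute Pearson correlation with an
    already-kept column exceeds ``r_max``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    kept: list = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0.0:
            continue
        ok = True
        for k in kept:
            r = np.corrcoef(col, X[:, k])[0, 1]
            if abs(r) > r_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return kept


@dataclass(frozen=True)
class SplitResult:
    train_indices: tuple
    test_indices: tuple
    selection_order: tuple

    def __post_init__(self):
        if set(self.train_indices) & set(self.test_indices):
            raise ValueError("train and test overlap")


def standardize(X: np.ndarray) -> np.ndarray:
    """Zero-mean/unit-variance columns; constant columns map to zero."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd


def kennard_stone_split(X: np.ndarray, n_train: int) -> SplitResult:
    """Deterministic Kennard-Stone max-min selection of a training subset.

    The pair at maximal Euclidean distance seeds the selection; each further
    training point is the candidate whose minimum distance to the already
    selected set is largest.  All ties break toward the lowest row index, so
    the split is identical across runs and platforms.  ``X`` should already
    be standardized.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= n_train < n:
        raise ValueError(f"need 2 <= n_train < n rows, got n_train={n_train}, n={n}")
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1)
    # seed pair: max distance, ties to lexicographically smallest (i, j)
    iu = np.triu_indices(n, k=1)
    flat = d2[iu]
    best = np.argmax(flat)  # argmax returns the first maximum: lowest (i, j)
    i0, j0 = iu[0][best], iu[1][best]
    order = [int(i0), int(j0)]
    selected = np.zeros(n, dtype=bool)
    selected[[i0, j0]] = True
    mind = np.minimum(d2[i0], d2[j0])
    while selected.sum() < n_train:
        mind[selected] = -np.inf
        nxt = int(np.argmax(mind))  # first max -> lowest index on ties
        order.append(nxt)
        selected[nxt] = True
        mind = np.minimum(mind, d2[nxt])
    train = tuple(sorted(order))
    test = tuple(i for i in range(n) if not selected[i])
    return SplitResult(train_indices=train, test_indices=test,
                       selection_order=tuple(order))


def assign_split(
    ds: QsarDataset,
    n_train: int,
    feature_columns: Sequence[str] = DESCRIPTOR_COLUMNS,
) -> tuple:
    """Kennard-Stone split a dataset in standardized descriptor space.

    Returns ``(dataset with filled split column, SplitResult)``.
    """
    X = standardize(ds.descriptor_matrix(feature_columns))
    result = kennard_stone_split(X, n_train)
    frame = ds.frame.copy()
    frame["split"] = "test"
    frame.loc[list(result.train_indices), "split"] = "train"
    out = QsarDataset(frame, descriptor_source=ds.descriptor_source,
                      removed_duplicates=list(ds.removed_duplicates))
    return out, result
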