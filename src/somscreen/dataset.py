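"""Replicated protein-expression tables and their preprocessing.

The unit of analysis is a *measurement*: one replicate quantification of a
full protein panel for one mouse.  Nominally each mouse contributes 15
measurements (three replicates of a five-point dilution series on a reverse
phase protein array), but technical artifacts can drop individual spots, so
readers tolerate fewer and record the actual counts.

Preprocessing follows the standard recipe for this kind of panel:

1. impute missing cells with the class mean of the protein,
2. optionally flag and drop outlier mice (mice missing the majority of
   their protein columns),
3. min-max normalize each protein column to [0, 1]:

   ``normalized(e_ij) = (e_ij - E_j,min) / (E_j,max - E_j,min)``

   where ``E_j,min``/``E_j,max`` are taken over the rows of the matrix
   actually being clustered, so normalization is recomputed after any
   class subsetting.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classes import MouseClass

#: Metadata column names recognized in input tables (case-insensitive).
_META_COLS = {"mouseid", "mouse_id", "genotype", "treatment", "behavior", "class"}


@dataclass
class ImputationRecord:
    protein: str
    mouse_id: str
    n_cells: int


@dataclass
class ExpressionDataset:
    """A replicate-level expression matrix with per-row mouse and class labels.

    ``values`` is (n_measurements, n_proteins) with ``NaN`` marking missing
    cells.  Rows of one mouse always carry the same :class:`MouseClass`.
    """

    values: np.ndarray
    protein_names: list[str]
    mouse_ids: np.ndarray          # per-row mouse identifier (str)
    classes: list[MouseClass]      # per-row class
    normalized: bool = False
    replicate_index: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mouse_ids = np.asarray(self.mouse_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, p = self.values.shape
        if len(self.protein_names) != p:
            raise ValueError("protein_names length mismatch")
        if len(set(self.protein_names)) != p:
            raise ValueError("duplicate protein names")
        if len(self.mouse_ids) != n or len(self.classes) != n:
            raise ValueError("row metadata length mismatch")
        if self.replicate_index is None:
            self.replicate_index = self._default_replicates()
        # class constant within mouse
        seen: dict[str, MouseClass] = {}
        for m, c in zip(self.mouse_ids, self.classes):
            if seen.setdefault(m, c) != c:
                raise ValueError(f"mouse {m!r} has inconsistent class labels")

    def _default_replicates(self) -> np.ndarray:
        counter: dict[str, int] = {}
        out = np.empty(len(self.mouse_ids), dtype=int)
        for i, m in enumerate(self.mouse_ids):
            counter[m] = counter.get(m, 0) + 1
            out[i] = counter[m]
        return out

    # -- convenience views ------------------------------------------------
    @property
    def n_measurements(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    @property
    def class_codes(self) -> np.ndarray:
        return np.asarray([c.code for c in self.classes], dtype=object)

    @property
    def mice(self) -> list[str]:
        """Distinct mouse ids in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for m in self.mouse_ids:
            if m not in seen:
                seen.add(m)
                out.append(m)
        return out

    def class_of_mouse(self, mouse_id: str) -> MouseClass:
        idx = np.nonzero(self.mouse_ids == mouse_id)[0]
        if idx.size == 0:
            raise KeyError(f"unknown mouse id {mouse_id!r}")
        return self.classes[idx[0]]

    def replicate_counts(self) -> dict[str, int]:
        """Actual number of measurement rows per mouse."""
        out: dict[str, int] = {}
        for m in self.mouse_ids:
            out[m] = out.get(m, 0) + 1
        return out

    def present_classes(self) -> list[MouseClass]:
        return sorted(set(self.classes))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.protein_names)
        df.insert(0, "MouseID",
                  [f"{m}_{r}" for m, r in zip(self.mouse_ids, self.replicate_index)])
        df["Genotype"] = [c.genotype for c in self.classes]
        df["Treatment"] = [c.treatment for c in self.classes]
        df["Behavior"] = [c.behavior for c in self.classes]
        df["class"] = [c.code for c in self.classes]
        return df


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _split_measurement_id(mid: str) -> tuple[str, int | None]:
    """Split ``<mouse>_<replicate>`` ids; tolerate ids without a suffix."""
    mid = str(mid)
    if "_" in mid:
        stem, _, suffix = mid.rpartition("_")
        if suffix.isdigit():
            return stem, int(suffix)
    return mid, None


def _class_from_row(row: pd.Series, colmap: dict[str, str]) -> MouseClass:
    if "class" in colmap:
        code = str(row[colmap["class"]])
        try:
            return MouseClass.from_code(code)
        except ValueError:
            if {"genotype", "behavior", "treatment"} <= colmap.keys():
                pass  # fall through to the triple
            else:
                raise
    if {"genotype", "behavior", "treatment"} <= colmap.keys():
        return MouseClass.from_fields(
            str(row[colmap["genotype"]]),
            str(row[colmap["behavior"]]),
            str(row[colmap["treatment"]]),
        )
    raise ValueError("no class code column and no genotype/behavior/treatment triple")


def read_expression_table(path: str | Path, dialect: str = "csv") -> ExpressionDataset:
    """Read a replicate-level expression table.

    ``dialect`` is ``"csv"`` (UTF-8, header row) or ``"spreadsheet"``
    (first sheet of an ``.xlsx`` workbook).  Every column whose header is
    not one of the recognized metadata names (MouseID, Genotype, Treatment,
    Behavior, class) is treated as a protein.  Blank and non-numeric cells
    are read as missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
    elif dialect == "spreadsheet":
        df = pd.read_excel(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    colmap = {c.strip().lower(): c for c in df.columns
              if c.strip().lower() in _META_COLS}
    if "mouseid" not in colmap and "mouse_id" not in colmap:
        raise ValueError("no mouse-identifier column (MouseID)")
    id_col = colmap.get("mouseid", colmap.get("mouse_id"))
    protein_cols = [c for c in df.columns
                    if c.strip().lower() not in _META_COLS]
    if len(set(protein_cols)) != len(protein_cols):
        raise ValueError("duplicate protein names")

    values = df[protein_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    mouse_ids, reps = [], []
    for mid in df[id_col]:
        stem, rep = _split_measurement_id(mid)
        mouse_ids.append(stem)
        reps.append(rep)
    classes = [_class_from_row(row, colmap) for _, row in df.iterrows()]
    replicate_index = None
    if all(r is not None for r in reps):
        replicate_index = np.asarray(reps, dtype=int)
    return ExpressionDataset(values, list(protein_cols),
                             np.asarray(mouse_ids, dtype=object), classes,
                             normalized=False, replicate_index=replicate_index)


def write_expression_table(ds: ExpressionDataset, path: str | Path) -> None:
    """Write the dataset as CSV in the same dialect the reader accepts."""
    ds.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def impute_class_mean(ds: ExpressionDataset) -> tuple[ExpressionDataset, list[ImputationRecord]]:
    """Replace each missing cell with the mean of that protein over all
    non-missing rows of the same class.

    Imputation operates on raw (pre-normalization) values, pooling all
    replicate rows of the class.  Returns the imputed dataset and a log of
    (protein, mouse, number of cells imputed).
    """
    if ds.normalized:
        raise ValueError("impute before normalizing")
    values = ds.values.copy()
    codes = ds.class_codes
    log: list[ImputationRecord] = []
    for j, protein in enumerate(ds.protein_names):
        col = values[:, j]
        missing = np.isnan(col)
        if not missing.any():
            continue
        for code in np.unique(codes[missing]):
            in_class = codes == code
            donors = col[in_class & ~missing]
            if donors.size == 0:
                raise ValueError(
                    f"protein {protein!r} entirely missing in class {code}")
            fill = float(donors.mean())
            rows = np.nonzero(in_class & missing)[0]
            col[rows] = fill
            for mouse in np.unique(ds.mouse_ids[rows]):
                n = int(np.sum(ds.mouse_ids[rows] == mouse))
                log.append(ImputationRecord(protein, str(mouse), n))
    out = replace(ds, values=values)
    return out, log


def flag_outlier_mice(ds: ExpressionDataset,
                      missing_fraction_threshold: float = 0.5) -> list[str]:
    """Advisory list of mice missing more than a threshold fraction of
    protein columns (a column counts as missing for a mouse if any of its
    replicate cells is missing).  Exclusion is a separate, explicit call
    (:func:`drop_mice`), mirroring the qualitative judgement involved in
    declaring a mouse an outlier.
    """
    if ds.normalized:
        raise ValueError("flag outliers before normalizing")
    flagged = []
    for mouse in ds.mice:
        rows = ds.values[ds.mouse_ids == mouse]
        frac = float(np.mean(np.isnan(rows).any(axis=0)))
        if frac > missing_fraction_threshold:
            flagged.append(mouse)
    return flagged


def drop_mice(ds: ExpressionDataset, mouse_ids: Iterable[str]) -> ExpressionDataset:
    """Remove all rows of the named mice, preserving the order of the rest."""
    to_drop = list(mouse_ids)
    known = set(ds.mice)
    for m in to_drop:
        if m not in known:
            raise KeyError(f"unknown mouse id {m!r}")
    keep = ~np.isin(ds.mouse_ids, to_drop)
    return replace(
        ds,
        values=ds.values[keep],
        mouse_ids=ds.mouse_ids[keep],
        classes=[c for c, k in zip(ds.classes, keep) if k],
        replicate_index=ds.replicate_index[keep],
    )


def normalize_minmax(ds: ExpressionDataset) -> ExpressionDataset:
    """Min-max normalize every protein column to [0, 1] over the current rows.

    Requires a complete matrix (impute first).  A constant column maps to
    all zeros; the value is immaterial to clustering since the column
    carries no information.
    """
    if np.isnan(ds.values).any():
        raise ValueError("missing cells present; impute before normalizing")
    lo = ds.values.min(axis=0)
    hi = ds.values.max(axis=0)
    span = hi - lo
    out = np.zeros_like(ds.values)
    nz = span > 0
    out[:, nz] = (ds.values[:, nz] - lo[nz]) / span[nz]
    return replace(ds, values=out, normalized=True)


def subset(ds: ExpressionDataset,
           classes: Sequence[MouseClass | str] | None = None,
           proteins: Sequence[str] | None = None) -> ExpressionDataset:
    """Restrict rows to the given classes and columns to the given proteins
    (in the requested order).  The normalized flag is reset: analysis
    subsets are re-normalized over their own rows.
    """
    if classes is None:
        keep = np.ones(ds.n_measurements, dtype=bool)
    else:
        wanted = {MouseClass.from_code(c) if isinstance(c, str) else c
                  for c in classes}
        keep = np.asarray([c in wanted for c in ds.classes])
    if proteins is None:
        cols = list(range(ds.n_proteins))
        names = list(ds.protein_names)
    else:
        index = {p: j for j, p in enumerate(ds.protein_names)}
        try:
            cols = [index[p] for p in proteins]
        except KeyError as e:
            raise ValueError(f"unknown protein {e.args[0]!r}") from None
        names = list(proteins)
    return ExpressionDataset(
        ds.values[np.ix_(keep, cols)],
        names,
        ds.mouse_ids[keep],
        [c for c, k in zip(ds.classes, keep) if k],
        normalized=False,
        replicate_index=ds.replicate_index[keep],
    )
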