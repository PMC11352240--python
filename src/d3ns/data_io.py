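"""Input/output layer: mutation calls, clinical tables and labeled matrices.

Somatic mutation calls arrive either as a MAF-style TSV (one row per variant,
with ``Tumor_Sample_Barcode``, ``Hugo_Symbol`` and ``Variant_Classification``
columns) or as a bare two-column patient/gene pairing.  They are collapsed
into a binary patients x genes mutation matrix: an entry is 1 when the patient
carries at least one retained variant in that gene, regardless of how many.
Clinical tables carry overall-survival time (months), the event indicator and
arbitrary covariate columns; missing covariate values are kept as explicit NA
and handled listwise per downstream analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "D3NSError",
    "FormatError",
    "ValidationError",
    "EmptyInputError",
    "MutationRecord",
    "MutationMatrix",
    "ClinicalTable",
    "DEFAULT_EXCLUDED_VARIANT_CLASSES",
    "read_mutations",
    "build_mutation_matrix",
    "matrix_sparsity",
    "read_clinical",
    "write_matrix",
    "read_matrix",
]


class D3NSError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(D3NSError, ValueError):
    """A file does not have the structure its dialect requires."""


class ValidationError(D3NSError, ValueError):
    """Parsed content violates a domain invariant."""


class EmptyInputError(D3NSError, ValueError):
    """An input that must contain data is empty."""


#: Variant classes dropped by default when reading mutation calls.
#: Configurable: pass a different set to :func:`read_mutations`.
DEFAULT_EXCLUDED_VARIANT_CLASSES = frozenset({"Nonsense_Mutation"})

_MAF_COLUMNS = ("Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant call: which patient, which gene, which class."""

    patient_id: str
    gene: str
    variant_class: str

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        if not self.gene:
            raise ValidationError("gene must be non-empty")


@dataclass
class MutationMatrix:
    """Binary patients x genes matrix; 1 = gene mutated in that patient.

    Patients and genes are kept lexicographically sorted at construction so
    every downstream result is order-deterministic.
    """

    patients: list[str]
    genes: list[str]
    values: np.ndarray  # shape (n_patients, n_genes), dtype int8, entries {0,1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, g = self.values.shape
        if n != len(self.patients) or g != len(self.genes):
            raise ValidationError("matrix shape does not match label lengths")
        if len(set(self.patients)) != n:
            raise ValidationError("patient ids must be unique")
        if len(set(self.genes)) != g:
            raise ValidationError("gene symbols must be unique")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("mutation matrix entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patients, columns=self.genes)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MutationMatrix":
        return cls(
            patients=[str(p) for p in df.index],
            genes=[str(g) for g in df.columns],
            values=df.to_numpy(dtype=np.int8),
        )

    def restrict_genes(self, genes: Sequence[str]) -> "MutationMatrix":
        """Column subset, keeping the given gene order."""
        idx = {g: j for j, g in enumerate(self.genes)}
        cols = [idx[g] for g in genes]
        return MutationMatrix(
            patients=list(self.patients),
            genes=list(genes),
            values=self.values[:, cols],
        )


@dataclass
class ClinicalTable:
    """Per-patient survival endpoint plus covariates.

    ``data`` is indexed by patient id with columns ``os_time`` (months,
    non-negative), ``os_event`` (0/1) and any further covariates.  Missing
    covariate values stay as NA; every analysis excludes them listwise and
    reports its own non-missing N.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("os_time", "os_event"):
            if col not in df.columns:
                raise FormatError(f"clinical table missing required column {col!r}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate patient id {dup!r} in clinical table")
        if (df["os_time"] < 0).any():
            bad = df.index[df["os_time"] < 0][0]
            raise ValidationError(f"negative os_time for patient {bad!r}")
        if not df["os_event"].isin((0, 1)).all():
            bad = df.index[~df["os_event"].isin((0, 1))][0]
            raise ValidationError(f"os_event not in {{0,1}} for patient {bad!r}")

    @property
    def patients(self) -> list[str]:
        return [str(p) for p in self.data.index]

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("os_time", "os_event")]

    def subset(self, patients: Iterable[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(patients)].copy())


def read_mutations(
    path: str | Path,
    dialect: str = "maf",
    excluded_variant_classes: Iterable[str] = DEFAULT_EXCLUDED_VARIANT_CLASSES,
) -> list[MutationRecord]:
    """Read per-variant mutation calls, dropping excluded variant classes.

    Parameters
    ----------
    path
        TSV file.  ``dialect='maf'`` expects the columns
        ``Tumor_Sample_Barcode``, ``Hugo_Symbol``, ``Variant_Classification``;
        ``dialect='pairs'`` expects two columns (patient, gene) and assigns
        every record the variant class ``"Unknown"``.
    excluded_variant_classes
        Records whose class is in this set are dropped.  The default drops
        nonsense mutations only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    if df.empty and df.columns.empty:
        raise EmptyInputError(f"{path} is empty")

    excluded = set(excluded_variant_classes)
    if dialect == "maf":
        for col in _MAF_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"MAF file {path} missing required column {col!r}")
        sub = df[list(_MAF_COLUMNS)]
    elif dialect == "pairs":
        if df.shape[1] < 2:
            raise FormatError(f"pairs file {path} needs two columns (patient, gene)")
        sub = df.iloc[:, :2].copy()
        sub.columns = ["Tumor_Sample_Barcode", "Hugo_Symbol"]
        sub["Variant_Classification"] = "Unknown"
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'maf' or 'pairs'")

    records: list[MutationRecord] = []
    for row_no, (pid, gene, vclass) in enumerate(sub.itertuples(index=False), start=2):
        if pd.isna(pid) or pd.isna(gene) or str(pid) == "" or str(gene) == "":
            raise FormatError(f"{path} row {row_no}: missing patient id or gene symbol")
        vclass = "" if pd.isna(vclass) else str(vclass)
        if vclass in excluded:
            continue
        records.append(MutationRecord(str(pid), str(gene), vclass))
    return records


def build_mutation_matrix(records: Sequence[MutationRecord]) -> MutationMatrix:
    """Collapse variant records into the binary mutation matrix.

    Entry (p, g) is 1 iff at least one record exists for that pair —
    multiplicity is deliberately discarded.  Idempotent under record
    duplication.
    """
    if not records:
        raise EmptyInputError("no mutation records to build a matrix from")
    patients = sorted({r.patient_id for r in records})
    genes = sorted({r.gene for r in records})
    p_idx = {p: i for i, p in enumerate(patients)}
    g_idx = {g: j for j, g in enumerate(genes)}
    values = np.zeros((len(patients), len(genes)), dtype=np.int8)
    for r in records:
        values[p_idx[r.patient_id], g_idx[r.gene]] = 1
    return MutationMatrix(patients=patients, genes=genes, values=values)


def matrix_sparsity(M: MutationMatrix | np.ndarray) -> float:
    """Fraction of zero entries, in [0, 1]."""
    values = M.values if isinstance(M, MutationMatrix) else np.asarray(M)
    if values.size == 0:
        raise EmptyInputError("cannot compute sparsity of an empty matrix")
    return float(np.count_nonzero(values == 0) / values.size)


def read_clinical(
    path: str | Path,
    id_col: str = "patient_id",
    time_col: str = "os_time",
    event_col: str = "os_event",
) -> ClinicalTable:
    """Read a clinical TSV with header; covariates are every extra column."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    for col in (id_col, time_col, event_col):
        if col not in df.columns:
            raise FormatError(f"clinical file {path} missing required column {col!r}")
    df = df.rename(columns={time_col: "os_time", event_col: "os_event"})
    df[id_col] = df[id_col].astype(str)
    df = df.set_index(id_col)
    df.index.name = "patient_id"
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=True, index_label="patient_id")


# ---------------------------------------------------------------------------
# Labeled-matrix round trips.  TSV for inspection; .npz as a compact
# binary container for large smoothed matrices.  Format chosen by suffix.
# ---------------------------------------------------------------------------


def _as_frame(matrix, rows: Sequence[str] | None, cols: Sequence[str] | None) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    if hasattr(matrix, "to_frame"):
        return matrix.to_frame()
    return pd.DataFrame(np.asarray(matrix), index=list(rows), columns=list(cols))


def write_matrix(matrix, path: str | Path, rows=None, cols=None) -> None:
    """Write a labeled matrix; ``.npz`` binary container or TSV otherwise.

    Floats are written at full precision so TSV round-trips are exact.
    """
    path = Path(path)
    df = _as_frame(matrix, rows, cols)
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            values=df.to_numpy(),
            rows=np.asarray(df.index, dtype=str),
            cols=np.asarray(df.columns, dtype=str),
        )
    else:
        df.to_csv(path, sep="\t", index=True, index_label="row", float_format="%.17g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return pd.DataFrame(
                z["values"], index=z["rows"].astype(str), columns=z["cols"].astype(str)
            )
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
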