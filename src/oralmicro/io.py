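"""Core data containers and TSV input/output.

The central container is :class:`AbundanceTable`, a taxa x samples matrix of
sequencing counts or relative abundances, the genus-level table every
downstream analysis consumes.  Sample metadata links each specimen to its
patient, specimen type (saliva, tumor-surface swab, outer tumor tissue,
inner tumor tissue, adjacent normal tissue, or lymph node) and clinical
variables.  Tables are fixed as taxa x samples; a transposed file is never
auto-detected, because silent transposition is a classic microbiome-pipeline
bug.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPECIMEN_TYPES = (
    "saliva",
    "swab",
    "outer_tumor",
    "inner_tumor",
    "adjacent_normal",
    "lymph_node",
)

T_STAGES = ("T1", "T2", "T3", "T4", "unknown")
N_STAGES = ("N0", "N1", "N2", "N3", "unknown")
TERNARY = ("negative", "positive", "unknown")
YES_NO = ("yes", "no", "unknown")

#: metadata columns beyond the three required ones; blanks map to "unknown"
CLINICAL_COLUMNS = {
    "t_stage": T_STAGES,
    "n_stage": N_STAGES,
    "ene": TERNARY,
    "lymphatic_metastasis": YES_NO,
    "culture_result": TERNARY,
}

REQUIRED_METADATA_COLUMNS = ("sample_id", "patient_id", "specimen_type")


class FormatError(ValueError):
    """Malformed input file (duplicate ids, missing columns, bad cells)."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


@dataclass
class AbundanceTable:
    """Taxa x samples abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by taxon id, columns by sample id, non-negative values.
    unit_kind : {"counts", "relative"}
        ``counts`` holds raw integer counts; ``relative`` holds per-sample
        fractions, each column summing to 1.
    """

    data: pd.DataFrame
    unit_kind: str = "counts"

    def __post_init__(self) -> None:
        if self.unit_kind not in ("counts", "relative"):
            raise ValidationError(f"unknown unit_kind {self.unit_kind!r}")
        self.data = self.data.rename_axis(index=None, columns=None)
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric values in abundance table")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise FormatError(
                f"non-numeric cell at taxon {idx[r]!r}, sample {cols[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at taxon {idx[r]!r}, sample {cols[c]!r}"
            )
        if self.unit_kind == "relative":
            sums = values.sum(axis=0)
            bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
            if bad.size:
                raise ValidationError(
                    "relative-abundance columns must sum to 1; offending "
                    f"samples: {list(cols[bad])}"
                )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def to_relative(self) -> "AbundanceTable":
        """Total-sum scale each sample column to relative abundance.

        Idempotent on relative tables.  No rarefaction is performed anywhere
        in this package; counts are always total-sum scaled.
        """
        sums = self.data.sum(axis=0)
        zero = sums.index[sums == 0].tolist()
        if zero:
            raise ValidationError(f"all-zero sample columns: {zero}")
        return AbundanceTable(self.data / sums, unit_kind="relative")

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples absent from table: {missing}")
        return AbundanceTable(self.data.loc[:, list(sample_ids)], self.unit_kind)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")


def read_abundance_table(path, unit_kind: str = "counts") -> AbundanceTable:
    """Read a taxa x samples TSV (first column ``taxon_id``, header = samples).

    Counts are parsed as integers, relative abundances as reals; row and
    column order are preserved as in the file.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dups = [h for i, h in enumerate(header) if h in header[:i]]
    if dups:
        raise FormatError(f"duplicate sample ids in header: {sorted(set(dups))}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate taxon ids: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        mask = numeric.isna()
        r = mask.any(axis=1).idxmax()
        c = mask.loc[r].idxmax()
        raise FormatError(
            f"non-numeric cell {df.loc[r, c]!r} at taxon {r!r}, sample {c!r}"
        )
    if unit_kind == "counts":
        vals = numeric.to_numpy()
        if not np.allclose(vals, np.round(vals)):
            raise FormatError("counts table contains non-integer values")
        numeric = numeric.round().astype(np.int64)
    return AbundanceTable(numeric, unit_kind=unit_kind)


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata TSV into a validated DataFrame.

    Required columns: sample_id, patient_id, specimen_type.  Clinical columns
    (t_stage, n_stage, ene, lymphatic_metastasis, culture_result) are
    optional; blank cells map to ``"unknown"``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    df = df.copy()
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids in metadata: {dups}")
    bad = sorted(set(df["specimen_type"]) - set(SPECIMEN_TYPES))
    if bad:
        raise ValidationError(
            f"unrecognized specimen_type values {bad}; allowed: "
            f"{list(SPECIMEN_TYPES)}"
        )
    for col, allowed in CLINICAL_COLUMNS.items():
        if col not in df.columns:
            df[col] = "unknown"
        else:
            df[col] = df[col].fillna("unknown").replace("", "unknown")
            bad = sorted(set(df[col]) - set(allowed))
            if bad:
                raise ValidationError(
                    f"unrecognized {col} values {bad}; allowed: {list(allowed)}"
                )
    return df.reset_index(drop=True)


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def align_samples(table: AbundanceTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Align metadata rows to the table's samples.

    A metadata row with no matching table column is a warning (extra
    specimens in the manifest are harmless); a table sample missing from
    the metadata is an error, because its group membership is undefined.
    """
    meta_ids = set(metadata["sample_id"])
    table_ids = table.sample_ids
    orphans = [s for s in table_ids if s not in meta_ids]
    if orphans:
        raise ValidationError(f"samples missing from metadata: {orphans}")
    extra = sorted(meta_ids - set(table_ids))
    if extra:
        warnings.warn(f"metadata rows without table samples: {extra}")
    aligned = metadata.set_index("sample_id").loc[table_ids].reset_index()
    return aligned


@dataclass
class ContingencyTable:
    """Labeled r x c table of non-negative integer counts."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), int))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValidationError("negative cell count")
        if self.counts.sum() <= 0:
            raise ValidationError("empty contingency table")

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def expected(self) -> np.ndarray:
        """Expected cell counts under independence of rows and columns."""
        r = self.counts.sum(axis=1, keepdims=True)
        c = self.counts.sum(axis=0, keepdims=True)
        return r * c / self.grand_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)

    def to_tsv(self, path) -> None:
        out = self.to_frame()
        out.index.name = "row"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ContingencyTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy())
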