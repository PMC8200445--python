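"""On-disk artifacts: expression matrices, sample sheets, GMT gene sets.

Expression interchange is plain TSV: a genes x samples matrix whose first
column holds gene IDs, paired with a sample sheet (sample_id, subject_id,
timepoint, dataset_id, condition).  The paired pre/post design is validated on
read: every subject must contribute exactly one "pre" and one "post" sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
]

CONDITIONS = ("disuse", "young_RET", "older_RET", "other")
TIMEPOINTS = ("pre", "post")

SAMPLESHEET_COLUMNS = ["sample_id", "subject_id", "timepoint",
                       "dataset_id", "condition"]


@dataclass
class ExpressionDataset:
    """One study's log2 expression matrix plus its paired pre/post design.

    ``X`` is genes x samples with columns ordered exactly as ``samples``.
    """

    dataset_id: str
    condition: str
    genes: list[str]
    X: np.ndarray
    samples: pd.DataFrame  # columns: sample_id, subject_id, timepoint

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.genes = list(self.genes)
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition {self.condition!r} not one of {CONDITIONS}")
        if self.X.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples")
        if len(set(self.genes)) != len(self.genes):
            dupes = pd.Index(self.genes)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        if not np.isfinite(self.X).all():
            raise ValueError("expression matrix contains non-finite values")
        self._validate_pairing()

    def _validate_pairing(self) -> None:
        sheet = self.samples
        missing = set(("sample_id", "subject_id", "timepoint")) - set(sheet)
        if missing:
            raise ValueError(f"sample sheet missing columns {sorted(missing)}")
        bad_tp = set(sheet["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"invalid timepoints {sorted(bad_tp)}")
        for subject, grp in sheet.groupby("subject_id", sort=False):
            tps = sorted(grp["timepoint"])
            if tps != ["post", "pre"]:
                raise ValueError(f"unpaired subject {subject}")

    @property
    def n_pairs(self) -> int:
        return self.samples["subject_id"].nunique()

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.samples["subject_id"]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=pd.Index(self.genes, name="gene_id"),
                            columns=list(self.samples["sample_id"]))

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        genes = list(genes)
        idx = pd.Index(self.genes).get_indexer(genes)
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise KeyError(f"genes absent from dataset: {missing[:5]}")
        return ExpressionDataset(self.dataset_id, self.condition, genes,
                                 self.X[idx], self.samples.copy())


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): term ID -> (description, member genes)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def genes(self, term: str) -> list[str]:
        return self.sets[term][1]


def read_expression(matrix_path: str | Path,
                    samplesheet_path: str | Path) -> ExpressionDataset:
    """Read a TSV expression matrix and its sample sheet into a dataset.

    The matrix must be tab-delimited with gene IDs in the first column and a
    header of sample IDs; sample order in the returned matrix follows the
    sheet.  Any mismatch between sheet and matrix samples, duplicate gene
    IDs, or an unpaired subject is an error.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0,
                      float_precision="round_trip")
    sheet = pd.read_csv(samplesheet_path, sep="\t", dtype=str)
    missing_cols = set(SAMPLESHEET_COLUMNS) - set(sheet.columns)
    if missing_cols:
        raise ValueError(
            f"sample sheet missing columns {sorted(missing_cols)}")
    if mat.index.duplicated().any():
        dupes = sorted(mat.index[mat.index.duplicated()].unique())
        raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
    sheet_samples = list(sheet["sample_id"])
    mat_samples = list(mat.columns)
    only_sheet = sorted(set(sheet_samples) - set(mat_samples))
    only_mat = sorted(set(mat_samples) - set(sheet_samples))
    if only_sheet or only_mat:
        raise ValueError(
            f"sample mismatch between sheet and matrix: "
            f"sheet-only={only_sheet[:5]} matrix-only={only_mat[:5]}")
    dataset_ids = sheet["dataset_id"].unique()
    conditions = sheet["condition"].unique()
    if len(dataset_ids) != 1 or len(conditions) != 1:
        raise ValueError("sample sheet must describe exactly one dataset")
    mat = mat[sheet_samples]
    return ExpressionDataset(
        dataset_id=str(dataset_ids[0]),
        condition=str(conditions[0]),
        genes=[str(g) for g in mat.index],
        X=mat.to_numpy(dtype=float),
        samples=sheet[["sample_id", "subject_id", "timepoint"]].reset_index(
            drop=True),
    )


def write_expression(ds: ExpressionDataset, matrix_path: str | Path,
                     samplesheet_path: str | Path) -> None:
    """Write the matrix and sheet as TSV, value-preserving on round-trip."""
    frame = ds.to_frame()
    frame.to_csv(matrix_path, sep="\t", float_format="%.17g")
    sheet = ds.samples.copy()
    sheet["dataset_id"] = ds.dataset_id
    sheet["condition"] = ds.condition
    sheet[SAMPLESHEET_COLUMNS].to_csv(samplesheet_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a standard GMT file: term, description, then member genes.

    Duplicate genes within a line are dropped (first occurrence kept); a
    line with fewer than three fields is an error naming the line number.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}")
            term, desc = fields[0], fields[1]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ValueError(f"GMT line {lineno}: no genes for {term!r}")
            sets[term] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in collection:
            fh.write("\t".join([term, desc, *genes]) + "\n")


def write_table(frame: pd.DataFrame, path: str | Path,
                index: bool = True) -> None:
    """TSV writer used for every tabular stage output (12+ sig digits)."""
    frame.to_csv(path, sep="\t", float_format="%.17g", index=index)
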