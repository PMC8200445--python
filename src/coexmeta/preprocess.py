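"""Data-driven preprocessing: quantile normalization, probe collapse,
cross-dataset gene intersection, zero-variance filtering.

Platform-specific background correction happens upstream; this module takes
(raw or normalized) log2 matrices and makes them comparable: equalize the
per-array empirical distributions, average probes mapping to the same gene,
and restrict every dataset of a group to the shared gene universe.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionDataset

__all__ = [
    "ProbeMap",
    "quantile_normalize",
    "collapse_probes",
    "intersect_genes",
    "drop_zero_variance",
    "log2_transform",
    "preprocess_group",
]

log = logging.getLogger(__name__)


@dataclass
class ProbeMap:
    """Probe -> gene mapping; probes without a gene are kept on record.

    The TSV form has columns ``probe_id`` and ``gene_id``; an empty
    ``gene_id`` marks an unmapped probe, which is dropped (never silently
    kept) and listed in :attr:`unmapped`.
    """

    mapping: dict[str, str]
    unmapped: list[str] = field(default_factory=list)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeMap":
        frame = pd.read_csv(path, sep="\t", dtype=str,
                            keep_default_na=False)
        if not {"probe_id", "gene_id"} <= set(frame.columns):
            raise ValueError("probe map needs columns probe_id, gene_id")
        mapped = frame[frame["gene_id"] != ""]
        unmapped = list(frame.loc[frame["gene_id"] == "", "probe_id"])
        return cls(dict(zip(mapped["probe_id"], mapped["gene_id"])), unmapped)


def quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Force every column onto the across-column mean empirical distribution.

    After normalization each column's sorted values equal the row-wise mean
    of all columns' sorted values; ties within a column receive the mean of
    the reference values spanning their tied ranks, and the original row
    order of each column is preserved.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains missing/non-finite values")
    if X.shape[1] < 2:
        warnings.warn("quantile normalization needs >=2 columns; "
                      "returning input unchanged")
        return X.copy()
    reference = np.sort(X, axis=0).mean(axis=1)
    # cumulative means give O(1) lookup of the reference mean over any
    # contiguous rank span [lo, hi]
    csum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        col = X[:, j]
        rmin = rankdata(col, method="min") - 1  # first index of tie span
        rmax = rankdata(col, method="max")      # one past last index
        out[:, j] = (csum[rmax] - csum[rmin]) / (rmax - rmin)
    assert out.shape == (n, X.shape[1])
    return out


def collapse_probes(X: pd.DataFrame, probe_map: ProbeMap,
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Average probe rows mapping to the same gene; drop unmapped probes.

    Returns the gene-level matrix (rows sorted by gene ID) and the list of
    probes that were dropped for lacking a gene mapping.
    """
    if not isinstance(X, pd.DataFrame):
        raise TypeError("collapse_probes expects a probe-indexed DataFrame")
    genes = X.index.map(lambda p: probe_map.mapping.get(str(p)))
    dropped = [str(p) for p, g in zip(X.index, genes) if g is None]
    keep = genes.notna()
    if not keep.any():
        raise ValueError("no probes remain after dropping unmapped probes")
    if dropped:
        log.info("dropped %d unmapped probes", len(dropped))
    collapsed = X[keep].groupby(genes[keep]).mean().sort_index()
    collapsed.index.name = "gene_id"
    return collapsed, dropped


def intersect_genes(datasets: list[ExpressionDataset],
                    ) -> list[ExpressionDataset]:
    """Restrict every dataset to the common gene set, identically ordered.

    The shared ordering is the first dataset's gene order filtered to the
    intersection, so downstream matrices align row-for-row.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to intersect")
    common = set(datasets[0].genes)
    for ds in datasets[1:]:
        common &= set(ds.genes)
    if not common:
        raise ValueError("empty gene intersection")
    ordered = [g for g in datasets[0].genes if g in common]
    return [ds.subset_genes(ordered) for ds in datasets]


def drop_zero_variance(datasets: list[ExpressionDataset],
                       ) -> tuple[list[ExpressionDataset], list[str]]:
    """Remove genes with zero variance in any dataset (correlation needs
    variance); the dropped genes are returned for the run report."""
    bad: set[str] = set()
    for ds in datasets:
        var = ds.X.var(axis=1)
        bad.update(g for g, v in zip(ds.genes, var) if v <= 0)
    if not bad:
        return datasets, []
    log.info("dropping %d zero-variance genes", len(bad))
    keep = [g for g in datasets[0].genes if g not in bad]
    if not keep:
        raise ValueError("all genes have zero variance somewhere")
    return [ds.subset_genes(keep) for ds in datasets], sorted(bad)


def log2_transform(X: np.ndarray) -> np.ndarray:
    """log2(x + 1) for raw-intensity-scale inputs (e.g. MAS5 signals)."""
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("raw-scale intensities must be non-negative")
    return np.log2(X + 1.0)


def preprocess_group(datasets: list[ExpressionDataset],
                     quantile: bool = True,
                     ) -> tuple[list[ExpressionDataset], dict]:
    """Quantile-normalize each dataset, intersect genes, drop degenerate
    genes.  Returns the processed group plus a small provenance record."""
    processed = []
    for ds in datasets:
        X = quantile_normalize(ds.X) if quantile else ds.X.copy()
        processed.append(ExpressionDataset(ds.dataset_id, ds.condition,
                                           ds.genes, X, ds.samples.copy()))
    if len(processed) >= 2:
        processed = intersect_genes(processed)
    processed, dropped = drop_zero_variance(processed)
    report = {
        "n_genes": len(processed[0].genes),
        "zero_variance_dropped": dropped,
        "quantile_normalized": quantile,
    }
    return processed, report
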