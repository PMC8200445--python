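"""Consensus hub genes: module membership, percentile selection, overlap.

A gene's module membership (kME) in one dataset is the Pearson correlation
of its expression profile with its own module's dataset-specific eigengene;
the associated p-value is one-sided (upper tail), matching the signed
network construction.  The consensus membership is the Stouffer Z of those
one-sided p-values across the group's datasets.  Within each module, genes
whose consensus membership lies strictly above the 85th percentile
(linearly interpolated) are consensus hub genes.  Hub sets of matched
modules from two conditions are compared with a hypergeometric overlap
test, and hubs are overlaid with the RRHO gene classes that match their
module's differential-regulation scenario.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .gene_meta import stouffer_combine
from .io import ExpressionDataset
from .network import EigengeneSet, ModulePartition

__all__ = [
    "module_membership",
    "consensus_membership",
    "select_hubs",
    "hub_table",
    "hub_overlap_test",
    "module_scenario",
    "overlay_hubs_rrho",
]

log = logging.getLogger(__name__)


def module_membership(ds: ExpressionDataset, eigengenes: EigengeneSet,
                      partition: ModulePartition) -> pd.DataFrame:
    """kME of every assigned gene vs. its own module's eigengene.

    Returns rows (gene_id, module, kME, p_right) for one dataset; the
    correlation-test p is upper-tailed (t transform of r with n-2 df).
    Constant genes have no defined kME and are excluded with a log entry.
    """
    scores = eigengenes.scores[ds.dataset_id]
    n = ds.X.shape[1]
    gene_pos = pd.Index(ds.genes)
    rows = []
    for module in partition.modules:
        if module not in scores.columns:
            continue
        eig = scores[module].to_numpy()
        genes = partition.genes_of(module)
        idx = gene_pos.get_indexer(genes)
        sub = ds.X[idx]
        sd = sub.std(axis=1)
        constant = sd == 0
        if constant.any():
            log.warning("%d constant genes excluded from kME in %s",
                        int(constant.sum()), ds.dataset_id)
        centered = sub - sub.mean(axis=1, keepdims=True)
        eig_c = eig - eig.mean()
        denom = np.sqrt((centered ** 2).sum(axis=1) * (eig_c ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            kme = (centered @ eig_c) / denom
        kme = np.clip(kme, -1.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = kme * np.sqrt((n - 2) / (1.0 - kme ** 2))
        tstat = np.where(kme >= 1.0, np.inf,
                         np.where(kme <= -1.0, -np.inf, tstat))
        p_right = stats.t.sf(tstat, n - 2)
        for g, r, p, const in zip(genes, kme, p_right, constant):
            if const:
                continue
            rows.append({"gene_id": g, "module": module,
                         "kME": float(r), "p_right": float(p)})
    return pd.DataFrame(rows)


def consensus_membership(kme_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Stouffer Z of one-sided kME p-values across datasets.

    A gene missing from any dataset's kME table is excluded from its
    module's ranking (logged).  Returns rows (gene_id, module, Z_MM).
    """
    if not kme_tables:
        raise ValueError("no kME tables supplied")
    merged = None
    for i, tab in enumerate(kme_tables):
        cur = tab[["gene_id", "module", "p_right"]].rename(
            columns={"p_right": f"p_{i}"})
        merged = cur if merged is None else merged.merge(
            cur, on=["gene_id", "module"], how="outer")
    p_cols = [c for c in merged.columns if c.startswith("p_")]
    complete = merged[p_cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.warning("%d (gene, module) entries lack kME in some dataset "
                    "and are excluded", n_dropped)
    merged = merged[complete]
    z, _ = stouffer_combine(merged[p_cols].to_numpy())
    out = merged[["gene_id", "module"]].copy()
    out["Z_MM"] = np.atleast_1d(z)
    return out.reset_index(drop=True)


def select_hubs(membership: pd.DataFrame,
                config: PipelineConfig) -> pd.DataFrame:
    """Flag genes strictly above their module's membership percentile.

    The threshold is the linearly interpolated ``hub_percentile`` quantile
    of Z_MM within the module; ties at the threshold are not hubs.
    """
    out = membership.copy()
    out["hub"] = False
    out["threshold"] = np.nan
    for module, grp in membership.groupby("module"):
        if len(grp) < 2:
            continue
        thr = float(np.percentile(grp["Z_MM"].to_numpy(),
                                  100.0 * config.hub_percentile))
        mask = out["module"] == module
        out.loc[mask, "threshold"] = thr
        out.loc[mask, "hub"] = out.loc[mask, "Z_MM"] > thr
    return out


def hub_table(datasets: list[ExpressionDataset], eigengenes: EigengeneSet,
              partition: ModulePartition,
              config: PipelineConfig) -> pd.DataFrame:
    """kME per dataset + consensus Z_MM + hub flags for one group."""
    kme_tables = [module_membership(ds, eigengenes, partition)
                  for ds in datasets]
    membership = consensus_membership(kme_tables)
    hubs = select_hubs(membership, config)
    for ds, tab in zip(datasets, kme_tables):
        hubs = hubs.merge(
            tab[["gene_id", "module", "kME"]].rename(
                columns={"kME": f"kME_{ds.dataset_id}"}),
            on=["gene_id", "module"], how="left")
    return hubs


def hub_overlap_test(hubs_a: set[str], hubs_b: set[str],
                     universe: set[str]) -> tuple[int, float]:
    """Hypergeometric upper-tail p of the shared-hub count.

    Draw |hubs_b| genes from the universe containing |hubs_a| successes;
    the p-value is the probability of an intersection at least as large as
    observed.
    """
    if not universe:
        raise ValueError("empty universe")
    if not (hubs_a <= universe and hubs_b <= universe):
        raise ValueError("hub sets must be subsets of the universe")
    k = len(hubs_a & hubs_b)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(hubs_a),
                                 len(hubs_b)))
    return k, p


def module_scenario(direction_a: str, direction_b: str) -> str | None:
    """Expected RRHO gene class for a module's cross-condition behaviour.

    ``direction_a``/``direction_b`` come from the two groups'
    differential-regulation calls for the (matched) module: "up", "down" or
    "none".  Returns the consistent gene class, or None when the module is
    regulated in neither condition.
    """
    key = (direction_a, direction_b)
    mapping = {
        ("up", "up"): "common-concordant-up",
        ("down", "down"): "common-concordant-down",
        ("up", "down"): "common-discordant-A-up-B-down",
        ("down", "up"): "common-discordant-A-down-B-up",
        ("up", "none"): "unique-A-up",
        ("down", "none"): "unique-A-down",
        ("none", "up"): "unique-B-up",
        ("none", "down"): "unique-B-down",
    }
    return mapping.get(key)


def overlay_hubs_rrho(hub_frame: pd.DataFrame, gene_classes: pd.Series,
                      scenarios: dict[str, str | None]) -> pd.DataFrame:
    """Annotate hubs whose RRHO class matches their module's scenario.

    ``scenarios`` maps module label -> expected gene class (from
    :func:`module_scenario`); a hub is a candidate when its own RRHO/DE
    class equals that expectation.  Genes with class "none" are never
    annotated.
    """
    out = hub_frame.copy()
    out["gene_class"] = gene_classes.reindex(out["gene_id"]).to_numpy()
    out["gene_class"] = out["gene_class"].fillna("none")
    expected = out["module"].map(lambda m: scenarios.get(m))
    out["candidate"] = (out["hub"] & expected.notna() &
                        (out["gene_class"] == expected))
    return out
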