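"""Cross-condition comparison: module label matching and RRHO gene classes.

Two consensus networks built independently carry arbitrary module labels; to
compare them, source-network modules are renamed after the reference-network
module they significantly overlap (one-sided Fisher's exact test per module
pair, BH across all pairs, greedy assignment in ascending p, no label used
twice) — the matchLabels idea.

At gene level, the rank-rank hypergeometric overlap (RRHO) procedure ranks
each condition's genes by sign(meta logFC) * (-log10 corrected meta p) and
scans a grid of rank-threshold pairs, scoring each by the hypergeometric
upper-tail p of the overlap between the two top-lists (and the analogous
bottom/top combinations for the discordant quadrants).  The grid point with
the strongest signal per quadrant defines the "optimal overlap" gene set.
Commonly regulated genes are then those DE in both conditions and inside an
optimal set of the matching quadrant; uniquely regulated genes are DE in
exactly one condition and inside no optimal set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .gene_meta import bh_adjust
from .network import ModulePartition

__all__ = [
    "ModuleMatch",
    "RRHOResult",
    "match_labels",
    "rrho",
    "classify_genes",
    "GENE_CLASSES",
]

log = logging.getLogger(__name__)

QUADRANTS = ("up-up", "down-down", "up-down", "down-up")

GENE_CLASSES = (
    "common-concordant-up",
    "common-concordant-down",
    "common-discordant-A-up-B-down",
    "common-discordant-A-down-B-up",
    "unique-A-up",
    "unique-A-down",
    "unique-B-up",
    "unique-B-down",
    "none",
)

#: q-values of exactly zero are clamped here before taking logs
Q_FLOOR = 1e-300


@dataclass
class ModuleMatch:
    """Fisher-overlap relabelling of a source network onto a reference."""

    overlap: pd.DataFrame          # reference modules x source modules
    p_values: pd.DataFrame         # one-sided Fisher p per cell
    q_values: pd.DataFrame         # BH across all cells
    relabel_map: dict[str, str]    # source label -> new label
    unmatched_source: list[str]


@dataclass
class RRHOResult:
    """Signed rank scores, significance grids, and optimal overlap sets."""

    rank_scores: pd.DataFrame      # columns: score_A, score_B
    step: int
    grids: dict[str, pd.DataFrame]  # quadrant -> -log10 p grid (i x j)
    optima: dict[str, tuple[int, int, float]]  # quadrant -> (i, j, peak)
    optimal_sets: dict[str, set[str]] = field(default_factory=dict)


def match_labels(reference: ModulePartition, source: ModulePartition,
                 alpha: float = 0.05) -> ModuleMatch:
    """Rename source modules after significantly overlapping reference ones.

    Every (reference, source) module pair gets a one-sided Fisher p on its
    2x2 overlap table; after BH across all cells, pairs are assigned
    greedily in ascending p among cells with corrected p < ``alpha``, each
    label used at most once.  Unmatched source modules receive fresh labels
    absent from the reference.
    """
    genes_ref = set(reference.labels.index)
    genes_src = set(source.labels.index)
    if genes_ref != genes_src:
        raise ValueError("module partitions cover different gene universes")
    universe = len(genes_ref)
    ref_modules = reference.modules
    src_modules = source.modules
    overlap = pd.DataFrame(0, index=ref_modules, columns=src_modules,
                           dtype=int)
    pvals = pd.DataFrame(1.0, index=ref_modules, columns=src_modules)
    for rm in ref_modules:
        rset = set(reference.genes_of(rm))
        for sm in src_modules:
            sset = set(source.genes_of(sm))
            k = len(rset & sset)
            overlap.loc[rm, sm] = k
            # hypergeometric upper tail == one-sided Fisher on the 2x2
            pvals.loc[rm, sm] = stats.hypergeom.sf(
                k - 1, universe, len(rset), len(sset))
    flat_q = bh_adjust(pvals.to_numpy().ravel())
    qvals = pd.DataFrame(flat_q.reshape(pvals.shape),
                         index=ref_modules, columns=src_modules)
    cells = [(pvals.loc[rm, sm], rm, sm)
             for rm in ref_modules for sm in src_modules
             if qvals.loc[rm, sm] < alpha]
    cells.sort(key=lambda c: (c[0], c[1], c[2]))
    used_ref: set[str] = set()
    relabel: dict[str, str] = {}
    for _, rm, sm in cells:
        if rm in used_ref or sm in relabel:
            continue
        relabel[sm] = rm
        used_ref.add(rm)
    unmatched = [sm for sm in src_modules if sm not in relabel]
    taken = set(ref_modules) | set(relabel.values())
    fresh = 1
    for sm in unmatched:
        while f"M{fresh}" in taken:
            fresh += 1
        relabel[sm] = f"M{fresh}"
        taken.add(f"M{fresh}")
    return ModuleMatch(overlap=overlap, p_values=pvals, q_values=qvals,
                       relabel_map=relabel, unmatched_source=unmatched)


def rank_scores(table: pd.DataFrame) -> pd.Series:
    """Signed rank score: sign(meta logFC) * (-log10 corrected meta p)."""
    q = table["q"].to_numpy().clip(Q_FLOOR, None)
    return pd.Series(np.sign(table["mean_logFC"].to_numpy()) *
                     (-np.log10(q)), index=table.index, name="score")


def _ordered(scores: pd.Series, descending: bool) -> list[str]:
    # ties broken by gene ID lexicographic order for determinism
    frame = scores.rename("s").rename_axis("g").reset_index()
    frame = frame.sort_values(["s", "g"], ascending=[not descending, True])
    return list(frame["g"])


def rrho(table_a: pd.DataFrame, table_b: pd.DataFrame,
         config: PipelineConfig) -> RRHOResult:
    """Rank-rank hypergeometric overlap between two meta tables.

    Both tables must cover the same gene universe (size >= 10).  Grid
    thresholds are multiples of ``step = max(1, round(rrho_step_fraction *
    N))``; per quadrant, thresholds on each condition's side are limited to
    that side's signed-score support (ranks within the up-scoring genes for
    "up", within the down-scoring genes for "down"), so optimal sets never
    reach across the zero-score boundary.
    """
    if not table_a.index.equals(table_b.index):
        if set(table_a.index) != set(table_b.index):
            raise ValueError("gene universes differ between conditions")
        table_b = table_b.loc[table_a.index]
    N = len(table_a)
    if N < 10:
        raise ValueError(f"gene universe too small for RRHO: {N} < 10")
    step = max(1, round(config.rrho_step_fraction * N))
    score_a = rank_scores(table_a)
    score_b = rank_scores(table_b)

    order = {
        ("A", "up"): _ordered(score_a, descending=True),
        ("A", "down"): _ordered(score_a, descending=False),
        ("B", "up"): _ordered(score_b, descending=True),
        ("B", "down"): _ordered(score_b, descending=False),
    }
    support = {
        ("A", "up"): int((score_a > 0).sum()),
        ("A", "down"): int((score_a < 0).sum()),
        ("B", "up"): int((score_b > 0).sum()),
        ("B", "down"): int((score_b < 0).sum()),
    }

    grids: dict[str, pd.DataFrame] = {}
    optima: dict[str, tuple[int, int, float]] = {}
    optimal_sets: dict[str, set[str]] = {}
    genes = list(table_a.index)
    gene_idx = {g: i for i, g in enumerate(genes)}
    for quadrant in QUADRANTS:
        side_a, side_b = quadrant.split("-")
        list_a = order[("A", side_a)]
        list_b = order[("B", side_b)]
        thr_a = np.arange(step, max(support[("A", side_a)], 0) + 1, step)
        thr_b = np.arange(step, max(support[("B", side_b)], 0) + 1, step)
        if thr_a.size == 0 or thr_b.size == 0:
            grids[quadrant] = pd.DataFrame()
            optima[quadrant] = (0, 0, 0.0)
            optimal_sets[quadrant] = set()
            continue
        rank_in_a = np.empty(N, dtype=int)
        rank_in_b = np.empty(N, dtype=int)
        for r, g in enumerate(list_a):
            rank_in_a[gene_idx[g]] = r
        for r, g in enumerate(list_b):
            rank_in_b[gene_idx[g]] = r
        # overlap counts at every (i, j) via a cumulative 2-D histogram
        bins_a = np.concatenate([[0], thr_a])
        bins_b = np.concatenate([[0], thr_b])
        hist, _, _ = np.histogram2d(
            rank_in_a, rank_in_b,
            bins=[np.concatenate([bins_a, [N + 1]]),
                  np.concatenate([bins_b, [N + 1]])])
        counts = hist.cumsum(axis=0).cumsum(axis=1)[:-1, :-1]
        II, JJ = np.meshgrid(thr_a, thr_b, indexing="ij")
        pgrid = stats.hypergeom.sf(counts - 1, N, II, JJ)
        neglog = -np.log10(np.clip(pgrid, Q_FLOOR, None))
        grid = pd.DataFrame(neglog, index=thr_a, columns=thr_b)
        grids[quadrant] = grid
        flat = int(np.argmax(neglog))
        oi, oj = np.unravel_index(flat, neglog.shape)
        peak = float(neglog[oi, oj])
        i_thr, j_thr = int(thr_a[oi]), int(thr_b[oj])
        optima[quadrant] = (i_thr, j_thr, peak)
        optimal_sets[quadrant] = set(list_a[:i_thr]) & set(list_b[:j_thr])

    return RRHOResult(
        rank_scores=pd.DataFrame({"score_A": score_a, "score_B": score_b}),
        step=step, grids=grids, optima=optima, optimal_sets=optimal_sets)


def classify_genes(table_a: pd.DataFrame, table_b: pd.DataFrame,
                   rrho_result: RRHOResult) -> pd.Series:
    """Label every gene with its cross-condition regulation class.

    Common classes need DE in both conditions plus membership of the
    optimal overlap set whose quadrant matches the two DE directions;
    unique classes need DE in exactly one condition and absence from every
    optimal set; everything else is "none".
    """
    table_b = table_b.loc[table_a.index]
    dir_a = table_a["direction"].to_numpy()
    dir_b = table_b["direction"].to_numpy()
    sets = rrho_result.optimal_sets
    any_optimal = set().union(*sets.values()) if sets else set()
    quadrant_of = {("up", "up"): "up-up", ("down", "down"): "down-down",
                   ("up", "down"): "up-down", ("down", "up"): "down-up"}
    class_of = {"up-up": "common-concordant-up",
                "down-down": "common-concordant-down",
                "up-down": "common-discordant-A-up-B-down",
                "down-up": "common-discordant-A-down-B-up"}
    labels = []
    for gene, da, db in zip(table_a.index, dir_a, dir_b):
        label = "none"
        if da != "none" and db != "none":
            quadrant = quadrant_of[(da, db)]
            if gene in sets.get(quadrant, set()):
                label = class_of[quadrant]
        elif da != "none" and gene not in any_optimal:
            label = f"unique-A-{da}"
        elif db != "none" and gene not in any_optimal:
            label = f"unique-B-{db}"
        labels.append(label)
    return pd.Series(labels, index=table_a.index, name="gene_class")
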