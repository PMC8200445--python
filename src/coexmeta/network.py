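"""Signed weighted consensus co-expression networks.

For each dataset of a condition group a signed adjacency
``Adj_ij = (0.5*(1 + cor(x_i, x_j)))^beta`` is built, with ``beta`` the
lowest integer whose scale-free topology fit reaches the configured
threshold.  Each adjacency becomes a topological overlap matrix (TOM); the
per-dataset TOMs are calibrated onto a common scale by equalizing one
off-diagonal quantile and combined by the component-wise ("parallel")
minimum into a consensus TOM.  Modules are branches of the average-linkage
dendrogram of 1 - cTOM, each summarized per dataset by its eigengene (first
principal component of the standardized module expression), and modules
whose eigengenes correlate above ``merge_cor_min`` in every dataset are
merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .config import PipelineConfig
from .io import ExpressionDataset

__all__ = [
    "AdjacencyMatrix",
    "TOMStack",
    "ModulePartition",
    "EigengeneSet",
    "signed_adjacency",
    "scale_free_fit",
    "pick_beta",
    "tom",
    "calibrate_toms",
    "consensus_tom",
    "detect_modules",
    "module_eigengenes",
    "merge_modules",
    "build_consensus_network",
]

log = logging.getLogger(__name__)

#: branches are only considered below this fraction of the top merge height
STATIC_CUT_FRACTION = 0.99
#: a merge-height gap this large separates clusters inside a branch
BRANCH_GAP = 0.02
#: genes whose minimum-across-datasets module membership (kME) falls below
#: this are pruned from a detected module before merging
KME_PRUNE_MIN = 0.5


@dataclass
class AdjacencyMatrix:
    A: np.ndarray
    beta: int
    genes: list[str] | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if A.min() < -1e-12 or A.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")
        self.A = A


@dataclass
class TOMStack:
    """Per-dataset TOMs plus their consensus."""

    toms: list[np.ndarray]
    scale_factors: list[float]
    calibration_quantile: float
    ctom: np.ndarray
    genes: list[str]

    @property
    def dis_ctom(self) -> np.ndarray:
        d = 1.0 - self.ctom
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class ModulePartition:
    """Gene -> module label ("M0" = unassigned), plus merge history."""

    labels: pd.Series
    merge_history: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        self.labels.name = "module"

    @property
    def modules(self) -> list[str]:
        present = [m for m in self.labels.unique() if m != "M0"]
        return sorted(present, key=lambda m: (-(self.labels == m).sum(), m))

    def genes_of(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != "M0"].value_counts()

    def relabel_by_size(self) -> "ModulePartition":
        """Rename modules M1..Mk by descending size (ties by old label)."""
        mapping = {old: f"M{i}" for i, old in enumerate(self.modules, 1)}
        mapping["M0"] = "M0"
        return ModulePartition(self.labels.map(mapping),
                               list(self.merge_history))


class EigengeneSet:
    """Per-dataset sample scores of each module's eigengene.

    ``scores[dataset_id]`` is a samples x modules DataFrame (unit-norm
    columns, oriented to correlate positively with the module's mean
    standardized expression); ``variance_explained[(module, dataset_id)]``
    records the share of module variance the eigengene captures.
    """

    def __init__(self) -> None:
        self.scores: dict[str, pd.DataFrame] = {}
        self.variance_explained: dict[tuple[str, str], float] = {}

    @property
    def modules(self) -> list[str]:
        first = next(iter(self.scores.values()))
        return list(first.columns)


def signed_adjacency(X: np.ndarray, beta: int,
                     genes: list[str] | None = None) -> AdjacencyMatrix:
    """Adj_ij = (0.5 * (1 + pearson(x_i, x_j)))^beta, diagonal 1."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    var = X.var(axis=1)
    if (var <= 0).any():
        idx = int(np.flatnonzero(var <= 0)[0])
        name = genes[idx] if genes else f"row {idx}"
        raise ValueError(f"zero-variance gene {name}")
    corr = np.corrcoef(X)
    corr = np.clip(corr, -1.0, 1.0)
    A = np.abs(0.5 * (1.0 + corr)) ** beta
    np.fill_diagonal(A, 1.0)
    return AdjacencyMatrix(A=A, beta=int(beta), genes=genes)


def scale_free_fit(A: AdjacencyMatrix, n_bins: int = 10,
                   ) -> tuple[float, float]:
    """Scale-free topology fit of the connectivity distribution.

    Whole-network connectivities k_i = sum_{j!=i} Adj_ij are binned into
    ``n_bins`` equal-width bins; the fit is the R^2 of regressing
    log10(mean frequency) on log10(mean k) over non-empty bins.  Returns
    (R^2, slope); all-equal connectivities give R^2 = 0 by convention.
    """
    M = A.A if isinstance(A, AdjacencyMatrix) else np.asarray(A, float)
    k = M.sum(axis=1) - np.diag(M)
    if np.ptp(k) == 0:
        log.info("all connectivities equal; scale-free fit defined as 0")
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    nonempty = counts > 0
    mean_k = np.array([k[which == b].mean() if counts[b] else np.nan
                       for b in range(n_bins)])
    freq = counts / k.size
    xs = np.log10(mean_k[nonempty])
    ys = np.log10(freq[nonempty])
    if xs.size < 3 or np.ptp(xs) == 0:
        return 0.0, 0.0
    fit = linregress(xs, ys)
    return float(fit.rvalue ** 2), float(fit.slope)


def pick_beta(X: np.ndarray, config: PipelineConfig,
              genes: list[str] | None = None,
              ) -> tuple[int, pd.DataFrame]:
    """Lowest integer beta whose scale-free fit reaches the threshold.

    Scans beta = 1..beta_max; requires a negative log-log slope.  If no
    beta qualifies (e.g. pure noise), returns the argmax-fit beta with a
    ``warning`` flag set in the returned scan table.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 100:
        log.warning("scale-free fit on %d genes is unstable", X.shape[0])
    base = signed_adjacency(X, 1, genes).A
    rows = []
    for beta in range(1, config.beta_max + 1):
        A = base ** beta
        np.fill_diagonal(A, 1.0)
        r2, slope = scale_free_fit(AdjacencyMatrix(A, beta, genes))
        rows.append({"beta": beta, "r_squared": r2, "slope": slope})
    scan = pd.DataFrame(rows)
    ok = scan[(scan["r_squared"] >= config.scale_free_r2_min) &
              (scan["slope"] < 0)]
    if len(ok):
        beta = int(ok["beta"].iloc[0])
        scan.attrs["warning"] = False
    else:
        beta = int(scan.loc[scan["r_squared"].idxmax(), "beta"])
        scan.attrs["warning"] = True
        log.warning("no beta reached scale-free fit >= %.2f; using argmax "
                    "beta=%d", config.scale_free_r2_min, beta)
    return beta, scan


def tom(A: AdjacencyMatrix) -> np.ndarray:
    """Topological overlap: shared-neighbour strength between gene pairs.

    TOM_ij = (l_ij + A_ij) / (min(k_i, k_j) + 1 - A_ij) with
    l_ij = sum_{u != i,j} A_iu * A_uj and k_i = sum_{u != i} A_iu;
    diagonal 1.
    """
    M = A.A if isinstance(A, AdjacencyMatrix) else np.asarray(A, float)
    n = M.shape[0]
    # (M @ M)_ij includes u = i and u = j; with unit diagonal both
    # contribute A_ij, so l_ij = (M @ M)_ij - 2 A_ij.
    L = M @ M - 2.0 * M
    k = M.sum(axis=1) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - M
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (L + M) / denom
    T[denom <= 0] = 1.0
    np.fill_diagonal(T, 1.0)
    T = np.clip(T, 0.0, 1.0)
    return 0.5 * (T + T.T)


def calibrate_toms(toms: list[np.ndarray], quantile: float = 0.95,
                   ) -> tuple[list[np.ndarray], list[float]]:
    """Scale every TOM so its off-diagonal quantile matches the reference.

    The reference level is the median of the per-dataset quantiles (a
    fixed-dataset reference is not scale-safe: one degenerate network as
    reference would crush every other TOM toward zero before the parallel
    minimum).  Each TOM is multiplied by ref_q / own_q and clipped to
    [0, 1].
    """
    if len(toms) < 2:
        raise ValueError("need at least two TOMs to calibrate")
    n = toms[0].shape[0]
    off = ~np.eye(n, dtype=bool)
    quantiles = [float(np.quantile(T[off], quantile)) for T in toms]
    if any(q <= 0 for q in quantiles):
        raise ValueError("TOM calibration quantile is zero")
    ref = float(np.median(quantiles))
    factors = [ref / q for q in quantiles]
    calibrated = [np.clip(T * f, 0.0, 1.0) for T, f in zip(toms, factors)]
    for C in calibrated:
        np.fill_diagonal(C, 1.0)
    return calibrated, factors


def consensus_tom(calibrated: list[np.ndarray],
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Parallel minimum across calibrated TOMs; dis-cTOM = 1 - cTOM."""
    ctom = np.minimum.reduce([np.asarray(T, float) for T in calibrated])
    dis = 1.0 - ctom
    np.fill_diagonal(dis, 0.0)
    return ctom, dis


def _tree_cut(Z: np.ndarray, n: int, min_size: int,
              cut_fraction: float = STATIC_CUT_FRACTION,
              gap: float = BRANCH_GAP) -> np.ndarray:
    """Deterministic two-stage cut of an average-linkage dendrogram.

    Stage one is a static cut at ``cut_fraction`` of the top merge height;
    the branches hanging below it are candidate clusters.  Stage two
    recursively inspects each candidate's internal merge heights: if the
    largest gap between consecutive sorted heights is at least ``gap``,
    the branch is re-cut inside that gap and the pieces are examined
    again (a gap that large separates a tight cluster from a looser
    super-structure).  Surviving clusters with >= ``min_size`` leaves get
    labels 1..k; all other genes stay 0 (unassigned).
    """
    n_nodes = Z.shape[0]
    if n_nodes == 0:
        return np.zeros(n, dtype=int)
    heights = Z[:, 2]
    cut_h = cut_fraction * heights[-1]

    # leaf membership per internal node, built bottom-up
    members: list[np.ndarray] = [None] * n_nodes
    for i in range(n_nodes):
        parts = []
        for child in (int(Z[i, 0]), int(Z[i, 1])):
            parts.append(np.array([child]) if child < n
                         else members[child - n])
        members[i] = np.concatenate(parts)

    def branches_below(node: int, t: float) -> list[int]:
        """Maximal subtree nodes (or leaves) with merge height <= t."""
        out: list[int] = []
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur < n or heights[cur - n] <= t:
                out.append(cur)
            else:
                stack.extend((int(Z[cur - n, 0]), int(Z[cur - n, 1])))
        return out

    def internal_heights(node: int) -> np.ndarray:
        out = []
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur >= n:
                out.append(heights[cur - n])
                stack.extend((int(Z[cur - n, 0]), int(Z[cur - n, 1])))
        return np.sort(np.asarray(out))

    def node_size(node: int) -> int:
        return 1 if node < n else members[node - n].size

    labels = np.zeros(n, dtype=int)
    next_label = 1
    root = n + n_nodes - 1
    queue = [b for b in branches_below(root, cut_h)]
    while queue:
        node = queue.pop()
        if node < n or members[node - n].size < min_size:
            continue
        hs = internal_heights(node)
        gaps = np.diff(hs)
        candidates = np.flatnonzero(gaps >= gap)
        # a gap only separates clusters (rather than peeling leaf-level
        # structure) if cutting inside it leaves >= 2 branches of module size
        split_done = False
        for k in candidates[np.argsort(gaps[candidates])[::-1]]:
            split_at = 0.5 * (hs[k] + hs[k + 1])
            pieces = branches_below(node, split_at)
            big = [b for b in pieces if node_size(b) >= min_size]
            if len(big) >= 2:
                queue.extend(pieces)
                split_done = True
                break
        if not split_done:
            labels[members[node - n]] = next_label
            next_label += 1
    return labels


def detect_modules(dis_tom: np.ndarray, config: PipelineConfig,
                   genes: list[str] | None = None) -> ModulePartition:
    """Average-linkage clustering of dis-cTOM plus deterministic tree cut.

    Returned labels are "M1".."Mk" ordered by descending module size, with
    "M0" for unassigned genes; every module has at least
    ``min_module_size`` genes.
    """
    dis = np.asarray(dis_tom, dtype=float)
    n = dis.shape[0]
    if genes is None:
        genes = [str(i) for i in range(n)]
    Z = linkage(squareform(dis, checks=False), method="average")
    raw = _tree_cut(Z, n, config.min_module_size)
    if raw.max() == 0:
        log.warning("no module of size >= %d found", config.min_module_size)
    labels = pd.Series([f"M{v}" for v in raw],
                       index=pd.Index(genes, name="gene_id"), name="module")
    return ModulePartition(labels).relabel_by_size()


def prune_by_membership(partition: ModulePartition,
                        datasets: list[ExpressionDataset],
                        kme_min: float = KME_PRUNE_MIN,
                        min_module_size: int = 2) -> ModulePartition:
    """Drop module genes whose eigengene correlation is not reproducible.

    Average-linkage clustering of a dissimilarity with a noise floor lets
    background genes accrete onto genuine module branches.  Each detected
    module is therefore screened once: a gene stays only if its
    correlation with the module eigengene (kME) reaches ``kme_min`` in
    every dataset of the group; pruned genes return to "M0", and modules
    falling below ``min_module_size`` dissolve entirely.  No gene is ever
    reassigned to a different module.
    """
    labels = partition.labels.copy()
    eg = module_eigengenes(partition, datasets)
    gene_pos = {ds.dataset_id: pd.Index(ds.genes) for ds in datasets}
    for module in partition.modules:
        genes = partition.genes_of(module)
        min_kme = np.full(len(genes), np.inf)
        for ds in datasets:
            eig = eg.scores[ds.dataset_id][module].to_numpy()
            idx = gene_pos[ds.dataset_id].get_indexer(genes)
            sub = ds.X[idx]
            centered = sub - sub.mean(axis=1, keepdims=True)
            eig_c = eig - eig.mean()
            denom = np.sqrt((centered ** 2).sum(axis=1) *
                            (eig_c ** 2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                kme = (centered @ eig_c) / denom
            min_kme = np.minimum(min_kme, np.nan_to_num(kme, nan=-1.0))
        drop = [g for g, k in zip(genes, min_kme) if k < kme_min]
        if drop:
            labels.loc[drop] = "M0"
        if (labels == module).sum() < min_module_size:
            labels.loc[labels == module] = "M0"
    out = ModulePartition(labels, list(partition.merge_history))
    return out.relabel_by_size()


def module_eigengenes(partition: ModulePartition,
                      datasets: list[ExpressionDataset]) -> EigengeneSet:
    """First principal component of each module's standardized expression.

    Per (module, dataset): rows are z-scored across samples, the first
    right-singular vector (unit norm) is the eigengene, sign-flipped if it
    correlates negatively with the module's mean standardized profile.
    """
    eg = EigengeneSet()
    modules = partition.modules
    gene_pos = {ds.dataset_id: pd.Index(ds.genes) for ds in datasets}
    for ds in datasets:
        cols = {}
        for module in modules:
            genes = partition.genes_of(module)
            if len(genes) < 2:
                raise ValueError(f"module {module} has fewer than 2 genes")
            idx = gene_pos[ds.dataset_id].get_indexer(genes)
            if (idx < 0).any():
                raise ValueError(
                    f"dataset {ds.dataset_id} lacks genes of {module}")
            sub = ds.X[idx]
            mu = sub.mean(axis=1, keepdims=True)
            sd = sub.std(axis=1, keepdims=True)
            if (sd == 0).any():
                raise ValueError(
                    f"constant gene inside module {module}")
            zed = (sub - mu) / sd
            U, S, Vt = np.linalg.svd(zed, full_matrices=False)
            scores = Vt[0]
            mean_profile = zed.mean(axis=0)
            if np.dot(scores, mean_profile) < 0:
                scores = -scores
            cols[module] = scores
            eg.variance_explained[(module, ds.dataset_id)] = float(
                S[0] ** 2 / (S ** 2).sum())
        eg.scores[ds.dataset_id] = pd.DataFrame(
            cols, index=list(ds.samples["sample_id"]))
    return eg


def _min_eigengene_cor(eg: EigengeneSet, a: str, b: str) -> float:
    cors = []
    for frame in eg.scores.values():
        va, vb = frame[a].to_numpy(), frame[b].to_numpy()
        cors.append(float(np.corrcoef(va, vb)[0, 1]))
    return min(cors)


def merge_modules(partition: ModulePartition, eigengenes: EigengeneSet,
                  datasets: list[ExpressionDataset],
                  config: PipelineConfig,
                  ) -> tuple[ModulePartition, EigengeneSet]:
    """Iteratively merge module pairs whose minimum-across-datasets
    eigengene correlation exceeds ``merge_cor_min``.

    At each step the best-correlated qualifying pair is merged and the
    eigengenes are recomputed, repeating to a fixed point; the result is
    relabelled by size with the merge history retained.
    """
    part = ModulePartition(partition.labels.copy(),
                           list(partition.merge_history))
    eg = eigengenes
    while True:
        modules = part.modules
        if len(modules) < 2:
            break
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(modules):
            for b in modules[i + 1:]:
                c = _min_eigengene_cor(eg, a, b)
                if c > config.merge_cor_min and \
                        (best is None or c > best[0]):
                    best = (c, a, b)
        if best is None:
            break
        _, a, b = best
        merged = part.labels.replace({b: a})
        part = ModulePartition(merged, part.merge_history +
                               [(a, b, f"{best[0]:.4f}")])
        eg = module_eigengenes(part, datasets)
    part = part.relabel_by_size()
    eg = module_eigengenes(part, datasets) if part.modules else EigengeneSet()
    return part, eg


@dataclass
class ConsensusNetwork:
    """End product of the network stage for one condition group."""

    partition: ModulePartition
    eigengenes: EigengeneSet
    tom_stack: TOMStack
    betas: dict[str, int]
    beta_scans: dict[str, pd.DataFrame]


def build_consensus_network(datasets: list[ExpressionDataset],
                            config: PipelineConfig) -> ConsensusNetwork:
    """Full network stage: beta per dataset, TOMs, calibration, consensus,
    modules, eigengenes, merging."""
    if not datasets:
        raise ValueError("no datasets supplied")
    genes = datasets[0].genes
    betas: dict[str, int] = {}
    scans: dict[str, pd.DataFrame] = {}
    toms: list[np.ndarray] = []
    for ds in datasets:
        beta, scan = pick_beta(ds.X, config, ds.genes)
        betas[ds.dataset_id] = beta
        scans[ds.dataset_id] = scan
        toms.append(tom(signed_adjacency(ds.X, beta, ds.genes)))
    if len(toms) >= 2:
        calibrated, factors = calibrate_toms(
            toms, config.calibration_quantile)
    else:
        calibrated, factors = toms, [1.0]
    ctom, dis = consensus_tom(calibrated) if len(calibrated) > 1 else (
        calibrated[0], 1.0 - calibrated[0])
    np.fill_diagonal(dis, 0.0)
    stack = TOMStack(toms=calibrated, scale_factors=factors,
                     calibration_quantile=config.calibration_quantile,
                     ctom=ctom, genes=genes)
    partition = detect_modules(dis, config, genes)
    if partition.modules:
        partition = prune_by_membership(
            partition, datasets, min_module_size=config.min_module_size)
    if partition.modules:
        eigengenes = module_eigengenes(partition, datasets)
        partition, eigengenes = merge_modules(partition, eigengenes,
                                              datasets, config)
    else:
        eigengenes = EigengeneSet()
    return ConsensusNetwork(partition=partition, eigengenes=eigengenes,
                            tom_stack=stack, betas=betas, beta_scans=scans)
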