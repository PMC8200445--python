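"""Gene-level meta-analysis across independent paired studies.

Within each dataset, differential expression post vs. pre is estimated with
an empirical-Bayes moderated paired t-test: the paired design reduces to a
one-sample test on per-subject (post - pre) differences, and per-gene
variances are shrunk toward a common prior fitted by matching the first two
moments of log sample variances to a scaled-F model (the limma approach).
Right-tailed per-dataset p-values are combined across datasets with
Stouffer's unweighted Z, corrected with Benjamini-Hochberg, and a gene is
called differentially expressed only if (i) its corrected meta p is at or
below ``alpha_meta``, (ii) its absolute meta mean log2 fold-change exceeds
``lfc_min``, and (iii) its per-dataset fold-changes share one direction.

Because purely right-tailed aggregation pushes down-regulated genes toward
p = 1, the final meta significance here is two-sided (p = 2*(1-Phi(|Z|)))
with the direction taken from the sign of Z; the right-tailed meta p is kept
as a column for rank-based downstream use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .io import ExpressionDataset

__all__ = [
    "ModerationParams",
    "paired_differences",
    "fit_moderation",
    "moderated_t",
    "stouffer_combine",
    "bh_adjust",
    "gene_meta_table",
    "call_de",
]

log = logging.getLogger(__name__)

P_CLAMP = 1e-15


@dataclass
class ModerationParams:
    """Empirical-Bayes variance prior for one dataset.

    ``d0`` is the prior degrees of freedom (``inf`` when the observed
    variances show no excess dispersion beyond sampling noise), ``s0_sq``
    the prior variance, ``df`` the residual degrees of freedom (pairs - 1).
    """

    d0: float
    s0_sq: float
    df: int
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be non-negative (or inf)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def paired_differences(ds: ExpressionDataset) -> pd.DataFrame:
    """Per-subject (post - pre) differences: genes x subjects."""
    sheet = ds.samples
    pos = {(r.subject_id, r.timepoint): i
           for i, r in enumerate(sheet.itertuples())}
    subjects = ds.subjects
    pre_idx = [pos[(s, "pre")] for s in subjects]
    post_idx = [pos[(s, "post")] for s in subjects]
    D = ds.X[:, post_idx] - ds.X[:, pre_idx]
    return pd.DataFrame(D, index=pd.Index(ds.genes, name="gene_id"),
                        columns=subjects)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the limma recurrence)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_moderation(D: pd.DataFrame | np.ndarray) -> ModerationParams:
    """Fit the variance prior (d0, s0^2) from per-gene sample variances.

    Under the scaled-F model s_g^2 ~ s0^2 * F(d, d0), log s_g^2 has mean
    log s0^2 + psi(d/2) - psi(d0/2) - log(d/2) + log(d0/2) and variance
    psi'(d/2) + psi'(d0/2); the two moments identify (d0, s0^2).  When the
    empirical variance of log s_g^2 does not exceed psi'(d/2), there is no
    excess dispersion and d0 = inf.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[1]
    if n < 3:
        raise ValueError(f"insufficient pairs for moderation: {n} < 3")
    df = n - 1
    s2 = D.var(axis=1, ddof=1)
    low_confidence = s2.size < 10
    if low_confidence:
        log.warning("moderation fitted on only %d genes; prior is "
                    "low-confidence", s2.size)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all per-gene variances are zero")
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) if e.size > 1 else 0.0
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if e_var < 1e-12:
        # literally identical variances: the common value is the prior
        return ModerationParams(d0=np.inf, s0_sq=float(np.exp(z.mean())),
                                df=df, low_confidence=low_confidence)
    if excess <= 0:
        return ModerationParams(d0=np.inf, s0_sq=float(np.exp(e_mean)),
                                df=df, low_confidence=low_confidence)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return ModerationParams(d0=float(d0), s0_sq=float(s0_sq), df=df,
                            low_confidence=low_confidence)


def moderated_t(D: pd.DataFrame, params: ModerationParams) -> pd.DataFrame:
    """Moderated one-sample t on paired differences; right-tailed p.

    The posterior variance is (d0*s0^2 + d*s_g^2)/(d0 + d); the moderated t
    has d0 + d degrees of freedom (a normal reference when d0 = inf, the
    classical t when d0 = 0).  Right-tailed, so down-shifts give p near 1.
    """
    X = np.asarray(D, dtype=float)
    n = X.shape[1]
    d = n - 1
    logfc = X.mean(axis=1)
    s2 = X.var(axis=1, ddof=1)
    if np.isinf(params.d0):
        s2_post = np.full_like(s2, params.s0_sq)
        df_total = np.inf
    else:
        s2_post = (params.d0 * params.s0_sq + d * s2) / (params.d0 + d)
        df_total = params.d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / np.sqrt(s2_post / n)
    # degenerate rows: identical differences everywhere
    degenerate = s2_post <= 0
    if degenerate.any():
        log.warning("%d genes have zero posterior variance", degenerate.sum())
        t = np.where(degenerate, np.sign(logfc) * np.inf, t)
        t = np.where(degenerate & (logfc == 0), 0.0, t)
    if np.isinf(df_total):
        p_right = stats.norm.sf(t)
    else:
        p_right = stats.t.sf(t, df_total)
    return pd.DataFrame({"logFC": logfc, "t": t, "p_right": p_right},
                        index=D.index if isinstance(D, pd.DataFrame)
                        else pd.RangeIndex(X.shape[0]))


def stouffer_combine(p_list: np.ndarray | list[float],
                     ) -> tuple[float, float] | tuple[np.ndarray, np.ndarray]:
    """Unweighted Stouffer combination of right-tailed p-values.

    Z = sum(Phi^-1(1 - p_i)) / sqrt(k); p_right = 1 - Phi(Z).  Accepts a
    1-D vector (one gene) or a genes x datasets matrix, combining across
    the last axis.  p-values exactly 0 or 1 are clamped to [1e-15, 1-1e-15].
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    clamped = np.clip(p, P_CLAMP, 1.0 - P_CLAMP)
    if not np.array_equal(clamped, p):
        log.info("clamped %d boundary p-values to [%g, 1-%g]",
                 int((clamped != p).sum()), P_CLAMP, P_CLAMP)
    k = p.shape[-1] if p.ndim > 1 else p.size
    z = stats.norm.isf(clamped).sum(axis=-1) / np.sqrt(k)
    p_right = stats.norm.sf(z)
    if p.ndim == 1:
        return float(z), float(p_right)
    return z, p_right


def bh_adjust(p_vec: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving, capped at 1."""
    p = np.asarray(p_vec, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def gene_meta_table(datasets: list[ExpressionDataset],
                    config: PipelineConfig) -> pd.DataFrame:
    """Full per-gene meta table for one condition group.

    Columns: per-dataset ``logFC_<id>``, ``t_<id>``, ``p_<id>`` (right
    tailed, moderated); meta ``Z``, ``p_meta`` (two-sided), ``p_meta_right``,
    ``q`` (BH of the two-sided meta p), ``mean_logFC``, ``direction``,
    ``de``.
    """
    if not datasets:
        raise ValueError("no datasets supplied")
    genes = datasets[0].genes
    for ds in datasets[1:]:
        if ds.genes != genes:
            raise ValueError("datasets must share an identical gene list; "
                             "run intersect_genes first")
    table = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    p_cols, lfc_cols = [], []
    for ds in datasets:
        D = paired_differences(ds)
        params = fit_moderation(D)
        res = moderated_t(D, params)
        table[f"logFC_{ds.dataset_id}"] = res["logFC"]
        table[f"t_{ds.dataset_id}"] = res["t"]
        table[f"p_{ds.dataset_id}"] = res["p_right"]
        p_cols.append(f"p_{ds.dataset_id}")
        lfc_cols.append(f"logFC_{ds.dataset_id}")
    z, p_right = stouffer_combine(table[p_cols].to_numpy())
    table["Z"] = z
    table["p_meta_right"] = p_right
    table["p_meta"] = 2.0 * stats.norm.sf(np.abs(z))
    table["q"] = bh_adjust(table["p_meta"].to_numpy())
    table["q_right"] = bh_adjust(table["p_meta_right"].to_numpy())
    table["mean_logFC"] = table[lfc_cols].mean(axis=1)
    table.attrs["dataset_ids"] = [ds.dataset_id for ds in datasets]
    return call_de(table, config)


def call_de(table: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Apply the three-part DE criterion and record direction.

    DE requires q <= alpha_meta, |mean logFC| > lfc_min, and a common sign
    of logFC across every dataset of the group.
    """
    lfc_cols = [c for c in table.columns if c.startswith("logFC_")]
    signs = np.sign(table[lfc_cols].to_numpy())
    common = (np.abs(signs.sum(axis=1)) == signs.shape[1]) & \
        (signs != 0).all(axis=1)
    de = (table["q"].to_numpy() <= config.alpha_meta) & \
        (np.abs(table["mean_logFC"].to_numpy()) > config.lfc_min) & common
    direction = np.where(de,
                         np.where(table["mean_logFC"] > 0, "up", "down"),
                         "none")
    out = table.copy()
    out.attrs.update(table.attrs)
    out["de"] = de
    out["direction"] = direction
    return out
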