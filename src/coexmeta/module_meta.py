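"""Meta-analysis of module eigengene regulation pre vs. post.

Mirrors the gene-level procedure at eigengene level: per dataset, a
classical one-sample paired t-test on per-subject (post - pre) eigengene
differences (right-tailed p); Stouffer combination across the group's
datasets; BH correction across the network's modules; and the three-part
call — corrected meta p <= alpha_meta, absolute meta mean shift above
``lfc_min``, and a common per-dataset direction of eigengene change.

Eigengene scores are standardized to unit variance within each dataset
before differencing, so the effect-size threshold is applied in subject-SD
units (the eigengene has no natural log-fold-change unit).  An ordinary
(unmoderated) t is used: one series per module offers no variance ensemble
to shrink over.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .gene_meta import bh_adjust, stouffer_combine
from .io import ExpressionDataset
from .network import EigengeneSet

__all__ = ["eigengene_paired_stats", "module_meta_call", "module_meta_table"]


def eigengene_paired_stats(eigengenes: EigengeneSet,
                           datasets: list[ExpressionDataset],
                           ) -> pd.DataFrame:
    """Per (module, dataset): mean paired eigengene shift, t, right-tail p."""
    rows = []
    by_id = {ds.dataset_id: ds for ds in datasets}
    for dataset_id, frame in eigengenes.scores.items():
        ds = by_id[dataset_id]
        if ds.n_pairs < 3:
            raise ValueError(
                f"dataset {dataset_id} has fewer than 3 subject pairs")
        sheet = ds.samples
        pos = {(r.subject_id, r.timepoint): i
               for i, r in enumerate(sheet.itertuples())}
        subjects = ds.subjects
        pre = [pos[(s, "pre")] for s in subjects]
        post = [pos[(s, "post")] for s in subjects]
        for module in frame.columns:
            scores = frame[module].to_numpy()
            sd = scores.std(ddof=1)
            std_scores = scores / sd if sd > 0 else scores
            diff = std_scores[post] - std_scores[pre]
            delta = float(diff.mean())
            se = diff.std(ddof=1) / np.sqrt(diff.size)
            if se > 0:
                t = delta / se
                p_right = float(stats.t.sf(t, diff.size - 1))
            else:
                t = 0.0 if delta == 0 else np.sign(delta) * np.inf
                p_right = 0.5 if delta == 0 else (0.0 if delta > 0 else 1.0)
            rows.append({"module": module, "dataset_id": dataset_id,
                         "delta": delta, "t": float(t), "p_right": p_right})
    return pd.DataFrame(rows)


def module_meta_call(stats_table: pd.DataFrame,
                     config: PipelineConfig) -> pd.DataFrame:
    """Combine per-dataset eigengene stats into per-module meta calls.

    BH is applied within this network's module set only.  ``diff_flag``
    requires q <= alpha_meta, |mean delta| > lfc_min (SD units), and a
    common sign of delta across all datasets.
    """
    modules = list(dict.fromkeys(stats_table["module"]))
    records = []
    for module in modules:
        sub = stats_table[stats_table["module"] == module]
        z, p_right = stouffer_combine(sub["p_right"].to_numpy())
        deltas = sub["delta"].to_numpy()
        signs = np.sign(deltas)
        common = bool((np.abs(signs.sum()) == signs.size) and
                      (signs != 0).all())
        records.append({
            "module": module,
            "Z": z,
            "p_meta_right": p_right,
            "p_meta": float(2.0 * stats.norm.sf(abs(z))),
            "mean_delta": float(deltas.mean()),
            "common_direction": common,
        })
    out = pd.DataFrame(records).set_index("module")
    out["q"] = bh_adjust(out["p_meta"].to_numpy())
    out["diff_flag"] = (out["q"] <= config.alpha_meta) & \
        (out["mean_delta"].abs() > config.lfc_min) & out["common_direction"]
    out["direction"] = np.where(
        out["diff_flag"], np.where(out["mean_delta"] > 0, "up", "down"),
        "none")
    return out


def module_meta_table(eigengenes: EigengeneSet,
                      datasets: list[ExpressionDataset],
                      config: PipelineConfig,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: per-dataset stats plus the meta call table."""
    per_dataset = eigengene_paired_stats(eigengenes, datasets)
    if per_dataset.empty:
        return per_dataset, pd.DataFrame(
            columns=["Z", "p_meta_right", "p_meta", "mean_delta",
                     "common_direction", "q", "diff_flag", "direction"])
    return per_dataset, module_meta_call(per_dataset, config)
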