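"""Synthetic multi-study paired expression data with planted structure.

The generator emulates the data layout the meta-analysis assumes: several
independent microarray-style studies per condition group, each measuring the
same gene universe on paired pre/post muscle biopsies from its own subjects.

Per dataset ``d`` and gene ``g`` the generative model is

    x[g, s, t] = mu_g + lambda_{g,d} * (f_{m(g), s} + shift_m * [t == post])
                 + effect_g * [t == post] + eps,    eps ~ N(0, sigma_d^2)

with baseline means ``mu_g ~ N(8, 1.5^2)`` on the log2 scale, one latent
subject factor ``f_{m,s} ~ N(0, 1)`` per planted module and subject (shared
by that subject's pre and post samples, which is what gives paired tests
their power), and loadings ``lambda_{g,d}`` chosen so the expected
within-module Pearson correlation matches the requested target.  Background
genes have no factor.  ``effect_g`` plants gene-level log2 fold-changes;
``shift_m`` plants a coherent module-level (eigengene) shift in subject-SD
units.  Module memberships are identical across the datasets of a group.

Two-group comparisons plant disjoint gene-effect classes — shared direction,
unique to either group, and inverted between groups — so that the RRHO
quadrant truth is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import ExpressionDataset

__all__ = [
    "SimulationSpec",
    "SimulationTruth",
    "ComparisonSpec",
    "ComparisonTruth",
    "simulate_group",
    "simulate_comparison",
]

BASELINE_MEAN = 8.0
BASELINE_SD = 1.5
#: half-width of the uniform jitter applied to per-gene correlation loadings
LOADING_JITTER = 0.1

EFFECT_CLASSES = ("shared", "unique_A", "unique_B", "inverted", "none")


@dataclass
class SimulationSpec:
    """Conditions for one condition group's worth of datasets.

    Defaults mirror the study design being emulated: three independent
    datasets per group, ~20 pre/post pairs each, a few-thousand-gene shared
    universe, planted modules of 80 genes with within-module correlation
    0.6, and dataset noise SD 0.5 on the log2 scale.
    """

    n_datasets: int = 3
    n_pairs: int | Sequence[int] = 20
    n_genes: int = 4000
    module_sizes: Sequence[int] = (80, 80, 80, 80, 80)
    module_cor: float = 0.6
    noise_sd: float | Sequence[float] = 0.5
    gene_effects: np.ndarray | None = None  # length n_genes, log2FC at post
    module_shifts: Sequence[float] | None = None  # per module, SD units
    condition: str = "other"
    dataset_prefix: str = "DS"
    seed: int | None = None

    def pairs_per_dataset(self) -> list[int]:
        if np.isscalar(self.n_pairs):
            return [int(self.n_pairs)] * self.n_datasets
        pairs = [int(p) for p in self.n_pairs]
        if len(pairs) != self.n_datasets:
            raise ValueError("n_pairs length must equal n_datasets")
        return pairs

    def noise_per_dataset(self) -> list[float]:
        if np.isscalar(self.noise_sd):
            sds = [float(self.noise_sd)] * self.n_datasets
        else:
            sds = [float(s) for s in self.noise_sd]
            if len(sds) != self.n_datasets:
                raise ValueError("noise_sd length must equal n_datasets")
        if any(s <= 0 for s in sds):
            raise ValueError("noise_sd must be positive")
        return sds


@dataclass
class SimulationTruth:
    """Ground truth planted by :func:`simulate_group`."""

    genes: list[str]
    module_assignment: pd.Series  # gene -> "M1".. or "M0" background
    gene_effects: pd.Series  # gene -> log2FC at post
    module_shifts: dict[str, float]  # module -> eigengene shift (SD units)
    noise_sd: dict[str, float]  # dataset_id -> sigma
    loadings: pd.Series  # gene -> correlation-scale loading (0 outside modules)

    def module_genes(self, module: str) -> list[str]:
        return list(self.module_assignment.index[
            self.module_assignment == module])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "module": self.module_assignment,
            "effect": self.gene_effects,
            "loading": self.loadings,
        }).rename_axis("gene_id")


def _gene_names(n_genes: int) -> list[str]:
    width = max(5, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def simulate_group(config: PipelineConfig, spec: SimulationSpec,
                   ) -> tuple[list[ExpressionDataset], SimulationTruth]:
    """Generate one group's datasets plus the planted ground truth.

    Reproducible: the same config/spec (and seed) yields identical matrices.
    """
    if sum(spec.module_sizes) > spec.n_genes:
        raise ValueError(
            f"module sizes sum to {sum(spec.module_sizes)} > "
            f"n_genes={spec.n_genes}")
    if not (0 < spec.module_cor < 1):
        raise ValueError("module_cor must lie in (0, 1)")
    seed = config.seed if spec.seed is None else spec.seed
    rng = np.random.default_rng(seed)

    genes = _gene_names(spec.n_genes)
    n_modules = len(spec.module_sizes)
    module_labels = [f"M{i}" for i in range(1, n_modules + 1)]
    assignment = np.array(["M0"] * spec.n_genes, dtype=object)
    start = 0
    for label, size in zip(module_labels, spec.module_sizes):
        assignment[start:start + size] = label
        start += size

    # Correlation-scale loadings a_g with E[a]^2 = module_cor, so the
    # expected pairwise within-module correlation a_i*a_j matches the target.
    loadings = np.zeros(spec.n_genes)
    in_module = assignment != "M0"
    base = np.sqrt(spec.module_cor)
    jitter = rng.uniform(-LOADING_JITTER, LOADING_JITTER, in_module.sum())
    loadings[in_module] = np.clip(base + jitter, 0.05, 0.98)

    effects = (np.zeros(spec.n_genes) if spec.gene_effects is None
               else np.asarray(spec.gene_effects, dtype=float))
    if effects.shape != (spec.n_genes,):
        raise ValueError("gene_effects must have length n_genes")
    if not np.isfinite(effects).all():
        raise ValueError("gene_effects must be finite")
    shifts = ([0.0] * n_modules if spec.module_shifts is None
              else [float(s) for s in spec.module_shifts])
    if len(shifts) != n_modules:
        raise ValueError("module_shifts length must match module_sizes")

    mu = rng.normal(BASELINE_MEAN, BASELINE_SD, spec.n_genes)
    module_index = {label: np.flatnonzero(assignment == label)
                    for label in module_labels}

    datasets: list[ExpressionDataset] = []
    noise = spec.noise_per_dataset()
    for d, (n_pairs, sigma) in enumerate(zip(spec.pairs_per_dataset(), noise)):
        dataset_id = f"{spec.dataset_prefix}{d + 1}"
        # lambda on the expression scale for this dataset's noise level
        lam = sigma * loadings / np.sqrt(1.0 - loadings ** 2)
        n_samples = 2 * n_pairs
        X = np.tile(mu[:, None], (1, n_samples))
        post = np.zeros(n_samples, dtype=bool)
        post[1::2] = True  # samples ordered (pre, post) per subject
        factors = rng.normal(size=(n_modules, n_pairs))
        for m, label in enumerate(module_labels):
            idx = module_index[label]
            f = np.repeat(factors[m], 2) + shifts[m] * post
            X[idx] += lam[idx, None] * f[None, :]
        X[:, post] += effects[:, None]
        X += rng.normal(0.0, sigma, size=X.shape)

        subjects = [f"{dataset_id}_S{j + 1}" for j in range(n_pairs)]
        sheet = pd.DataFrame({
            "sample_id": [f"{s}_{tp}" for s in subjects
                          for tp in ("pre", "post")],
            "subject_id": np.repeat(subjects, 2),
            "timepoint": ["pre", "post"] * n_pairs,
        })
        datasets.append(ExpressionDataset(
            dataset_id=dataset_id, condition=spec.condition,
            genes=genes, X=X, samples=sheet))

    truth = SimulationTruth(
        genes=genes,
        module_assignment=pd.Series(assignment, index=genes, name="module"),
        gene_effects=pd.Series(effects, index=genes, name="effect"),
        module_shifts=dict(zip(module_labels, shifts)),
        noise_sd={ds.dataset_id: s for ds, s in zip(datasets, noise)},
        loadings=pd.Series(loadings, index=genes, name="loading"),
    )
    return datasets, truth


@dataclass
class ComparisonSpec:
    """Two condition groups over one gene universe with planted classes.

    Effect classes are assigned to disjoint background genes: ``n_shared``
    genes move in the same direction in both groups, ``n_unique_a`` /
    ``n_unique_b`` move in only one group, and ``n_inverted`` move in
    opposite directions.  Signs are randomized per gene so both up- and
    down-regulation occur.  Module-level shifts are planted independently
    per group via ``module_shifts_a`` / ``module_shifts_b``.
    """

    n_genes: int = 4000
    module_sizes: Sequence[int] = (80, 80, 80, 80, 80)
    module_cor: float = 0.6
    n_datasets_a: int = 3
    n_datasets_b: int = 3
    n_pairs: int | Sequence[int] = 20
    noise_sd: float | Sequence[float] = 0.5
    n_shared: int = 100
    n_unique_a: int = 100
    n_unique_b: int = 100
    n_inverted: int = 50
    effect_size: float = 0.5
    module_shifts_a: Sequence[float] | None = None
    module_shifts_b: Sequence[float] | None = None
    condition_a: str = "young_RET"
    condition_b: str = "disuse"
    seed: int | None = None


@dataclass
class ComparisonTruth:
    truth_a: SimulationTruth
    truth_b: SimulationTruth
    effect_class: pd.Series = field(default=None)  # gene -> EFFECT_CLASSES

    def class_genes(self, cls: str) -> list[str]:
        return list(self.effect_class.index[self.effect_class == cls])


def simulate_comparison(config: PipelineConfig, spec: ComparisonSpec,
                        ) -> tuple[list[ExpressionDataset],
                                   list[ExpressionDataset],
                                   ComparisonTruth]:
    """Generate paired groups A and B sharing a gene universe and modules."""
    seed = config.seed if spec.seed is None else spec.seed
    rng = np.random.default_rng(seed)
    genes = _gene_names(spec.n_genes)

    n_module_genes = sum(spec.module_sizes)
    n_planted = spec.n_shared + spec.n_unique_a + spec.n_unique_b + \
        spec.n_inverted
    if n_module_genes + n_planted > spec.n_genes:
        raise ValueError("planted modules plus effect classes exceed n_genes")

    # effect classes live on background genes, after the module block
    background = np.arange(n_module_genes, spec.n_genes)
    chosen = rng.choice(background, size=n_planted, replace=False)
    classes = np.array(["none"] * spec.n_genes, dtype=object)
    eff_a = np.zeros(spec.n_genes)
    eff_b = np.zeros(spec.n_genes)
    cursor = 0
    for cls, count in (("shared", spec.n_shared),
                       ("unique_A", spec.n_unique_a),
                       ("unique_B", spec.n_unique_b),
                       ("inverted", spec.n_inverted)):
        idx = chosen[cursor:cursor + count]
        cursor += count
        classes[idx] = cls
        signs = rng.choice([-1.0, 1.0], size=count)
        if cls in ("shared", "unique_A", "inverted"):
            eff_a[idx] = signs * spec.effect_size
        if cls == "shared":
            eff_b[idx] = signs * spec.effect_size
        elif cls == "unique_B":
            eff_b[idx] = signs * spec.effect_size
        elif cls == "inverted":
            eff_b[idx] = -signs * spec.effect_size

    seed_a, seed_b = rng.integers(0, 2 ** 31 - 1, size=2)
    common = dict(n_genes=spec.n_genes, module_sizes=spec.module_sizes,
                  module_cor=spec.module_cor, n_pairs=spec.n_pairs,
                  noise_sd=spec.noise_sd)
    spec_a = SimulationSpec(n_datasets=spec.n_datasets_a,
                            gene_effects=eff_a,
                            module_shifts=spec.module_shifts_a,
                            condition=spec.condition_a,
                            dataset_prefix="A", seed=int(seed_a), **common)
    spec_b = SimulationSpec(n_datasets=spec.n_datasets_b,
                            gene_effects=eff_b,
                            module_shifts=spec.module_shifts_b,
                            condition=spec.condition_b,
                            dataset_prefix="B", seed=int(seed_b), **common)
    ds_a, truth_a = simulate_group(config, spec_a)
    ds_b, truth_b = simulate_group(config, spec_b)
    truth = ComparisonTruth(
        truth_a=truth_a, truth_b=truth_b,
        effect_class=pd.Series(classes, index=genes, name="effect_class"))
    return ds_a, ds_b, truth
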