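"""Run configuration.

A single flat key/value file (YAML subset) holds every threshold used by the
pipeline, so that one auditable record exists per run.  All thresholds default
to the values used throughout the analysis: a meta FDR of 0.1 combined with a
minimum absolute meta log2 fold-change of 0.1 and a common per-dataset
direction defines differential expression; consensus modules need at least 50
genes and are merged when their eigengenes correlate above 0.75 in every
dataset; hub genes sit above the 85th percentile of consensus module
membership; the soft-threshold exponent is the lowest integer whose scale-free
fit reaches 0.8.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their defaults.

    Parameters
    ----------
    alpha_meta:
        BH-corrected meta p-value threshold for calling a gene or module
        differentially expressed/regulated (unitless FDR level).
    lfc_min:
        Minimum absolute meta mean log2 fold-change (log2 units; for module
        eigengenes the same threshold is applied on the per-dataset
        standardized eigengene scale, i.e. SD units).
    min_module_size:
        Smallest gene count an accepted co-expression module may have.
    merge_cor_min:
        Modules are merged while their eigengene correlation, minimized
        across datasets, exceeds this value.
    hub_percentile:
        Within-module quantile of consensus module membership above which a
        gene is a hub.
    scale_free_r2_min:
        Required scale-free topology fit (R^2) when picking the
        soft-threshold exponent beta.
    beta_max:
        Largest integer beta scanned.
    calibration_quantile:
        Off-diagonal TOM quantile equalized across datasets before the
        parallel-minimum consensus.
    rrho_step_fraction:
        RRHO rank-grid step as a fraction of the gene-list length.
    ora_alpha:
        BH threshold for calling a gene-set term enriched.
    seed:
        Base seed for every stochastic component.
    """

    alpha_meta: float = 0.1
    lfc_min: float = 0.1
    min_module_size: int = 50
    merge_cor_min: float = 0.75
    hub_percentile: float = 0.85
    scale_free_r2_min: float = 0.8
    beta_max: int = 20
    calibration_quantile: float = 0.95
    rrho_step_fraction: float = 0.01
    ora_alpha: float = 0.05
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("alpha_meta", "merge_cor_min", "hub_percentile",
                     "scale_free_r2_min", "calibration_quantile",
                     "rrho_step_fraction", "ora_alpha"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v!r}")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be non-negative")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.beta_max < 1:
            raise ValueError("beta_max must be >= 1")
        self.min_module_size = int(self.min_module_size)
        self.beta_max = int(self.beta_max)
        self.seed = int(self.seed)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **overrides: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **overrides)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{k}: {v}\n" for k, v in self.to_dict().items())
        )

    def run_report(self, **extra: Any) -> dict[str, Any]:
        """JSON-serializable provenance record carried by every run."""
        report = {"config": self.to_dict(), "seed": self.seed}
        report.update(extra)
        return report

    def write_run_report(self, path: str | Path, **extra: Any) -> None:
        Path(path).write_text(json.dumps(self.run_report(**extra), indent=2,
                                         default=str) + "\n")


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> PipelineConfig:
    """Load a config file (flat ``key: value`` pairs); overrides win.

    With no path and no overrides this returns the documented defaults.
    Unknown keys raise, so silent typos cannot change a run.
    """
    values: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} is not a flat mapping")
        values.update(loaded)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**values)
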