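"""Flat key-value run configuration (YAML)."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .feature_assembly import CANCER_MARKS, ORIGIN_MARKS


@dataclass
class RunConfig:
    """Tunable parameters of a pipeline run.

    Defaults follow the best-performing operating point of the method:
    10 bp recurrence window, 100 kbp background window, recurrence p-value
    cutoff 5e-6, false:true ratio 3, motif match threshold 1e-4, 1000-tree
    forest evaluated by 10-repeated 5-fold CV.
    """

    recurrence_window: int = 10
    background_window: int = 100_000
    pvalue_cutoff: float = 5e-6
    raw_threshold: int = 4
    false_true_ratio: int = 3
    motif_alpha: float = 1e-4
    n_trees: int = 1000
    cv_folds: int = 5
    cv_repeats: int = 10
    seed: int = 0
    strip_chr_prefix: bool = False
    exclude_core_from_background: bool = False
    cgs_cumulative: bool = False
    regnet_hops: int = 3
    gwas_sentinel: float = 2.5e8
    early_late_cap: float = 100.0
    cancer_marks: tuple = CANCER_MARKS
    origin_marks: tuple = ORIGIN_MARKS
    paths: dict = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = {f.name: getattr(cfg, f.name) for f in fields(cfg)}
    data["cancer_marks"] = list(data["cancer_marks"])
    data["origin_marks"] = list(data["origin_marks"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
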