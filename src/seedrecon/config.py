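"""Declarative pipeline configuration (YAML) with strict validation.

Unknown keys are rejected; defaults equal the method's headline settings
(98% recruitment identity, multiplicity cap 3, 99% OTU clustering, 800 nt
report length, 99% reconstruction-success identity).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .assemble import AssemblyParams
from .recruit import RecruitParams
from .simulate import SimParams


@dataclass
class SeedParams:
    cluster_identity: float = 0.99
    n_samples: int | None = None  # None: use all samples
    top_k: int = 300
    min_len: int = 150
    max_len: int = 600
    reference: str | None = None  # FASTA of known 16S for novelty filtering
    filter_order: str = "before_topk"  # or after_topk
    rank_statistic: str = "max"

    def validate(self) -> list[str]:
        errs = []
        if not (0.5 < self.cluster_identity <= 1.0):
            errs.append("cluster_identity must be in (0.5, 1.0]")
        if self.top_k < 1:
            errs.append("top_k must be >= 1")
        if self.filter_order not in ("before_topk", "after_topk"):
            errs.append("filter_order must be before_topk or after_topk")
        if self.rank_statistic not in ("max", "mean"):
            errs.append("rank_statistic must be max or mean")
        return errs


@dataclass
class EvalParams:
    success_identity: float = 99.0
    seed_truth_identity: float = 99.0
    chimera_min_div: float = 3.0
    chimera_min_improve: float = 2.0

    def validate(self) -> list[str]:
        errs = []
        if not (50.0 <= self.success_identity <= 100.0):
            errs.append("success_identity must be in [50, 100]")
        return errs


@dataclass
class PipelineConfig:
    seed: int = 1
    simulate: SimParams = field(default_factory=SimParams)
    seeds: SeedParams = field(default_factory=SeedParams)
    recruit: RecruitParams = field(default_factory=RecruitParams)
    assemble: AssemblyParams = field(default_factory=AssemblyParams)
    evaluate: EvalParams = field(default_factory=EvalParams)
    run_simulation: bool = True
    run_evaluation: bool = True
    log_level: str = "INFO"

    def validate(self) -> list[str]:
        errs = []
        self_sim = dataclasses.replace(self.simulate, rng_seed=self.seed)
        for name, block in (
            ("simulate", self_sim), ("seeds", self.seeds), ("recruit", self.recruit),
            ("assemble", self.assemble), ("evaluate", self.evaluate),
        ):
            for e in block.validate():
                errs.append(f"{name}.{e}")
        return errs


def _build(cls: type, data: dict[str, Any], prefix: str, violations: list[str]):
    names = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in data.items():
        if key not in names:
            violations.append(f"unknown key: {prefix}{key}")
            continue
        f = names[key]
        if dataclasses.is_dataclass(f.type) or f.name in (
            "simulate", "seeds", "recruit", "assemble", "evaluate",
        ):
            sub_cls = {
                "simulate": SimParams, "seeds": SeedParams, "recruit": RecruitParams,
                "assemble": AssemblyParams, "evaluate": EvalParams,
            }.get(f.name)
            if sub_cls is not None and isinstance(val, dict):
                kwargs[key] = _build(sub_cls, val, f"{prefix}{key}.", violations)
                continue
        if isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        violations.append(f"{prefix[:-1] or 'config'}: {exc}")
        return cls()


def load_config(path: str | Path) -> PipelineConfig:
    cfg, violations = try_load_config(path)
    if violations:
        raise ValueError("invalid config:\n" + "\n".join(f"  - {v}" for v in violations))
    return cfg


def try_load_config(path: str | Path) -> tuple[PipelineConfig, list[str]]:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        return PipelineConfig(), ["config root must be a mapping"]
    violations: list[str] = []
    cfg = _build(PipelineConfig, raw, "", violations)
    violations.extend(cfg.validate())
    return cfg, violations


def validate_config(path: str | Path) -> list[str]:
    """Pure check: empty list means the config is valid."""
    _, violations = try_load_config(path)
    return violations
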