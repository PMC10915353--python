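"""Run configuration: one validated record of every tunable, loadable from YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All tunables of the inference pipeline with their defaults.

    Unknown keys in a YAML file are rejected so typos cannot silently fall
    back to defaults.
    """

    xi: float = 0.1
    gamma: float = 0.0
    c_shrink: float = 0.0
    lam_grid: list | None = None
    n_grid: int = 12
    max_outer_iters: int = 20
    weight_tol: float = 1e-4
    sparsify_threshold: float = 1e-3
    pard_tol: float = 1e-3
    pard_max_iter: int = 200
    s_beta: float = 1e-2
    r_beta: float = 1e-2
    linkage: str = "complete"
    min_cluster_size: int = 10
    deep_split: int = 2
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.xi <= 1.0:
            raise ValueError("xi must lie in [0, 1]")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if not 0.0 <= self.c_shrink < 1.0:
            raise ValueError("c_shrink must lie in [0, 1)")
        if self.linkage.lower() not in {"ward", "ward.d2", "complete", "average"}:
            raise ValueError(f"unsupported linkage: {self.linkage}")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be at least 1")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(
            f"{path}: unknown configuration key(s): {', '.join(unknown)}; "
            f"known keys are: {', '.join(sorted(known))}")
    return RunConfig(**raw)
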