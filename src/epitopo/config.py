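"""Run configuration: one YAML file driving all three models.

A flat key-value schema with range validation; unknown keys are rejected so
typos fail loudly.  All randomness flows from the single ``seed`` —
per-module generators are spawned deterministically from it.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

__all__ = ["RunConfig", "run_config"]

log = logging.getLogger("epitopo")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    # kernel
    weights: str = "gpnp"
    min_sides: int = 4
    # markov chain
    chain_tol: float = 1e-12
    chain_max_iter: int = 10_000
    chain_s_max: int = 64
    # markov process
    process_n0: int = 1000
    process_target_n: int = 1_000_000
    lam: float = 1.0
    distinct_recipients: bool = False
    # scem
    scem_seed_cells: int = 37
    scem_n0: int = 32
    target_cells: int = 150
    alpha: float = 0.55
    p_rep: float = 0.01
    core_fraction: float = 0.5
    # neighbor stats
    delta_grid: tuple = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0)
    min_contacts: int = 1
    margin: float | None = None

    def __post_init__(self) -> None:
        if self.weights not in ("gpnp", "strict"):
            raise ValueError(f"weights must be gpnp or strict, got {self.weights!r}")
        if self.min_sides not in (2, 3, 4):
            raise ValueError(f"min_sides must be 2, 3 or 4, got {self.min_sides}")
        if not 0.5 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0.5, 1.0), got {self.alpha}")
        if self.chain_tol <= 0:
            raise ValueError("chain_tol must be positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if any(not 1.0 <= d <= 2.0 for d in self.delta_grid):
            raise ValueError("delta_grid values must lie within [1.0, 2.0]")
        if self.min_contacts not in (1, 2):
            raise ValueError("min_contacts must be 1 or 2")
        object.__setattr__(self, "delta_grid", tuple(self.delta_grid))

    def rng(self, module: str) -> np.random.Generator:
        """Deterministic per-module substream of the master seed."""
        import zlib

        key = zlib.crc32(module.encode())
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)

    def log_resolved(self) -> None:
        log.info("resolved config: %s", asdict(self))


def run_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.log_resolved()
    return cfg
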