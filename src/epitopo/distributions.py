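"""Cell-sidedness (cell-neighbor-number) distributions.

The common output container of the chain, process and spatial models: the
fraction of cells in each sidedness class.  Internally a dense probability
vector indexed directly by sidedness, so ``probs[s]`` is the fraction of
s-sided cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SidednessDistribution"]


@dataclass(frozen=True)
class SidednessDistribution:
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 1 or len(p) < 3:
            raise ValueError("probs must be a 1-d vector indexed by sidedness")
        if np.any(p < -1e-12):
            raise ValueError("negative fraction in sidedness distribution")
        total = p.sum()
        if not np.isclose(total, 1.0, rtol=0, atol=1e-9):
            raise ValueError(f"fractions must sum to 1, got {total!r}")

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "SidednessDistribution":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("empty population has no sidedness distribution")
        return cls(counts / total)

    @classmethod
    def delta(cls, s: int, s_max: int | None = None) -> "SidednessDistribution":
        """Point mass at sidedness ``s``."""
        n = (s_max if s_max is not None else s) + 1
        p = np.zeros(n)
        p[s] = 1.0
        return cls(p)

    @classmethod
    def from_dict(cls, fractions: dict[int, float]) -> "SidednessDistribution":
        s_max = max(fractions)
        p = np.zeros(s_max + 1)
        for s, f in fractions.items():
            if s < 0:
                raise ValueError("sidedness must be non-negative")
            p[s] = f
        return cls(p)

    @property
    def s_max(self) -> int:
        return len(self.probs) - 1

    def __getitem__(self, s: int) -> float:
        if s < 0:
            raise IndexError("sidedness must be non-negative")
        return float(self.probs[s]) if s < len(self.probs) else 0.0

    def mean(self) -> float:
        return float(np.arange(len(self.probs)) @ self.probs)

    def mode(self) -> int:
        """Sidedness of the most populated class (smallest wins ties)."""
        return int(np.argmax(self.probs))

    def support(self) -> np.ndarray:
        return np.nonzero(self.probs > 0)[0]

    def padded(self, s_max: int) -> np.ndarray:
        """Probability vector zero-padded/truncation-checked to length s_max+1."""
        if s_max >= self.s_max:
            return np.pad(self.probs, (0, s_max - self.s_max))
        if np.any(self.probs[s_max + 1 :] != 0):
            raise ValueError("cannot truncate a distribution with tail mass")
        return self.probs[: s_max + 1]

    def l1(self, other: "SidednessDistribution") -> float:
        n = max(self.s_max, other.s_max)
        return float(np.abs(self.padded(n) - other.padded(n)).sum())

    def tail_mass(self, s_from: int) -> float:
        return float(self.probs[s_from:].sum()) if s_from <= self.s_max else 0.0

    def to_series(self):
        import pandas as pd

        sup = self.support()
        return pd.Series(self.probs[sup], index=pd.Index(sup, name="sides"),
                         name="fraction")
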