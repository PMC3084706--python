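"""CSV interchange: sidedness histograms, sheet snapshots, division logs.

The histogram CSV (columns ``sides,fraction``) is the single interchange
format across the chain, process and spatial models, so their outputs are
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .distributions import SidednessDistribution
from .scem import DivisionEvent, GrowthParams, PotentialParams, Sheet

__all__ = [
    "HistogramRecord",
    "read_histogram_csv",
    "write_histogram_csv",
    "write_snapshot_csv",
    "read_snapshot_csv",
    "write_event_log_csv",
    "read_event_log_csv",
]


@dataclass(frozen=True)
class HistogramRecord:
    label: str
    distribution: SidednessDistribution
    n_cells: int | None = None


def write_histogram_csv(h: SidednessDistribution, path) -> None:
    h.to_series().to_csv(path)


def read_histogram_csv(path) -> SidednessDistribution:
    df = pd.read_csv(path)
    if list(df.columns) != ["sides", "fraction"]:
        raise ValueError(
            f"{path}: expected header 'sides,fraction', got {list(df.columns)}"
        )
    if df["sides"].le(0).any() or (df["sides"] != df["sides"].astype(int)).any():
        raise ValueError(f"{path}: sidedness keys must be positive integers")
    if df["fraction"].lt(0).any():
        raise ValueError(f"{path}: negative fraction")
    total = df["fraction"].sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{path}: fractions sum to {total!r}, not 1")
    return SidednessDistribution.from_dict(
        dict(zip(df["sides"].astype(int), df["fraction"]))
    )


def write_snapshot_csv(sheet: Sheet, path) -> None:
    pd.DataFrame({
        "element_id": np.arange(sheet.n_elements),
        "cell_id": sheet.cell_of,
        "x": sheet.pos[:, 0],
        "y": sheet.pos[:, 1],
    }).to_csv(path, index=False)


def read_snapshot_csv(path, params: PotentialParams | None = None) -> Sheet:
    df = pd.read_csv(path)
    required = ["element_id", "cell_id", "x", "y"]
    if list(df.columns) != required:
        raise ValueError(f"{path}: expected header {','.join(required)}")
    cell_of = df["cell_id"].to_numpy(dtype=np.int64)
    n_min = int(np.bincount(cell_of - cell_of.min()).max())
    return Sheet(
        pos=np.ascontiguousarray(df[["x", "y"]].to_numpy(dtype=float)),
        cell_of=cell_of,
        params=params or PotentialParams(),
        growth=GrowthParams(n0=max(2, n_min)),
        next_cell_id=int(cell_of.max()) + 1,
    )


def write_event_log_csv(events, path) -> None:
    pd.DataFrame(
        [
            {
                "time": e.time,
                "mother": e.mother,
                "daughter1": e.daughter1,
                "daughter2": e.daughter2,
                "axis_angle": e.axis_angle,
            }
            for e in events
        ],
        columns=["time", "mother", "daughter1", "daughter2", "axis_angle"],
    ).to_csv(path, index=False)


def read_event_log_csv(path) -> list[DivisionEvent]:
    df = pd.read_csv(path)
    return [
        DivisionEvent(r.time, int(r.mother), int(r.daughter1),
                      int(r.daughter2), r.axis_angle)
        for r in df.itertuples()
    ]
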