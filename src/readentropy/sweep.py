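"""Entropy-loss profiles across read lengths and the minimal read length.

A profile evaluates the relative entropy loss dH at each read length on
a grid; the minimal read length is the smallest grid point whose loss
falls strictly below a threshold (default 1%).  No interpolation between
grid points is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .entropy_core import EntropyResult, assess
from .errors import DegenerateInputError
from .fasta_io import SequenceRecord, write_tsv

DEFAULT_GRID: tuple[int, ...] = tuple(range(20, 121, 10))
DEFAULT_THRESHOLD = 0.01


@dataclass(frozen=True)
class EntropyProfile:
    """dH-vs-k curve for one target: one EntropyResult per grid point.

    A grid point whose computation was degenerate (e.g. every record
    shorter than k) carries None instead of a result.
    """

    target_label: str
    grid: tuple[int, ...]
    results: tuple[Optional[EntropyResult], ...]

    def delta_H(self, k: int) -> Optional[float]:
        """Loss fraction at grid point k, or None if degenerate there."""
        res = self.results[self.grid.index(k)]
        return None if res is None else res.delta_H


def _validate_grid(grid: Sequence[int]) -> tuple[int, ...]:
    grid = tuple(int(k) for k in grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    if any(k < 1 for k in grid):
        raise ValueError("grid read lengths must be >= 1")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")
    return grid


def entropy_profile(
    records: Iterable[SequenceRecord],
    grid: Sequence[int] = DEFAULT_GRID,
    prefix_length: int = 0,
    target_label: str = "target",
) -> EntropyProfile:
    """Assess a sequence set at every read length on the grid.

    Grid points where the input is degenerate (no valid windows) are
    recorded as None rather than aborting the profile.
    """
    grid = _validate_grid(grid)
    records = list(records)
    results: list[Optional[EntropyResult]] = []
    for k in grid:
        try:
            results.append(assess(records, k, prefix_length))
        except DegenerateInputError:
            results.append(None)
    return EntropyProfile(target_label=target_label, grid=grid, results=tuple(results))


def min_read_length(profile: EntropyProfile, threshold: float = DEFAULT_THRESHOLD) -> Optional[int]:
    """Smallest grid read length with dH strictly below threshold.

    Returns None when no grid point is below the threshold ("not
    reached").  Degenerate grid points never qualify.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if not profile.grid:
        raise ValueError("empty profile")
    for k, res in zip(profile.grid, profile.results):
        if res is not None and res.delta_H < threshold:
            return k
    return None


def recommend_insert_size(min_k: Optional[int]) -> Optional[tuple[int, int]]:
    """Heuristic paired-end insert-size range [4*k, 6*k] for a minimal read length.

    Short inserts spanning just past the dominant repeat length resolve
    local ambiguities better than kilobase inserts.  Returns None when
    no minimal read length was reached.
    """
    if min_k is None:
        return None
    if min_k < 1:
        raise ValueError(f"read length must be >= 1, got {min_k}")
    return (4 * min_k, 6 * min_k)


def write_profile_tsv(profile: EntropyProfile, path: str | Path) -> None:
    """Serialize a profile as TSV (percentages with 6 decimals)."""
    rows = []
    for k, res in zip(profile.grid, profile.results):
        if res is None:
            rows.append(
                {"k": k, "H": float("nan"), "H_max": float("nan"),
                 "delta_H": float("nan"), "repeat": float("nan"),
                 "total_instances": 0, "n_distinct": 0, "status": "degenerate"}
            )
        else:
            rows.append(
                {"k": k, "H": res.H, "H_max": res.H_max, "delta_H": res.delta_H,
                 "repeat": res.repeat_fraction, "total_instances": res.total_instances,
                 "n_distinct": res.n_distinct, "status": "ok"}
            )
    write_tsv(
        rows,
        path,
        column_order=["k", "H", "H_max", "delta_H", "repeat",
                      "total_instances", "n_distinct", "status"],
        percent_columns=["delta_H", "repeat"],
        percent_decimals=6,
    )
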