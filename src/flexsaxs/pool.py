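"""Pool reduction and augmentation.

A Monte Carlo run easily produces tens of thousands of conformers — too
many to compute scattering profiles for.  A stride/offset sub-selection
keeps every nth accepted frame; an Rg-histogram comparison (total-variation
distance) lets the user judge whether the reduced pool still represents
the full pool's size distribution.  After ensemble preselection, frames
adjacent to the selected ones (skipped by the stride) can be pulled back
in for the final refinement round.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "ReductionSpec",
    "reduce_pool",
    "rg_histogram_compare",
    "augment_adjacent",
    "HistogramComparison",
]


@dataclass(frozen=True)
class ReductionSpec:
    """Keep every ``stride``-th frame after skipping the first ``offset``."""

    stride: int = 10
    offset: int = 0

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


def reduce_pool(pool_size: int, spec: ReductionSpec) -> list[int]:
    """1-based positions kept by a stride/offset reduction.

    Positions are offset+1, offset+1+stride, ... up to ``pool_size``; the
    count is floor((pool_size - offset - 1)/stride) + 1.  Extracted frames
    keep their original model numbers (see
    :meth:`~flexsaxs.structure.ConformerPool.subset_by_position`).
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if spec.offset >= pool_size:
        raise ValueError(
            f"offset {spec.offset} must be smaller than the pool size {pool_size}"
        )
    return list(range(spec.offset + 1, pool_size + 1, spec.stride))


class HistogramComparison(NamedTuple):
    hist_full: np.ndarray
    hist_reduced: np.ndarray
    bin_edges: np.ndarray
    tv_distance: float


def rg_histogram_compare(
    rg_full: Sequence[float],
    rg_reduced: Sequence[float],
    bin_width: float = 1.0,
) -> HistogramComparison:
    """Unit-mass Rg histograms of full vs reduced pool on shared bins.

    The total-variation distance 0.5*sum|h_full - h_reduced| in [0, 1] is
    reported for the user's judgment; the workflow sets no hard threshold.
    """
    full = np.asarray(rg_full, dtype=float)
    red = np.asarray(rg_reduced, dtype=float)
    if full.size == 0 or red.size == 0:
        raise ValueError("Rg lists must be non-empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(min(full.min(), red.min()) / bin_width) * bin_width
    hi = np.ceil(max(full.max(), red.max()) / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    h_full, _ = np.histogram(full, bins=edges)
    h_red, _ = np.histogram(red, bins=edges)
    h_full = h_full / h_full.sum()
    h_red = h_red / h_red.sum()
    tv = 0.5 * float(np.abs(h_full - h_red).sum())
    return HistogramComparison(h_full, h_red, edges, tv)


def augment_adjacent(
    selected_frames: Sequence[int],
    k: int,
    stride: int,
    pool_size: int,
) -> list[int]:
    """Add up to ``k`` flanking frames on both sides of each selection.

    Frames skipped by the stride but adjacent (in the original accepted
    pool) to preselected models may fit better; ``k`` may not exceed half
    the stride, which guarantees augmented neighborhoods of consecutive
    kept frames cannot leapfrog each other.  Returns the sorted,
    deduplicated union clipped to [1, pool_size].
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > stride // 2:
        raise ValueError(
            f"adjacent frame count {k} exceeds half the stride ({stride // 2})"
        )
    out: set[int] = set()
    for f in selected_frames:
        if not 1 <= f <= pool_size:
            raise ValueError(f"frame {f} outside pool [1, {pool_size}]")
        lo = max(1, f - k)
        hi = min(pool_size, f + k)
        out.update(range(lo, hi + 1))
    return sorted(out)
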