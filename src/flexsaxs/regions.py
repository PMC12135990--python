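"""Flexible-region detection from per-residue model confidence.

AlphaFold's pLDDT (0-100, stored in the B-factor column) is low in
disordered linkers and tails; maximal runs of at least ``min_run``
consecutive residues with confidence strictly below a threshold are
candidate flexible regions for Monte Carlo torsion sampling.  Manually
entered ranges go through the same validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "FlexibleRegion",
    "detect_flexible_regions",
    "validate_alignment_range",
    "flexible_residues",
    "parse_region",
]


@dataclass(frozen=True, order=True)
class FlexibleRegion:
    """A 1-based, inclusive residue range [start, end]."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, residue: int) -> bool:
        return self.start <= residue <= self.end

    def overlaps(self, other: "FlexibleRegion") -> bool:
        return self.start <= other.end and other.start <= self.end

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


def parse_region(text: str) -> FlexibleRegion:
    """Parse ``"start:end"`` or ``"start-end"`` into a region."""
    sep = ":" if ":" in text else "-"
    try:
        start, end = (int(p) for p in text.split(sep))
    except ValueError:
        raise ValueError(f"cannot parse residue range {text!r}") from None
    return FlexibleRegion(start, end)


def detect_flexible_regions(
    confidence: Sequence[float],
    threshold: float = 60.0,
    min_run: int = 5,
) -> list[FlexibleRegion]:
    """Find maximal low-confidence runs of length >= ``min_run``.

    A residue is flexible when its confidence is strictly below
    ``threshold``; runs touching the termini are eligible (disordered
    tails count).  Returned regions are sorted, disjoint and maximal.
    """
    if len(confidence) == 0:
        raise ValueError("confidence list is empty")
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    regions: list[FlexibleRegion] = []
    start = None
    for i, c in enumerate(confidence, start=1):
        if c < threshold:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_run:
                regions.append(FlexibleRegion(start, i - 1))
            start = None
    if start is not None and len(confidence) - start + 1 >= min_run:
        regions.append(FlexibleRegion(start, len(confidence)))
    return regions


def validate_alignment_range(
    regions: Sequence[FlexibleRegion],
    align_range: FlexibleRegion,
    n_residues: int,
) -> None:
    """Check that the alignment range is rigid and inside the sequence.

    The range used to superpose sampled conformers must not intersect any
    flexible region (aligning on moving residues would be meaningless).
    Raises ``ValueError`` naming the offending region on failure.
    """
    if align_range.start < 1 or align_range.end > n_residues:
        raise ValueError(
            f"alignment range {align_range} outside sequence 1-{n_residues}"
        )
    for region in regions:
        if align_range.overlaps(region):
            raise ValueError(
                f"alignment range {align_range} overlaps flexible region {region}"
            )


def flexible_residues(regions: Sequence[FlexibleRegion]) -> list[int]:
    """All residue indices covered by the regions, sorted, deduplicated."""
    out: set[int] = set()
    for r in regions:
        out.update(range(r.start, r.end + 1))
    return sorted(out)
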