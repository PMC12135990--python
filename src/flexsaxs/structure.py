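"""Protein structure I/O and in-memory containers.

Structures are read from PDB or mmCIF files (via gemmi) into a flat,
ordered list of atoms carrying coordinates, element-derived constants
(electron count, mass) and the per-residue model confidence that AlphaFold
stores in the B-factor column.  Only single-chain proteins are accepted.

Conformer pools (the output of the Monte Carlo sampler) are exchanged as
NMR-style multi-model PDB files, one MODEL/ENDMDL block per frame.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .elements import atomic_mass, electrons

__all__ = [
    "Atom",
    "Structure",
    "ConformerPool",
    "read_structure",
    "write_multimodel_pdb",
    "read_multimodel_pdb",
    "write_curves_csv",
]


@dataclass
class Atom:
    """One atom: identity, element-derived constants and coordinates.

    ``confidence`` is the per-residue model confidence (pLDDT, 0-100)
    copied from the B-factor column when the source is a predicted model;
    for experimental structures it simply carries the B factor.
    """

    name: str
    element: str
    electrons: int
    mass: float
    residue_index: int
    residue_name: str
    coords: np.ndarray  # shape (3,), Å
    confidence: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.electrons < 1:
            raise ValueError(f"atom {self.name}: electron count must be >= 1")
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be positive")
        if self.residue_index < 1:
            raise ValueError("residue_index is 1-based and must be >= 1")


@dataclass
class Structure:
    """A single-chain protein: ordered atoms plus file-level metadata."""

    atoms: list[Atom]
    chain_id: str = "A"
    title: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        idx = [a.residue_index for a in self.atoms]
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise ValueError("atoms must be grouped with non-decreasing residue_index")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array, Å (a copy)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def molecular_mass(self) -> float:
        """Sum of atomic masses, Da (conformation-independent)."""
        return float(sum(a.mass for a in self.atoms))

    @property
    def electron_counts(self) -> np.ndarray:
        return np.array([a.electrons for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def residue_indices(self) -> list[int]:
        """Sorted unique residue indices."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen[a.residue_index] = None
        return list(seen)

    @property
    def n_residues(self) -> int:
        return len(self.residue_indices)

    def residue_confidence(self) -> list[float]:
        """Per-residue confidence, one value per residue in sequence order.

        Uses the B-factor/confidence of the first atom of each residue
        (AlphaFold writes identical values for every atom of a residue).
        """
        out: list[float] = []
        seen: set[int] = set()
        for a in self.atoms:
            if a.residue_index not in seen:
                seen.add(a.residue_index)
                out.append(a.confidence)
        return out

    def atom_indices_for_residues(self, residues: Iterable[int]) -> np.ndarray:
        wanted = set(residues)
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.residue_index in wanted],
            dtype=int,
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """A copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms, self.chain_id, self.title, self.source)


@dataclass
class ConformerPool:
    """Accepted Monte Carlo frames, numbered by position in the output pool.

    ``frames`` maps 1-based, strictly increasing model numbers (positions in
    the accepted pool) to structures sharing one atom ordering.
    ``trial_index`` records, per frame, the 1-based trial that produced it;
    ``acceptance_log`` has one accepted/rejected flag per trial.
    """

    frames: list[tuple[int, Structure]]
    acceptance_log: list[bool] = field(default_factory=list)
    rg: np.ndarray = field(default_factory=lambda: np.array([]))
    trial_index: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        nums = [n for n, _ in self.frames]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError("model numbers must be strictly increasing")
        counts = {len(s.atoms) for _, s in self.frames}
        if len(counts) > 1:
            raise ValueError("all frames must have identical atom counts")
        self.rg = np.asarray(self.rg, dtype=float)
        if self.rg.size and np.any(self.rg <= 0):
            raise ValueError("per-frame Rg must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def model_numbers(self) -> list[int]:
        return [n for n, _ in self.frames]

    def subset_by_position(self, positions: Sequence[int]) -> "ConformerPool":
        """New pool holding the frames at the given 1-based positions.

        Frames keep their original model numbers, so downstream reports
        always index the original pool.
        """
        for p in positions:
            if not 1 <= p <= len(self.frames):
                raise IndexError(f"position {p} outside pool of {len(self.frames)}")
        frames = [self.frames[p - 1] for p in positions]
        rg = self.rg[[p - 1 for p in positions]] if self.rg.size else np.array([])
        trials = [self.trial_index[p - 1] for p in positions] if self.trial_index else []
        return ConformerPool(frames, [], rg, trials)


# ---------------------------------------------------------------------------
# reading


def _element_from_name(name: str) -> str:
    """Heuristic element guess from an atom name (PDB files lacking col 77-78)."""
    stripped = name.strip()
    # two-letter elements in proteins are rare; digits and primes are remote marks
    letters = "".join(ch for ch in stripped if ch.isalpha())
    if not letters:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    if letters[:2].upper() in ("SE",) and stripped.upper().startswith("SE"):
        return "SE"
    return letters[0].upper()


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a single-chain protein structure from PDB or mmCIF.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (sniff from the extension /
        content via gemmi).

    Confidence is copied from the B-factor column; elements come from the
    element column with an atom-name fallback; unknown elements raise.
    Multi-chain files are rejected (single-chain pipeline).
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format in ("mmcif", "cif"):
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
        elif format == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise ValueError(f"could not parse {path.name}: {exc}") from exc

    if len(st) == 0:
        raise ValueError(f"{path.name}: no models found")
    model = st[0]
    chains = [ch.name for ch in model]
    if len(chains) != 1:
        raise ValueError(
            f"{path.name}: expected a single chain, found {len(chains)}: "
            + ", ".join(chains)
        )
    chain = model[0]

    atoms: list[Atom] = []
    for residue in chain:
        seqid = residue.seqid.num
        for at in residue:
            elem = at.element.name.upper() if at.element and at.element.name else ""
            if not elem or elem == "X":
                elem = _element_from_name(at.name)
            try:
                z = electrons(elem)
                m = atomic_mass(elem)
            except KeyError:
                raise ValueError(
                    f"{path.name}: unknown element {elem!r} "
                    f"(atom {at.name} in residue {residue.name} {seqid})"
                ) from None
            atoms.append(
                Atom(
                    name=at.name,
                    element=elem,
                    electrons=z,
                    mass=m,
                    residue_index=seqid,
                    residue_name=residue.name,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    confidence=float(at.b_iso),
                )
            )
    if not atoms:
        raise ValueError(f"{path.name}: chain {chain.name} contains no atoms")
    title = st.name or ""
    return Structure(atoms, chain_id=chain.name, title=title, source=str(path))


# ---------------------------------------------------------------------------
# writing


def _pdb_atom_line(serial: int, a: Atom, chain_id: str) -> str:
    name = a.name
    if len(name) < 4:
        # standard alignment: 1-letter elements start in column 14
        name = f" {name:<3s}" if len(a.element) == 1 else f"{name:<4s}"
    x, y, z = a.coords
    elem = a.element.upper()
    return (
        f"ATOM  {serial:5d} {name:4s} {a.residue_name:>3s} {chain_id:1s}"
        f"{a.residue_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{1.00:6.2f}{a.confidence:6.2f}          {elem:>2s}"
    )


def write_multimodel_pdb(pool: ConformerPool, path: str | Path) -> None:
    """Write a pool as an NMR-style multi-model PDB.

    One MODEL/ENDMDL block per frame; the MODEL serial is the frame's model
    number, so frame identity survives the round trip.
    """
    if len(pool) == 0:
        raise ValueError("cannot write an empty pool")
    n_atoms = len(pool.frames[0][1].atoms)
    for num, s in pool.frames:
        if len(s.atoms) != n_atoms:
            raise ValueError("inconsistent atom counts across frames")
    lines: list[str] = []
    for num, s in pool.frames:
        lines.append(f"MODEL     {num:4d}")
        for i, a in enumerate(s.atoms, start=1):
            lines.append(_pdb_atom_line(i, a, s.chain_id))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_multimodel_pdb(path: str | Path) -> ConformerPool:
    """Read a multi-model PDB written by :func:`write_multimodel_pdb`."""
    import gemmi

    st = gemmi.read_pdb(str(Path(path)))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    frames: list[tuple[int, Structure]] = []
    for model in st:
        chain = model[0]
        atoms: list[Atom] = []
        for residue in chain:
            for at in residue:
                elem = at.element.name.upper()
                if not elem or elem == "X":
                    elem = _element_from_name(at.name)
                atoms.append(
                    Atom(
                        name=at.name,
                        element=elem,
                        electrons=electrons(elem),
                        mass=atomic_mass(elem),
                        residue_index=residue.seqid.num,
                        residue_name=residue.name,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        confidence=float(at.b_iso),
                    )
                )
        num = int(model.num) if model.num > 0 else len(frames) + 1
        frames.append((num, Structure(atoms, chain_id=chain.name)))
    from .profiles import rg_from_coords

    rg = np.array([rg_from_coords(s) for _, s in frames])
    return ConformerPool(frames, [], rg)


def write_curves_csv(
    curves: Sequence,
    labels: Sequence[str],
    path: str | Path,
    grid_label: str | None = None,
) -> None:
    """Write curves sharing one abscissa grid as a labelled CSV.

    Column 1 is the shared grid (q or r); one column per curve follows.
    Accepts any objects exposing ``.grid``/``.values`` pairs — in practice
    :class:`~flexsaxs.profiles.ScatteringCurve` (q, intensity) and
    :class:`~flexsaxs.profiles.PofR` (r, p).
    """
    if len(curves) == 0:
        raise ValueError("no curves to write")
    if len(labels) != len(curves):
        raise ValueError("need one label per curve")

    def grid_of(c):
        return getattr(c, "q", None) if hasattr(c, "q") else getattr(c, "r", None)

    def values_of(c):
        return c.intensity if hasattr(c, "q") else c.p

    grid = np.asarray(grid_of(curves[0]), dtype=float)
    for c in curves[1:]:
        g = np.asarray(grid_of(c), dtype=float)
        if g.shape != grid.shape or not np.allclose(g, grid, rtol=0, atol=1e-12):
            raise ValueError("curves do not share one abscissa grid")
    if grid_label is None:
        grid_label = "q" if hasattr(curves[0], "q") else "r"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([grid_label, *labels])
        cols = [np.asarray(values_of(c), dtype=float) for c in curves]
        for i in range(grid.size):
            writer.writerow(
                [f"{grid[i]:.12e}", *(f"{col[i]:.12e}" for col in cols)]
            )
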