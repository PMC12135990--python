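"""Monte Carlo conformer generation by backbone torsion sampling.

Each trial perturbs one phi or psi dihedral of one residue inside a
flexible region by a uniform angle in [-max_angle, +max_angle], rotating
everything C-terminal of the pivot bond rigidly.  Trials producing steric
clashes (hard-sphere overlap on a chosen atom basis) are rejected; after a
run of consecutive rejections the working coordinates reset to the last
accepted frame.  Accepted frames are superposed on the starting structure
over a rigid alignment range and collected into a :class:`ConformerPool`.

There is no force-field energy here: selection pressure in this pipeline
comes from the downstream SAXS fit, not from sampler energetics.  The
config accepts a temperature for interface parity; it only matters if a
user-supplied torsion-energy callback is provided, in which case Metropolis
acceptance at that temperature applies on top of the clash check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .elements import vdw_radius
from .regions import FlexibleRegion, flexible_residues, validate_alignment_range
from .structure import ConformerPool, Structure

__all__ = [
    "MCConfig",
    "TorsionMove",
    "apply_torsion",
    "check_overlap",
    "bond_exclusions",
    "superpose",
    "run_mc",
]

CLASH_VDW_SCALE = 0.8  # clash when d < 0.8*(vdw_i + vdw_j)
BOLTZMANN_KCAL = 0.0019872041  # kcal/(mol K)


@dataclass
class MCConfig:
    """Run parameters for the torsion Monte Carlo sampler."""

    trial_attempts: int = 50000
    max_angle: float = 30.0  # degrees per move
    temperature: float = 300.0  # K; inert without an energy callback
    return_after_fails: int = 20
    overlap_basis: str = "heavy"  # heavy | backbone | all
    align_range: Optional[FlexibleRegion] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trial_attempts < 0:
            raise ValueError("trial_attempts must be >= 0")
        if not 0 < self.max_angle <= 180:
            raise ValueError("max_angle must be in (0, 180] degrees")
        if self.return_after_fails < 1:
            raise ValueError("return_after_fails must be >= 1")
        if self.overlap_basis not in ("heavy", "backbone", "all"):
            raise ValueError(f"unknown overlap basis {self.overlap_basis!r}")


@dataclass(frozen=True)
class TorsionMove:
    """Rotate one backbone dihedral of one residue by ``delta`` degrees."""

    residue_index: int
    angle_name: str  # "phi" | "psi"
    delta: float

    def __post_init__(self) -> None:
        if self.angle_name not in ("phi", "psi"):
            raise ValueError(f"unknown torsion {self.angle_name!r}")


# ---------------------------------------------------------------------------
# topology helpers

_BACKBONE = ("N", "CA", "C", "O")


def _backbone_index(structure: Structure) -> dict[tuple[int, str], int]:
    """(residue_index, atom_name) -> flat atom index for backbone atoms."""
    out: dict[tuple[int, str], int] = {}
    for i, a in enumerate(structure.atoms):
        if a.name in _BACKBONE and (a.residue_index, a.name) not in out:
            out[(a.residue_index, a.name)] = i
    return out


def _moved_atom_mask(structure: Structure, move: TorsionMove) -> np.ndarray:
    """Boolean mask of atoms C-terminal of the rotated bond (N->C sense).

    phi (N-CA axis): everything attached through CA moves — the sidechain,
    the carbonyl group and every later residue (CA itself lies on the axis;
    only the amide group N/H stays put).  Keeping the sidechain with the
    rotating branch is what preserves the fixed bond angles around CA.
    psi (CA-C axis): the carbonyl oxygen and every later residue move; the
    sidechain stays with CA.
    """
    mask = np.zeros(len(structure), dtype=bool)
    if move.angle_name == "phi":
        stays = {"N", "H", "HN", "H1", "H2", "H3"}
        for i, a in enumerate(structure.atoms):
            if a.residue_index > move.residue_index:
                mask[i] = True
            elif a.residue_index == move.residue_index and a.name not in stays:
                mask[i] = True
    else:
        moves = {"O", "OXT"}
        for i, a in enumerate(structure.atoms):
            if a.residue_index > move.residue_index:
                mask[i] = True
            elif a.residue_index == move.residue_index and a.name in moves:
                mask[i] = True
    return mask


def apply_torsion(structure: Structure, move: TorsionMove) -> Structure:
    """Rigidly rotate the atoms downstream of a phi/psi bond by ``delta``.

    Internal geometry of the moved set is preserved exactly (one rigid
    rotation); all other atoms are untouched.  Raises at the termini where
    the torsion is undefined (phi of residue 1, psi of the last residue).
    """
    res_ids = structure.residue_indices
    if move.residue_index not in set(res_ids):
        raise ValueError(f"residue {move.residue_index} not in structure")
    if move.angle_name == "phi" and move.residue_index == res_ids[0]:
        raise ValueError("phi is undefined for the first residue")
    if move.angle_name == "psi" and move.residue_index == res_ids[-1]:
        raise ValueError("psi is undefined for the last residue")

    bb = _backbone_index(structure)
    if move.angle_name == "phi":
        a_key, b_key = (move.residue_index, "N"), (move.residue_index, "CA")
    else:
        a_key, b_key = (move.residue_index, "CA"), (move.residue_index, "C")
    try:
        ia, ib = bb[a_key], bb[b_key]
    except KeyError as exc:
        raise ValueError(f"missing backbone atom {exc} for torsion") from None

    coords = structure.coords
    origin = coords[ia]
    axis = coords[ib] - origin
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("degenerate torsion axis (coincident atoms)")
    axis = axis / norm

    theta = math.radians(move.delta)
    mask = _moved_atom_mask(structure, move)
    rel = coords[mask] - origin
    # Rodrigues rotation about the unit axis
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    rotated = (
        rel * cos_t
        + np.cross(axis, rel) * sin_t
        + np.outer(rel @ axis, axis) * (1.0 - cos_t)
    )
    new_coords = coords.copy()
    new_coords[mask] = rotated + origin
    return structure.with_coords(new_coords)


# ---------------------------------------------------------------------------
# clash detection

_COVALENT_MAX = {"H": 1.3}  # element-specific bond-length caps; default below
_COVALENT_DEFAULT = 1.95


def _bonds(structure: Structure) -> list[tuple[int, int]]:
    """Covalent bonds inferred from interatomic distances."""
    coords = structure.coords
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=_COVALENT_DEFAULT, output_type="ndarray")
    bonds = []
    for i, j in pairs:
        ei = structure.atoms[i].element.upper()
        ej = structure.atoms[j].element.upper()
        cap = min(
            _COVALENT_MAX.get(ei, _COVALENT_DEFAULT),
            _COVALENT_MAX.get(ej, _COVALENT_DEFAULT),
        )
        if np.linalg.norm(coords[i] - coords[j]) <= cap:
            bonds.append((int(i), int(j)))
    return bonds


def bond_exclusions(structure: Structure) -> frozenset[tuple[int, int]]:
    """Atom-index pairs separated by fewer than 3 bonds (1-2 and 1-3).

    These pairs are geometrically constrained by bond lengths and angles,
    not by van der Waals contact, so the clash check skips them.  Bond
    topology is conformation-independent; compute this once per molecule.
    """
    adj: dict[int, set[int]] = {}
    for i, j in _bonds(structure):
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    excluded: set[tuple[int, int]] = set()
    for i, nbrs in adj.items():
        for j in nbrs:
            excluded.add((min(i, j), max(i, j)))
            for k in adj.get(j, ()):  # 1-3 via j
                if k != i:
                    excluded.add((min(i, k), max(i, k)))
    return frozenset(excluded)


def _basis_indices(structure: Structure, basis: str) -> np.ndarray:
    if basis == "heavy":
        idx = [i for i, a in enumerate(structure.atoms) if a.element.upper() != "H"]
    elif basis == "backbone":
        idx = [
            i
            for i, a in enumerate(structure.atoms)
            if a.name in _BACKBONE and a.element.upper() != "H"
        ]
    elif basis == "all":
        if not any(a.element.upper() == "H" for a in structure.atoms):
            raise ValueError(
                "overlap basis 'all' requires hydrogen atoms in the structure"
            )
        idx = list(range(len(structure)))
    else:
        raise ValueError(f"unknown overlap basis {basis!r}")
    if not idx:
        raise ValueError(f"overlap basis {basis!r} selects no atoms")
    return np.array(idx, dtype=int)


def check_overlap(
    structure: Structure,
    basis: str = "heavy",
    cutoff: Optional[float] = None,
    exclusions: Optional[frozenset[tuple[int, int]]] = None,
) -> bool:
    """True iff any non-excluded atom pair of the basis is in steric clash.

    A pair clashes when its distance is strictly below the cutoff; with
    ``cutoff=None`` a per-pair cutoff of 0.8 times the sum of van der Waals
    radii is used.  Pairs separated by fewer than 3 bonds are skipped
    (pass a precomputed ``exclusions`` set to avoid re-deriving topology).
    """
    idx = _basis_indices(structure, basis)
    if exclusions is None:
        exclusions = bond_exclusions(structure)
    coords = structure.coords[idx]
    radii = np.array([vdw_radius(structure.atoms[i].element) for i in idx])
    r_max = cutoff if cutoff is not None else CLASH_VDW_SCALE * 2.0 * radii.max()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=r_max, output_type="ndarray")
    for a, b in pairs:
        i, j = int(idx[a]), int(idx[b])
        if (min(i, j), max(i, j)) in exclusions:
            continue
        d = np.linalg.norm(coords[a] - coords[b])
        limit = cutoff if cutoff is not None else CLASH_VDW_SCALE * (radii[a] + radii[b])
        if d < limit:
            return True
    return False


# ---------------------------------------------------------------------------
# superposition


def _kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rotation R and translation t mapping mobile onto reference."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])  # no reflections
    rot = vt.T @ corr @ u.T
    t = rc - rot @ mc
    return rot, t


def superpose(
    mobile: Structure,
    reference: Structure,
    align_range: FlexibleRegion,
) -> tuple[Structure, float]:
    """Least-squares rigid superposition on Cα atoms of a residue range.

    Returns the transformed mobile structure (all atoms moved) and the
    RMSD over the alignment Cα set.
    """
    if len(mobile) != len(reference):
        raise ValueError("structures must share atom ordering")
    idx = [
        i
        for i, a in enumerate(mobile.atoms)
        if a.name == "CA" and align_range.start <= a.residue_index <= align_range.end
    ]
    if len(idx) < 3:
        raise ValueError(
            f"alignment range {align_range} contains fewer than 3 Cα atoms"
        )
    mob = mobile.coords
    ref = reference.coords
    rot, t = _kabsch(mob[idx], ref[idx])
    moved = mob @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved[idx] - ref[idx]) ** 2, axis=1))))
    return mobile.with_coords(moved), rmsd


# ---------------------------------------------------------------------------
# the sampler


def run_mc(
    structure: Structure,
    regions: Sequence[FlexibleRegion],
    config: MCConfig,
    energy_fn: Optional[Callable[[Structure], float]] = None,
) -> ConformerPool:
    """Generate a conformer pool by seeded torsion Monte Carlo.

    Exactly ``config.trial_attempts`` trials run.  Each draws a flexible
    residue, a torsion (phi/psi) and a uniform angle; the move is accepted
    iff the result is clash-free (and, with an ``energy_fn``, passes
    Metropolis at ``config.temperature``).  Accepted frames are aligned to
    the start over ``config.align_range`` and numbered consecutively
    (their position in the accepted pool); the trial that produced each
    frame is kept in ``trial_index``.  Identical seeds give identical
    pools.
    """
    if not regions:
        raise ValueError("no flexible regions: nothing to sample")
    n_res = structure.n_residues
    if config.align_range is not None:
        validate_alignment_range(regions, config.align_range, n_res)
    res_ids = structure.residue_indices
    first_res, last_res = res_ids[0], res_ids[-1]
    flex = flexible_residues(regions)
    for r in flex:
        if r not in set(res_ids):
            raise ValueError(f"flexible residue {r} not present in the structure")

    from .profiles import rg_from_coords

    rng = np.random.default_rng(config.seed)
    exclusions = bond_exclusions(structure)
    reference = structure

    working = structure
    last_accepted = structure
    fails = 0
    frames: list[tuple[int, Structure]] = []
    trial_of_frame: list[int] = []
    rgs: list[float] = []
    log: list[bool] = []
    current_energy = energy_fn(structure) if energy_fn is not None else 0.0

    for trial in range(1, config.trial_attempts + 1):
        residue = int(rng.choice(flex))
        angle = "phi" if rng.integers(2) == 0 else "psi"
        delta = float(rng.uniform(-config.max_angle, config.max_angle))

        undefined = (angle == "phi" and residue == first_res) or (
            angle == "psi" and residue == last_res
        )
        accepted = False
        if not undefined:
            proposal = apply_torsion(
                working, TorsionMove(residue, angle, delta)
            )
            if not check_overlap(
                proposal, config.overlap_basis, exclusions=exclusions
            ):
                if energy_fn is not None:
                    new_energy = energy_fn(proposal)
                    beta = 1.0 / (BOLTZMANN_KCAL * config.temperature)
                    d_e = new_energy - current_energy
                    if d_e <= 0 or rng.random() < math.exp(-beta * d_e):
                        accepted = True
                        current_energy = new_energy
                else:
                    accepted = True
            if accepted:
                working = proposal

        log.append(accepted)
        if accepted:
            fails = 0
            last_accepted = working
            if config.align_range is not None:
                aligned, _ = superpose(working, reference, config.align_range)
            else:
                aligned = working
            frames.append((len(frames) + 1, aligned))
            trial_of_frame.append(trial)
            rgs.append(rg_from_coords(aligned))
        else:
            fails += 1
            if fails >= config.return_after_fails:
                working = last_accepted
                fails = 0

    return ConformerPool(frames, log, np.array(rgs), trial_of_frame)
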