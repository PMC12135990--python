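"""Synthetic inputs: an ideal-geometry toy protein and fake experiments.

The toy chain is a poly-alanine backbone (N, CA, C, O, CB) built from
ideal internal coordinates in an extended conformation: two "domains" with
high synthetic confidence joined by a low-confidence "linker", emulating
the two-domain-plus-disordered-linker topology the pipeline targets.  It
is clash-free under the default overlap basis and every non-terminal
residue has both phi and psi defined, so it is a valid Monte Carlo start.

Synthetic experiments mix the Debye I(q) (and P(r)) of chosen pool
conformers with known weights and optional multiplicative Gaussian noise,
giving ground truth for weight-recovery tests of the NNLS selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .profiles import PofR, ScatteringCurve, compute_iq_debye, compute_pr, pr_on_grid
from .structure import Atom, ConformerPool, Structure

__all__ = ["ToySpec", "SyntheticExperiment", "build_toy_chain", "make_synthetic_experiment"]

# ideal backbone internal coordinates
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.229
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_N_CA_CB = 110.4
OMEGA = 180.0
# extended (beta-like) backbone keeps the chain clash-free
PHI = -139.0
PSI = 135.0
# improper torsion C(i)-N(i)-CA(i)-CB placing CB with L-amino-acid handedness
CB_IMPROPER = -122.5


@dataclass
class ToySpec:
    """Two high-confidence domains joined by a low-confidence linker."""

    n_domain1: int = 20
    n_linker: int = 10
    n_domain2: int = 20
    domain_confidence: float = 90.0
    linker_confidence: float = 40.0

    def __post_init__(self) -> None:
        if min(self.n_domain1, self.n_linker, self.n_domain2) < 1:
            raise ValueError("all residue counts must be >= 1")
        for c in (self.domain_confidence, self.linker_confidence):
            if not 0 <= c <= 100:
                raise ValueError("confidences must be in [0, 100]")

    @property
    def n_residues(self) -> int:
        return self.n_domain1 + self.n_linker + self.n_domain2

    def confidence_track(self) -> list[float]:
        return (
            [self.domain_confidence] * self.n_domain1
            + [self.linker_confidence] * self.n_linker
            + [self.domain_confidence] * self.n_domain2
        )


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position D given chain A-B-C, |CD|, angle BCD, torsion ABCD."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_toy_chain(spec: ToySpec = ToySpec()) -> Structure:
    """Ideal-geometry poly-alanine chain with a synthetic confidence track."""
    confidences = spec.confidence_track()
    n_res = spec.n_residues

    from .elements import atomic_mass, electrons

    def mk(name: str, element: str, res: int, xyz: np.ndarray) -> Atom:
        return Atom(
            name=name,
            element=element,
            electrons=electrons(element),
            mass=atomic_mass(element),
            residue_index=res,
            residue_name="ALA",
            coords=xyz,
            confidence=confidences[res - 1],
        )

    atoms: list[Atom] = []
    # residue 1 backbone seeds the frame
    n1 = np.array([0.0, 0.0, 0.0])
    ca1 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c1 = ca1 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])

    prev = {"N": n1, "CA": ca1, "C": c1}
    for res in range(1, n_res + 1):
        if res == 1:
            n, ca, c = n1, ca1, c1
        else:
            n = _place(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, PSI)
            ca = _place(prev["CA"], prev["C"], n, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
            c = _place(prev["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, PHI)
        o = _place(n, ca, c, BOND_C_O, ANGLE_CA_C_O, PSI + 180.0)
        cb = _place(c, n, ca, BOND_CA_CB, ANGLE_N_CA_CB, CB_IMPROPER)
        atoms.append(mk("N", "N", res, n))
        atoms.append(mk("CA", "C", res, ca))
        atoms.append(mk("C", "C", res, c))
        atoms.append(mk("O", "O", res, o))
        atoms.append(mk("CB", "C", res, cb))
        prev = {"N": n, "CA": ca, "C": c}

    return Structure(atoms, chain_id="A", title="synthetic two-domain toy chain")


@dataclass
class SyntheticExperiment:
    """Ground-truth mixture defining a fake experimental I(q)/P(r) pair."""

    model_numbers: Sequence[int]
    true_weights: Sequence[float]
    noise_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.true_weights, dtype=float)
        if len(self.model_numbers) != w.size:
            raise ValueError("one weight per chosen conformer required")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum():.12f})")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")


def make_synthetic_experiment(
    pool: ConformerPool,
    exp_spec: SyntheticExperiment,
    q_grid: np.ndarray,
    pr_bin_width: float = 1.0,
) -> tuple[ScatteringCurve, PofR]:
    """Noisy weighted mixture of pool conformers' I(q) and P(r).

    I_exp(q) = sum_i w_i I_i(q) * (1 + eps(q)) with eps ~ N(0, nf^2) from
    the seeded generator; the SD column is nf * I (the applied noise
    scale), so SD weighting downstream is exercised honestly.  With
    ``noise_fraction=0`` the curves are exact and carry no SD column.
    """
    num_to_frame = {n: s for n, s in pool.frames}
    structures = []
    for n in exp_spec.model_numbers:
        if n not in num_to_frame:
            raise ValueError(f"model {n} not in the pool")
        structures.append(num_to_frame[n])
    w = np.asarray(exp_spec.true_weights, dtype=float)
    rng = np.random.default_rng(exp_spec.seed)

    q = np.asarray(q_grid, dtype=float)
    iq_cols = np.stack(
        [compute_iq_debye(s, q).intensity for s in structures], axis=1
    )
    iq_mix = iq_cols @ w

    prs = [compute_pr(s, bin_width=pr_bin_width) for s in structures]
    n_bins = max(pr.r.size for pr in prs)
    r = np.arange(n_bins) * pr_bin_width
    pr_cols = np.stack([pr_on_grid(pr, r).p for pr in prs], axis=1)
    pr_mix = pr_cols @ w

    if exp_spec.noise_fraction > 0:
        nf = exp_spec.noise_fraction
        iq_noisy = iq_mix * (1.0 + nf * rng.standard_normal(iq_mix.size))
        pr_noisy = pr_mix * (1.0 + nf * rng.standard_normal(pr_mix.size))
        pr_noisy = np.clip(pr_noisy, 0.0, None)
        iq_sd = np.maximum(nf * np.abs(iq_noisy), 1e-12 * np.abs(iq_noisy).max())
        pr_sd = nf * np.abs(pr_mix) + 1e-12 * np.abs(pr_mix).max()
        curve = ScatteringCurve(q, iq_noisy, iq_sd)
        pofr = PofR(r, pr_noisy, pr_sd)
    else:
        curve = ScatteringCurve(q, iq_mix)
        pofr = PofR(r, pr_mix)
    return curve, pofr
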