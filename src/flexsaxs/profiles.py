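"""SAXS observables computed from atomic coordinates.

P(r) — the pair-distance distribution — is a histogram of all interatomic
distances, weighted by the product of the electron counts of each pair and
rescaled so the area equals the molecular mass in Da (the field convention
for comparing structures of a known protein on an absolute footing).

I(q) comes from the Debye equation, the exact orientational average for a
rigid set of point scatterers:

    I(q) = sum_ij f_i(q) f_j(q) sin(q r_ij) / (q r_ij)

with either constant form factors f_i = Z_i ("point" mode) or 4-Gaussian
Cromer-Mann form factors.  This is a vacuum calculation (no excluded
volume, no hydration shell); external calculators with solvent terms can be
plugged in upstream, their output flows through the same interpolation and
scaling steps.

Calculated curves are linearly interpolated onto the experimental q grid
and scaled to the data by the SD-weighted least-squares factor

    c = sum(I_e I_c / s^2) / sum(I_c^2 / s^2)

with the normalized chi-square of the scaling reported as
nchi2 = sum(((I_e - c I_c)/s)^2) / (N - 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist

from .elements import CROMER_MANN
from .structure import Structure

__all__ = [
    "ScatteringCurve",
    "PofR",
    "ScaleResult",
    "load_curve_text",
    "convert_units",
    "compute_pr",
    "pr_on_grid",
    "compute_iq_debye",
    "interpolate_to_grid",
    "scale_and_chi2",
    "rg_from_coords",
    "rg_from_pr",
]


@dataclass
class ScatteringCurve:
    """I(q) on a strictly increasing q grid in Å⁻¹, optional per-point SD."""

    q: np.ndarray
    intensity: np.ndarray
    sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if np.any(self.q < 0):
            raise ValueError("q must be non-negative")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.q.shape:
                raise ValueError("sd must match the q grid length")
            if np.any(self.sd <= 0):
                raise ValueError("sd values must be strictly positive")

    def __len__(self) -> int:
        return self.q.size


@dataclass
class PofR:
    """Pair-distance distribution on uniform bins.

    ``r`` holds bin left edges starting at 0 with uniform spacing equal to
    the bin width; ``p`` the per-bin frequency; ``normalization`` the
    molecular mass (Da) the area was scaled to, when normalized.
    """

    r: np.ndarray
    p: np.ndarray
    sd: Optional[np.ndarray] = None
    normalization: Optional[float] = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.r.ndim != 1 or self.r.shape != self.p.shape:
            raise ValueError("r and p must be 1-D arrays of equal length")
        if self.r.size < 1 or abs(self.r[0]) > 1e-12:
            raise ValueError("r must start at 0")
        if self.r.size > 1:
            dr = np.diff(self.r)
            if np.any(dr <= 0) or not np.allclose(dr, dr[0], rtol=1e-9, atol=1e-12):
                raise ValueError("r must be uniformly spaced and increasing")
        if np.any(self.p < -1e-12):
            raise ValueError("p must be non-negative")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.r.shape:
                raise ValueError("sd must match the r grid length")

    def __len__(self) -> int:
        return self.r.size

    @property
    def bin_width(self) -> float:
        return float(self.r[1] - self.r[0]) if self.r.size > 1 else 1.0

    @property
    def area(self) -> float:
        return float(np.sum(self.p) * self.bin_width)

    @property
    def dmax(self) -> float:
        """Right edge of the last non-empty bin, Å."""
        nz = np.nonzero(self.p)[0]
        if nz.size == 0:
            return 0.0
        return float(self.r[nz[-1]] + self.bin_width)


@dataclass
class ScaleResult:
    """Least-squares scaling of a calculated curve to experimental data."""

    scale: float
    nchi2: float
    rmsd: float


# ---------------------------------------------------------------------------
# text I/O and units


def load_curve_text(path: str | Path, kind: str = "iq") -> ScatteringCurve | PofR:
    """Read a 2/3-column whitespace- or comma-delimited SAXS text file.

    Columns are (q, I, [SD]) for ``kind="iq"`` or (r, P, [SD]) for
    ``kind="pr"``; lines starting with ``#`` are skipped.  Units are taken
    as given — run :func:`convert_units` afterwards if the file is in nm.
    """
    rows: list[list[float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        text = line.split("#", 1)[0].strip()
        if not text:
            continue
        parts = text.replace(",", " ").split()
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            raise ValueError(f"{path}: cannot parse line {lineno}: {line!r}") from None
        if len(vals) not in (2, 3):
            raise ValueError(f"{path}: line {lineno} has {len(vals)} columns")
        rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncols = min(len(r) for r in rows)
    data = np.array([r[:ncols] for r in rows], dtype=float)
    sd = data[:, 2] if ncols == 3 else None
    if kind == "iq":
        return ScatteringCurve(data[:, 0], data[:, 1], sd)
    if kind == "pr":
        return PofR(data[:, 0], data[:, 1], sd)
    raise ValueError(f"unknown curve kind {kind!r}")


def convert_units(curve, unit: str):
    """Convert a curve's abscissa to the internal units (Å⁻¹ for q, Å for r).

    ``unit`` names the units the data are currently in:
    ``"inv_nm"``/``"inv_angstrom"`` for I(q), ``"nm"``/``"angstrom"`` for
    P(r).  P(r) frequencies are rescaled to the new bin width so the area
    under the curve is conserved.
    """
    if isinstance(curve, ScatteringCurve):
        if unit in ("inv_angstrom", "1/A", "A^-1"):
            return curve
        if unit in ("inv_nm", "1/nm", "nm^-1"):
            return ScatteringCurve(curve.q / 10.0, curve.intensity.copy(),
                                   None if curve.sd is None else curve.sd.copy())
        raise ValueError(f"unknown q unit {unit!r}")
    if isinstance(curve, PofR):
        if unit in ("angstrom", "A"):
            return curve
        if unit == "nm":
            sd = None if curve.sd is None else curve.sd / 10.0
            return PofR(curve.r * 10.0, curve.p / 10.0, sd, curve.normalization)
        raise ValueError(f"unknown r unit {unit!r}")
    raise TypeError("convert_units expects a ScatteringCurve or PofR")


# ---------------------------------------------------------------------------
# P(r)

_PAIR_CHUNK = 4_000_000  # pairs per histogram chunk, bounds memory


def _pair_distances_weights(structure: Structure, weighting: str):
    coords = structure.coords
    n = coords.shape[0]
    if weighting == "electrons":
        w = structure.electron_counts
    elif weighting == "uniform":
        w = np.ones(n)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    d = pdist(coords)
    iu, ju = np.triu_indices(n, k=1)
    wprod = w[iu] * w[ju]
    return d, wprod


def compute_pr(
    structure: Structure,
    bin_width: float = 1.0,
    weighting: str = "electrons",
) -> PofR:
    """Electron-weighted pair-distance histogram, area-normalized to mass.

    Every unordered atom pair contributes w_i*w_j to the bin
    [k*dr, (k+1)*dr) containing its distance (self terms excluded); the
    histogram is then rescaled so that sum(p)*dr equals the molecular mass
    in Da.
    """
    if len(structure) < 2:
        raise ValueError("P(r) needs at least 2 atoms")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d, wprod = _pair_distances_weights(structure, weighting)
    n_bins = int(np.floor(d.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    hist = np.zeros(n_bins)
    for lo in range(0, d.size, _PAIR_CHUNK):
        sl = slice(lo, lo + _PAIR_CHUNK)
        # np.histogram closes the last bin on the right; the extra edge
        # above max(d) keeps every bin effectively left-closed/right-open
        h, _ = np.histogram(d[sl], bins=edges, weights=wprod[sl])
        hist += h
    mass = structure.molecular_mass
    hist *= mass / (hist.sum() * bin_width)
    return PofR(edges[:-1], hist, normalization=mass)


def pr_on_grid(pr: PofR, r: np.ndarray) -> PofR:
    """Zero-pad / truncate-check a P(r) onto a longer common grid.

    Grids must share bin width and origin; bins beyond the curve's range
    are zero.  Raises if the target grid would cut off non-zero bins.
    """
    r = np.asarray(r, dtype=float)
    if r.size < pr.r.size:
        if np.any(pr.p[r.size:] != 0):
            raise ValueError("target grid shorter than the curve's support")
    if pr.r.size > 1 and r.size > 1 and not np.isclose(
        r[1] - r[0], pr.bin_width, rtol=1e-9
    ):
        raise ValueError("bin widths differ")
    p = np.zeros(r.size)
    n = min(r.size, pr.r.size)
    p[:n] = pr.p[:n]
    sd = None
    if pr.sd is not None:
        sd = np.zeros(r.size)
        sd[:n] = pr.sd[:n]
    return PofR(r, p, sd, pr.normalization)


# ---------------------------------------------------------------------------
# I(q)


def _form_factors(structure: Structure, q: np.ndarray, mode: str) -> np.ndarray:
    """Per-atom form factors, shape (n_q, n_atoms)."""
    n = len(structure)
    if mode == "point":
        return np.broadcast_to(structure.electron_counts, (q.size, n)).copy()
    if mode == "cromer_mann":
        s2 = (q / (4.0 * np.pi)) ** 2  # (sin theta / lambda)^2
        cache: dict[str, np.ndarray] = {}
        out = np.empty((q.size, n))
        for j, atom in enumerate(structure.atoms):
            el = atom.element.upper()
            if el not in cache:
                try:
                    a, b, c = CROMER_MANN[el]
                except KeyError:
                    raise ValueError(
                        f"no Cromer-Mann coefficients for element {el!r}"
                    ) from None
                f = np.full(q.size, c)
                for ai, bi in zip(a, b):
                    f += ai * np.exp(-bi * s2)
                cache[el] = f
            out[:, j] = cache[el]
        return out
    raise ValueError(f"unknown form-factor mode {mode!r}")


def compute_iq_debye(
    structure: Structure,
    q_grid: np.ndarray,
    mode: str = "point",
) -> ScatteringCurve:
    """Vacuum Debye-equation intensity on the given q grid.

    Exact pairwise sum; sin(x)/x is taken as 1 in the x -> 0 limit, so
    I(0) equals (sum of form factors)^2.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    if len(structure) < 1:
        raise ValueError("structure has no atoms")
    f = _form_factors(structure, q, mode)  # (nq, n)
    intensity = np.sum(f * f, axis=1)  # self terms
    if len(structure) > 1:
        coords = structure.coords
        d = pdist(coords)
        iu, ju = np.triu_indices(len(structure), k=1)
        for lo in range(0, d.size, _PAIR_CHUNK // max(1, q.size)):
            sl = slice(lo, lo + _PAIR_CHUNK // max(1, q.size))
            x = np.outer(q, d[sl])  # (nq, chunk)
            sinc = np.sinc(x / np.pi)  # sin(x)/x with the x->0 limit
            ff = f[:, iu[sl]] * f[:, ju[sl]]
            intensity += 2.0 * np.sum(ff * sinc, axis=1)
    return ScatteringCurve(q, intensity)


def interpolate_to_grid(curve: ScatteringCurve, target_q: np.ndarray) -> ScatteringCurve:
    """Piecewise-linear interpolation of a curve onto the experimental grid.

    Extrapolation is refused: every target q must lie inside the source
    range.
    """
    tq = np.asarray(target_q, dtype=float)
    if tq.min() < curve.q[0] - 1e-12 or tq.max() > curve.q[-1] + 1e-12:
        raise ValueError(
            f"target grid [{tq.min():g}, {tq.max():g}] extends beyond source "
            f"[{curve.q[0]:g}, {curve.q[-1]:g}]; extrapolation is not supported"
        )
    intensity = np.interp(tq, curve.q, curve.intensity)
    sd = None if curve.sd is None else np.interp(tq, curve.q, curve.sd)
    return ScatteringCurve(tq, intensity, sd)


def scale_and_chi2(calc: ScatteringCurve, exp: ScatteringCurve) -> ScaleResult:
    """Scale a calculated curve to experimental data; report nchi2 and RMSD.

    The scale c minimizes the SD-weighted squared residual; with no SDs the
    unweighted formulas apply (sigma = 1).  Grids must already match.
    """
    if calc.q.shape != exp.q.shape or not np.allclose(calc.q, exp.q, rtol=0, atol=1e-12):
        raise ValueError("curves must share one q grid (interpolate first)")
    n = exp.q.size
    if n < 2:
        raise ValueError("need at least 2 points to scale")
    ic, ie = calc.intensity, exp.intensity
    if np.all(ic == 0):
        raise ValueError("calculated curve is identically zero")
    sigma = exp.sd if exp.sd is not None else np.ones(n)
    w = 1.0 / sigma**2
    c = float(np.sum(ie * ic * w) / np.sum(ic**2 * w))
    resid = ie - c * ic
    nchi2 = float(np.sum((resid / sigma) ** 2) / (n - 1))
    rmsd = float(np.sqrt(np.mean(resid**2)))
    return ScaleResult(scale=c, nchi2=nchi2, rmsd=rmsd)


# ---------------------------------------------------------------------------
# radius of gyration


def rg_from_coords(structure: Structure, weighting: str = "electrons") -> float:
    """Rg as the weighted RMS distance of atoms from their weighted centroid."""
    coords = structure.coords
    if weighting == "electrons":
        w = structure.electron_counts
    elif weighting == "mass":
        w = structure.masses
    elif weighting == "uniform":
        w = np.ones(len(structure))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    centroid = np.average(coords, axis=0, weights=w)
    d2 = np.sum((coords - centroid) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=w)))


def rg_from_pr(pr: PofR) -> float:
    """Rg from the second moment of P(r): Rg² = ∫r²P dr / (2 ∫P dr).

    Evaluated discretely at bin centers.
    """
    total = np.sum(pr.p)
    if total <= 0:
        raise ValueError("P(r) has zero total area")
    centers = pr.r + pr.bin_width / 2.0
    rg2 = np.sum(pr.p * centers**2) / (2.0 * total)
    return float(np.sqrt(rg2))
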