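"""Per-element constants used throughout the package.

Scattering weights (electron counts), atomic masses for molecular-mass
normalization of P(r), van der Waals radii for hard-sphere clash checks,
and 4-Gaussian Cromer–Mann X-ray form-factor coefficients.

Only elements that occur in proteins (plus a handful of common ions) are
tabulated; anything else is treated as an error by the structure reader so
that a mis-parsed element column cannot silently corrupt scattering weights.
"""

from __future__ import annotations

# element symbol -> (electron count Z, atomic mass in Da)
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "S": (16, 32.06),
    "SE": (34, 78.971),
    "P": (15, 30.974),
    "NA": (11, 22.990),
    "MG": (12, 24.305),
    "K": (19, 39.098),
    "CA": (20, 40.078),
    "CL": (17, 35.45),
    "ZN": (30, 65.38),
    "FE": (26, 55.845),
    "MN": (25, 54.938),
    "CU": (29, 63.546),
}

# van der Waals radii, Å (Bondi). Used as 0.8*(r_i + r_j) clash cutoffs.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "SE": 1.90,
    "P": 1.80,
    "NA": 2.27,
    "MG": 1.73,
    "K": 2.75,
    "CA": 2.31,
    "CL": 1.75,
    "ZN": 1.39,
    "FE": 1.56,
    "MN": 1.61,
    "CU": 1.40,
}

# Cromer–Mann coefficients (a1..a4, b1..b4, c); f(q) = sum a_i exp(-b_i s^2) + c
# with s = q/(4*pi). International Tables for Crystallography Vol. C values.
CROMER_MANN: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "H": (
        (0.489918, 0.262003, 0.196767, 0.049879),
        (20.6593, 7.74039, 49.5519, 2.20159),
        0.001305,
    ),
    "C": (
        (2.31000, 1.02000, 1.58860, 0.865000),
        (20.8439, 10.2075, 0.568700, 51.6512),
        0.215600,
    ),
    "N": (
        (12.2126, 3.13220, 2.01250, 1.16630),
        (0.005700, 9.89330, 28.9975, 0.582600),
        -11.529,
    ),
    "O": (
        (3.04850, 2.28680, 1.54630, 0.867000),
        (13.2771, 5.70110, 0.323900, 32.9089),
        0.250800,
    ),
    "S": (
        (6.90530, 5.20340, 1.43790, 1.58630),
        (1.46790, 22.2151, 0.253600, 56.1720),
        0.866900,
    ),
    "SE": (
        (17.0006, 5.81960, 3.97310, 4.35430),
        (2.40980, 0.272600, 15.2372, 43.8163),
        2.84090,
    ),
    "P": (
        (6.43450, 4.17910, 1.78000, 1.49080),
        (1.90670, 27.1570, 0.526000, 68.1645),
        1.11490,
    ),
}


def electrons(symbol: str) -> int:
    """Electron count Z for an element symbol (case-insensitive)."""
    try:
        return ELEMENTS[symbol.upper()][0]
    except KeyError:
        raise KeyError(f"element {symbol!r} not in the built-in table") from None


def atomic_mass(symbol: str) -> float:
    """Atomic mass in Da for an element symbol (case-insensitive)."""
    try:
        return ELEMENTS[symbol.upper()][1]
    except KeyError:
        raise KeyError(f"element {symbol!r} not in the built-in table") from None


def vdw_radius(symbol: str) -> float:
    try:
        return VDW_RADII[symbol.upper()]
    except KeyError:
        raise KeyError(f"no van der Waals radius for element {symbol!r}") from None
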