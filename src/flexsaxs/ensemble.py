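"""Non-negative least-squares ensemble selection.

Given calculated profiles (I(q) or P(r)) for a pool of conformers, find
non-negative weights w minimizing ||W(Aw - b)||2 against the experimental
curve b, with W = diag(1/SD) when SD weighting is requested and available.
The Lawson-Hanson active-set algorithm (scipy.optimize.nnls) solves the
problem exactly; models with strictly positive weight form the selected
ensemble, reported as percent contributions.

Columns enter unscaled: the weights absorb the overall scale, keeping them
identifiable as fractional contributions.  The ensemble's radius of
gyration is the root of the contribution-weighted mean of squared
per-model Rg values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls as _lawson_hanson_nnls

from .profiles import PofR, ScatteringCurve

__all__ = [
    "EnsembleFit",
    "nnls_select",
    "kkt_check",
    "weighted_rg",
    "reconstruct_curve",
    "reconstruct_pr",
]


@dataclass
class EnsembleFit:
    """Result of an NNLS ensemble selection.

    Only models with strictly positive weight are retained; ``percents``
    are 100*w_i/sum(w) and total 100.  ``nchi2`` is the normalized
    chi-square of the fitted sum against the experimental curve with an
    N - m denominator (m positive weights fitted).  ``weighted_rg`` is
    filled by the caller once per-model Rg values are known.
    """

    model_numbers: list[int]
    weights: np.ndarray
    percents: np.ndarray
    nchi2: float
    reconstructed: np.ndarray
    reconstructed_sd: Optional[np.ndarray] = None
    weighted_rg: Optional[float] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.percents = np.asarray(self.percents, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("ensemble weights must be non-negative")
        if self.percents.size and abs(self.percents.sum() - 100.0) > 1e-9:
            raise ValueError("percents must total 100")
        nums = list(self.model_numbers)
        if nums != sorted(nums):
            raise ValueError("model_numbers must be sorted ascending")


def _experimental_parts(experimental) -> tuple[np.ndarray, Optional[np.ndarray]]:
    if isinstance(experimental, ScatteringCurve):
        return experimental.intensity, experimental.sd
    if isinstance(experimental, PofR):
        return experimental.p, experimental.sd
    b = np.asarray(experimental, dtype=float)
    return b, None


def nnls_select(
    profiles: np.ndarray,
    experimental,
    use_sd_weighting: bool = False,
    model_numbers: Optional[Sequence[int]] = None,
) -> EnsembleFit:
    """Select a weighted ensemble whose summed profiles best match the data.

    Parameters
    ----------
    profiles:
        (n_points, n_models) matrix, one column per model, on the
        experimental grid.
    experimental:
        :class:`ScatteringCurve`, :class:`PofR` or plain array on the same
        grid.
    use_sd_weighting:
        Weight rows by 1/SD.  If no SDs are present the fit falls back to
        unweighted with a warning.
    model_numbers:
        Original pool model number per column (defaults to 1..M).
    """
    a = np.asarray(profiles, dtype=float)
    if a.ndim != 2 or a.shape[1] < 1:
        raise ValueError("profiles must be a 2-D matrix with >= 1 column")
    b, sd = _experimental_parts(experimental)
    if b.shape[0] != a.shape[0]:
        raise ValueError(
            f"grid mismatch: profiles have {a.shape[0]} rows, "
            f"experimental has {b.shape[0]} points"
        )
    if model_numbers is None:
        model_numbers = list(range(1, a.shape[1] + 1))
    model_numbers = list(model_numbers)
    if len(model_numbers) != a.shape[1]:
        raise ValueError("need one model number per profile column")

    if use_sd_weighting and sd is None:
        warnings.warn(
            "SD weighting requested but the experimental curve has no SDs; "
            "falling back to the unweighted fit",
            stacklevel=2,
        )
        use_sd_weighting = False
    if use_sd_weighting:
        w_row = 1.0 / sd
    else:
        w_row = np.ones(b.shape[0])

    weights, _ = _lawson_hanson_nnls(a * w_row[:, None], b * w_row)

    # weights at the solver's numerical floor are zeros, not contributions
    if weights.max() > 0:
        weights[weights <= 1e-9 * weights.max()] = 0.0
    fitted = a @ weights
    positive = weights > 0
    m = int(positive.sum())
    sigma = sd if sd is not None else np.ones(b.shape[0])
    dof = max(b.shape[0] - m, 1)
    nchi2 = float(np.sum(((b - fitted) / sigma) ** 2) / dof)

    sel = np.nonzero(positive)[0]
    sel_numbers = [model_numbers[i] for i in sel]
    order = np.argsort(sel_numbers)
    sel = sel[order]
    sel_numbers = sorted(sel_numbers)
    w_sel = weights[sel]
    percents = 100.0 * w_sel / w_sel.sum() if w_sel.size else np.array([])
    # exact renormalization guards against accumulated rounding
    if percents.size:
        percents *= 100.0 / percents.sum()
    return EnsembleFit(
        model_numbers=sel_numbers,
        weights=w_sel,
        percents=percents,
        nchi2=nchi2,
        reconstructed=fitted,
    )


def kkt_check(
    profiles: np.ndarray,
    experimental,
    fit: EnsembleFit,
    use_sd_weighting: bool = False,
    model_numbers: Optional[Sequence[int]] = None,
) -> tuple[float, float]:
    """Karush-Kuhn-Tucker certificate for an NNLS solution.

    Returns ``(max_active_violation, min_zero_gradient)``: at the optimum
    the weighted residual is orthogonal to every active (positive-weight)
    column, and the gradient along every zero-weight column is
    non-negative.  A valid solution has the first ~0 and the second >= ~0,
    independent of which solver produced the weights.
    """
    a = np.asarray(profiles, dtype=float)
    b, sd = _experimental_parts(experimental)
    w_row = 1.0 / sd if (use_sd_weighting and sd is not None) else np.ones(b.shape[0])
    if model_numbers is None:
        model_numbers = list(range(1, a.shape[1] + 1))
    full_w = np.zeros(a.shape[1])
    num_to_col = {n: i for i, n in enumerate(model_numbers)}
    for n, w in zip(fit.model_numbers, fit.weights):
        full_w[num_to_col[n]] = w
    aw = a * w_row[:, None]
    resid = aw @ full_w - b * w_row
    grad = aw.T @ resid  # gradient of 0.5||Aw-b||^2
    active = full_w > 0
    max_active = float(np.max(np.abs(grad[active]))) if active.any() else 0.0
    min_zero = float(np.min(grad[~active])) if (~active).any() else 0.0
    return max_active, min_zero


def weighted_rg(rg: Sequence[float], percents: Sequence[float]) -> float:
    """Ensemble Rg: sqrt of the contribution-weighted mean of Rg squared."""
    rg = np.asarray(rg, dtype=float)
    pct = np.asarray(percents, dtype=float)
    if rg.shape != pct.shape:
        raise ValueError("rg and percents must have the same length")
    if abs(pct.sum() - 100.0) > 1e-6:
        raise ValueError(f"percents total {pct.sum():.8f}, expected 100")
    return float(np.sqrt(np.sum((pct / 100.0) * rg**2)))


def reconstruct_curve(
    profiles: np.ndarray,
    weights: Sequence[float],
    sds: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Weighted sum of profile columns with propagated SDs.

    value = sum_i w_i * col_i; when per-column SDs exist,
    SD = sqrt(sum_i (w_i * sd_i)^2) pointwise.
    """
    a = np.asarray(profiles, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.size != a.shape[1]:
        raise ValueError("one weight per profile column required")
    if np.all(w == 0):
        raise ValueError("all weights are zero")
    value = a @ w
    sd = None
    if sds is not None:
        s = np.asarray(sds, dtype=float)
        if s.shape != a.shape:
            raise ValueError("sds must match the profiles matrix shape")
        sd = np.sqrt(np.sum((s * w) ** 2, axis=1))
    return value, sd


def reconstruct_pr(
    pr_profiles: Sequence[PofR],
    percents: Sequence[float],
    experimental_pr: PofR,
) -> tuple[PofR, float]:
    """Percent-weighted composite P(r) and its RMSD to the experimental one.

    All curves must share the experimental r grid (zero-pad shorter model
    curves first with :func:`~flexsaxs.profiles.pr_on_grid`).
    """
    pct = np.asarray(percents, dtype=float)
    if len(pr_profiles) != pct.size:
        raise ValueError("one percent per P(r) profile required")
    r = experimental_pr.r
    for pr in pr_profiles:
        if pr.r.shape != r.shape or not np.allclose(pr.r, r, rtol=0, atol=1e-12):
            raise ValueError("P(r) grids do not match the experimental grid")
    stack = np.stack([pr.p for pr in pr_profiles], axis=1)
    composite = stack @ (pct / 100.0)
    rmsd = float(np.sqrt(np.mean((composite - experimental_pr.p) ** 2)))
    return PofR(r.copy(), composite), rmsd
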