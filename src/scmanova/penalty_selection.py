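"""Feasible-set construction and information-criterion choice of the ridge penalty.

The covariance estimator is positive definite only for penalties in the
feasible set ``Phi`` (``Phi_0`` under the null).  Writing ``d_j`` for the
presence count of variable ``j`` and ``A`` for the unpenalized entry-wise
ratio estimator, the penalized estimator factors as

    Sigma_hat(lambda) = D^{1/2} (B + diag(lambda)) D^{1/2},
    D = diag(1 / d_j),   B = sqrt(d) sqrt(d)^T * A   (entry-wise),

so ``Sigma_hat(lambda)`` and ``B + diag(lambda)`` are congruent and share
their inertia: positive definiteness is a condition on the eigenvalues of
``B`` alone, and for a scalar penalty the whole grid is screened with a
single symmetric eigendecomposition.  Feasibility is therefore monotone in
the scalar penalty by construction.

Among feasible candidates, ``lambda`` is chosen by minimizing the
information criterion

    M(lambda) = -2 l(theta_hat_lambda)
                + [log(n) + log(p)/2] * sum_i tr( Sigma_hat(lambda)_{V_i}^{-1} ),

where ``l`` is the *unpenalized* log-likelihood at the penalized estimates
and the trace of the Fisher information over each observation's support
measures model complexity.  Ties are broken toward the smaller penalty
(less bias).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .core_model import (
    SemicontDataset,
    SingularModelError,
    _as_penalty_vector,
    _pattern_groups,
    estimate_mu,
    estimate_sigma,
    fit_model,
    loglik,
)

__all__ = [
    "PenaltyGrid",
    "FeasibilityError",
    "default_grid",
    "is_feasible",
    "ic_value",
    "select_lambda",
]

#: relative positive-definiteness tolerance (scale-free)
PD_RELATIVE_TOL = 1e-10

#: default grid geometry: {0} plus GRID_SIZE log-spaced candidates spanning
#: [GRID_LO, GRID_HI] times the mean unpenalized variance diagonal
GRID_SIZE = 25
GRID_LO = 1e-3
GRID_HI = 1e2


class FeasibilityError(RuntimeError):
    """No candidate penalty yields a positive definite covariance estimator."""


@dataclass
class PenaltyGrid:
    """Candidate scalar penalties with feasibility and criterion bookkeeping."""

    values: np.ndarray
    feasible: np.ndarray | None = None
    ic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("penalty grid must contain at least one candidate")
        if (self.values < 0).any():
            raise ValueError("penalty candidates must be nonnegative")
        if (np.diff(self.values) < 0).any():
            raise ValueError("penalty candidates must be sorted ascending")


def _congruent_matrix(dataset: SemicontDataset, null_model: bool) -> np.ndarray:
    """``B = sqrt(d) sqrt(d)^T * A`` with ``A`` the unpenalized ratio estimator."""
    mu = estimate_mu(dataset, null_model)
    A = estimate_sigma(dataset, mu, 0.0, null_model)
    sd = np.sqrt(dataset.Y.sum(axis=0).astype(float))
    return A * np.outer(sd, sd)


def default_grid(dataset: SemicontDataset, null_model: bool = False,
                 size: int = GRID_SIZE, lo: float = GRID_LO, hi: float = GRID_HI) -> PenaltyGrid:
    """Scale-aware default candidate grid.

    ``{0}`` plus ``size`` log-spaced values between ``lo * dbar`` and
    ``hi * dbar``, where ``dbar`` is the mean diagonal of the unpenalized
    entry-wise ratio estimator (a typical log-scale variance), so the grid
    adapts to the measurement scale of the data.
    """
    mu = estimate_mu(dataset, null_model)
    A = estimate_sigma(dataset, mu, 0.0, null_model)
    dbar = float(np.mean(np.diag(A)))
    if dbar <= 0:
        dbar = 1.0
    values = np.concatenate(
        [[0.0], dbar * np.logspace(math.log10(lo), math.log10(hi), size)]
    )
    return PenaltyGrid(values=values)


def is_feasible(lam, dataset: SemicontDataset, null_model: bool = False) -> bool:
    """Whether the penalized covariance estimator is positive definite.

    Checked on the congruent matrix ``B + diag(lambda)`` (same inertia as
    the estimator itself): smallest eigenvalue must exceed
    ``PD_RELATIVE_TOL`` times the largest.
    """
    lam = _as_penalty_vector(lam, dataset.p)
    B = _congruent_matrix(dataset, null_model)
    ev = np.linalg.eigvalsh(B + np.diag(lam))
    return bool(ev[0] > PD_RELATIVE_TOL * ev[-1])


def trace_inverse_sum(sigma: np.ndarray, dataset: SemicontDataset) -> float:
    """``sum_i tr(Sigma_{V_i}^{-1})`` over observation supports (empty supports add 0)."""
    total = 0.0
    for key, rows in _pattern_groups(dataset).items():
        V = np.flatnonzero(np.frombuffer(key, dtype=bool))
        if V.size == 0:
            continue
        try:
            cf = cho_factor(sigma[np.ix_(V, V)], lower=True)
        except LinAlgError as exc:
            raise SingularModelError(
                f"singular covariance submatrix for presence pattern {V.tolist()}"
            ) from exc
        total += len(rows) * float(np.trace(cho_solve(cf, np.eye(V.size))))
    return total


def ic_value(lam, dataset: SemicontDataset, null_model: bool = False) -> float:
    """Information-criterion value ``M(lambda)`` at a feasible penalty."""
    if not is_feasible(lam, dataset, null_model):
        raise FeasibilityError(f"penalty {lam!r} is outside the feasible set")
    params = fit_model(dataset, lam, null_model)
    ll = loglik(params, dataset)
    const = math.log(dataset.n) + 0.5 * math.log(dataset.p)
    return -2.0 * ll + const * trace_inverse_sum(params.sigma, dataset)


#: golden-section constants (shared with the compiled fast path)
_INVPHI = 0.6180339887498949
_REFINE_REL_TOL = 1e-9
_REFINE_MAX_ITER = 80


def _golden_min(f, a: float, b: float):
    """Golden-section minimum of a unimodal ``f`` on ``[a, b]`` (left-biased ties)."""
    x1 = b - _INVPHI * (b - a)
    x2 = a + _INVPHI * (b - a)
    f1, f2 = f(x1), f(x2)
    it = 0
    while (b - a) > _REFINE_REL_TOL * (1.0 + b) and it < _REFINE_MAX_ITER:
        if f1 <= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - _INVPHI * (b - a)
            f1 = f(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + _INVPHI * (b - a)
            f2 = f(x2)
        it += 1
    mid = 0.5 * (a + b)
    return mid, f(mid)


def select_lambda(dataset: SemicontDataset, grid: PenaltyGrid | None = None,
                  null_model: bool = False, refine: bool = True):
    """Feasible penalty minimizing the information criterion.

    The grid is scanned first (ties broken toward the smaller candidate);
    with ``refine=True`` (default) the minimum is then located to continuous
    precision by golden-section search between the neighbouring candidates,
    with the positive-definiteness boundary as the lower edge.  The
    refinement matters for the permutation test: a penalty restricted to a
    coarse grid jumps between candidates across permutations, which adds
    selection noise to the statistic.

    Returns ``(lam_hat, grid)`` where the grid carries per-candidate
    feasibility flags and criterion values for diagnostics.  Raises
    :class:`FeasibilityError` when no candidate is feasible (extend the grid
    upward).
    """
    if grid is None:
        grid = default_grid(dataset, null_model)
    values = grid.values
    B = _congruent_matrix(dataset, null_model)
    ev = np.linalg.eigvalsh(B)
    feasible = (ev[0] + values) > PD_RELATIVE_TOL * (ev[-1] + values)
    ic = np.full(values.size, np.inf)
    const = math.log(dataset.n) + 0.5 * math.log(dataset.p)

    def criterion(lam: float) -> float:
        params = fit_model(dataset, lam, null_model)
        ll = loglik(params, dataset)
        return -2.0 * ll + const * trace_inverse_sum(params.sigma, dataset)

    best = None
    for g in np.flatnonzero(feasible):
        ic[g] = criterion(values[g])
        if best is None or ic[g] < ic[best]:
            best = g
    grid = PenaltyGrid(values=values, feasible=feasible, ic=ic)
    if best is None:
        raise FeasibilityError(
            "no candidate penalty yields a positive definite estimator; extend the grid upward"
        )
    lam_hat = float(values[best])
    ic_best = float(ic[best])
    if refine and values.size > 1:
        lam_crit = max(0.0, (PD_RELATIVE_TOL * ev[-1] - ev[0]) / (1.0 - PD_RELATIVE_TOL))
        a = values[best - 1] if best > 0 and feasible[best - 1] else lam_crit
        b = values[best + 1] if best < values.size - 1 else values[-1]
        if b > a:
            lam_mid, ic_mid = _golden_min(criterion, float(a), float(b))
            if ic_mid < ic_best:
                lam_hat = lam_mid
    return lam_hat, grid
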