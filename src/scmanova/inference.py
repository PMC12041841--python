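"""Likelihood-ratio-type statistic and group-label permutation test.

The hypothesis of interest is that all groups share the same presence-size
probabilities and the same conditional means of the log-abundances:

    H0:  pi_1(s) = ... = pi_K(s) for all s   and   mu_1 = ... = mu_K.

The test statistic is

    D = -2 [ l0(pi0_hat, mu0_hat, Sigma0_hat(lambda0_hat))
             - l(pi_hat,  mu_hat,  Sigma_hat(lambda_hat)) ],

with the *unpenalized* log-likelihoods evaluated at the penalized estimates
and the penalties chosen by the information criterion under each hypothesis.
With complete data, ``n > p`` and both penalties zero this is the classical
Gaussian MANOVA likelihood-ratio statistic; in general its null distribution
is obtained by recomputing the statistic on datasets whose group labels are
permuted uniformly at random (group sizes preserved).  Re-selecting the
penalty on each permuted dataset lets the permutation distribution absorb
the extra variability of the data-driven penalty choice; the null-model
estimates (and hence ``lambda0_hat``) are invariant under label permutation,
so only the alternative fit is recomputed per permutation.

Because ``lambda_hat`` and ``lambda0_hat`` may differ, ``D`` can be
(slightly) negative; permutation calibration makes this harmless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _fastpath
from .core_model import (
    DegenerateDataError,
    SemicontDataset,
    derive_presence,
    filter_pairwise_support,
    fit_model,
    loglik,
    penalty_term,
)
from .penalty_selection import FeasibilityError, PenaltyGrid

logger = logging.getLogger("scmanova")

__all__ = ["TestResult", "lrt_statistic", "permutation_test"]


def lrt_statistic(dataset: SemicontDataset, lam, lam0,
                  penalized_ratio: bool = False) -> float:
    """Statistic ``D`` at given penalties (dataset must already be filtered).

    With ``penalized_ratio=True`` the *penalized* log-likelihoods are
    differenced instead (sensitivity analysis; the default follows the
    likelihood-ratio form with unpenalized log-likelihoods at the penalized
    estimates).
    """
    alt = fit_model(dataset, lam, null_model=False)
    nul = fit_model(dataset, lam0, null_model=True)
    ll_alt = loglik(alt, dataset)
    ll_nul = loglik(nul, dataset)
    if penalized_ratio:
        ll_alt -= 0.5 * penalty_term(alt.lam, alt.sigma, dataset)
        ll_nul -= 0.5 * penalty_term(nul.lam, nul.sigma, dataset)
    return -2.0 * (ll_nul - ll_alt)


@dataclass
class TestResult:
    """Outcome of the regularized MANOVA permutation test."""

    statistic: float
    p_value: float
    lambda_hat: float
    lambda0_hat: float
    p_star: int
    removed: list
    B: int
    seed: int | None
    perm_statistics: np.ndarray | None = field(default=None, repr=False)
    n_failed_permutations: int = 0
    p_value_mode: str = "add_one"
    reselect: bool = True

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "lambda_hat": self.lambda_hat,
            "lambda0_hat": self.lambda0_hat,
            "p_star": self.p_star,
            "removed": list(self.removed),
            "B": self.B,
            "seed": self.seed,
            "n_failed_permutations": self.n_failed_permutations,
            "p_value_mode": self.p_value_mode,
            "reselect": self.reselect,
        }


def permutation_test(
    dataset: SemicontDataset,
    B: int = 1000,
    seed=None,
    reselect: bool = True,
    grid: PenaltyGrid | np.ndarray | None = None,
    p_value_mode: str = "add_one",
    penalized_ratio: bool = False,
    store_null: bool = True,
    apply_filter: bool = True,
) -> TestResult:
    """Group-label permutation test of the homogeneity hypothesis.

    Pipeline: pairwise-support filtering, information-criterion selection of
    ``(lambda_hat, lambda0_hat)`` on the observed data, observed statistic,
    then ``B`` uniform label permutations (group sizes preserved).  With
    ``reselect=True`` (default) the alternative penalty is re-selected on
    every permuted dataset; with ``reselect=False`` the observed
    ``lambda_hat`` is reused for speed.

    ``p_value_mode='add_one'`` returns ``(1 + #{D_b >= D_obs}) / (B + 1)``
    (guarantees validity); ``'strict'`` returns ``#{D_b >= D_obs} / B``, the
    plain proportion of at-least-as-extreme resampled statistics — for
    continuous data this almost surely equals the fraction of strictly
    larger statistics, while remaining sensible (p = 1) when every
    permutation reproduces the observed fit exactly.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if p_value_mode not in ("add_one", "strict"):
        raise ValueError("p_value_mode must be 'add_one' or 'strict'")
    dataset = derive_presence(dataset)
    if dataset.K < 2:
        raise DegenerateDataError("the test requires at least two groups")

    if apply_filter:
        fds, report = filter_pairwise_support(dataset)
        removed = [dataset.column_name(j) for j in report.removed]
    else:
        fds, removed = dataset, []

    rng = np.random.default_rng(seed)
    codes = fds.group_codes
    labels = np.empty((B + 1, fds.n), dtype=np.int64)
    labels[0] = codes
    for b in range(1, B + 1):
        labels[b] = rng.permutation(codes)
    if B >= 1 and bool((labels[1:] == labels[0]).all()):
        logger.warning("all sampled permutations equal the observed labels; p-value is 1")

    grid_values = None
    if grid is not None:
        grid_values = grid.values if isinstance(grid, PenaltyGrid) else np.asarray(grid, float)

    # null fit: label-invariant, computed once
    nul = _fastpath.evaluate_labelings(
        fds, np.zeros((1, fds.n), dtype=np.int64), K=1, grid_values=grid_values
    )
    if not nul["ok"][0]:
        raise FeasibilityError(
            "no feasible penalty for the null covariance estimator; extend the grid upward"
        )
    ll0 = nul["ll"][0]
    lam0_hat = float(nul["lam"][0])
    if penalized_ratio:
        ll0 -= 0.5 * lam0_hat * nul["trace"][0]

    # alternative fits: observed labeling plus permutations
    alt = _fastpath.evaluate_labelings(fds, labels, K=fds.K, grid_values=grid_values)
    if not alt["ok"][0]:
        raise FeasibilityError(
            "no feasible penalty for the alternative covariance estimator; extend the grid upward"
        )
    lam_hat = float(alt["lam"][0])
    if not reselect:
        alt_perm = _fastpath.evaluate_labelings(
            fds, labels[1:], K=fds.K, grid_values=np.asarray([lam_hat]), refine=False
        )
        for key in ("ll", "lam", "trace", "ic", "ok"):
            alt[key] = np.concatenate([alt[key][:1], alt_perm[key]])

    ll_alt = alt["ll"].copy()
    if penalized_ratio:
        ll_alt = ll_alt - 0.5 * alt["lam"] * alt["trace"]
    D = -2.0 * (ll0 - ll_alt)
    D_obs = float(D[0])
    ok_perm = alt["ok"][1:]
    D_perm = D[1:][ok_perm]
    n_failed = int(B - ok_perm.sum())
    if n_failed:
        logger.warning("%d of %d permutations had no feasible penalty and were dropped",
                       n_failed, B)
    B_eff = int(ok_perm.sum())
    if B_eff == 0:
        raise FeasibilityError("no permutation produced a feasible fit")

    # Ties count as at-least-as-extreme in both modes (for continuous data
    # exact ties have probability zero, so the strict proportion is a.s. the
    # plain "larger than observed" fraction; on degenerate all-tie data this
    # gives p = 1 rather than a spurious 0).  A small relative tolerance
    # absorbs floating-point noise from the continuous penalty selection;
    # borderline values inflate the p-value, never deflate it.
    eps_tie = 1e-7 * max(1.0, abs(D_obs))
    n_extreme = int((D_perm >= D_obs - eps_tie).sum())
    if p_value_mode == "add_one":
        p_value = (1.0 + n_extreme) / (B_eff + 1.0)
    else:
        p_value = n_extreme / B_eff

    return TestResult(
        statistic=D_obs,
        p_value=float(p_value),
        lambda_hat=lam_hat,
        lambda0_hat=lam0_hat,
        p_star=fds.p,
        removed=removed,
        B=B_eff,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        perm_statistics=D_perm if store_null else None,
        n_failed_permutations=n_failed,
        p_value_mode=p_value_mode,
        reselect=reselect,
    )
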