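"""Data model and penalized closed-form estimation for semicontinuous observations.

Semicontinuous data are nonnegative measurements with a probability mass at
exactly zero: each entry of the ``n x p`` matrix ``X`` is either zero (the
variable is *absent* from that observation) or a positive abundance /
expression value.  The model used throughout this package is a two-part
model:

* the binary presence pattern ``Y = 1(X > 0)`` of each observation follows an
  *exchangeable* multivariate Bernoulli law: every configuration ``a`` with
  the same number ``s`` of present components has the same probability
  ``pi_k(s)`` in group ``k`` (``p + 1`` free parameters per group instead of
  ``2**p - 1``);
* conditionally on the presence pattern, the logarithms of the positive
  components follow the corresponding marginal of a ``p``-variate Gaussian
  ``N(mu_k, Sigma)`` with a covariance matrix shared by all groups
  (homoskedasticity).

Because ``p`` may exceed ``n``, the Gaussian part is estimated by maximizing
a ridge-penalized likelihood.  The penalty is the diagonal-loading term

    P(lambda, Sigma) = sum_k sum_i tr( Lambda_V  Sigma_V^{-1} ),

where ``V`` is the support (set of present components) of each observation,
``Lambda = diag(lambda)``, and the penalized log-likelihood is
``l(pi, mu, Sigma) - P(lambda, Sigma) / 2``.  The maximizers have closed
forms: group-wise configuration frequencies for ``pi``, observed-components
means for ``mu``, and an entry-wise ratio of co-observed cross-products (with
``Lambda`` added to the numerator's diagonal) for ``Sigma``.  With complete
data and ``lambda = 0`` they reduce to the classical Gaussian MLEs.

This module provides the dataset container, the pairwise-co-observation
variable filter, the closed-form estimators, and (penalized) log-likelihood
evaluation.  Penalty selection and the permutation test live in
:mod:`scmanova.penalty_selection` and :mod:`scmanova.inference`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.special import gammaln

logger = logging.getLogger("scmanova")

LOG_2PI = math.log(2.0 * math.pi)

__all__ = [
    "SemicontDataset",
    "ModelParams",
    "FilterReport",
    "InvalidDataError",
    "DegenerateDataError",
    "SingularModelError",
    "derive_presence",
    "filter_pairwise_support",
    "estimate_pi",
    "estimate_mu",
    "estimate_sigma",
    "fit_model",
    "loglik",
    "penalty_term",
]


class InvalidDataError(ValueError):
    """Input matrix violates the semicontinuous-data contract (negative or NaN)."""


class DegenerateDataError(ValueError):
    """Data carry too little information for the requested fit."""


class SingularModelError(ArithmeticError):
    """A covariance submatrix required by the likelihood is singular."""


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------


@dataclass
class SemicontDataset:
    """An ``n x p`` semicontinuous matrix with group labels and derived masks.

    Parameters
    ----------
    X:
        Nonnegative ``n x p`` matrix; zeros encode absence.  NaN entries are
        rejected: a missing value and a structural zero are semantically
        different and silent coercion would corrupt the Bernoulli part.
    groups:
        Length-``n`` vector of group labels (any hashable values, ``K``
        distinct ones).
    columns:
        Optional variable names (used when reporting removed variables).

    Derived attributes
    ------------------
    ``Y``            boolean presence indicators, ``Y = (X > 0)``;
    ``Xlog``         ``log X`` where present, NaN where absent (never read
                     at absent positions);
    ``nik``          per-row support size ``|V(Y_i)|``;
    ``group_codes``  integer codes ``0..K-1`` aligned with ``group_names``;
    ``nk``           per-group sample sizes.
    """

    X: np.ndarray
    groups: np.ndarray
    columns: tuple | None = None

    # derived (populated in __post_init__)
    Y: np.ndarray = field(init=False, repr=False)
    Xlog: np.ndarray = field(init=False, repr=False)
    nik: np.ndarray = field(init=False, repr=False)
    group_codes: np.ndarray = field(init=False, repr=False)
    group_names: tuple = field(init=False, repr=False)
    nk: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise InvalidDataError(f"X must be 2-dimensional, got shape {X.shape}")
        if np.isnan(X).any():
            i, j = np.argwhere(np.isnan(X))[0]
            raise InvalidDataError(
                f"NaN at row {i}, column {j}: missing values are not zeros and are not supported"
            )
        if (X < 0).any():
            i, j = np.argwhere(X < 0)[0]
            raise InvalidDataError(f"negative entry {X[i, j]} at row {i}, column {j}")
        groups = np.asarray(self.groups)
        if groups.shape != (X.shape[0],):
            raise InvalidDataError(
                f"groups must have length n={X.shape[0]}, got shape {groups.shape}"
            )
        self.X = X
        self.groups = groups
        if self.columns is not None:
            self.columns = tuple(str(c) for c in self.columns)
            if len(self.columns) != X.shape[1]:
                raise InvalidDataError("columns must match the number of variables")

        self.Y = X > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            self.Xlog = np.where(self.Y, np.log(np.where(self.Y, X, 1.0)), np.nan)
        self.nik = self.Y.sum(axis=1).astype(np.int64)
        names, codes = np.unique(groups, return_inverse=True)
        self.group_names = tuple(names.tolist())
        self.group_codes = codes.astype(np.int64)
        self.nk = np.bincount(codes, minlength=len(names)).astype(np.int64)

    # -- basic shape accessors ------------------------------------------------

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def K(self) -> int:
        return len(self.group_names)

    @property
    def xlog0(self) -> np.ndarray:
        """Log-values with zeros at absent positions (safe for masked algebra)."""
        return np.where(self.Y, self.Xlog, 0.0)

    def support(self, i: int) -> np.ndarray:
        """Indices of the present components of row ``i`` (the set ``V(Y_i)``)."""
        return np.flatnonzero(self.Y[i])

    def subset_columns(self, keep: np.ndarray) -> "SemicontDataset":
        keep = np.asarray(keep)
        cols = None if self.columns is None else tuple(self.columns[j] for j in keep)
        return SemicontDataset(self.X[:, keep], self.groups, cols)

    def column_name(self, j: int) -> str:
        return self.columns[j] if self.columns is not None else str(j)


def derive_presence(dataset: SemicontDataset) -> SemicontDataset:
    """Return the dataset with presence indicators and log-values derived.

    Derivation happens on construction, so this is idempotent; it exists so
    pipelines can state the step explicitly and revalidate inputs built by
    other code paths.
    """
    if isinstance(dataset, SemicontDataset):
        return dataset
    raise TypeError("derive_presence expects a SemicontDataset")


# ---------------------------------------------------------------------------
# variable filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """Outcome of the pairwise-co-observation filter.

    ``removed`` lists removed column indices (relative to the *original*
    matrix) in removal order, aligned with ``reasons``; ``p_star`` is the
    retained dimension.
    """

    removed: list
    reasons: list
    p_original: int

    @property
    def p_star(self) -> int:
        return self.p_original - len(self.removed)


def filter_pairwise_support(dataset: SemicontDataset):
    """Remove variables until every retained pair is co-observed at least once.

    The entry-wise denominator of the penalized covariance estimator is the
    matrix of co-presence counts ``sum_i Y_ij1 Y_ij2`` (pooled over groups);
    every entry must be positive for the estimator to exist.  Variables that
    break the condition are removed greedily, starting from those with the
    largest number of absent components; among equally absent columns the
    largest index is removed first, which makes the outcome independent of
    row order.  Columns with no presences at all are removed as well.

    Returns
    -------
    (filtered_dataset, FilterReport)
    """
    Y = dataset.Y.astype(np.int64)
    n, p = Y.shape
    co = Y.T @ Y
    presences = np.diag(co).copy()
    retained = np.ones(p, dtype=bool)
    removed: list = []
    reasons: list = []

    for j in np.flatnonzero(presences == 0):
        retained[j] = False
        removed.append(int(j))
        reasons.append("no presences")

    while True:
        idx = np.flatnonzero(retained)
        if idx.size < 2:
            raise DegenerateDataError(
                "fewer than 2 variables survive the pairwise co-observation filter"
            )
        sub = co[np.ix_(idx, idx)]
        viol = sub == 0
        np.fill_diagonal(viol, False)
        if not viol.any():
            break
        cand = idx[viol.any(axis=0)]
        absences = n - presences[cand]
        worst = cand[absences == absences.max()]
        j = int(worst.max())  # tie-break: largest column index first
        retained[j] = False
        removed.append(j)
        reasons.append("never co-observed with another retained variable")

    report = FilterReport(removed=removed, reasons=reasons, p_original=p)
    if not removed:
        return dataset, report
    logger.info(
        "pairwise-support filter removed %d of %d variables (p*=%d)",
        len(removed), p, report.p_star,
    )
    return dataset.subset_columns(np.flatnonzero(retained)), report


# ---------------------------------------------------------------------------
# closed-form penalized estimators
# ---------------------------------------------------------------------------


def _log_config_coef(p: int) -> np.ndarray:
    """``log[s! (p-s)! / p!]`` for s = 0..p, i.e. minus the log binomial coefficient."""
    s = np.arange(p + 1, dtype=float)
    return gammaln(s + 1.0) + gammaln(p - s + 1.0) - gammaln(p + 1.0)


def estimate_pi(dataset: SemicontDataset, null_model: bool = False) -> np.ndarray:
    """Configuration-probability estimates of the exchangeable Bernoulli part.

    ``pi_k(s)`` is the probability of one *specific* configuration with ``s``
    presences: the empirical frequency of support size ``s`` divided by the
    number ``C(p, s)`` of such configurations.  Under the null the groups are
    pooled.  Returns a ``K x (p+1)`` table (alternative) or a length-``p+1``
    vector (null), indexed by ``s``.
    """
    p = dataset.p
    coef = np.exp(_log_config_coef(p))
    if null_model:
        counts = np.bincount(dataset.nik, minlength=p + 1).astype(float)
        return coef * counts / dataset.n
    out = np.empty((dataset.K, p + 1))
    for k in range(dataset.K):
        counts = np.bincount(
            dataset.nik[dataset.group_codes == k], minlength=p + 1
        ).astype(float)
        out[k] = coef * counts / dataset.nk[k]
    return out


def estimate_mu(dataset: SemicontDataset, null_model: bool = False) -> np.ndarray:
    """Observed-components-only means of the log-values.

    Alternative: ``K x p`` matrix of within-group means over present entries.
    A column with no presences in some group has an *unidentified* mean for
    that group; the entry is set to NaN.  Such an entry never enters the
    likelihood (the column belongs to no support set of that group), so the
    fit is well defined regardless.  Null: pooled length-``p`` means, which
    the pairwise filter guarantees to exist.
    """
    Y = dataset.Y
    xs = dataset.xlog0
    if null_model:
        cnt = Y.sum(axis=0).astype(float)
        if (cnt == 0).any():
            raise DegenerateDataError(
                "a variable has no presences pooled across groups; run filter_pairwise_support first"
            )
        return xs.sum(axis=0) / cnt
    out = np.empty((dataset.K, dataset.p))
    for k in range(dataset.K):
        rows = dataset.group_codes == k
        cnt = Y[rows].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[k] = np.where(cnt > 0, xs[rows].sum(axis=0) / np.maximum(cnt, 1.0), np.nan)
    return out


def _as_penalty_vector(lam, p: int) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if lam.ndim == 0:
        lam = np.full(p, float(lam))
    if lam.shape != (p,):
        raise ValueError(f"penalty vector must be scalar or length {p}")
    if (lam < 0).any():
        raise ValueError("penalty values must be nonnegative")
    return lam


def _residual_matrix(dataset: SemicontDataset, mu: np.ndarray, null_model: bool) -> np.ndarray:
    """Masked residuals: ``(xlog - mu) * Y`` with zeros at absent entries."""
    if null_model:
        mu_rows = np.broadcast_to(mu, (dataset.n, dataset.p))
    else:
        mu_rows = mu[dataset.group_codes]
    return np.where(dataset.Y, dataset.xlog0 - np.where(dataset.Y, mu_rows, 0.0), 0.0)


def estimate_sigma(
    dataset: SemicontDataset,
    mu: np.ndarray,
    lam,
    null_model: bool = False,
) -> np.ndarray:
    """Entry-wise ratio estimator of the common covariance of log-values.

    Entry ``(j1, j2)`` is the cross-product of residuals over observations
    where both variables are present, plus ``Lambda[j1, j2]`` (so the
    penalty loads only the diagonal), divided by the co-presence count.
    With ``lam = 0`` and complete data this is the n-divisor Gaussian MLE.
    """
    lam = _as_penalty_vector(lam, dataset.p)
    Z = _residual_matrix(dataset, mu, null_model)
    num = Z.T @ Z
    num[np.diag_indices_from(num)] += lam
    den = (dataset.Y.astype(float).T @ dataset.Y.astype(float))
    if (den == 0).any():
        raise SingularModelError(
            "a co-presence denominator is zero: filter_pairwise_support contract violated"
        )
    sigma = num / den
    return (sigma + sigma.T) / 2.0


@dataclass
class ModelParams:
    """Fitted parameters (pi, mu, Sigma) together with the penalty that produced Sigma.

    ``pi`` is ``K x (p+1)`` under the alternative and length ``p+1`` under
    the null; ``mu`` is ``K x p`` or length ``p`` accordingly.  ``Sigma`` is
    common to the groups.  ``n_parameters`` is the free-parameter count
    ``2 K p + p (p + 1) / 2`` (with ``K = 1`` under the null).
    """

    pi: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    lam: np.ndarray
    null_model: bool = False

    @property
    def p(self) -> int:
        return self.sigma.shape[0]

    @property
    def K(self) -> int:
        return 1 if self.null_model else self.pi.shape[0]

    @property
    def n_parameters(self) -> int:
        return 2 * self.K * self.p + self.p * (self.p + 1) // 2

    def to_dict(self) -> dict:
        return {
            "null_model": self.null_model,
            "pi": np.asarray(self.pi).tolist(),
            "mu": np.asarray(self.mu).tolist(),
            "sigma": np.asarray(self.sigma).tolist(),
            "lambda": np.asarray(self.lam).tolist(),
            "p": self.p,
            "n_parameters": self.n_parameters,
        }


def fit_model(dataset: SemicontDataset, lam, null_model: bool = False) -> ModelParams:
    """Penalized closed-form fit of the full model (pi, mu, Sigma)."""
    pi = estimate_pi(dataset, null_model)
    mu = estimate_mu(dataset, null_model)
    sigma = estimate_sigma(dataset, mu, lam, null_model)
    return ModelParams(pi=pi, mu=mu, sigma=sigma,
                       lam=_as_penalty_vector(lam, dataset.p), null_model=null_model)


# ---------------------------------------------------------------------------
# likelihood evaluation
# ---------------------------------------------------------------------------


def _pattern_groups(dataset: SemicontDataset) -> dict:
    """Rows grouped by presence pattern (patterns repeat across permutations,
    so per-pattern factorizations are computed once and reused)."""
    groups: dict = {}
    for i in range(dataset.n):
        groups.setdefault(dataset.Y[i].tobytes(), []).append(i)
    return groups


def loglik(params: ModelParams, dataset: SemicontDataset) -> float:
    """Unpenalized log-likelihood of ``params`` on ``dataset``.

    Sum over observations of the log configuration probability (the
    probability of the observed pattern itself, *not* of its support size)
    plus the Gaussian log-density of the observed log-values under the
    corresponding marginal ``N(mu_V, Sigma_V)``.  An all-absent observation
    contributes only ``log pi(0)``.  Returns ``-inf`` (with a log record) if
    an observed configuration has zero probability under ``params``.
    """
    p = dataset.p
    codes = dataset.group_codes
    total = 0.0
    pi = np.asarray(params.pi, dtype=float)
    for i in range(dataset.n):
        s = int(dataset.nik[i])
        val = pi[s] if params.null_model else pi[codes[i], s]
        if val <= 0.0:
            logger.warning(
                "observed configuration with %d presences has zero probability; log-likelihood is -inf", s
            )
            return -np.inf
        total += math.log(val)

    mu = np.asarray(params.mu, dtype=float)
    sigma = np.asarray(params.sigma, dtype=float)
    for key, rows in _pattern_groups(dataset).items():
        V = np.flatnonzero(np.frombuffer(key, dtype=bool))
        s = V.size
        if s == 0:
            continue
        sig_V = sigma[np.ix_(V, V)]
        try:
            cf = cho_factor(sig_V, lower=True)
        except LinAlgError as exc:
            raise SingularModelError(
                f"singular covariance submatrix for presence pattern {V.tolist()}"
            ) from exc
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        for i in rows:
            mu_i = mu[V] if params.null_model else mu[codes[i], V]
            e = dataset.Xlog[i, V] - mu_i
            qf = float(e @ cho_solve(cf, e))
            total += -0.5 * (s * LOG_2PI + logdet + qf)
    return total


def penalty_term(lam, sigma: np.ndarray, dataset: SemicontDataset) -> float:
    """Diagonal-loading penalty ``P(lambda, Sigma)`` summed over observation supports.

    ``P = sum_i tr(Lambda_V Sigma_V^{-1})`` over each observation's support
    ``V``; empty supports contribute 0.  The penalized log-likelihood is
    ``loglik - penalty_term / 2``.
    """
    lam = _as_penalty_vector(lam, dataset.p)
    sigma = np.asarray(sigma, dtype=float)
    total = 0.0
    for key, rows in _pattern_groups(dataset).items():
        V = np.flatnonzero(np.frombuffer(key, dtype=bool))
        if V.size == 0:
            continue
        sig_V = sigma[np.ix_(V, V)]
        try:
            cf = cho_factor(sig_V, lower=True)
        except LinAlgError as exc:
            raise SingularModelError(
                f"singular covariance submatrix for presence pattern {V.tolist()}"
            ) from exc
        inv_diag = np.diag(cho_solve(cf, np.eye(V.size)))
        total += len(rows) * float(lam[V] @ inv_diag)
    return total
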