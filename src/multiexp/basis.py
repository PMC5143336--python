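"""Linear algebra of the non-orthogonal exponential basis.

The decay curve is modelled as a linear combination of decaying exponentials
``phi_i(t) = exp(-k_i t)`` with rate constants (decrements) ``k_i > 0``.  The
basis is not orthogonal, so the optimal weights are obtained through the Gram
matrix ``G`` of pairwise inner products and its inverse, which defines the
reciprocal (biorthogonal) basis ``theta_j``:

    G a = beta,        beta_i = (x, phi_i),
    alpha_i = (x, theta_i),   theta_j = sum_k Gamma_jk phi_k,  Gamma = G^-1.

On sampled data the inner product is the plain discrete dot product over the
sample grid, which makes the projection exactly a discrete least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .exceptions import IllConditionedBasisError
from .signal import SampledSignal

__all__ = [
    "ExponentialBasis",
    "GramMatrix",
    "ReciprocalBasis",
    "evaluate_basis",
    "gram_matrix",
    "reciprocal_basis",
    "project_weights",
    "dispersion",
]

#: Gram condition number above which a candidate basis is considered invalid.
DEFAULT_CONDITION_LIMIT = 1e12


@dataclass(frozen=True)
class ExponentialBasis:
    """Decaying exponentials evaluated on a sampling grid.

    Attributes
    ----------
    decrements : ndarray, shape (n,)
        Rate constants ``k_i`` in 1/s, strictly positive, pairwise distinct.
    grid : ndarray, shape (N,)
        The sampling times, strictly increasing, first time >= 0.
    values : ndarray, shape (n, N)
        ``values[i, j] = exp(-k_i * t_j)``; each entry lies in (0, 1].
    """

    decrements: np.ndarray
    grid: np.ndarray
    values: np.ndarray

    @property
    def n(self) -> int:
        return self.decrements.size


@dataclass(frozen=True)
class GramMatrix:
    """Gram matrix of an exponential basis, with the projected signal.

    ``entries[i, j] = (phi_i, phi_j)`` (symmetric by construction) and, when a
    signal was supplied, ``beta[i] = (x, phi_i)``.  ``condition`` is the
    2-norm condition number estimate; callers treat bases whose condition
    exceeds their limit as invalid rather than inverting them.
    """

    entries: np.ndarray
    condition: float
    beta: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def ill_conditioned(self, limit: float = DEFAULT_CONDITION_LIMIT) -> bool:
        return not np.isfinite(self.condition) or self.condition > limit


@dataclass(frozen=True)
class ReciprocalBasis:
    """Basis biorthogonal to an exponential basis: ``(phi_i, theta_j) = delta_ij``.

    ``gamma`` is the inverse Gram matrix (real symmetric, so conjugation is
    trivial) and ``theta[j] = sum_k gamma[j, k] * phi_k`` evaluated on the grid.
    """

    gamma: np.ndarray
    theta: np.ndarray


def evaluate_basis(decrements, grid) -> ExponentialBasis:
    """Evaluate the exponential basis ``exp(-k_i t_j)`` on a time grid.

    Parameters
    ----------
    decrements : array-like
        Rate constants in 1/s; strictly positive and pairwise distinct.
    grid : array-like
        Strictly increasing times in seconds, first time >= 0.

    Returns
    -------
    ExponentialBasis
    """
    ks = np.atleast_1d(np.asarray(decrements, dtype=float))
    t = np.atleast_1d(np.asarray(grid, dtype=float))
    if ks.size == 0:
        raise ValueError("at least one decrement is required")
    if t.size == 0:
        raise ValueError("the time grid is empty")
    if np.any(~np.isfinite(ks)) or np.any(ks <= 0):
        raise ValueError("decrements must be finite and strictly positive")
    if np.unique(ks).size != ks.size:
        raise ValueError("decrements must be pairwise distinct "
                         "(duplicates make the basis linearly dependent)")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("grid times must be strictly increasing")
    if t[0] < 0:
        raise ValueError("grid times must be non-negative")
    values = np.exp(-np.outer(ks, t))
    return ExponentialBasis(decrements=ks, grid=t, values=values)


def gram_matrix(basis: ExponentialBasis, signal: SampledSignal | None = None) -> GramMatrix:
    """Build the Gram matrix ``G_ij = (phi_i, phi_j)`` (and ``beta`` if given a signal).

    The inner product is the discrete dot product over the sample grid.  The
    matrix is symmetrized explicitly so ``G == G.T`` holds exactly.  A large
    condition number is recorded, not raised: upstream sweeps use it to
    reject near-degenerate candidate bases.
    """
    if signal is not None and not np.array_equal(basis.grid, signal.times):
        raise ValueError("basis grid and signal times must be identical")
    m = basis.values @ basis.values.T
    g = 0.5 * (m + m.T)
    condition = float(np.linalg.cond(g))
    beta = basis.values @ signal.amplitudes if signal is not None else None
    return GramMatrix(entries=g, condition=condition, beta=beta)


def reciprocal_basis(
    gram: GramMatrix,
    basis: ExponentialBasis,
    condition_limit: float = DEFAULT_CONDITION_LIMIT,
) -> ReciprocalBasis:
    """Construct the reciprocal basis from ``Gamma = G^-1``.

    Raises
    ------
    IllConditionedBasisError
        If the Gram matrix condition exceeds ``condition_limit`` or the
        Cholesky factorization fails (G not numerically positive definite).
    """
    if gram.ill_conditioned(condition_limit):
        raise IllConditionedBasisError(
            f"Gram condition {gram.condition:.3g} exceeds limit {condition_limit:.3g}"
        )
    try:
        factor = cho_factor(gram.entries, lower=True)
    except LinAlgError as exc:
        raise IllConditionedBasisError(
            "Gram matrix is not positive definite"
        ) from exc
    gamma = cho_solve(factor, np.eye(gram.n))
    gamma = 0.5 * (gamma + gamma.T)
    theta = gamma @ basis.values
    return ReciprocalBasis(gamma=gamma, theta=theta)


def project_weights(
    signal: SampledSignal,
    basis: ExponentialBasis,
    condition_limit: float = DEFAULT_CONDITION_LIMIT,
) -> np.ndarray:
    """Optimal weights ``alpha_i = (x, theta_i)`` of the signal in the basis.

    Equivalent to solving the normal equations ``G a = beta`` by a stable
    Cholesky factorization; the result minimizes the sum of squared residuals
    over the basis span.  Signs are unconstrained at this layer — positivity
    is a policy of the optimizer, enforced by candidate rejection.
    """
    gram = gram_matrix(basis, signal)
    if gram.ill_conditioned(condition_limit):
        raise IllConditionedBasisError(
            f"Gram condition {gram.condition:.3g} exceeds limit {condition_limit:.3g}"
        )
    try:
        factor = cho_factor(gram.entries, lower=True)
    except LinAlgError as exc:
        raise IllConditionedBasisError(
            "Gram matrix is not positive definite"
        ) from exc
    return cho_solve(factor, gram.beta)


def dispersion(signal: SampledSignal, model) -> float:
    """Mean squared residual of the peak-normalized signal under a model.

    ``model`` is anything with a ``predict(times)`` method returning the
    modelled amplitude on the signal's scale (e.g. a
    :class:`~multiexp.optimize.DecompositionModel`).  Residuals are divided
    by the first-sample amplitude before squaring, so a noise level quoted as
    a fraction of the initial amplitude maps directly onto ``sqrt(dispersion)``.
    Returns 0 exactly when the model reproduces the signal exactly.
    """
    x0 = signal.amplitudes[0]
    if x0 == 0:
        raise ValueError("dispersion is undefined for a signal starting at zero")
    r = (signal.amplitudes - model.predict(signal.times)) / x0
    return float(r @ r) / r.size
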