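"""Parameter containers and transforms for the state-switching SSF.

Movement coefficients on (L, log L, cos theta) map one-to-one onto gamma
step-length and von Mises turning-angle parameters.  Transition
probabilities follow a multinomial logit with covariates and structural
zeros on the diagonal linear predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SsfCoefficients",
    "TransitionModel",
    "HmmSsfModel",
    "MovementParams",
    "gamma_from_coeffs",
    "coeffs_from_gamma",
    "vonmises_from_coeff",
    "coeff_from_vonmises",
    "transition_matrix",
    "stationary_distribution",
    "rss",
    "selection_ratio",
]


@dataclass
class MovementParams:
    """Natural-scale movement parameters for one state."""

    mean_length: float
    sd_length: float
    angle_mean: float  # 0 or pi
    concentration: float
    valid: bool = True


def gamma_from_coeffs(beta_length: float, beta_log_length: float):
    """Gamma step-length mean/SD implied by the (L, log L) coefficients.

    shape = beta_log_length + 2 and rate = -beta_length, so
    mean = (beta_log_length + 2) / (-beta_length) and
    sd = sqrt(beta_log_length + 2) / (-beta_length).

    Unconstrained estimates may not correspond to a valid distribution
    (shape or rate nonpositive); a validity flag is returned instead of
    raising.
    """
    shape = beta_log_length + 2.0
    rate = -beta_length
    if shape <= 0 or rate <= 0:
        return np.nan, np.nan, False
    return shape / rate, np.sqrt(shape) / rate, True


def coeffs_from_gamma(mean_length: float, sd_length: float) -> tuple[float, float]:
    """Inverse of :func:`gamma_from_coeffs`."""
    if mean_length <= 0 or sd_length <= 0:
        raise ValueError("gamma mean and sd must be positive")
    shape = (mean_length / sd_length) ** 2
    rate = mean_length / sd_length**2
    return -rate, shape - 2.0


def vonmises_from_coeff(beta_cos_angle: float) -> tuple[float, float]:
    """Von Mises turning-angle (mean, concentration) from the cos-theta
    coefficient: mean 0 for a nonnegative coefficient, pi otherwise;
    concentration is the absolute value."""
    mu = 0.0 if beta_cos_angle >= 0 else np.pi
    return mu, abs(beta_cos_angle)


def coeff_from_vonmises(angle_mean: float, concentration: float) -> float:
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    sign = 1.0 if np.cos(angle_mean) >= 0 else -1.0
    return sign * concentration


def selection_ratio(beta: float) -> float:
    """exp(beta): multiplicative effect on the selection density of a unit
    covariate increase."""
    return float(np.exp(beta))


def rss(beta: float) -> float:
    """Relative selection strength of the *reference* category versus the
    category carrying coefficient ``beta``: 1/exp(beta)."""
    return float(1.0 / np.exp(beta))


# ---------------------------------------------------------------------------
# Coefficient containers

@dataclass
class SsfCoefficients:
    """Per-state selection coefficients aligned to design columns."""

    beta: np.ndarray  # (K, p)
    colnames: list[str]

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if self.beta.shape[1] != len(self.colnames):
            raise ValueError("beta width must match column names")

    @property
    def n_states(self) -> int:
        return self.beta.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.beta[:, self.colnames.index(name)]

    def movement_params(self, k: int) -> MovementParams:
        """Natural-scale movement parameters of state k (0-based)."""
        names = self.colnames
        if "length" not in names or "log_length" not in names:
            raise ValueError("formula lacks gamma movement terms")
        mu, sd, ok = gamma_from_coeffs(
            self.beta[k, names.index("length")],
            self.beta[k, names.index("log_length")],
        )
        if "cos_angle" in names:
            am, kappa = vonmises_from_coeff(self.beta[k, names.index("cos_angle")])
        else:
            am, kappa = 0.0, 0.0
        return MovementParams(mu, sd, am, kappa, valid=ok)


def _pair_order(K: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(K) for j in range(K) if i != j]


@dataclass
class TransitionModel:
    """Multinomial-logit transition probabilities with covariates.

    ``alpha`` has one row per ordered state pair (i, j), i != j, in
    row-major order, and columns (intercept, covariate 1..P).  Diagonal
    linear predictors are structurally zero.
    """

    n_states: int
    covariates: list[str] = field(default_factory=list)
    alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        K, P = self.n_states, len(self.covariates)
        if self.alpha is None:
            self.alpha = np.zeros((K * (K - 1), P + 1))
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        if self.alpha.shape != (K * (K - 1), P + 1):
            raise ValueError(
                f"alpha must be ({K * (K - 1)}, {P + 1}), got {self.alpha.shape}"
            )

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return _pair_order(self.n_states)

    def linear_predictors(self, omega: np.ndarray) -> np.ndarray:
        """eta as a (T, K, K) array with zero diagonal; omega is (T, P)."""
        K = self.n_states
        omega = np.atleast_2d(np.asarray(omega, dtype=float))
        T = omega.shape[0]
        if omega.shape[1] != len(self.covariates):
            raise ValueError("omega width must match covariate count")
        X = np.column_stack([np.ones(T), omega])
        eta_flat = X @ self.alpha.T  # (T, K(K-1))
        eta = np.zeros((T, K, K))
        for idx, (i, j) in enumerate(self.pairs):
            eta[:, i, j] = eta_flat[:, idx]
        return eta


def transition_matrix(transitions: TransitionModel, omega) -> np.ndarray:
    """Transition probability matrices Gamma^(t), one per covariate row.

    gamma_ij = exp(eta_ij) / sum_k exp(eta_ik) with eta_ii = 0; each row
    sums to one and all entries lie in (0, 1).  A single covariate row
    yields a single (K, K) matrix.
    """
    single = np.ndim(omega) <= 1
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    eta = transitions.linear_predictors(omega)
    eta -= eta.max(axis=2, keepdims=True)
    ex = np.exp(eta)
    gam = ex / ex.sum(axis=2, keepdims=True)
    return gam[0] if single else gam


def stationary_distribution(gamma: np.ndarray) -> np.ndarray:
    """Stationary distribution delta with delta @ Gamma = delta, sum 1.

    Solved as a linear system — (I - Gamma)' with the last balance
    equation replaced by the normalisation constraint — not by matrix
    powers.  Requires an irreducible chain (all-positive entries suffice).
    """
    gamma = np.asarray(gamma, dtype=float)
    K = gamma.shape[0]
    if gamma.shape != (K, K):
        raise ValueError("Gamma must be square")
    A = np.eye(K) - gamma.T
    A[-1, :] = 1.0
    b = np.zeros(K)
    b[-1] = 1.0
    try:
        delta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate transition matrix") from exc
    if not np.all(np.isfinite(delta)) or np.any(delta < -1e-10):
        raise ValueError("transition matrix is reducible or degenerate")
    delta = np.clip(delta, 0.0, None)
    return delta / delta.sum()


@dataclass
class HmmSsfModel:
    """Full model: K states, per-state SSF coefficients, transition model.

    The number of states is fixed a priori, never estimated.  For
    reporting, states are ordered by ascending mean step length (slow
    state first), which resolves label switching deterministically.
    """

    ssf: SsfCoefficients
    transitions: TransitionModel

    def __post_init__(self) -> None:
        if self.ssf.n_states != self.transitions.n_states:
            raise ValueError("ssf and transition model disagree on K")

    @property
    def n_states(self) -> int:
        return self.ssf.n_states

    def movement_params(self) -> list[MovementParams]:
        return [self.ssf.movement_params(k) for k in range(self.n_states)]

    def state_order(self) -> np.ndarray:
        """Permutation sorting states by ascending mean step length."""
        try:
            mus = [self.ssf.movement_params(k).mean_length for k in range(self.n_states)]
        except ValueError:
            return np.arange(self.n_states)
        mus = [np.inf if not np.isfinite(m) else m for m in mus]
        return np.argsort(mus, kind="stable")

    def relabelled(self) -> "HmmSsfModel":
        """Model with states permuted into reporting order."""
        perm = self.state_order()
        if np.array_equal(perm, np.arange(self.n_states)):
            return self
        return permute_states(self, perm)


def permute_states(model: HmmSsfModel, perm: np.ndarray) -> HmmSsfModel:
    """Relabel states: new state k is old state perm[k]."""
    K = model.n_states
    beta = model.ssf.beta[perm]
    old_pairs = _pair_order(K)
    new_alpha = np.empty_like(model.transitions.alpha)
    lookup = {pair: r for r, pair in enumerate(old_pairs)}
    for r, (i, j) in enumerate(old_pairs):
        new_alpha[r] = model.transitions.alpha[lookup[(perm[i], perm[j])]]
    return HmmSsfModel(
        ssf=SsfCoefficients(beta, list(model.ssf.colnames)),
        transitions=TransitionModel(
            K, list(model.transitions.covariates), new_alpha
        ),
    )
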