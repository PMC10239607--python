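"""Likelihood approximation, maximum-likelihood fitting and uncertainty.

The state-dependent density of each observed step is approximated by the
case-control Monte Carlo sum (importance-weighted when controls come from
a non-uniform scheme), and the model likelihood is evaluated with the
scaled forward algorithm over the latent state chain.  Fitting is
unconstrained quasi-Newton minimisation of the negative log-likelihood
with multiple starting points; standard errors come from the inverse of a
finite-difference Hessian at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .design import StepSets
from .model import (
    HmmSsfModel,
    SsfCoefficients,
    TransitionModel,
    coeff_from_vonmises,
    coeffs_from_gamma,
    permute_states,
    stationary_distribution,
    transition_matrix,
)

__all__ = [
    "log_state_densities",
    "forward_nll",
    "fit",
    "FitResult",
    "transition_cis",
    "numerical_hessian",
]

Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# State-dependent densities

def log_state_densities(step_sets: StepSets, beta: np.ndarray,
                        use_importance: bool = True) -> np.ndarray:
    """Log approximate step density per (step, state).

    numerator:   exp{c(y_t, z_0t) . beta_k}
    denominator: (1 / n_valid) * sum_i exp{c(y_t, z_it) . beta_k} / h_it
    over valid endpoints, with h = 1 for plain Monte Carlo.  Everything is
    computed on the log scale with log-sum-exp.  Rows for unusable steps
    are NaN (the forward algorithm substitutes identity matrices).
    """
    if step_sets.covariates is None:
        raise ValueError("run build_design before computing densities")
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    C = step_sets.covariates
    valid = step_sets.valid
    usable = step_sets.usable
    n_valid = valid.sum(axis=1)
    if np.any(usable & (n_valid < 2)):
        bad = np.flatnonzero(usable & (n_valid < 2))[:5]
        raise ValueError(f"steps with fewer than 2 valid endpoints: {bad.tolist()}")

    scores = np.einsum("smp,kp->smk", np.nan_to_num(C), beta)
    if use_importance:
        with np.errstate(divide="ignore", invalid="ignore"):
            logh = np.log(step_sets.h)
        terms = scores - np.nan_to_num(logh)[..., None]
    else:
        terms = scores
    terms = np.where(valid[..., None], terms, -np.inf)
    with np.errstate(invalid="ignore"):
        logden = special.logsumexp(terms, axis=1) - np.log(
            np.maximum(n_valid, 1)
        )[:, None]
    out = scores[:, 0, :] - logden
    out[~usable] = np.nan
    return out


# ---------------------------------------------------------------------------
# Forward algorithm

def _track_slices(steps: pd.DataFrame) -> list[slice]:
    ids = steps["track_id"].to_numpy()
    change = np.flatnonzero(ids[1:] != ids[:-1]) + 1
    bounds = np.concatenate([[0], change, [len(ids)]])
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def _forward_track_py(ld: np.ndarray, gm: np.ndarray, delta: np.ndarray) -> float:
    T, K = ld.shape
    ll = 0.0
    v = delta.copy()
    for t in range(T):
        if t > 0:
            v = v @ gm[t]
        row = ld[t]
        usable = True
        m = -np.inf
        for k in range(K):
            x = row[k]
            if not np.isfinite(x):
                usable = False
                break
            if x > m:
                m = x
        if usable:
            for k in range(K):
                v[k] = v[k] * np.exp(row[k] - m)
            ll += m
        c = v.sum()
        if c <= 0 or not np.isfinite(c):
            return np.nan
        ll += np.log(c)
        v = v / c
    return ll


try:  # jitted hot loop; identical semantics to the python fallback
    from numba import njit

    _forward_track = njit(cache=False, fastmath=False)(_forward_track_py)
except ImportError:  # pragma: no cover
    _forward_track = _forward_track_py


def forward_nll(log_dens: np.ndarray, gammas: np.ndarray,
                track_slices: list[slice]) -> float:
    """Scaled-forward negative log-likelihood, pooled over tracks.

    ``log_dens`` is (S, K) with NaN rows for steps excluded from the
    likelihood (missing data, undefined turning angle); those contribute
    identity observation matrices.  ``gammas`` is (S, K, K): the matrix at
    position t applies *before* step t's density; the first matrix of each
    track is only used for the stationary initial distribution.  Tracks
    share parameters and their log-likelihoods add.
    """
    log_dens = np.ascontiguousarray(log_dens, dtype=float)
    gammas = np.ascontiguousarray(gammas, dtype=float)
    total = 0.0
    for sl in track_slices:
        delta = stationary_distribution(gammas[sl][0])
        ll = _forward_track(log_dens[sl], gammas[sl], delta)
        if not np.isfinite(ll):
            raise ValueError("forward pass underflow or invalid density")
        total += ll
    return -total


# ---------------------------------------------------------------------------
# Parameter packing

@dataclass
class ParameterLayout:
    n_states: int
    colnames: list[str]
    transition_covariates: list[str]

    @property
    def n_beta(self) -> int:
        return self.n_states * len(self.colnames)

    @property
    def n_alpha(self) -> int:
        K = self.n_states
        return K * (K - 1) * (len(self.transition_covariates) + 1)

    @property
    def size(self) -> int:
        return self.n_beta + self.n_alpha

    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        K, p = self.n_states, len(self.colnames)
        beta = theta[: self.n_beta].reshape(K, p)
        q = len(self.transition_covariates) + 1
        alpha = theta[self.n_beta:].reshape(K * (K - 1), q)
        return beta, alpha

    def pack(self, beta: np.ndarray, alpha: np.ndarray) -> np.ndarray:
        return np.concatenate([np.ravel(beta), np.ravel(alpha)])

    def names(self) -> list[str]:
        K = self.n_states
        out = [
            f"beta[{k + 1}]:{c}" for k in range(K) for c in self.colnames
        ]
        acols = ["intercept"] + list(self.transition_covariates)
        for i in range(K):
            for j in range(K):
                if i != j:
                    out.extend(f"alpha[{i + 1}->{j + 1}]:{c}" for c in acols)
        return out

    def to_model(self, theta: np.ndarray) -> HmmSsfModel:
        beta, alpha = self.unpack(theta)
        return HmmSsfModel(
            ssf=SsfCoefficients(beta, list(self.colnames)),
            transitions=TransitionModel(
                self.n_states, list(self.transition_covariates), alpha
            ),
        )

    def from_model(self, model: HmmSsfModel) -> np.ndarray:
        return self.pack(model.ssf.beta, model.transitions.alpha)

    def state_permutation_vector(self, perm: np.ndarray) -> np.ndarray:
        """Index vector relabelling the packed parameters by state."""
        base = self.to_model(np.arange(self.size, dtype=float))
        permuted = permute_states(base, perm)
        return self.from_model(permuted).astype(int)


def make_nll(step_sets: StepSets, layout: ParameterLayout,
             use_importance: bool = True):
    """Closure evaluating the pooled NLL for a packed parameter vector.

    Design arrays are cached outside the closure so repeated evaluations
    inside the optimiser only pay for the linear algebra.
    """
    omega = step_sets.transition_covariates(layout.transition_covariates)
    slices = _track_slices(step_sets.steps)
    K = layout.n_states
    usable = step_sets.usable
    valid = step_sets.valid
    n_valid = np.maximum(valid.sum(axis=1), 1)
    C = np.nan_to_num(step_sets.covariates)
    S, M, _ = C.shape
    Cflat = np.ascontiguousarray(C.reshape(S * M, -1))
    if use_importance:
        with np.errstate(divide="ignore", invalid="ignore"):
            offset = -np.nan_to_num(np.log(step_sets.h))
    else:
        offset = np.zeros((S, M))
    offset = np.where(valid, offset, -np.inf)[..., None]
    X = np.column_stack([np.ones(S), omega])  # transition design
    pairs = _pair_order_cache(K)
    log_n_valid = np.log(n_valid)[:, None]

    def nll(theta: np.ndarray) -> float:
        beta, alpha = layout.unpack(theta)
        scores = (Cflat @ beta.T).reshape(S, M, K)
        terms = scores + offset
        m = terms.max(axis=1)
        with np.errstate(invalid="ignore"):
            logden = m + np.log(
                np.exp(terms - m[:, None, :]).sum(axis=1)
            ) - log_n_valid
        ld = scores[:, 0, :] - logden
        ld[~usable] = np.nan
        eta_flat = X @ alpha.T  # (S, K(K-1))
        eta = np.zeros((S, K, K))
        for idx, (i, j) in enumerate(pairs):
            eta[:, i, j] = eta_flat[:, idx]
        eta -= eta.max(axis=2, keepdims=True)
        ex = np.exp(eta)
        gammas = ex / ex.sum(axis=2, keepdims=True)
        try:
            return forward_nll(ld, gammas, slices)
        except ValueError:
            return np.inf

    return nll


def _pair_order_cache(K: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(K) for j in range(K) if i != j]


# ---------------------------------------------------------------------------
# Fitting

@dataclass
class FitResult:
    """Maximum-likelihood fit: estimates, uncertainty and diagnostics."""

    model: HmmSsfModel
    layout: ParameterLayout
    theta: np.ndarray
    nll: float
    converged: bool
    start_nlls: list[float]
    cov: np.ndarray | None = None
    se: np.ndarray | None = None
    seed: int | None = None
    n_controls: int | None = None
    messages: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return self.layout.names()

    @property
    def ci_lower(self) -> np.ndarray | None:
        return None if self.se is None else self.theta - Z95 * self.se

    @property
    def ci_upper(self) -> np.ndarray | None:
        return None if self.se is None else self.theta + Z95 * self.se

    def summary(self) -> pd.DataFrame:
        n = self.layout.size
        se = np.full(n, np.nan) if self.se is None else self.se
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.theta,
                "se": se,
                "ci_lower": self.theta - Z95 * se,
                "ci_upper": self.theta + Z95 * se,
            }
        )


def _initial_values(step_sets: StepSets, layout: ParameterLayout,
                    rng: np.random.Generator, n_starts: int) -> list[np.ndarray]:
    """Starting vectors around pooled movement-moment heuristics.

    Movement coefficients come from a moment fit of the pooled observed
    step lengths, with per-state multiplicative spread so states start
    separated; habitat and transition coefficients start as diffuse noise.
    """
    steps = step_sets.steps
    lengths = steps["length"].to_numpy()
    lengths = lengths[np.isfinite(lengths) & (lengths > 0)]
    mean, sd = float(lengths.mean()), float(lengths.std(ddof=1))
    K, cols = layout.n_states, layout.colnames
    centre = np.linspace(-1.0, 1.0, K) if K > 1 else np.zeros(1)
    starts = []
    for _ in range(n_starts):
        beta = np.zeros((K, len(cols)))
        factors = np.exp(centre + rng.normal(0, 0.3, size=K))
        factors.sort()
        for k in range(K):
            bl, bll = coeffs_from_gamma(mean * factors[k], sd * factors[k])
            for j, c in enumerate(cols):
                if c == "length":
                    beta[k, j] = bl
                elif c == "log_length":
                    beta[k, j] = bll
                elif c == "cos_angle":
                    beta[k, j] = coeff_from_vonmises(0.0, abs(rng.normal(0, 0.5)))
                else:
                    beta[k, j] = rng.normal(0, 0.5)
        alpha = np.zeros((K * (K - 1), len(layout.transition_covariates) + 1))
        alpha[:, 0] = rng.normal(-1.5, 0.5, size=alpha.shape[0])
        if alpha.shape[1] > 1:
            alpha[:, 1:] = rng.normal(0, 0.3, size=(alpha.shape[0], alpha.shape[1] - 1))
        starts.append(layout.pack(beta, alpha))
    return starts


def numerical_hessian(fun, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    x = np.asarray(x, dtype=float)
    n = x.size
    hs = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = hs[i]
        H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / hs[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * hs[i] * hs[j])
    return H


def fit(
    step_sets: StepSets,
    n_states: int,
    transition_covariates: tuple[str, ...] = (),
    n_starts: int = 10,
    seed: int = 0,
    use_importance: bool = True,
    compute_se: bool = True,
    maxiter: int = 1000,
    ftol: float = 1e-8,
    relabel: bool = True,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Fit the model by direct likelihood maximisation.

    Runs ``n_starts`` quasi-Newton minimisations from heuristic starting
    values (or a single run from ``x0`` when given) and keeps the lowest
    NLL.  States are relabelled by ascending mean step length.  Standard
    errors come from the pseudo-inverse of a finite-difference Hessian;
    a singular Hessian leaves SEs unavailable but the fit is returned.
    """
    if step_sets.covariates is None:
        raise ValueError("run build_design before fitting")
    layout = ParameterLayout(
        n_states, list(step_sets.colnames), list(transition_covariates)
    )
    n_usable = int(step_sets.usable.sum())
    if n_usable < layout.size * 10:
        warnings.warn(
            f"only {n_usable} usable steps for {layout.size} parameters",
            stacklevel=2,
        )
    nll = make_nll(step_sets, layout, use_importance=use_importance)
    rng = np.random.default_rng(seed)
    if x0 is not None:
        starts = [np.asarray(x0, dtype=float)]
    else:
        starts = _initial_values(step_sets, layout, rng, n_starts)

    best = None
    start_nlls: list[float] = []
    messages: list[str] = []
    for s, x_init in enumerate(starts):
        try:
            res = optimize.minimize(
                nll, x_init, method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": ftol},
            )
        except Exception as exc:  # pragma: no cover - defensive
            start_nlls.append(np.inf)
            messages.append(f"start {s}: {exc}")
            continue
        start_nlls.append(float(res.fun))
        if not res.success:
            messages.append(f"start {s}: {res.message}")
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"all {len(starts)} starts failed: {messages}")

    theta = np.asarray(best.x, dtype=float)
    model = layout.to_model(theta)
    if relabel:
        perm = model.state_order()
        if not np.array_equal(perm, np.arange(n_states)):
            idx = layout.state_permutation_vector(perm)
            theta = theta[idx]
            model = layout.to_model(theta)

    cov = se = None
    if compute_se:
        H = numerical_hessian(nll, theta)
        eig = np.linalg.eigvalsh((H + H.T) / 2)
        if eig.min() < 1e-10 * max(eig.max(), 1e-300):
            messages.append(
                "Hessian is ill-conditioned or not positive definite; "
                "standard errors use a pseudo-inverse and may be unreliable"
            )
        try:
            cov = np.linalg.pinv((H + H.T) / 2)
            diag = np.diag(cov)
            se = np.sqrt(np.where(diag > 0, diag, np.nan))
        except np.linalg.LinAlgError:
            messages.append("singular Hessian: standard errors unavailable")
            cov = se = None

    return FitResult(
        model=model,
        layout=layout,
        theta=theta,
        nll=float(best.fun),
        converged=bool(best.success),
        start_nlls=start_nlls,
        cov=cov,
        se=se,
        seed=seed,
        n_controls=step_sets.n_controls,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# Delta-method bands for transition probabilities

def transition_cis(fit_result: FitResult, omega_grid: np.ndarray,
                   level: float = 0.95):
    """Pointwise confidence bands for every transition probability.

    The band is built on the linear-predictor scale — for each ordered
    pair (i, j) the variance of eta_ij comes from the alpha-block
    covariance — and mapped through the multinomial-logit transform with
    the other linear predictors held at their estimates, so bands stay
    inside [0, 1].
    """
    if fit_result.cov is None:
        raise ValueError("fit has no covariance; cannot build bands")
    layout = fit_result.layout
    tm = fit_result.model.transitions
    K = layout.n_states
    omega_grid = np.atleast_2d(np.asarray(omega_grid, dtype=float))
    G = omega_grid.shape[0]
    X = np.column_stack([np.ones(G), omega_grid])
    q = X.shape[1]
    z = float(-special.ndtri((1 - level) / 2))

    acov = fit_result.cov[layout.n_beta:, layout.n_beta:]
    eta = tm.linear_predictors(omega_grid)  # (G, K, K)
    point = transition_matrix(tm, omega_grid)
    lower = np.array(point)
    upper = np.array(point)
    for idx, (i, j) in enumerate(tm.pairs):
        block = acov[idx * q:(idx + 1) * q, idx * q:(idx + 1) * q]
        var = np.einsum("gp,pq,gq->g", X, block, X)
        se = np.sqrt(np.clip(var, 0.0, None))
        for sign, out in ((-1.0, lower), (1.0, upper)):
            eta_mod = eta.copy()
            eta_mod[:, i, j] = eta[:, i, j] + sign * z * se
            ex = np.exp(eta_mod[:, i, :] - eta_mod[:, i, :].max(axis=1, keepdims=True))
            out[:, i, j] = ex[:, j] / ex.sum(axis=1)
    lo = np.minimum(lower, upper)
    hi = np.maximum(lower, upper)
    return point, lo, hi
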