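"""Simulation from a (fitted or specified) model, utilisation
distributions, and the parameter-recovery harness.

Track simulation first draws the latent state sequence from the
transition model, then selects each new location among uniformly
proposed endpoints on a disc, with probability proportional to the
state's selection weight.  Points outside the study boundary get weight
zero, which keeps tracks inside (a reflective-by-rejection boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .design import Formula, build_design, sample_controls
from .landscape import CONTINUOUS, CovariateLayer, Landscape, extract
from .model import HmmSsfModel, stationary_distribution, transition_matrix
from .tracks import Track, cyclic_time_covariates

__all__ = [
    "SimulationSpec",
    "UdGrid",
    "simulate_track",
    "estimate_ud",
    "recovery_study",
]

#: transition covariates the simulator can evaluate from timestamps
_TIME_COVARIATES = ("tod_cos", "tod_sin")


@dataclass
class SimulationSpec:
    """Settings for track simulation."""

    model: HmmSsfModel
    landscape: Landscape | None
    n_tracks: int = 1
    track_length: int = 1000
    interval_hours: float = 0.5
    n_proposals: int = 10_000
    radius: float | None = None
    burn_in: int = 0
    seed: int = 0
    start: tuple[float, float] | None = None
    start_time: str = "2020-01-01T00:00:00"

    def __post_init__(self) -> None:
        if self.n_proposals < 1:
            raise ValueError("need at least one proposal per step")
        if self.burn_in >= self.track_length:
            raise ValueError("burn_in must be smaller than track_length")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("disc radius must be positive")


def default_radius(model: HmmSsfModel) -> float:
    """Proposal-disc radius covering the bulk of the step-length mass:
    mean + 5 SD of the fastest state's gamma distribution."""
    best = 0.0
    for mp in model.movement_params():
        if mp.valid:
            best = max(best, mp.mean_length + 5 * mp.sd_length)
    if best <= 0:
        raise ValueError("model has no valid step-length distribution")
    return best


def _omega_from_times(names: list[str], times: pd.DatetimeIndex) -> np.ndarray:
    cols = []
    cosd, sind = cyclic_time_covariates(times)
    for n in names:
        if n == "tod_cos":
            cols.append(cosd)
        elif n == "tod_sin":
            cols.append(sind)
        else:
            raise ValueError(
                f"cannot evaluate transition covariate {n!r} in simulation; "
                f"supported: {_TIME_COVARIATES}"
            )
    if not cols:
        return np.zeros((len(times), 0))
    return np.column_stack(cols)


def _endpoint_design(
    landscape: Landscape | None,
    colnames: list[str],
    anchor: np.ndarray,
    points: np.ndarray,
    prev_bearing: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Design rows for candidate endpoints of one step.

    With no previous bearing (first step of a track) the turning-angle
    covariate is omitted, i.e. contributes zero to the linear predictor.
    """
    M = len(points)
    diff = points - anchor
    L = np.hypot(diff[:, 0], diff[:, 1])
    with np.errstate(divide="ignore"):
        logL = np.log(L)
    if prev_bearing is None:
        cosang = np.zeros(M)
    else:
        cosang = np.cos(np.arctan2(diff[:, 1], diff[:, 0]) - prev_bearing)
    movement = {"length": L, "log_length": logL, "cos_angle": cosang}
    valid = np.ones(M, dtype=bool)
    values: dict[str, np.ndarray] = {}
    if landscape is not None:
        values, ok = extract(landscape, points)
        valid &= ok
    C = np.empty((M, len(colnames)))
    for j, c in enumerate(colnames):
        if c in movement:
            C[:, j] = movement[c]
        elif c in values:
            C[:, j] = values[c]
        else:
            hname, mname = c.split(":")
            C[:, j] = values[hname] * movement[mname]
    return C, valid


def simulate_track(spec_or_model, landscape=None, **kwargs):
    """Simulate one track; returns ``(Track, states)``.

    Accepts a :class:`SimulationSpec` or a model plus keyword fields.
    States are per step (length T - 1, 1-based).  The first ``burn_in``
    locations (and their states) are discarded.
    """
    if isinstance(spec_or_model, SimulationSpec):
        spec = spec_or_model
    else:
        spec = SimulationSpec(model=spec_or_model, landscape=landscape, **kwargs)
    model = spec.model
    land = spec.landscape
    rng = np.random.default_rng(spec.seed)
    K = model.n_states
    beta = model.ssf.beta
    colnames = list(model.ssf.colnames)
    r = spec.radius if spec.radius is not None else default_radius(model)

    T = spec.track_length
    times = pd.date_range(
        spec.start_time, periods=T, freq=pd.Timedelta(hours=spec.interval_hours)
    )
    omega = _omega_from_times(model.transitions.covariates, times[:-1])
    gammas = transition_matrix(model.transitions, omega)
    if gammas.ndim == 2:
        gammas = np.broadcast_to(gammas, (T - 1, K, K))

    # latent state chain, initialised from the stationary distribution
    states = np.empty(T - 1, dtype=int)
    delta = stationary_distribution(gammas[0])
    states[0] = rng.choice(K, p=delta)
    u = rng.uniform(size=T - 1)
    for t in range(1, T - 1):
        states[t] = min(
            int(np.searchsorted(np.cumsum(gammas[t, states[t - 1]]), u[t])), K - 1
        )

    if spec.start is not None:
        pos = np.asarray(spec.start, dtype=float)
    elif land is not None:
        bx0, bx1, by0, by1 = land.boundary
        pos = np.array([rng.uniform(bx0, bx1), rng.uniform(by0, by1)])
    else:
        pos = np.zeros(2)

    xy = np.empty((T, 2))
    xy[0] = pos
    bearing: float | None = None
    M = spec.n_proposals
    for t in range(T - 1):
        rad = r * np.sqrt(rng.uniform(size=M))
        ang = rng.uniform(-np.pi, np.pi, size=M)
        props = pos + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        C, valid = _endpoint_design(land, colnames, pos, props, bearing)
        score = C @ beta[states[t]]
        score[~valid] = -np.inf
        if land is not None:
            score[~land.contains(props[:, 0], props[:, 1])] = -np.inf
        finite = np.isfinite(score)
        if not finite.any():
            raise RuntimeError(
                f"all proposal weights are zero at step {t} near {tuple(pos)}; "
                "the track is starved by the boundary or missing data"
            )
        w = np.exp(score - score[finite].max())
        w[~finite] = 0.0
        pick = rng.choice(M, p=w / w.sum())
        new = props[pick]
        bearing = float(np.arctan2(new[1] - pos[1], new[0] - pos[0]))
        pos = new
        xy[t + 1] = pos

    b = spec.burn_in
    track = Track(
        individual_id=f"sim{spec.seed}",
        times=times[b:],
        xy=xy[b:],
        observed=np.ones(T - b, dtype=bool),
    )
    return track, states[b:] + 1


# ---------------------------------------------------------------------------
# Utilisation distributions

@dataclass
class UdGrid:
    """Utilisation density on a landscape lattice (Gaussian KDE)."""

    grid: np.ndarray
    xmin: float
    ymin: float
    resolution: float
    bandwidth: float

    @property
    def cell_area(self) -> float:
        return self.resolution**2

    def total_mass(self) -> float:
        return float(self.grid.sum() * self.cell_area)

    def to_layer(self, name: str = "ud") -> CovariateLayer:
        return CovariateLayer(
            name, CONTINUOUS, self.grid, self.xmin, self.ymin, self.resolution
        )


def estimate_ud(
    locations: np.ndarray,
    bandwidth: float,
    grid: Landscape | CovariateLayer,
    states: np.ndarray | None = None,
    state: int | None = None,
) -> UdGrid:
    """Gaussian kernel density estimate of space use on the lattice.

    Locations are binned onto the lattice and smoothed with a Gaussian
    kernel of standard deviation ``bandwidth`` (map units), then
    renormalised so the density integrates to one over the grid.  Pass
    ``states``/``state`` to keep only locations in one behavioural state.
    """
    layer = grid.layers[0] if isinstance(grid, Landscape) else grid
    pts = np.asarray(locations, dtype=float)
    if state is not None:
        if states is None:
            raise ValueError("state filter requires a states array")
        keep = np.asarray(states) == state
        pts = pts[keep]
    if len(pts) == 0:
        raise ValueError("no locations selected")
    nrow, ncol = layer.shape
    x0, x1, y0, y1 = layer.extent
    hist, _, _ = np.histogram2d(
        pts[:, 1], pts[:, 0],
        bins=(nrow, ncol), range=((y0, y1), (x0, x1)),
    )
    sigma = bandwidth / layer.resolution
    dens = ndimage.gaussian_filter(hist, sigma=sigma, mode="constant")
    total = dens.sum() * layer.resolution**2
    return UdGrid(dens / total, layer.xmin, layer.ymin, layer.resolution, bandwidth)


# ---------------------------------------------------------------------------
# Parameter recovery harness

def recovery_study(
    true_model: HmmSsfModel,
    landscape: Landscape | None,
    formula: Formula,
    n_steps: int = 1000,
    n_replicates: int = 50,
    seed: int = 0,
    n_controls: int = 25,
    n_proposals: int = 500,
    interval_hours: float = 0.5,
    burn_in: int = 50,
    n_starts: int = 3,
) -> pd.DataFrame:
    """Simulate-then-fit loop reporting bias, RMSE and 95% CI coverage.

    Each replicate draws its own sub-seed deterministically from the
    master seed, so results do not depend on execution order.  Fit
    failures are counted (``n_fail`` attribute on the result) rather than
    fatal.
    """
    from .inference import ParameterLayout, fit as fit_model

    layout = ParameterLayout(
        true_model.n_states,
        list(true_model.ssf.colnames),
        list(true_model.transitions.covariates),
    )
    truth = layout.from_model(true_model)
    names = layout.names()
    ests, ses = [], []
    n_fail = 0
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    for rep in range(n_replicates):
        sub = int(children[rep].generate_state(1)[0] % (2**31))
        try:
            track, _ = simulate_track(
                true_model, landscape,
                track_length=n_steps + burn_in + 1,
                interval_hours=interval_hours,
                n_proposals=n_proposals,
                burn_in=burn_in,
                seed=sub,
            )
            ss = sample_controls(
                [track], n_controls=n_controls, scheme="gamma_radial", seed=sub
            )
            build_design(ss, landscape, formula)
            res = fit_model(
                ss, true_model.n_states,
                transition_covariates=tuple(true_model.transitions.covariates),
                n_starts=n_starts, seed=sub,
            )
            if res.se is None:
                raise RuntimeError("no standard errors")
        except (RuntimeError, ValueError):
            n_fail += 1
            continue
        ests.append(res.theta)
        ses.append(res.se)
    if not ests:
        raise RuntimeError("every replicate failed")
    E = np.vstack(ests)
    SE = np.vstack(ses)
    err = E - truth
    with np.errstate(invalid="ignore"):
        cover = (np.abs(err) <= 1.959963984540054 * SE)
    out = pd.DataFrame(
        {
            "term": names,
            "truth": truth,
            "mean_estimate": E.mean(axis=0),
            "bias": err.mean(axis=0),
            "rmse": np.sqrt((err**2).mean(axis=0)),
            "coverage": np.nanmean(np.where(np.isfinite(SE), cover, np.nan), axis=0),
            "n_replicates": len(ests),
        }
    )
    out.attrs["n_fail"] = n_fail
    return out
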