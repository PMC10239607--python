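"""Case-control design: control endpoints, importance densities, covariates.

For each usable observed step the normalising integral of the selection
density is approximated by Monte Carlo: the observed endpoint (the case,
always index 0) plus N random control endpoints, each carrying its
covariate row and the density h of the sampling scheme so the estimator
can re-weight by 1/h (importance sampling).  Plain Monte Carlo is the
special case h = constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import Landscape, extract, indicator_columns
from .tracks import Track, cyclic_time_covariates, step_metrics, time_of_day

__all__ = [
    "Formula",
    "UniformDisc",
    "GammaRadial",
    "StepSets",
    "build_step_table",
    "sample_controls",
    "importance_density",
    "build_design",
]

MOVEMENT_TERMS = ("length", "log_length", "cos_angle")


# ---------------------------------------------------------------------------
# Sampling schemes

@dataclass
class UniformDisc:
    """Controls uniform on the disc of radius R around the step's start."""

    radius: float

    name = "uniform_disc"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("disc radius must be positive")

    def sample(self, rng: np.random.Generator, anchors: np.ndarray,
               prev_bearings: np.ndarray, n: int) -> np.ndarray:
        S = len(anchors)
        r = self.radius * np.sqrt(rng.uniform(size=(S, n)))
        a = rng.uniform(-np.pi, np.pi, size=(S, n))
        return anchors[:, None, :] + np.stack(
            [r * np.cos(a), r * np.sin(a)], axis=-1
        )

    def density(self, anchors: np.ndarray, points: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(points - anchors[..., None, :], axis=-1)
        return np.where(r <= self.radius, 1.0 / (np.pi * self.radius**2), 0.0)


@dataclass
class GammaRadial:
    """Radial gamma importance scheme.

    Control distance r is gamma-distributed (moment-matched to the pooled
    observed step lengths); direction is the previous bearing plus a
    Uniform(-pi, pi) angle, i.e. isotropic.  The planar density is
    ``h(z) = f_gamma(r) / (2 pi r)`` — the 1/(2 pi r) factor is the
    polar-coordinates Jacobian for a uniform angle.
    """

    shape: float
    rate: float

    name = "gamma_radial"

    @classmethod
    def from_moments(cls, mean: float, sd: float) -> "GammaRadial":
        if not (np.isfinite(mean) and np.isfinite(sd)) or mean <= 0 or sd <= 0:
            raise ValueError("pooled step lengths give degenerate gamma moments")
        return cls(shape=(mean / sd) ** 2, rate=mean / sd**2)

    def sample(self, rng: np.random.Generator, anchors: np.ndarray,
               prev_bearings: np.ndarray, n: int) -> np.ndarray:
        S = len(anchors)
        r = rng.gamma(self.shape, 1.0 / self.rate, size=(S, n))
        base = np.where(np.isfinite(prev_bearings), prev_bearings, 0.0)
        a = base[:, None] + rng.uniform(-np.pi, np.pi, size=(S, n))
        return anchors[:, None, :] + np.stack(
            [r * np.cos(a), r * np.sin(a)], axis=-1
        )

    def density(self, anchors: np.ndarray, points: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(points - anchors[..., None, :], axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = stats.gamma.pdf(r, a=self.shape, scale=1.0 / self.rate) / (
                2 * np.pi * r
            )
        if np.any(r == 0):
            raise ValueError("gamma_radial density undefined at r = 0")
        return h


def importance_density(scheme, anchor, points) -> np.ndarray:
    """Density of the control-sampling scheme at points, given the anchor."""
    anchor = np.asarray(anchor, float)
    pts = np.atleast_2d(np.asarray(points, float))
    return scheme.density(anchor[None, :], pts[None, ...])[0]


# ---------------------------------------------------------------------------
# Formula and step sets

@dataclass
class Formula:
    """Model terms: habitat layers, movement transforms, interactions.

    ``movement`` entries come from {"length", "log_length", "cos_angle"};
    ``interactions`` are (habitat column, movement term) pairs whose
    product is appended as an extra column.
    """

    habitat: list[str] = field(default_factory=list)
    movement: list[str] = field(
        default_factory=lambda: list(MOVEMENT_TERMS)
    )
    interactions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.movement:
            if m not in MOVEMENT_TERMS:
                raise ValueError(f"unknown movement term {m!r}")

    @property
    def includes_angle(self) -> bool:
        return "cos_angle" in self.movement or any(
            m == "cos_angle" for _, m in self.interactions
        )

    def column_names(self, landscape: Landscape | None) -> list[str]:
        cols: list[str] = []
        for lname in self.habitat:
            if landscape is None:
                cols.append(lname)
                continue
            cols.extend(indicator_columns(landscape[lname]))
        cols.extend(self.movement)
        cols.extend(f"{h}:{m}" for h, m in self.interactions)
        return cols


@dataclass
class StepSets:
    """All observed steps with their case+control endpoints, stacked.

    Arrays are shaped (S, M, ...) with S the total number of steps across
    tracks (usable or not, in track order) and M = N + 1 endpoints; index
    0 is always the case.  Unusable steps hold NaN rows and all-False
    validity; they contribute identity matrices in the forward algorithm.
    """

    steps: pd.DataFrame
    endpoints: np.ndarray
    h: np.ndarray
    valid: np.ndarray
    n_controls: int
    scheme: object
    seed: int | None = None
    covariates: np.ndarray | None = None
    colnames: list[str] | None = None

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def usable(self) -> np.ndarray:
        return self.steps["usable"].to_numpy()

    def transition_covariates(self, names: list[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.steps.columns]
        if missing:
            raise KeyError(f"transition covariates not in step table: {missing}")
        return self.steps[list(names)].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Long case-control table (one row per endpoint)."""
        if self.covariates is None:
            raise ValueError("build_design has not been run")
        S, M, _ = self.endpoints.shape
        rec = {
            "track_id": np.repeat(self.steps["track_id"].to_numpy(), M),
            "step": np.repeat(self.steps["step"].to_numpy(), M),
            "endpoint": np.tile(np.arange(M), S),
            "case": np.tile(np.arange(M) == 0, S),
            "x": self.endpoints[..., 0].ravel(),
            "y": self.endpoints[..., 1].ravel(),
            "h": self.h.ravel(),
            "valid": self.valid.ravel(),
        }
        for j, c in enumerate(self.colnames):
            rec[c] = self.covariates[..., j].ravel()
        return pd.DataFrame(rec)


def build_step_table(tracks: list[Track]) -> pd.DataFrame:
    """Concatenate per-track step geometry plus temporal covariates."""
    frames = []
    for tr in tracks:
        sm = step_metrics(tr)
        sm.insert(0, "track_id", tr.individual_id)
        start_times = tr.times[:-1]
        sm["time"] = start_times
        sm["tau"] = time_of_day(start_times)
        cosd, sind = cyclic_time_covariates(start_times)
        sm["tod_cos"] = cosd
        sm["tod_sin"] = sind
        prev = np.full(len(sm), np.nan)
        prev[1:] = sm["bearing"].to_numpy()[:-1]
        sm["prev_bearing"] = prev
        frames.append(sm)
    return pd.concat(frames, ignore_index=True)


def pooled_length_moments(steps: pd.DataFrame) -> tuple[float, float]:
    """Mean and SD of observed step lengths, pooled over individuals."""
    lengths = steps["length"].to_numpy()
    lengths = lengths[np.isfinite(lengths)]
    if lengths.size < 2:
        raise ValueError("not enough observed steps to pool moments")
    return float(lengths.mean()), float(lengths.std(ddof=1))


def make_scheme(scheme, steps: pd.DataFrame, radius: float | None = None):
    """Resolve a scheme name to a scheme object using pooled step data."""
    if not isinstance(scheme, str):
        return scheme
    if scheme == "gamma_radial":
        mean, sd = pooled_length_moments(steps)
        return GammaRadial.from_moments(mean, sd)
    if scheme == "uniform_disc":
        if radius is None:
            lengths = steps["length"].to_numpy()
            radius = float(np.nanmax(lengths)) * 1.1
        return UniformDisc(radius)
    raise ValueError(f"unknown sampling scheme {scheme!r}")


def sample_controls(
    tracks: list[Track],
    n_controls: int = 25,
    scheme="gamma_radial",
    seed: int = 0,
    radius: float | None = None,
    require_angle: bool = True,
) -> StepSets:
    """Draw N control endpoints for every usable observed step.

    ``scheme`` is ``"gamma_radial"`` (default, importance sampling with
    pooled-moment gamma distances), ``"uniform_disc"`` or a scheme object.
    The case endpoint occupies index 0 and its importance weight uses h
    evaluated at the observed endpoint; h(case) = 0 is an error (disc
    radius too small).  Reproducible given ``seed``.
    """
    if n_controls < 1:
        raise ValueError("need at least one control per step")
    steps = build_step_table(tracks)
    if not require_angle:
        # usable without a previous bearing: only both endpoints needed
        steps["usable"] = np.isfinite(steps["length"].to_numpy())
    scheme = make_scheme(scheme, steps, radius=radius)
    rng = np.random.default_rng(seed)
    S = len(steps)
    M = n_controls + 1
    endpoints = np.full((S, M, 2), np.nan)
    h = np.full((S, M), np.nan)
    valid = np.zeros((S, M), dtype=bool)

    usable = steps["usable"].to_numpy()
    idx = np.flatnonzero(usable)
    if idx.size == 0:
        raise ValueError("no usable steps")
    anchors = steps.loc[idx, ["x0", "y0"]].to_numpy(dtype=float)
    bearings = steps.loc[idx, "prev_bearing"].to_numpy(dtype=float)
    cases = steps.loc[idx, ["x1", "y1"]].to_numpy(dtype=float)

    endpoints[idx, 0] = cases
    endpoints[idx, 1:] = scheme.sample(rng, anchors, bearings, n_controls)
    h[idx] = scheme.density(anchors, endpoints[idx])
    if np.any(h[idx, 0] <= 0):
        bad = idx[h[idx, 0] <= 0][:5]
        raise ValueError(
            f"importance density is zero at observed endpoints (steps {bad.tolist()}); "
            "under uniform_disc this means the disc radius is too small"
        )
    valid[idx] = h[idx] > 0
    return StepSets(
        steps=steps,
        endpoints=endpoints,
        h=h,
        valid=valid,
        n_controls=n_controls,
        scheme=scheme,
        seed=seed,
    )


def build_design(step_sets: StepSets, landscape: Landscape | None,
                 formula: Formula) -> StepSets:
    """Fill in the covariate matrix c(y_t, z_it) for every endpoint.

    Movement covariates of each endpoint are measured from the step's
    start; the turning angle of a control is taken against the bearing
    *into* the start location, the same reference as the case, so the
    case row reproduces the observed step metrics exactly.  Endpoints on
    missing cells or outside the extent are flagged invalid and excluded
    from the Monte Carlo sum downstream.
    """
    for lname in formula.habitat:
        if landscape is None:
            raise ValueError("formula has habitat terms but no landscape given")
        landscape[lname]  # raises KeyError if unknown
    steps = step_sets.steps
    S, M, _ = step_sets.endpoints.shape
    cols = formula.column_names(landscape)
    C = np.full((S, M, len(cols)), np.nan)
    valid = step_sets.valid.copy()

    idx = np.flatnonzero(steps["usable"].to_numpy())
    pts = step_sets.endpoints[idx].reshape(-1, 2)
    anchors = steps.loc[idx, ["x0", "y0"]].to_numpy(dtype=float)
    prev_b = steps.loc[idx, "prev_bearing"].to_numpy(dtype=float)

    values: dict[str, np.ndarray] = {}
    if formula.habitat:
        hv, ok = extract(landscape, pts)
        values.update({k: v.reshape(len(idx), M) for k, v in hv.items()})
        valid[idx] &= ok.reshape(len(idx), M)

    diff = step_sets.endpoints[idx] - anchors[:, None, :]
    L = np.hypot(diff[..., 0], diff[..., 1])
    with np.errstate(divide="ignore"):
        logL = np.log(L)
    bearing = np.arctan2(diff[..., 1], diff[..., 0])
    cosang = np.cos(bearing - prev_b[:, None])
    movement = {"length": L, "log_length": logL, "cos_angle": cosang}

    for j, c in enumerate(cols):
        if c in values:
            C[idx, :, j] = values[c]
        elif c in movement:
            C[idx, :, j] = movement[c]
        else:  # interaction "hab:mov"
            hname, mname = c.split(":")
            C[idx, :, j] = values[hname] * movement[mname]

    step_sets.covariates = C
    step_sets.colnames = cols
    step_sets.valid = valid
    return step_sets
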