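"""Track data model, regular-grid validation and step geometry.

A track is a sequence of locations on a strictly regular time grid; gaps
are explicit missing rows, never absent rows.  The latent state attaches
to *steps*: step ``t`` runs from location ``t`` to location ``t+1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "read_tracks",
    "write_tracks",
    "step_metrics",
    "cyclic_time_covariates",
    "time_of_day",
]

#: fraction of the sampling interval a timestamp may deviate from the grid
GRID_TOLERANCE = 0.1


@dataclass
class Track:
    """Regular-interval telemetry series for one individual.

    ``observed[t]`` is False for missing locations; their ``xy`` rows are
    NaN.  Timestamps are pandas ``DatetimeIndex`` at fixed spacing.
    """

    individual_id: str
    times: pd.DatetimeIndex
    xy: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        T = len(self.times)
        if self.xy.shape != (T, 2):
            raise ValueError("xy must be (T, 2)")
        if self.observed.shape != (T,):
            raise ValueError("observed must be length T")
        if T >= 2:
            deltas = np.diff(self.times.view("int64"))
            if deltas.min() <= 0:
                raise ValueError("times must be strictly increasing")
            if not (deltas == deltas[0]).all():
                raise ValueError("times must be equally spaced")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def interval(self) -> pd.Timedelta:
        return pd.Timedelta(self.times[1] - self.times[0])

    @property
    def n_steps(self) -> int:
        return len(self) - 1


def read_tracks(path, interval, jitter_zero_steps: float = 0.0,
                seed: int = 0) -> list[Track]:
    """Read tracks from a CSV of (id, time, x, y) and regularise each.

    Rows are snapped to the regular grid anchored at each individual's
    first fix; grid times with no fix become missing rows.  Timestamps
    further than ``GRID_TOLERANCE`` of the interval from the nearest grid
    point are an error, as are duplicates on one grid point.

    Zero-length steps make ``log L`` undefined downstream.  By default
    they raise, naming the offending rows; pass ``jitter_zero_steps=r`` to
    instead perturb every location uniformly within radius ``r``.
    """
    df = pd.read_csv(path)
    required = {"id", "time", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"track file needs columns {sorted(required)}")
    df["time"] = pd.to_datetime(df["time"])
    interval = pd.Timedelta(interval)
    tracks = []
    for ind, sub in df.groupby("id", sort=False):
        sub = sub.sort_values("time")
        t0 = sub["time"].iloc[0]
        offset = (sub["time"] - t0) / interval
        slot = offset.round().astype(int)
        err = (offset - slot).abs()
        if (err > GRID_TOLERANCE).any():
            bad = sub.loc[err > GRID_TOLERANCE, "time"].tolist()
            raise ValueError(
                f"individual {ind!r}: timestamps not on a {interval} grid: {bad[:5]}"
            )
        if slot.duplicated().any():
            dup = sub.loc[slot.duplicated(), "time"].tolist()
            raise ValueError(f"individual {ind!r}: duplicate timestamps {dup[:5]}")
        T = int(slot.iloc[-1]) + 1
        xy = np.full((T, 2), np.nan)
        observed = np.zeros(T, dtype=bool)
        xy[slot.to_numpy()] = sub[["x", "y"]].to_numpy(dtype=float)
        observed[slot.to_numpy()] = True
        times = pd.date_range(t0, periods=T, freq=interval)
        track = Track(str(ind), times, xy, observed)
        _handle_zero_steps(track, jitter_zero_steps, seed)
        tracks.append(track)
    return tracks


def _handle_zero_steps(track: Track, jitter: float, seed: int) -> None:
    d = np.linalg.norm(np.diff(track.xy, axis=0), axis=1)
    both = track.observed[:-1] & track.observed[1:]
    zero = both & (d == 0.0)
    if not zero.any():
        return
    if jitter <= 0:
        rows = np.flatnonzero(zero)
        raise ValueError(
            f"individual {track.individual_id!r}: zero-length steps at rows "
            f"{rows.tolist()[:10]}; log step length is undefined. "
            "Pass jitter_zero_steps=<radius> to perturb coordinates."
        )
    rng = np.random.default_rng(seed)
    n = len(track.xy)
    r = jitter * np.sqrt(rng.uniform(size=n))
    a = rng.uniform(0, 2 * np.pi, size=n)
    track.xy[track.observed] += np.column_stack([r * np.cos(a), r * np.sin(a)])[
        track.observed
    ]


def write_tracks(tracks: list[Track], path) -> None:
    """Write tracks in the same CSV dialect read_tracks accepts."""
    frames = []
    for tr in tracks:
        obs = tr.observed
        frames.append(
            pd.DataFrame(
                {
                    "id": tr.individual_id,
                    "time": tr.times[obs].strftime("%Y-%m-%dT%H:%M:%S"),
                    "x": tr.xy[obs, 0],
                    "y": tr.xy[obs, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def step_metrics(track: Track) -> pd.DataFrame:
    """Per-step geometry: Euclidean length, bearing and turning angle.

    The turning angle of step ``t`` is the signed change from the bearing
    of step ``t-1``, counter-clockwise positive, in ``(-pi, pi]``.  It is
    undefined (NaN) for the first step of a track and wherever any of the
    three locations involved is missing.  ``usable`` flags steps whose
    start, end *and* previous location are all observed — the requirement
    for a model that includes turning angle.
    """
    if len(track) < 2:
        raise ValueError("need at least two locations")
    xy = track.xy
    obs = track.observed
    d = np.diff(xy, axis=0)
    length = np.hypot(d[:, 0], d[:, 1])
    bearing = np.arctan2(d[:, 1], d[:, 0])
    turn = np.full(track.n_steps, np.nan)
    turn[1:] = _wrap_angle(bearing[1:] - bearing[:-1])
    ends_ok = obs[:-1] & obs[1:]
    prev_ok = np.zeros(track.n_steps, dtype=bool)
    prev_ok[1:] = obs[:-2]
    usable = ends_ok & prev_ok
    length = np.where(ends_ok, length, np.nan)
    bearing = np.where(ends_ok, bearing, np.nan)
    turn = np.where(usable, turn, np.nan)
    return pd.DataFrame(
        {
            "step": np.arange(track.n_steps),
            "x0": xy[:-1, 0],
            "y0": xy[:-1, 1],
            "x1": xy[1:, 0],
            "y1": xy[1:, 1],
            "length": length,
            "bearing": bearing,
            "turn_angle": turn,
            "usable": usable,
        }
    )


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    w = np.mod(-np.asarray(a) + np.pi, 2 * np.pi)
    return -(w - np.pi)


def time_of_day(times: pd.DatetimeIndex) -> np.ndarray:
    """Hour of day as a float in [0, 24)."""
    t = pd.DatetimeIndex(times)
    return (
        t.hour.to_numpy()
        + t.minute.to_numpy() / 60.0
        + t.second.to_numpy() / 3600.0
    )


def cyclic_time_covariates(times) -> tuple[np.ndarray, np.ndarray]:
    """Cyclic time-of-day covariates cos(2*pi*tau/24), sin(2*pi*tau/24)."""
    if isinstance(times, (pd.DatetimeIndex, pd.Series)):
        tau = time_of_day(pd.DatetimeIndex(times))
    else:
        tau = np.asarray(times, dtype=float)
    ang = 2 * np.pi * tau / 24.0
    return np.cos(ang), np.sin(ang)
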