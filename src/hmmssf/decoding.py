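"""State decoding: Viterbi (global), forward-backward (local), and
stationary state probabilities over a transition-covariate grid.

Decoding runs per track with that track's initial distribution.  Steps
that are excluded from the likelihood (first step of a track, missing
data) receive no decoded state: the Viterbi label is -1 and the local
probability row is NaN, rather than an imputed value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import StepSets
from .inference import FitResult, _track_slices, log_state_densities
from .model import stationary_distribution, transition_matrix

__all__ = [
    "StateInference",
    "viterbi",
    "local_probs",
    "stationary_probs",
    "decode",
]


@dataclass
class StateInference:
    """Decoded states per step (1-based labels; -1 where undecodable)."""

    viterbi: np.ndarray
    local_probs: np.ndarray
    max_prob_states: np.ndarray

    def to_frame(self, step_sets: StepSets) -> pd.DataFrame:
        K = self.local_probs.shape[1]
        df = step_sets.steps[
            ["track_id", "step", "time", "x0", "y0", "x1", "y1", "usable"]
        ].copy()
        df["viterbi"] = self.viterbi
        for k in range(K):
            df[f"prob_state_{k + 1}"] = self.local_probs[:, k]
        return df


def _per_track(log_dens, gammas, slices):
    for sl in slices:
        yield sl, log_dens[sl], gammas[sl]


def viterbi(log_dens: np.ndarray, gammas: np.ndarray,
            track_slices: list[slice]) -> np.ndarray:
    """Most likely full state sequence, computed in log space.

    Ties break toward the lower state index.  Steps with NaN densities
    take no part in the observation term (log-density 0) and are labelled
    -1 in the output.
    """
    S, K = log_dens.shape
    out = np.full(S, -1, dtype=int)
    for sl, ld, gm in _per_track(log_dens, gammas, track_slices):
        T = ld.shape[0]
        usable = np.isfinite(ld).all(axis=1)
        obs = np.where(usable[:, None], ld, 0.0)
        with np.errstate(divide="ignore"):
            logGam = np.log(gm)
            delta = np.log(stationary_distribution(gm[0]))
        score = delta + obs[0]
        back = np.zeros((T, K), dtype=int)
        for t in range(1, T):
            cand = score[:, None] + logGam[t]  # (from, to)
            # argmax returns the lowest index on ties
            back[t] = np.argmax(cand, axis=0)
            score = cand[back[t], np.arange(K)] + obs[t]
        states = np.empty(T, dtype=int)
        states[-1] = int(np.argmax(score))
        for t in range(T - 2, -1, -1):
            states[t] = back[t + 1][states[t + 1]]
        labels = np.where(usable, states + 1, -1)
        out[sl] = labels
    return out


def local_probs(log_dens: np.ndarray, gammas: np.ndarray,
                track_slices: list[slice]) -> np.ndarray:
    """Pr(S_t = k | all data) per step via scaled forward-backward."""
    S, K = log_dens.shape
    out = np.full((S, K), np.nan)
    for sl, ld, gm in _per_track(log_dens, gammas, track_slices):
        T = ld.shape[0]
        usable = np.isfinite(ld).all(axis=1)
        # scaled densities: per-step rescaling cancels in the marginals
        p = np.ones((T, K))
        rows = ld[usable]
        p[usable] = np.exp(rows - rows.max(axis=1, keepdims=True))
        fwd = np.empty((T, K))
        v = stationary_distribution(gm[0]) * p[0]
        fwd[0] = v / v.sum()
        for t in range(1, T):
            v = (fwd[t - 1] @ gm[t]) * p[t]
            fwd[t] = v / v.sum()
        bwd = np.empty((T, K))
        bwd[-1] = 1.0
        for t in range(T - 2, -1, -1):
            w = gm[t + 1] @ (p[t + 1] * bwd[t + 1])
            bwd[t] = w / w.sum()
        post = fwd * bwd
        post /= post.sum(axis=1, keepdims=True)
        post[~usable] = np.nan
        out[sl] = post
    return out


def stationary_probs(transitions, omega_grid: np.ndarray) -> np.ndarray:
    """Stationary state distribution at each covariate-grid point."""
    gam = transition_matrix(transitions, np.atleast_2d(omega_grid))
    return np.stack([stationary_distribution(g) for g in gam])


def decode(fit_result: FitResult, step_sets: StepSets,
           use_importance: bool = True) -> StateInference:
    """Viterbi sequence and local state probabilities for fitted data."""
    layout = fit_result.layout
    if list(step_sets.colnames) != list(layout.colnames):
        raise ValueError(
            "step sets and fitted model disagree on design columns: "
            f"{step_sets.colnames} vs {layout.colnames}"
        )
    ld = log_state_densities(
        step_sets, fit_result.model.ssf.beta, use_importance=use_importance
    )
    omega = step_sets.transition_covariates(layout.transition_covariates)
    gammas = transition_matrix(fit_result.model.transitions, omega)
    slices = _track_slices(step_sets.steps)
    vit = viterbi(ld, gammas, slices)
    lp = local_probs(ld, gammas, slices)
    with np.errstate(invalid="ignore"):
        mp = np.where(
            np.isfinite(lp).all(axis=1), np.argmax(np.nan_to_num(lp), axis=1) + 1, -1
        )
    return StateInference(viterbi=vit, local_probs=lp, max_prob_states=mp)
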