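"""Canned synthetic scenarios used by the test-suite, docs and examples.

Everything here is generated programmatically — no bundled data files.
"""

from __future__ import annotations

import numpy as np

from .design import Formula
from .landscape import Landscape, generate_landscape
from .model import (
    HmmSsfModel,
    SsfCoefficients,
    TransitionModel,
    coeff_from_vonmises,
    coeffs_from_gamma,
)

__all__ = [
    "example_model",
    "example_landscape",
    "example_formula",
    "habitat_model",
    "habitat_landscape",
]

#: canonical 2-state scenario: one continuous habitat covariate, gamma
#: step lengths, von Mises turning angles, cyclic time-of-day switching
_SLOW = dict(mean=0.4, sd=0.3, kappa=0.3, habitat=0.6)
_FAST = dict(mean=1.2, sd=0.8, kappa=1.2, habitat=-0.4)
_ALPHA = np.array([[-2.0, 0.3, 0.8], [-1.2, 0.2, 0.1]])


def example_formula() -> Formula:
    return Formula(habitat=["res"], movement=["length", "log_length", "cos_angle"])


def example_landscape(seed: int = 11, size: float = 50.0,
                      resolution: float = 0.5,
                      patch_scale: float = 0.8) -> Landscape:
    """Continuous resource field on a square arena."""
    return generate_landscape(
        seed,
        (0.0, size, 0.0, size),
        resolution,
        continuous={"res": {"patch_scale": patch_scale, "variance": 1.0}},
    )


def example_model() -> HmmSsfModel:
    """Known 2-state model with time-of-day transition covariates."""
    rows = []
    for st in (_SLOW, _FAST):
        bl, bll = coeffs_from_gamma(st["mean"], st["sd"])
        rows.append([st["habitat"], bl, bll, coeff_from_vonmises(0.0, st["kappa"])])
    beta = np.asarray(rows)
    return HmmSsfModel(
        ssf=SsfCoefficients(beta, ["res", "length", "log_length", "cos_angle"]),
        transitions=TransitionModel(2, ["tod_cos", "tod_sin"], _ALPHA.copy()),
    )


def habitat_landscape(seed: int = 7, size: float = 40.0,
                      resolution: float = 0.5,
                      patch_scale: float = 2.0,
                      proportions=(0.4, 0.3, 0.2, 0.1)) -> Landscape:
    """Four-level categorical vegetation map (reference: grassland)."""
    return generate_landscape(
        seed,
        (0.0, size, 0.0, size),
        resolution,
        categorical={
            "veg": {
                "levels": ["grassland", "bushed_grassland", "bushland", "woodland"],
                "proportions": list(proportions),
                "patch_scale": patch_scale,
                "reference": "grassland",
            }
        },
    )


def habitat_model(selection=(0.5, -1.0, -1.5)) -> HmmSsfModel:
    """2-state model over the categorical vegetation map; the exploratory
    state carries the given selection coefficients (vs grassland), the
    encamped state half of them."""
    sel = np.asarray(selection, dtype=float)
    slow = list(np.asarray(sel) / 2)
    bl1, bll1 = coeffs_from_gamma(0.3, 0.25)
    bl2, bll2 = coeffs_from_gamma(1.0, 0.7)
    beta = np.array(
        [slow + [bl1, bll1, 0.2], list(sel) + [bl2, bll2, 1.3]]
    )
    cols = [
        "veg_bushed_grassland", "veg_bushland", "veg_woodland",
        "length", "log_length", "cos_angle",
    ]
    return HmmSsfModel(
        ssf=SsfCoefficients(beta, cols),
        transitions=TransitionModel(2, [], np.array([[-1.8], [-1.3]])),
    )
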