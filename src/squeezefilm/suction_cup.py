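"""Whole-body suction-cup mechanics.

The climbing fish's conformed body encloses a water-filled chamber.
Because water is nearly incompressible, an external pull-off force is
balanced quasi-statically by the chamber's pressure deficit over the cup
footprint: ΔP = F / A, up to the seal limit the rim can sustain.  The
rim's micro-setae provide only a tiny hydrodynamic preload, so sliding
friction stays low while the available suction capacity is large — the
low-friction / high-adhesion balance this module makes quantitative.

The friction measurements under imposed pull-off loads are summarised by
an affine (Amontons-style) law ``friction = f0 + mu_f * pull`` fitted by
ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hydrodynamics import REFERENCE_PATCH, SetaePatch

__all__ = [
    "SuctionCup",
    "CupState",
    "FrictionModel",
    "REFERENCE_CUP",
    "chamber_response",
    "max_pulloff_force",
    "fit_friction_model",
    "predict_friction",
]


@dataclass(frozen=True)
class SuctionCup:
    """Chamber geometry, compliance and seal strength.

    Defaults: the resting rear-cup contact area of 203.2 mm² and the
    measured maximum sustainable pressure difference of 58.07 kPa.
    ``membrane_compliance`` converts pressure difference to chamber
    volume change for bookkeeping; with an incompressible filling it
    does not enter the force balance.
    """

    cup_area: float = 203.2e-6
    membrane_compliance: float = 1.0e-12
    seal_limit: float = 58.07e3
    rim_patch: SetaePatch = REFERENCE_PATCH

    def __post_init__(self) -> None:
        if not self.cup_area > 0:
            raise ValueError("cup_area must be > 0")
        if self.membrane_compliance < 0:
            raise ValueError("membrane_compliance must be >= 0")
        if not self.seal_limit > 0:
            raise ValueError("seal_limit must be > 0")


#: Cup with the measured defaults.
REFERENCE_CUP = SuctionCup()


@dataclass(frozen=True)
class CupState:
    """Chamber response: pressure deficit (ambient − chamber), volume change, seal."""

    pressure_difference: float
    volume_change: float
    sealed: bool


@dataclass(frozen=True)
class FrictionModel:
    """Affine load–friction law: friction = baseline + coefficient × pull."""

    friction_coefficient: float
    baseline_friction: float

    def __post_init__(self) -> None:
        if self.friction_coefficient < 0 or self.baseline_friction < 0:
            raise ValueError("friction model parameters must be >= 0")


def chamber_response(cup: SuctionCup, pull_force: float) -> CupState:
    """Quasi-static chamber state under an external pull-off force.

    While sealed, ΔP = pull_force / cup_area; at zero pull the pressure
    deficit is zero (the passive, dead-fish observation).  Beyond the
    seal limit the rim leaks: the state is returned unsealed with ΔP
    capped at the seal limit.
    """
    if pull_force < 0:
        raise ValueError("pull_force must be >= 0")
    dp = pull_force / cup.cup_area
    sealed = dp <= cup.seal_limit
    dp = min(dp, cup.seal_limit)
    return CupState(
        pressure_difference=dp,
        volume_change=cup.membrane_compliance * dp,
        sealed=sealed,
    )


def max_pulloff_force(cup: SuctionCup) -> float:
    """Largest pull-off force the sealed cup can balance: seal_limit × area."""
    return cup.seal_limit * cup.cup_area


def fit_friction_model(
    pull_forces: Sequence[float], frictions: Sequence[float]
) -> FrictionModel:
    """Least-squares affine fit of friction versus imposed pull-off force."""
    x = np.asarray(pull_forces, dtype=float)
    y = np.asarray(frictions, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pull_forces and frictions must be 1-D of equal length")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct pull forces to fit a line")
    slope, intercept = np.polyfit(x, y, 1)
    return FrictionModel(
        friction_coefficient=max(0.0, float(slope)),
        baseline_friction=max(0.0, float(intercept)),
    )


def predict_friction(model: FrictionModel, pull_force: float) -> float:
    """Predicted friction at a pull-off force, clamped at >= 0."""
    if pull_force < 0:
        raise ValueError("pull_force must be >= 0")
    return max(0.0, model.baseline_friction + model.friction_coefficient * pull_force)
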