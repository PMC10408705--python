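"""Closed-form squeeze-film (Stefan) forces.

When two closely spaced surfaces in a viscous liquid move apart (or
together) along their normal, the thin film between them must be refilled
(or drained) through its edge.  In the lubrication limit this produces a
pressure field whose resultant — the Stefan force — resists the motion,
scaling with viscosity and speed and, for a disc of radius ``R`` at gap
``h``, as ``R**4 / h**3``:

    F = 3 * pi * mu * R**4 * hdot / (2 * h**3)

This module provides that closed form for discs and 1-D strips, and the
cooperative effective-disc model for a patch of micro-setae: a dense,
sealing array of micron-scale pillars behaves hydrodynamically like one
large disc of the patch footprint rather than like the sum of its
individual pillars, which is why a setae patch can generate measurable
wet adhesion where a handful of isolated setae cannot.

Sign convention: ``gap_rate > 0`` means the surfaces separate, and the
returned force is positive when it resists the imposed motion — i.e. a
positive value during separation is an adhesive (attractive) film force.
All quantities are strict SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FluidMedium",
    "SetaePatch",
    "FilmState",
    "WATER",
    "REFERENCE_PATCH",
    "squeeze_film_force_disc",
    "squeeze_film_force_strip",
    "array_effective_force",
    "film_coefficient_disc",
    "cooperative_film_coefficient",
]


@dataclass(frozen=True)
class FluidMedium:
    """An incompressible Newtonian liquid.

    Parameters
    ----------
    viscosity : float
        Dynamic viscosity, Pa·s.
    density : float
        Mass density, kg/m³.  Used only for Reynolds-number sanity
        checks; the lubrication forces themselves are inertia-free.
    """

    viscosity: float
    density: float = 997.0

    def __post_init__(self) -> None:
        if not self.viscosity > 0:
            raise ValueError(f"viscosity must be > 0, got {self.viscosity}")
        if not self.density > 0:
            raise ValueError(f"density must be > 0, got {self.density}")


#: Water at room temperature.
WATER = FluidMedium(viscosity=1.0e-3, density=997.0)


@dataclass(frozen=True)
class SetaePatch:
    """Geometry and sealing quality of a micro-setae array patch.

    The measured fin-surface setae are keratinous pillars roughly
    2–6 µm in diameter and 12–14 µm tall at ~9–10 × 10³ per mm².
    ``sealing_fraction`` is this model's leakage parameter: 1 means the
    patch rim seals perfectly and the patch acts as a full effective
    disc, 0 means the film leaks freely and the cooperative force
    vanishes.

    Parameters
    ----------
    seta_radius : float
        Single-seta radius, m.
    seta_height : float
        Seta height, m.
    inclination_deg : float
        Inclination from the substrate, degrees.  Carried for footprint
        projection by the pressure-field solver; it does not enter the
        effective-disc force.
    areal_density : float
        Setae per m².
    patch_area : float
        Patch footprint, m².
    sealing_fraction : float
        Leakage attenuation of the cooperative film force, in [0, 1].
    """

    seta_radius: float
    seta_height: float
    inclination_deg: float
    areal_density: float
    patch_area: float
    sealing_fraction: float

    def __post_init__(self) -> None:
        for name in ("seta_radius", "seta_height", "patch_area"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.areal_density > 0:
            raise ValueError("areal_density must be > 0")
        if not 0.0 <= self.sealing_fraction <= 1.0:
            raise ValueError(
                f"sealing_fraction must lie in [0, 1], got {self.sealing_fraction}"
            )
        solid = self.areal_density * math.pi * self.seta_radius**2
        if solid > 1.0:
            raise ValueError(
                f"solid fraction {solid:.3f} exceeds 1: density and radius inconsistent"
            )

    @property
    def n_setae(self) -> float:
        """Expected number of setae on the patch."""
        return self.areal_density * self.patch_area

    @property
    def effective_radius(self) -> float:
        """Radius of the equal-area effective disc, sqrt(A/pi)."""
        return math.sqrt(self.patch_area / math.pi)


#: Measured fin-seta geometry (4 µm diameter, 13 µm height, 9500/mm²)
#: over the default 40 µm × 40 µm probe-contact patch with a half-sealed rim.
REFERENCE_PATCH = SetaePatch(
    seta_radius=2.0e-6,
    seta_height=13.0e-6,
    inclination_deg=45.0,
    areal_density=9.5e9,
    patch_area=(40e-6) ** 2,
    sealing_fraction=0.5,
)


@dataclass(frozen=True)
class FilmState:
    """Instantaneous film thickness and its rate of change.

    ``gap_rate > 0`` means the film is thickening (surfaces separating).
    """

    gap: float
    gap_rate: float

    def __post_init__(self) -> None:
        if not self.gap > 0:
            raise ValueError(f"gap must be > 0, got {self.gap}")


def film_coefficient_disc(gap: float, disc_radius: float, fluid: FluidMedium) -> float:
    """Damping coefficient C(h) of a disc squeeze film, so F = C(h) * hdot.

    C(h) = 3 pi mu R^4 / (2 h^3), in N·s/m.
    """
    if not gap > 0:
        raise ValueError(f"gap must be > 0, got {gap}")
    if not disc_radius > 0:
        raise ValueError(f"disc_radius must be > 0, got {disc_radius}")
    return 3.0 * math.pi * fluid.viscosity * disc_radius**4 / (2.0 * gap**3)


def squeeze_film_force_disc(
    state: FilmState, disc_radius: float, fluid: FluidMedium
) -> float:
    """Stefan force on a rigid disc separating from a parallel wall.

    F = 3 pi mu R^4 hdot / (2 h^3): the resultant of the parabolic
    lubrication pressure p(r) = 3 mu hdot (r² − R²) / h³ over the disc.
    Positive when it resists the imposed ``gap_rate``.
    """
    return film_coefficient_disc(state.gap, disc_radius, fluid) * state.gap_rate


def squeeze_film_force_strip(
    state: FilmState, width: float, depth: float, fluid: FluidMedium
) -> float:
    """1-D analogue of the disc force for a strip of ``width`` × ``depth``.

    The 1-D Reynolds equation with ambient ends gives a parabolic
    pressure profile whose resultant is F = mu * depth * width³ * hdot / h³.
    Used as the closed-form cross-check for the pressure-field solver.
    """
    if not width > 0 or not depth > 0:
        raise ValueError("width and depth must be > 0")
    return fluid.viscosity * depth * width**3 * state.gap_rate / state.gap**3


def cooperative_film_coefficient(
    gap: float, patch: SetaePatch, fluid: FluidMedium
) -> float:
    """Damping coefficient of a setae patch acting as a sealed effective disc.

    The patch is modelled as one disc of radius sqrt(A/pi), its force
    attenuated by ``sealing_fraction`` to account for rim leakage.
    """
    return patch.sealing_fraction * film_coefficient_disc(
        gap, patch.effective_radius, fluid
    )


def array_effective_force(
    state: FilmState, patch: SetaePatch, fluid: FluidMedium, mode: str = "cooperative"
) -> float:
    """Film force of a setae patch in either of two limiting models.

    ``mode="independent"`` treats every seta as an isolated disc and sums
    N = areal_density × patch_area single-seta forces — the appropriate
    model when only a few setae touch the probe, and it predicts forces
    below AFM detectability for a handful of micron-scale setae.

    ``mode="cooperative"`` treats the sealed patch as one effective disc
    of the patch footprint, attenuated by ``sealing_fraction``.  Because
    the disc force scales as R⁴, the cooperative force exceeds the
    independent sum by orders of magnitude for realistic patches, which
    is the hydrodynamic origin of the array's wet adhesion.
    """
    if mode == "cooperative":
        return cooperative_film_coefficient(state.gap, patch, fluid) * state.gap_rate
    if mode == "independent":
        per_seta = squeeze_film_force_disc(state, patch.seta_radius, fluid)
        return patch.n_setae * per_seta
    raise ValueError(f"unknown mode {mode!r}: expected 'cooperative' or 'independent'")
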