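"""Synthetic measurement generators.

Emulates the three measured signal families so every analysis stage is
testable end-to-end without instrument data:

* AFM approach/retract force curves with a viscous-adhesion dip
  (``gen_force_curve``), with presets matching the reported biomimetic
  setae-array (174.5 nN over 4.6 µm) and flat-base (122.2 nN over
  ~1 µm) adhesion;
* contact-intensity frames with a programmed contact area and peak
  count (``gen_contact_frames``);
* periodic chamber-pressure traces with state-dependent per-cycle peak
  statistics (``gen_pressure_traces``): static 113.11 ± 19.02 Pa,
  crawling 276.27 ± 59.82 Pa, defending 596.79 ± 150.8 Pa.

All generators are pure functions of their spec (including its seed).
The dip is a raised cosine, so force, work and distance have closed
forms; noise models are Gaussian for force, Poisson for image counts
and Gaussian jitter for pressure peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .afm import ForceCurve
from .analysis import ContactImage

__all__ = [
    "CurveSpec",
    "FrameSpec",
    "TraceSpec",
    "SETAE_CURVE",
    "FLAT_CURVE",
    "STATE_PEAKS",
    "curve_preset",
    "gen_force_curve",
    "gen_contact_frames",
    "gen_pressure_traces",
]


@dataclass(frozen=True)
class CurveSpec:
    """Programmed adhesion dip of a synthetic retract curve.

    The retract force is a raised-cosine dip of depth ``adhesion_force``
    recovering to baseline over ``adhesion_distance``, so the programmed
    features have closed forms: force = depth, distance = span, work =
    depth × span / 2.
    """

    adhesion_force: float
    adhesion_distance: float
    approach_repulsion_scale: float = 50.0e-9
    noise_sd: float = 0.0
    n_samples: int = 1200
    seed: int = 0
    min_separation: float = 10.0e-9
    spring_constant: float = 0.24

    def __post_init__(self) -> None:
        for name in ("adhesion_force", "adhesion_distance", "approach_repulsion_scale", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_samples < 50:
            raise ValueError("n_samples must be >= 50")

    @property
    def max_separation(self) -> float:
        """Far end of the ramp: leaves a dip-free baseline window."""
        d = self.adhesion_distance
        return self.min_separation + max(2.5 * d, d + 2.0e-6)


#: Biomimetic setae-array preset: 174.5 nN dip over 4.6 µm.
SETAE_CURVE = CurveSpec(adhesion_force=174.5e-9, adhesion_distance=4.6e-6)
#: Flat-base preset: 122.2 nN dip over ~1 µm.
FLAT_CURVE = CurveSpec(adhesion_force=122.2e-9, adhesion_distance=1.0e-6)


def curve_preset(name: str, **overrides) -> CurveSpec:
    """Named curve preset (``"setae"`` or ``"flat"``), optionally overridden."""
    presets = {"setae": SETAE_CURVE, "flat": FLAT_CURVE}
    try:
        base = presets[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}: expected one of {sorted(presets)}")
    return replace(base, **overrides) if overrides else base


def gen_force_curve(spec: CurveSpec) -> ForceCurve:
    """Synthesise one approach–retract force curve from a ``CurveSpec``.

    Approach: monotone repulsive wall decaying over ~100 nm.  Retract:
    raised-cosine adhesive dip of the programmed depth and span, then a
    flat baseline.  Gaussian force noise of ``noise_sd`` is added to
    both branches; the nominal gap channel is reconstructed from the
    spring constant so the curve satisfies force = k (h − Z).
    """
    rng = np.random.default_rng(spec.seed)
    s_min, s_max = spec.min_separation, spec.max_separation
    n = spec.n_samples
    ramp_speed = 4.0e-6

    s_app = np.linspace(s_max, s_min, n)
    f_app = spec.approach_repulsion_scale * np.exp(-(s_app - s_min) / 100e-9)
    s_ret = np.linspace(s_min, s_max, n)
    u = s_ret - s_min
    d = spec.adhesion_distance
    with np.errstate(invalid="ignore"):
        dip = np.where(
            u <= d,
            -0.5 * spec.adhesion_force * (1.0 + np.cos(math.pi * np.minimum(u, d) / max(d, 1e-30))),
            0.0,
        )
    f_ret = dip
    h = np.concatenate([s_app, s_ret])
    # nominal gap from the noise-free deflection: the drive stays clean
    z = h - np.concatenate([f_app, f_ret]) / spec.spring_constant
    if spec.noise_sd > 0:
        f_app = f_app + rng.normal(0.0, spec.noise_sd, n)
        f_ret = f_ret + rng.normal(0.0, spec.noise_sd, n)
    force = np.concatenate([f_app, f_ret])
    phase = np.array(["approach"] * n + ["retract"] * n)
    time = np.concatenate(
        [(s_max - s_app) / ramp_speed, (s_max - s_min + (s_ret - s_min)) / ramp_speed]
    )
    return ForceCurve(
        time=time, z=z, h=h, force=force, phase=phase,
        spring_constant=spec.spring_constant,
    )


@dataclass(frozen=True)
class FrameSpec:
    """Programmed contact blob of a synthetic contact-intensity frame.

    The blob is an ellipse of area ``programmed_area`` at plateau
    ``peak_counts`` on a ``background_counts`` floor, with a narrow
    cosine rim centred on the ellipse boundary — a threshold midway
    between background and peak recovers the programmed area exactly
    (up to pixelation).
    """

    programmed_area: float
    peak_counts: float = 980.0
    background_counts: float = 120.0
    pixel_size: float = 0.1e-3
    seed: int = 0
    frame_shape: tuple = (220, 220)
    axis_ratio: float = 1.3
    edge_width: float = 0.03
    poisson_noise: bool = False

    def __post_init__(self) -> None:
        if not self.programmed_area > 0:
            raise ValueError("programmed_area must be > 0")
        if not self.peak_counts > self.background_counts >= 0:
            raise ValueError("require peak_counts > background_counts >= 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        a, b = self._semi_axes()
        half_y = self.frame_shape[0] * self.pixel_size / 2.0
        half_x = self.frame_shape[1] * self.pixel_size / 2.0
        margin = 1.0 + self.edge_width
        if a * margin >= half_x or b * margin >= half_y:
            raise ValueError("programmed blob does not fit in the frame")

    def _semi_axes(self) -> tuple[float, float]:
        a = math.sqrt(self.programmed_area * self.axis_ratio / math.pi)
        return a, a / self.axis_ratio


def gen_contact_frames(specs: Sequence[FrameSpec]) -> list[ContactImage]:
    """Synthesise contact-intensity frames, one per ``FrameSpec``."""
    frames = []
    for spec in specs:
        a, b = spec._semi_axes()
        ny, nx = spec.frame_shape
        y = (np.arange(ny) - (ny - 1) / 2.0) * spec.pixel_size
        x = (np.arange(nx) - (nx - 1) / 2.0) * spec.pixel_size
        yy, xx = np.meshgrid(y, x, indexing="ij")
        rho = np.sqrt((xx / a) ** 2 + (yy / b) ** 2)
        w = spec.edge_width
        profile = np.clip((1.0 + w / 2.0 - rho) / w, 0.0, 1.0)
        profile = 0.5 * (1.0 - np.cos(math.pi * profile))
        counts = spec.background_counts + (spec.peak_counts - spec.background_counts) * profile
        if spec.poisson_noise:
            rng = np.random.default_rng(spec.seed)
            counts = rng.poisson(counts).astype(float)
        frames.append(ContactImage(intensity=counts, pixel_size=spec.pixel_size))
    return frames


#: Per-cycle peak pressure (mean, SD) in Pa for the three adhesion states.
STATE_PEAKS = {
    "static": (113.11, 19.02),
    "crawling": (276.27, 59.82),
    "defending": (596.79, 150.8),
}


@dataclass(frozen=True)
class TraceSpec:
    """Programmed periodic chamber-pressure trace.

    ``state`` selects the measured default (mean, SD) of the per-cycle
    peak pressure difference; explicit ``mean_peak``/``sd_peak``
    override it.
    """

    state: str = "static"
    mean_peak: float | None = None
    sd_peak: float | None = None
    n_cycles: int = 15
    period: float = 1.0
    samples_per_cycle: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state not in STATE_PEAKS and self.mean_peak is None:
            raise ValueError(f"unknown state {self.state!r} and no mean_peak given")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not self.period > 0:
            raise ValueError("period must be > 0")
        if self.resolved_mean <= 0:
            raise ValueError("mean_peak must be > 0")

    @property
    def resolved_mean(self) -> float:
        return self.mean_peak if self.mean_peak is not None else STATE_PEAKS[self.state][0]

    @property
    def resolved_sd(self) -> float:
        return self.sd_peak if self.sd_peak is not None else STATE_PEAKS[self.state][1]


def gen_pressure_traces(spec: TraceSpec) -> pd.DataFrame:
    """Synthesise one periodic chamber-pressure trace.

    Each cycle is a sin² bump of the cycle's peak value, drawn as
    Normal(mean_peak, sd_peak) and floored at 0.  Columns: ``time_s``,
    ``pressure_Pa``.
    """
    rng = np.random.default_rng(spec.seed)
    peaks = np.maximum(
        0.0, rng.normal(spec.resolved_mean, spec.resolved_sd, spec.n_cycles)
    )
    n = spec.samples_per_cycle
    t = np.arange(spec.n_cycles * n) * (spec.period / n)
    shape = np.sin(math.pi * (t % spec.period) / spec.period) ** 2
    pressure = np.repeat(peaks, n) * shape
    return pd.DataFrame({"time_s": t, "pressure_Pa": pressure})
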