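"""Measurement-side analysis: force-curve features, contact images,
chamber-pressure statistics and group comparison.

Implements the quantities reported from the experiments:

* adhesion force / work / distance read off a retract force curve after
  baseline correction (``extract_features``);
* contact area and peak intensity from frustrated-total-internal-
  reflection contact frames (``contact_area``);
* per-cycle peak statistics of periodic chamber-pressure traces
  (``peak_pressure_stats``);
* two-group Mann–Whitney–Wilcoxon comparison (``compare_groups``);
* the percent-change arithmetic used to compare areas and adhesion
  means (``percent_change``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import mannwhitneyu
from skimage.filters import threshold_otsu

from .afm import ForceCurve

__all__ = [
    "CurveFeatures",
    "ContactImage",
    "ContactMetrics",
    "GroupSample",
    "extract_features",
    "percent_change",
    "contact_area",
    "peak_pressure_stats",
    "compare_groups",
]


@dataclass(frozen=True)
class CurveFeatures:
    """Adhesion features of one retract branch.

    ``adhesion_force`` is the depth of the adhesive dip below baseline,
    ``adhesion_distance`` the separation span from the force minimum to
    the return to baseline, and ``adhesion_work`` the area between the
    retract force and the baseline over that span.  ``event`` is False
    when the dip did not clear the noise threshold (features are then 0).
    """

    adhesion_force: float
    adhesion_work: float
    adhesion_distance: float
    event: bool = True

    def __post_init__(self) -> None:
        if min(self.adhesion_force, self.adhesion_work, self.adhesion_distance) < 0:
            raise ValueError("curve features must be >= 0")


@dataclass(frozen=True)
class ContactImage:
    """A contact-intensity frame with its pixel calibration."""

    intensity: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("intensity must be a non-empty 2-D array")
        if np.any(arr < 0):
            raise ValueError("intensity counts must be >= 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")


@dataclass(frozen=True)
class ContactMetrics:
    """Contact area (m²) and peak intensity (counts) of one frame."""

    contact_area: float
    max_intensity: float


@dataclass(frozen=True)
class GroupSample:
    """A labelled sample of values sharing one unit."""

    label: str
    values: tuple

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError(f"group {self.label!r} is empty")


def percent_change(reference: float, new: float) -> float:
    """Signed percent change of ``new`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * (new - reference) / reference


def extract_features(
    curve: ForceCurve,
    baseline_window: float = 0.2,
    noise_threshold: float = 3.0,
) -> CurveFeatures:
    """Read adhesion force, work and distance off the retract branch.

    The baseline is the mean force over the far-separation window (the
    top ``baseline_window`` fraction of the retract separation range);
    if the adhesive dip reaches into that window it is widened away from
    the dip with a warning.  A dip shallower than ``noise_threshold``
    baseline standard deviations is reported as a non-event with all
    features zero.
    """
    if not 0 < baseline_window < 1:
        raise ValueError("baseline_window must lie in (0, 1)")
    retract = curve.branch("retract")
    if len(retract) < 10:
        raise ValueError("curve needs a retract phase with >= 10 samples")
    s = retract["h_m"].to_numpy()
    f = retract["force_N"].to_numpy()
    order = np.argsort(s)
    s, f = s[order], f[order]

    window = baseline_window
    i_min_raw = int(np.argmin(f))
    while True:
        cut = s[-1] - window * (s[-1] - s[0])
        in_window = s >= cut
        if in_window.sum() < 2:
            raise ValueError("baseline window too narrow for this curve")
        if s[i_min_raw] >= cut and window < 0.95:
            warnings.warn(
                "baseline window overlaps the adhesive dip; widening",
                stacklevel=2,
            )
            window = min(0.95, window + 0.1)
            continue
        break
    baseline = float(f[in_window].mean())
    noise_sd = float(f[in_window].std(ddof=0))

    g = f - baseline
    i_min = int(np.argmin(g))
    depth = -g[i_min]
    if depth < noise_threshold * noise_sd or depth <= 0:
        return CurveFeatures(0.0, 0.0, 0.0, event=False)

    # return to baseline: first sample past the minimum back within the noise band
    after = np.nonzero(g[i_min:] >= -noise_threshold * noise_sd)[0]
    i_ret = i_min + int(after[0]) if after.size else len(g) - 1
    distance = s[i_ret] - s[i_min]
    seg = slice(i_min, i_ret + 1)
    work = float(np.trapezoid(np.clip(-g[seg], 0.0, None), s[seg]))
    return CurveFeatures(
        adhesion_force=float(depth),
        adhesion_work=work,
        adhesion_distance=float(distance),
    )


def contact_area(
    image: ContactImage, threshold: float | str = "otsu"
) -> ContactMetrics:
    """Contact area and peak intensity of a contact frame.

    The contact region is the set of pixels at or above ``threshold``
    (a count value, or ``"otsu"`` for automatic bimodal thresholding);
    its area is the pixel count times ``pixel_size²``.
    """
    arr = np.asarray(image.intensity, dtype=float)
    max_intensity = float(arr.max())
    if threshold == "otsu":
        thr = float(threshold_otsu(arr))
    else:
        thr = float(threshold)
        if thr > max_intensity:
            warnings.warn(
                "threshold exceeds the maximum count; contact area is zero",
                stacklevel=2,
            )
    n_contact = int(np.count_nonzero(arr >= thr))
    return ContactMetrics(
        contact_area=n_contact * image.pixel_size**2,
        max_intensity=max_intensity,
    )


def peak_pressure_stats(
    traces: Sequence, min_period: float = 0.5, time_column: str = "time_s",
    pressure_column: str = "pressure_Pa",
) -> tuple[float, float | None, int]:
    """Mean ± SD of per-cycle pressure peaks pooled over traces.

    Each trace is a DataFrame (or mapping) with time and pressure
    columns; peaks are local maxima of the pressure difference separated
    by at least ``min_period`` seconds.  Returns (mean, sd, n); the SD
    is ``None`` when only one peak was found, and a flat trace raises.
    """
    peaks: list[float] = []
    for trace in traces:
        t = np.asarray(trace[time_column], dtype=float)
        p = np.asarray(trace[pressure_column], dtype=float)
        if np.ptp(p) == 0:
            raise ValueError("flat pressure trace: no peaks to detect")
        dt = float(np.median(np.diff(t)))
        distance = max(1, int(round(min_period / dt)))
        idx, _ = find_peaks(p, distance=distance, prominence=0.05 * np.ptp(p))
        if idx.size == 0:
            # single-cycle trace whose maximum sits at a boundary plateau
            idx = np.array([int(np.argmax(p))])
        peaks.extend(p[idx])
    n = len(peaks)
    arr = np.array(peaks)
    sd = float(arr.std(ddof=1)) if n > 1 else None
    return float(arr.mean()), sd, n


def compare_groups(
    x: GroupSample, y: GroupSample, alternative: str = "two-sided"
) -> tuple[float, float, str]:
    """Mann–Whitney–Wilcoxon comparison of two groups.

    Uses the exact sampling distribution when both groups have at most
    12 observations and there are no ties, and the normal approximation
    with tie correction otherwise.  Returns (U, p, method).
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    xv = np.asarray(x.values, dtype=float)
    yv = np.asarray(y.values, dtype=float)
    pooled = np.concatenate([xv, yv])
    has_ties = np.unique(pooled).size < pooled.size
    exact = len(xv) <= 12 and len(yv) <= 12 and not has_ties
    method = "exact" if exact else "approx"
    if np.ptp(pooled) == 0:
        warnings.warn("both groups are one identical constant; p = 1", stacklevel=2)
        u = len(xv) * len(yv) / 2.0
        return u, 1.0, method
    res = mannwhitneyu(
        xv, yv, alternative=alternative,
        method="exact" if exact else "asymptotic",
    )
    return float(res.statistic), float(min(1.0, res.pvalue)), method
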