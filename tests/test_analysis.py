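"""Feature extraction, contact-area metrics, pressure statistics and the
Mann-Whitney comparison, each against an independent oracle."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from squeezefilm.afm import ForceCurve
from squeezefilm.analysis import (
    ContactImage,
    GroupSample,
    compare_groups,
    contact_area,
    extract_features,
    peak_pressure_stats,
    percent_change,
)
from squeezefilm.synthetic import (
    FLAT_CURVE,
    SETAE_CURVE,
    CurveSpec,
    TraceSpec,
    gen_force_curve,
    gen_pressure_traces,
)


def sawtooth_curve(depth, span, s_max=10e-6, n=2000, baseline=0.0):
    """Retract-only curve: an instant dip of ``depth`` at the smallest
    separation recovering linearly over ``span`` — closed-form features
    (force=depth, distance=span, work=depth*span/2)."""
    s = np.linspace(10e-9, s_max, n)
    force = np.where(s - s[0] <= span, -depth * (1 - (s - s[0]) / span), 0.0) + baseline
    return ForceCurve(
        time=np.arange(n, dtype=float),
        z=s.copy(),
        h=s,
        force=force,
        phase=np.array(["retract"] * n),
    )


class TestExtractFeatures:
    def test_sawtooth_closed_form(self):
        feats = extract_features(sawtooth_curve(depth=2e-7, span=4e-6))
        assert feats.adhesion_force == pytest.approx(2e-7, rel=5e-3)
        assert feats.adhesion_distance == pytest.approx(4e-6, rel=5e-3)
        assert feats.adhesion_work == pytest.approx(2e-7 * 4e-6 / 2, rel=5e-3)
        assert feats.adhesion_work <= feats.adhesion_force * feats.adhesion_distance

    def test_baseline_offset_invariance(self):
        f0 = extract_features(sawtooth_curve(2e-7, 4e-6, baseline=0.0))
        f1 = extract_features(sawtooth_curve(2e-7, 4e-6, baseline=3.3e-8))
        assert f0.adhesion_force == pytest.approx(f1.adhesion_force, rel=1e-9)
        assert f0.adhesion_work == pytest.approx(f1.adhesion_work, rel=1e-9)
        assert f0.adhesion_distance == pytest.approx(f1.adhesion_distance, rel=1e-9)

    def test_noiseless_generator_round_trip(self):
        for spec in (SETAE_CURVE, FLAT_CURVE):
            feats = extract_features(gen_force_curve(spec))
            assert feats.adhesion_force == pytest.approx(spec.adhesion_force, rel=5e-3)
            assert feats.adhesion_distance == pytest.approx(spec.adhesion_distance, rel=5e-3)
            expected_work = spec.adhesion_force * spec.adhesion_distance / 2.0
            assert feats.adhesion_work == pytest.approx(expected_work, rel=5e-3)

    def test_printed_distance_ratio_recovered(self):
        setae = extract_features(gen_force_curve(SETAE_CURVE))
        flat = extract_features(gen_force_curve(FLAT_CURVE))
        assert setae.adhesion_distance / flat.adhesion_distance == pytest.approx(4.6, rel=0.01)

    def test_noise_only_curve_reports_no_event(self):
        spec = CurveSpec(adhesion_force=0.0, adhesion_distance=1e-6,
                         approach_repulsion_scale=0.0, noise_sd=1e-9, seed=4)
        feats = extract_features(gen_force_curve(spec), noise_threshold=5.0)
        assert not feats.event
        assert feats.adhesion_force == 0.0 and feats.adhesion_work == 0.0

    def test_dip_in_baseline_window_widens_with_warning(self):
        n = 2000
        s = np.linspace(10e-9, 10e-6, n)
        # dip centred at 95% of the range, inside the default window
        force = -2e-7 * np.exp(-((s - 9.5e-6) ** 2) / (2 * (0.2e-6) ** 2))
        curve = ForceCurve(np.arange(n, dtype=float), s.copy(), s, force,
                           np.array(["retract"] * n))
        with pytest.warns(UserWarning, match="widening"):
            extract_features(curve)

    def test_missing_retract_phase_raises(self):
        curve = sawtooth_curve(1e-7, 1e-6)
        approach_only = ForceCurve(curve.time, curve.z, curve.h, curve.force,
                                   np.array(["approach"] * len(curve.time)))
        with pytest.raises(ValueError):
            extract_features(approach_only)


class TestPercentChange:
    @pytest.mark.parametrize(
        "reference, new, expected, tol",
        [
            (203.20, 182.33, -10.27, 5e-3),
            (122.2, 174.5, 42.8, 0.1),
            (7.5, 7.5, 0.0, 1e-12),
        ],
    )
    def test_printed_values(self, reference, new, expected, tol):
        assert percent_change(reference, new) == pytest.approx(expected, abs=tol)

    def test_unrounded_adhesion_change_brackets_printed_value(self):
        assert 42.7 <= percent_change(122.2, 174.5) <= 42.8

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestContactArea:
    def test_square_blob_area(self):
        img = np.zeros((50, 50))
        img[10:20, 15:25] = 1000.0
        metrics = contact_area(ContactImage(img, pixel_size=0.1e-3), threshold=500.0)
        assert metrics.contact_area == pytest.approx(1.0e-6, rel=1e-12)  # 1 mm^2
        assert metrics.max_intensity == 1000.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        img = ContactImage(rng.integers(0, 1200, (64, 64)).astype(float), 1e-4)
        areas = [contact_area(img, thr).contact_area for thr in (100.0, 400.0, 800.0, 1100.0)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_threshold_above_max_warns_zero_area(self):
        img = ContactImage(np.full((8, 8), 10.0), 1e-4)
        with pytest.warns(UserWarning):
            metrics = contact_area(img, threshold=100.0)
        assert metrics.contact_area == 0.0


class TestPeakPressureStats:
    def test_constant_amplitude_cycles(self):
        trace = gen_pressure_traces(TraceSpec(mean_peak=250.0, sd_peak=0.0, n_cycles=6))
        mean, sd, n = peak_pressure_stats([trace])
        assert mean == pytest.approx(250.0, rel=1e-6)
        assert sd == pytest.approx(0.0, abs=1e-9)
        assert n == 6

    def test_single_cycle_sd_absent(self):
        trace = gen_pressure_traces(TraceSpec(mean_peak=100.0, sd_peak=0.0, n_cycles=1))
        mean, sd, n = peak_pressure_stats([trace])
        assert n == 1 and sd is None
        assert mean == pytest.approx(100.0, rel=1e-6)

    def test_flat_trace_raises(self):
        import pandas as pd

        flat = pd.DataFrame({"time_s": np.arange(10.0), "pressure_Pa": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            peak_pressure_stats([flat])

    def test_recovers_defending_state_mean_within_two_se(self):
        spec = TraceSpec(state="defending", n_cycles=15, seed=11)
        mean, _, n = peak_pressure_stats([gen_pressure_traces(spec)])
        se = 150.8 / math.sqrt(15)
        assert n == 15
        assert abs(mean - 596.79) < 2 * se


def exact_mwu_pvalue(x, y, alternative="two-sided"):
    """Exhaustive permutation null of the U statistic (no ties)."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_of(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_of(x, y)
    us = [
        u_of(comb, [v for i, v in enumerate(pooled) if i not in idx])
        for idx in itertools.combinations(range(len(pooled)), n)
        for comb in [[pooled[i] for i in idx]]
    ]
    us = np.array(us)
    total = len(us)
    p_le = np.sum(us <= u_obs) / total
    p_ge = np.sum(us >= u_obs) / total
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestCompareGroups:
    def test_separated_triplets(self):
        u, p, method = compare_groups(
            GroupSample("x", (1, 2, 3)), GroupSample("y", (4, 5, 6))
        )
        assert u == 0.0
        assert p == pytest.approx(0.1, rel=1e-9)
        assert method == "exact"

    def test_identical_samples_give_p_one(self):
        u, p, method = compare_groups(
            GroupSample("x", (1.0, 2.0, 3.0)), GroupSample("y", (1.0, 2.0, 3.0))
        )
        assert p == pytest.approx(1.0)

    def test_constant_identical_groups_warn(self):
        with pytest.warns(UserWarning):
            _, p, _ = compare_groups(GroupSample("x", (5.0, 5.0)), GroupSample("y", (5.0, 5.0)))
        assert p == 1.0

    @pytest.mark.parametrize("nx, ny, seed", [(3, 4, 1), (5, 5, 2), (8, 6, 3), (8, 8, 4)])
    def test_exact_matches_exhaustive_enumeration(self, nx, ny, seed):
        rng = np.random.default_rng(seed)
        x = tuple(rng.normal(size=nx))
        y = tuple(rng.normal(0.5, size=ny))
        for alternative in ("two-sided", "less", "greater"):
            _, p, method = compare_groups(
                GroupSample("x", x), GroupSample("y", y), alternative
            )
            assert method == "exact"
            assert p == pytest.approx(exact_mwu_pvalue(x, y, alternative), abs=1e-12)

    def test_exact_close_to_normal_approximation(self):
        rng = np.random.default_rng(7)
        x = tuple(rng.normal(size=8))
        y = tuple(rng.normal(0.3, size=8))
        _, p_exact, _ = compare_groups(GroupSample("x", x), GroupSample("y", y))
        p_approx = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert abs(p_exact - p_approx) < 0.02

    def test_unknown_alternative_raises(self):
        with pytest.raises(ValueError):
            compare_groups(GroupSample("x", (1,)), GroupSample("y", (2,)), "sideways")
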