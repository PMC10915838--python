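"""Energy-span TOF model, scaling-relation fits and volcano construction."""

import math

import numpy as np
import pytest

from gencat.constants import R_KCAL, kbt_over_h
from gencat.benchmark import PLANTED_LINES, PLANTED_PEAK
from gencat.volcano import (
    EnergyProfile,
    build_volcano,
    degree_of_tof_control,
    energy_span,
    fit_lfesr,
    gaussian_activity,
    log10_tof,
    log10_tof_summed,
    profile_from_fit,
)

T = 298.15


def profile(states, dgr=-5.0, mech="C2"):
    return EnergyProfile("p", mech, tuple(states), dgr)


def brute_force_span(prof):
    """Independent positional pair scan (the oracle for energy_span)."""
    seq = [("ref", 0.0, False)] + [
        (l, e, l.upper().startswith("TS")) for l, e in prof.states
    ]
    best = -math.inf
    for i, (_, te, is_ts) in enumerate(seq):
        if not is_ts:
            continue
        for j, (_, ie, is_ts_j) in enumerate(seq):
            if is_ts_j:
                continue
            span = te - ie + (prof.dgr if i < j else 0.0)
            best = max(best, span)
    return best


def test_eyring_prefactor_constant():
    assert math.log10(kbt_over_h(T)) == pytest.approx(12.793, abs=1e-3)


def test_single_ts_closed_form():
    p = profile([("TS1", 10.0)], dgr=-5.0)
    assert energy_span(p) == pytest.approx(10.0)
    assert log10_tof(p, T) == pytest.approx(5.46, abs=5e-3)


def test_intermediate_before_ts_closed_form():
    p = profile([("1", -3.0), ("TS1", 8.0)], dgr=-5.0)
    assert energy_span(p) == pytest.approx(11.0)
    assert log10_tof(p, T) == pytest.approx(4.73, abs=5e-3)


def test_span_matches_brute_force_on_random_profiles(rng):
    labels = ["1", "TS1", "1B", "TS2", "2", "TS3"]
    for _ in range(1000):
        energies = rng.normal(0.0, 8.0, size=6)
        p = profile(list(zip(labels, energies)), dgr=float(rng.normal(-8, 3)))
        assert energy_span(p) == pytest.approx(brute_force_span(p), abs=1e-10)


def test_no_ts_raises():
    with pytest.raises(ValueError, match="transition state"):
        energy_span(profile([("1", 2.0)]))


def test_tof_monotone_in_state_energies(rng):
    """Raising a TS lowers the TOF; raising the span-active intermediate
    raises it (the gap to the following TS shrinks)."""
    p = profile([("1", -3.0), ("TS1", 9.0)], dgr=-6.0)
    assert log10_tof(profile([("1", -3.0), ("TS1", 10.0)], dgr=-6.0), T) < log10_tof(p, T)
    assert log10_tof(profile([("1", -2.0), ("TS1", 9.0)], dgr=-6.0), T) > log10_tof(p, T)


def test_tof_invariant_under_state_relabeling():
    a = profile([("1", -2.0), ("TS1", 7.0), ("2", -4.0), ("TS3", 5.0)], dgr=-9.0)
    b = profile([("1B", -2.0), ("TS2", 7.0), ("P", -4.0), ("TS9", 5.0)], dgr=-9.0)
    assert log10_tof(a, T) == pytest.approx(log10_tof(b, T), abs=1e-12)


def test_degree_of_control_single_ts_is_one():
    w = degree_of_tof_control(profile([("TS1", 10.0)], dgr=-5.0), T)
    assert w == pytest.approx({"TS1": 1.0}, abs=1e-6)


def test_degree_of_control_symmetric_split():
    # pair spans are mirror images: TS1 sees {10, 5}, TS2 sees {5, 10}
    p = profile([("TS1", 10.0), ("1", -5.0), ("TS2", 5.0)], dgr=-10.0)
    w = degree_of_tof_control(p, T)
    assert w["TS1"] == pytest.approx(0.5, abs=1e-3)
    assert w["TS2"] == pytest.approx(0.5, abs=1e-3)


def test_degree_of_control_sums_to_one(rng):
    labels = ["1", "TS1", "1B", "TS2", "2", "TS3"]
    for _ in range(50):
        energies = rng.normal(0.0, 6.0, size=6)
        p = profile(list(zip(labels, energies)), dgr=float(-rng.uniform(5, 15)))
        w = degree_of_tof_control(p, T)
        assert all(v >= 0 for v in w.values())
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-6)


def _exact_profiles(lines, dgr_line, xs, mech="C2"):
    out = []
    for i, x in enumerate(xs):
        states = tuple((l, s * x + b) for l, (s, b) in lines.items())
        out.append(EnergyProfile(f"r{i}", mech, states, dgr_line[0] * x + dgr_line[1]))
    return out


def test_lfesr_recovers_exact_lines():
    lines = {"1": (0.8, 2.0), "TS1": (0.6, 9.0), "2": (1.0, 0.0)}
    profs = _exact_profiles(lines, (0.0, -10.0), np.linspace(-5, 10, 7))
    fit = fit_lfesr(profs)
    for label, (slope, intercept) in lines.items():
        assert fit.fits[label].slope == pytest.approx(slope, abs=1e-10)
        assert fit.fits[label].intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.fits[label].r2 == pytest.approx(1.0, abs=1e-10)


def test_descriptor_state_fit_is_identity(noise_free_landscape):
    from gencat.benchmark import emit_profiles

    fit = fit_lfesr(emit_profiles(noise_free_landscape, 10, 0))
    f = fit.fits["2"]
    assert (f.slope, f.intercept) == (1.0, 0.0)


def test_lfesr_slope_confidence_coverage(rng):
    """Fitted 95% CIs on a planted slope cover the truth in >= 93/100 sets."""
    from scipy import stats

    slope, intercept, sigma, n = 0.7, 3.0, 0.5, 40
    hits = 0
    for _ in range(100):
        x = rng.uniform(-10, 15, size=n)
        y = slope * x + intercept + rng.normal(0, sigma, size=n)
        res = stats.linregress(x, y)
        half = stats.t.ppf(0.975, n - 2) * res.stderr
        hits += abs(res.slope - slope) <= half
    assert hits >= 93


def test_volcano_peak_at_planted_crossing(noise_free_landscape):
    from gencat.benchmark import emit_profiles

    for mech in ("C2", "C3"):
        profs = emit_profiles(noise_free_landscape, 12, 0, mechanism=mech)
        fit = fit_lfesr(profs)
        grid = np.linspace(-25.0, 25.0, 251)
        model = build_volcano(fit, grid, T)
        assert model.peak_descriptor == pytest.approx(PLANTED_PEAK[mech], abs=0.2)


def test_volcano_matches_pointwise_closed_form(noise_free_landscape):
    from gencat.benchmark import emit_profiles

    profs = emit_profiles(noise_free_landscape, 12, 0)
    fit = fit_lfesr(profs)
    grid = np.linspace(-20.0, 20.0, 41)
    model = build_volcano(fit, grid, T)
    lines = PLANTED_LINES["C2"]
    for x, y in zip(model.grid, model.log_tof):
        states = tuple((l, s * x + b) for l, (s, b) in lines.items())
        expected = log10_tof(EnergyProfile("x", "C2", states, -12.0), T)
        assert y == pytest.approx(expected, abs=1e-8)


def test_flat_ts_line_gives_flat_curve():
    # a flat TS line and a strongly exergonic cycle: the TS/reactants pair
    # dominates everywhere, so the curve carries no descriptor dependence
    profs = _exact_profiles({"TS1": (0.0, 8.0), "2": (1.0, 0.0)}, (0.0, -40.0),
                            np.linspace(1.0, 5.0, 5))
    fit = fit_lfesr(profs)
    model = build_volcano(fit, np.linspace(1.0, 5.0, 21), T)
    assert np.ptp(model.log_tof) < 1e-9


def test_volcano_band_brackets_curve(landscape):
    from gencat.benchmark import emit_profiles

    fit = fit_lfesr(emit_profiles(landscape, 44, 3))
    model = build_volcano(fit, np.linspace(-20, 20, 51), T)
    assert np.all(model.lo95 <= model.log_tof + 1e-12)
    assert np.all(model.hi95 >= model.log_tof - 1e-12)


def test_volcano_grid_range_checked(noise_free_landscape):
    from gencat.benchmark import emit_profiles

    fit = fit_lfesr(emit_profiles(noise_free_landscape, 5, 0))
    with pytest.raises(ValueError, match="range"):
        build_volcano(fit, np.array([-200.0, 0.0, 200.0]), T)


def test_gaussian_activity_shape():
    assert gaussian_activity(-9.0, -9.0, 3.0) == 1.0
    assert gaussian_activity(-6.0, -9.0, 3.0) == pytest.approx(math.exp(-0.5))
    assert gaussian_activity(-12.0, -9.0, 3.0) == pytest.approx(math.exp(-0.5))
    xs = np.linspace(-9.0, 10.0, 50)
    f = [gaussian_activity(x, -9.0, 3.0) for x in xs]
    assert all(b < a for a, b in zip(f, f[1:]))
    with pytest.raises(ValueError):
        gaussian_activity(0.0, -9.0, 0.0)


def test_summed_tof_below_max_span_bound(rng):
    """The smoothed expression never exceeds the max-span estimate by more
    than the pair-count entropy allows, and both agree when one pair
    dominates."""
    p = profile([("TS1", 25.0), ("1", -2.0)], dgr=-30.0)
    assert log10_tof_summed(p, T) <= log10_tof(p, T) + 1e-9
    assert log10_tof_summed(p, T) == pytest.approx(log10_tof(p, T), abs=0.05)
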