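"""TOF volcano plots from linear free-energy scaling relationships.

A catalytic cycle is summarized by a free-energy profile: ordered relative
Gibbs energies of intermediates and transition states, with the separated
reactants as the zero reference and an overall reaction free energy dG_r.
The energy-span model converts a profile into a turnover frequency,

    TOF = (k_B*T/h) * exp(-dE / RT),

where the energy span dE is the largest effective gap between a transition
state T_i and an intermediate I_j:  T_i - I_j when the TS follows the
intermediate in the cycle, and T_i - I_j + dG_r when it precedes it.

Linear free-energy scaling relationships (LFESRs) regress every state's
energy against a single descriptor — here the relative energy of the
protonated tetrahydro-beta-carboline intermediate, state "2" — across a set
of reactions.  Reconstructing profiles from the fitted lines over a grid of
descriptor values and applying the energy-span model yields the TOF volcano
curve, whose peak marks the maximum attainable activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from .constants import R_KCAL, T_DEFAULT, kbt_over_h

DESCRIPTOR_STATE = "2"
DGR_KEY = "dGr"


def is_ts_label(label: str) -> bool:
    return label.upper().startswith("TS")


@dataclass(frozen=True)
class EnergyProfile:
    """Ordered relative Gibbs energies (kcal/mol) of one cycle's states.

    ``states`` runs along the reaction coordinate; the separated reactants
    (energy 0) are an implicit leading intermediate.  ``dgr`` is the overall
    reaction free energy.
    """

    reaction_id: str
    mechanism: str  # "C2" (concerted) or "C3" (stepwise, via spiroindolenine)
    states: tuple[tuple[str, float], ...]
    dgr: float

    def __post_init__(self) -> None:
        for _, e in self.states:
            if not math.isfinite(e):
                raise ValueError(f"profile {self.reaction_id}: non-finite energy")
        if not math.isfinite(self.dgr):
            raise ValueError(f"profile {self.reaction_id}: non-finite dGr")

    @property
    def descriptor(self) -> float | None:
        """Relative energy of intermediate 2 (the volcano descriptor)."""
        for label, e in self.states:
            if label == DESCRIPTOR_STATE:
                return e
        return None

    def ts_states(self) -> list[tuple[str, float]]:
        return [(l, e) for l, e in self.states if is_ts_label(l)]

    def intermediates(self) -> list[tuple[str, float]]:
        """Intermediates including the reactant reference at position -1."""
        out = [("ref", 0.0)]
        out.extend((l, e) for l, e in self.states if not is_ts_label(l))
        return out


def _pair_spans(profile: EnergyProfile):
    """Effective span for every (TS, intermediate) pair.

    Yields (ts_label, span) where span = T_i - I_j (+ dG_r if the TS
    precedes the intermediate in the cycle).
    """
    positions = {"ref": -1}
    for pos, (label, _) in enumerate(profile.states):
        positions[label] = pos
    ts = profile.ts_states()
    if not ts:
        raise ValueError(f"profile {profile.reaction_id}: no transition state")
    for t_label, t_e in ts:
        for i_label, i_e in profile.intermediates():
            span = t_e - i_e
            if positions[t_label] < positions[i_label]:
                span += profile.dgr
            yield t_label, span


def energy_span(profile: EnergyProfile) -> float:
    """dE: the maximum effective (TS, intermediate) gap, kcal/mol."""
    return max(span for _, span in _pair_spans(profile))


def tof_energy_span(profile: EnergyProfile, temperature: float = T_DEFAULT) -> float:
    """Turnover frequency (s^-1) from the max-span exponential."""
    return kbt_over_h(temperature) * math.exp(-energy_span(profile) / (R_KCAL * temperature))


def log10_tof(profile: EnergyProfile, temperature: float = T_DEFAULT) -> float:
    rt = R_KCAL * temperature
    return math.log10(kbt_over_h(temperature)) - energy_span(profile) / (rt * math.log(10.0))


def log10_tof_summed(profile: EnergyProfile, temperature: float = T_DEFAULT) -> float:
    """Smoothed TOF from the full summed energy-span expression.

    log10 of  (k_B T/h) * (exp(-dG_r/RT) - 1) / sum_ij exp((span_ij - dG_r)/RT).
    Requires an exergonic cycle (dG_r < 0).  Evaluated in log space.
    """
    rt = R_KCAL * temperature
    if profile.dgr >= 0:
        raise ValueError("summed TOF expression requires dG_r < 0")
    spans = np.array([s for _, s in _pair_spans(profile)])
    log_den = logsumexp((spans - profile.dgr) / rt)
    # log(exp(-dgr/RT) - 1); -dgr/RT > 0 so the term is positive
    a = -profile.dgr / rt
    log_num = a + math.log1p(-math.exp(-a))
    ln10 = math.log(10.0)
    return math.log10(kbt_over_h(temperature)) + (log_num - log_den) / ln10


def degree_of_tof_control(
    profile: EnergyProfile, temperature: float = T_DEFAULT, h: float = 1e-4
) -> dict[str, float]:
    """Per-TS sensitivity weights X_TOF of the summed TOF expression.

    X_i = -RT * d(ln TOF)/d(T_i), evaluated by central differences; the
    weights are non-negative and sum to 1 over the transition states.
    """
    rt = R_KCAL * temperature
    weights = {}
    for ts_label, _ in profile.ts_states():
        def shifted(delta: float) -> EnergyProfile:
            states = tuple(
                (l, e + delta if l == ts_label else e) for l, e in profile.states
            )
            return EnergyProfile(profile.reaction_id, profile.mechanism, states, profile.dgr)

        up = log10_tof_summed(shifted(+h), temperature)
        dn = log10_tof_summed(shifted(-h), temperature)
        x = -rt * (up - dn) * math.log(10.0) / (2.0 * h)
        weights[ts_label] = max(x, 0.0)
    return weights


@dataclass(frozen=True)
class StateFit:
    """OLS line of one state's energy against the descriptor."""

    slope: float
    intercept: float
    r2: float
    resid_se: float
    n: int
    fittable: bool = True


@dataclass
class LFESRFit:
    """Per-state linear free-energy scaling relationships.

    The descriptor state's own relation is the identity by definition; the
    overall reaction free energy is fitted like a state under key ``dGr``.
    """

    mechanism: str
    state_order: tuple[str, ...]
    fits: dict[str, StateFit]

    def states(self) -> tuple[str, ...]:
        return self.state_order


def fit_lfesr(profiles) -> LFESRFit:
    """Least-squares scaling relations over a set of profiles.

    Each state's energies are regressed against the profiles' descriptor
    values; states observed fewer than 3 times are flagged unfittable.
    """
    profiles = list(profiles)
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles to fit scaling relations")
    xs = []
    for p in profiles:
        if p.descriptor is None:
            raise ValueError(f"profile {p.reaction_id}: no descriptor state")
        xs.append(p.descriptor)
    xs = np.asarray(xs)

    state_order: list[str] = []
    for p in profiles:
        for label, _ in p.states:
            if label not in state_order:
                state_order.append(label)

    mechanism = profiles[0].mechanism
    fits: dict[str, StateFit] = {}
    for label in state_order + [DGR_KEY]:
        if label == DESCRIPTOR_STATE:
            fits[label] = StateFit(1.0, 0.0, 1.0, 0.0, len(profiles))
            continue
        pairs = []
        for p, x in zip(profiles, xs):
            if label == DGR_KEY:
                pairs.append((x, p.dgr))
            else:
                for l, e in p.states:
                    if l == label:
                        pairs.append((x, e))
        if len(pairs) < 3:
            fits[label] = StateFit(np.nan, np.nan, np.nan, np.nan, len(pairs), fittable=False)
            continue
        px = np.array([a for a, _ in pairs])
        py = np.array([b for _, b in pairs])
        res = stats.linregress(px, py)
        resid = py - (res.slope * px + res.intercept)
        dof = max(len(pairs) - 2, 1)
        fits[label] = StateFit(
            float(res.slope),
            float(res.intercept),
            float(res.rvalue**2),
            float(np.sqrt(np.sum(resid**2) / dof)),
            len(pairs),
        )
    return LFESRFit(mechanism, tuple(state_order), fits)


def profile_from_fit(fit: LFESRFit, x: float, reaction_id: str = "lfesr") -> EnergyProfile:
    """Reconstruct a profile at descriptor value ``x`` from the fitted lines."""
    states = []
    for label in fit.state_order:
        f = fit.fits[label]
        if not f.fittable:
            raise ValueError(f"state {label} is unfittable (n = {f.n} < 3)")
        states.append((label, f.slope * x + f.intercept))
    dgr_fit = fit.fits[DGR_KEY]
    return EnergyProfile(reaction_id, fit.mechanism, tuple(states), dgr_fit.slope * x + dgr_fit.intercept)


@dataclass
class VolcanoModel:
    """A TOF volcano curve on a descriptor grid, with 95% bands and peak."""

    mechanism: str
    grid: np.ndarray            # descriptor values, kcal/mol
    log_tof: np.ndarray         # log10 TOF, s^-1
    lo95: np.ndarray
    hi95: np.ndarray
    peak_descriptor: float
    peak_log_tof: float
    temperature: float
    fit: LFESRFit = field(repr=False, default=None)

    def log10_tof_at(self, x: float) -> float:
        return log10_tof(profile_from_fit(self.fit, x), self.temperature)


def build_volcano(
    fit: LFESRFit,
    grid: np.ndarray,
    temperature: float = T_DEFAULT,
) -> VolcanoModel:
    """Evaluate the volcano curve over ``grid`` and locate its peak.

    At each grid point the profile is reconstructed from the scaling lines
    and the max-span TOF computed.  The 95% band is a conservative envelope:
    every state is shifted by +/- t_(0.975, n-2) times its residual standard
    error, with signs chosen to maximize (upper) or minimize (lower) the TOF
    (transition states down and intermediates up for the upper edge, and
    vice versa).  The peak is the grid argmax refined by bounded local
    search between its neighbors.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("grid must have at least 2 points")
    if np.max(np.abs(grid)) > 100:
        raise ValueError("descriptor grid outside a physically sensible range")

    def t_margin(label: str) -> float:
        f = fit.fits[label]
        if f.resid_se == 0 or f.n < 3:
            return 0.0
        return float(stats.t.ppf(0.975, f.n - 2) * f.resid_se)

    def curve(sign: int) -> np.ndarray:
        # sign=0 central; +1 upper envelope; -1 lower envelope
        out = np.empty_like(grid)
        for i, x in enumerate(grid):
            states = []
            for label in fit.state_order:
                f = fit.fits[label]
                if not f.fittable:
                    raise ValueError(f"state {label} unfittable; cannot build volcano")
                e = f.slope * x + f.intercept
                if sign:
                    m = t_margin(label)
                    e += (-sign if is_ts_label(label) else sign) * m
                states.append((label, e))
            dgr_fit = fit.fits[DGR_KEY]
            # raising dG_r enlarges the TS-precedes-intermediate spans, so
            # the upper TOF envelope takes dG_r at its lower band edge
            dgr = dgr_fit.slope * x + dgr_fit.intercept - sign * t_margin(DGR_KEY)
            p = EnergyProfile("grid", fit.mechanism, tuple(states), dgr)
            out[i] = log10_tof(p, temperature)
        return out

    log_tof = curve(0)
    hi95 = curve(+1)
    lo95 = curve(-1)

    k = int(np.argmax(log_tof))
    lo_x = grid[max(k - 1, 0)]
    hi_x = grid[min(k + 1, grid.size - 1)]
    if hi_x > lo_x:
        res = optimize.minimize_scalar(
            lambda x: -log10_tof(profile_from_fit(fit, x), temperature),
            bounds=(lo_x, hi_x),
            method="bounded",
            options={"xatol": 1e-6},
        )
        peak_x, peak_y = float(res.x), float(-res.fun)
    else:
        peak_x, peak_y = float(grid[k]), float(log_tof[k])

    return VolcanoModel(
        fit.mechanism, grid, log_tof, lo95, hi95, peak_x, peak_y, temperature, fit=fit
    )


def combined_log_tof(models, x: float) -> float:
    """Operative activity at ``x``: the larger of the mechanisms' curves."""
    return max(m.log10_tof_at(x) for m in models)


def gaussian_activity(x: float, target: float = -9.0, width: float = 3.0) -> float:
    """Unit-peak Gaussian merit of a descriptor value.

    f = exp(-(x - target)^2 / (2 width^2)); equals 1 at the volcano peak
    target (default -9.0 kcal/mol) and decays with distance from it.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    return math.exp(-((x - target) ** 2) / (2.0 * width**2))


def read_profiles(path) -> list[EnergyProfile]:
    """Read ``profiles.csv``: one row per (reaction_id, mechanism), one
    column per state label, plus ``dgr_kcal``.  Missing cells skip states."""
    import pandas as pd

    df = pd.read_csv(path)
    meta = {"reaction_id", "mechanism", "dgr_kcal"}
    state_cols = [c for c in df.columns if c not in meta]
    profiles = []
    for _, row in df.iterrows():
        states = tuple(
            (c, float(row[c])) for c in state_cols if np.isfinite(row[c])
        )
        profiles.append(
            EnergyProfile(str(row["reaction_id"]), str(row["mechanism"]), states, float(row["dgr_kcal"]))
        )
    return profiles


def write_profiles(profiles, path) -> None:
    import pandas as pd

    labels: list[str] = []
    for p in profiles:
        for l, _ in p.states:
            if l not in labels:
                labels.append(l)
    rows = []
    for p in profiles:
        row = {"reaction_id": p.reaction_id, "mechanism": p.mechanism, "dgr_kcal": p.dgr}
        row.update({l: e for l, e in p.states})
        rows.append(row)
    pd.DataFrame(rows, columns=["reaction_id", "mechanism", *labels, "dgr_kcal"]).to_csv(
        path, index=False
    )
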