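"""Compartment-cascade simulation and effect links.

All model structures used here are linear three-stage cascades

    dX0/dt = -a*X0,          X0(0) = A
    dX1/dt = a*X0 - b*X1,    X1(0) = 0
    dX2/dt = X1 - c*X2,      X2(0) = 0

(the inflow into the third stage carries a unit-coefficient per hour; the
half-effect constants downstream absorb the implied scale). Closed-form
bi/tri-exponential solutions are the default evaluator, with exact degenerate
branches (t*exp(-k t) terms) when decay rates coincide; a general-purpose
numeric integrator is kept behind the same interface as a cross-check.

Effect links: a Hill (Emax) function of the tissue concentration for the
PK-driven readouts, and a dose-triggered cascade for the activation-based
readout, where the administered dose (not the concentration time-course)
sets the cascade's initial condition through a Hill function of dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .types import (ActivationParameters, EmaxLink, GlobalParameters,
                    PKParameters, ValidationError)

# Relative separation below which two decay rates are treated as a repeated
# eigenvalue; chosen so both the distinct-rate and the degenerate branch are
# accurate to well below 1e-6 at the crossover.
_EQ_RTOL = 1e-7


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= _EQ_RTOL * max(abs(a), abs(b))


def cascade_stage2(a: float, b: float, t: np.ndarray) -> np.ndarray:
    """Impulse response of two chained decays: exp(-a t) convolved with exp(-b t)."""
    t = np.asarray(t, float)
    if _close(a, b):
        return t * np.exp(-0.5 * (a + b) * t)
    return (np.exp(-a * t) - np.exp(-b * t)) / (b - a)


def cascade_stage3(a: float, b: float, c: float, t: np.ndarray) -> np.ndarray:
    """Triple convolution exp(-a t) * exp(-b t) * exp(-c t).

    Handles every coincidence pattern of the three decay rates with the exact
    degenerate closed form (t- and t^2-weighted exponentials).
    """
    t = np.asarray(t, float)
    ab, ac, bc = _close(a, b), _close(a, c), _close(b, c)
    if ab and ac:
        k = (a + b + c) / 3.0
        return 0.5 * t**2 * np.exp(-k * t)
    if ab or ac or bc:
        # exactly one coincident pair: conv of t*exp(-mu t) with exp(-nu t)
        if ab:
            mu, nu = 0.5 * (a + b), c
        elif ac:
            mu, nu = 0.5 * (a + c), b
        else:
            mu, nu = 0.5 * (b + c), a
        d = mu - nu
        return (np.exp(-nu * t) - (1.0 + d * t) * np.exp(-mu * t)) / d**2
    # all distinct: partial fractions
    return (np.exp(-a * t) / ((b - a) * (c - a))
            + np.exp(-b * t) / ((a - b) * (c - b))
            + np.exp(-c * t) / ((a - c) * (b - c)))


@dataclass
class Trajectory:
    """Time-indexed compartment states and per-readout effect series."""

    times: np.ndarray
    states: dict[str, np.ndarray] = field(default_factory=dict)
    effects: dict[str, np.ndarray] = field(default_factory=dict)
    dose: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        n = len(self.times)
        for name, s in {**self.states, **self.effects}.items():
            if len(s) != n:
                raise ValidationError(f"series {name!r} length != len(times)")

    def to_dataframe(self):
        import pandas as pd
        frames = []
        for kind, series in (("state", self.states), ("effect", self.effects)):
            for name, vals in series.items():
                frames.append(pd.DataFrame({"time": self.times, "name": name,
                                            "kind": kind, "value": vals,
                                            "dose": self.dose}))
        return pd.concat(frames, ignore_index=True)


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, float)
    if times.ndim != 1 or np.any(times < 0):
        raise ValidationError("times must be a 1-d non-negative array")
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing")
    return times


def solve_linear_cascade(k01: float, k10: float, k20: float,
                         initial_state: float, times: np.ndarray) -> Trajectory:
    """Closed-form solution of the three-stage cascade seeded with ``initial_state``.

    Stage 0 decays at ``k01`` feeding stage 1 (rate coefficient ``k01``),
    stage 1 decays at ``k10`` feeding stage 2 with unit coefficient, stage 2
    is eliminated at ``k20``.
    """
    for name, v in (("k01", k01), ("k10", k10), ("k20", k20)):
        if v <= 0:
            raise ValidationError(f"rate {name} must be > 0")
    times = _check_times(times)
    A = float(initial_state)
    s0 = A * np.exp(-k01 * times)
    s1 = A * k01 * cascade_stage2(k01, k10, times)
    s2 = A * k01 * cascade_stage3(k01, k10, k20, times)
    return Trajectory(times, states={"C0": s0, "C1": s1, "C2": s2})


def solve_linear_cascade_numeric(k01: float, k10: float, k20: float,
                                 initial_state: float, times: np.ndarray,
                                 rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Numeric cross-check integrator for the same cascade (LSODA)."""
    times = _check_times(times)
    t0 = min(0.0, times[0])

    def rhs(_t, y):
        return [-k01 * y[0], k01 * y[0] - k10 * y[1], y[1] - k20 * y[2]]

    sol = solve_ivp(rhs, (t0, times[-1] if len(times) else t0),
                    [float(initial_state), 0.0, 0.0], t_eval=times,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover - LSODA is robust on linear systems
        raise RuntimeError(f"integration failed: {sol.message}")
    return Trajectory(times, states={"C0": sol.y[0], "C1": sol.y[1], "C2": sol.y[2]})


def pk_concentrations(pk: PKParameters, k20: float, dose: float,
                      times: np.ndarray) -> Trajectory:
    """Absorption/central/tissue concentrations after an i.p. dose (mg/kg).

    The initial absorption-compartment concentration is dose/Vd; all
    compartments scale linearly in dose.
    """
    if dose < 0:
        raise ValidationError("dose must be >= 0")
    traj = solve_linear_cascade(pk.k01, pk.k10, k20, dose / pk.vd, times)
    traj.dose = dose
    return traj


def hill(x, x50: float, gamma: float):
    """Saturable fraction x^g / (x50^g + x^g), 0 at x = 0."""
    x = np.asarray(x, float)
    with np.errstate(divide="ignore"):
        r = np.where(x > 0, (np.minimum(x, 1e300) / x50) ** gamma, 0.0)
    return r / (1.0 + r)


def emax_effect(link: EmaxLink, driver: np.ndarray) -> np.ndarray:
    """Hill effect of a non-negative driver series (concentration)."""
    driver = np.asarray(driver, float)
    if np.any(driver < 0):
        raise ValidationError("driver concentrations must be >= 0")
    return link.epsilon + (link.emax - link.epsilon) * hill(driver, link.ec50, link.gamma)


def activation_effect(act: ActivationParameters, dose: float, times: np.ndarray,
                      form: str | None = None) -> np.ndarray:
    """Effect of the dose-triggered cascade at one dose over a time grid.

    ``global`` form: seed E00(D) = hill(D), equal rates k2, effect
    epsilon + efficacy*E2(t). ``independent`` form: seed includes baseline and
    maximal activation, rates (k01, k10, k20), effect efficacy*E2(t) — note
    the independent form therefore starts at 0 at t = 0 rather than at the
    baseline (the additive-baseline variant is the global form).
    """
    if dose < 0:
        raise ValidationError("dose must be >= 0")
    times = _check_times(times)
    form = form or act.form
    if form == "global":
        if act.k2 is None:
            raise ValidationError("global-form activation requires k2")
        e00 = float(hill(dose, act.ed50, act.gamma))
        e2 = e00 * act.k2 * cascade_stage3(act.k2, act.k2, act.k2, times)
        return act.epsilon + act.efficacy * e2
    if form == "independent":
        if None in (act.k01, act.k10, act.k20):
            raise ValidationError("independent-form activation requires k01, k10, k20")
        e00 = act.epsilon + (act.emax - act.epsilon) * float(hill(dose, act.ed50, act.gamma))
        e2 = e00 * act.k01 * cascade_stage3(act.k01, act.k10, act.k20, times)
        return act.efficacy * e2
    raise ValidationError(f"unknown activation form {form!r}")


def activation_states(act: ActivationParameters, dose: float,
                      times: np.ndarray) -> Trajectory:
    """Full cascade states for the global-form activation model."""
    times = _check_times(times)
    e00 = float(hill(dose, act.ed50, act.gamma))
    k2 = act.k2
    traj = solve_linear_cascade(k2, k2, k2, e00, times)
    traj.states = {"E0i": traj.states["C0"], "E1i": traj.states["C1"],
                   "E2i": traj.states["C2"]}
    traj.effects = {"invasion": act.epsilon + act.efficacy * traj.states["E2i"]}
    traj.dose = dose
    return traj


def simulate_independent(family: str, params, dose: float,
                         times: np.ndarray) -> np.ndarray:
    """Single-readout effect series under one of the two model families.

    ``pk_based`` expects ``params`` = (PKParameters, EmaxLink, k20);
    ``activation_based`` expects an :class:`ActivationParameters`.
    """
    if family == "pk_based":
        try:
            pk, link, k20 = params
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                "pk_based expects params = (PKParameters, EmaxLink, k20)") from exc
        traj = pk_concentrations(pk, k20, dose, times)
        return emax_effect(link, traj.states["C2"])
    if family == "activation_based":
        if not isinstance(params, ActivationParameters):
            raise ValidationError("activation_based expects ActivationParameters")
        return activation_effect(params, dose, times)
    raise ValidationError(f"unknown model family {family!r}")


def simulate_global(gp: GlobalParameters, dose: float, times: np.ndarray) -> Trajectory:
    """All compartments and the three readout effects of the global model.

    Migration and CEP effects share the central concentration C1 but have
    their own tissue compartments; invasion follows the dose-triggered
    equal-rate cascade.
    """
    if dose < 0:
        raise ValidationError("dose must be >= 0")
    times = _check_times(times)
    pk = gp.pk
    A = dose / pk.vd
    c0 = A * np.exp(-pk.k01 * times)
    c1 = A * pk.k01 * cascade_stage2(pk.k01, pk.k10, times)
    c2m = A * pk.k01 * cascade_stage3(pk.k01, pk.k10, gp.k20_m, times)
    c2c = A * pk.k01 * cascade_stage3(pk.k01, pk.k10, gp.k20_c, times)
    inv = activation_states(gp.invasion, dose, times)
    states = {"C0": c0, "C1": c1, "C2m": c2m, "C2c": c2c, **inv.states}
    effects = {
        "migration": emax_effect(gp.migration_link, c2m),
        "cep": emax_effect(gp.cep_link, c2c),
        "invasion": inv.effects["invasion"],
    }
    return Trajectory(times, states=states, effects=effects, dose=dose)


#: Default rendering grid: 0-200 h at 1 h resolution.
def default_time_grid(t_max: float = 200.0, step: float = 1.0) -> np.ndarray:
    return np.arange(0.0, t_max + 0.5 * step, step)
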