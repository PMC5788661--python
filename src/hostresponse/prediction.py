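"""Dose x duration effect surfaces, threshold diagnostics and point predictions.

The two model families leave distinct fingerprints on the dose-duration
plane. For the activation-based readout, effect-minus-baseline factorizes
into (dose factor) x (time profile), so the dose threshold at which the
effect turns on is the same at every time — a duration-independent
threshold. PK-driven Hill readouts do not factorize (for any Hill exponent
once the link is nonlinear over the traversed concentrations): their onset
threshold drifts with time and the duration of the effect grows with dose.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .dynamics import simulate_global
from .types import GlobalParameters, ValidationError


@dataclass
class EffectSurface:
    """Per-readout effect intensity on a dose grid x time grid."""

    dose_grid: np.ndarray
    time_grid: np.ndarray
    values: dict[str, np.ndarray]  # readout -> (n_dose, n_time)
    params_used: GlobalParameters

    def __post_init__(self) -> None:
        shape = (len(self.dose_grid), len(self.time_grid))
        for r, m in self.values.items():
            if m.shape != shape:
                raise ValidationError(f"surface for {r!r} has shape {m.shape}, "
                                      f"expected {shape}")
            if not np.all(np.isfinite(m)):
                raise ValidationError(f"surface for {r!r} contains non-finite values")

    def to_dataframe(self):
        import pandas as pd
        frames = []
        for r, m in self.values.items():
            d, t = np.meshgrid(self.dose_grid, self.time_grid, indexing="ij")
            frames.append(pd.DataFrame({"readout": r, "dose": d.ravel(),
                                        "time": t.ravel(), "value": m.ravel()}))
        return pd.concat(frames, ignore_index=True)


def effect_surface(params: GlobalParameters,
                   dose_range: tuple[float, float] = (0.0, 25.0),
                   time_range: tuple[float, float] = (0.0, 200.0),
                   n_doses: int = 26, n_times: int = 201) -> EffectSurface:
    """Evaluate the global model on a regular dose x time grid.

    Defaults cover 0-25 mg/kg at 1 mg/kg and 0-200 h at 1 h resolution.
    """
    if dose_range[0] < 0:
        raise ValidationError("doses must be >= 0")
    if n_doses < 2 or n_times < 2:
        raise ValidationError("need at least 2 grid points per axis")
    if dose_range[1] <= dose_range[0] or time_range[1] <= time_range[0]:
        raise ValidationError("grid ranges must be non-degenerate")
    doses = np.linspace(*dose_range, n_doses)
    times = np.linspace(*time_range, n_times)
    values = {r: np.empty((n_doses, n_times)) for r in
              ("cep", "migration", "invasion")}
    for i, d in enumerate(doses):
        traj = simulate_global(params, float(d), times)
        for r in values:
            values[r][i] = traj.effects[r]
    return EffectSurface(doses, times, values, params)


def threshold_profile(surface: EffectSurface, level: float = 0.5,
                      readout: str | None = None,
                      noise_floor: float = 0.01):
    """Per-time onset dose threshold: at each time, the smallest grid dose
    whose effect exceeds baseline + level * (that time's maximum - baseline).

    Time slices whose dynamic range is below ``noise_floor`` times the
    surface-wide range are below the noise floor and yield NaN. Returns one
    curve per readout (dict) or a single array when ``readout`` is given.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError("level must be in (0, 1)")
    baselines = surface.params_used.baselines
    out = {}
    for r, m in surface.values.items():
        eps = baselines[r]
        span_global = float(np.max(m) - eps)
        slice_max = m.max(axis=0)
        span_t = slice_max - eps
        curve = np.full(len(surface.time_grid), np.nan)
        ok = span_t > noise_floor * max(span_global, 0.0)
        if span_global > 0:
            exceeds = m >= eps + level * span_t[None, :]
            has = exceeds.any(axis=0)
            first = exceeds.argmax(axis=0)
            sel = ok & has
            curve[sel] = surface.dose_grid[first[sel]]
        out[r] = curve
    if readout is not None:
        return out[readout]
    return out


def duration_above(params: GlobalParameters, readout: str, doses,
                   level: float = 0.5, t_max: float = 200.0,
                   dt: float = 0.25) -> np.ndarray:
    """Hours spent above baseline + level * (that dose's own peak - baseline).

    For a separable (activation) readout this duration is dose-independent;
    for a PK-driven Hill readout it grows with dose.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError("level must be in (0, 1)")
    times = np.arange(0.0, t_max + 0.5 * dt, dt)
    eps = params.baselines[readout]
    out = np.empty(len(list(doses)))
    for i, d in enumerate(doses):
        e = simulate_global(params, float(d), times).effects[readout]
        peak = float(e.max())
        if peak <= eps:
            out[i] = 0.0
            continue
        out[i] = dt * float(np.count_nonzero(e > eps + level * (peak - eps)))
    return out


def rebaseline(params: GlobalParameters,
               control_means: Mapping[str, float]) -> GlobalParameters:
    """Replace the baseline effects with per-readout control means.

    Mirrors the validation procedure for a new experiment: baselines are
    re-anchored to the new controls while every dynamic parameter stays
    untouched. For the additive invasion readout, effect-minus-baseline is
    invariant under this operation.
    """
    missing = {"cep", "migration", "invasion"} - set(control_means)
    if missing:
        raise ValidationError(f"control mean missing for readout(s): {sorted(missing)}")
    return dataclasses.replace(
        params,
        migration_link=dataclasses.replace(params.migration_link,
                                           epsilon=float(control_means["migration"])),
        cep_link=dataclasses.replace(params.cep_link,
                                     epsilon=float(control_means["cep"])),
        invasion=dataclasses.replace(params.invasion,
                                     epsilon=float(control_means["invasion"])),
    )


def predict_condition(params: GlobalParameters, dose: float,
                      time: float) -> dict[str, float]:
    """Model effects at a single (dose, time) condition, by exact simulation
    (no grid interpolation)."""
    if dose < 0 or time < 0:
        raise ValidationError("dose and time must be >= 0")
    times = np.array([time]) if time > 0 else np.array([0.0])
    traj = simulate_global(params, float(dose), times)
    return {r: float(v[0]) for r, v in traj.effects.items()}


def separability_diagnostic(surface: EffectSurface, readout: str,
                            cv_threshold: float = 0.01) -> dict:
    """Classify a readout surface as separable (duration-independent
    threshold) or not, from the coefficient of variation of its onset
    threshold curve. The two labels are mutually exclusive by construction.
    """
    curve = threshold_profile(surface, 0.5, readout=readout)
    vals = curve[np.isfinite(curve)]
    if len(vals) < 2:
        return {"readout": readout, "cv": float("nan"), "separable": None,
                "n_times": int(len(vals))}
    cv = float(np.std(vals) / np.mean(vals)) if np.mean(vals) > 0 else float("inf")
    return {"readout": readout, "cv": cv, "separable": bool(cv < cv_threshold),
            "n_times": int(len(vals))}
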