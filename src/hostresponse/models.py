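"""Fittable model wrappers: named free-parameter vectors over the simulators.

A model object exposes the contract the inference layer needs:

* ``free_names`` — ordered names of the estimated structural parameters,
* ``init_theta()`` — starting values taken from the base parameter set,
* ``predict_cells(theta, cells)`` — model means for arbitrary
  (dose, time) cells per readout, vectorized through the closed-form
  cascade solutions,
* ``with_theta(theta)`` — the full domain parameter object at ``theta``.

All free parameters here are positive by construction (rates, half-effect
constants, efficacies and assay baselines), which lets the optimizer search
in log space without constraints.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from . import dynamics
from .types import (ActivationParameters, EmaxLink, GlobalParameters,
                    PKParameters)

Cells = Mapping[str, tuple[np.ndarray, np.ndarray]]


class ConfigurationError(ValueError):
    """Model and data/parameters are inconsistent."""


def _theta_dict(names: Sequence[str], theta) -> dict[str, float]:
    theta = np.asarray(theta, float)
    if theta.shape != (len(names),):
        raise ConfigurationError(
            f"theta has length {theta.size}, expected {len(names)}")
    return dict(zip(names, theta))


class GlobalModel:
    """The pooled three-readout model, in one of the four tie variants.

    ``variant`` controls which of (EC50, k20) are shared between the
    migration and CEP sub-models: M1 shares both, M2 shares k20, M3 shares
    EC50, M4 shares neither. Baselines and Hill exponents are fixed at their
    base values by default (baselines are typically pinned to control-cell
    means; exponents to their configured values); ``fit_baselines`` /
    ``fit_gamma`` add them to the free vector.
    """

    readouts = ("cep", "migration", "invasion")

    def __init__(self, base: GlobalParameters, variant: str | None = None,
                 fit_baselines: bool = False, fit_gamma: bool = False) -> None:
        self.variant = variant or base.variant
        if self.variant not in ("M1", "M2", "M3", "M4"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        self.base = base
        self.fit_baselines = fit_baselines
        self.fit_gamma = fit_gamma
        names = ["emax_m", "emax_c"]
        names += ["ec50"] if self.variant in ("M1", "M3") else ["ec50_m", "ec50_c"]
        names += ["k20"] if self.variant in ("M1", "M2") else ["k20_m", "k20_c"]
        names += ["ed50", "k2", "e_i"]
        if fit_baselines:
            names += ["eps_m", "eps_c", "eps_i"]
        if fit_gamma:
            names += ["gamma"]
        self.free_names: tuple[str, ...] = tuple(names)
        self.label = f"global-{self.variant}"

    # -- parameter plumbing ------------------------------------------------
    def _base_values(self) -> dict[str, float]:
        b = self.base
        vals = {
            "emax_m": b.migration_link.emax, "emax_c": b.cep_link.emax,
            "ec50_m": b.migration_link.ec50, "ec50_c": b.cep_link.ec50,
            "ec50": b.migration_link.ec50,
            "k20_m": b.k20_m, "k20_c": b.k20_c, "k20": b.k20_m,
            "ed50": b.invasion.ed50, "k2": b.invasion.k2,
            "e_i": b.invasion.efficacy,
            "eps_m": b.migration_link.epsilon, "eps_c": b.cep_link.epsilon,
            "eps_i": b.invasion.epsilon, "gamma": b.migration_link.gamma,
        }
        return vals

    def init_theta(self) -> np.ndarray:
        vals = self._base_values()
        return np.array([vals[n] for n in self.free_names], float)

    def _resolved(self, theta) -> dict[str, float]:
        vals = self._base_values()
        vals.update(_theta_dict(self.free_names, theta))
        if self.variant in ("M1", "M3"):
            vals["ec50_m"] = vals["ec50_c"] = vals["ec50"]
        if self.variant in ("M1", "M2"):
            vals["k20_m"] = vals["k20_c"] = vals["k20"]
        if not self.fit_gamma:
            vals["gamma"] = self.base.migration_link.gamma
        return vals

    def with_theta(self, theta) -> GlobalParameters:
        v = self._resolved(theta)
        b = self.base
        gm = v["gamma"] if self.fit_gamma else b.migration_link.gamma
        gc = v["gamma"] if self.fit_gamma else b.cep_link.gamma
        gi = v["gamma"] if self.fit_gamma else b.invasion.gamma
        return GlobalParameters(
            pk=b.pk,
            migration_link=EmaxLink(v["eps_m"], v["emax_m"], v["ec50_m"], gm),
            k20_m=v["k20_m"],
            cep_link=EmaxLink(v["eps_c"], v["emax_c"], v["ec50_c"], gc),
            k20_c=v["k20_c"],
            invasion=dataclasses.replace(
                b.invasion, ed50=v["ed50"], k2=v["k2"],
                efficacy=v["e_i"], epsilon=v["eps_i"], gamma=gi),
            variant=self.variant,
        )

    def rebaselined(self, control_means: Mapping[str, float]) -> "GlobalModel":
        """A copy whose base baselines are set to per-readout control means."""
        from .prediction import rebaseline
        return GlobalModel(rebaseline(self.base, control_means), self.variant,
                           self.fit_baselines, self.fit_gamma)

    # -- prediction ---------------------------------------------------------
    def predict_cells(self, theta, cells: Cells) -> dict[str, np.ndarray]:
        v = self._resolved(theta)
        pk = self.base.pk
        gm = v["gamma"] if self.fit_gamma else self.base.migration_link.gamma
        gc = v["gamma"] if self.fit_gamma else self.base.cep_link.gamma
        gi = v["gamma"] if self.fit_gamma else self.base.invasion.gamma
        out: dict[str, np.ndarray] = {}
        for readout, (dose, time) in cells.items():
            dose = np.asarray(dose, float)
            time = np.asarray(time, float)
            if readout == "migration":
                c2 = (dose / pk.vd) * pk.k01 * dynamics.cascade_stage3(
                    pk.k01, pk.k10, v["k20_m"], time)
                out[readout] = v["eps_m"] + (v["emax_m"] - v["eps_m"]) * dynamics.hill(
                    c2, v["ec50_m"], gm)
            elif readout == "cep":
                c2 = (dose / pk.vd) * pk.k01 * dynamics.cascade_stage3(
                    pk.k01, pk.k10, v["k20_c"], time)
                out[readout] = v["eps_c"] + (v["emax_c"] - v["eps_c"]) * dynamics.hill(
                    c2, v["ec50_c"], gc)
            elif readout == "invasion":
                e00 = dynamics.hill(dose, v["ed50"], gi)
                e2 = e00 * v["k2"] * dynamics.cascade_stage3(
                    v["k2"], v["k2"], v["k2"], time)
                out[readout] = v["eps_i"] + v["e_i"] * e2
            else:
                raise ConfigurationError(f"readout {readout!r} not part of this model")
        return out


class PKEffectModel:
    """Single-readout PK-based model: tissue concentration -> Hill effect.

    The plasma kinetics (vd, k01, k10) are fixed inputs; the free structural
    parameters default to (epsilon, emax, ec50, k20) with the Hill exponent
    held at its base value.
    """

    def __init__(self, readout: str, pk: PKParameters, link: EmaxLink,
                 k20: float, fit_gamma: bool = False) -> None:
        self.readout = readout
        self.readouts = (readout,)
        self.pk = pk
        self.link = link
        self.k20 = k20
        self.fit_gamma = fit_gamma
        self.free_names = ("epsilon", "emax", "ec50", "k20") + (
            ("gamma",) if fit_gamma else ())
        self.label = f"pk-{readout}"

    def init_theta(self) -> np.ndarray:
        vals = [self.link.epsilon, self.link.emax, self.link.ec50, self.k20]
        if self.fit_gamma:
            vals.append(self.link.gamma)
        return np.array(vals, float)

    def with_theta(self, theta):
        v = _theta_dict(self.free_names, theta)
        g = v.get("gamma", self.link.gamma)
        return (self.pk, EmaxLink(v["epsilon"], v["emax"], v["ec50"], g), v["k20"])

    def predict_cells(self, theta, cells: Cells) -> dict[str, np.ndarray]:
        v = _theta_dict(self.free_names, theta)
        g = v.get("gamma", self.link.gamma)
        if set(cells) - {self.readout}:
            raise ConfigurationError(
                f"model for {self.readout!r} cannot predict {set(cells) - {self.readout}}")
        dose, time = cells[self.readout]
        c2 = (np.asarray(dose, float) / self.pk.vd) * self.pk.k01 * \
            dynamics.cascade_stage3(self.pk.k01, self.pk.k10, v["k20"],
                                    np.asarray(time, float))
        return {self.readout: v["epsilon"] + (v["emax"] - v["epsilon"])
                * dynamics.hill(c2, v["ec50"], g)}


class ActivationEffectModel:
    """Single-readout activation-based model (dose-triggered cascade).

    Uses the additive-baseline equal-rate form: effect =
    epsilon + efficacy * E2(t) with E00(D) = hill(D; ed50, gamma) and shared
    cascade rate k2. Free parameters default to
    (epsilon, efficacy, ed50, k2).
    """

    def __init__(self, readout: str, base: ActivationParameters,
                 fit_gamma: bool = False) -> None:
        if base.form != "global":
            raise ConfigurationError("ActivationEffectModel requires the "
                                     "additive-baseline (global) form with k2 set")
        self.readout = readout
        self.readouts = (readout,)
        self.base = base
        self.fit_gamma = fit_gamma
        self.free_names = ("epsilon", "efficacy", "ed50", "k2") + (
            ("gamma",) if fit_gamma else ())
        self.label = f"activation-{readout}"

    def init_theta(self) -> np.ndarray:
        b = self.base
        vals = [b.epsilon, b.efficacy, b.ed50, b.k2]
        if self.fit_gamma:
            vals.append(b.gamma)
        return np.array(vals, float)

    def with_theta(self, theta) -> ActivationParameters:
        v = _theta_dict(self.free_names, theta)
        return dataclasses.replace(self.base, epsilon=v["epsilon"],
                                   efficacy=v["efficacy"], ed50=v["ed50"],
                                   k2=v["k2"],
                                   gamma=v.get("gamma", self.base.gamma))

    def predict_cells(self, theta, cells: Cells) -> dict[str, np.ndarray]:
        v = _theta_dict(self.free_names, theta)
        g = v.get("gamma", self.base.gamma)
        if set(cells) - {self.readout}:
            raise ConfigurationError(
                f"model for {self.readout!r} cannot predict {set(cells) - {self.readout}}")
        dose, time = cells[self.readout]
        e00 = dynamics.hill(np.asarray(dose, float), v["ed50"], g)
        e2 = e00 * v["k2"] * dynamics.cascade_stage3(
            v["k2"], v["k2"], v["k2"], np.asarray(time, float))
        return {self.readout: v["epsilon"] + v["efficacy"] * e2}
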