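"""Synthetic datasets with the statistical structure the analysis assumes.

The raw per-mouse measurements behind the study design exist only as figure
summaries, so this module generates stand-in data: model-mean trajectories
under a known ground truth plus i.i.d. Gaussian measurement noise, laid out
on the study's experimental design — a dose sweep {0, 5, 10, 25} mg/kg read
at 24 h and a time sweep {24, 48, 72, 96, 168} h at 25 mg/kg, for each of
the three readouts, plus a separate validation experiment at (25 mg/kg,
24 h) and (15 mg/kg, 72 h) with dose-0 controls.

The canonical ground truth (:func:`default_true_params`) is a model-3 (tied
EC50, distinct k20) parameter set chosen to reproduce the qualitative
findings: CEP levels back to baseline within 48 h, migration elevated
through 48 h and gone by 72 h, invasion peaking near 50 h and still elevated
at 96 h, and an invasion dose threshold of 7 mg/kg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import simulate_global
from .types import (ActivationParameters, Dataset, EmaxLink, GlobalParameters,
                    Measurement, PKParameters, ValidationError, READOUTS)

DOSE_SWEEP = (0.0, 5.0, 10.0, 25.0)      # mg/kg, read at t = 24 h
TIME_SWEEP = (24.0, 48.0, 72.0, 96.0, 168.0)  # h, at D = 25 mg/kg
SWEEP_TIME = 24.0
SWEEP_DOSE = 25.0

#: Default replicate count per design cell (the study reports group sizes of
#: this order for the in-vivo arms; per-cell counts are not tabulated).
DEFAULT_REPLICATES = 5

#: Default measurement noise as a fraction of each readout's simulated
#: dynamic range over the design.
DEFAULT_NOISE_FRAC = 0.05


@dataclass(frozen=True)
class Design:
    """A set of (readout, dose, time) cells with replicate counts."""

    cells: tuple[tuple[str, float, float, int], ...]
    label: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for readout, dose, time, n in self.cells:
            if n < 1:
                raise ValidationError("n_replicates must be >= 1")
            key = (readout, dose, time)
            if key in seen:
                raise ValidationError(f"duplicate design cell {key}")
            seen.add(key)

    @property
    def n_measurements(self) -> int:
        return sum(n for *_cell, n in self.cells)

    def conditions(self, readout: str) -> list[tuple[float, float]]:
        return [(d, t) for r, d, t, _n in self.cells if r == readout]


def paper_design(n_replicates: int = DEFAULT_REPLICATES) -> Design:
    """The study design: dose sweep at 24 h plus time sweep at 25 mg/kg.

    The shared (25 mg/kg, 24 h) cell appears once, giving 8 cells per
    readout (4 doses + 5 times - 1).
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    cells = []
    for r in READOUTS:
        for d in DOSE_SWEEP:
            cells.append((r, d, SWEEP_TIME, n_replicates))
        for t in TIME_SWEEP:
            if not (t == SWEEP_TIME):  # shared cell already present
                cells.append((r, SWEEP_DOSE, t, n_replicates))
    return Design(tuple(cells), label=f"dose+time sweeps, {n_replicates}/cell")


def validation_design(n_replicates: int = DEFAULT_REPLICATES) -> Design:
    """The validation experiment: control, (25 mg/kg, 24 h), (15 mg/kg, 72 h)."""
    cells = []
    for r in READOUTS:
        cells.append((r, 0.0, SWEEP_TIME, n_replicates))
        cells.append((r, 25.0, 24.0, n_replicates))
        cells.append((r, 15.0, 72.0, n_replicates))
    return Design(tuple(cells), label=f"validation, {n_replicates}/cell")


def default_true_params() -> GlobalParameters:
    """Canonical model-3 ground truth used throughout the simulation studies.

    PK constants are configurable placeholders on the scale of rapid i.p.
    paclitaxel kinetics in mice; effect parameters are set to reproduce the
    qualitative dose thresholds and effect durations of the three readouts
    (see module docstring). Hill exponents of 4 give the sharp onset between
    5 and 10 mg/kg; the invasion cascade rate 0.04/h puts the invasion peak
    at 2/k2 = 50 h.
    """
    pk = PKParameters(vd=6.0, k01=6.0, k10=0.6)
    ec50 = 0.27  # shared by migration and CEP links (model 3 tie)
    return GlobalParameters(
        pk=pk,
        migration_link=EmaxLink(epsilon=10.0, emax=45.0, ec50=ec50, gamma=4.0),
        k20_m=0.06,
        cep_link=EmaxLink(epsilon=55.0, emax=260.0, ec50=ec50, gamma=4.0),
        k20_c=0.12,
        invasion=ActivationParameters(ed50=7.0, gamma=4.0, efficacy=3.7,
                                      epsilon=8.0, k2=0.04),
        variant="M3",
    )


def model_means(params: GlobalParameters, design: Design) -> dict[tuple, float]:
    """Noise-free model mean per design cell, keyed by (readout, dose, time)."""
    out = {}
    by_readout: dict[str, list[tuple[float, float]]] = {}
    for r, d, t, _n in design.cells:
        by_readout.setdefault(r, []).append((d, t))
    for r, conds in by_readout.items():
        for d, t in conds:
            tgrid = np.array([t]) if t > 0 else np.array([0.0])
            out[(r, d, t)] = float(simulate_global(params, d, tgrid).effects[r][0])
    return out


def dynamic_range_sigma(params: GlobalParameters, design: Design,
                        frac: float = DEFAULT_NOISE_FRAC) -> dict[str, float]:
    """Per-readout noise SD = ``frac`` times the spread of the noise-free
    means over the design cells of that readout."""
    means = model_means(params, design)
    out = {}
    for r in READOUTS:
        vals = [v for (ro, _d, _t), v in means.items() if ro == r]
        if vals:
            out[r] = frac * (max(vals) - min(vals))
    return out


def _as_sigma_map(sigma, params, design) -> dict[str, float]:
    if sigma is None:
        return dynamic_range_sigma(params, design)
    if np.isscalar(sigma):
        if sigma < 0:
            raise ValidationError("sigma must be >= 0")
        return {r: float(sigma) for r in READOUTS}
    bad = [r for r, s in dict(sigma).items() if s < 0]
    if bad:
        raise ValidationError(f"sigma must be >= 0 (negative for {bad})")
    return {r: float(s) for r, s in dict(sigma).items()}


def generate(true_params: GlobalParameters, design: Design | None = None,
             sigma=None, seed: int = 0, truncate_negative: bool = False) -> Dataset:
    """Simulate a dataset: model means plus N(0, sigma^2) noise.

    ``sigma`` may be a scalar, a per-readout mapping, or None for the
    default 5%-of-dynamic-range noise. Negative simulated values are kept by
    default (the Gaussian error model permits them); ``truncate_negative``
    clips at 0 for realism demonstrations only. The ground truth travels in
    ``Dataset.metadata``.
    """
    design = design or paper_design()
    sigma_map = _as_sigma_map(sigma, true_params, design)
    means = model_means(true_params, design)
    rng = np.random.default_rng(seed)
    measurements = []
    for r, d, t, n in design.cells:
        mu = means[(r, d, t)]
        draws = mu + sigma_map[r] * rng.standard_normal(n)
        if truncate_negative:
            draws = np.maximum(draws, 0.0)
        for i, v in enumerate(draws, start=1):
            measurements.append(Measurement(r, d, t, float(v), i))
    meta = {
        "generator": "hostresponse.synthetic.generate",
        "seed": int(seed),
        "sigma": {r: float(s) for r, s in sigma_map.items()},
        "design": design.label,
        "truth": true_params.to_dict(),
    }
    return Dataset(measurements, metadata=meta)


def generate_validation(true_params: GlobalParameters, sigma=None,
                        seed: int = 0,
                        n_replicates: int = DEFAULT_REPLICATES) -> Dataset:
    """Simulate the validation experiment (controls + two new conditions).

    Noise defaults to 5% of the dynamic range over the *calibration* design,
    so the validation data carry the same error scale as the main dataset.
    """
    design = validation_design(n_replicates)
    if sigma is None:
        sigma = dynamic_range_sigma(true_params, paper_design(n_replicates))
    return generate(true_params, design, sigma=sigma, seed=seed)
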