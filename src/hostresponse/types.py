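"""Core domain types: measurements, experimental designs and model parameter sets.

Units are fixed package-wide: dose in mg/kg, time in hours post-administration.
Readout values are opaque assay units (cell counts per blood sample for CEP
levels, % membrane coverage for the migration and invasion assays); the models
are unit-agnostic up to the scaling absorbed by ``EC50`` / ``efficacy``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: The three host-response readouts, in canonical order.
READOUTS = ("cep", "migration", "invasion")

#: Global-model variants: ties between the migration and CEP sub-models.
#: M1 ties both the tissue elimination rate k20 and the half-effect
#: concentration EC50, M2 ties only k20, M3 ties only EC50, M4 ties neither.
VARIANTS = ("M1", "M2", "M3", "M4")


class ValidationError(ValueError):
    """A record or parameter set violates a domain invariant."""


class SchemaError(ValueError):
    """An input table does not have the expected columns."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class Measurement:
    """One replicate observation Y(t, D) of a host-response readout."""

    readout: str
    dose: float
    time: float
    value: float
    replicate: int = 1

    def __post_init__(self) -> None:
        _require(self.readout in READOUTS,
                 f"unknown readout {self.readout!r}; expected one of {READOUTS}")
        _require(self.dose >= 0, f"dose must be >= 0, got {self.dose}")
        _require(self.time >= 0, f"time must be >= 0, got {self.time}")
        _require(math.isfinite(self.value), f"value must be finite, got {self.value}")
        _require(self.replicate >= 1, f"replicate index must be >= 1, got {self.replicate}")


class Dataset:
    """A validated collection of replicate measurements with design metadata.

    Thin wrapper around a tidy DataFrame with columns
    ``readout, dose, time, value, replicate``. ``metadata`` carries free-form
    provenance (e.g. the generating ground truth for synthetic data).
    """

    COLUMNS = ("readout", "dose", "time", "value", "replicate")

    def __init__(self, measurements: Iterable[Measurement],
                 metadata: dict | None = None) -> None:
        rows = list(measurements)
        _require(len(rows) > 0, "dataset must contain at least one measurement")
        self.measurements = rows
        self.metadata = dict(metadata or {})
        self._df = pd.DataFrame(
            [(m.readout, m.dose, m.time, m.value, m.replicate) for m in rows],
            columns=list(self.COLUMNS),
        )

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, metadata: dict | None = None) -> "Dataset":
        """Build from a tidy table; replicate indices are auto-assigned in
        input order within each (readout, dose, time) cell when absent."""
        missing = [c for c in ("readout", "dose", "time", "value") if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.copy()
        if "replicate" not in df.columns or df["replicate"].isna().all():
            df["replicate"] = df.groupby(["readout", "dose", "time"]).cumcount() + 1
        ms = []
        for idx, row in df.iterrows():
            try:
                ms.append(Measurement(str(row["readout"]), float(row["dose"]),
                                      float(row["time"]), float(row["value"]),
                                      int(row["replicate"])))
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"row {idx}: {exc}") from exc
        return cls(ms, metadata)

    # -- views ------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def n_tot(self) -> int:
        """Total number of observations pooled into the likelihood."""
        return len(self.measurements)

    @property
    def design(self) -> pd.DataFrame:
        """The (readout, dose, time) cells with their replicate counts."""
        return (self._df.groupby(["readout", "dose", "time"], as_index=False)
                .size().rename(columns={"size": "n_replicates"}))

    @property
    def readouts(self) -> tuple[str, ...]:
        return tuple(r for r in READOUTS if r in set(self._df["readout"]))

    def arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-readout (dose, time, value) arrays in original row order."""
        out = {}
        for r in self.readouts:
            sub = self._df[self._df["readout"] == r]
            out[r] = (sub["dose"].to_numpy(float), sub["time"].to_numpy(float),
                      sub["value"].to_numpy(float))
        return out

    def row_order(self) -> dict[str, np.ndarray]:
        """Original row indices per readout (to restore dataset order)."""
        return {r: self._df.index[self._df["readout"] == r].to_numpy()
                for r in self.readouts}

    def control_means(self) -> dict[str, float]:
        """Mean of the dose-0 control cells per readout."""
        ctrl = self._df[self._df["dose"] == 0]
        out = {}
        for r in self.readouts:
            vals = ctrl.loc[ctrl["readout"] == r, "value"]
            if len(vals):
                out[r] = float(vals.mean())
        return out

    def subset(self, readouts: Iterable[str]) -> "Dataset":
        keep = set(readouts)
        ms = [m for m in self.measurements if m.readout in keep]
        return Dataset(ms, self.metadata)

    def __len__(self) -> int:
        return self.n_tot

    def __repr__(self) -> str:
        return (f"Dataset(n_tot={self.n_tot}, readouts={self.readouts}, "
                f"cells={len(self.design)})")


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PKParameters:
    """Two-compartment (plus absorption) paclitaxel kinetics.

    vd: volume of distribution of the central compartment; k01: absorption
    rate (1/h); k10: central elimination rate (1/h). These are taken as
    known inputs, not estimated from effect data.
    """

    vd: float
    k01: float
    k10: float

    def __post_init__(self) -> None:
        for name in ("vd", "k01", "k10"):
            _require(getattr(self, name) > 0, f"PK parameter {name} must be > 0")


@dataclass(frozen=True)
class EmaxLink:
    """Hill (Emax) concentration-effect link E = eps + (emax-eps)*C^g/(ec50^g+C^g)."""

    epsilon: float
    emax: float
    ec50: float
    gamma: float

    def __post_init__(self) -> None:
        _require(self.ec50 > 0, "ec50 must be > 0")
        _require(self.gamma > 0, "gamma must be > 0")
        _require(math.isfinite(self.emax) and math.isfinite(self.epsilon),
                 "emax and epsilon must be finite")


@dataclass(frozen=True)
class ActivationParameters:
    """Dose-triggered effect cascade parameters.

    Two forms are supported:

    * ``global`` form (used inside the global model): the cascade is seeded
      with the saturable dose fraction E00(D) = D^g/(ed50^g + D^g), all three
      cascade rates share the single value ``k2``, and the observed effect is
      ``epsilon + efficacy * E2(t)``.
    * ``independent`` form: the cascade is seeded with
      E00(D) = epsilon + (emax-epsilon)*D^g/(ed50^g+D^g), runs with rates
      ``k01, k10, k20``, and the observed effect is ``efficacy * E2(t)``.
    """

    ed50: float
    gamma: float
    efficacy: float = 1.0
    epsilon: float = 0.0
    emax: float = 1.0
    k2: float | None = None
    k01: float | None = None
    k10: float | None = None
    k20: float | None = None

    def __post_init__(self) -> None:
        _require(self.ed50 > 0, "ed50 must be > 0")
        _require(self.gamma > 0, "gamma must be > 0")
        for name in ("k2", "k01", "k10", "k20"):
            v = getattr(self, name)
            _require(v is None or v > 0, f"rate {name} must be > 0 when set")

    @property
    def form(self) -> str:
        return "global" if self.k2 is not None else "independent"


@dataclass(frozen=True)
class GlobalParameters:
    """Full parameterization of the global three-readout model.

    Migration and CEP levels are driven by the shared plasma concentration
    through readout-specific tissue compartments (elimination rates ``k20_m``,
    ``k20_c``) and Hill links; invasion follows a dose-triggered equal-rate
    cascade. ``variant`` records which ties hold between the two PK-driven
    sub-models (see :data:`VARIANTS`).
    """

    pk: PKParameters
    migration_link: EmaxLink
    k20_m: float
    cep_link: EmaxLink
    k20_c: float
    invasion: ActivationParameters
    variant: str = "M4"

    def __post_init__(self) -> None:
        _require(self.variant in VARIANTS, f"variant must be one of {VARIANTS}")
        _require(self.k20_m > 0 and self.k20_c > 0, "k20 rates must be > 0")
        _require(self.invasion.form == "global",
                 "the global model requires the global-form invasion cascade (k2 set)")
        if self.variant in ("M1", "M2"):
            _require(self.k20_m == self.k20_c,
                     f"variant {self.variant} requires k20_m == k20_c")
        if self.variant in ("M1", "M3"):
            _require(self.migration_link.ec50 == self.cep_link.ec50,
                     f"variant {self.variant} requires EC50_m == EC50_c")

    @property
    def baselines(self) -> dict[str, float]:
        return {"cep": self.cep_link.epsilon,
                "migration": self.migration_link.epsilon,
                "invasion": self.invasion.epsilon}

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "pk": dataclasses.asdict(self.pk),
            "migration": {**dataclasses.asdict(self.migration_link), "k20": self.k20_m},
            "cep": {**dataclasses.asdict(self.cep_link), "k20": self.k20_c},
            "invasion": {k: v for k, v in dataclasses.asdict(self.invasion).items()
                         if v is not None},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GlobalParameters":
        def link(sub: Mapping) -> tuple[EmaxLink, float]:
            sub = dict(sub)
            k20 = float(sub.pop("k20"))
            return EmaxLink(**{k: float(v) for k, v in sub.items()}), k20
        mig, k20_m = link(d["migration"])
        cep, k20_c = link(d["cep"])
        inv = ActivationParameters(**{k: float(v) for k, v in d["invasion"].items()})
        return cls(pk=PKParameters(**{k: float(v) for k, v in d["pk"].items()}),
                   migration_link=mig, k20_m=k20_m, cep_link=cep, k20_c=k20_c,
                   invasion=inv, variant=str(d.get("variant", "M4")))
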