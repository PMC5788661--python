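"""Readers and writers: measurement tables (CSV), parameter sets (YAML/JSON),
selection tables and fit results.

CSV files are RFC-4180, UTF-8, '.'-decimal. Numeric output keeps at least 10
significant digits unless a format override is given. Synthetic datasets may
carry their generating ground truth in a JSON metadata sidecar
(``<name>.meta.json``) so recovery experiments are self-contained.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import IO, Union

import pandas as pd
import yaml

from .types import Dataset, GlobalParameters, SchemaError

PathOrBuffer = Union[str, os.PathLike, IO]

#: default numeric format: shortest round-trippable representation of a double
_FLOAT_FMT = "%.17g"


def read_measurements(source: PathOrBuffer) -> Dataset:
    """Read a tidy measurement table (columns: readout, dose, time, value,
    optional replicate) into a validated :class:`Dataset`.

    If ``source`` is a path and a ``<name>.meta.json`` sidecar exists, it is
    loaded into ``Dataset.metadata``.
    """
    df = pd.read_csv(source, float_precision="round_trip")
    metadata = None
    if isinstance(source, (str, os.PathLike)):
        sidecar = Path(source).with_suffix(".meta.json")
        if sidecar.exists():
            metadata = json.loads(sidecar.read_text())
    return Dataset.from_dataframe(df, metadata)


def write_measurements(dataset: Dataset, sink: PathOrBuffer,
                       float_format: str = _FLOAT_FMT,
                       sidecar: bool = True) -> None:
    """Write a dataset as CSV; metadata goes to a JSON sidecar for paths."""
    dataset.to_dataframe().to_csv(sink, index=False, float_format=float_format)
    if sidecar and dataset.metadata and isinstance(sink, (str, os.PathLike)):
        Path(sink).with_suffix(".meta.json").write_text(
            json.dumps(dataset.metadata, indent=2, sort_keys=True))


def write_selection_table(table, sink: PathOrBuffer,
                          float_format: str = _FLOAT_FMT) -> None:
    """Write a model-selection table (one row per model, ranked by AIC)."""
    df = table.to_dataframe()
    if len(df) == 0:
        raise SchemaError("selection table is empty")
    df.to_csv(sink, index=False, float_format=float_format)


def read_selection_table(source: PathOrBuffer) -> pd.DataFrame:
    return pd.read_csv(source)


def write_parameters(params: GlobalParameters, sink: PathOrBuffer) -> None:
    """Serialize a global parameter set to YAML (or JSON by extension)."""
    d = params.to_dict()
    if isinstance(sink, (str, os.PathLike)):
        text = (json.dumps(d, indent=2) if str(sink).endswith(".json")
                else yaml.safe_dump(d, sort_keys=False))
        Path(sink).write_text(text)
    else:
        yaml.safe_dump(d, sink, sort_keys=False)


def read_parameters(source: PathOrBuffer) -> GlobalParameters:
    """Read a global parameter set from YAML or JSON."""
    if isinstance(source, (str, os.PathLike)):
        text = Path(source).read_text()
    else:
        text = source.read()
    d = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(d, dict):
        raise SchemaError("parameter file must contain a mapping")
    missing = {"pk", "migration", "cep", "invasion"} - set(d)
    if missing:
        raise SchemaError(f"parameter file missing section(s): {sorted(missing)}")
    return GlobalParameters.from_dict(d)


def write_fit_result(fit, sink: PathOrBuffer) -> None:
    """Serialize a :class:`~hostresponse.inference.FitResult` to JSON."""
    d = fit.to_dict()
    if isinstance(sink, (str, os.PathLike)):
        Path(sink).write_text(json.dumps(d, indent=2))
    else:
        json.dump(d, sink, indent=2)
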