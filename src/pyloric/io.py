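"""CSV/JSON readers and writers for the package's interchange formats.

Formats (all plain text):

* spike CSV — columns ``unit`` (PD/LP/PY) and ``time_s``
* temperature CSV — columns ``time_s`` and ``temp_c``
* clamp CSV — columns ``step_mv``, ``time_s``, ``current_na``
* per-cycle CSV — the table produced by :mod:`pyloric.bursts`
* JSON — summaries and ground truth
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bursts import UNITS, SpikeTrain
from .errors import DataError
from .synth import ClampStep
from .thermal import TemperatureTrace


def write_spikes(trains: dict[str, SpikeTrain], path) -> None:
    frames = [
        pd.DataFrame({"unit": unit, "time_s": trains[unit].times})
        for unit in UNITS
        if unit in trains
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spikes(path) -> dict[str, SpikeTrain]:
    df = pd.read_csv(path)
    if not {"unit", "time_s"}.issubset(df.columns):
        raise DataError("spike CSV must have columns: unit, time_s")
    out = {}
    for unit, grp in df.groupby("unit"):
        times = np.sort(grp["time_s"].to_numpy(dtype=float))
        out[str(unit)] = SpikeTrain(unit=str(unit), times=times)
    return out


def write_temperature(trace: TemperatureTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_temperature(path) -> TemperatureTrace:
    df = pd.read_csv(path)
    if not {"time_s", "temp_c"}.issubset(df.columns):
        raise DataError("temperature CSV must have columns: time_s, temp_c")
    return TemperatureTrace(
        times=df["time_s"].to_numpy(dtype=float),
        temps=df["temp_c"].to_numpy(dtype=float),
    )


def write_clamp(steps: list[ClampStep], path) -> None:
    frames = [
        pd.DataFrame(
            {"step_mv": s.step_voltage, "time_s": s.times, "current_na": s.current}
        )
        for s in steps
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_clamp(path) -> list[ClampStep]:
    df = pd.read_csv(path)
    if not {"step_mv", "time_s", "current_na"}.issubset(df.columns):
        raise DataError("clamp CSV must have columns: step_mv, time_s, current_na")
    steps = []
    for v, grp in df.groupby("step_mv", sort=True):
        grp = grp.sort_values("time_s")
        steps.append(
            ClampStep(
                step_voltage=float(v),
                times=grp["time_s"].to_numpy(dtype=float),
                current=grp["current_na"].to_numpy(dtype=float),
            )
        )
    return steps


def write_cycles(cycles: pd.DataFrame, path) -> None:
    cycles.to_csv(path, index=False)


def read_cycles(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path) -> None:
    payload = obj.to_dict() if hasattr(obj, "to_dict") else obj
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=_default))


def _default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
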