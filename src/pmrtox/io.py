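"""Tabular and image IO for the pipeline.

Interchange formats are plain delimited text with documented headers
(decimal-point numerics only), YAML/JSON for configuration, JSON for estimate
reports, and multi-page TIFF for image stacks.

Trace tables are tidy: one row per (well, time point) with columns
``plate, well, status, group, concentration, age_hpf, time_s, activity``
(plus ``sampling`` and ``frame_rate``).  Unknown columns are preserved on
round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .doseresponse import ConcResponseTable, TSKResults
from .protocol import PlateLayout, PMRProtocol
from .trace import ActivityTrace

__all__ = [
    "traces_to_frame",
    "frame_to_traces",
    "write_trace_table",
    "read_trace_table",
    "write_conc_response",
    "read_conc_response",
    "write_estimates",
    "read_layout",
    "read_protocol",
    "write_stack",
    "read_stack",
]

TRACE_COLUMNS = [
    "plate", "well", "status", "group", "concentration", "age_hpf",
    "sampling", "frame_rate", "time_s", "activity",
]


def traces_to_frame(traces: Iterable[ActivityTrace]) -> pd.DataFrame:
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame(dict(
            plate=tr.plate,
            well=tr.well_id,
            status=tr.status,
            group=tr.group,
            concentration=tr.concentration,
            age_hpf=tr.age_hpf,
            sampling=tr.sampling,
            frame_rate=tr.frame_rate,
            time_s=tr.time_s,
            activity=tr.activity,
        )))
    if not frames:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list[ActivityTrace]:
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace table missing columns {sorted(missing)}")
    traces = []
    for (plate, well), grp in df.groupby(["plate", "well"], sort=False):
        grp = grp.sort_values("time_s")
        traces.append(ActivityTrace(
            well_id=str(well),
            plate=str(plate),
            time_s=grp["time_s"].to_numpy(float),
            activity=grp["activity"].to_numpy(float),
            status=str(grp["status"].iloc[0]),
            group=str(grp["group"].iloc[0]),
            concentration=float(grp["concentration"].iloc[0]),
            age_hpf=float(grp["age_hpf"].iloc[0]),
            sampling=str(grp["sampling"].iloc[0]),
            frame_rate=float(grp["frame_rate"].iloc[0]),
        ))
    return traces


def write_trace_table(
    traces: Iterable[ActivityTrace] | pd.DataFrame, path: str | Path
) -> None:
    df = traces if isinstance(traces, pd.DataFrame) else traces_to_frame(traces)
    df.to_csv(path, index=False)


def read_trace_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[(df["activity"] < 0) | (df["activity"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: row {bad[0]}: activity outside [0, 1]")
    return df


def write_conc_response(table: ConcResponseTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_conc_response(path: str | Path) -> ConcResponseTable:
    df = pd.read_csv(path)
    missing = {"concentration", "n", "affected"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[(df["affected"] < 0) | (df["affected"] > df["n"])]
    if len(bad):
        raise ValueError(f"{path}: row {bad[0]}: affected outside [0, n]")
    return ConcResponseTable.from_dataframe(df)


def write_estimates(
    estimates: dict[str, TSKResults] | TSKResults, path: str | Path
) -> None:
    """JSON report of one or more fitted estimates."""
    if isinstance(estimates, TSKResults):
        estimates = {"estimate": estimates}
    payload = {k: v.to_dict() for k, v in estimates.items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_layout(path: str | Path) -> PlateLayout:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if "control_columns" in cfg:
        cfg["control_columns"] = frozenset(cfg["control_columns"])
    if "treatment_column_pairs" in cfg:
        cfg["treatment_column_pairs"] = tuple(
            tuple(p) for p in cfg["treatment_column_pairs"]
        )
    return PlateLayout(**cfg)


def read_protocol(path: str | Path) -> PMRProtocol:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("background", "excitatory", "refractory", "flash_times"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return PMRProtocol(**cfg)


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(stack))


def read_stack(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
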