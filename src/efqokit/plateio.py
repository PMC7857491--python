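"""Reading and writing plate-reader kinetic data, layouts and results.

Two delimited-text dialects are supported for kinetic data:

* long — header ``well,time_min,rfu``; one row per (well, read)
* wide — header ``time_min,<well>,<well>,…``; one row per read

Layouts use the header ``well,role,condition,enzyme,protein_mg,substrate,
substrate_conc_M,inhibitor,inhibitor_conc_M,pH,temp_C,replicate`` (extra
columns are preserved).  All files are UTF-8; comma and tab delimiters are
auto-detected and can be forced.  Floats are written at 6 significant
digits.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, TraceValidationError
from .types import (
    LAYOUT_COLUMNS,
    ActivityResult,
    KineticTrace,
    PlateDataset,
    PlateLayout,
    WellRole,
)

__all__ = [
    "read_kinetics",
    "write_kinetics",
    "read_layout",
    "write_layout",
    "assemble_dataset",
    "write_results",
    "results_to_frame",
    "read_results",
]

FLOAT_FMT = "%.6g"


def _detect_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_kinetics(path, dialect: str = "long", sep: str | None = None) -> list[KineticTrace]:
    """Read kinetic traces from a delimited text file.

    Returns traces sorted by well id; roles default to ``sample`` until a
    layout is joined (see :func:`assemble_dataset`).
    """
    path = Path(path)
    if dialect not in ("long", "wide"):
        raise ValueError("dialect must be 'long' or 'wide'")
    df = pd.read_csv(path, sep=_detect_sep(path, sep))
    if dialect == "long":
        for col in ("well", "time_min", "rfu"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column '{col}'")
        for col in ("time_min", "rfu"):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
                raise TraceValidationError(
                    f"{path}: non-numeric value in column '{col}' at row {row}"
                )
        df["time_min"] = pd.to_numeric(df["time_min"])
        df["rfu"] = pd.to_numeric(df["rfu"])
        traces = []
        for well, grp in df.groupby("well", sort=True):
            grp = grp.sort_values("time_min")
            if grp["time_min"].duplicated().any():
                raise TraceValidationError(f"{path}: duplicate time in well {well}")
            traces.append(
                KineticTrace(str(well), grp["time_min"].to_numpy(), grp["rfu"].to_numpy())
            )
        return traces
    # wide
    if "time_min" not in df.columns:
        raise FormatError(f"{path}: missing required column 'time_min'")
    wells = [c for c in df.columns if c != "time_min"]
    if not wells:
        raise FormatError(f"{path}: wide file has no well columns")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise TraceValidationError(
                f"{path}: non-numeric value in column '{col}' at row {row}"
            )
    t = pd.to_numeric(df["time_min"]).to_numpy()
    if not np.all(np.diff(t) > 0):
        raise TraceValidationError(f"{path}: times must be strictly increasing")
    return [
        KineticTrace(str(w), t, pd.to_numeric(df[w]).to_numpy())
        for w in sorted(wells)
    ]


def write_kinetics(traces: Iterable[KineticTrace], path, dialect: str = "long",
                   sep: str = ",") -> None:
    """Write kinetic traces in the long or wide dialect."""
    path = Path(path)
    traces = sorted(traces, key=lambda tr: tr.well_id)
    if dialect == "long":
        frames = [
            pd.DataFrame({"well": tr.well_id, "time_min": tr.times, "rfu": tr.intensities})
            for tr in traces
        ]
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["well", "time_min", "rfu"]
        )
    elif dialect == "wide":
        if not traces:
            df = pd.DataFrame(columns=["time_min"])
        else:
            t0 = traces[0].times
            for tr in traces[1:]:
                if len(tr.times) != len(t0) or not np.allclose(tr.times, t0):
                    raise TraceValidationError("wide dialect requires one shared time grid")
            df = pd.DataFrame({"time_min": t0})
            for tr in traces:
                df[tr.well_id] = tr.intensities
    else:
        raise ValueError("dialect must be 'long' or 'wide'")
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def read_layout(path, sep: str | None = None) -> PlateLayout:
    """Read a plate layout table (one record per well)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep))
    if "well" not in df.columns:
        raise FormatError(f"{path}: missing required column 'well'")
    return PlateLayout(df)


def write_layout(layout: PlateLayout, path, sep: str = ",") -> None:
    layout.table.reset_index().to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def assemble_dataset(traces: Sequence[KineticTrace], layout: PlateLayout,
                     metadata: dict | None = None) -> PlateDataset:
    """Join traces with a layout, assigning roles from the layout.

    Layout wells without a trace produce a warning (they may simply be
    unread); trace wells absent from the layout are an error.
    """
    annotated = []
    for tr in traces:
        if tr.well_id in layout.wells:
            role = layout.role_of(tr.well_id)
        else:
            role = tr.role
        annotated.append(KineticTrace(tr.well_id, tr.times, tr.intensities, role))
    unread = set(layout.wells) - {tr.well_id for tr in traces}
    if unread:
        warnings.warn(f"layout wells without kinetic data: {sorted(unread)}",
                      stacklevel=2)
    return PlateDataset(traces=annotated, layout=layout, metadata=metadata or {})


RESULT_COLUMNS = [
    "well", "condition", "activity_mol_per_min", "specific_activity_mol_per_min_per_mg",
    "integrated_activity_mol_min", "rate_slope_AU_per_min", "fit_t_start_min",
    "fit_t_end_min", "fit_r_squared", "below_detection",
]


def results_to_frame(results: Sequence[ActivityResult]) -> pd.DataFrame:
    rows = [
        {
            "well": r.well_id,
            "condition": r.condition,
            "activity_mol_per_min": r.activity,
            "specific_activity_mol_per_min_per_mg": r.specific_activity,
            "integrated_activity_mol_min": r.integrated_activity,
            "rate_slope_AU_per_min": r.rate_slope,
            "fit_t_start_min": r.fit_window[0],
            "fit_t_end_min": r.fit_window[1],
            "fit_r_squared": r.fit_r_squared,
            "below_detection": r.below_detection,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS).sort_values("well").reset_index(drop=True)


def write_results(results, path, sep: str = ",") -> None:
    """Write activity results (or any result DataFrame) as delimited text.

    Column names carry units; rows are ordered by well id; floats use 6
    significant digits.
    """
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        results = list(results)
        if not results:
            raise ValueError("results must be non-empty")
        df = results_to_frame(results)
    if df.empty:
        raise ValueError("results must be non-empty")
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def read_results(path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_detect_sep(path, sep))
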