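"""Shared I/O: trace tables (CSV) and two-channel TIFF movies."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .simkit import IntensityTrace

__all__ = [
    "read_movie",
    "write_movie",
    "read_traces",
    "write_traces",
    "traces_from_table",
    "traces_to_table",
]

TRACE_COLUMNS = ["trace_id", "t", "intensity"]


def read_movie(
    path: str | Path, deinterleave: str = "alternating"
) -> dict[int, np.ndarray]:
    """Read a multi-page TIFF into per-channel stacks.

    ``deinterleave="alternating"`` splits even pages into channel 0 (DNA,
    488 nm) and odd pages into channel 1 (protein, 647 nm), the acquisition
    order of alternating two-color imaging; the page count must then be
    even.  ``deinterleave="single"`` returns the whole stack as channel 0.
    """
    try:
        stack = tifffile.imread(str(path))
    except (OSError, ValueError, tifffile.TiffFileError) as err:
        raise IOError(f"cannot read TIFF movie {path}: {err}") from err
    stack = np.atleast_3d(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if deinterleave == "single":
        return {0: stack}
    if deinterleave == "alternating":
        if stack.shape[0] % 2:
            raise ValueError(
                f"alternating de-interleave requires an even page count, got {stack.shape[0]}"
            )
        return {0: stack[0::2], 1: stack[1::2]}
    raise ValueError(f"unknown de-interleave rule {deinterleave!r}")


def write_movie(path: str | Path, stack: np.ndarray) -> None:
    """Write one channel stack as a multi-page float32 TIFF."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def traces_to_table(traces: Sequence[IntensityTrace]) -> pd.DataFrame:
    """Long-format table (trace_id, t, intensity) of an ensemble."""
    frames = [
        pd.DataFrame({"trace_id": tr.trace_id, "t": tr.t, "intensity": tr.intensity})
        for tr in traces
    ]
    if not frames:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def traces_from_table(table: pd.DataFrame) -> list[IntensityTrace]:
    missing = [c for c in TRACE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trace table is missing columns {missing}")
    extra = [c for c in table.columns if c not in TRACE_COLUMNS]
    if extra:
        warnings.warn(f"trace table has extra columns {extra}; preserved but unused",
                      stacklevel=2)
    out = []
    for tid, grp in table.groupby("trace_id", sort=False):
        grp = grp.sort_values("t")
        out.append(IntensityTrace(
            t=grp["t"].to_numpy(float),
            intensity=grp["intensity"].to_numpy(float),
            trace_id=str(tid),
        ))
    return out


def write_traces(path: str | Path, traces: Sequence[IntensityTrace]) -> None:
    traces_to_table(traces).to_csv(path, index=False)


def read_traces(path: str | Path) -> list[IntensityTrace]:
    return traces_from_table(pd.read_csv(path))
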