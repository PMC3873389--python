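"""CSV readers and writers for activity series and sampled time courses.

Dialect: comma-separated, header row, UTF-8, '.' decimal separator,
times serialized as decimal hours at 9 significant digits (so a
write -> read round trip is exact on values).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    TIMECOURSE_COLUMNS,
    ActivitySeries,
    GeneTimecourse,
    HormoneTimecourse,
)
from .schedules import LightSchedule

__all__ = [
    "write_activity_csv",
    "read_activity_csv",
    "write_timecourse_csv",
    "read_timecourse_csv",
]

_FLOAT_FMT = "%.9g"


def write_activity_csv(series: ActivitySeries, path) -> None:
    """Write columns day, bin_index, clock_time_h, zt_h, counts."""
    series.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_activity_csv(
    path,
    schedule: LightSchedule,
    subject_id: str = "",
    genotype: str = "",
    modality: str = "locomotor",
) -> ActivitySeries:
    """Read an activity CSV written by :func:`write_activity_csv`.

    Bin width is inferred from consecutive clock times; schedule and
    labels are supplied by the caller (they are not serialized).
    """
    df = pd.read_csv(path)
    missing = [c for c in ("bin_index", "zt_h", "counts") if c not in df.columns]
    if missing:
        raise ValueError(f"activity CSV missing column(s): {missing}")
    if len(df) < 2:
        raise ValueError("activity CSV needs >= 2 bins")
    df = df.sort_values("bin_index")
    zt = df["zt_h"].to_numpy(dtype=float)
    step_h = float((zt[1] - zt[0]) % schedule.cycle_length_h)
    bin_width_min = int(round(step_h * 60))
    counts = df["counts"].to_numpy()
    if not np.all(counts == np.round(counts)):
        raise ValueError("counts must be integers")
    return ActivitySeries(
        subject_id=subject_id,
        genotype=genotype,
        modality=modality,
        bin_width_min=bin_width_min,
        counts=counts.astype(int),
        schedule=schedule,
    )


def write_timecourse_csv(
    tc: GeneTimecourse | HormoneTimecourse, path, double_plot: bool = False
) -> None:
    """Write columns subject_id, zt_h, value, replicate, below_detection.

    ``double_plot=True`` additionally duplicates ZT0 rows at ZT24, the
    plotting convention for daily profiles; such files are for display
    only and are rejected by the reader (ZT must lie in [0, 24)).
    """
    df = tc.data[TIMECOURSE_COLUMNS].copy()
    if double_plot:
        z0 = df[df["zt_h"] == 0.0].copy()
        z0["zt_h"] = 24.0
        df = pd.concat([df, z0], ignore_index=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_timecourse_frame(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = [c for c in ("subject_id", "zt_h", "value") if c not in df.columns]
    if missing:
        raise ValueError(f"timecourse CSV missing column(s): {missing}")
    return df


def read_timecourse_csv(
    path,
    kind: str = "gene",
    gene: str = "",
    tissue: str = "",
    genotype: str = "",
    hormone: str = "corticosterone",
) -> GeneTimecourse | HormoneTimecourse:
    """Read a timecourse CSV as a gene or hormone container.

    An empty file with a valid header yields an empty timecourse; a
    missing column or a ZT value outside [0, 24) is an error.
    """
    df = _read_timecourse_frame(path)
    if kind == "gene":
        return GeneTimecourse(gene=gene, tissue=tissue, genotype=genotype, data=df)
    if kind == "hormone":
        return HormoneTimecourse(hormone=hormone, genotype=genotype, data=df)
    raise ValueError(f"unknown timecourse kind: {kind!r}")
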