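"""In-memory containers for activity series and sampled time courses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedules import LightSchedule

__all__ = ["ActivitySeries", "GeneTimecourse", "HormoneTimecourse"]

#: Columns of the tidy timecourse representation.
TIMECOURSE_COLUMNS = ["subject_id", "zt_h", "value", "replicate", "below_detection"]


@dataclass
class ActivitySeries:
    """Binned activity counts for one animal.

    ``counts[i]`` covers the half-open interval
    ``[start + i*bin, start + (i+1)*bin)`` hours from recording start,
    which is anchored at lights-on (ZT0) of day 0.
    """

    subject_id: str
    genotype: str
    modality: str  # "wheel" or "locomotor"
    bin_width_min: int
    counts: np.ndarray
    schedule: LightSchedule
    start_clock_time_h: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if 60 % self.bin_width_min != 0:
            raise ValueError("bin width must divide 60 minutes")
        if self.modality not in ("wheel", "locomotor"):
            raise ValueError(f"unknown modality: {self.modality!r}")
        if self.start_clock_time_h is None:
            self.start_clock_time_h = self.schedule.lights_on_clock_h

    @property
    def bins_per_day(self) -> int:
        return int(round(self.schedule.cycle_length_h * 60 / self.bin_width_min))

    @property
    def n_days(self) -> float:
        return len(self.counts) / self.bins_per_day

    def bin_start_h(self, i) -> np.ndarray:
        """Hours from recording start of the left edge of bin(s) ``i``."""
        return np.asarray(i) * self.bin_width_min / 60.0

    def zt_of_bin(self, i) -> np.ndarray:
        """ZT (hours) of the left edge of bin(s) ``i``."""
        return self.bin_start_h(i) % self.schedule.cycle_length_h

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: day, bin_index, clock_time_h, zt_h, counts."""
        idx = np.arange(len(self.counts))
        t = self.bin_start_h(idx)
        return pd.DataFrame(
            {
                "day": (t // self.schedule.cycle_length_h).astype(int),
                "bin_index": idx,
                "clock_time_h": (self.start_clock_time_h + t) % 24.0,
                "zt_h": self.zt_of_bin(idx),
                "counts": self.counts,
            }
        )


def _validate_timecourse_frame(data: pd.DataFrame) -> pd.DataFrame:
    data = data.copy()
    missing = [c for c in ("subject_id", "zt_h", "value") if c not in data.columns]
    if missing:
        raise ValueError(f"timecourse missing required column(s): {missing}")
    if "replicate" not in data.columns:
        data["replicate"] = 0
    if "below_detection" not in data.columns:
        data["below_detection"] = False
    if len(data):
        zt = pd.to_numeric(data["zt_h"], errors="raise")
        if ((zt < 0) | (zt >= 24)).any():
            raise ValueError("zt_h values must lie in [0, 24)")
        vals = pd.to_numeric(data["value"], errors="raise")
        if not np.isfinite(vals).all():
            raise ValueError("values must be finite")
    return data[TIMECOURSE_COLUMNS]


@dataclass
class GeneTimecourse:
    """Per-animal relative expression values over ZT sampling points."""

    gene: str
    tissue: str
    genotype: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = _validate_timecourse_frame(self.data)

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["zt_h"].unique())

    def group_means(self) -> pd.Series:
        """Mean value per ZT sampling point."""
        return self.data.groupby("zt_h")["value"].mean()

    def n_per_time(self) -> pd.Series:
        return self.data.groupby("zt_h")["subject_id"].nunique()


@dataclass
class HormoneTimecourse:
    """Per-animal hormone concentrations (replicated assay wells) over ZT."""

    hormone: str
    genotype: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = _validate_timecourse_frame(self.data)

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["zt_h"].unique())

    def collapse_replicates(self) -> pd.DataFrame:
        """Average assay duplicates: one row per subject x time."""
        return (
            self.data.groupby(["subject_id", "zt_h"], as_index=False)
            .agg(value=("value", "mean"), below_detection=("below_detection", "all"))
        )
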