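"""Light schedules and Zeitgeber Time arithmetic.

Zeitgeber Time (ZT) counts hours after lights-on: ZT0 = lights on,
ZT12 = dark onset under a 12 h light / 12 h dark (LD 12:12) cycle.
Constant darkness (DD) has no zeitgeber; ZT labels then refer to the
projected cycle of the preceding LD entrainment.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Regime(str, Enum):
    LD = "LD"
    DD = "DD"


@dataclass(frozen=True)
class LightSchedule:
    """An LD/DD lighting regime.

    Parameters
    ----------
    regime : Regime
        ``LD`` for a light-dark cycle (optionally switching to constant
        darkness at ``dd_start_day``), ``DD`` for constant darkness from
        the start of the recording.
    photoperiod_h : float
        Hours of light per cycle (12 for LD 12:12).
    cycle_length_h : float
        Length of the external cycle in hours (24).
    lights_on_clock_h : float
        Clock time of lights-on; defines ZT0.
    dd_start_day : int or None
        Day index (0-based) at which constant darkness begins.  ``None``
        means the LD cycle runs for the whole recording.  For a ``DD``
        regime this is implicitly day 0.
    """

    regime: Regime = Regime.LD
    photoperiod_h: float = 12.0
    cycle_length_h: float = 24.0
    lights_on_clock_h: float = 8.0
    dd_start_day: int | None = None

    def __post_init__(self) -> None:
        if self.regime not in (Regime.LD, Regime.DD):
            raise ValueError(f"unknown regime: {self.regime!r}")
        if not (0 < self.photoperiod_h < self.cycle_length_h):
            raise ValueError(
                "photoperiod must lie strictly between 0 and the cycle length"
            )
        if self.dd_start_day is not None and self.dd_start_day < 0:
            raise ValueError("dd_start_day must be non-negative")

    @property
    def dark_onset_zt(self) -> float:
        """ZT of dark onset (= photoperiod; ZT12 for LD 12:12)."""
        return self.photoperiod_h

    def dd_start_h(self) -> float | None:
        """Hours from recording start (ZT0 of day 0) to the DD transition."""
        if self.regime is Regime.DD:
            return 0.0
        if self.dd_start_day is None:
            return None
        return self.dd_start_day * self.cycle_length_h

    def is_dd_at(self, t_h: float) -> bool:
        """Whether time ``t_h`` (hours from recording start) is in DD."""
        start = self.dd_start_h()
        return start is not None and t_h >= start

    def is_light_at(self, t_h: float) -> bool:
        """Whether the lights are on at time ``t_h`` (hours from start)."""
        if self.is_dd_at(t_h):
            return False
        return (t_h % self.cycle_length_h) < self.photoperiod_h

    def zt_at(self, t_h: float) -> float:
        """ZT of time ``t_h`` hours after recording start (start = ZT0)."""
        return t_h % self.cycle_length_h


#: Standard LD 12:12 schedule (lights on at 08:00).
LD12_12 = LightSchedule(regime=Regime.LD)

#: Constant darkness from day 0.
DD = LightSchedule(regime=Regime.DD, dd_start_day=0)


def ld_then_dd(ld_days: int) -> LightSchedule:
    """LD 12:12 for ``ld_days`` days, then release into constant darkness."""
    if ld_days < 0:
        raise ValueError("ld_days must be non-negative")
    return LightSchedule(regime=Regime.LD, dd_start_day=ld_days)
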