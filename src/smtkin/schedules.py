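"""Illumination schedules for time-lapse and interlaced single-molecule imaging.

A schedule describes when the excitation laser is on.  Three modes are
supported:

``continuous``
    back-to-back frames, ``tau_tl == tau_on``.
``timelapse``
    one illuminated frame of length ``tau_on`` every ``tau_tl`` seconds;
    the dark time per cycle is ``tau_tl - tau_on``.  Varying ``tau_tl`` at
    fixed ``tau_on`` decouples photobleaching (proportional to illuminated
    time) from dissociation (proportional to wall-clock time).
``interlaced``
    bursts of ``frames_per_burst`` back-to-back frames followed by a long
    dark time ``dark_long`` (interlaced time-lapse microscopy, ITM).

All times are in seconds.  Frame index 0 starts at wall time 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IlluminationSchedule", "continuous", "timelapse", "interlaced"]


@dataclass(frozen=True)
class IlluminationSchedule:
    """Timing pattern of illuminated frames.

    Parameters
    ----------
    mode : {"continuous", "timelapse", "interlaced"}
    tau_on : float
        Illumination time per frame (s).
    tau_tl : float
        Cycle time, illumination plus dark (s).  For interlaced schedules
        this is the spacing of frames *within* a burst and equals
        ``tau_on`` (frames back-to-back).
    frames_per_burst : int
        Number of back-to-back frames per burst (interlaced only; 1
        otherwise).
    dark_long : float
        Long dark time between bursts (interlaced only).
    activation_time : float
        Duration of the photoactivation pulse preceding acquisition (s).
        Bookkeeping only; acquisition time 0 is the end of the pulse.
    """

    mode: str
    tau_on: float
    tau_tl: float
    frames_per_burst: int = 1
    dark_long: float = 0.0
    activation_time: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "timelapse", "interlaced"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.tau_on <= 0:
            raise ValueError("tau_on must be positive")
        if self.tau_tl < self.tau_on:
            raise ValueError("tau_tl must be >= tau_on")
        if self.mode == "continuous" and self.tau_tl != self.tau_on:
            raise ValueError("continuous mode requires tau_tl == tau_on")
        if self.mode == "interlaced":
            if self.frames_per_burst < 2:
                raise ValueError("interlaced mode requires frames_per_burst >= 2")
            if self.dark_long <= self.tau_on:
                raise ValueError("interlaced mode requires dark_long > tau_on")
            if self.tau_tl != self.tau_on:
                raise ValueError("interlaced frames are back-to-back (tau_tl == tau_on)")

    # ------------------------------------------------------------------
    # timing helpers
    # ------------------------------------------------------------------
    @property
    def cycle_time(self) -> float:
        """Wall-clock period of the repeating unit (s)."""
        if self.mode == "interlaced":
            return self.frames_per_burst * self.tau_on + self.dark_long
        return self.tau_tl

    @property
    def illuminated_per_cycle(self) -> float:
        """Illuminated seconds within one cycle."""
        if self.mode == "interlaced":
            return self.frames_per_burst * self.tau_on
        return self.tau_on

    def frame_start(self, index):
        """Wall-clock start time of acquisition ``index`` (0-based)."""
        index = np.asarray(index)
        if self.mode == "interlaced":
            burst, within = divmod(index, self.frames_per_burst)
            return burst * self.cycle_time + within * self.tau_on
        return index * self.tau_tl

    def burst_of(self, index):
        """Burst number of acquisition ``index`` (identity spacing if not ITM)."""
        index = np.asarray(index)
        if self.mode == "interlaced":
            return index // self.frames_per_burst
        return index

    def cumulative_illumination(self, t):
        """Illuminated seconds accumulated in wall interval ``[0, t)``.

        Vectorized; piecewise linear and non-decreasing in ``t``.
        """
        t = np.asarray(t, dtype=float)
        T = self.cycle_time
        on = self.illuminated_per_cycle
        ncyc = np.floor(t / T)
        rem = t - ncyc * T
        return ncyc * on + np.minimum(rem, on)

    def illuminated_between(self, t0, t1):
        """Illuminated seconds in wall interval ``[t0, t1)``."""
        return self.cumulative_illumination(t1) - self.cumulative_illumination(t0)

    def wall_time_at_illumination(self, g):
        """Wall time at which cumulative illumination first reaches ``g``.

        Inverse of :meth:`cumulative_illumination` (the right-continuous
        inverse: dark plateaus map to the start of the next frame).
        """
        g = np.asarray(g, dtype=float)
        T = self.cycle_time
        on = self.illuminated_per_cycle
        ncyc = np.floor(g / on)
        rem = g - ncyc * on
        # exact multiples of a full cycle's illumination belong to the
        # previous cycle's last illuminated instant
        exact = (rem == 0) & (g > 0)
        ncyc = np.where(exact, ncyc - 1, ncyc)
        rem = np.where(exact, on, rem)
        return ncyc * T + rem


def continuous(tau_on: float, **kw) -> IlluminationSchedule:
    return IlluminationSchedule("continuous", tau_on, tau_on, **kw)


def timelapse(tau_on: float, tau_tl: float, **kw) -> IlluminationSchedule:
    mode = "continuous" if tau_tl == tau_on else "timelapse"
    return IlluminationSchedule(mode, tau_on, tau_tl, **kw)


def interlaced(
    tau_on: float = 0.165,
    frames_per_burst: int = 2,
    dark_long: float = 0.75,
    **kw,
) -> IlluminationSchedule:
    """The ITM acquisition used throughout: two 165 ms frames (330 ms total
    illumination) followed by a 750 ms dark time."""
    return IlluminationSchedule(
        "interlaced", tau_on, tau_on, frames_per_burst=frames_per_burst,
        dark_long=dark_long, **kw,
    )
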