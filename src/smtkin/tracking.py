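"""Track linking and bound-molecule classification.

Localizations are linked between consecutive acquisitions by greedy
nearest-neighbour assignment under a spatial gate; a link across a
scheduled dark time is allowed under the same gate.  Two classification
criteria operate on the resulting tracks:

* time-lapse bound criterion — the molecule stays within an area of
  0.2 µm² for at least 100 ms;
* ITM classes — a molecule seen in at least two successive acquisitions
  is an "all binding" event, and one whose track survives at least one
  long dark time is a "long binding" event (long ⊆ all ⊆ detected).

Within a burst of illuminated frames a missed detection terminates the
visible on-time (no gap closing), so visible durations count consecutive
frames only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedules import IlluminationSchedule

__all__ = [
    "Track",
    "BindingEvent",
    "link_tracks",
    "classify_bound",
    "classify_itm",
    "ITM_GATE_UM",
    "BOUND_AREA_UM2",
    "BOUND_MIN_TIME_S",
]

log = logging.getLogger(__name__)

#: linking gate for interlaced acquisitions (one pixel)
ITM_GATE_UM = 0.166
#: confinement area of the time-lapse bound criterion
BOUND_AREA_UM2 = 0.2
#: minimum confined time of the time-lapse bound criterion
BOUND_MIN_TIME_S = 0.1


@dataclass
class Track:
    """An ordered sequence of localizations of one putative molecule."""

    frames: np.ndarray        # acquisition indices, strictly increasing
    x_um: np.ndarray
    y_um: np.ndarray
    schedule: IlluminationSchedule
    gaps: list = field(default_factory=list)   # indices where a dark time was crossed

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_consecutive(self) -> int:
        """Longest run of consecutive acquisitions starting at the first frame."""
        run = 1
        for a, b in zip(self.frames, self.frames[1:]):
            if b == a + 1:
                run += 1
            else:
                break
        return run


@dataclass
class BindingEvent:
    """Classification of one track."""

    track: Track
    start_s: float
    duration_s: float
    duration_frames: int
    confinement_area_um2: float
    label: str                 # "bound" | "unbound"
    itm_class: str = "none"    # "long_bound" | "all_bound" | "none"


def link_tracks(localizations, schedule, gate_radius_um):
    """Greedy nearest-neighbour linking of localizations into tracks.

    Localizations of consecutive acquisitions are linked when their
    distance is within ``gate_radius_um``; links across scheduled dark
    times use the same gate.  When several localizations compete for one
    track end the smallest displacement wins (ties broken by earlier
    localization index) and the loser starts a new track.

    Parameters
    ----------
    localizations : DataFrame with columns ``frame, x_um, y_um``
        Sorted by frame.
    """
    df = localizations
    if not df["frame"].is_monotonic_increasing:
        raise ValueError("localizations must be sorted by frame")
    tracks: list[dict] = []
    open_tracks: list[dict] = []   # tracks whose last frame is the previous acquisition
    prev_frame = None
    for frame, group in df.groupby("frame", sort=True):
        if prev_frame is not None and frame != prev_frame + 1:
            open_tracks = []       # a skipped acquisition closes everything
        xs = group["x_um"].to_numpy()
        ys = group["y_um"].to_numpy()
        order = np.arange(len(xs))
        assigned = {}
        if open_tracks:
            # candidate links: (distance, loc index, track index)
            cand = []
            for ti, tr in enumerate(open_tracks):
                d = np.hypot(xs - tr["x"][-1], ys - tr["y"][-1])
                for li in order:
                    if d[li] <= gate_radius_um:
                        cand.append((d[li], li, ti))
            cand.sort(key=lambda c: (c[0], c[1]))
            used_tracks = set()
            for d, li, ti in cand:
                if li in assigned or ti in used_tracks:
                    if li not in assigned and ti in used_tracks:
                        log.debug("localization %d lost tie for track %d", li, ti)
                    continue
                assigned[li] = ti
                used_tracks.add(ti)
        next_open = []
        for li in order:
            if li in assigned:
                tr = open_tracks[assigned[li]]
                if schedule.burst_of(frame) != schedule.burst_of(frame - 1):
                    tr["gaps"].append(len(tr["frames"]))
            else:
                tr = {"frames": [], "x": [], "y": [], "gaps": []}
                tracks.append(tr)
            tr["frames"].append(int(frame))
            tr["x"].append(float(xs[li]))
            tr["y"].append(float(ys[li]))
            next_open.append(tr)
        open_tracks = next_open
        prev_frame = frame
    return [
        Track(
            frames=np.array(t["frames"]), x_um=np.array(t["x"]),
            y_um=np.array(t["y"]), schedule=schedule, gaps=t["gaps"],
        )
        for t in tracks
    ]


def _bbox_area(x, y):
    return (x.max() - x.min()) * (y.max() - y.min())


def _pairwise_ok(x, y, max_area):
    # alternative confinement: max pairwise distance within the diameter
    # of a circle of the given area
    diam = 2.0 * np.sqrt(max_area / np.pi)
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    return np.hypot(dx, dy).max() <= diam


def classify_bound(
    track,
    max_area_um2=BOUND_AREA_UM2,
    min_time_s=BOUND_MIN_TIME_S,
    area_mode="bbox",
):
    """Apply the time-lapse bound criterion to a track.

    A molecule is bound if some sub-track of consecutive acquisitions
    lasting at least ``min_time_s`` stays within ``max_area_um2``; a
    sub-track needs at least two localizations (confinement cannot be
    assessed from a single position, so one-frame tracks are always
    unbound).  The
    area of a sub-track is the area of the axis-aligned bounding box of
    its positions (``area_mode="bbox"``); ``area_mode="pairwise"``
    instead requires the maximum pairwise distance to fit the diameter of
    a circle of that area.  The longest qualifying duration is reported.

    The dwell time of a sub-track of ``m`` consecutive frames is
    ``m * tau_tl`` (one frame of a 250 ms acquisition already spans the
    100 ms criterion).
    """
    if len(track) == 0:
        raise ValueError("empty track")
    tau = track.schedule.tau_tl
    frames, x, y = track.frames, track.x_um, track.y_um
    best = 0
    # consecutive runs only: a dark gap breaks the dwell
    run_start = 0
    for i in range(1, len(frames) + 1):
        if i == len(frames) or frames[i] != frames[i - 1] + 1:
            lo, hi = run_start, i
            for a in range(lo, hi):
                for b in range(hi, a + 1, -1):
                    m = b - a
                    if m < 2 or m * tau < max(best * tau, min_time_s) or m <= best:
                        break
                    xs, ys = x[a:b], y[a:b]
                    ok = (
                        _bbox_area(xs, ys) <= max_area_um2
                        if area_mode == "bbox"
                        else _pairwise_ok(xs, ys, max_area_um2)
                    )
                    if ok and m * tau >= min_time_s:
                        best = m
                        break
            run_start = i
    if best == 0:
        area = _bbox_area(x, y) if len(track) > 1 else 0.0
        return BindingEvent(
            track, frames[0] * tau, 0.0, 0, area, "unbound")
    return BindingEvent(
        track, frames[0] * tau, best * tau, best, max_area_um2, "bound")


def classify_itm(track, schedule=None):
    """Assign the ITM class of a track.

    ``long_bound`` if the track was linked across at least one long dark
    time (within the ITM gate, already enforced at linking); otherwise
    ``all_bound`` if it appears in at least two successive acquisitions;
    ``none`` otherwise.  Every track counts toward the detected
    denominator.
    """
    schedule = schedule or track.schedule
    if schedule.mode != "interlaced":
        raise ValueError("ITM classification requires an interlaced schedule")
    bursts = schedule.burst_of(track.frames)
    long_b = bool(bursts.max() > bursts.min()) if len(track) > 1 else False
    all_b = long_b or bool(np.any(np.diff(track.frames) == 1))
    itm = "long_bound" if long_b else ("all_bound" if all_b else "none")
    tau = schedule.tau_on
    duration_frames = len(track)
    return BindingEvent(
        track,
        start_s=float(schedule.frame_start(track.frames[0])),
        duration_s=float(
            schedule.frame_start(track.frames[-1]) - schedule.frame_start(track.frames[0]) + tau
        ),
        duration_frames=duration_frames,
        confinement_area_um2=_bbox_area(track.x_um, track.y_um) if len(track) > 1 else 0.0,
        label="bound" if itm != "none" else "unbound",
        itm_class=itm,
    )
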