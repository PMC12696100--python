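"""Merge consecutive-frame localizations of one blinking molecule.

A fluorophore that stays "on" across several camera frames yields one
localization per frame; these are chained when the next-frame localization
falls within ``factor`` (default 2.5) times the calibrated average
localization precision of the chain's running mean, and the chain is
collapsed to a single photon-weighted coordinate — one blinking event.
Localizations in the same frame never merge with each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

import numpy as np

from .localize import Localization, PrecisionCalibration

__all__ = ["BlinkEvent", "link_events"]


@dataclass
class BlinkEvent:
    """Consecutive-frame localizations merged to one molecular coordinate."""

    x_nm: float
    y_nm: float
    first_frame: int
    last_frame: int
    n_locs: int
    total_photons: float
    channel: str = "ch0"


class _Chain:
    __slots__ = ("locs", "wx", "wy", "w")

    def __init__(self, loc: Localization):
        self.locs = [loc]
        self.w = loc.photons
        self.wx = loc.photons * loc.x_nm
        self.wy = loc.photons * loc.y_nm

    @property
    def mean(self) -> tuple[float, float]:
        return self.wx / self.w, self.wy / self.w

    def add(self, loc: Localization) -> None:
        self.locs.append(loc)
        self.w += loc.photons
        self.wx += loc.photons * loc.x_nm
        self.wy += loc.photons * loc.y_nm

    def to_event(self) -> BlinkEvent:
        return BlinkEvent(
            x_nm=self.wx / self.w, y_nm=self.wy / self.w,
            first_frame=self.locs[0].frame, last_frame=self.locs[-1].frame,
            n_locs=len(self.locs), total_photons=self.w,
            channel=self.locs[0].channel)


def link_events(localizations: list[Localization],
                calibration: PrecisionCalibration | None,
                factor: float = 2.5,
                gate_on: str = "mean") -> list[BlinkEvent]:
    """Link localizations in consecutive frames into blinking events.

    The linking radius is ``factor * calibration.center_nm``.  A
    localization in frame f+1 within that radius of an active chain's
    photon-weighted mean (or its last position when ``gate_on="last"``)
    extends the chain; chains with no continuation terminate and emit one
    :class:`BlinkEvent`.  Ambiguous continuations go to the nearest chain;
    ties are broken by higher photon count, then input order.
    """
    if calibration is None:
        raise ValueError("missing precision calibration: run calibrate_precision "
                         "on the localizations first")
    if gate_on not in ("mean", "last"):
        raise ValueError("gate_on must be 'mean' or 'last'")
    if not localizations:
        return []
    radius = factor * calibration.center_nm
    r2 = radius * radius

    order = sorted(range(len(localizations)), key=lambda i: localizations[i].frame)
    events: list[BlinkEvent] = []
    active: list[_Chain] = []
    active_frame = None

    for frame, group in groupby(order, key=lambda i: localizations[i].frame):
        idxs = list(group)
        if active_frame is not None and frame != active_frame + 1:
            events.extend(ch.to_event() for ch in active)
            active = []
        # candidate links: (distance, -photons, input order, chain, loc index)
        candidates = []
        for ci, ch in enumerate(active):
            gx, gy = ch.mean if gate_on == "mean" else (ch.locs[-1].x_nm,
                                                        ch.locs[-1].y_nm)
            for li in idxs:
                loc = localizations[li]
                d2 = (loc.x_nm - gx) ** 2 + (loc.y_nm - gy) ** 2
                if d2 <= r2:
                    candidates.append((d2, -loc.photons, li, ci))
        candidates.sort()
        used_chains: set[int] = set()
        used_locs: set[int] = set()
        for d2, _, li, ci in candidates:
            if ci in used_chains or li in used_locs:
                continue
            active[ci].add(localizations[li])
            used_chains.add(ci)
            used_locs.add(li)
        # chains not extended terminate; unmatched localizations start chains
        surviving = [ch for ci, ch in enumerate(active) if ci in used_chains]
        events.extend(ch.to_event() for ci, ch in enumerate(active)
                      if ci not in used_chains)
        surviving.extend(_Chain(localizations[li]) for li in idxs
                         if li not in used_locs)
        active = surviving
        active_frame = frame

    events.extend(ch.to_event() for ch in active)
    events.sort(key=lambda e: (e.first_frame, e.x_nm, e.y_nm))
    return events
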