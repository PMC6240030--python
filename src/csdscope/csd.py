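"""CSD detection, frequency and propagation speed.

A cortical spreading depression appears in the DC-coupled trace as an
initial brief depolarizing deflection followed by a pronounced, slow
negative shift.  Detection runs on the CSD-conditioned trace
(0.005 Hz high-pass, 100 Hz low-pass): a robust spread estimate sets a
negative amplitude threshold; excursions sustained long enough and far
enough apart become events.  The onset of the depolarization wave is the
last downward crossing of a fixed fraction of the trough depth before the
trough, which is also how the simulator's ground-truth onsets are defined.

CSD frequency is the event count per hour on a reference ipsilateral
channel; propagation speed divides the 2 mm electrode separation by the
onset difference of the first CSD between S1 and M1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import QualityError, UndefinedSpeedError
from .recording import ELECTRODE_DISTANCE_MM
from .utils import background_spread, robust_spread


@dataclass(frozen=True)
class CsdDetectParams:
    """Detection thresholds.  CSD identification criteria in the
    literature are qualitative; these numeric defaults are the package's
    own and live in configuration."""

    amp_threshold: float = 8.0       # x robust spread of the DC trace
    amp_floor_mv: float = 2.0        # absolute minimum trough depth
    min_duration_s: float = 10.0     # time the shift must stay below threshold
    min_separation_s: float = 60.0   # merge window between excursions
    onset_fraction: float = 0.2      # fraction of trough depth defining onset
    smooth_s: float = 2.0            # moving-average window isolating the
                                     # slow DC shift from superimposed spikes

    def __post_init__(self) -> None:
        if not (0 < self.onset_fraction < 1):
            raise ValueError("onset_fraction must be in (0, 1)")
        for name in ("amp_threshold", "amp_floor_mv", "min_duration_s",
                     "min_separation_s", "smooth_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class CsdEvent:
    """One detected CSD on one channel (seconds, mV)."""

    channel: str
    onset_s: float
    trough_s: float
    amplitude_mv: float
    duration_s: float

    def __post_init__(self) -> None:
        if not self.onset_s < self.trough_s:
            raise ValueError("onset must precede trough")
        if self.amplitude_mv >= 0:
            raise ValueError("amplitude_mv is a trough depth and must be < 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    def to_dict(self) -> dict:
        return {"channel": self.channel, "onset_s": self.onset_s,
                "trough_s": self.trough_s, "amplitude_mv": self.amplitude_mv,
                "duration_s": self.duration_s}


@dataclass
class CsdSummary:
    """Headline per-subject CSD numbers."""

    frequency_per_hr: float
    propagation_speed_mm_per_min: float | None
    n_events: dict[str, int]


def detect_csds(trace_dc: np.ndarray, fs: float,
                params: CsdDetectParams = CsdDetectParams(),
                channel: str = "") -> list[CsdEvent]:
    """Detect CSD events in a DC-conditioned trace.

    Returns events sorted by onset.  Raises :class:`QualityError` when the
    baseline spread estimate is degenerate (flat input) or when the trace
    is dominated by an un-removed DC offset, both signs that the CSD
    filter chain was not applied.
    """
    import scipy.ndimage

    raw = np.asarray(trace_dc, dtype=float)
    # centered moving average: epileptic spikes (~0.1 s) superimposed on a
    # CSD must not fragment or fake the slow shift
    win = max(int(round(params.smooth_s * fs)), 1)
    x = scipy.ndimage.uniform_filter1d(raw, size=win, mode="nearest")
    # spread comes from event-free blocks of the unsmoothed trace (the
    # full-band background the threshold is a multiple of); thresholding
    # and timing then run on the smoothed trace, where superimposed
    # spikes are gone
    spread = background_spread(raw, fs)
    if spread <= 0 or not np.isfinite(spread):
        raise QualityError("flat trace: robust spread is zero")
    med = np.median(x[::10]) if x.size > 300_000 else np.median(x)
    if abs(med) > 10.0 * spread:
        raise QualityError("trace dominated by a DC offset; apply the "
                           "0.005 Hz high-pass chain before detection")
    threshold = -max(params.amp_threshold * spread, params.amp_floor_mv)

    below = x < threshold
    if not below.any():
        return []
    # contiguous sub-threshold runs
    d = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if below[0]:
        starts = np.r_[0, starts]
    if below[-1]:
        ends = np.r_[ends, x.size]

    # merge runs closer than min_separation_s, then enforce min duration
    min_sep = int(round(params.min_separation_s * fs))
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < min_sep:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])
    min_dur = int(round(params.min_duration_s * fs))
    regions = [(s, e) for s, e in merged if e - s >= min_dur]

    # a trough at the very edge of the trace is a truncated wave or a
    # filter boundary transient, not a measurable event
    guard = int(round(max(2 * params.smooth_s, 5.0) * fs))

    events: list[CsdEvent] = []
    for s, e in regions:
        i_tr = s + int(np.argmin(x[s:e]))
        if i_tr < guard or i_tr > x.size - guard:
            continue
        depth = float(x[i_tr])
        level = params.onset_fraction * depth  # negative
        # onset: last downward crossing of the level before the trough
        pre = x[:i_tr + 1]
        above = np.flatnonzero(pre > level)
        i_on = int(above[-1]) if above.size else 0
        # recovery: first return above the level after the trough
        post = np.flatnonzero(x[i_tr:] > level)
        i_off = i_tr + int(post[0]) if post.size else x.size - 1
        events.append(CsdEvent(
            channel=channel, onset_s=i_on / fs, trough_s=i_tr / fs,
            amplitude_mv=depth, duration_s=(i_off - i_on) / fs))
    events.sort(key=lambda ev: ev.onset_s)
    return events


def csd_frequency(events: list[CsdEvent], duration_s: float) -> float:
    """Events per hour: ``count * 3600 / duration_s``."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    return len(events) * 3600.0 / duration_s


def propagation_speed(events_m1: list[CsdEvent], events_s1: list[CsdEvent],
                      distance_mm: float = ELECTRODE_DISTANCE_MM) -> float:
    """Speed in mm/min from the first CSD's onset difference.

    ``distance / |onset(first S1) - onset(first M1)|`` with the 2 mm
    electrode separation as the default distance.
    """
    if distance_mm <= 0:
        raise ValueError("distance_mm must be > 0")
    if not events_m1 or not events_s1:
        raise UndefinedSpeedError("need at least one CSD on each ipsilateral "
                                  "channel to compute propagation speed")
    dt = abs(events_s1[0].onset_s - events_m1[0].onset_s)
    if dt <= 0:
        raise UndefinedSpeedError("onset difference below timing resolution")
    return distance_mm / (dt / 60.0)


def per_event_speeds(events_m1: list[CsdEvent], events_s1: list[CsdEvent],
                     distance_mm: float = ELECTRODE_DISTANCE_MM) -> list[float]:
    """Convenience speed for every paired event (headline uses the first)."""
    out = []
    for a, b in zip(events_m1, events_s1):
        dt = abs(b.onset_s - a.onset_s)
        if dt > 0:
            out.append(distance_mm / (dt / 60.0))
    return out


def assert_contralateral_silent(events_contra: list[CsdEvent]) -> bool:
    """True iff no CSD was detected on the contralateral channel."""
    return len(events_contra) == 0


def summarize_csd(events_by_channel: dict[str, list[CsdEvent]],
                  duration_s: float,
                  count_channel: str = "S1_left") -> CsdSummary:
    """Headline numbers from per-channel detections.

    Frequency counts events on *count_channel*; speed comes from the
    first M1/S1 event pair and is None when undefined.
    """
    try:
        speed = propagation_speed(events_by_channel.get("M1_left", []),
                                  events_by_channel.get("S1_left", []))
    except UndefinedSpeedError:
        speed = None
    return CsdSummary(
        frequency_per_hr=csd_frequency(events_by_channel.get(count_channel, []),
                                       duration_s),
        propagation_speed_mm_per_min=speed,
        n_events={ch: len(ev) for ch, ev in events_by_channel.items()})
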