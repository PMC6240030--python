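"""Epileptiform spike detection, bouts, onset, class and severity.

Spikes are detected on the epileptiform-conditioned trace (0.5 Hz
high-pass, 100 Hz low-pass) as suprathreshold absolute deflections, one
per refractory window, with a robust (clipped-MAD) spread setting the
threshold.  Spikes are grouped into bouts; a recording's terminal class is
*continuous* when the final assessment window is spanned by spiking with
no gap longer than ``continuous_max_gap_s``, *bouts* when spikes exist but
that fails, *none* otherwise.  Onset is simply the first spike time.

Severity is a dimensionless band-power ratio: mean 0.5-4 Hz spectral
power over the last 10 minutes divided by the same quantity over the
first 10 minutes, from Welch-averaged periodograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .exceptions import QualityError, UndefinedSeverityError
from .utils import background_spread

#: the low-frequency band in which epileptic spikes concentrate power (Hz)
SPIKE_BAND = (0.5, 4.0)


@dataclass(frozen=True)
class SpikeDetectParams:
    amp_threshold: float = 5.0      # x robust spread of the filtered trace
    refractory_s: float = 0.05
    biphasic_merge_s: float = 0.12  # afterwave within this window of a larger
                                    # opposite peak counts as the same spike
    bout_max_gap_s: float = 2.0
    bout_min_spikes: int = 3
    continuous_max_gap_s: float = 2.0
    class_window_s: float = 600.0   # terminal window assessed for the class

    def __post_init__(self) -> None:
        for name in ("amp_threshold", "refractory_s", "bout_max_gap_s",
                     "bout_min_spikes", "continuous_max_gap_s", "class_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.continuous_max_gap_s > self.bout_max_gap_s:
            raise ValueError("continuous_max_gap_s must be <= bout_max_gap_s")


@dataclass
class EpiAnnotation:
    """Per-channel epileptiform annotation."""

    channel: str
    spike_times_s: np.ndarray
    bouts: list[tuple[float, float]]
    onset_s: float | None
    activity_class: str
    severity: float | None = None
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"channel": self.channel,
                "spike_times_s": list(map(float, self.spike_times_s)),
                "bouts": [list(b) for b in self.bouts],
                "onset_s": self.onset_s,
                "activity_class": self.activity_class,
                "severity": self.severity,
                "flags": self.flags}


def detect_spikes(trace_hp: np.ndarray, fs: float,
                  params: SpikeDetectParams = SpikeDetectParams()) -> np.ndarray:
    """Times (s) of suprathreshold deflections, one per refractory window."""
    x = np.asarray(trace_hp, dtype=float)
    spread = background_spread(x, fs)
    if spread <= 0 or not np.isfinite(spread):
        raise QualityError("flat trace: robust spread is zero")
    thr = params.amp_threshold * spread
    dist = max(int(round(params.refractory_s * fs)), 1)
    peaks, _ = scipy.signal.find_peaks(np.abs(x), height=thr, distance=dist)
    # an interictal spike is multiphasic: count the sharp deflection and its
    # afterwave as one event, keeping the largest phase
    merge = int(round(params.biphasic_merge_s * fs))
    kept: list[int] = []
    for i in peaks:
        if kept and i - kept[-1] <= merge:
            if abs(x[i]) > abs(x[kept[-1]]):
                kept[-1] = i
        else:
            kept.append(i)
    return np.asarray(kept) / fs


def group_bouts(spike_times: np.ndarray,
                params: SpikeDetectParams = SpikeDetectParams()
                ) -> list[tuple[float, float]]:
    """Maximal runs of >= ``bout_min_spikes`` spikes with gaps <=
    ``bout_max_gap_s``; each bout spans first to last spike."""
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(t) > params.bout_max_gap_s)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, t.size - 1]
    return [(float(t[s]), float(t[e]))
            for s, e in zip(starts, ends)
            if e - s + 1 >= params.bout_min_spikes]


def epileptiform_onset(spike_times: np.ndarray) -> float | None:
    """First moment at which distinguishable spikes occur, or None."""
    t = np.asarray(spike_times, dtype=float)
    return float(t.min()) if t.size else None


def classify_activity(spike_times: np.ndarray, duration_s: float,
                      params: SpikeDetectParams = SpikeDetectParams()) -> str:
    """Terminal activity class: ``none`` / ``bouts`` / ``continuous``.

    Epileptiform activity means organized discharges: a recording with no
    bout at all (only isolated suprathreshold crossings, if anything) is
    classed *none*.  *continuous* requires the terminal ``class_window_s``
    to be spanned by spiking with every gap (including window edges) at
    most ``continuous_max_gap_s``.
    """
    t = np.asarray(spike_times, dtype=float)
    if not group_bouts(t, params):
        return "none"
    w0 = max(duration_s - params.class_window_s, 0.0)
    tw = t[(t >= w0) & (t <= duration_s)]
    if tw.size:
        gaps = np.diff(np.r_[w0, tw, duration_s])
        if gaps.max() <= params.continuous_max_gap_s:
            return "continuous"
    return "bouts"


def annotate_channel(trace_hp: np.ndarray, fs: float, channel: str = "",
                     params: SpikeDetectParams = SpikeDetectParams(),
                     compute_severity: bool = True) -> EpiAnnotation:
    """Full per-channel annotation: spikes, bouts, onset, class, severity."""
    duration_s = trace_hp.size / fs
    spikes = detect_spikes(trace_hp, fs, params)
    bouts = group_bouts(spikes, params)
    # the onset of "clearly distinguishable spikes" is the first bout:
    # a lone crossing that never organizes into a discharge train is noise
    ann = EpiAnnotation(
        channel=channel, spike_times_s=spikes, bouts=bouts,
        onset_s=bouts[0][0] if bouts else None,
        activity_class=classify_activity(spikes, duration_s, params))
    if compute_severity:
        try:
            ann.severity = severity(trace_hp, fs)
            if duration_s < 3600.0:
                ann.flags["short_recording"] = True
        except (UndefinedSeverityError, ValueError) as exc:
            ann.flags["severity_error"] = str(exc)
    return ann


# ------------------------------------------------------------- band power

_SEGMENT_S = 30.0  # Welch segment length


def power_spectrum(trace: np.ndarray, fs: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD (Hann taper, 30 s segments, 50% overlap), in mV^2/Hz."""
    nper = int(round(_SEGMENT_S * fs))
    if trace.size < nper:
        raise ValueError("trace shorter than one spectral segment (30 s)")
    f, p = scipy.signal.welch(trace, fs=fs, window="hann", nperseg=nper,
                              noverlap=nper // 2)
    return f, p


def band_power(trace: np.ndarray, fs: float, t_start: float, t_stop: float,
               band: tuple[float, float] = SPIKE_BAND) -> float:
    """Mean spectral power density over *band* in the window [t_start, t_stop]."""
    if not (0 < band[0] < band[1] < fs / 2):
        raise ValueError(f"band {band} outside (0, fs/2)")
    i0, i1 = int(round(t_start * fs)), int(round(t_stop * fs))
    seg = np.asarray(trace, dtype=float)[i0:i1]
    f, p = power_spectrum(seg, fs)
    sel = (f >= band[0]) & (f <= band[1])
    return float(p[sel].mean())


def severity(trace_hp: np.ndarray, fs: float,
             window_s: float = 600.0,
             band: tuple[float, float] = SPIKE_BAND) -> float:
    """Band-power ratio, last ``window_s`` over first ``window_s``.

    A value of 1 means no change in 0.5-4 Hz power over the recording;
    epileptiform escalation drives it above 1.
    """
    duration_s = trace_hp.size / fs
    if duration_s < 2 * window_s:
        raise ValueError(f"recording shorter than two {window_s:g}-s windows")
    first = band_power(trace_hp, fs, 0.0, window_s, band)
    last = band_power(trace_hp, fs, duration_s - window_s, duration_s, band)
    if first <= 0:
        raise UndefinedSeverityError("zero band power in the first window")
    return last / first


def is_generalized(annotations: dict[str, EpiAnnotation],
                   ipsi: str = "M1_left", contra: str = "M1_right",
                   tolerance_s: float = 60.0) -> bool:
    """Whether activity appears contralaterally near the ipsilateral onset."""
    a, b = annotations[ipsi], annotations[contra]
    if a.onset_s is None or b.onset_s is None:
        return False
    return abs(b.onset_s - a.onset_s) <= tolerance_s
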