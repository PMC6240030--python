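"""Synthetic awake-mouse DC-ECoG generator with known ground truth.

Emulates one-hour, three-channel (M1 left / S1 left / M1 right) recordings
during occipital KCl application:

* **CSD events** — large slow negative DC shifts (brief depolarizing
  deflection, deep trough, slow recovery with a mild after-depolarization)
  appearing only ipsilaterally, with the S1 electrode registering each
  wave ``d / v`` after M1 (electrode separation d = 2 mm, propagation
  speed v in mm/min).  KCl-driven CSDs recur near-rhythmically, so
  inter-event intervals follow a low-CV gamma renewal process.
* **Epileptiform spikes** — sharp low-frequency transients starting in
  bouts at a configurable onset, optionally escalating to continuous
  activity; generalized across hemispheres with small, fixed inter-channel
  lags plus per-channel timing jitter (M1 left leads).
* **Background** — independent 1/f^alpha noise per channel.

Every recording is paired with a :class:`GroundTruth` listing the true
event times, so detector recall/precision and timing error are measurable
without any real data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import warnings

import numpy as np

from .exceptions import CsdScopeError
from .recording import (ELECTRODE_DISTANCE_MM, GENOTYPES, GROUPS, ROLES,
                        Recording, SubjectMeta)

ESCALATIONS = ("none", "bouts", "continuous")


@dataclass
class SimParams:
    """All knobs of the generator.

    Units: seconds, Hz, mV, mm/min.  ``csd_amplitude_mv`` is the trough
    depth and therefore negative.  ``severity_growth`` multiplies the
    spike amplitude linearly from 1 at epileptiform onset to the given
    factor at the end of the recording.
    """

    duration_s: float = 3600.0
    fs: float = 300.0
    csd_rate_per_hr: float = 12.0
    csd_amplitude_mv: float = -10.0
    csd_duration_s: float = 60.0
    propagation_speed_mm_per_min: float = 5.0
    epi_onset_s: float | None = 900.0
    epi_escalation: str = "continuous"
    spike_rate_hz: float = 2.0
    spike_amplitude_mv: float = 2.2
    interhemispheric_lag_s: float = 0.030
    intrahemispheric_lag_s: float = 0.010
    spike_jitter_s: float = 0.005
    noise_scale_mv: float = 0.6
    noise_exponent: float = 1.0
    severity_growth: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.csd_rate_per_hr < 0:
            raise ValueError("csd_rate_per_hr must be >= 0")
        if self.csd_rate_per_hr > 0 and self.propagation_speed_mm_per_min <= 0:
            raise ValueError("propagation speed must be > 0 when CSDs occur")
        if self.epi_escalation not in ESCALATIONS:
            raise ValueError(f"epi_escalation must be one of {ESCALATIONS}")
        if self.interhemispheric_lag_s < 0 or self.intrahemispheric_lag_s < 0:
            raise ValueError("inter-channel lags must be >= 0")

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """True event times backing a simulated recording.

    ``csd_onsets`` are the times at which the noiseless DC template
    crosses 20% of its trough depth on the descending limb — the
    operational "onset of the wave of depolarization" that a
    fraction-of-trough detector estimates.  The S1-minus-M1 onset
    difference is exactly ``d / speed`` for every event.
    """

    csd_onsets: dict[str, np.ndarray]
    spike_times: dict[str, np.ndarray]
    true_params: SimParams

    def to_dict(self) -> dict:
        return {
            "csd_onsets": {k: list(map(float, v)) for k, v in self.csd_onsets.items()},
            "spike_times": {k: list(map(float, v)) for k, v in self.spike_times.items()},
            "true_params": dataclasses.asdict(self.true_params),
        }


# ------------------------------------------------------------ CSD template

_TROUGH_U = 0.25      # trough position as fraction of template duration
_SIGMA_LEFT = 0.045   # descending-limb width: the depolarization front is
                      # steep (a few seconds for a ~1 min event)
_SIGMA_RIGHT = 0.24   # slow recovery width


def _csd_shape(u: np.ndarray) -> np.ndarray:
    """Unnormalized template on u = t_rel / duration in [0, 1]."""
    u = np.asarray(u, dtype=float)
    sigma = np.where(u < _TROUGH_U, _SIGMA_LEFT, _SIGMA_RIGHT)
    trough = -np.exp(-0.5 * ((u - _TROUGH_U) / sigma) ** 2)
    depol = 0.12 * np.exp(-0.5 * ((u - 0.07) / 0.025) ** 2)
    after = 0.14 * np.exp(-0.5 * ((u - 0.84) / 0.07) ** 2)
    s = trough + depol + after
    # smooth taper to zero over the last 10% of the support
    taper = np.clip((1.0 - u) / 0.1, 0.0, 1.0)
    s = s * np.where(u > 0.9, 0.5 - 0.5 * np.cos(np.pi * taper), 1.0)
    return np.where((u >= 0) & (u <= 1), s, 0.0)


def _shape_constants() -> tuple[float, float, float]:
    """(shape minimum, trough u, onset u at 20% of trough depth)."""
    u = np.linspace(0.0, 1.0, 200_001)
    s = _csd_shape(u)
    i_min = int(np.argmin(s))
    s_min = float(s[i_min])
    level = 0.2 * s_min
    below = np.nonzero(s[:i_min + 1] <= level)[0]
    u_onset = float(u[below[0]]) if below.size else 0.0
    return s_min, float(u[i_min]), u_onset


_S_MIN, _U_TROUGH, _U_ONSET = _shape_constants()


def csd_waveform(t_rel, amplitude_mv: float, duration_s: float):
    """Evaluate the CSD DC-shift template.

    The template minimum over its support equals ``amplitude_mv`` (the
    trough depth, negative) and the value is 0 outside [0, duration_s].
    """
    u = np.asarray(t_rel, dtype=float) / duration_s
    out = _csd_shape(u) * (amplitude_mv / _S_MIN)
    return out if out.ndim else float(out)


def csd_onset_offset_s(duration_s: float, fs: float | None = None) -> float:
    """Delay from template start to the 20%-of-trough onset crossing.

    With ``fs`` given, the crossing is measured on the template after the
    offline CSD conditioning chain (0.005 Hz high-pass, 100 Hz low-pass),
    i.e. on the DC shift as the analysis actually sees it; this is the
    definition ground truth uses.  Without ``fs`` the crossing is on the
    ideal template.
    """
    if fs is None:
        return _U_ONSET * duration_s
    return _filtered_onset_offset(float(duration_s), float(fs))


def _filtered_onset_offset(duration_s: float, fs: float,
                           _cache: dict = {}) -> float:
    key = (duration_s, fs)
    if key not in _cache:
        from .filters import apply_filter
        from .recording import CSD_FILTER

        pad = int(round(4 * duration_s * fs))
        n = int(round(duration_s * fs))
        t_rel = (np.arange(2 * pad + n) - pad) / fs
        y = csd_waveform(t_rel, -1.0, duration_s)
        yf = apply_filter(y, fs, CSD_FILTER)
        i_tr = int(np.argmin(yf))
        level = 0.2 * yf[i_tr]
        above = np.flatnonzero(yf[:i_tr + 1] > level)
        i_on = int(above[-1]) if above.size else 0
        _cache[key] = float(t_rel[i_on])
    return _cache[key]


def csd_trough_offset_s(duration_s: float) -> float:
    """Delay from template start to the trough."""
    return _U_TROUGH * duration_s


# -------------------------------------------------------------- primitives

def one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                     alpha: float = 1.0, scale: float = 1.0) -> np.ndarray:
    """1/f^alpha Gaussian noise with standard deviation *scale*."""
    f = np.fft.rfftfreq(n, 1.0 / fs).astype(np.float32)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** np.float32(-alpha / 2.0)
    # single-precision spectrum synthesis: ~1e-7 relative error, far below
    # the noise floor being modelled, at half the FFT cost
    re = rng.standard_normal(f.size, dtype=np.float32)
    im = rng.standard_normal(f.size, dtype=np.float32)
    x = np.fft.irfft(amp * (re + 1j * im), n=n).astype(np.float64)
    sd = x.std()
    return x * (scale / sd) if sd > 0 else x


_SPIKE_SIGMA = 0.022      # main (negative) lobe width, s
_SPIKE_REBOUND = 0.25     # positive after-wave relative amplitude
_SPIKE_REBOUND_DT = 0.05  # after-wave delay, s
_SPIKE_REBOUND_SIGMA = 0.030
_SPIKE_HALF_SUPPORT = 0.16  # evaluation window half-width, s


def _spike_shape(t: np.ndarray) -> np.ndarray:
    main = -np.exp(-0.5 * (t / _SPIKE_SIGMA) ** 2)
    reb = _SPIKE_REBOUND * np.exp(
        -0.5 * ((t - _SPIKE_REBOUND_DT) / _SPIKE_REBOUND_SIGMA) ** 2)
    return main + reb


_SPIKE_MIN = float(_spike_shape(np.linspace(-0.2, 0.2, 20001)).min())


def spike_waveform(t_rel, amplitude_mv: float):
    """Sharp biphasic interictal-spike template.

    The dominant deflection is negative-going with depth ``amplitude_mv``
    (given as a positive magnitude), followed by a smaller positive
    after-wave.
    """
    t = np.asarray(t_rel, dtype=float)
    return _spike_shape(t) * (amplitude_mv / -_SPIKE_MIN)


def _add_events(sig: np.ndarray, fs: float, times: np.ndarray,
                amps: np.ndarray, shape_fn, half_support_s: float) -> None:
    """Accumulate shifted copies of a template into *sig* (in place)."""
    if times.size == 0:
        return
    half = int(np.ceil(half_support_s * fs))
    offs = np.arange(-half, half + 1)
    idx = np.round(times * fs).astype(int)[:, None] + offs[None, :]
    t_rel = idx / fs - times[:, None]
    vals = shape_fn(t_rel) * amps[:, None]
    ok = (idx >= 0) & (idx < sig.size)
    np.add.at(sig, idx[ok], vals[ok])


def _add_csds(sig: np.ndarray, fs: float, starts: np.ndarray,
              amplitude_mv: float, duration_s: float) -> None:
    n = sig.size
    for t0 in starts:
        i0 = max(int(np.ceil(t0 * fs)), 0)
        i1 = min(int(np.floor((t0 + duration_s) * fs)) + 1, n)
        if i1 <= i0:
            continue
        t_rel = np.arange(i0, i1) / fs - t0
        sig[i0:i1] += csd_waveform(t_rel, amplitude_mv, duration_s)


# -------------------------------------------------------------- event times

def _csd_start_times(rng: np.random.Generator, p: SimParams) -> np.ndarray:
    """Template start times from a low-CV gamma renewal process."""
    if p.csd_rate_per_hr <= 0:
        return np.array([])
    mean_iei = 3600.0 / p.csd_rate_per_hr
    min_sep = p.csd_duration_s + 5.0
    if mean_iei < min_sep:
        warnings.warn("csd_rate_per_hr too high for non-overlapping events; "
                      "event count truncated", stacklevel=2)
        mean_iei = min_sep
    cv = 0.2
    k = 1.0 / cv ** 2
    times, t = [], 0.0
    # last event must fit entirely (plus the S1 propagation delay)
    lag = ELECTRODE_DISTANCE_MM / p.propagation_speed_mm_per_min * 60.0
    t_max = p.duration_s - p.csd_duration_s - lag
    while True:
        t += max(rng.gamma(k, mean_iei / k), min_sep)
        if t > t_max:
            break
        times.append(t)
    return np.asarray(times)


def _master_spike_times(rng: np.random.Generator, p: SimParams) -> np.ndarray:
    """Spike times on the leading channel (M1 left)."""
    if p.epi_escalation == "none" or p.epi_onset_s is None:
        return np.array([])
    t_on, T = float(p.epi_onset_s), p.duration_s
    if t_on >= T:
        return np.array([])
    isi = 1.0 / p.spike_rate_hz

    def bout(t_start: float, t_stop: float) -> list[float]:
        out, t = [], t_start
        while t < t_stop:
            out.append(t)
            t += isi * rng.uniform(0.7, 1.3)
        return out

    times: list[float] = []
    if p.epi_escalation == "continuous":
        # bout phase, then an uninterrupted ramp covering the terminal window
        t_cont = min(t_on + 0.3 * (T - t_on), max(T - 700.0, t_on))
        t = t_on
        first = True
        while t < t_cont:
            end = min(t + rng.uniform(4.0, 12.0), t_cont)
            times.extend(bout(t, end))
            first = False
            t = end + 10.0 + rng.exponential(35.0)
        t = t_cont if not first else t_on
        while t < T:
            times.append(t)
            t += isi * rng.uniform(0.75, 1.25)
    else:  # bouts throughout
        t = t_on
        while t < T:
            end = min(t + rng.uniform(4.0, 12.0), T)
            times.extend(bout(t, end))
            t = end + 10.0 + rng.exponential(35.0)
    times = np.asarray(times)
    times[0] = t_on  # the true onset is the first spike
    return times[times < T]


# ---------------------------------------------------------------- simulate

#: relative spike gain per channel (activity is strongest at ipsilateral M1)
_CHANNEL_SPIKE_GAIN = {"M1_left": 1.0, "S1_left": 0.95, "M1_right": 0.85}


def simulate_recording(params: SimParams,
                       subject: SubjectMeta | None = None
                       ) -> tuple[Recording, GroundTruth]:
    """Generate one recording plus its ground truth.

    CSDs appear on M1 left and S1 left only (S1 delayed by d/speed);
    spikes appear on all three channels after ``epi_onset_s`` with fixed
    lags (M1 left leads) and per-channel Gaussian timing jitter.  The same
    ``params.seed`` always reproduces the identical recording.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration_s * p.fs))
    data = np.empty((3, n))
    for i in range(3):
        data[i] = one_over_f_noise(rng, n, p.fs, p.noise_exponent,
                                   p.noise_scale_mv)

    # --- CSDs (ipsilateral only) ---
    starts = _csd_start_times(rng, p)
    lag_s1 = ELECTRODE_DISTANCE_MM / p.propagation_speed_mm_per_min * 60.0
    onset_off = csd_onset_offset_s(p.csd_duration_s, p.fs)
    _add_csds(data[0], p.fs, starts, p.csd_amplitude_mv, p.csd_duration_s)
    _add_csds(data[1], p.fs, starts + lag_s1, p.csd_amplitude_mv, p.csd_duration_s)
    csd_onsets = {
        "M1_left": starts + onset_off,
        "S1_left": starts + onset_off + lag_s1,
        "M1_right": np.array([]),
    }

    # --- epileptiform spikes (generalized) ---
    master = _master_spike_times(rng, p)
    spike_times: dict[str, np.ndarray] = {}
    chan_lags = {"M1_left": 0.0, "S1_left": p.intrahemispheric_lag_s,
                 "M1_right": p.interhemispheric_lag_s}
    if master.size and p.epi_onset_s is not None:
        frac = (master - p.epi_onset_s) / max(p.duration_s - p.epi_onset_s, 1.0)
        base_amp = p.spike_amplitude_mv * (1.0 + (p.severity_growth - 1.0) * frac)
    else:
        base_amp = np.array([])
    for i, role in enumerate(ROLES):
        if master.size == 0:
            spike_times[role] = np.array([])
            continue
        t = master + chan_lags[role]
        if role != "M1_left":
            t = t + rng.normal(0.0, p.spike_jitter_s, size=t.size)
        amps = base_amp * _CHANNEL_SPIKE_GAIN[role] \
            * (1.0 + 0.1 * rng.standard_normal(master.size))
        keep = (t >= 0) & (t < p.duration_s)
        t, amps = t[keep], amps[keep]
        order = np.argsort(t)
        t, amps = t[order], amps[order]
        _add_events(data[i], p.fs, t, amps, _unit_spike, _SPIKE_HALF_SUPPORT)
        spike_times[role] = t

    rec = Recording(data=data, fs=p.fs, channels=ROLES, subject=subject)
    truth = GroundTruth(csd_onsets=csd_onsets, spike_times=spike_times,
                        true_params=p)
    return rec, truth


def _unit_spike(t_rel: np.ndarray) -> np.ndarray:
    """Spike shape normalized to unit trough depth."""
    return _spike_shape(t_rel) / -_SPIKE_MIN


# ------------------------------------------------------------ group presets

# Only the orderings between cells are fixed by the modelled phenotypes
# (mutants above wild types in rate and speed; post-menopausal mutant
# females below the other mutant cells in rate; mutant epileptiform onset
# earlier and escalation more severe).  Magnitudes sit in the
# physiological CSD range and are plain data here, overridable per study.
_PRESETS: dict[tuple[str, str], dict] = {}
for _g in GROUPS:
    _PRESETS[("WT", _g)] = dict(
        csd_rate_per_hr=6.0, propagation_speed_mm_per_min=3.5,
        epi_onset_s=2400.0, epi_escalation="none", severity_growth=1.0)
    _PRESETS[("G301R", _g)] = dict(
        csd_rate_per_hr=12.0, propagation_speed_mm_per_min=5.0,
        epi_onset_s=900.0, epi_escalation="continuous", severity_growth=2.0)
_PRESETS[("G301R", "PM_female")].update(
    csd_rate_per_hr=8.0, epi_onset_s=1200.0, epi_escalation="bouts",
    severity_growth=1.6)

#: probability of each terminal class when sampling subjects from a preset
CLASS_PROBS = {
    "WT": {"none": 0.7, "bouts": 0.3, "continuous": 0.0},
    "G301R": {"none": 0.0, "bouts": 0.45, "continuous": 0.55},
}


def group_preset(genotype: str, group: str, seed: int = 0) -> SimParams:
    """Default simulator parameters for one genotype x group cell."""
    if genotype not in GENOTYPES:
        raise ValueError(f"genotype must be one of {GENOTYPES}")
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    kw = dict(_PRESETS[(genotype, group)])
    if kw["epi_escalation"] == "none":
        kw["epi_onset_s"] = None
    return SimParams(seed=seed, **kw)


def sample_subject_params(preset: SimParams, rng: np.random.Generator,
                          genotype: str) -> SimParams:
    """Draw one subject's parameters around a cell preset.

    Adds the between-animal variability real cohorts show:
    Gaussian jitter on propagation speed, log-normal jitter on the
    inter-channel conduction lags, a genotype-specific draw of the
    terminal activity class (most wild types never develop spikes), and a
    latent per-animal susceptibility that couples an earlier epileptiform
    onset to faster severity growth, emulating the covariation between
    phenotype measures seen across animals.
    """
    probs = CLASS_PROBS[genotype]
    classes = list(probs)
    cls = classes[rng.choice(len(classes), p=[probs[c] for c in classes])]
    speed = preset.propagation_speed_mm_per_min * float(rng.normal(1.0, 0.08))
    speed = max(speed, 0.5)
    kw: dict = dict(
        propagation_speed_mm_per_min=speed, epi_escalation=cls,
        intrahemispheric_lag_s=preset.intrahemispheric_lag_s
        * float(rng.lognormal(0.0, 0.25)),
        interhemispheric_lag_s=preset.interhemispheric_lag_s
        * float(rng.lognormal(0.0, 0.25)))
    suscept = float(rng.normal(0.0, 1.0))
    base_onset = preset.epi_onset_s if preset.epi_onset_s is not None else 2400.0
    if cls == "none":
        kw["epi_onset_s"] = None
    else:
        onset = base_onset * float(np.exp(-0.25 * suscept))
        kw["epi_onset_s"] = float(np.clip(onset, 60.0, preset.duration_s - 900.0))
        growth = preset.severity_growth
        if cls == "continuous" and growth < 1.5:
            growth = 1.8
        kw["severity_growth"] = max(1.0, 1.0 + (growth - 1.0)
                                    * float(np.exp(0.2 * suscept)))
    kw["seed"] = int(rng.integers(0, 2**31 - 1))
    return preset.replace(**kw)
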