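"""Zero-phase offline filtering and anti-aliased downsampling.

The offline conditioning chain: all traces are decimated to 300 Hz,
then filtered with a 0.005 Hz
high-pass for DC-shift (CSD) analysis or a 0.5 Hz high-pass for
epileptiform analysis, with a 100 Hz low-pass in both chains.  Filtering
is forward-backward (zero group delay) with second-order Butterworth
sections, so event onset times are not biased by the filter.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import scipy.signal

from .exceptions import FilterError
from .recording import FilterSpec, Recording


def design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Second-order sections implementing *spec* at sampling rate *fs*."""
    spec.validate_for(fs)
    sections = []
    if spec.highpass_hz is not None:
        sections.append(scipy.signal.butter(
            spec.order, spec.highpass_hz, btype="highpass", fs=fs, output="sos"))
    if spec.lowpass_hz is not None:
        sections.append(scipy.signal.butter(
            spec.order, spec.lowpass_hz, btype="lowpass", fs=fs, output="sos"))
    if not sections:
        raise FilterError("FilterSpec has neither high-pass nor low-pass cutoff")
    return np.vstack(sections)


def _padlen(spec: FilterSpec, fs: float, n: int) -> int:
    # pad past the edge transient of the lowest-cutoff stage (time
    # constant 1 / 2*pi*f_c)
    f_ref = spec.highpass_hz if spec.highpass_hz is not None else spec.lowpass_hz
    return int(min(n - 1, max(round(fs / f_ref), 24)))


def apply_filter(trace: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase filter a trace (1-D, or 2-D along the last axis).

    Runs the forward-backward filter in both time directions and averages,
    so the output is exactly symmetric under time reversal (no residual
    direction-dependent edge transient) and has zero group delay and the
    input's length.
    """
    trace = np.asarray(trace, dtype=float)
    sos = design_sos(spec, fs)
    padlen = _padlen(spec, fs, trace.shape[-1])
    fwd = scipy.signal.sosfiltfilt(sos, trace, axis=-1, padlen=padlen)
    rev = scipy.signal.sosfiltfilt(sos, trace[..., ::-1], axis=-1,
                                   padlen=padlen)[..., ::-1]
    return 0.5 * (fwd + rev)


def filter_recording(rec: Recording, spec: FilterSpec) -> Recording:
    """Apply :func:`apply_filter` to every channel of a recording."""
    return rec.copy_with(data=apply_filter(rec.data, rec.fs, spec))


def downsample(rec: Recording, target_hz: float) -> Recording:
    """Anti-aliased resampling of a recording to *target_hz*.

    Uses polyphase FIR resampling; the rate ratio must be rational
    (as it is for the standard 300 Hz target).  Duration is preserved
    to within one sample of the target rate.
    """
    if target_hz > rec.fs:
        raise FilterError(f"target_hz {target_hz} exceeds recording fs {rec.fs}")
    if target_hz == rec.fs:
        return rec.copy_with(data=rec.data.copy())
    ratio = Fraction(target_hz / rec.fs).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    out = scipy.signal.resample_poly(rec.data, up, down, axis=-1)
    return rec.copy_with(data=out, fs=rec.fs * up / down)
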