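"""Signal preprocessing: zero-phase Butterworth filtering, Hilbert envelope,
and resampling of raw EMG/MMG recordings to 200 Hz band-power envelopes.

Pipeline (``preprocess_recording``): demean -> 25-100 Hz band-pass ->
49-51 Hz band-stop -> |Hilbert| envelope -> resample to 200 Hz.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import EnvelopeSeries, Recording

#: default analysis band (Hz)
DEFAULT_BAND = (25.0, 100.0)
#: default line-noise notch band (Hz)
DEFAULT_NOTCH = (49.0, 51.0)
#: default envelope sampling rate (Hz)
DEFAULT_FS_OUT = 200.0


def _check_band(fs: float, low: float, high: float) -> None:
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(
            f"band edges ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({fs / 2} Hz)"
        )


def _padlen(sos: np.ndarray) -> int:
    """Reflect-pad length for the forward-backward pass: long enough for the
    filter transient to decay below 1e-9, so that zero-phase filtering is
    symmetric under time reversal. Narrow-band filters (e.g. a 2 Hz notch)
    have poles close to the unit circle and need seconds of padding."""
    poles = signal.tf2zpk(*signal.sos2tf(sos))[1]
    r = float(np.max(np.abs(poles)))
    r = min(r, 1.0 - 1e-12)
    return int(np.ceil(np.log(1e-9) / np.log(r)))


def _sosfiltfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    padlen = _padlen(sos)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"signal ({x.shape[-1]} samples) shorter than the filter's padding "
            f"requirement ({padlen} samples)"
        )
    # reflect (mirror) padding for the forward-backward pass
    return signal.sosfiltfilt(sos, x, axis=-1, padtype="even", padlen=padlen)


def bandpass(
    x: np.ndarray, fs: float, low: float = 25.0, high: float = 100.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    The filter is designed at the given order and applied forward-backward
    (``sosfiltfilt``), so the effective magnitude response is the squared
    one-way response and the phase response is zero.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains NaN or Inf")
    _check_band(fs, low, high)
    sos = signal.butter(order, [low, high], btype="bandpass", output="sos", fs=fs)
    return _sosfiltfilt(sos, x)


def bandstop(
    x: np.ndarray, fs: float, low: float = 49.0, high: float = 51.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-stop (line-noise notch) along the last axis."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains NaN or Inf")
    _check_band(fs, low, high)
    sos = signal.butter(order, [low, high], btype="bandstop", output="sos", fs=fs)
    return _sosfiltfilt(sos, x)


def envelope(x: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude: magnitude of the analytic (Hilbert) signal."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains NaN or Inf")
    return np.abs(signal.hilbert(x, axis=-1))


def resample(x: np.ndarray, fs_in: float, fs_out: float = DEFAULT_FS_OUT) -> np.ndarray:
    """FFT-based resampling along the last axis to ``round(n * fs_out / fs_in)``
    samples. Upsampling is not supported."""
    x = np.asarray(x, dtype=float)
    if fs_out > fs_in:
        raise ValueError("upsampling (fs_out > fs_in) is not supported")
    n_out = int(round(x.shape[-1] * fs_out / fs_in))
    if n_out < 1:
        raise ValueError("resampled signal would be empty")
    return signal.resample(x, n_out, axis=-1)


def preprocess_recording(
    rec: Recording,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    notch: tuple[float, float] = DEFAULT_NOTCH,
    fs_out: float = DEFAULT_FS_OUT,
    order: int = 4,
) -> EnvelopeSeries:
    """Run the full envelope pipeline on a recording.

    Demeaning is per channel over the whole session. The envelope is clipped at
    zero after FFT resampling (ringing can produce tiny negative excursions).
    """
    x = rec.data - rec.data.mean(axis=-1, keepdims=True)
    x = bandpass(x, rec.fs, low=low, high=high, order=order)
    x = bandstop(x, rec.fs, low=notch[0], high=notch[1], order=order)
    x = envelope(x)
    x = resample(x, rec.fs, fs_out)
    np.clip(x, 0.0, None, out=x)
    return EnvelopeSeries(data=x, fs=fs_out, channels=list(rec.channels), session_id=rec.session_id)
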