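"""Conversion of digital audio to calibrated pressure and band-limited SPL.

All sound-pressure levels are expressed in dB re 20 uPa unless noted
otherwise.  The calibration chain is::

    digital full-scale units  --(mic sensitivity + gain + ADC range)-->  Pa
    Pa  --(band-pass, windowed RMS)-->  SPL series

Digital samples are dimensionless in [-1, 1]; the unit state of a clip is
tracked explicitly so the conversion cannot be applied twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "AudioClip",
    "CalibrationSpec",
    "REFERENCE_PRESSURE_PA",
    "SILENCE_DB",
    "pressure_from_digital",
    "digital_from_pressure",
    "spl",
    "bandpass",
    "band_rms_spl",
    "read_wav",
    "write_wav",
]

#: Standard airborne reference pressure (Pa).
REFERENCE_PRESSURE_PA = 20e-6

#: Sentinel returned by :func:`spl` for zero RMS pressure.
SILENCE_DB = -np.inf


@dataclass
class AudioClip:
    """A mono or multi-channel audio buffer with an explicit unit flag.

    Parameters
    ----------
    samples : ndarray
        Shape ``(n,)`` for mono or ``(n, channels)``.  Dimensionless
        full-scale units in ``[-1, 1]`` when ``units == "digital"``,
        pascals when ``units == "pa"``.
    sample_rate : float
        Sampling rate in Hz, > 0.
    units : str
        ``"digital"`` or ``"pa"``.
    """

    samples: np.ndarray
    sample_rate: float
    units: str = "digital"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.units not in ("digital", "pa"):
            raise ValueError(f"units must be 'digital' or 'pa', got {self.units!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return self.n_samples / self.sample_rate

    def to_mono(self, channel: int | None = None) -> "AudioClip":
        """Collapse to one channel, either by averaging or by selection."""
        if self.samples.ndim == 1:
            return self
        mono = self.samples[:, channel] if channel is not None else self.samples.mean(axis=1)
        return replace(self, samples=mono)


@dataclass(frozen=True)
class CalibrationSpec:
    """Recording-chain constants mapping digital amplitude to pressure.

    ``mic_sensitivity`` is in dB re 1 V/Pa (typically negative), ``gain``
    in dB, ``adc_full_scale`` is the voltage mapped to digital 1.0.
    """

    mic_sensitivity: float = -36.0
    gain: float = 0.0
    adc_full_scale: float = 1.0
    reference_pressure: float = REFERENCE_PRESSURE_PA

    def __post_init__(self) -> None:
        if self.adc_full_scale <= 0:
            raise ValueError("adc_full_scale must be > 0")
        if self.reference_pressure <= 0:
            raise ValueError("reference_pressure must be > 0")

    @property
    def volts_per_pascal(self) -> float:
        """Linear end-to-end sensitivity of mic + gain stage (V/Pa)."""
        return 10.0 ** ((self.mic_sensitivity + self.gain) / 20.0)


def pressure_from_digital(clip: AudioClip, calib: CalibrationSpec) -> AudioClip:
    """Convert a digital clip to pascals: ``p = x * V_fs / 10^((S+G)/20)``.

    Raises
    ------
    ValueError
        If the clip is already in pascals (the conversion is stateful and
        must be applied exactly once).
    """
    if clip.units != "digital":
        raise ValueError("clip is already in Pa; conversion applied twice")
    scale = calib.adc_full_scale / calib.volts_per_pascal
    return AudioClip(clip.samples * scale, clip.sample_rate, units="pa")


def digital_from_pressure(clip: AudioClip, calib: CalibrationSpec) -> AudioClip:
    """Exact inverse of :func:`pressure_from_digital`."""
    if clip.units != "pa":
        raise ValueError("clip is not in Pa")
    scale = calib.volts_per_pascal / calib.adc_full_scale
    return AudioClip(clip.samples * scale, clip.sample_rate, units="digital")


def spl(p_rms, reference_pressure: float = REFERENCE_PRESSURE_PA):
    """Sound-pressure level ``20*log10(p_rms / p_ref)`` in dB.

    Accepts scalars or arrays; zero pressure maps to ``-inf`` and negative
    pressure raises.
    """
    p = np.asarray(p_rms, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("RMS pressure must be >= 0")
    with np.errstate(divide="ignore"):
        out = 20.0 * np.log10(p / reference_pressure)
    return float(out) if np.isscalar(p_rms) else out


def pressure_from_spl(level_db, reference_pressure: float = REFERENCE_PRESSURE_PA):
    """Inverse of :func:`spl`: RMS pressure (Pa) at the given level."""
    return reference_pressure * 10.0 ** (np.asarray(level_db, dtype=float) / 20.0)


def _band_sos(f_lo: float, f_hi: float, sample_rate: float, order: int = 4):
    nyq = sample_rate / 2.0
    if not (0 <= f_lo < f_hi):
        raise ValueError(f"need 0 <= f_lo < f_hi, got ({f_lo}, {f_hi})")
    if f_hi > nyq:
        raise ValueError(f"f_hi {f_hi} Hz exceeds Nyquist {nyq} Hz")
    if f_lo == 0:
        return signal.butter(order, f_hi, btype="lowpass", fs=sample_rate, output="sos")
    return signal.butter(order, (f_lo, f_hi), btype="bandpass", fs=sample_rate, output="sos")


def bandpass(clip: AudioClip, f_lo: float, f_hi: float, order: int = 4) -> AudioClip:
    """Zero-phase Butterworth band-pass (forward-backward, order doubled).

    ``f_lo == 0`` degenerates to a low-pass.  Unit flag is preserved.
    """
    sos = _band_sos(f_lo, f_hi, clip.sample_rate, order)
    filtered = signal.sosfiltfilt(sos, clip.samples, axis=0)
    return replace(clip, samples=filtered)


def rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(np.asarray(x, dtype=np.float64)))))


def band_rms_spl(
    clip: AudioClip,
    calib: CalibrationSpec | None,
    band: tuple[float, float],
    window_s: float,
) -> np.ndarray:
    """Band-limited SPL per non-overlapping window.

    The clip is band-passed once, converted to pascals (if still digital),
    then split into consecutive ``window_s`` windows aligned to the clip
    start; the trailing partial window is dropped.  Returns one SPL value
    (dB re 20 uPa) per complete window.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    work = clip.to_mono()
    if work.units == "digital":
        if calib is None:
            raise ValueError("digital clip requires a CalibrationSpec")
        work = pressure_from_digital(work, calib)
    work = bandpass(work, *band)
    n_win = int(work.n_samples // round(window_s * work.sample_rate))
    step = int(round(window_s * work.sample_rate))
    if n_win == 0:
        warnings.warn("window longer than clip; empty SPL series", stacklevel=2)
        return np.empty(0)
    frames = work.samples[: n_win * step].reshape(n_win, step)
    p_rms = np.sqrt(np.mean(np.square(frames), axis=1))
    ref = calib.reference_pressure if calib is not None else REFERENCE_PRESSURE_PA
    return spl(p_rms, ref)


def read_wav(path, channel: int | None = None) -> AudioClip:
    """Read a PCM WAV file into a digital-unit clip scaled to [-1, 1].

    16-, 24- (read as 32-bit by scipy) and 32-bit integer PCM plus float
    WAVs are supported.  ``channel`` selects one channel of a multi-channel
    file; by default channels are kept.
    """
    sr, data = wavfile.read(path)
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32/float64 already full-scale
        x = data.astype(np.float64)
    if channel is not None and x.ndim > 1:
        x = x[:, channel]
    return AudioClip(x, float(sr), units="digital")


def write_wav(path, clip: AudioClip) -> int:
    """Write a digital-unit clip as 16-bit PCM WAV.

    Samples outside [-1, 1] are clipped; returns the clipped-sample count
    (also emitted as a warning when non-zero).
    """
    if clip.units != "digital":
        raise ValueError("convert to digital units before writing")
    x = clip.samples
    n_clipped = int(np.count_nonzero((x > 1.0) | (x < -1.0)))
    if n_clipped:
        warnings.warn(f"{n_clipped} samples clipped on WAV write", stacklevel=2)
    scaled = np.clip(np.round(np.clip(x, -1.0, 1.0) * 32768.0), -32768, 32767)
    wavfile.write(path, int(round(clip.sample_rate)), scaled.astype(np.int16))
    return n_clipped
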