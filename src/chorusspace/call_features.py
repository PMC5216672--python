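"""Per-call acoustic measurements from directional recordings.

Calls are delimited by manually drawn (or, here, synthetically generated)
selection-table annotations.  For each accepted call the module measures
duration, band-limited spectral centroid frequency, received band SPL, and
the back-calculated source level at 1 m; per-frog aggregates add the call
rate (calls per minute of recording).

Measurement conventions:

* a 0.05-s buffer is added to either side of the annotation for energy
  measurements (duration itself is annotation-bounded);
* recordings are polyphase-downsampled to 11,025 Hz before analysis
  (configurable off);
* centroid frequency uses a 4,096-point FFT restricted to 1.0-4.5 kHz;
* received-level energy is integrated over the buffered window but
  normalized by the annotated call duration, so a call whose source clip
  was calibrated over its own extent round-trips to the same SPL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .calibration import AudioClip, CalibrationSpec, bandpass, pressure_from_digital, spl
from .commspace import PropagationParams

__all__ = [
    "CallAnnotation",
    "CallMeasurement",
    "FrogRecord",
    "ExcludedFrog",
    "ANALYSIS_BAND",
    "ANALYSIS_RATE",
    "read_selection_table",
    "write_selection_table",
    "select_calls",
    "call_duration",
    "centroid_frequency",
    "received_band_spl",
    "source_level_1m",
    "call_rate",
    "aggregate_frog",
    "downsample",
    "measure_calls",
]

#: Band holding the bulk of call energy (Hz); measurements are restricted
#: to it to exclude low-frequency road noise.
ANALYSIS_BAND = (1000.0, 4500.0)

#: Analysis sampling rate after downsampling (Hz).
ANALYSIS_RATE = 11025

#: Buffer added to either side of an annotation for energy measures (s).
ENERGY_BUFFER_S = 0.05

#: Default minimum call SNR (dB above site median ambient) for acceptance.
DEFAULT_MIN_SNR_DB = 10.0

_SELECTION_COLUMNS = ["Begin Time (s)", "End Time (s)", "Low Freq (Hz)", "High Freq (Hz)"]


@dataclass(frozen=True)
class CallAnnotation:
    """One selection: temporal extent, frequency bounds, quality flags."""

    begin: float
    end: float
    low_freq: float = ANALYSIS_BAND[0]
    high_freq: float = ANALYSIS_BAND[1]
    overlapped: bool = False
    frog: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.begin:
            raise ValueError(f"end ({self.end}) must exceed begin ({self.begin})")
        if not (0 <= self.low_freq < self.high_freq):
            raise ValueError("need 0 <= low_freq < high_freq")


@dataclass(frozen=True)
class CallMeasurement:
    duration: float
    centroid_frequency: float
    received_spl: float
    source_level: float


@dataclass(frozen=True)
class FrogRecord:
    """Per-frog aggregate over accepted calls."""

    frog: str
    site: str
    date: str
    temperature_c: float
    source_level_db: float
    centroid_frequency_hz: float
    duration_s: float
    call_rate_cpm: float
    n_calls: int = 0


@dataclass(frozen=True)
class ExcludedFrog:
    frog: str
    reason: str


def read_selection_table(path) -> pd.DataFrame:
    """Read a tab-separated selection table (Raven dialect).

    Requires the Begin/End Time and Low/High Freq columns; extra columns
    (annotation channel, frog id, ...) are preserved.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SELECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"selection table missing columns: {missing}")
    return df


def write_selection_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def annotations_from_table(df: pd.DataFrame) -> list[CallAnnotation]:
    """Turn selection-table rows into :class:`CallAnnotation` objects."""
    out = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        out.append(
            CallAnnotation(
                begin=d["Begin Time (s)"],
                end=d["End Time (s)"],
                low_freq=d["Low Freq (Hz)"],
                high_freq=d["High Freq (Hz)"],
                overlapped=bool(d.get("overlapped", False)),
                frog=d.get("frog"),
            )
        )
    return out


def select_calls(
    annotations: list[CallAnnotation],
    received_spls: list[float],
    ambient_db: float,
    min_snr: float = DEFAULT_MIN_SNR_DB,
) -> list[CallAnnotation]:
    """Keep non-overlapped calls whose SNR (call band SPL minus the site
    median ambient level) meets ``min_snr``; order is preserved."""
    if len(annotations) != len(received_spls):
        raise ValueError("annotations and received_spls length mismatch")
    return [
        a
        for a, level in zip(annotations, received_spls)
        if not a.overlapped and (level - ambient_db) >= min_snr
    ]


def call_duration(
    ann: CallAnnotation,
    buffer_s: float = ENERGY_BUFFER_S,
    clip_duration: float | None = None,
) -> tuple[float, tuple[float, float]]:
    """Annotation-bounded duration plus the buffered analysis window.

    The window ``[begin - buffer, end + buffer]`` is used by energy
    measurements only; it is clamped (with a warning) to the clip bounds
    when they are known.
    """
    lo, hi = ann.begin - buffer_s, ann.end + buffer_s
    clamp_hi = clip_duration if clip_duration is not None else np.inf
    if lo < 0 or hi > clamp_hi:
        warnings.warn("analysis buffer clamped to clip bounds", stacklevel=2)
        lo, hi = max(lo, 0.0), min(hi, clamp_hi)
    return ann.end - ann.begin, (lo, hi)


def _segment(clip: AudioClip, window: tuple[float, float]) -> np.ndarray:
    i0 = max(0, int(round(window[0] * clip.sample_rate)))
    i1 = min(clip.n_samples, int(round(window[1] * clip.sample_rate)))
    if i1 <= i0:
        raise ValueError("analysis window outside clip")
    return clip.to_mono().samples[i0:i1]


def centroid_frequency(
    clip: AudioClip,
    window: tuple[float, float],
    band: tuple[float, float] = ANALYSIS_BAND,
    fft_size: int = 4096,
    spectral_window: str = "hann",
) -> float:
    """Energy-weighted mean frequency over in-band FFT bins.

    Segments longer than ``fft_size`` use a Welch-averaged power spectrum
    (50% overlap); shorter segments use a single zero-padded periodogram.
    Returns NaN when the in-band energy is zero.
    """
    x = _segment(clip, window)
    if x.size >= fft_size:
        f, p = signal.welch(
            x, fs=clip.sample_rate, window=spectral_window,
            nperseg=fft_size, noverlap=fft_size // 2,
        )
    else:
        f, p = signal.periodogram(
            x, fs=clip.sample_rate, window=spectral_window, nfft=fft_size
        )
    in_band = (f >= band[0]) & (f <= band[1])
    e = p[in_band].sum()
    # leakage floor: treat in-band energy below 1e-9 of the total as zero
    if e <= 0 or e < 1e-9 * p.sum():
        return float("nan")
    return float((f[in_band] * p[in_band]).sum() / e)


def received_band_spl(
    clip: AudioClip,
    window: tuple[float, float],
    band: tuple[float, float] = ANALYSIS_BAND,
    call_duration_s: float | None = None,
) -> float:
    """Band-limited SPL of a call, dB re 20 uPa.  Clip must be in Pa.

    Energy is summed over the buffered window; when ``call_duration_s`` is
    given the RMS is normalized to the call extent rather than the window
    length (see module docstring).
    """
    if clip.units != "pa":
        raise ValueError("clip must be calibrated to Pa first")
    x = _segment(bandpass(clip, *band), window)
    norm_n = (
        x.size if call_duration_s is None else call_duration_s * clip.sample_rate
    )
    return spl(float(np.sqrt(np.sum(np.square(x)) / norm_n)))


def source_level_1m(
    received_spl: float,
    distance: float,
    params: PropagationParams = PropagationParams(),
) -> float:
    """Back-calculate source level at 1 m: ``s = RL + 20*log10(r) + A_e*r``."""
    if distance <= 0:
        raise ValueError("distance must be > 0")
    return received_spl + 20.0 * np.log10(distance) + params.linear_loss * distance


def call_rate(n_calls: int, recording_length_s: float) -> float:
    """Calls per minute of recording: ``60 * count / length``."""
    if recording_length_s <= 0:
        raise ValueError("recording length must be > 0")
    if n_calls < 0:
        raise ValueError("call count must be >= 0")
    return 60.0 * n_calls / recording_length_s


def aggregate_frog(
    measurements: list[CallMeasurement],
    rate: float,
    frog: str,
    site: str = "",
    date: str = "",
    temperature_c: float = float("nan"),
) -> FrogRecord | ExcludedFrog:
    """Unweighted per-frog means over accepted calls; frogs with no
    accepted calls yield an :class:`ExcludedFrog` record instead."""
    if not measurements:
        return ExcludedFrog(frog=frog, reason="no accepted calls")
    return FrogRecord(
        frog=frog,
        site=site,
        date=date,
        temperature_c=temperature_c,
        source_level_db=float(np.mean([m.source_level for m in measurements])),
        centroid_frequency_hz=float(np.nanmean([m.centroid_frequency for m in measurements])),
        duration_s=float(np.mean([m.duration for m in measurements])),
        call_rate_cpm=rate,
        n_calls=len(measurements),
    )


def downsample(clip: AudioClip, target_rate: int = ANALYSIS_RATE) -> AudioClip:
    """Polyphase resampling to the analysis rate."""
    if clip.sample_rate == target_rate:
        return clip
    from fractions import Fraction

    frac = Fraction(int(target_rate), int(round(clip.sample_rate))).limit_denominator(1000)
    y = signal.resample_poly(clip.to_mono().samples, frac.numerator, frac.denominator)
    return AudioClip(y, float(target_rate), units=clip.units)


def measure_calls(
    clip: AudioClip,
    annotations: list[CallAnnotation],
    calib: CalibrationSpec,
    distance_m: float,
    ambient_db: float,
    params: PropagationParams = PropagationParams(),
    band: tuple[float, float] = ANALYSIS_BAND,
    min_snr: float = DEFAULT_MIN_SNR_DB,
    buffer_s: float = ENERGY_BUFFER_S,
    do_downsample: bool = True,
) -> tuple[list[CallAnnotation], list[CallMeasurement]]:
    """Full per-call measurement chain on one directional recording.

    Converts to pressure, optionally downsamples, measures every
    annotation, then applies the overlap/SNR acceptance filter.  Returns
    the accepted annotations and their measurements (in the same order).
    """
    work = clip if clip.units == "pa" else pressure_from_digital(clip.to_mono(), calib)
    if do_downsample:
        work = downsample(work)
    all_measurements = []
    for ann in annotations:
        duration, window = call_duration(ann, buffer_s, work.duration)
        rl = received_band_spl(work, window, band, call_duration_s=duration)
        all_measurements.append(
            CallMeasurement(
                duration=duration,
                centroid_frequency=centroid_frequency(work, window, band),
                received_spl=rl,
                source_level=source_level_1m(rl, distance_m, params),
            )
        )
    accepted = select_calls(
        annotations, [m.received_spl for m in all_measurements], ambient_db, min_snr
    )
    keep = {id(a) for a in accepted}
    measurements = [m for a, m in zip(annotations, all_measurements) if id(a) in keep]
    return accepted, measurements
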