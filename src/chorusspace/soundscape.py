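"""Ambient road-noise characterization per site-night.

Band-limited SPL series are extracted in non-overlapping windows from
timestamped passive recordings; the site-night ambient level ``n`` is the
median of the windows whose start falls inside a pre-chorus evaluation
interval (default 16:00-17:00 local standard time).  Site medians are then
modelled against ``A = 1/distance^2``, the inverse-square-law regressor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .calibration import AudioClip, CalibrationSpec, band_rms_spl

__all__ = [
    "MASKING_BAND",
    "TRAFFIC_BAND",
    "SiteMetadata",
    "NoiseProfile",
    "InverseSquareFit",
    "ambient_profile",
    "fit_inverse_square",
    "read_site_metadata",
]

#: Call-energy band used for the masking model (Hz).
MASKING_BAND = (1000.0, 4500.0)
#: Low-frequency traffic band; the lower edge is 10 Hz rather than DC for
#: filter stability (negligible energy below 10 Hz in synthesized scenes).
TRAFFIC_BAND = (10.0, 1000.0)

#: Default pre-chorus evaluation interval (local standard time).
DEFAULT_EVAL_INTERVAL = (time(16, 0), time(17, 0))

#: Default analysis window (15 min).
DEFAULT_WINDOW_S = 900.0


@dataclass(frozen=True)
class SiteMetadata:
    site: str
    distance_to_road_m: float
    gain_db: float = 0.0
    recorder_model: str = ""

    def __post_init__(self) -> None:
        if self.distance_to_road_m <= 0:
            raise ValueError("distance_to_road_m must be > 0")

    @property
    def inverse_square(self) -> float:
        """A = 1/distance^2 regressor value (1/m^2)."""
        return 1.0 / self.distance_to_road_m**2


@dataclass
class NoiseProfile:
    """Windowed SPL series for one site-night and its median ambient level."""

    site: str
    date: str
    band: tuple[float, float]
    window_s: float
    spl_series: np.ndarray
    median_ambient: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.site,
                "date": self.date,
                "band_lo_hz": self.band[0],
                "band_hi_hz": self.band[1],
                "median_db": self.median_ambient,
            },
            index=[0],
        )


@dataclass(frozen=True)
class InverseSquareFit:
    """OLS of site median noise on A = 1/distance^2."""

    intercept: float
    slope: float
    t_slope: float
    p_slope: float
    r_squared: float
    df_resid: int


def _window_starts(start: datetime, n_windows: int, window_s: float):
    return [start + timedelta(seconds=k * window_s) for k in range(n_windows)]


def ambient_profile(
    clips: list[tuple[datetime, AudioClip]],
    calib: CalibrationSpec,
    band: tuple[float, float] = MASKING_BAND,
    window_s: float = DEFAULT_WINDOW_S,
    eval_interval: tuple[time, time] = DEFAULT_EVAL_INTERVAL,
    site: str = "",
    date: str = "",
) -> NoiseProfile:
    """Median band SPL over windows starting inside the evaluation interval.

    ``clips`` are (start timestamp, clip) pairs in local standard time.
    Windows are non-overlapping, aligned to each clip's start; partial
    trailing windows are dropped.  With no window in the interval the
    median is NaN (with a warning).
    """
    lo, hi = eval_interval
    levels = []
    for start, clip in clips:
        series = band_rms_spl(clip, calib, band, window_s)
        for t0, level in zip(_window_starts(start, series.size, window_s), series):
            if lo <= t0.time() < hi:
                levels.append(level)
    series = np.asarray(levels, dtype=float)
    if series.size == 0:
        warnings.warn(
            f"no analysis windows start within {lo}-{hi}; median is NaN",
            stacklevel=2,
        )
        median = float("nan")
    else:
        median = float(np.median(series))
    return NoiseProfile(
        site=site, date=date, band=band, window_s=window_s,
        spl_series=series, median_ambient=median,
    )


def fit_inverse_square(medians, distances) -> InverseSquareFit:
    """OLS of site median ambient noise on A = 1/distance^2.

    Requires at least 3 sites with distinct distances; the slope t-test
    uses n - 2 residual degrees of freedom.
    """
    y = np.asarray(medians, dtype=float)
    d = np.asarray(distances, dtype=float)
    if y.size != d.size:
        raise ValueError("medians and distances length mismatch")
    if y.size < 3:
        raise ValueError("need at least 3 sites")
    if np.any(d <= 0):
        raise ValueError("distances must be > 0")
    if np.unique(d).size < 2:
        raise ValueError("distances must not all coincide")
    a = 1.0 / d**2
    res = sm.OLS(y, sm.add_constant(a)).fit()
    return InverseSquareFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        t_slope=float(res.tvalues[1]),
        p_slope=float(res.pvalues[1]),
        r_squared=float(res.rsquared),
        df_resid=int(res.df_resid),
    )


def read_site_metadata(path) -> list[SiteMetadata]:
    """Load site metadata from CSV (site, distance_to_road_m[, gain_db,
    recorder_model])."""
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            SiteMetadata(
                site=str(d["site"]),
                distance_to_road_m=float(d["distance_to_road_m"]),
                gain_db=float(d.get("gain_db", 0.0)),
                recorder_model=str(d.get("recorder_model", "")),
            )
        )
    return out
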