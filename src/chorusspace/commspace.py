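"""Spatiotemporal communication-space model.

Received level at range r from a caller with source level s (dB re 20 uPa
at 1 m) is modelled as spherical spreading plus a linear excess-attenuation
term::

    RL(r) = s - 20*log10(r) - A_e*r - absorption*r

The masking radius is the unique r > 0 at which RL falls to the ambient
noise level n (plus an optional detection threshold).  The communication
space is the hemisphere of that radius above the caller, and the
time-volume statistic multiplies it by call duration and call rate to give
m^3*s of communication per minute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import lambertw

__all__ = [
    "PropagationParams",
    "CommSpace",
    "BarrierSpec",
    "received_level",
    "masking_radius",
    "hemisphere_volume",
    "time_volume",
    "comm_space",
    "barrier_scenario",
]

_LN10_OVER_20 = math.log(10.0) / 20.0


@dataclass(frozen=True)
class PropagationParams:
    """Spreading-law constants.

    excess_attenuation : dB/m beyond spherical spreading (default 0.2).
    atmospheric_absorption : optional extra linear dB/m term (default 0).
    reference_distance : m at which source level is defined (1 m).
    detection_threshold : dB above ambient noise required for detection.
    """

    excess_attenuation: float = 0.2
    atmospheric_absorption: float = 0.0
    reference_distance: float = 1.0
    detection_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.excess_attenuation < 0:
            raise ValueError("excess_attenuation must be >= 0")
        if self.atmospheric_absorption < 0:
            raise ValueError("atmospheric_absorption must be >= 0")
        if self.detection_threshold < 0:
            raise ValueError("detection_threshold must be >= 0")

    @property
    def linear_loss(self) -> float:
        """Total linear attenuation (dB/m)."""
        return self.excess_attenuation + self.atmospheric_absorption


@dataclass(frozen=True)
class CommSpace:
    """Masking radius (m), hemispherical volume (m^3) and time-volume
    (m^3*s per minute) for one caller; ``sub_reference`` flags radii
    below the 1 m reference distance."""

    radius: float
    volume: float
    time_volume: float
    sub_reference: bool = False


@dataclass(frozen=True)
class BarrierSpec:
    """Acoustic barrier applied as a constant insertion loss (dB) on the
    ambient noise level.  ``loss_per_distance``/``distance_basis`` record
    the descriptive per-distance basis (default 5 dB per 30.48 m) as
    metadata only; the model applies ``insertion_loss`` as one number."""

    insertion_loss: float
    loss_per_distance: float = 5.0
    distance_basis: float = 30.48

    def __post_init__(self) -> None:
        if self.insertion_loss < 0:
            raise ValueError("insertion_loss must be >= 0")


def received_level(s: float, r, params: PropagationParams = PropagationParams()):
    """RL(r) = s - 20*log10(r) - (A_e + absorption)*r.  Strictly decreasing
    in r; requires r > 0."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise ValueError("distance must be > 0")
    out = s - 20.0 * np.log10(r) - params.linear_loss * r
    return float(out) if out.ndim == 0 else out


def masking_radius(
    s: float, n: float, params: PropagationParams = PropagationParams()
) -> float:
    """Radius r* > 0 at which RL(r*) equals n + detection_threshold.

    Solved in closed form via the Lambert W function: with
    ``b = a*ln(10)/20`` and ``k = (s - n')*ln(10)/20``,
    ``ln r + b r = k`` gives ``r = W(b*exp(k))/b``.  Falls back to a
    bracketed Brent solve if the closed form overflows.  Radii below the
    reference distance are returned as-is (flag them via
    :func:`comm_space` if needed).
    """
    if not (np.isfinite(s) and np.isfinite(n)):
        raise ValueError("s and n must be finite")
    target = n + params.detection_threshold
    a = params.linear_loss
    k = (s - target) * _LN10_OVER_20
    if a == 0:
        return math.exp(k)
    b = a * _LN10_OVER_20
    arg = b * math.exp(k)
    if math.isfinite(arg):
        r = float(np.real(lambertw(arg)))
        if np.isfinite(r) and r > 0:
            return r / b
    # overflow regime: bracket around the no-attenuation radius
    hi = math.exp(k)
    return brentq(
        lambda rr: received_level(s, rr, params) - target,
        np.finfo(float).tiny,
        max(hi, 1.0),
        xtol=1e-15,
        rtol=8.9e-16,
    )


def hemisphere_volume(r) -> float:
    """Volume of a hemisphere of radius r: (2/3)*pi*r^3."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("radius must be >= 0")
    out = (2.0 / 3.0) * np.pi * r**3
    return float(out) if out.ndim == 0 else out


def time_volume(d: float, rate: float, r: float) -> float:
    """Time-volume per minute: duration (s) * call rate (/min) * hemisphere
    volume at radius r (m)."""
    if d < 0 or rate < 0:
        raise ValueError("duration and call rate must be >= 0")
    return d * rate * hemisphere_volume(r)


def comm_space(
    s: float,
    n: float,
    d: float,
    rate: float,
    params: PropagationParams = PropagationParams(),
) -> CommSpace:
    """Full communication-space summary for one caller."""
    r = masking_radius(s, n, params)
    return CommSpace(
        radius=r,
        volume=hemisphere_volume(r),
        time_volume=time_volume(d, rate, r),
        sub_reference=r < params.reference_distance,
    )


def barrier_scenario(
    s: float,
    n: float,
    barrier: BarrierSpec,
    params: PropagationParams = PropagationParams(),
) -> tuple[float, float, float]:
    """Masking radius before and after inserting a noise barrier.

    The barrier reduces ambient noise by its insertion loss; returns
    ``(radius_before, radius_after, delta)`` with ``delta >= 0``.
    """
    before = masking_radius(s, n, params)
    after = masking_radius(s, n - barrier.insertion_loss, params)
    return before, after, after - before
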