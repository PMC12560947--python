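"""Dry-bulb/relative-humidity to wet-bulb temperature conversion.

Wet-bulb temperature (Tw) is the lowest temperature air can reach by
evaporative cooling and is the standard joint heat-stress metric for
temperature and humidity.  The workhorse here is Stull's empirical
closed-form fit, valid at standard sea-level pressure for roughly
RH in [5, 99] % and T in [-20, 50] degC.  An independent iterative solver
of the psychrometric balance is provided purely for validation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wet_bulb_stull", "wet_bulb_oracle", "stull_domain_valid", "STULL_DOMAIN"]

# Fitted domain of the Stull relation: (RH_min, RH_max, T_min, T_max).
STULL_DOMAIN = (5.0, 99.0, -20.0, 50.0)


def wet_bulb_stull(T, RH):
    """Wet-bulb temperature (degC) from Stull's empirical relationship.

    Parameters
    ----------
    T : array_like
        Dry-bulb temperature in degC.
    RH : array_like
        Relative humidity in percent, in [0, 100].

    Returns
    -------
    Tw : ndarray or float
        Wet-bulb temperature in degC.  Values are computed even outside
        the fitted domain; use :func:`stull_domain_valid` to flag them.

    Notes
    -----
    The fit assumes standard sea-level pressure (101.325 kPa).  NaN inputs
    propagate to NaN outputs so gappy sensor series pass through cleanly.
    """
    T = np.asarray(T, dtype=float)
    RH = np.asarray(RH, dtype=float)
    if np.any(np.isinf(T)) or np.any(np.isinf(RH)):
        raise ValueError("non-finite T or RH")
    with np.errstate(invalid="ignore"):
        bad = (RH < 0) | (RH > 100)
    if np.any(bad):
        raise ValueError(
            f"RH outside [0, 100]: offending values {np.asarray(RH)[bad][:5]}"
        )
    Tw = (
        T * np.arctan(0.151977 * np.sqrt(RH + 8.313659))
        + np.arctan(T + RH)
        - np.arctan(RH - 1.676331)
        + 0.00391838 * RH ** 1.5 * np.arctan(0.023101 * RH)
        - 4.686035
    )
    if Tw.ndim == 0:
        return float(Tw)
    return Tw


def stull_domain_valid(T, RH):
    """Boolean mask: True where (T, RH) lies inside Stull's fitted domain."""
    T = np.asarray(T, dtype=float)
    RH = np.asarray(RH, dtype=float)
    rh_lo, rh_hi, t_lo, t_hi = STULL_DOMAIN
    return (RH >= rh_lo) & (RH <= rh_hi) & (T >= t_lo) & (T <= t_hi)


# Magnus saturation vapor pressure over water, kPa; T in degC.
# Constants: Alduchov & Eskridge (1996) improved Magnus form.
_MAGNUS_A = 0.61094  # kPa
_MAGNUS_B = 17.625
_MAGNUS_C = 243.04  # degC

# Psychrometer coefficient for an aspirated (Assmann) psychrometer,
# kPa per (kPa * degC) -- the classic 6.6e-4 K^-1 value.
_GAMMA = 6.6e-4


def _svp(T):
    return _MAGNUS_A * np.exp(_MAGNUS_B * T / (_MAGNUS_C + T))


def wet_bulb_oracle(T: float, RH: float, pressure: float = 101.325) -> float:
    """Wet-bulb temperature by bisection on the psychrometric balance.

    Solves ``e(Tw) - gamma * P * (T - Tw) = (RH/100) * e(T)`` for Tw on
    [-40, T], where e is the Magnus saturation vapor pressure and gamma
    the psychrometer coefficient.  Converges to 1e-4 degC.

    This solver is deliberately independent of the Stull fit: it exists
    to validate it, not to replace it.
    """
    if not (0.0 < RH <= 100.0):
        raise ValueError(f"RH must be in (0, 100], got {RH}")
    e_actual = RH / 100.0 * _svp(T)

    def balance(tw):
        return _svp(tw) - _GAMMA * pressure * (T - tw) - e_actual

    lo, hi = -40.0, float(T)
    f_lo, f_hi = balance(lo), balance(hi)
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"psychrometric balance not bracketed on [{lo}, {hi}] for T={T}, RH={RH}"
        )
    while hi - lo > 1e-4:
        mid = 0.5 * (lo + hi)
        if balance(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
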