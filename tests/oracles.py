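"""Independent oracles used by the test suite.

Each oracle is written as a separate computation path from the package
code it checks: the solar oracle uses the Fourier-series declination and
equation of time with bisection on the solar altitude (the package uses
the Julian-century ephemeris and the closed-form hour angle); the AIC
oracle evaluates the full Gaussian log-likelihood including its additive
constant; the subset oracle is a naive exhaustive search with
``numpy.linalg.lstsq`` refits.
"""

from __future__ import annotations

import math
from datetime import date

import numpy as np


# ---------------------------------------------------------------------------
# Solar geometry: equatorial sun coordinates + sidereal-time hour angle.
# The package derives day length from the closed-form sunrise hour angle in
# the "true solar time" frame; this oracle instead computes the sun's right
# ascension and declination, takes the local hour angle from Greenwich mean
# sidereal time (no equation of time anywhere), and bisects the altitude
# crossings of -0.833 degrees.

def _jd(when: date, hour_utc: float) -> float:
    return when.toordinal() + 1721424.5 + hour_utc / 24.0


def _sun_ra_dec_deg(jd: float) -> tuple[float, float]:
    """Apparent right ascension and declination of the sun, degrees."""
    t = (jd - 2451545.0) / 36525.0
    l0 = (280.46646 + 36000.76983 * t + 0.0003032 * t * t) % 360.0
    m = math.radians(357.52911 + 35999.05029 * t - 0.0001537 * t * t)
    c = (
        (1.914602 - 0.004817 * t - 0.000014 * t * t) * math.sin(m)
        + (0.019993 - 0.000101 * t) * math.sin(2 * m)
        + 0.000289 * math.sin(3 * m)
    )
    omega = math.radians(125.04 - 1934.136 * t)
    lam = math.radians(l0 + c - 0.00569 - 0.00478 * math.sin(omega))
    eps0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - 0.001813 * t))) / 60.0) / 60.0
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))
    ra = math.degrees(math.atan2(math.cos(eps) * math.sin(lam), math.cos(lam))) % 360.0
    dec = math.degrees(math.asin(math.sin(eps) * math.sin(lam)))
    return ra, dec


def _gmst_deg(jd: float) -> float:
    t = (jd - 2451545.0) / 36525.0
    gmst = (
        280.46061837
        + 360.98564736629 * (jd - 2451545.0)
        + 0.000387933 * t * t
        - t * t * t / 38710000.0
    )
    return gmst % 360.0


def _solar_altitude_deg(when: date, hour_utc: float, lat: float, lon: float) -> float:
    jd = _jd(when, hour_utc)
    ra, dec = _sun_ra_dec_deg(jd)
    local_ha = math.radians((_gmst_deg(jd) + lon - ra) % 360.0)
    phi, decl = math.radians(lat), math.radians(dec)
    sin_alt = math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.cos(local_ha)
    return math.degrees(math.asin(sin_alt))


def day_length_oracle(when: date, lat: float, lon: float, target_alt: float = -0.833) -> float:
    """Sunrise-to-sunset hours by bisection on the solar altitude curve."""
    noon_utc = 12.0 - lon / 15.0

    def alt(h: float) -> float:
        return _solar_altitude_deg(when, h, lat, lon) - target_alt

    def crossing(lo: float, hi: float) -> float:
        flo = alt(lo)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            fmid = alt(mid)
            if flo * fmid <= 0:
                hi = mid
            else:
                lo, flo = mid, fmid
        return 0.5 * (lo + hi)

    # scan outward from solar noon for the first sign change on each side
    assert alt(noon_utc) > 0, "sun below horizon at noon: unsupported case"
    lo = noon_utc
    while alt(lo - 0.5) > 0:
        lo -= 0.5
    sunrise = crossing(lo, lo - 0.5)
    hi = noon_utc
    while alt(hi + 0.5) > 0:
        hi += 0.5
    sunset = crossing(hi, hi + 0.5)
    return sunset - sunrise


# ---------------------------------------------------------------------------
# Full Gaussian AIC (additive constant retained)

def gaussian_aic_oracle(rss: float, n: int, k_params: int) -> float:
    """AIC = -2·logL + 2k with the exact Gaussian log-likelihood at the MLE."""
    sigma2 = rss / n
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    return -2.0 * loglik + 2.0 * k_params


# ---------------------------------------------------------------------------
# Naive OLS / exhaustive subsets

def ols_rss_oracle(X: np.ndarray, y: np.ndarray) -> float:
    """RSS of OLS with intercept via a plain lstsq refit."""
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(np.sum((y - design @ coef) ** 2))


def best_subset_oracle(X: np.ndarray, y: np.ndarray, size: int) -> tuple[tuple[int, ...], float]:
    """Exhaustive minimum-RSS subset of the given size (column indices)."""
    from itertools import combinations

    best_combo, best_rss = None, math.inf
    for combo in combinations(range(X.shape[1]), size):
        rss = ols_rss_oracle(X[:, combo], y)
        if rss < best_rss:
            best_combo, best_rss = combo, rss
    assert best_combo is not None
    return best_combo, best_rss
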