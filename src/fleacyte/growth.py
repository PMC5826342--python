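"""Specific growth rates from dilution-punctuated culture series.

Semi-continuous (turbidostat-like) cultures are kept near a target biomass by
periodic dilution with fresh medium; between dilutions the population grows
exponentially, so the specific growth rate over a window free of dilution
events is

    mu = (ln N_f - ln N_i) / (t_f - t_i)      [per day]

where N is cell density at the initial (i) and final (f) sample of the
window. Density is obtained from chlorophyll fluorescence through a monotone
conversion curve; for any *linear* curve the slope cancels in the log ratio,
so mu does not depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

#: conversion curve: None (identity), a positive slope, a callable, or a
#: pair of arrays (chl_points, density_points) for piecewise-linear interpolation
Conversion = None | float | Callable[[np.ndarray], np.ndarray] | tuple


class DilutionInWindowError(ValueError):
    """A dilution event falls strictly inside the requested growth window."""


@dataclass
class GrowthSeries:
    """Chlorophyll time series with dilution events for one culture replicate."""

    times_days: np.ndarray
    chl_ug_L: np.ndarray
    dilution_times_days: np.ndarray = field(default_factory=lambda: np.array([]))
    dilution_factors: np.ndarray = field(default_factory=lambda: np.array([]))
    conversion: Conversion = None

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.chl_ug_L = np.asarray(self.chl_ug_L, dtype=float)
        self.dilution_times_days = np.asarray(self.dilution_times_days, dtype=float)
        self.dilution_factors = np.asarray(self.dilution_factors, dtype=float)
        if np.isnan(self.times_days).any() or np.isnan(self.chl_ug_L).any():
            raise ValueError("NaN in growth series")
        if self.times_days.shape != self.chl_ug_L.shape:
            raise ValueError("times and chlorophyll series differ in length")
        if not np.all(np.diff(self.times_days) > 0):
            raise ValueError("times must be strictly increasing")
        if (self.chl_ug_L <= 0).any():
            raise ValueError("chlorophyll values must be positive")
        if self.dilution_times_days.shape != self.dilution_factors.shape:
            raise ValueError("dilution times and factors differ in length")
        if (self.dilution_factors < 1).any():
            raise ValueError("dilution factors must be >= 1")
        if self.dilution_times_days.size and (
            self.dilution_times_days.min() < self.times_days[0]
            or self.dilution_times_days.max() > self.times_days[-1]
        ):
            raise ValueError("dilution times outside the observation window")

    def to_frame(self):
        """Series as a DataFrame: time_days, chl_ug_L, event in {none, dilution:<f>}."""
        import pandas as pd

        events = np.array(["none"] * self.times_days.size, dtype=object)
        for t, f in zip(self.dilution_times_days, self.dilution_factors):
            idx = int(np.argmin(np.abs(self.times_days - t)))
            events[idx] = f"dilution:{f:g}"
        return pd.DataFrame(
            {"time_days": self.times_days, "chl_ug_L": self.chl_ug_L, "event": events}
        )


def chl_to_density(chl_ug_L, conversion: Conversion = None) -> np.ndarray:
    """Convert chlorophyll fluorescence to cell density through a monotone curve.

    ``None`` or a float means a linear curve through the origin (default slope
    1); a ``(chl_points, density_points)`` pair is interpolated piecewise
    linearly and must be strictly increasing; a callable is applied as-is.
    """
    chl = np.asarray(chl_ug_L, dtype=float)
    if (chl <= 0).any():
        raise ValueError("chlorophyll must be positive")
    if conversion is None:
        return chl.copy()
    if isinstance(conversion, (int, float)):
        if conversion <= 0:
            raise ValueError("linear conversion slope must be positive")
        return conversion * chl
    if isinstance(conversion, tuple):
        x, y = (np.asarray(a, dtype=float) for a in conversion)
        if not (np.all(np.diff(x) > 0) and np.all(np.diff(y) > 0)):
            raise ValueError("conversion curve must be strictly increasing")
        return np.interp(chl, x, y)
    return np.asarray(conversion(chl), dtype=float)


def _resolve_window(series: GrowthSeries, window) -> tuple[float, float, bool]:
    """Return (t_lo, t_hi, open_interval) bounds for the requested window.

    ``("between_dilutions", i, j)`` uses 1-based dilution indices and selects
    samples strictly after dilution i and strictly before dilution j;
    ``("explicit", t_i, t_f)`` uses the closed interval [t_i, t_f].
    """
    dil = np.sort(series.dilution_times_days)
    kind = window[0]
    if kind == "between_dilutions":
        i, j = int(window[1]), int(window[2])
        if not 1 <= i < j <= dil.size:
            raise ValueError(
                f"dilution indices ({i},{j}) out of range for {dil.size} dilutions"
            )
        return float(dil[i - 1]), float(dil[j - 1]), True
    if kind == "explicit":
        t_i, t_f = float(window[1]), float(window[2])
        if not t_f > t_i:
            raise ValueError("window end must be after window start")
        return t_i, t_f, False
    raise ValueError(f"unknown window kind {kind!r}")


def growth_rate(
    series: GrowthSeries,
    window=("between_dilutions", 2, 3),
    method: str = "endpoints",
) -> float:
    """Specific growth rate mu (per day) over a dilution-free window.

    Parameters
    ----------
    series
        The chlorophyll/density time series.
    window
        ``("between_dilutions", i, j)`` (1-based dilution indices; the default
        spans the period between the second and third dilutions) or
        ``("explicit", t_i, t_f)``.
    method
        ``"endpoints"`` — mu from the first and last sample of the window;
        ``"regression"`` — least-squares slope of ln N against time over all
        window samples (equivalent for noise-free exponential growth).

    Raises
    ------
    DilutionInWindowError
        If a dilution event falls strictly inside the window; estimate per
        inter-dilution window instead.
    """
    t_lo, t_hi, open_iv = _resolve_window(series, window)
    inside = (series.dilution_times_days > t_lo) & (series.dilution_times_days < t_hi)
    if inside.any():
        raise DilutionInWindowError(
            f"dilution at t={series.dilution_times_days[inside]} inside window "
            f"({t_lo}, {t_hi}); estimate growth per inter-dilution window"
        )
    t = series.times_days
    sel = (t > t_lo) & (t < t_hi) if open_iv else (t >= t_lo) & (t <= t_hi)
    if sel.sum() < 2:
        raise ValueError(f"fewer than two samples in window ({t_lo}, {t_hi})")
    tw = t[sel]
    dens = chl_to_density(series.chl_ug_L[sel], series.conversion)
    if (dens <= 0).any():
        raise ValueError("non-positive density in window")
    log_n = np.log(dens)
    if method == "endpoints":
        return float((log_n[-1] - log_n[0]) / (tw[-1] - tw[0]))
    if method == "regression":
        slope = np.polyfit(tw, log_n, 1)[0]
        return float(slope)
    raise ValueError(f"unknown method {method!r}")
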