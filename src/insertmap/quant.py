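"""Bioprocess quantitation for batch cultures.

Unit conventions are fixed: VCD in cells/mL, titer in ug/mL, specific
productivity q_p in pg/cell/day ("pcd"), IVCD in cell*day/mL; 1 ug/mL equals
1e6 pg/mL.  Rounding is half-to-even and applied at presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import CultureTimeSeries


@dataclass
class ProductivitySummary:
    ivcd: float  # cell*day/mL over the interval
    q_p: float  # pg/cell/day
    p_max: float  # ug/mL, maximum of the titer series
    interval: tuple[float, float]  # day range used


def _value_at(series: CultureTimeSeries, column: np.ndarray, day: float) -> float:
    if day < series.day[0] or day > series.day[-1]:
        raise ValueError(f"day {day} outside the sampled range")
    return float(np.interp(day, series.day, column))


def ivcd(series: CultureTimeSeries, from_day: float, to_day: float) -> float:
    """Integral viable cell density: trapezoidal integral of VCD over
    [from_day, to_day] (cell*day/mL)."""
    if to_day < from_day:
        raise ValueError("reversed interval")
    if to_day == from_day:
        return 0.0
    inside = (series.day > from_day) & (series.day < to_day)
    days = np.concatenate([[from_day], series.day[inside], [to_day]])
    vcd = np.array([_value_at(series, series.vcd, d) for d in days])
    return float(np.trapezoid(vcd, days))


def specific_productivity(series: CultureTimeSeries, from_day: float, to_day: float) -> float:
    """q_p = titer gain (converted to pg/mL) divided by the IVCD of the
    interval; units pg/cell/day."""
    denom = ivcd(series, from_day, to_day)
    if denom <= 0:
        raise ValueError("IVCD is zero over the interval")
    dt = _value_at(series, series.titer, to_day) - _value_at(series, series.titer, from_day)
    return float(dt * 1e6 / denom)


def p_max(series: CultureTimeSeries) -> float:
    return float(series.titer.max())


def summarize(series: CultureTimeSeries, from_day: float, to_day: float) -> ProductivitySummary:
    return ProductivitySummary(
        ivcd=ivcd(series, from_day, to_day),
        q_p=specific_productivity(series, from_day, to_day),
        p_max=p_max(series),
        interval=(from_day, to_day),
    )


def fold_change(value_test: float, value_control: float, decimals: int = 2) -> float:
    """Ratio test/control, rounded half-to-even to ``decimals``."""
    if value_control <= 0:
        raise ValueError("control value must be positive")
    return round(value_test / value_control, decimals)


def per_copy_normalize(readout: float, copies: int) -> float:
    """Expression readout (e.g. fluorescence intensity) per transgene copy."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    return readout / copies


def detect_exponential_phase(
    series: CultureTimeSeries, min_r2: float = 0.98, min_points: int = 3
) -> tuple[float, float]:
    """Longest day interval with a log-linear VCD fit of R^2 >= ``min_r2``.

    Offered as a helper for choosing the q_p interval; it is never applied
    silently — summaries always state the interval used."""
    day, vcd = series.day, series.vcd
    best: tuple[float, float] | None = None
    n = len(day)
    for i in range(n):
        for j in range(i + min_points - 1, n):
            y = np.log(np.clip(vcd[i : j + 1], 1e-12, None))
            x = day[i : j + 1]
            coef = np.polyfit(x, y, 1)
            resid = y - np.polyval(coef, x)
            ss_tot = float(((y - y.mean()) ** 2).sum())
            r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
            if r2 >= min_r2 and coef[0] > 0:
                if best is None or (x[-1] - x[0]) > (best[1] - best[0]):
                    best = (float(x[0]), float(x[-1]))
    if best is None:
        raise ValueError("no log-linear growth interval found")
    return best
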