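"""Retention-index calibration from an n-alkane ladder.

Retention indices normalise retention times to the C8-C40 n-alkane ladder
(RI(Cn) = 100 n). Because the oven is temperature-programmed, the linear
(van den Dool & Kratz) definition is used rather than the isothermal
logarithmic one:

    RI(rt) = 100 * (n + (rt - rt_n) / (rt_{n+1} - rt_n))

for rt between the anchors of Cn and Cn+1. Outside the ladder the terminal
segment is extrapolated linearly and the value is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import RT_CAL_COLUMNS, RTCalibrationTable

__all__ = ["RICalibration", "calibrate", "compute_ri", "ri_delta", "ri_to_rt"]


@dataclass
class RICalibration:
    """Ordered (carbon number, retention time in seconds) anchors."""

    carbon_numbers: np.ndarray
    rt_s: np.ndarray

    def __post_init__(self) -> None:
        self.carbon_numbers = np.asarray(self.carbon_numbers, dtype=float)
        self.rt_s = np.asarray(self.rt_s, dtype=float)
        if self.carbon_numbers.size < 2:
            raise ValueError("calibration needs at least 2 anchors")
        order = np.argsort(self.carbon_numbers)
        self.carbon_numbers = self.carbon_numbers[order]
        self.rt_s = self.rt_s[order]
        if np.any(np.diff(self.carbon_numbers) == 0):
            raise ValueError("duplicate carbon numbers in calibration")
        if np.any(np.diff(self.rt_s) <= 0):
            raise ValueError("retention times must increase strictly with carbon number")

    @property
    def rt_range(self) -> tuple[float, float]:
        return float(self.rt_s[0]), float(self.rt_s[-1])


def calibrate(source) -> RICalibration:
    """Build a calibration from an RT-calibration table, deconvolved alkane
    components, or explicit (carbon number, rt seconds) pairs.

    Components (objects with ``apex_rt``) are assumed to be the alkane ladder
    in elution order starting at C8.
    """
    if isinstance(source, RTCalibrationTable):
        return RICalibration(source.carbon_numbers, source.rt_seconds)
    source = list(source)
    if source and hasattr(source[0], "apex_rt"):
        rts = sorted(float(c.apex_rt) for c in source)
        ns = np.arange(8, 8 + len(rts), dtype=float)
        return RICalibration(ns, np.asarray(rts))
    arr = np.asarray(source, dtype=float)
    return RICalibration(arr[:, 0], arr[:, 1])


def compute_ri(rt_s: float, cal: RICalibration, return_flag: bool = False):
    """Linear retention index of a retention time (seconds).

    With ``return_flag`` the result is ``(ri, extrapolated)`` where
    ``extrapolated`` marks values outside the ladder's RT span.
    """
    n = np.interp(rt_s, cal.rt_s, cal.carbon_numbers)
    lo, hi = cal.rt_range
    extrapolated = bool(rt_s < lo or rt_s > hi)
    if rt_s < lo:
        slope = (cal.carbon_numbers[1] - cal.carbon_numbers[0]) / (cal.rt_s[1] - cal.rt_s[0])
        n = cal.carbon_numbers[0] + slope * (rt_s - cal.rt_s[0])
    elif rt_s > hi:
        slope = (cal.carbon_numbers[-1] - cal.carbon_numbers[-2]) / (
            cal.rt_s[-1] - cal.rt_s[-2]
        )
        n = cal.carbon_numbers[-1] + slope * (rt_s - cal.rt_s[-1])
    ri = float(100.0 * n)
    return (ri, extrapolated) if return_flag else ri


def ri_to_rt(ri: float, cal: RICalibration) -> float:
    """Inverse of :func:`compute_ri` (piecewise linear, extrapolating)."""
    n = ri / 100.0
    lo, hi = cal.carbon_numbers[0], cal.carbon_numbers[-1]
    if n < lo:
        slope = (cal.rt_s[1] - cal.rt_s[0]) / (cal.carbon_numbers[1] - cal.carbon_numbers[0])
        return float(cal.rt_s[0] + slope * (n - lo))
    if n > hi:
        slope = (cal.rt_s[-1] - cal.rt_s[-2]) / (
            cal.carbon_numbers[-1] - cal.carbon_numbers[-2]
        )
        return float(cal.rt_s[-1] + slope * (n - hi))
    return float(np.interp(n, cal.carbon_numbers, cal.rt_s))


def ri_delta(component_ri: float | None, library_ri: float | None) -> float | None:
    """|RI difference|, or None when either side lacks an RI (the
    identification gate then falls back to spectrum + mass accuracy only)."""
    if component_ri is None or library_ri is None:
        return None
    return abs(float(component_ri) - float(library_ri))


def to_rt_calibration_table(cal: RICalibration) -> RTCalibrationTable:
    """Render a calibration as the four-column CSV table."""
    import pandas as pd

    n = cal.carbon_numbers.astype(int)
    df = pd.DataFrame(
        {
            RT_CAL_COLUMNS[0]: [f"C{k} alkane" for k in n],
            RT_CAL_COLUMNS[1]: ["" for _ in n],
            RT_CAL_COLUMNS[2]: (cal.carbon_numbers * 100).astype(float),
            RT_CAL_COLUMNS[3]: cal.rt_s / 60.0,
        }
    )
    return RTCalibrationTable(table=df)
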