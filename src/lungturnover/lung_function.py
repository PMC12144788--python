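"""Cumulative lung-function change and its power-law rate b.

Lung function is tracked as %FEV1 (forced expiratory volume in one second,
percent of predicted). Cumulative absolute change between consecutive
non-missing timepoints is fitted against elapsed time in days with the power
model ``dFEV1 = a * T**b``; b is the rate of change of lung function with
time. Missing spirometry values are skipped and differences bridged across
the gap, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .turnover import PowerFit, fit_power


@dataclass(frozen=True)
class LungFunctionCurve:
    """Running sum of |consecutive %FEV1 change| vs elapsed days.

    Day 0 is the first sample with a non-missing %FEV1; the curve starts at 0
    there and is non-decreasing.
    """

    days: np.ndarray
    cumulative_change: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cumulative_change) < 0):
            raise ValueError("cumulative change must be non-decreasing")


def cumulative_abs_change(
    days: np.ndarray, fev1: np.ndarray
) -> LungFunctionCurve | None:
    """Cumulative absolute %FEV1 change over non-missing timepoints.

    ``days`` are elapsed days on any anchor (re-anchored internally to the
    first usable timepoint); NaNs in ``fev1`` are skipped. Returns None when
    fewer than 3 non-missing values exist (insufficient lung-function data).
    """
    days = np.asarray(days, dtype=float)
    fev1 = np.asarray(fev1, dtype=float)
    ok = ~np.isnan(fev1)
    if ok.sum() < 3:
        return None
    d = days[ok]
    v = fev1[ok]
    cum = np.concatenate([[0.0], np.cumsum(np.abs(np.diff(v)))])
    return LungFunctionCurve(days=d - d[0], cumulative_change=cum)


def fit_lft(curve: LungFunctionCurve | None) -> PowerFit | None:
    """Power fit of cumulative |change| against days.

    Only points with strictly positive elapsed days *and* strictly positive
    cumulative change enter the log-log fit (the anchor point at day 0 /
    change 0 is excluded by construction). A flat curve (no change at all)
    yields the degenerate b = 0 convention; otherwise fewer than 3 usable
    points yields None ("insufficient").
    """
    if curve is None:
        return None
    pos = (curve.days > 0) & (curve.cumulative_change > 0)
    if pos.sum() < 3:
        if np.all(curve.cumulative_change == 0):
            return PowerFit(
                c=0.0,
                exponent=0.0,
                r_squared=1.0,
                f_stat=float("nan"),
                df_num=1,
                df_den=max(len(curve.days) - 2, 0),
                p_value=float("nan"),
                n_points=len(curve.days),
                degenerate=True,
            )
        return None
    return fit_power(curve.days[pos], curve.cumulative_change[pos])
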