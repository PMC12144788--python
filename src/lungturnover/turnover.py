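"""Species-time relationships (STRs) and the temporal-turnover exponent w.

The STR describes how observed taxon richness S accumulates with observation
time T and is modelled by the power law ``S = c * T**w``; the exponent w is
the temporal scaling (turnover) exponent. Curves are constructed with the
moving-window method: for every window length L, cumulative richness (the
number of distinct taxa detected at least once inside the window) is averaged
over all contiguous windows of that length. Unlike one-direction (nested)
accumulation, this construction reflects immigration, local extinction and
recolonization symmetrically along the series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CohortConfig, PatientSeries


@dataclass(frozen=True)
class StrCurve:
    """Moving-window mean cumulative richness per window length."""

    window_lengths: np.ndarray  # 1..N
    mean_richness: np.ndarray
    n_windows: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.mean_richness) < -1e-9):
            raise ValueError("mean cumulative richness must be non-decreasing")


@dataclass(frozen=True)
class PowerFit:
    """Power-law fit ``y = c * x**exponent`` via OLS on (log x, log y).

    The same container serves STR fits (exponent = w), persistence-style
    fits, and lung-function fits (exponent = b). ``degenerate`` marks the
    all-y-equal convention where the exponent is 0 by definition and no
    regression test applies (p reported as NaN).
    """

    c: float
    exponent: float
    r_squared: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    n_points: int
    degenerate: bool = False


def accumulate_moving_window(presence: np.ndarray) -> StrCurve:
    """Moving-window species accumulation over a boolean taxa x samples matrix.

    For each window length ``L`` in ``1..N`` the cumulative richness of every
    contiguous window of that length (the size of the union of the taxa
    present in its samples) is averaged over all ``N - L + 1`` windows.
    """
    presence = np.asarray(presence, dtype=bool)
    if presence.ndim != 2 or presence.size == 0:
        raise ValueError("presence matrix must be a non-empty 2-D array")
    n_taxa, n = presence.shape
    if n < 2:
        raise ValueError("moving-window accumulation requires >= 2 samples")
    if not presence.any():
        raise ValueError("no taxon is present in any sample")
    lengths = np.arange(1, n + 1)
    mean_rich = np.empty(n, dtype=float)
    n_windows = n - lengths + 1
    # cumulative "ever seen by sample j" counts per window start, built
    # incrementally: union over window [i, i+L) as a running boolean OR.
    for L in lengths:
        total = 0
        for start in range(n - L + 1):
            total += int(presence[:, start : start + L].any(axis=1).sum())
        mean_rich[L - 1] = total / (n - L + 1)
    return StrCurve(window_lengths=lengths, mean_richness=mean_rich, n_windows=n_windows)


def fit_power(x: np.ndarray, y: np.ndarray) -> PowerFit:
    """Fit ``y = c * x**exponent`` by OLS on natural-log transformed data.

    Requires >= 3 strictly positive (x, y) points. When all y are identical
    the fit is bypassed: exponent 0, c = y, R² = 1 by convention and p = NaN
    ("no turnover" is the correct ecological reading, not an error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("power fit requires at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power fit requires strictly positive x and y")
    if np.ptp(y) == 0:
        return PowerFit(
            c=float(y[0]),
            exponent=0.0,
            r_squared=1.0,
            f_stat=float("nan"),
            df_num=1,
            df_den=len(x) - 2,
            p_value=float("nan"),
            n_points=len(x),
            degenerate=True,
        )
    res = stats.linregress(np.log(x), np.log(y))
    f = np.inf if res.stderr == 0 else (res.slope / res.stderr) ** 2
    return PowerFit(
        c=float(np.exp(res.intercept)),
        exponent=float(res.slope),
        r_squared=float(res.rvalue**2),
        f_stat=float(f),
        df_num=1,
        df_den=len(x) - 2,
        p_value=float(res.pvalue),
        n_points=len(x),
    )


def window_times(
    curve: StrCurve,
    unit: str = "sample_count",
    days: np.ndarray | None = None,
) -> np.ndarray:
    """Time axis T for fitting an STR curve.

    ``sample_count`` uses the ordinal window length. ``days`` maps each
    length L to the mean duration spanned by windows of that length plus one
    mean inter-sample interval, so length-1 windows carry a positive T and a
    perfectly even schedule reproduces the ordinal axis up to a constant
    factor.
    """
    if unit == "sample_count":
        return curve.window_lengths.astype(float)
    if unit != "days":
        raise ValueError("unit must be 'sample_count' or 'days'")
    if days is None:
        raise ValueError("days mode requires per-sample elapsed days")
    days = np.asarray(days, dtype=float)
    n = len(days)
    mean_interval = (days[-1] - days[0]) / (n - 1)
    out = np.empty(n, dtype=float)
    for L in curve.window_lengths:
        spans = days[L - 1 :] - days[: n - L + 1]
        out[L - 1] = spans.mean() + mean_interval
    return out


def compute_str(
    series: PatientSeries,
    subset: str,
    labels: dict[str, str],
    config: CohortConfig | None = None,
) -> PowerFit | None:
    """Whole-series STR power fit for one patient and taxon subset.

    ``subset`` is ``"whole"``, ``"chronic"`` or ``"intermittent"``; subset
    membership comes from whole-series colonization ``labels``. Returns None
    for an empty subset (e.g. a patient with no chronic taxa) rather than
    raising.
    """
    config = config or CohortConfig()
    if subset == "whole":
        keep = np.ones(series.n_taxa, dtype=bool)
    elif subset in ("chronic", "intermittent"):
        keep = np.array([labels.get(t) == subset for t in series.taxon_ids])
    else:
        raise ValueError(f"unknown subset {subset!r}")
    presence = series.presence(config.presence_threshold)[keep]
    if presence.size == 0 or not presence.any():
        return None
    curve = accumulate_moving_window(presence)
    x = window_times(curve, config.str_time_unit, days=series.days_from_start())
    return fit_power(x, curve.mean_richness)
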