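"""Sliding-quadrat profiling of turnover and lung-function rates.

A temporal "quadrat" of ``quadrat_size`` consecutive timepoints (default 5)
slides one timepoint at a time along a patient's series. Inside each quadrat
a local STR is built by moving-window accumulation over the quadrat's
samples (sub-window lengths 1..quadrat_size, ordinal time axis) and its
power-law exponent gives the local turnover ``w_local``; the quadrat's
%FEV1 values likewise give a local lung-function rate ``b_local`` where
enough positive cumulative change exists. Values are indexed to the middle
timepoint of each quadrat, carrying its date and BETR disease state, so that
turnover excursions can be read against the clinical timeline.

Profiling uses the whole-microbiota presence matrix; chronic/intermittent
membership never varies across quadrats. Note that the whole-series w is not
a mean of the w_local values: the two are fitted on different window-length
ranges and are related only qualitatively.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CohortConfig, PatientSeries
from .turnover import accumulate_moving_window, fit_power, window_times


@dataclass(frozen=True)
class FineScalePoint:
    midpoint_index: int
    midpoint_date: _dt.date
    disease_state: str
    w_local: float
    b_local: float | None


@dataclass
class FineScaleSeries:
    """Per-midpoint local turnover/lung-function profile for one patient.

    ``status`` is ``"ok"`` or ``"series_too_short"`` (fewer samples than one
    quadrat); in the latter case ``points`` is empty.
    """

    patient_id: str
    quadrat_size: int
    points: list[FineScalePoint] = field(default_factory=list)
    status: str = "ok"

    def w_values(self) -> np.ndarray:
        return np.array([p.w_local for p in self.points], dtype=float)

    def peak_w(self) -> float:
        if not self.points:
            raise ValueError("no fine-scale points")
        return float(self.w_values().max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": self.patient_id,
                    "midpoint_index": p.midpoint_index,
                    "midpoint_date": p.midpoint_date.isoformat(),
                    "disease_state": p.disease_state,
                    "w_local": p.w_local,
                    "b_local": np.nan if p.b_local is None else p.b_local,
                }
                for p in self.points
            ]
        )


def sliding_quadrat(
    series: PatientSeries, config: CohortConfig | None = None
) -> FineScaleSeries:
    """Profile w_local (and b_local when available) along the series.

    Produces ``N - quadrat_size + 1`` points ordered by midpoint date. Local
    fits use the ordinal sub-window axis by default (``config.str_time_unit``
    applies); negative w_local values from noisy quadrat fits are preserved,
    never clipped. ``b_local`` is absent unless the quadrat holds at least 3
    strictly positive cumulative-change points.
    """
    config = config or CohortConfig()
    q = config.quadrat_size
    out = FineScaleSeries(patient_id=series.patient_id, quadrat_size=q)
    if series.n_samples < q:
        out.status = "series_too_short"
        return out
    presence = series.presence(config.presence_threshold)
    days = series.days_from_start()
    mid_offset = q // 2
    from .lung_function import cumulative_abs_change, fit_lft

    for start in range(series.n_samples - q + 1):
        sl = slice(start, start + q)
        curve = accumulate_moving_window(presence[:, sl])
        x = window_times(curve, config.str_time_unit, days=days[sl])
        w_fit = fit_power(x, curve.mean_richness)
        lf_curve = cumulative_abs_change(days[sl], series.fev1_percent[sl])
        b_fit = fit_lft(lf_curve)
        b_local = (
            b_fit.exponent if (b_fit is not None and not b_fit.degenerate) else None
        )
        mid = start + mid_offset
        out.points.append(
            FineScalePoint(
                midpoint_index=mid,
                midpoint_date=series.sample_dates[mid],
                disease_state=series.disease_state[mid],
                w_local=w_fit.exponent,
                b_local=b_local,
            )
        )
    return out
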