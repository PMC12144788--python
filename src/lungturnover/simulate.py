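"""Synthetic longitudinal CF-like cohorts with recorded ground truth.

The generator emulates the statistical structure the analysis assumes: each
patient carries a chronic core of high-persistence, high-abundance taxa
(including one dominant pathogen) plus a large pool of rare, intermittently
detected satellite taxa whose per-sample detection counts follow a Poisson
immigration process. Patients that undergo a pulmonary exacerbation (PEx)
receive a BETR disease-state schedule, an immigration burst (rate multiplied
by kappa) that switches on at a known onset day before treatment, and a
%FEV1 trajectory whose absolute changes co-vary with realized turnover when
coupling is enabled. Ground truth (onset day, burst rates, chronic set) is
recorded alongside but never consumed by the analysis modules.

All randomness flows from one cohort seed through per-patient spawned
seeds, so cohorts are reproducible and stable under patient reordering.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    PatientSeries,
    write_sample_metadata,
    write_taxon_table,
)

_START_DATE = _dt.date(2010, 1, 6)


@dataclass
class GeneratorParams:
    """Study-condition knobs for synthetic cohorts.

    Defaults reproduce the cohort regime the analysis is designed for:
    12 patients of whom 2 never exacerbate; PEx patients sampled 16-35 times
    over roughly 220-370 days, non-PEx comparison patients sampled sparsely
    (6-9 samples over ~300-313 days); a 12-taxon chronic core detected with
    probability 0.9 per sample; a 90-taxon intermittent pool with a baseline
    immigration rate of 2 expected detections per sample, multiplied by
    ``burst_multiplier`` from ``onset_lead_days`` before treatment start
    until treatment end.
    """

    n_patients: int = 12
    n_no_pex: int = 2
    n_samples_mean: float = 22.2
    n_samples_sd: float = 5.1
    n_samples_range: tuple[int, int] = (16, 35)
    series_days_mean: float = 315.9
    series_days_sd: float = 42.7
    series_days_range: tuple[int, int] = (221, 368)
    no_pex_n_samples_range: tuple[int, int] = (6, 9)
    no_pex_series_days_range: tuple[int, int] = (300, 313)
    n_chronic_taxa: int = 12
    chronic_presence_prob: float = 0.9
    chronic_abundance_scale: float = 3.0
    dominant_abundance_scale: float = 50.0
    intermittent_pool_size: int = 90
    intermittent_pool_min: int = 60  # per-patient accessible pool drawn in [min, size]
    intermittent_abundance_scale: float = 0.3
    baseline_immigration_rate: float = 2.0
    baseline_rate_jitter: float = 0.3
    burst_multiplier: float = 8.0
    burst_multiplier_jitter: float = 0.8
    onset_lead_days: float = 21.0
    exacerbation_window_days: float = 30.0
    recovery_window_days: float = 30.0
    treatment_start_frac: tuple[float, float] = (0.45, 0.65)
    treatment_duration_range: tuple[float, float] = (10.0, 18.0)
    exacerbation_sampling_boost: float = 1.0  # >1 densifies clinic visits inside E u T
    fev1_baseline_mean: float = 50.0
    fev1_baseline_sd: float = 17.0
    fev1_baseline_range: tuple[float, float] = (22.0, 85.0)
    fev1_noise_sd: float = 0.3
    fev1_decline_per_day: float = 0.5
    fev1_recovery_per_day: float = 0.7
    fev1_missing_prob: float = 0.08
    fev1_resolution: float = 0.25  # spirometry recording resolution; 0 = raw
    coupling_on: bool = True
    coupling_coefficient: float = 1.2
    coupling_threshold: float = 3.0  # new-taxon excess below this leaves %FEV1 unmoved
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.chronic_presence_prob <= 1.0:
            raise ValueError("chronic_presence_prob must lie in [0, 1]")
        if self.baseline_immigration_rate < 0:
            raise ValueError("immigration rate must be >= 0")
        if self.burst_multiplier < 1:
            raise ValueError("burst multiplier kappa must be >= 1")
        if self.onset_lead_days > self.exacerbation_window_days:
            raise ValueError(
                "infeasible schedule: onset precedes the exacerbation window "
                f"({self.onset_lead_days} > {self.exacerbation_window_days} days "
                "before treatment start)"
            )
        if self.onset_lead_days < 0:
            raise ValueError("infeasible schedule: onset after treatment start")


def _taxon_names(params: GeneratorParams) -> list[str]:
    core = [f"core_{i + 1:02d}" for i in range(params.n_chronic_taxa)]
    sats = [f"sat_{i + 1:02d}" for i in range(params.intermittent_pool_size)]
    return core + sats


def _sample_days(
    rng: np.random.Generator,
    n: int,
    span: float,
    dense_interval: tuple[float, float] | None = None,
    boost: float = 1.0,
) -> np.ndarray:
    """Strictly increasing integer day offsets covering ``span`` days.

    Jittered near-regular spacing; when ``dense_interval`` is given, visit
    density inside it is multiplied by ``boost`` (a time-warp of the same
    jittered grid), mimicking intensified surveillance around an
    exacerbation.
    """
    intervals = rng.gamma(shape=8.0, scale=1.0, size=n - 1)
    grid = np.concatenate([[0.0], np.cumsum(intervals)])
    grid /= grid[-1]
    if dense_interval is not None and boost != 1.0:
        a, b = dense_interval
        a, b = max(0.0, a), min(span, b)
        total = span + (boost - 1.0) * (b - a)
        m = grid * total
        days_f = np.where(
            m < a,
            m,
            np.where(m <= a + boost * (b - a), a + (m - a) / boost, m - (boost - 1.0) * (b - a)),
        )
    else:
        days_f = grid * span
    days = np.round(days_f).astype(int)
    for i in range(1, n):
        if days[i] <= days[i - 1]:
            days[i] = days[i - 1] + 1
    return days


def generate_patient(
    params: GeneratorParams,
    patient_id: str,
    seed: np.random.SeedSequence | int,
    no_pex: bool = False,
) -> tuple[PatientSeries, dict]:
    """Simulate one patient; returns the series and its ground-truth record."""
    rng = np.random.default_rng(seed)
    if no_pex:
        lo, hi = params.no_pex_n_samples_range
        n = int(rng.integers(lo, hi + 1))
        lo_d, hi_d = params.no_pex_series_days_range
        span = float(rng.uniform(lo_d, hi_d))
    else:
        n = int(
            np.clip(
                round(rng.normal(params.n_samples_mean, params.n_samples_sd)),
                *params.n_samples_range,
            )
        )
        span = float(
            np.clip(
                rng.normal(params.series_days_mean, params.series_days_sd),
                *params.series_days_range,
            )
        )
    # BETR schedule (drawn before the visit days so that surveillance can
    # densify around the exacerbation window)
    if no_pex:
        onset_day = treat_start = treat_end = None
        kappa = 1.0
        days = _sample_days(rng, n, span)
        states = ["B0"] * n
    else:
        treat_start = float(np.round(rng.uniform(*params.treatment_start_frac) * span))
        treat_end = treat_start + float(np.round(rng.uniform(*params.treatment_duration_range)))
        onset_day = treat_start - params.onset_lead_days
        if onset_day > treat_start:
            raise ValueError("infeasible schedule: onset after treatment start")
        jit = params.burst_multiplier_jitter
        kappa = params.burst_multiplier * float(rng.uniform(1.0 - jit, 1.0 + jit))
        kappa = max(kappa, 1.0)
        e_start = treat_start - params.exacerbation_window_days
        r_end = treat_end + params.recovery_window_days
        days = _sample_days(
            rng,
            n,
            span,
            dense_interval=(e_start, treat_end),
            boost=params.exacerbation_sampling_boost,
        )
        states = []
        for d in days:
            if d < e_start:
                states.append("B0")
            elif d < treat_start:
                states.append("E")
            elif d <= treat_end:
                states.append("T")
            elif d <= r_end:
                states.append("R")
            else:
                states.append("B1")

    taxa = _taxon_names(params)
    n_core = params.n_chronic_taxa
    pool = params.intermittent_pool_size
    abundance = np.zeros((len(taxa), n), dtype=float)

    # chronic core: i.i.d. presence, lognormal abundance, taxon 1 dominant
    core_scale = np.full(n_core, params.chronic_abundance_scale)
    if n_core:
        core_scale[0] = params.dominant_abundance_scale
    core_present = rng.random((n_core, n)) < params.chronic_presence_prob
    core_present[0, :] = True  # the dominant pathogen is never lost
    core_values = core_scale[:, None] * rng.lognormal(0.0, 0.5, size=(n_core, n))
    abundance[:n_core] = np.where(core_present, core_values, 0.0)

    # intermittent satellites: Poisson immigration, bursts inside E u T.
    # Interpatient variability enters through the per-patient baseline rate
    # and the size of the satellite pool the patient can draw from (patients
    # differ widely in how many distinct rare taxa ever visit their airways).
    rj = params.baseline_rate_jitter
    base_rate = params.baseline_immigration_rate * float(rng.uniform(1.0 - rj, 1.0 + rj))
    pool_size = int(rng.integers(params.intermittent_pool_min, pool + 1))
    active_pool = rng.choice(pool, size=pool_size, replace=False)
    lam = np.full(n, base_rate, dtype=float)
    if not no_pex:
        burst = (days >= onset_day) & (days <= treat_end)
        lam[burst] *= kappa
    seen = np.zeros(pool, dtype=bool)
    novel_count = np.zeros(n, dtype=int)
    for j in range(n):
        k = int(min(rng.poisson(lam[j]), pool_size))
        if k == 0:
            continue
        picks = active_pool[rng.choice(pool_size, size=k, replace=False)]
        novel_count[j] = int(np.sum(~seen[picks]))
        seen[picks] = True
        abundance[n_core + picks, j] = params.intermittent_abundance_scale * rng.lognormal(
            0.0, 1.0, size=k
        )

    # %FEV1 trajectory. With coupling on, lung function tracks the disease
    # course: an exacerbation decline from onset, recovery under treatment,
    # and excursions proportional to the realized new-taxon count, on top of
    # observation noise. With coupling off the trajectory is stationary
    # noise around the baseline (a true null for turnover/lung-function
    # association tests).
    baseline = float(
        np.clip(
            rng.normal(params.fev1_baseline_mean, params.fev1_baseline_sd),
            *params.fev1_baseline_range,
        )
    )
    mu = np.full(n, baseline)
    if not no_pex and params.coupling_on:
        for j, d in enumerate(days):
            if onset_day <= d < treat_start:
                mu[j] = baseline - params.fev1_decline_per_day * (d - onset_day)
            elif d >= treat_start:
                nadir = baseline - params.fev1_decline_per_day * (treat_start - onset_day)
                mu[j] = min(
                    baseline,
                    nadir + params.fev1_recovery_per_day * (d - treat_start),
                )
    fev1 = mu + rng.normal(0.0, params.fev1_noise_sd, size=n)
    if params.coupling_on:
        # colonization waves well above the patient's norm depress that
        # visit's %FEV1, so cumulative lung-function change tracks realized
        # turnover; ordinary immigration fluctuation stays below threshold
        excess = np.maximum(0.0, novel_count - base_rate - params.coupling_threshold)
        fev1 = fev1 - params.coupling_coefficient * excess
    if params.fev1_resolution > 0:
        fev1 = np.round(fev1 / params.fev1_resolution) * params.fev1_resolution
    missing = rng.random(n) < params.fev1_missing_prob
    if (~missing).sum() < 3:  # keep lung-function fits feasible
        missing[:3] = False
    fev1 = np.where(missing, np.nan, fev1)

    dates = [_START_DATE + _dt.timedelta(days=int(d)) for d in days]
    series = PatientSeries(
        patient_id=patient_id,
        sample_ids=[f"{patient_id}_S{j + 1:02d}" for j in range(n)],
        sample_dates=dates,
        abundance=abundance,
        taxon_ids=taxa,
        fev1_percent=fev1,
        disease_state=states,
        treatment_start_date=None
        if no_pex
        else _START_DATE + _dt.timedelta(days=int(treat_start)),
        treatment_end_date=None
        if no_pex
        else _START_DATE + _dt.timedelta(days=int(treat_end)),
    ).normalized()
    series.validate()
    truth = {
        "patient_id": patient_id,
        "no_pex": no_pex,
        "n_samples": n,
        "series_days": span,
        "mean_interval_days": span / (n - 1),
        "true_onset_day": np.nan if no_pex else float(onset_day),
        "treatment_start_day": np.nan if no_pex else float(treat_start),
        "treatment_end_day": np.nan if no_pex else float(treat_end),
        "kappa": kappa,
        "baseline_immigration_rate": base_rate,
        "pool_size": pool_size,
        "coupling_on": params.coupling_on,
        "chronic_taxa": ";".join(taxa[:n_core]),
    }
    return series, truth


@dataclass
class SyntheticCohort:
    params: GeneratorParams
    patients: dict[str, PatientSeries]
    ground_truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> list[Path]:
        """Write per-patient taxon tables, cohort metadata, and ground truth.

        Emits exactly the external formats the core readers accept; the
        ground-truth file is separate and never read by the analysis path.
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        meta_rows = []
        for pid, series in self.patients.items():
            detected = series.abundance.sum(axis=1) > 0
            table = pd.DataFrame(
                series.abundance[detected],
                index=[t for t, d in zip(series.taxon_ids, detected) if d],
                columns=series.sample_ids,
            )
            p = out_dir / f"taxon_table_{pid}.tsv"
            write_taxon_table(table, p)
            written.append(p)
            for j in range(series.n_samples):
                meta_rows.append(
                    {
                        "patient_id": pid,
                        "sample_id": series.sample_ids[j],
                        "date": series.sample_dates[j],
                        "fev1_percent": series.fev1_percent[j],
                        "disease_state": series.disease_state[j],
                        "treatment_start": series.treatment_start_date,
                        "treatment_end": series.treatment_end_date,
                    }
                )
        meta = pd.DataFrame(meta_rows)
        meta_path = out_dir / "sample_metadata.csv"
        write_sample_metadata(meta, meta_path)
        written.append(meta_path)
        gt_path = out_dir / "ground_truth.tsv"
        self.ground_truth.to_csv(gt_path, sep="\t", index=False, float_format="%.12g")
        written.append(gt_path)
        return written


def generate_cohort(params: GeneratorParams | None = None) -> SyntheticCohort:
    """Simulate a full cohort; deterministic under ``params.rng_seed``."""
    params = params or GeneratorParams()
    root = np.random.SeedSequence(params.rng_seed)
    child_seeds = root.spawn(params.n_patients)
    patients: dict[str, PatientSeries] = {}
    truths = []
    # the last n_no_pex patients are the non-exacerbating comparators
    for i in range(params.n_patients):
        pid = f"SP{i + 1:02d}"
        no_pex = i >= params.n_patients - params.n_no_pex
        series, truth = generate_patient(params, pid, child_seeds[i], no_pex=no_pex)
        patients[pid] = series
        truths.append(truth)
    return SyntheticCohort(
        params=params,
        patients=patients,
        ground_truth=pd.DataFrame(truths),
    )
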