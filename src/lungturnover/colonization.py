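"""Chronic/intermittent colonization classification and persistence-abundance fits.

A taxon's *temporal persistence* is the fraction of a patient's samples in
which it is detected. Under the modified Leeds criterion a patient is
considered chronically colonized by a taxon with persistence strictly greater
than 50%, and intermittently colonized otherwise. The persistence-abundance
relationship (PAR) regresses log10 mean relative abundance (over the samples
where the taxon was detected) on persistence; in CF lung microbiota these
relationships are characteristically positive: persistent taxa are common,
infrequent taxa are rare.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CohortConfig, PatientSeries


@dataclass(frozen=True)
class ColonizationProfile:
    """Per-taxon temporal persistence and abundance summary for one patient."""

    taxon_id: str
    n_detected: int
    n_samples: int
    persistence: float
    mean_abundance_when_present: float
    label: str  # "chronic" | "intermittent"


@dataclass(frozen=True)
class ParFit:
    """OLS fit of log10 mean abundance (when present) on persistence."""

    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    n_taxa: int


def compute_persistence(
    series: PatientSeries, config: CohortConfig | None = None
) -> list[ColonizationProfile]:
    """Profile every taxon detected at least once in the series.

    Persistence and the chronic/intermittent label are computed over the
    whole series; never-detected taxa are excluded.
    """
    config = config or CohortConfig()
    if series.n_samples < 2:
        raise ValueError("persistence requires at least 2 samples")
    present = series.presence(config.presence_threshold)
    n_samples = series.n_samples
    profiles = []
    for i, taxon in enumerate(series.taxon_ids):
        n_det = int(present[i].sum())
        if n_det == 0:
            continue
        persistence = n_det / n_samples
        mean_ab = float(series.abundance[i, present[i]].mean())
        label = (
            "chronic"
            if persistence > config.chronic_persistence_cutoff
            else "intermittent"
        )
        profiles.append(
            ColonizationProfile(
                taxon_id=taxon,
                n_detected=n_det,
                n_samples=n_samples,
                persistence=persistence,
                mean_abundance_when_present=mean_ab,
                label=label,
            )
        )
    return profiles


def fit_par(
    profiles: list[ColonizationProfile], log_persistence: bool = False
) -> ParFit:
    """Fit the persistence-abundance relationship by ordinary least squares.

    ``log_persistence`` switches the predictor from the raw persistence
    fraction to log10 persistence. A positive slope is reported, never
    assumed.
    """
    if len(profiles) < 3:
        raise ValueError("PAR fit requires at least 3 taxon profiles")
    x = np.array([p.persistence for p in profiles], dtype=float)
    if log_persistence:
        x = np.log10(x)
    y = np.log10([p.mean_abundance_when_present for p in profiles])
    if np.ptp(x) == 0:
        raise ValueError("PAR fit undefined: zero variance in persistence")
    res = stats.linregress(x, y)
    n = len(profiles)
    r2 = res.rvalue**2
    f = np.inf if res.stderr == 0 else (res.slope / res.stderr) ** 2
    return ParFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        f_stat=float(f),
        df_num=1,
        df_den=n - 2,
        p_value=float(res.pvalue),
        n_taxa=n,
    )


def count_by_label(profiles: list[ColonizationProfile]) -> tuple[int, int]:
    """Return (n_chronic, n_intermittent); the two counts partition the taxa."""
    n_chronic = sum(1 for p in profiles if p.label == "chronic")
    return n_chronic, len(profiles) - n_chronic


def labels_by_taxon(profiles: list[ColonizationProfile]) -> dict[str, str]:
    return {p.taxon_id: p.label for p in profiles}


def profiles_to_frame(profiles: list[ColonizationProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon_id": p.taxon_id,
                "n_detected": p.n_detected,
                "n_samples": p.n_samples,
                "persistence": p.persistence,
                "mean_abundance": p.mean_abundance_when_present,
                "label": p.label,
            }
            for p in profiles
        ]
    )
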