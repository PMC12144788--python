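"""Cohort-level inference: group comparisons of w and b-on-w regressions.

Turnover exponents are compared between taxon subsets (whole / chronic /
intermittent) with the tie-corrected Kruskal-Wallis test followed by Dunn's
post-hoc pairwise z tests on pooled ranks. The rate of lung-function change
b is linearly regressed on the turnover exponent w across patients. All
p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    z: float
    p_value: float
    p_adjusted: float


@dataclass
class GroupComparison:
    """Kruskal-Wallis H with optional Dunn post-hoc pairwise results."""

    h_stat: float
    p_value: float
    group_labels: list[str]
    group_sizes: list[int]
    pairwise: list[PairwiseResult] = field(default_factory=list)


def kruskal_wallis(
    groups: list[np.ndarray], labels: list[str] | None = None
) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with a chi-square (k-1 df) p-value.

    Identical pooled values across all groups yield H = 0, p = 1 rather than
    scipy's all-ties error.
    """
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    labels = labels or [f"group{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return GroupComparison(
            h_stat=0.0, p_value=1.0, group_labels=list(labels),
            group_sizes=[len(g) for g in groups],
        )
    h, p = stats.kruskal(*groups)
    return GroupComparison(
        h_stat=float(h),
        p_value=float(p),
        group_labels=list(labels),
        group_sizes=[len(g) for g in groups],
    )


def dunn_posthoc(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    adjustment: str = "bonferroni",
) -> list[PairwiseResult]:
    """Dunn's pairwise z statistics from pooled ranks, with tie correction.

    For groups i, j with mean pooled ranks Rbar_i, Rbar_j over N pooled
    values,

        z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - C) (1/n_i + 1/n_j))

    where C = sum(t^3 - t) / (12 (N - 1)) over tie-group sizes t. Two-sided
    normal p-values; ``adjustment`` is "none", "bonferroni" (p_adj =
    min(1, m p)) or "holm".
    """
    if len(groups) < 2:
        raise ValueError("Dunn test requires at least 2 groups")
    if adjustment not in ("none", "bonferroni", "holm"):
        raise ValueError("adjustment must be none|bonferroni|holm")
    groups = [np.asarray(g, dtype=float) for g in groups]
    labels = labels or [f"group{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_term = n_total * (n_total + 1) / 12.0 - tie_corr
    results = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = float(2 * stats.norm.sf(abs(z)))
            results.append((labels[i], labels[j], float(z), p))
    raw_p = [r[3] for r in results]
    if adjustment == "none":
        adj = raw_p
    else:
        adj = multipletests(raw_p, method=adjustment)[1]
    return [
        PairwiseResult(a, b, z, p, float(pa))
        for (a, b, z, p), pa in zip(results, adj)
    ]


def compare_groups(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    adjustment: str = "bonferroni",
) -> GroupComparison:
    """Kruskal-Wallis followed by Dunn's post-hoc in one call."""
    comp = kruskal_wallis(groups, labels)
    comp.pairwise = dunn_posthoc(groups, labels, adjustment)
    return comp


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    n_points: int


def regress_b_on_w(pairs: list[tuple[float, float]]) -> LinearFit:
    """OLS of the lung-function rate b on the turnover exponent w.

    ``pairs`` holds per-patient (w, b) tuples; standard F-test diagnostics
    with (1, n-2) degrees of freedom.
    """
    if len(pairs) < 3:
        raise ValueError("regression requires at least 3 (w, b) pairs")
    w = np.array([p[0] for p in pairs], dtype=float)
    b = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(w) == 0:
        raise ValueError("regression undefined: zero variance in w")
    res = stats.linregress(w, b)
    f = np.inf if res.stderr == 0 else (res.slope / res.stderr) ** 2
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        f_stat=float(f),
        df_num=1,
        df_den=len(pairs) - 2,
        p_value=float(res.pvalue),
        n_points=len(pairs),
    )


def _mean_sd(values: list[float]) -> dict[str, float]:
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if len(arr) == 0:
        return {"n": 0, "mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan}
    return {
        "n": int(len(arr)),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else np.nan,
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def summarize_cohort(
    str_fits: dict[str, dict[str, object]],
    label_counts: dict[str, tuple[int, int]],
    peak_w: dict[str, float] | None = None,
    onset_summary: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cohort summary table: mean +/- SD (n-1) of w per subset, taxa counts,
    peak fine-scale w, and lead days per threshold.

    ``str_fits`` maps patient -> subset -> PowerFit or None; an empty subset
    contributes no value and subsets with no values at all are flagged
    absent (n = 0).
    """
    rows = []
    for subset in ("whole", "chronic", "intermittent"):
        vals = []
        for fits in str_fits.values():
            fit = fits.get(subset)
            if fit is not None:
                vals.append(fit.exponent)
        rows.append({"statistic": f"w_{subset}", **_mean_sd(vals)})
    rows.append(
        {"statistic": "n_chronic_taxa", **_mean_sd([c[0] for c in label_counts.values()])}
    )
    rows.append(
        {
            "statistic": "n_intermittent_taxa",
            **_mean_sd([c[1] for c in label_counts.values()]),
        }
    )
    if peak_w:
        rows.append({"statistic": "peak_w", **_mean_sd(list(peak_w.values()))})
    out = pd.DataFrame(rows)
    if onset_summary is not None:
        extra = []
        for rec in onset_summary.to_dict("records"):
            extra.append(
                {
                    "statistic": f"lead_days_thr_{rec['threshold']:g}",
                    "n": rec["n_with_lead"],
                    "mean": rec["mean_lead_days"],
                    "sd": rec["sd_lead_days"],
                    "min": np.nan,
                    "max": np.nan,
                }
            )
        out = pd.concat([out, pd.DataFrame(extra)], ignore_index=True)
    return out
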