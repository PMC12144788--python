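"""End-to-end cohort analysis: stages, outputs, and the run manifest.

Stage order per patient: colonization profiling -> whole/chronic/intermittent
STR fits -> lung-function fit -> fine-scale quadrat profile -> onset
detection; then cohort-level statistics across patients. A failing patient is
isolated (recorded in the manifest with its reason) and the run continues;
a cohort with no valid patients is a hard error.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    CohortConfig,
    CohortDataError,
    PatientSeries,
    assemble_patient_series,
    read_sample_metadata,
    read_taxon_table,
)
from .colonization import (
    compute_persistence,
    count_by_label,
    fit_par,
    labels_by_taxon,
    profiles_to_frame,
)
from .turnover import PowerFit, compute_str
from .lung_function import cumulative_abs_change, fit_lft
from .fine_scale import FineScaleSeries, sliding_quadrat
from .onset import OnsetEstimate, cohort_onset_summary, detect_onset, estimates_to_frame
from .cohort_stats import compare_groups, regress_b_on_w, summarize_cohort

logger = logging.getLogger("lungturnover")

SUBSETS = ("whole", "chronic", "intermittent")


@dataclass
class PatientResult:
    series: PatientSeries
    profiles: list
    par_fit: object | None
    str_fits: dict[str, PowerFit | None]
    lft_fit: PowerFit | None
    fine: FineScaleSeries
    onsets: list[OnsetEstimate]


def analyze_patient(series: PatientSeries, config: CohortConfig) -> PatientResult:
    """Run every per-patient stage on one series."""
    profiles = compute_persistence(series, config)
    labels = labels_by_taxon(profiles)
    try:
        par = fit_par(profiles, log_persistence=config.par_log_persistence)
    except ValueError as exc:
        logger.warning("%s: PAR fit skipped (%s)", series.patient_id, exc)
        par = None
    str_fits = {s: compute_str(series, s, labels, config) for s in SUBSETS}
    curve = cumulative_abs_change(series.days_from_start(), series.fev1_percent)
    lft = fit_lft(curve)
    if lft is None:
        logger.warning("%s: insufficient lung-function data", series.patient_id)
    fine = sliding_quadrat(series, config)
    onsets = []
    if fine.points:
        for thr in config.onset_thresholds:
            onsets.append(
                detect_onset(
                    fine,
                    series.treatment_start_date,
                    thr,
                    sustained_windows=config.sustained_windows,
                )
            )
    return PatientResult(
        series=series,
        profiles=profiles,
        par_fit=par,
        str_fits=str_fits,
        lft_fit=lft,
        fine=fine,
        onsets=onsets,
    )


def _power_fit_row(pid: str, subset: str, fit: PowerFit | None) -> dict:
    if fit is None:
        return {
            "patient_id": pid, "subset": subset, "c": np.nan, "w": np.nan,
            "R2": np.nan, "F": np.nan, "df_num": np.nan, "df_den": np.nan,
            "p": np.nan, "n_points": 0, "status": "subset_empty",
        }
    return {
        "patient_id": pid, "subset": subset, "c": fit.c, "w": fit.exponent,
        "R2": fit.r_squared, "F": fit.f_stat, "df_num": fit.df_num,
        "df_den": fit.df_den, "p": fit.p_value, "n_points": fit.n_points,
        "status": "degenerate" if fit.degenerate else "ok",
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_cohort(input_dir: str | Path, config: CohortConfig) -> dict[str, PatientSeries]:
    """Read every ``taxon_table_*.tsv`` plus ``sample_metadata.csv``.

    A single cohort-wide table named ``taxon_table.tsv`` is also accepted.
    Per-patient tables are joined on the metadata's patient grouping.
    """
    input_dir = Path(input_dir)
    meta = read_sample_metadata(input_dir / "sample_metadata.csv")
    tables = sorted(input_dir.glob("taxon_table*.tsv")) + sorted(
        input_dir.glob("taxon_table*.biom.json")
    )
    if not tables:
        raise CohortDataError(f"no taxon tables found in {input_dir}")
    series: dict[str, PatientSeries] = {}
    failures: dict[str, str] = {}
    for path in tables:
        try:
            table = read_taxon_table(path)
            sub_meta = meta[meta["sample_id"].isin(set(map(str, table.columns)))]
            if sub_meta.empty:
                raise CohortDataError(f"{path}: no metadata rows for its samples")
            series.update(assemble_patient_series(table, sub_meta, config))
        except (CohortDataError, ValueError) as exc:
            failures[path.name] = str(exc)
            logger.error("failed to load %s: %s", path.name, exc)
    if not series:
        raise CohortDataError(f"no valid patients loaded from {input_dir}: {failures}")
    series = dict(sorted(series.items()))
    for s in series.values():
        s._load_failures = failures  # attached for the manifest
    return series


def run_pipeline(
    config: CohortConfig,
    input_dir: str | Path,
    output_dir: str | Path,
) -> dict:
    """Execute the full analysis; write module TSVs and the run manifest."""
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    series = load_cohort(input_dir, config)
    load_failures = getattr(next(iter(series.values())), "_load_failures", {})

    results: dict[str, PatientResult] = {}
    failures: dict[str, str] = dict(load_failures)
    for pid, s in series.items():
        try:
            results[pid] = analyze_patient(s, config)
        except (CohortDataError, ValueError) as exc:
            failures[pid] = str(exc)
            logger.error("patient %s failed: %s", pid, exc)
    if not results:
        raise CohortDataError("no patient could be analyzed")

    outputs: list[Path] = []

    col_frames = []
    for pid, res in results.items():
        df = profiles_to_frame(res.profiles)
        df.insert(0, "patient_id", pid)
        col_frames.append(df)
    outputs.append(_write(output_dir / "colonization.tsv", pd.concat(col_frames)))

    par_rows = [
        {
            "patient_id": pid,
            "slope": res.par_fit.slope, "intercept": res.par_fit.intercept,
            "R2": res.par_fit.r_squared, "F": res.par_fit.f_stat,
            "df_num": res.par_fit.df_num, "df_den": res.par_fit.df_den,
            "p": res.par_fit.p_value, "n_taxa": res.par_fit.n_taxa,
        }
        for pid, res in results.items()
        if res.par_fit is not None
    ]
    outputs.append(_write(output_dir / "par_fits.tsv", pd.DataFrame(par_rows)))

    str_rows = [
        _power_fit_row(pid, subset, res.str_fits[subset])
        for pid, res in results.items()
        for subset in SUBSETS
    ]
    outputs.append(_write(output_dir / "str_fits.tsv", pd.DataFrame(str_rows)))

    lft_rows = []
    for pid, res in results.items():
        row = _power_fit_row(pid, "lung_function", res.lft_fit)
        row["a"] = row.pop("c")
        row["b"] = row.pop("w")
        if res.lft_fit is None:
            row["status"] = "insufficient_lung_function_data"
        lft_rows.append({"patient_id": pid, **{k: v for k, v in row.items() if k != "subset"}})
    outputs.append(_write(output_dir / "lung_function_fits.tsv", pd.DataFrame(lft_rows)))

    fine_frames = [res.fine.to_frame() for res in results.values() if res.fine.points]
    outputs.append(
        _write(
            output_dir / "fine_scale.tsv",
            pd.concat(fine_frames) if fine_frames else pd.DataFrame(),
        )
    )

    all_onsets = [e for res in results.values() for e in res.onsets]
    outputs.append(_write(output_dir / "onset.tsv", estimates_to_frame(all_onsets)))

    # cohort-level statistics
    w_groups, w_labels = [], []
    for subset in SUBSETS:
        vals = [
            res.str_fits[subset].exponent
            for res in results.values()
            if res.str_fits[subset] is not None
        ]
        if len(vals) >= 2:
            w_groups.append(np.array(vals))
            w_labels.append(subset)
    comp_rows = []
    if len(w_groups) >= 2:
        comp = compare_groups(w_groups, w_labels, adjustment=config.dunn_adjustment)
        for pw in comp.pairwise:
            comp_rows.append(
                {
                    "H": comp.h_stat, "H_p": comp.p_value,
                    "group_a": pw.group_a, "group_b": pw.group_b,
                    "dunn_z": pw.z, "dunn_p": pw.p_value, "dunn_p_adj": pw.p_adjusted,
                }
            )
    outputs.append(_write(output_dir / "group_comparisons.tsv", pd.DataFrame(comp_rows)))

    reg_rows = []
    for subset in SUBSETS:
        pairs = [
            (res.str_fits[subset].exponent, res.lft_fit.exponent)
            for res in results.values()
            if res.str_fits[subset] is not None and res.lft_fit is not None
        ]
        if len(pairs) >= 3:
            fit = regress_b_on_w(pairs)
            reg_rows.append(
                {
                    "subset": subset, "slope": fit.slope, "intercept": fit.intercept,
                    "R2": fit.r_squared, "F": fit.f_stat, "df_num": fit.df_num,
                    "df_den": fit.df_den, "p": fit.p_value, "n": fit.n_points,
                }
            )
    outputs.append(_write(output_dir / "b_on_w_regressions.tsv", pd.DataFrame(reg_rows)))

    onset_sum = cohort_onset_summary(all_onsets) if all_onsets else pd.DataFrame()
    peak_w = {
        pid: res.fine.peak_w() for pid, res in results.items() if res.fine.points
    }
    summary = summarize_cohort(
        {pid: res.str_fits for pid, res in results.items()},
        {pid: count_by_label(res.profiles) for pid, res in results.items()},
        peak_w=peak_w,
        onset_summary=onset_sum if not onset_sum.empty else None,
    )
    outputs.append(_write(output_dir / "cohort_summary.tsv", summary))
    if not onset_sum.empty:
        outputs.append(_write(output_dir / "onset_summary.tsv", onset_sum))

    manifest = {
        "package_version": __version__,
        "generated_at": _dt.datetime.now().isoformat(timespec="seconds"),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in config.__dict__.items()
        },
        "seed": config.rng_seed,
        "input_dir": str(input_dir),
        "inputs": {
            p.name: _sha256(p)
            for p in sorted(input_dir.iterdir())
            if p.is_file() and p.name != "ground_truth.tsv"
        },
        "patients_succeeded": sorted(results),
        "patients_failed": failures,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(output_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write(path: Path, df: pd.DataFrame) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def render_report(output_dir: str | Path) -> str:
    """Plain-text cohort report from a completed run's output directory."""
    output_dir = Path(output_dir)
    lines = ["Cohort turnover analysis report", "=" * 32]
    summary = pd.read_csv(output_dir / "cohort_summary.tsv", sep="\t")
    for rec in summary.to_dict("records"):
        mean, sd = rec.get("mean"), rec.get("sd")
        lines.append(
            f"{rec['statistic']:<24} n={rec['n']:<4} "
            f"mean={mean:.4g} sd={sd:.4g}"
            if pd.notna(mean)
            else f"{rec['statistic']:<24} absent"
        )
    gc = output_dir / "group_comparisons.tsv"
    if gc.exists():
        df = pd.read_csv(gc, sep="\t")
        if not df.empty:
            lines.append("")
            lines.append("Subset comparisons of w (Kruskal-Wallis + Dunn):")
            for rec in df.to_dict("records"):
                lines.append(
                    f"  {rec['group_a']} vs {rec['group_b']}: "
                    f"z={rec['dunn_z']:.3f} p_adj={rec['dunn_p_adj']:.4g} "
                    f"(H={rec['H']:.3f}, p={rec['H_p']:.4g})"
                )
    reg = output_dir / "b_on_w_regressions.tsv"
    if reg.exists():
        df = pd.read_csv(reg, sep="\t")
        if not df.empty:
            lines.append("")
            lines.append("Lung-function rate b on turnover w:")
            for rec in df.to_dict("records"):
                lines.append(
                    f"  {rec['subset']}: slope={rec['slope']:.3f} "
                    f"R2={rec['R2']:.3f} F({rec['df_num']},{rec['df_den']})="
                    f"{rec['F']:.2f} p={rec['p']:.4g}"
                )
    return "\n".join(lines) + "\n"
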