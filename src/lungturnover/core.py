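"""Core data contract: patient time series, configuration, and file I/O.

A patient's longitudinal record couples a taxon-by-sample abundance matrix
with calendar dates, per-sample lung function (%FEV1, percent of predicted),
a disease-state label per sample, and optional antibiotic-treatment dates.
Disease states follow the BETR partition of an exacerbation (PEx) event:

* ``B0`` baseline before the exacerbation,
* ``E``  exacerbation (within 30 days before treatment start),
* ``T``  antibiotic treatment,
* ``R``  recovery (within 30 days after treatment end),
* ``B1`` baseline after the exacerbation.

All downstream modules (colonization, turnover, lung function, fine-scale
profiling, onset detection) consume :class:`PatientSeries` objects produced
by :func:`assemble_patient_series`.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("lungturnover")

DISEASE_STATES = ("B0", "E", "T", "R", "B1")

METADATA_COLUMNS = (
    "patient_id",
    "sample_id",
    "date",
    "fev1_percent",
    "disease_state",
    "treatment_start",
    "treatment_end",
)


class CohortDataError(ValueError):
    """Raised when input files or assembled series violate the data contract."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Analysis constants shared across the pipeline.

    Parameters
    ----------
    presence_threshold
        Minimal relative abundance for a taxon to count as present in a
        sample. Presence is *strictly greater than* this value; the default 0
        treats any nonzero abundance as a detection (processed tables are
        assumed denoised upstream).
    chronic_persistence_cutoff
        A taxon is chronic when its temporal persistence is strictly greater
        than this fraction (modified Leeds criterion; ties are intermittent).
    str_time_unit
        ``"sample_count"`` fits species-time relationships against ordinal
        window length; ``"days"`` uses the mean spanned duration of each
        window length plus one mean inter-sample interval.
    quadrat_size
        Number of consecutive timepoints per fine-scale sliding window.
    onset_thresholds
        Turnover-exponent thresholds whose first exceedance dates PEx onset.
    sustained_windows
        Number of consecutive fine-scale midpoints that must exceed the
        threshold for a crossing (1 = plain first exceedance).
    par_log_persistence
        Fit the persistence-abundance relationship against log10 persistence
        instead of the raw fraction.
    dunn_adjustment
        Multiplicity adjustment for Dunn's post-hoc test
        (``"none"``, ``"bonferroni"``, ``"holm"``).
    """

    presence_threshold: float = 0.0
    chronic_persistence_cutoff: float = 0.5
    str_time_unit: str = "sample_count"
    quadrat_size: int = 5
    onset_thresholds: tuple[float, ...] = (0.5, 1.0)
    rng_seed: int = 0
    sustained_windows: int = 1
    par_log_persistence: bool = False
    dunn_adjustment: str = "bonferroni"

    def __post_init__(self) -> None:
        if not 0.0 <= self.presence_threshold < 1.0:
            raise ValueError("presence_threshold must lie in [0, 1)")
        if self.quadrat_size < 3:
            raise ValueError("quadrat_size must be >= 3")
        if any(t <= 0 for t in self.onset_thresholds):
            raise ValueError("onset thresholds must be positive")
        if self.str_time_unit not in ("sample_count", "days"):
            raise ValueError("str_time_unit must be 'sample_count' or 'days'")
        if self.dunn_adjustment not in ("none", "bonferroni", "holm"):
            raise ValueError("dunn_adjustment must be none|bonferroni|holm")
        self.onset_thresholds = tuple(float(t) for t in self.onset_thresholds)

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise CohortDataError(f"config file {path} is not a key: value mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise CohortDataError(f"unknown config keys: {sorted(unknown)}")
        if "onset_thresholds" in raw:
            raw = dict(raw)
            raw["onset_thresholds"] = tuple(raw["onset_thresholds"])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Patient series
# ---------------------------------------------------------------------------


@dataclass
class PatientSeries:
    """One patient's time-ordered microbiota and clinical record.

    ``abundance`` is taxa x samples, non-negative; after assembly each column
    is a relative-abundance vector summing to 1. ``fev1_percent`` uses NaN for
    missing spirometry. Dates are :class:`datetime.date` and strictly
    increasing.
    """

    patient_id: str
    sample_ids: list[str]
    sample_dates: list[_dt.date]
    abundance: np.ndarray
    taxon_ids: list[str]
    fev1_percent: np.ndarray
    disease_state: list[str]
    treatment_start_date: _dt.date | None = None
    treatment_end_date: _dt.date | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def days_from_start(self) -> np.ndarray:
        """Elapsed days since this patient's first sample (day 0)."""
        d0 = self.sample_dates[0]
        return np.array([(d - d0).days for d in self.sample_dates], dtype=float)

    def presence(self, threshold: float = 0.0) -> np.ndarray:
        """Boolean taxa x samples detection matrix (abundance > threshold)."""
        return self.abundance > threshold

    def validate(self) -> None:
        a = self.abundance
        if a.shape != (self.n_taxa, self.n_samples):
            raise CohortDataError(
                f"{self.patient_id}: abundance shape {a.shape} does not match "
                f"{self.n_taxa} taxa x {self.n_samples} samples"
            )
        if len(self.sample_dates) != self.n_samples or len(self.disease_state) != self.n_samples:
            raise CohortDataError(f"{self.patient_id}: per-sample fields misaligned")
        if np.any(a < 0):
            raise CohortDataError(f"{self.patient_id}: negative abundance values")
        diffs = np.diff([d.toordinal() for d in self.sample_dates])
        if np.any(diffs <= 0):
            raise CohortDataError(f"{self.patient_id}: sample dates not strictly increasing")
        bad = [s for s in self.disease_state if s not in DISEASE_STATES]
        if bad:
            raise CohortDataError(f"{self.patient_id}: unknown disease states {sorted(set(bad))}")
        colsums = a.sum(axis=0)
        if np.any(colsums == 0):
            zero = [self.sample_ids[i] for i in np.flatnonzero(colsums == 0)]
            raise CohortDataError(f"{self.patient_id}: all-zero sample columns {zero}")
        if self.treatment_start_date is not None and self.treatment_end_date is not None:
            t0, t1 = self.treatment_start_date, self.treatment_end_date
            if t1 < t0:
                raise CohortDataError(f"{self.patient_id}: treatment end before start")
            for sid, day, state in zip(self.sample_ids, self.sample_dates, self.disease_state):
                if state == "T" and not (t0 <= day <= t1):
                    raise CohortDataError(
                        f"{self.patient_id}: sample {sid} labelled T on {day} lies "
                        f"outside treatment window [{t0}, {t1}]"
                    )

    def normalized(self) -> "PatientSeries":
        """Return a copy with each sample column scaled to sum to 1."""
        colsums = self.abundance.sum(axis=0)
        if np.any(colsums == 0):
            zero = [self.sample_ids[i] for i in np.flatnonzero(colsums == 0)]
            raise CohortDataError(f"{self.patient_id}: cannot normalize all-zero samples {zero}")
        return replace(self, abundance=self.abundance / colsums)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _check_unique(labels: Sequence[str], what: str, path: str | Path) -> None:
    seen: dict[str, int] = {}
    dups = []
    for lab in labels:
        seen[lab] = seen.get(lab, 0) + 1
    dups = sorted(lab for lab, n in seen.items() if n > 1)
    if dups:
        raise CohortDataError(f"{path}: duplicate {what} labels {dups}")


def read_taxon_table(path: str | Path, format: str = "auto") -> pd.DataFrame:
    """Read a taxon x sample table.

    ``format`` is ``"tsv"`` (first column ``taxon_id``, remaining columns
    sample IDs), ``"biom"`` (BIOM v1 JSON, dense or sparse), or ``"auto"``
    (sniff: files starting with ``{`` are treated as BIOM JSON).

    Returns a DataFrame indexed by taxon with sample columns. Duplicate
    labels, negative or non-numeric cells, and all-zero sample columns are
    rejected.
    """
    path = Path(path)
    if format == "auto":
        with open(path) as fh:
            head = fh.read(1)
        format = "biom" if head == "{" else "tsv"
    if format == "biom":
        table = _read_biom_json(path)
    elif format == "tsv":
        table = _read_tsv_table(path)
    else:
        raise ValueError(f"unknown taxon-table format {format!r}")
    if np.any(table.to_numpy() < 0):
        raise CohortDataError(f"{path}: negative abundance values")
    colsums = table.to_numpy().sum(axis=0)
    if np.any(colsums == 0):
        zero = [table.columns[i] for i in np.flatnonzero(colsums == 0)]
        raise CohortDataError(f"{path}: all-zero sample columns {zero}")
    return table


def _read_tsv_table(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    cols = first.split("\t")  # pandas mangles duplicate headers, so check raw
    if not cols:
        raise CohortDataError(f"{path}: empty table")
    if cols[0] != "taxon_id":
        if "taxon_id" in cols:
            # Obviously inverted layout (taxa in columns): transpose is safe
            # only because the header disambiguates.
            raw = pd.read_csv(path, sep="\t")
            raw = raw.set_index(raw.columns[0]).T
            raw.index.name = "taxon_id"
            logger.warning("%s: transposed sample x taxon layout", path)
            table = raw
        else:
            raise CohortDataError(
                f"{path}: first column must be 'taxon_id' (got {cols[0]!r})"
            )
    else:
        _check_unique(cols[1:], "sample", path)
        table = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(list(table.index.astype(str)), "taxon", path)
    _check_unique(list(table.columns.astype(str)), "sample", path)
    try:
        values = table.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise CohortDataError(f"{path}: non-numeric abundance cells ({exc})") from exc
    if np.any(~np.isfinite(values)):
        raise CohortDataError(f"{path}: non-finite abundance cells")
    return pd.DataFrame(values, index=table.index.astype(str), columns=table.columns.astype(str))


def _read_biom_json(path: Path) -> pd.DataFrame:
    """Minimal reader for BIOM v1 (JSON) tables, dense or sparse."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        taxa = [str(r["id"]) for r in doc["rows"]]
        samples = [str(c["id"]) for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mtype = doc.get("matrix_type", "dense")
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise CohortDataError(f"{path}: malformed BIOM JSON ({exc})") from exc
    if shape != (len(taxa), len(samples)):
        raise CohortDataError(f"{path}: BIOM shape {shape} inconsistent with row/column lists")
    _check_unique(taxa, "taxon", path)
    _check_unique(samples, "sample", path)
    mat = np.zeros(shape, dtype=float)
    if mtype == "dense":
        mat[:] = np.asarray(data, dtype=float)
    elif mtype == "sparse":
        for i, j, v in data:
            mat[int(i), int(j)] = float(v)
    else:
        raise CohortDataError(f"{path}: unsupported BIOM matrix_type {mtype!r}")
    return pd.DataFrame(mat, index=taxa, columns=samples)


def write_taxon_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a taxon x sample table in the TSV layout `read_taxon_table` accepts.

    Integer-valued matrices are written as integers so count tables
    round-trip bit-exactly.
    """
    out = table.copy()
    values = out.to_numpy(dtype=float)
    if np.allclose(values, np.round(values)) and np.all(np.abs(values) < 2**53):
        out = pd.DataFrame(values.astype(np.int64), index=out.index, columns=out.columns)
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t", float_format="%.12g")


def _parse_date(value: str, where: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise CohortDataError(f"{where}: unparsable ISO date {value!r}") from exc


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample clinical metadata (CSV).

    Required columns: ``patient_id, sample_id, date, fev1_percent,
    disease_state, treatment_start, treatment_end`` (empty string = missing).
    Records are returned grouped by patient and sorted by date; out-of-order
    input rows are sorted with a logged warning. Unknown disease states or
    unparsable dates raise :class:`CohortDataError` naming the row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise CohortDataError(f"{path}: missing metadata columns {missing}")
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        where = f"{path} row {row_no}"
        state = row.disease_state.strip()
        if state not in DISEASE_STATES:
            raise CohortDataError(f"{where}: unknown disease_state {state!r}")
        fev1 = row.fev1_percent.strip()
        records.append(
            {
                "patient_id": row.patient_id.strip(),
                "sample_id": row.sample_id.strip(),
                "date": _parse_date(row.date, where),
                "fev1_percent": float(fev1) if fev1 else np.nan,
                "disease_state": state,
                "treatment_start": _parse_date(row.treatment_start, where)
                if row.treatment_start.strip()
                else None,
                "treatment_end": _parse_date(row.treatment_end, where)
                if row.treatment_end.strip()
                else None,
            }
        )
    out = pd.DataFrame.from_records(records)
    _check_unique(list(out["sample_id"]), "sample", path)
    for pid, grp in out.groupby("patient_id", sort=False):
        if not grp["date"].is_monotonic_increasing:
            logger.warning("%s: samples for patient %s out of date order; sorting", path, pid)
    out = out.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)
    n_missing = int(out["fev1_percent"].isna().sum())
    if n_missing:
        logger.warning("%s: %d samples missing fev1_percent", path, n_missing)
    return out


def write_sample_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    df = metadata.copy()
    for col in ("date", "treatment_start", "treatment_end"):
        df[col] = df[col].map(lambda d: d.isoformat() if d is not None and not pd.isna(d) else "")
    df["fev1_percent"] = df["fev1_percent"].map(
        lambda v: "" if pd.isna(v) else format(float(v), ".12g")
    )
    df[list(METADATA_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble_patient_series(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    config: CohortConfig | None = None,
) -> dict[str, PatientSeries]:
    """Join a taxon table with sample metadata into per-patient series.

    Columns are normalized to relative abundance (column / column sum).
    Every metadata sample must appear in the table and vice versa; orphans on
    either side raise :class:`CohortDataError` listing the offending IDs.
    """
    del config  # reserved: assembly itself is configuration-free
    table_samples = set(map(str, table.columns))
    meta_samples = set(metadata["sample_id"])
    orphans_table = sorted(table_samples - meta_samples)
    orphans_meta = sorted(meta_samples - table_samples)
    if orphans_table or orphans_meta:
        raise CohortDataError(
            "sample mismatch between taxon table and metadata: "
            f"in table only {orphans_table}; in metadata only {orphans_meta}"
        )
    series: dict[str, PatientSeries] = {}
    for pid, grp in metadata.groupby("patient_id", sort=True):
        grp = grp.sort_values("date", kind="stable")
        sample_ids = list(grp["sample_id"])
        sub = table[sample_ids].to_numpy(dtype=float)
        treat_start = _single_value(grp["treatment_start"], pid, "treatment_start")
        treat_end = _single_value(grp["treatment_end"], pid, "treatment_end")
        ps = PatientSeries(
            patient_id=str(pid),
            sample_ids=sample_ids,
            sample_dates=list(grp["date"]),
            abundance=sub,
            taxon_ids=list(map(str, table.index)),
            fev1_percent=grp["fev1_percent"].to_numpy(dtype=float),
            disease_state=list(grp["disease_state"]),
            treatment_start_date=treat_start,
            treatment_end_date=treat_end,
        )
        ps = ps.normalized()
        ps.validate()
        series[str(pid)] = ps
    if not series:
        raise CohortDataError("no patients found in metadata")
    return series


def _single_value(col: pd.Series, pid: str, name: str) -> _dt.date | None:
    vals = {v for v in col if v is not None and not pd.isna(v)}
    if len(vals) > 1:
        raise CohortDataError(f"patient {pid}: conflicting {name} values {sorted(map(str, vals))}")
    return vals.pop() if vals else None
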