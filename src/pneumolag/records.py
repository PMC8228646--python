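"""Admission-record handling: keyword screening, date reconstruction, daily aggregation.

Suspected-pneumonia admissions are identified from the free-text reason
for admission by case-insensitive substring screening (no tokenization —
the screening terms are wildcarded fragments such as ``monia`` and
``brpn``), with exclusion terms taking precedence to drop aspiration
pneumonia, chemical pneumonitis and pneumothorax.  Records missing the
admission date are recovered as discharge date minus length of stay;
records with a discharge date but no length of stay are routed to
multiple imputation, and records with neither date are excluded.
Resolved records are aggregated to a contiguous zero-filled daily count
series joined to the daily meteorology.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AdmissionRecord",
    "ReconstructionResult",
    "INCLUSION_TERMS",
    "EXCLUSION_TERMS",
    "filter_pneumonia",
    "reconstruct_admission_dates",
    "aggregate_daily",
    "validate_daily_series",
    "read_records",
    "write_records",
    "write_daily_series",
    "read_daily_series",
]

#: Case-insensitive substrings flagging a suspected-pneumonia admission.
INCLUSION_TERMS = ("monia", "brpn", "bpn", "pcp")
#: Substrings that veto inclusion (aspiration pneumonia, chemical
#: pneumonitis, pneumothorax are not counted as pneumonia admissions).
EXCLUSION_TERMS = ("chem", "pneumothorax", "asp")


@dataclass
class AdmissionRecord:
    """One hospitalization; any field beyond the reason text may be missing.

    ``covariates`` carries auxiliary predictors for length-of-stay
    imputation (day of year, day of week, week, month, year, season and
    daily temperature/humidity summaries), keyed by name.
    """

    reason_text: str
    admission_date: dt.date | None = None
    discharge_date: dt.date | None = None
    length_of_stay: int | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_of_stay is not None:
            self.length_of_stay = int(self.length_of_stay)
            if self.length_of_stay < 0:
                raise ValueError("length_of_stay must be non-negative")
        if (
            self.admission_date is not None
            and self.discharge_date is not None
            and self.admission_date > self.discharge_date
        ):
            raise ValueError("admission_date must not follow discharge_date")


def _is_pneumonia(text: str) -> bool:
    low = text.lower()
    if any(term in low for term in EXCLUSION_TERMS):
        return False
    return any(term in low for term in INCLUSION_TERMS)


def filter_pneumonia(records: list[AdmissionRecord]) -> list[AdmissionRecord]:
    """Keep records whose reason text screens positive for pneumonia.

    A record is kept iff its text contains at least one inclusion
    substring and no exclusion substring (exclusion wins).  Order is
    preserved and the input list is not modified.
    """
    return [r for r in records if _is_pneumonia(r.reason_text)]


@dataclass
class ReconstructionResult:
    """Outcome of admission-date recovery.

    ``resolved`` have an admission date (original or recomputed);
    ``needs_imputation`` have a discharge date but no length of stay;
    ``excluded`` lack both dates and cannot enter the time series.
    """

    resolved: list[AdmissionRecord]
    needs_imputation: list[AdmissionRecord]
    excluded: list[AdmissionRecord]


def reconstruct_admission_dates(records: list[AdmissionRecord]) -> ReconstructionResult:
    """Recover missing admission dates as discharge minus length of stay.

    Records with an admission date pass through unchanged.  A length of
    stay of 0 means same-day admission and discharge.
    """
    resolved: list[AdmissionRecord] = []
    needs: list[AdmissionRecord] = []
    excluded: list[AdmissionRecord] = []
    for rec in records:
        if rec.admission_date is not None:
            resolved.append(rec)
        elif rec.discharge_date is None:
            excluded.append(rec)
        elif rec.length_of_stay is None:
            needs.append(rec)
        else:
            resolved.append(
                replace(
                    rec,
                    admission_date=rec.discharge_date
                    - dt.timedelta(days=rec.length_of_stay),
                )
            )
    if excluded:
        logger.info("excluded %d records missing both dates", len(excluded))
    return ReconstructionResult(resolved, needs, excluded)


def aggregate_daily(
    records: list[AdmissionRecord],
    start_date: dt.date,
    end_date: dt.date,
    meteorology: pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate resolved records to a zero-filled daily series with weather.

    Returns one row per calendar day in ``[start_date, end_date]`` with
    columns ``count``, ``mean_temp``, ``rh``, ``dtr`` and ``dow``
    (ISO day of week, Monday=1..Sunday=7), indexed by date.  Days with no
    admissions get count 0; records outside the window are dropped (and
    counted in the log).  Meteorology must cover every day of the window.
    """
    if start_date > end_date:
        raise ValueError("start_date must not follow end_date")
    idx = pd.date_range(start_date, end_date, freq="D")

    met = meteorology.copy()
    if "date" in met.columns:
        met = met.set_index("date")
    met.index = pd.to_datetime(met.index)
    if "dtr" not in met.columns:
        if {"max_temp", "min_temp"} <= set(met.columns):
            met["dtr"] = met["max_temp"] - met["min_temp"]
        else:
            raise ValueError("meteorology needs a dtr column or min/max temperature")
    missing = idx.difference(met.index)
    if len(missing) > 0:
        shown = ", ".join(d.strftime("%Y-%m-%d") for d in missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        raise ValueError(f"meteorology gap within study window: {shown}{more}")

    dates = [r.admission_date for r in records]
    if any(d is None for d in dates):
        raise ValueError("all records must have a resolved admission date")
    dates = pd.to_datetime(dates)
    in_range = (dates >= idx[0]) & (dates <= idx[-1])
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.info("dropped %d records outside the study window", n_dropped)
    counts = (
        pd.Series(1, index=dates[in_range]).groupby(level=0).sum()
        if in_range.any()
        else pd.Series(dtype=int)
    )

    daily = pd.DataFrame(index=idx)
    daily["count"] = counts.reindex(idx, fill_value=0).astype(int)
    for col in ("mean_temp", "rh", "dtr"):
        if col not in met.columns:
            raise ValueError(f"meteorology is missing column '{col}'")
        daily[col] = met.loc[idx, col].to_numpy()
    daily["dow"] = daily.index.dayofweek + 1  # ISO: Monday=1 .. Sunday=7
    daily.index.name = "date"
    validate_daily_series(daily)
    return daily


def validate_daily_series(daily: pd.DataFrame) -> None:
    """Check the daily-series invariants; raise ``ValueError`` on violation."""
    if len(daily) == 0:
        raise ValueError("empty daily series")
    diffs = np.diff(daily.index.values).astype("timedelta64[D]").astype(int)
    if len(diffs) and not np.all(diffs == 1):
        raise ValueError("dates must be strictly consecutive with no gaps")
    if (daily["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if ((daily["rh"] < 0) | (daily["rh"] > 100)).any():
        raise ValueError("relative humidity must lie in [0, 100]")
    if (daily["dtr"] < 0).any():
        raise ValueError("daily temperature range must be non-negative")


# ---------------------------------------------------------------------------
# delimited-text interfaces

_DEFAULT_COLS = {
    "reason": "reason_text",
    "admission": "admission_date",
    "discharge": "discharge_date",
    "los": "length_of_stay",
}


def read_records(path, sep: str = ",", columns: dict[str, str] | None = None) -> list[AdmissionRecord]:
    """Read admission records from delimited text (ISO-8601 dates).

    ``columns`` remaps logical names (``reason``, ``admission``,
    ``discharge``, ``los``) to the file's column headers; any remaining
    numeric columns are carried as imputation covariates.
    """
    cols = dict(_DEFAULT_COLS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=sep)
    known = set(cols.values())
    extra = [c for c in df.columns if c not in known]
    out: list[AdmissionRecord] = []
    for _, row in df.iterrows():
        def _date(col):
            v = row.get(col)
            if pd.isna(v) or v == "":
                return None
            return pd.Timestamp(v).date()

        los = row.get(cols["los"])
        los = None if pd.isna(los) else int(los)
        cov = {c: float(row[c]) for c in extra if pd.notna(row[c])}
        out.append(
            AdmissionRecord(
                reason_text=str(row[cols["reason"]]) if pd.notna(row[cols["reason"]]) else "",
                admission_date=_date(cols["admission"]),
                discharge_date=_date(cols["discharge"]),
                length_of_stay=los,
                covariates=cov,
            )
        )
    return out


def write_records(records: list[AdmissionRecord], path, sep: str = ",") -> None:
    """Write records (and their covariates) as delimited text."""
    cov_keys = sorted({k for r in records for k in r.covariates})
    rows = []
    for r in records:
        row = {
            "reason_text": r.reason_text,
            "admission_date": r.admission_date.isoformat() if r.admission_date else "",
            "discharge_date": r.discharge_date.isoformat() if r.discharge_date else "",
            "length_of_stay": "" if r.length_of_stay is None else r.length_of_stay,
        }
        for k in cov_keys:
            row[k] = r.covariates.get(k, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def write_daily_series(daily: pd.DataFrame, path, sep: str = ",") -> None:
    """Write the daily series (date, count, mean_temp, rh, dtr, dow)."""
    daily.to_csv(path, sep=sep, index=True, date_format="%Y-%m-%d")


def read_daily_series(path, sep: str = ",") -> pd.DataFrame:
    daily = pd.read_csv(path, sep=sep, parse_dates=["date"]).set_index("date")
    validate_daily_series(daily)
    return daily
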