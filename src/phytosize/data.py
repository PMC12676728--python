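"""Ingestion, validation and joining of observation and environment tables.

Observation tables are long-format records: one row per
(station, month, species) with cell abundance (cells/L) and mean cell
biovolume (um^3/cell).  Environment tables are wide: one row per
(station, month) with named parameters (temperature in degC, DIN in mg/L,
PO4 in ug/L, ...).  Dates carry year and month only; the regression time
axis is the "lagged month" -- whole months elapsed since the first
sampling occasion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GROUPS = ("diatom", "dinoflagellate", "other")

#: atomic masses used for molar N/P (g/mol)
_M_N = 14.007
_M_P = 30.974

OBS_COLUMNS = ["station_id", "wcz", "date", "species_id", "group", "abundance", "cell_biovolume"]
ENV_KEY_COLUMNS = ["station_id", "date"]


@dataclass
class ReadResult:
    """Validated records plus row-indexed rejection diagnostics."""

    records: pd.DataFrame
    rejected: pd.DataFrame  # columns: row, reason

    def __iter__(self):
        return iter((self.records, self.rejected))


def _parse_month(values) -> pd.PeriodIndex:
    """Parse year-month strings (day-of-month, if present, is discarded)."""
    return pd.PeriodIndex(pd.to_datetime(values), freq="M")


def month_str(dates) -> pd.Series:
    return pd.Series(np.asarray(dates.astype(str)))


def read_observations(path, dialect: dict | None = None) -> ReadResult:
    """Read a delimited observation table into validated long-format records.

    Parameters
    ----------
    path : str or file-like
        CSV/TSV with a header row.
    dialect : mapping, optional
        Maps canonical column names (``station_id``, ``wcz``, ``date``,
        ``species_id``, ``group``, ``abundance``, ``cell_biovolume``) to the
        file's column names.  Identity by default.

    Rows violating the record invariants (negative abundance, positive
    abundance with missing/non-positive biovolume, unknown group) are
    rejected with a per-row reason; duplicate (station, date, species)
    rows keep the first occurrence.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep)
    dialect = dialect or {}
    rename = {v: k for k, v in dialect.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in OBS_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    df = raw[OBS_COLUMNS].copy()
    return validate_observations(df)


def validate_observations(df: pd.DataFrame) -> ReadResult:
    """Apply the observation invariants to an in-memory table."""
    df = df.copy().reset_index(drop=True)
    df["date"] = _parse_month(df["date"])
    df["abundance"] = pd.to_numeric(df["abundance"], errors="coerce")
    df["cell_biovolume"] = pd.to_numeric(df["cell_biovolume"], errors="coerce")

    reasons = pd.Series("", index=df.index, dtype=object)
    bad_abund = df["abundance"].isna() | (df["abundance"] < 0)
    reasons[bad_abund] = "abundance missing or negative"
    needs_bv = (df["abundance"] > 0) & ~bad_abund
    bad_bv = needs_bv & (
        df["cell_biovolume"].isna()
        | (df["cell_biovolume"] <= 0)
        | ~np.isfinite(df["cell_biovolume"].fillna(np.inf))
    )
    reasons[bad_bv & df["cell_biovolume"].isna()] = "biovolume missing"
    reasons[bad_bv & ~df["cell_biovolume"].isna()] = "biovolume non-positive or non-finite"
    bad_group = ~df["group"].isin(GROUPS) & (reasons == "")
    reasons[bad_group] = "unknown group"

    ok = reasons == ""
    rejected = pd.DataFrame({"row": df.index[~ok], "reason": reasons[~ok]}).reset_index(drop=True)
    records = df[ok].copy()

    dup = records.duplicated(subset=["station_id", "date", "species_id"], keep="first")
    if dup.any():
        warnings.warn(f"{int(dup.sum())} duplicate (station, date, species) rows dropped (kept first)")
        records = records[~dup]
    records = records.reset_index(drop=True)
    log.info("observations: %d accepted, %d rejected", len(records), len(rejected))
    return ReadResult(records, rejected)


def write_observations(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = out["date"].astype(str)
    out[OBS_COLUMNS].to_csv(path, index=False)


def read_environment(path, dialect: dict | None = None, dl_rule: str = "half") -> ReadResult:
    """Read a wide environment table, handling below-detection-limit entries.

    Values written as ``"<x"`` are below the detection limit ``x`` and are
    substituted per ``dl_rule``: ``half`` (x/2, the monitoring convention),
    ``zero``, or ``asis`` (keep x).  Substituted cells are flagged in a
    boolean companion column ``<param>_bdl``.  Negative concentrations are
    rejected row-wise.
    """
    if dl_rule not in ("half", "zero", "asis"):
        raise ValueError(f"dl_rule must be half|zero|asis, got {dl_rule!r}")
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    dialect = dialect or {}
    raw = raw.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in ENV_KEY_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")

    params = [c for c in raw.columns if c not in ENV_KEY_COLUMNS]
    out = raw[ENV_KEY_COLUMNS].copy()
    out["date"] = _parse_month(out["date"])
    reasons = pd.Series("", index=raw.index, dtype=object)
    for p in params:
        col = raw[p].astype(str).str.strip()
        bdl = col.str.startswith("<")
        limit = pd.to_numeric(col.str.lstrip("<"), errors="coerce")
        value = limit.copy()
        if dl_rule == "half":
            value[bdl] = limit[bdl] / 2.0
        elif dl_rule == "zero":
            value[bdl] = 0.0
        neg = value < 0
        reasons[neg & (reasons == "")] = f"negative concentration in {p}"
        out[p] = value
        out[p + "_bdl"] = bdl.fillna(False)

    ok = reasons == ""
    rejected = pd.DataFrame({"row": raw.index[~ok], "reason": reasons[~ok]}).reset_index(drop=True)
    records = out[ok].reset_index(drop=True)
    dup = records.duplicated(subset=ENV_KEY_COLUMNS, keep="first")
    if dup.any():
        warnings.warn(f"{int(dup.sum())} duplicate (station, date) environment rows dropped")
        records = records[~dup].reset_index(drop=True)
    log.info("environment: %d accepted, %d rejected", len(records), len(rejected))
    return ReadResult(records, rejected)


def write_environment(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = out["date"].astype(str)
    out = out[[c for c in out.columns if not c.endswith("_bdl")]]
    out.to_csv(path, index=False)


def lagged_month(date, origin) -> int | np.ndarray:
    """Whole-month difference from the first sampling month (origin -> 0)."""
    d = pd.PeriodIndex(np.atleast_1d(np.asarray(date, dtype=object)), freq="M")
    o = pd.Period(origin, freq="M")
    diff = (d.year - o.year) * 12 + (d.month - o.month)
    if (diff < 0).any():
        raise ValueError("date precedes the origin month")
    scalar = np.isscalar(date) or isinstance(date, (str, pd.Period, pd.Timestamp))
    return int(diff[0]) if scalar else np.asarray(diff)


def add_lagged_month(df: pd.DataFrame, origin=None) -> pd.DataFrame:
    """Attach a ``lagged_month`` column; origin defaults to the earliest date."""
    origin = origin if origin is not None else df["date"].min()
    out = df.copy()
    out["lagged_month"] = lagged_month(out["date"].values, origin)
    return out


def molar_np_ratio(din_mg_per_l, po4_ug_per_l):
    """Molar N/P ratio from DIN (mg N/L) and phosphate (ug P/L).

    Comparable to the Redfield ratio of 16.  A zero or missing phosphate
    value yields a missing ratio (never infinity).
    """
    din = np.asarray(din_mg_per_l, dtype=float)
    po4 = np.asarray(po4_ug_per_l, dtype=float)
    n_umol = din * 1000.0 / _M_N
    p_umol = po4 / _M_P
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p_umol > 0, n_umol / np.where(p_umol > 0, p_umol, 1.0), np.nan)
    if np.isscalar(din_mg_per_l) and np.isscalar(po4_ug_per_l):
        if not po4 > 0:
            warnings.warn("phosphate is zero or missing; N/P reported as missing")
        return float(ratio)
    return ratio


def join_env(observations: pd.DataFrame, environment: pd.DataFrame):
    """Inner-join observations with environment rows on (station, date).

    Returns ``(joined, unmatched)`` where ``unmatched`` lists observation
    sample keys that found no environment row.
    """
    obs_keys = observations[["station_id", "date"]].drop_duplicates()
    env_keys = environment[["station_id", "date"]].drop_duplicates()
    merged_keys = obs_keys.merge(env_keys, on=["station_id", "date"], how="left", indicator=True)
    unmatched = (
        merged_keys[merged_keys["_merge"] == "left_only"][["station_id", "date"]]
        .reset_index(drop=True)
    )
    joined = observations.merge(environment, on=["station_id", "date"], how="inner")
    if joined.empty:
        raise ValueError(
            "no overlapping (station, date) keys between observations "
            f"({len(obs_keys)} keys) and environment ({len(env_keys)} keys)"
        )
    joined = joined.sort_values(["station_id", "date", "species_id"], kind="mergesort").reset_index(drop=True)
    return joined, unmatched
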