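"""Reading and writing visit tables, assessments and policy configuration.

Visit files are UTF-8 delimited text (comma or tab, sniffed from the header
line) with columns ``donor_id, sex, date, hb``; dates are ISO-8601
(YYYY-MM-DD) and sex is coded M/F or male/female, case-insensitive. An
optional ``flagged`` column (0/1, true/false) marks visits to feed the
record-filter hook. Malformed rows are rejected and counted, never silently
dropped.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    HB_PLAUSIBLE_RANGE,
    DonorHistory,
    PolicyConfig,
    Sex,
    ValidationReport,
    VisitAssessment,
    VisitRecord,
    get_preset,
    parse_sex,
)

__all__ = [
    "read_visits",
    "write_visits",
    "load_policy",
    "write_assessments",
    "read_assessments",
    "histories_to_frame",
]

REQUIRED_COLUMNS = ("donor_id", "sex", "date", "hb")
_TRUTHY = {"1", "true", "yes", "y"}


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"empty visits file: {path}")
    return "\t" if "\t" in header else ","


def read_visits(
    path: str | Path, config: PolicyConfig | None = None
) -> tuple[list[DonorHistory], ValidationReport]:
    """Read a visits file into per-donor chronological histories.

    Hb values are converted to g/dL when ``config.units == 'g_L'`` (divide by
    10) and must then fall in the plausible range [5, 25] g/dL. Multiple
    measurements of one donor on the same date are collapsed according to
    ``config.same_day_rule`` (default: keep the highest). Returns the
    histories together with a :class:`ValidationReport` accounting for every
    input row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    config = config or PolicyConfig()

    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"visits file {path} is missing required column(s): {', '.join(missing)}"
        )
    if df.empty:
        raise ValueError(f"visits file {path} contains a header but no rows")

    n_read = len(df)
    donor = df["donor_id"].str.strip()
    date = pd.to_datetime(df["date"].str.strip(), format="%Y-%m-%d", errors="coerce")
    hb = pd.to_numeric(df["hb"].str.strip(), errors="coerce")
    if config.units == "g_L":
        hb = hb / 10.0
    sex_raw = df["sex"].str.strip().str.lower()
    sex_ok = sex_raw.isin(["m", "male", "f", "female"])
    lo, hi = HB_PLAUSIBLE_RANGE

    # first failing reason wins, in a fixed priority order
    reason = pd.Series("", index=df.index)
    reason = reason.mask((reason == "") & (donor == ""), "missing_donor_id")
    reason = reason.mask((reason == "") & date.isna(), "unparseable_date")
    reason = reason.mask((reason == "") & ~sex_ok, "invalid_sex")
    reason = reason.mask((reason == "") & hb.isna(), "unparseable_hb")
    reason = reason.mask(
        (reason == "") & ((hb <= 0) | (hb < lo) | (hb > hi)), "hb_out_of_range"
    )
    ok = reason == ""
    reasons = reason[~ok].value_counts().to_dict()
    n_rejected = int((~ok).sum())

    kept = pd.DataFrame(
        {
            "donor_id": donor[ok],
            "sex": sex_raw[ok].map(lambda s: parse_sex(s)),
            "date": date[ok].dt.date,
            "hb": hb[ok],
        }
    )
    if "flagged" in df.columns:
        kept["flagged"] = (
            df.loc[ok, "flagged"].str.strip().str.lower().isin(_TRUTHY)
        )
    else:
        kept["flagged"] = False

    agg = {"max": "max", "min": "min", "mean": "mean"}[config.same_day_rule]
    grouped = (
        kept.groupby(["donor_id", "date"], sort=False)
        .agg(sex=("sex", "first"), hb=("hb", agg), flagged=("flagged", "any"))
        .reset_index()
    )
    n_collapsed = len(kept) - len(grouped)
    grouped = grouped.sort_values(["donor_id", "date"], kind="stable")

    histories = [
        DonorHistory(
            donor_id,
            [
                VisitRecord(donor_id, row.sex, row.date, float(row.hb), bool(row.flagged))
                for row in sub.itertuples(index=False)
            ],
        )
        for donor_id, sub in grouped.groupby("donor_id", sort=False)
    ]

    report = ValidationReport(
        n_rows_read=n_read,
        n_rows_rejected=n_rejected,
        n_collapsed_same_day=n_collapsed,
        n_visits=len(grouped),
        reasons=reasons,
    )
    return histories, report


def histories_to_frame(histories: Iterable[DonorHistory]) -> pd.DataFrame:
    """Flatten donor histories into one visit-level DataFrame."""
    rows = [
        (v.donor_id, v.sex.value, v.visit_date, v.hb, v.flagged)
        for h in histories
        for v in h.visits
    ]
    return pd.DataFrame(
        rows, columns=["donor_id", "sex", "date", "hb", "flagged"]
    )


def write_visits(histories: Iterable[DonorHistory], path: str | Path) -> None:
    """Write donor histories as a comma-delimited visits file (4 decimals)."""
    df = histories_to_frame(histories)
    out = df[["donor_id", "sex", "date", "hb"]].copy()
    if df["flagged"].any():
        out["flagged"] = df["flagged"].astype(int)
    out.to_csv(path, index=False, float_format="%.4f")


_POLICY_KEYS = {f.name for f in dc_fields(PolicyConfig)}


def load_policy(path: str | Path) -> PolicyConfig:
    """Load a policy configuration from a YAML key-value file.

    A ``preset`` key selects a country's thresholds; explicit keys override
    the preset. Absent fields take the package defaults (alpha_mean 0,
    alpha_outlier 0.999, EU thresholds 13.5/12.5 g/dL). Unknown keys raise a
    warning but are not fatal; invalid values are.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return policy_from_mapping(raw or {})


def policy_from_mapping(raw: dict) -> PolicyConfig:
    if not isinstance(raw, dict):
        raise ValueError("policy configuration must be a key-value mapping")
    raw = dict(raw)
    kwargs: dict = {}
    preset_name = raw.pop("preset", None)
    if preset_name is not None:
        preset = get_preset(str(preset_name))
        kwargs["threshold_male"] = preset.threshold_male
        kwargs["threshold_female"] = preset.threshold_female
    for key, value in raw.items():
        if key not in _POLICY_KEYS:
            warnings.warn(f"ignoring unknown policy key {key!r}", stacklevel=2)
            continue
        kwargs[key] = value
    return PolicyConfig(**kwargs)


_ASSESS_COLUMNS = [
    "donor_id",
    "date",
    "sex",
    "hb",
    "n_prior",
    "hist_mean",
    "ci_bound",
    "outlier_cutoff",
    "current_decision",
    "alt_decision",
    "reason",
]


def _assessments_frame(
    assessments: Sequence[VisitAssessment] | pd.DataFrame,
) -> pd.DataFrame:
    if isinstance(assessments, pd.DataFrame):
        df = assessments.copy()
        if "reason" not in df.columns:
            raise ValueError("assessment frame lacks a 'reason' column")
        return df[_ASSESS_COLUMNS]
    rows = [
        (
            a.donor_id,
            a.visit_date,
            a.sex.value,
            a.hb,
            a.n_prior,
            a.hist_mean,
            a.ci_bound,
            a.outlier_cutoff,
            a.current_decision,
            a.alt_decision,
            a.reason,
        )
        for a in assessments
    ]
    return pd.DataFrame(rows, columns=_ASSESS_COLUMNS)


def write_assessments(
    assessments: Sequence[VisitAssessment] | pd.DataFrame, path: str | Path
) -> None:
    """Write per-visit assessments as comma-delimited text (4-decimal floats).

    Visits that could not be assessed (too few prior measurements) carry the
    reason code 'NA' and empty numeric fields.
    """
    df = _assessments_frame(assessments)
    if df.empty:
        raise ValueError("refusing to write an empty assessment table")
    df["reason"] = df["reason"].replace("", "-")
    df.to_csv(path, index=False, float_format="%.4f")


def read_assessments(path: str | Path) -> pd.DataFrame:
    """Read an assessment table written by :func:`write_assessments`."""
    df = pd.read_csv(
        path, dtype={"donor_id": str, "reason": str}, keep_default_na=False
    )
    for col in ("hb", "hist_mean", "ci_bound", "outlier_cutoff"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["n_prior"] = pd.to_numeric(df["n_prior"]).astype(int)
    df["reason"] = df["reason"].replace("-", "")
    return df
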