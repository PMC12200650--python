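"""Incident-user cohort construction with the new-user (washout) design.

An index date is the first opioid issue after >=365 opioid-free days.  An
index event enters the chronic-non-cancer-pain (CNCP) cohort when the
patient is an adult at index, has >=365 days of prior registration, has a
CNCP code any time before or up to 183 days after the index date, and has
no non-NMSC cancer code in the 3650 days up to and including the index
date.  Follow-up runs to the earliest of death, a cancer diagnosis,
transfer out of the practice, the practice's last collection date, or the
study end.

Age uses year of birth only (the database records no finer resolution):
adult means index_year - birth_year >= 18.  A patient may contribute
several index events provided each has its own clean washout.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

from .config import (DAYS_PER_YEAR, SIX_MONTHS_DAYS, TEN_YEARS_DAYS)

INDEX_COLUMNS = ["patient_id", "index_date", "index_year", "followup_end",
                 "censor_reason"]

# tie-break priority for simultaneous censoring events (highest wins)
_REASON_PRIORITY = ["death", "cancer", "transfer", "last_collection", "study_end"]


class CohortError(ValueError):
    pass


def find_incident_index_dates(clean_rx: pd.DataFrame, patients: pd.DataFrame,
                              study_start: date, study_end: date,
                              washout_days: int = DAYS_PER_YEAR,
                              min_registration_days: int = DAYS_PER_YEAR,
                              min_age: int = 18) -> pd.DataFrame:
    """Candidate index events: issue dates with a clean washout, adult age
    and sufficient prior registration, inside the study window.

    Washout is evaluated on issue dates of analysable (non-excluded) opioid
    prescriptions, including issues before the study window.
    """
    if clean_rx.empty:
        return pd.DataFrame(columns=["patient_id", "index_date", "index_year"])
    rx = clean_rx[["patient_id", "supply_start"]].drop_duplicates() \
        .sort_values(["patient_id", "supply_start"], kind="mergesort")
    prev = rx.groupby("patient_id")["supply_start"].shift(1)
    gap = (rx["supply_start"] - prev).dt.days
    incident = prev.isna() | (gap > washout_days)
    cand = rx.loc[incident].rename(columns={"supply_start": "index_date"})

    pat = patients.set_index("patient_id")
    cand = cand.join(pat[["birth_year", "registration_start"]], on="patient_id")
    cand["index_year"] = cand["index_date"].dt.year
    age_ok = (cand["index_year"] - cand["birth_year"]) >= min_age
    reg_ok = (cand["index_date"] - cand["registration_start"]).dt.days \
        >= min_registration_days
    in_window = (cand["index_date"] >= pd.Timestamp(study_start)) \
        & (cand["index_date"] <= pd.Timestamp(study_end))
    cand = cand.loc[age_ok & reg_ok & in_window,
                    ["patient_id", "index_date", "index_year"]]
    return cand.reset_index(drop=True)


def apply_cncp_and_cancer_rules(candidates: pd.DataFrame, events: pd.DataFrame,
                                cncp_after_days: int = SIX_MONTHS_DAYS,
                                cancer_lookback_days: int = TEN_YEARS_DAYS,
                                ) -> pd.DataFrame:
    """Keep candidates with a CNCP code in (-inf, index + 183 d] and no
    non-NMSC cancer code in [index - 3650 d, index]."""
    if candidates.empty:
        return candidates.copy()
    ev = events.copy()
    ev["category"] = ev["category"].str.lower()
    cncp = ev.loc[ev["category"] == "cncp", ["patient_id", "event_date"]]
    cancer = ev.loc[ev["category"] == "cancer", ["patient_id", "event_date"]]

    c = candidates.reset_index(drop=True).copy()
    c["_row"] = np.arange(len(c))

    m = c.merge(cncp, on="patient_id", how="left")
    has_cncp = m.loc[
        m["event_date"].notna()
        & ((m["event_date"] - m["index_date"]).dt.days <= cncp_after_days),
        "_row"].unique()

    m = c.merge(cancer, on="patient_id", how="left")
    delta = (m["index_date"] - m["event_date"]).dt.days
    has_cancer = m.loc[
        m["event_date"].notna() & (delta >= 0) & (delta <= cancer_lookback_days),
        "_row"].unique()

    keep = c["_row"].isin(has_cncp) & ~c["_row"].isin(has_cancer)
    return c.loc[keep].drop(columns="_row").reset_index(drop=True)


def compute_followup_end(events_df: pd.DataFrame, patients: pd.DataFrame,
                         events: pd.DataFrame, study_end: date) -> pd.DataFrame:
    """Attach follow-up end = earliest of death, post-index cancer, transfer
    out, last collection date, study end — with a deterministic reason
    tie-break (death > cancer > transfer > last_collection > study_end)."""
    if events_df.empty:
        out = events_df.copy()
        out["followup_end"] = pd.Series(dtype="datetime64[ns]")
        out["censor_reason"] = pd.Series(dtype=object)
        return out
    pat = patients.set_index("patient_id")
    out = events_df.reset_index(drop=True).copy()
    joined = out.join(pat[["registration_end", "death_date",
                           "last_collection_date"]], on="patient_id")

    ev = events.copy()
    ev["category"] = ev["category"].str.lower()
    cancer = ev.loc[ev["category"] == "cancer", ["patient_id", "event_date"]]
    m = out.reset_index().merge(cancer, on="patient_id", how="left")
    m = m.loc[m["event_date"] > m["index_date"]]
    first_cancer = m.groupby("index")["event_date"].min()

    dates = pd.DataFrame({
        "death": joined["death_date"],
        "cancer": first_cancer.reindex(out.index),
        "transfer": joined["registration_end"],
        "last_collection": joined["last_collection_date"],
        "study_end": pd.Timestamp(study_end),
    })
    # column order encodes the tie-break priority; idxmin takes the first
    # minimising column
    fu = dates.min(axis=1)
    reason = dates.apply(lambda r: r.idxmin(), axis=1)
    if (fu < out["index_date"]).any():
        bad = out.loc[fu < out["index_date"], "patient_id"].tolist()
        raise CohortError(f"follow-up end precedes index date for {bad[:5]}")
    out["followup_end"] = fu
    out["censor_reason"] = reason
    return out[INDEX_COLUMNS]


def registered_denominator(patients: pd.DataFrame, years: list[int],
                           min_prior_days: int = DAYS_PER_YEAR) -> pd.Series:
    """Registered-patient denominator per calendar year: registered for at
    least one day of the year with >=365 days of registration by year end."""
    counts = {}
    for y in years:
        y0, y1 = pd.Timestamp(date(y, 1, 1)), pd.Timestamp(date(y, 12, 31))
        active = (patients["registration_start"] <= y1) \
            & (patients["registration_end"] >= y0)
        mature = (y1 - patients["registration_start"]).dt.days >= min_prior_days
        counts[y] = int((active & mature).sum())
    return pd.Series(counts, name="n_registered").rename_axis("year")


def build_cohort(clean_rx: pd.DataFrame, patients: pd.DataFrame,
                 events: pd.DataFrame, study_start: date, study_end: date,
                 washout_days: int = DAYS_PER_YEAR) -> pd.DataFrame:
    """Full cohort pipeline: washout candidates -> CNCP/cancer rules ->
    follow-up end."""
    cand = find_incident_index_dates(clean_rx, patients, study_start,
                                     study_end, washout_days)
    kept = apply_cncp_and_cancer_rules(cand, events)
    return compute_followup_end(kept, patients, events, study_end)
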