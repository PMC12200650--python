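"""L-TOT phenotyping and discontinuation detection.

Long-term opioid therapy (L-TOT) is evaluated over days 30..364 after the
index date (index = day 0; the initial 30 days are excluded from both
criteria):

* criterion A (``count_window``): some 90-consecutive-day span contains
  >=3 prescription issues falling inside the evaluation window;
* criterion B (``supply_days``): >=90 distinct calendar days of the window
  are covered by at least one supply interval (overlaps not double-counted).

Discontinuation: an opioid-free gap of >=180 days whose first day lies in
days 365..729 after index, with the whole confirmation window observable
(before the patient's registration end and the data horizon).  Events are
attributed to the index year.

``detect_ltot`` is the production implementation; ``brute_force_oracle``
re-evaluates both criteria by exhaustive day-grid enumeration and exists
solely as an independent check.
"""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import PhenotypingConstants

LTOT_COLUMNS = ["is_ltot", "criterion", "qualification_day",
                "n_issues_in_window", "covered_days_in_window"]


class PhenotypingError(ValueError):
    pass


def _day_offsets(index_date: pd.Timestamp, rx: pd.DataFrame):
    """Issue-day and supply-interval offsets (days since index) for one event."""
    if len(rx) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    d0 = (pd.to_datetime(rx["supply_start"]) - index_date).dt.days.to_numpy()
    d1 = d0 + rx["supply_days"].to_numpy().astype(int) - 1
    return d0, d1


def detect_ltot(index_date: pd.Timestamp, rx: pd.DataFrame,
                constants: PhenotypingConstants | None = None) -> dict:
    """Classify one index event.  ``rx`` holds the patient's cleaned
    prescriptions (any date range; the function windows them itself).

    Returns a dict with keys ``is_ltot``, ``criterion`` (none |
    count_window | supply_days | both), ``qualification_day`` (day offset
    from index on which a criterion first became satisfied, or None),
    ``n_issues_in_window`` and ``covered_days_in_window``.
    """
    k = constants or PhenotypingConstants()
    w0, w1 = k.window_start, k.window_end
    issues, ends = _day_offsets(index_date, rx)

    win_issues = np.sort(issues[(issues >= w0) & (issues <= w1)])
    n_issues = int(win_issues.size)

    # criterion A: three window issues within a span of span_days
    a_day = None
    if n_issues >= k.min_issues:
        m = k.min_issues
        span_ok = win_issues[m - 1:] - win_issues[:n_issues - m + 1] <= k.span_days - 1
        hits = np.flatnonzero(span_ok)
        if hits.size:
            a_day = int(win_issues[hits[0] + m - 1])

    # criterion B: distinct covered days inside the window
    covered = np.zeros(w1 - w0 + 1, dtype=bool)
    s = np.maximum(issues, w0)
    e = np.minimum(ends, w1)
    for lo, hi in zip(s, e):
        if hi >= w0 and lo <= hi:
            covered[lo - w0:hi - w0 + 1] = True
    n_cov = int(covered.sum())
    b_day = None
    if n_cov >= k.min_covered_days:
        b_day = int(np.flatnonzero(covered.cumsum() == k.min_covered_days)[0]) + w0

    crit = {(False, False): "none", (True, False): "count_window",
            (False, True): "supply_days", (True, True): "both"}[
        (a_day is not None, b_day is not None)]
    qual = min((d for d in (a_day, b_day) if d is not None), default=None)
    return {"is_ltot": crit != "none", "criterion": crit,
            "qualification_day": qual, "n_issues_in_window": n_issues,
            "covered_days_in_window": n_cov}


def brute_force_oracle(index_date: pd.Timestamp, rx: pd.DataFrame,
                       constants: PhenotypingConstants | None = None) -> dict:
    """Exhaustive re-evaluation of both L-TOT criteria on a day grid.

    Enumerates every possible 90-day span start and every window day
    directly; intentionally naive and independent of :func:`detect_ltot`.
    """
    k = constants or PhenotypingConstants()
    if len(rx) > 200:
        raise PhenotypingError("oracle is for small instances (<=200 issues)")
    w0, w1 = k.window_start, k.window_end
    issues, ends = _day_offsets(index_date, rx)

    a_day = None
    for start in range(w0 - k.span_days + 1, w1 + 1):
        span = [d for d in issues
                if start <= d <= start + k.span_days - 1 and w0 <= d <= w1]
        if len(span) >= k.min_issues:
            day = sorted(span)[k.min_issues - 1]
            a_day = day if a_day is None else min(a_day, day)
    covered_days = []
    for day in range(w0, w1 + 1):
        if any(s <= day <= e for s, e in zip(issues, ends)):
            covered_days.append(day)
    b_day = covered_days[k.min_covered_days - 1] \
        if len(covered_days) >= k.min_covered_days else None

    crit = {(False, False): "none", (True, False): "count_window",
            (False, True): "supply_days", (True, True): "both"}[
        (a_day is not None, b_day is not None)]
    qual = min((d for d in (a_day, b_day) if d is not None), default=None)
    n_issues = sum(1 for d in issues if w0 <= d <= w1)
    return {"is_ltot": crit != "none", "criterion": crit,
            "qualification_day": qual, "n_issues_in_window": n_issues,
            "covered_days_in_window": len(covered_days)}


def detect_discontinuation(index_date: pd.Timestamp, rx: pd.DataFrame,
                           observable_end: pd.Timestamp,
                           constants: PhenotypingConstants | None = None
                           ) -> dict | None:
    """Earliest confirmed discontinuation for one L-TOT event, or None.

    A gap qualifies when it starts (day after a supply run ends) within
    days 365..729 after index, lasts >=180 opioid-free days, and its whole
    confirmation window lies on or before ``observable_end`` (typically
    min(registration end, data horizon))."""
    k = constants or PhenotypingConstants()
    issues, ends = _day_offsets(index_date, rx)
    horizon = (observable_end - index_date).days
    keep = issues <= horizon
    issues, ends = issues[keep], np.minimum(ends[keep], horizon)
    if issues.size == 0:
        return None
    order = np.argsort(issues, kind="stable")
    issues, ends = issues[order], ends[order]

    # merge supply intervals into maximal covered runs
    runs: list[list[int]] = []
    for s0, e0 in zip(issues, ends):
        if runs and s0 <= runs[-1][1] + 1:
            runs[-1][1] = max(runs[-1][1], int(e0))
        else:
            runs.append([int(s0), int(e0)])

    for i, (s0, e0) in enumerate(runs):
        gap_start = e0 + 1
        gap_end = runs[i + 1][0] - 1 if i + 1 < len(runs) else horizon
        if not (k.disc_start <= gap_start <= k.disc_end):
            continue
        confirmation_day = gap_start + k.gap_days - 1
        if gap_end >= confirmation_day and confirmation_day <= horizon:
            return {
                "last_supply_end": index_date + timedelta(days=int(e0)),
                "gap_start": index_date + timedelta(days=int(gap_start)),
                "confirmation_date": index_date + timedelta(days=int(confirmation_day)),
                "confirmed": True,
            }
    return None


# ---------------------------------------------------------------------------
# cohort-level drivers


def classify_cohort(events_df: pd.DataFrame, clean_rx: pd.DataFrame,
                    patients: pd.DataFrame,
                    data_horizon: pd.Timestamp,
                    constants: PhenotypingConstants | None = None
                    ) -> pd.DataFrame:
    """Run L-TOT and discontinuation detection for every index event.

    Returns ``events_df`` with the classification columns appended:
    is_ltot, criterion, qualification_day, n_issues_in_window,
    covered_days_in_window, is_discontinuer, gap_start.
    """
    k = constants or PhenotypingConstants()
    rx_by_pat = {p: g for p, g in clean_rx.groupby("patient_id")}
    reg_end = patients.set_index("patient_id")["registration_end"]
    rows = []
    for ev in events_df.itertuples(index=False):
        rx = rx_by_pat.get(ev.patient_id)
        if rx is None:
            rx = clean_rx.iloc[0:0]
        cls = detect_ltot(ev.index_date, rx, k)
        disc = None
        if cls["is_ltot"]:
            observable = min(pd.Timestamp(reg_end.loc[ev.patient_id]),
                             pd.Timestamp(data_horizon))
            disc = detect_discontinuation(ev.index_date, rx, observable, k)
        rows.append({**cls,
                     "is_discontinuer": disc is not None,
                     "gap_start": disc["gap_start"] if disc else pd.NaT})
    out = events_df.reset_index(drop=True).copy()
    return pd.concat([out, pd.DataFrame(rows)], axis=1)


def assemble_annual_series(classified: pd.DataFrame,
                           registered_by_year: pd.Series,
                           years: list[int]) -> pd.DataFrame:
    """Aggregate classified index events into the three annual series.

    One row per calendar year: registered patients, incident users, L-TOT
    users, discontinuers (all attributed to the index year) and the three
    rates.  Raises if any numerator exceeds its denominator.
    """
    by_year = classified.groupby("index_year")
    inc = by_year.size().reindex(years, fill_value=0)
    ltot = by_year["is_ltot"].sum().reindex(years, fill_value=0).astype(int)
    disc = by_year["is_discontinuer"].sum().reindex(years, fill_value=0).astype(int)
    reg = registered_by_year.reindex(years)
    out = pd.DataFrame({
        "year": years,
        "n_registered": reg.to_numpy(),
        "n_incident": inc.to_numpy(),
        "n_ltot": ltot.to_numpy(),
        "n_discontinuers": disc.to_numpy(),
    })
    for num, den in (("n_incident", "n_registered"), ("n_ltot", "n_incident"),
                     ("n_discontinuers", "n_ltot")):
        if (out[num] > out[den]).any():
            bad = out.loc[out[num] > out[den], "year"].tolist()
            raise PhenotypingError(f"{num} exceeds {den} in years {bad}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rate_incident"] = np.where(out["n_registered"] > 0,
                                        100 * out["n_incident"] / out["n_registered"], 0.0)
        out["rate_ltot"] = np.where(out["n_incident"] > 0,
                                    100 * out["n_ltot"] / out["n_incident"], 0.0)
        out["rate_discontinuers"] = np.where(out["n_ltot"] > 0,
                                             100 * out["n_discontinuers"] / out["n_ltot"], 0.0)
    return out
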