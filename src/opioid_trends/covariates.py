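"""Baseline covariate profiles and descriptive (Table-1-style) summaries.

Comorbidity and concurrent-drug flags use a 5-year lookback
[index - 1825 d, index) excluding the index day.  The Charlson comorbidity
index (CCI) is computed from a configurable condition -> weight map and
graded low (0-2), medium (3-4), high (>=5).  Missing categoricals map to
an explicit "unknown" level.  Opioid dose/formulation covariates summarise
the first year of follow-up: mean daily MME, its band, and patient-level
weak-opioid / short-acting flags that are true only when *all* first-year
opioid products are weak (resp. short-acting).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import FIVE_YEARS_DAYS, DAYS_PER_YEAR

# standard Charlson weights for the conditions the synthetic generator emits;
# the map is configuration, not a clinical authority
CHARLSON_WEIGHTS: dict[str, int] = {
    "myocardial_infarction": 1,
    "heart_failure": 1,
    "copd": 1,
    "diabetes": 1,
    "rheumatoid_arthritis": 1,
    "liver_disease": 1,
    "renal_disease": 2,
    "cancer": 2,
}

COMORBIDITY_FLAGS = ["rheumatoid_arthritis", "osteoarthritis", "anxiety",
                     "depression", "schizophrenia", "alcohol_dependence",
                     "epilepsy", "substance_misuse"]
DRUG_FLAGS = ["rx_benzodiazepines", "rx_antidepressants", "rx_gabapentinoids",
              "rx_muscle_relaxants", "rx_z_drugs", "rx_nsaids"]

AGE_BANDS = [(18, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 79),
             (80, 89), (90, 200)]
DOSE_BANDS = ["<50", "[50,90)", "[90,120)", ">=120"]


def grade_cci(score: int) -> str:
    """CCI grade: 0-2 low, 3-4 medium, >=5 high."""
    if score < 0:
        raise ValueError("CCI score must be non-negative")
    if score <= 2:
        return "low"
    if score <= 4:
        return "medium"
    return "high"


def categorize_dose(mme_per_day: float) -> str:
    """Daily-MME band; left-closed right-open boundaries at 50, 90, 120."""
    if mme_per_day < 0:
        raise ValueError("daily MME must be non-negative")
    if mme_per_day < 50:
        return "<50"
    if mme_per_day < 90:
        return "[50,90)"
    if mme_per_day < 120:
        return "[90,120)"
    return ">=120"


def age_band(age: int) -> str:
    for lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return "≥90 years" if lo == 90 else f"{lo}-{hi} years"
    return "unknown"


def _unknown_if_missing(value) -> str:
    return "unknown" if value is None or (isinstance(value, float) and np.isnan(value)) \
        or pd.isna(value) else str(value)


def assemble_profiles(events_df: pd.DataFrame, clean_rx: pd.DataFrame,
                      events: pd.DataFrame, patients: pd.DataFrame,
                      lookback_days: int = FIVE_YEARS_DAYS) -> pd.DataFrame:
    """One covariate profile per index event."""
    pat = patients.set_index("patient_id")
    ev = events.copy()
    ev["category"] = ev["category"].str.lower()
    ev_by_pat = {p: g for p, g in ev.groupby("patient_id")}
    rx_by_pat = {p: g for p, g in clean_rx.groupby("patient_id")}

    rows = []
    for e in events_df.itertuples(index=False):
        p = pat.loc[e.patient_id]
        age = int(e.index_year - p["birth_year"])
        profile = {
            "patient_id": e.patient_id,
            "index_date": e.index_date,
            "sex": _unknown_if_missing(p["sex"]),
            "age": age,
            "age_band": age_band(age),
            "imd_quintile": ("unknown" if pd.isna(p["imd_quintile"])
                             else str(int(p["imd_quintile"]))),
            "region": _unknown_if_missing(p["region"]),
            "ethnicity": _unknown_if_missing(p["ethnicity"]),
            "smoking": _unknown_if_missing(p["smoking"]),
            "drinking": _unknown_if_missing(p["drinking"]),
        }
        g = ev_by_pat.get(e.patient_id)
        if g is not None:
            delta = (e.index_date - g["event_date"]).dt.days
            in_lb = (delta > 0) & (delta <= lookback_days)
            cats = set(g.loc[in_lb, "category"])
        else:
            cats = set()
        for flag in COMORBIDITY_FLAGS + DRUG_FLAGS:
            profile[flag] = flag in cats
        score = sum(w for cond, w in CHARLSON_WEIGHTS.items() if cond in cats)
        profile["cci_score"] = score
        profile["cci_grade"] = grade_cci(score)

        rx = rx_by_pat.get(e.patient_id)
        if rx is not None:
            offs = (rx["supply_start"] - e.index_date).dt.days
            first_year = rx.loc[(offs >= 0) & (offs < DAYS_PER_YEAR)]
        else:
            first_year = None
        if first_year is not None and len(first_year):
            mean_mme = float(first_year["daily_mme"].mean())
            profile["mean_daily_mme"] = mean_mme
            profile["dose_band"] = categorize_dose(mean_mme)
            profile["weak_opioid"] = bool((first_year["potency_class"] == "weak").all())
            profile["short_acting"] = bool(
                (first_year["action_class"] == "short-acting").all())
        else:
            profile["mean_daily_mme"] = np.nan
            profile["dose_band"] = "unknown"
            profile["weak_opioid"] = False
            profile["short_acting"] = False
        rows.append(profile)
    return pd.DataFrame(rows)


_TABLE1_CATEGORICALS = [
    ("Sex", "sex", ["F", "M"]),
    ("Age group", "age_band", [f"{lo}-{hi} years" for lo, hi in AGE_BANDS[:-1]]
     + ["≥90 years"]),
    ("IMD quintile", "imd_quintile", ["1", "2", "3", "4", "5", "unknown"]),
    ("Region", "region", ["North England", "Midland", "South England", "London"]),
    ("Ethnicity", "ethnicity", ["White", "Asian", "Black", "Mixed", "Other",
                                "unknown"]),
    ("Dose band", "dose_band", DOSE_BANDS),
    ("Drinking status", "drinking", ["Current", "Never", "Former", "unknown"]),
    ("Smoking status", "smoking", ["Current", "Never", "Former", "unknown"]),
    ("CCI", "cci_grade", ["low", "medium", "high"]),
]


def build_table1(profiles: pd.DataFrame, group: pd.Series) -> pd.DataFrame:
    """Descriptive summary by group (e.g. persistent L-TOT vs discontinuer).

    Long format: variable, level, then per group its count and column
    percentage; means +- SD for age and daily dose.  Percentages are over
    the group total; empty groups yield zero counts without division errors.
    """
    groups = list(pd.unique(group))
    rows = []
    totals = {g: int((group == g).sum()) for g in groups}

    def pct(n, total):
        return round(100.0 * n / total, 2) if total else 0.0

    for g in groups:
        rows.append({"variable": "N", "level": "", "group": g,
                     "count": totals[g], "percent": 100.0 if totals[g] else 0.0})
    for var, col, mask_levels in _TABLE1_CATEGORICALS:
        for level in mask_levels:
            for g in groups:
                sub = profiles.loc[(group == g).to_numpy()]
                n = int((sub[col].astype(str) == level).sum())
                rows.append({"variable": var, "level": level, "group": g,
                             "count": n, "percent": pct(n, totals[g])})
    for var, col in [("Age (mean±SD)", "age"),
                     ("Average daily dose (MME mg/day)", "mean_daily_mme")]:
        for g in groups:
            sub = profiles.loc[(group == g).to_numpy(), col]
            rows.append({"variable": var, "level": "mean", "group": g,
                         "count": round(float(sub.mean()), 2) if len(sub) else np.nan,
                         "percent": round(float(sub.std()), 2) if len(sub) > 1 else np.nan})
    for var, col in ([("Comorbidity", f) for f in COMORBIDITY_FLAGS]
                     + [("Concurrent drug use", f) for f in DRUG_FLAGS]
                     + [("Opioid characteristics", "weak_opioid"),
                        ("Opioid characteristics", "short_acting")]):
        for g in groups:
            sub = profiles.loc[(group == g).to_numpy()]
            n = int(sub[col].sum())
            rows.append({"variable": var, "level": col, "group": g,
                         "count": n, "percent": pct(n, totals[g])})
    return pd.DataFrame(rows)
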