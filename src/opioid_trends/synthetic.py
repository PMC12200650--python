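"""Synthetic CPRD-Aurum-like data generator.

Emulates the *structure* of UK primary-care records needed by the analysis —
a patient/registration table, an opioid prescription-issue table and a coded
clinical-event table — together with planted ground-truth episode labels so
the phenotyping stages can be validated exactly.  No real clinical coding
vocabulary, regional weighting or linkage mechanics are emulated; see
docs/methods.md for what the generator does and does not reproduce.

Design: incident opioid episodes are planted as explicit templates (index
date + refill pattern).  An episode is L-TOT with probability ``p_ltot``;
an L-TOT episode discontinues in its second year with probability
``p_discontinue``.  Refill patterns are constructed so the classification
is unambiguous under the downstream cleaning rules:

* L-TOT, discontinuing:   issues day 0 then every 28 d from day 30 to 338
  (28-day supplies) -> coverage ends day 365, the opioid-free gap starts
  day 366 and is confirmed on day 545.
* L-TOT, persisting:      the same chain continued through day ~730, so no
  qualifying gap starts inside days 365-729.
* non-L-TOT:              1-2 issues with <=28-day supplies, at most one of
  them inside the day-30-364 evaluation window.

Episodes are only planted where the full pattern plus its confirmation
window fits inside the patient's registration, and successive episodes are
separated by the 365-day washout, so planted labels coincide with what the
phenotyper should find.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (ConfigurationError, SimulationConfig, DAYS_PER_YEAR,
                     TEN_YEARS_DAYS)
from .products import Product

PATIENT_COLUMNS = [
    "patient_id", "sex", "birth_year", "registration_start", "registration_end",
    "death_date", "last_collection_date", "region", "imd_quintile", "ethnicity",
    "smoking", "drinking",
]
PRESCRIPTION_COLUMNS = [
    "patient_id", "issue_date", "product_id", "quantity", "daily_dose_units",
    "duration_days",
]
EVENT_COLUMNS = ["patient_id", "event_date", "category"]
EPISODE_COLUMNS = [
    "patient_id", "index_date", "product_id", "is_ltot", "is_discontinuer",
    "in_cohort", "exclusion_reason",
]

REGIONS = ["North England", "Midland", "South England", "London"]
REGION_W = [0.31, 0.20, 0.36, 0.13]
ETHNICITIES = ["White", "Asian", "Black", "Mixed", "Other"]
ETHNICITY_W = [0.88, 0.05, 0.04, 0.01, 0.02]
SMOKING = ["Current", "Never", "Former"]
SMOKING_W = [0.22, 0.46, 0.32]
DRINKING = ["Current", "Never", "Former"]
DRINKING_W = [0.76, 0.22, 0.02]

COMORBIDITY_PREVALENCE = {
    "rheumatoid_arthritis": 0.03,
    "osteoarthritis": 0.10,
    "anxiety": 0.34,
    "depression": 0.43,
    "schizophrenia": 0.025,
    "alcohol_dependence": 0.046,
    "epilepsy": 0.03,
    "substance_misuse": 0.045,
    # Charlson-weighted conditions
    "diabetes": 0.12,
    "copd": 0.08,
    "myocardial_infarction": 0.04,
    "heart_failure": 0.03,
    "renal_disease": 0.04,
    "liver_disease": 0.015,
}
DRUG_CLASS_PREVALENCE = {
    "rx_benzodiazepines": 0.22,
    "rx_antidepressants": 0.47,
    "rx_gabapentinoids": 0.008,
    "rx_muscle_relaxants": 0.011,
    "rx_z_drugs": 0.13,
    "rx_nsaids": 0.60,
}


@dataclass
class SyntheticDataset:
    """The generated tables plus planted ground truth.

    ``episodes`` is the truth table: one row per planted incident episode
    with its intended phenotype labels and cohort-eligibility flag.
    """

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    events: pd.DataFrame
    episodes: pd.DataFrame
    config: SimulationConfig | None = None

    def write_csv(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("patients", "prescriptions", "events", "episodes"):
            p = out / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        return paths

    @classmethod
    def read_csv(cls, in_dir: str | Path) -> "SyntheticDataset":
        in_dir = Path(in_dir)
        date_cols = {
            "patients": ["registration_start", "registration_end", "death_date",
                         "last_collection_date"],
            "prescriptions": ["issue_date"],
            "events": ["event_date"],
            "episodes": ["index_date"],
        }
        frames = {}
        for name, cols in date_cols.items():
            df = pd.read_csv(in_dir / f"{name}.csv")
            for c in cols:
                if c in df.columns:
                    df[c] = pd.to_datetime(df[c])
            frames[name] = df
        return cls(patients=frames["patients"],
                   prescriptions=frames["prescriptions"],
                   events=frames["events"], episodes=frames["episodes"])


def _empty_dataset(config: SimulationConfig) -> SyntheticDataset:
    def empty(cols, datecols):
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
        for c in datecols:
            df[c] = pd.Series(dtype="datetime64[ns]")
        return df

    return SyntheticDataset(
        patients=empty(PATIENT_COLUMNS, ["registration_start", "registration_end",
                                         "death_date", "last_collection_date"]),
        prescriptions=empty(PRESCRIPTION_COLUMNS, ["issue_date"]),
        events=empty(EVENT_COLUMNS, ["event_date"]),
        episodes=empty(EPISODE_COLUMNS, ["index_date"]),
        config=config,
    )


def _plan_episode(rng: np.random.Generator, cfg: SimulationConfig,
                  index_day: int, reg_end_day: int) -> tuple[list[tuple[int, int | None]], bool, bool]:
    """Return (issues, is_ltot, is_disc) for one episode.

    ``issues`` is a list of (day offset from index, explicit duration or
    None).  All issue days fit within the patient's registration by
    construction (the caller guarantees index_day + 550 <= reg_end_day).
    """
    step = cfg.refill_interval          # 28
    supply = cfg.refill_interval        # 28-day supplies throughout
    is_ltot = rng.random() < cfg.p_ltot
    if not is_ltot:
        issues: list[tuple[int, int | None]] = [(0, None)]
        if rng.random() < 0.5:
            # one extra issue, either early (outside the evaluation window)
            # or isolated inside it; never enough for either criterion
            extra = int(rng.integers(60, 300)) if rng.random() < 0.6 else int(rng.integers(7, 25))
            issues.append((extra, None))
        return issues, False, False
    is_disc = rng.random() < cfg.p_discontinue
    last_day = 338 if is_disc else 338 + 14 * step  # persist through day ~730
    days = [0] + list(range(30, last_day + 1, step))
    # cap persisting chains at the registration edge (supply must fit)
    days = [d for d in days if index_day + d + supply - 1 <= reg_end_day]
    issues = [(d, None) for d in days]
    if is_disc:
        # the final refill carries an explicit duration so dose imputation
        # can never move the start of the opioid-free gap
        issues[-1] = (issues[-1][0], supply)
    return issues, True, is_disc


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate patient, prescription and coded-event tables with planted truth.

    Deterministic: identical config + seed give byte-identical tables.
    """
    cfg = config
    if cfg.n_patients == 0:
        return _empty_dataset(cfg)

    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.study_start)
    end = pd.Timestamp(cfg.study_end)
    data_end = pd.Timestamp(cfg.data_end)
    day0 = pd.Timestamp(date(2000, 1, 1))

    def to_day(ts: pd.Timestamp) -> int:
        return (ts - day0).days

    study_start_d, study_end_d = to_day(start), to_day(end)
    data_end_d = to_day(data_end)

    n = cfg.n_patients
    pid = np.array([f"p{str(i).zfill(6)}" for i in range(n)])
    sex = rng.choice(["F", "M"], size=n, p=[0.57, 0.43])
    birth_year = rng.integers(1925, 2001, size=n)
    # 75% registered before the study starts, 25% join during it
    pre = rng.random(n) < 0.75
    reg_start_d = np.where(
        pre,
        study_start_d - rng.integers(1, 3651, size=n),
        study_start_d + rng.integers(0, study_end_d - DAYS_PER_YEAR - study_start_d, size=n),
    )
    reg_end_d = np.full(n, data_end_d)
    transfer = rng.random(n) < cfg.p_transfer
    t_end = reg_start_d + 400 + rng.integers(
        0, np.maximum(data_end_d - reg_start_d - 400, 1), size=n)
    reg_end_d = np.where(transfer, np.minimum(t_end, data_end_d), reg_end_d)
    death = (rng.random(n) < cfg.p_death) & ~transfer
    death_d = reg_start_d + 365 + rng.integers(
        0, np.maximum(data_end_d - reg_start_d - 365, 1), size=n)
    death_d = np.minimum(death_d, data_end_d)
    reg_end_d = np.where(death, death_d, reg_end_d)

    def cat(levels, weights, miss_key):
        v = rng.choice(levels, size=n, p=weights).astype(object)
        m = rng.random(n) < cfg.missingness.get(miss_key, 0.0)
        v[m] = None
        return v

    imd = rng.integers(1, 6, size=n).astype(object)
    imd[rng.random(n) < cfg.missingness.get("imd_quintile", 0.0)] = None
    patients = pd.DataFrame({
        "patient_id": pid,
        "sex": sex,
        "birth_year": birth_year,
        "registration_start": day0 + pd.to_timedelta(reg_start_d, unit="D"),
        "registration_end": day0 + pd.to_timedelta(reg_end_d, unit="D"),
        "death_date": pd.Series(
            np.where(death, death_d, np.nan), dtype=float),
        "last_collection_date": data_end,
        "region": rng.choice(REGIONS, size=n, p=REGION_W),
        "imd_quintile": imd,
        "ethnicity": cat(ETHNICITIES, ETHNICITY_W, "ethnicity"),
        "smoking": cat(SMOKING, SMOKING_W, "smoking"),
        "drinking": cat(DRINKING, DRINKING_W, "drinking"),
    })
    patients["death_date"] = day0 + pd.to_timedelta(patients["death_date"], unit="D")

    products = [p for p in cfg.formulary if not p.excluded_flag]
    weights = np.array([cfg.product_weights.get(p.product_id, 0.0) for p in products])
    if weights.sum() <= 0:
        weights = np.ones(len(products))
    weights = weights / weights.sum()
    prod_by_id = {p.product_id: p for p in cfg.formulary}

    # phenotype-affecting patient roles, drawn once per patient
    no_cncp = rng.random(n) < cfg.p_no_cncp
    prior_cancer = rng.random(n) < cfg.p_prior_cancer
    has_nmsc = rng.random(n) < cfg.p_nmsc

    horizon_need = cfg.phenotyping.disc_start + cfg.phenotyping.gap_days  # 545

    rx_rows: list[tuple] = []       # (pid, issue_day, product_id, qty, dd, dur)
    ep_rows: list[tuple] = []
    ev_rows: list[tuple] = []       # (pid, day, category)

    adult_from = birth_year + 18    # first calendar year aged >=18

    for i in range(n):
        rs, re = int(reg_start_d[i]), int(reg_end_d[i])
        next_free = rs + DAYS_PER_YEAR  # first day with a full clean lookback
        my_episodes: list[tuple[int, str, bool, bool]] = []
        for year in cfg.years:
            if year < adult_from[i]:
                continue
            h = cfg.hazard(year)
            if h <= 0 or rng.random() >= h:
                continue
            y0 = to_day(pd.Timestamp(date(year, 1, 1)))
            y1 = to_day(pd.Timestamp(date(year, 12, 31)))
            lo = max(y0, next_free, rs + DAYS_PER_YEAR)
            hi = min(y1, study_end_d, re - horizon_need - 5)
            if lo > hi:
                continue
            index_day = int(rng.integers(lo, hi + 1))
            prod = products[int(rng.choice(len(products), p=weights))]
            issues, is_ltot, is_disc = _plan_episode(rng, cfg, index_day, re)
            qty = prod.typical_quantity
            for off, dur in issues:
                jitter = 1.0 if is_ltot else float(rng.choice([0.5, 1.0, 1.0]))
                rx_rows.append((pid[i], index_day + off, prod.product_id,
                                qty * jitter, prod.typical_daily_units, dur))
            my_episodes.append((index_day, prod.product_id, is_ltot, is_disc))
            last_cover = index_day + max(off for off, _ in issues) + cfg.refill_interval
            next_free = last_cover + DAYS_PER_YEAR + 1

        # clinical events and per-episode cohort-eligibility truth
        cancer_day = None
        if my_episodes:
            first_index_day = my_episodes[0][0]
            if not no_cncp[i]:
                if rng.random() < 0.10:
                    ev_rows.append((pid[i], first_index_day + int(rng.integers(0, 183)),
                                    "cncp"))
                else:
                    back = int(rng.integers(30, min(900, first_index_day - rs)))
                    ev_rows.append((pid[i], first_index_day - back, "cncp"))
            if prior_cancer[i]:
                back = int(rng.integers(0, 3600))
                cancer_day = max(rs, first_index_day - back)
                ev_rows.append((pid[i], cancer_day, "cancer"))
            if has_nmsc[i]:
                back = int(rng.integers(0, min(3000, max(first_index_day - rs, 1))))
                ev_rows.append((pid[i], first_index_day - back, "nmsc"))
            for index_day, prod_id, is_ltot, is_disc in my_episodes:
                if no_cncp[i]:
                    in_cohort, reason = False, "no_cncp"
                elif cancer_day is not None and index_day - cancer_day <= TEN_YEARS_DAYS:
                    in_cohort, reason = False, "prior_cancer"
                else:
                    in_cohort, reason = True, ""
                ep_rows.append((pid[i], index_day, prod_id, is_ltot, is_disc,
                                in_cohort, reason))
        elif rng.random() < 0.25:   # background CNCP without opioid use
            if re > rs + 30:
                ev_rows.append((pid[i], int(rng.integers(rs + 1, re)), "cncp"))

    # background comorbidity / concurrent-drug events for everyone
    span = np.maximum(reg_end_d - reg_start_d - 1, 1)
    for cat_name, prev in {**COMORBIDITY_PREVALENCE, **DRUG_CLASS_PREVALENCE}.items():
        hit = rng.random(n) < prev
        days = reg_start_d + 1 + (rng.random(n) * span).astype(int)
        for j in np.flatnonzero(hit):
            ev_rows.append((pid[j], int(days[j]), cat_name))

    # noise issues of excluded products (dependence treatment, filtered later)
    noisy = np.flatnonzero(rng.random(n) < cfg.p_excluded_product_noise)
    excluded_products = [p for p in cfg.formulary if p.excluded_flag]
    for j in noisy:
        if not excluded_products or reg_end_d[j] <= reg_start_d[j] + 30:
            continue
        p = excluded_products[int(rng.integers(len(excluded_products)))]
        d = int(rng.integers(reg_start_d[j] + 1, reg_end_d[j]))
        rx_rows.append((pid[j], d, p.product_id, p.typical_quantity,
                        p.typical_daily_units, None))

    prescriptions = pd.DataFrame(
        rx_rows, columns=["patient_id", "issue_day", "product_id", "quantity",
                          "daily_dose_units", "duration_days"])
    prescriptions["issue_date"] = day0 + pd.to_timedelta(
        prescriptions.pop("issue_day"), unit="D")
    prescriptions = prescriptions[PRESCRIPTION_COLUMNS].sort_values(
        ["patient_id", "issue_date", "product_id"], kind="mergesort",
    ).reset_index(drop=True)

    # inject missing / implausible values (after generation, by masking)
    m = cfg.missingness
    nrx = len(prescriptions)
    qmiss = rng.random(nrx) < m.get("quantity", 0.0)
    dmiss = rng.random(nrx) < m.get("daily_dose_units", 0.0)
    qbad = rng.random(nrx) < m.get("quantity_implausible", 0.0)
    dbad = rng.random(nrx) < m.get("daily_dose_implausible", 0.0)
    prescriptions.loc[qmiss, "quantity"] = np.nan
    prescriptions.loc[dmiss, "daily_dose_units"] = np.nan
    prescriptions.loc[qbad & ~qmiss, "quantity"] = -5.0
    prescriptions.loc[dbad & ~dmiss, "daily_dose_units"] = 48.0

    events = pd.DataFrame(ev_rows, columns=["patient_id", "event_day", "category"])
    events["event_date"] = day0 + pd.to_timedelta(events.pop("event_day"), unit="D")
    events = events[EVENT_COLUMNS].sort_values(
        ["patient_id", "event_date", "category"], kind="mergesort").reset_index(drop=True)
    # clip events into registration (background draws can land near edges)
    reg = patients.set_index("patient_id")
    ev_start = reg["registration_start"].reindex(events["patient_id"]).to_numpy()
    ev_end = reg["registration_end"].reindex(events["patient_id"]).to_numpy()
    events["event_date"] = np.minimum(np.maximum(events["event_date"].to_numpy(),
                                                 ev_start), ev_end)

    episodes = pd.DataFrame(ep_rows, columns=["patient_id", "index_day",
                                              "product_id", "is_ltot",
                                              "is_discontinuer", "in_cohort",
                                              "exclusion_reason"])
    episodes["index_date"] = day0 + pd.to_timedelta(episodes.pop("index_day"), unit="D")
    episodes = episodes[EPISODE_COLUMNS].sort_values(
        ["patient_id", "index_date"], kind="mergesort").reset_index(drop=True)

    return SyntheticDataset(patients=patients, prescriptions=prescriptions,
                            events=events, episodes=episodes, config=cfg)


# ---------------------------------------------------------------------------
# model-level count simulator


def simulate_segmented_counts(beta, offsets: dict[int, float],
                              dispersion: float = 0.0,
                              excluded_years: set[int] = frozenset(),
                              seed: int = 0,
                              break_year: int = 2014) -> pd.DataFrame:
    """Draw an annual count series directly from the segmented count model.

    ``beta`` = (b0, b1, b2, b3) on the log scale with the package's design
    coding (t = year - first_year, I = year > break_year,
    X = (year - break_year - 1) * I); ``offsets`` maps year -> denominator.
    Counts are NB2 (gamma-Poisson mixture) with variance mu + dispersion*mu^2,
    reducing to Poisson when ``dispersion == 0``.  The returned frame covers
    every year in ``offsets`` (including any the fit will later exclude).
    """
    if not offsets:
        raise ConfigurationError("offsets must be non-empty")
    if len(offsets) < 6:
        raise ConfigurationError("need >= 6 years of offsets")
    if dispersion < 0:
        raise ConfigurationError("dispersion must be >= 0")
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (4,):
        raise ConfigurationError("beta must be a 4-vector")
    years = np.array(sorted(offsets))
    den = np.array([offsets[y] for y in years], dtype=float)
    if np.any(den <= 0):
        raise ConfigurationError("denominators must be positive")
    first = years[0]
    t = years - first
    I = (years > break_year).astype(float)
    X = (years - (break_year + 1)) * I
    mu = np.exp(beta[0] + beta[1] * t + beta[2] * I + beta[3] * X) * den
    rng = np.random.default_rng(seed)
    if dispersion == 0:
        num = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
        num = rng.poisson(lam)
    return pd.DataFrame({
        "year": years,
        "numerator": num.astype(int),
        "denominator": den,
        "excluded": np.isin(years, list(excluded_years)),
    })
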