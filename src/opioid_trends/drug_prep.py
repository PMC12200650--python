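"""Prescription cleaning: imputation, supply-day derivation and MME conversion.

Raw prescription issues carry a quantity (dose units), a daily dose
(units/day) and occasionally an explicit duration; any of these may be
missing or implausible.  Cleaning proceeds in the population-level spirit of
published drug-preparation algorithms:

1. drop issues of excluded products (methadone, sublingual buprenorphine)
   and fail loudly on unknown product ids;
2. replace missing/implausible quantity and daily dose with the
   product-level median of plausible observed values, falling back to the
   formulary's typical values, flagging every imputation;
3. supply days = explicit duration when present and plausible, else
   ceil(quantity / daily dose), clamped to [1, 90];
4. daily MME = daily dose units x strength_mg x per-product MME factor.

Supply intervals are closed: a prescription issued on day d with s supply
days covers days d .. d+s-1 inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DrugPreparationError(ValueError):
    pass


@dataclass
class PlausibilityBounds:
    """Acceptance ranges for raw prescription fields."""

    quantity_min: float = 1.0
    quantity_max: float = 1000.0
    daily_dose_max: float = 24.0     # daily dose must be in (0, 24]
    duration_min: int = 1
    duration_max: int = 90
    max_supply_days: int = 90


CLEAN_COLUMNS = [
    "patient_id", "supply_start", "supply_days", "supply_end", "daily_mme",
    "product_id", "potency_class", "action_class", "imputed_quantity",
    "imputed_daily_dose",
]


def _plausible_quantity(q: pd.Series, bounds: PlausibilityBounds) -> pd.Series:
    return q.notna() & (q >= bounds.quantity_min) & (q <= bounds.quantity_max)


def _plausible_daily_dose(d: pd.Series, bounds: PlausibilityBounds) -> pd.Series:
    return d.notna() & (d > 0) & (d <= bounds.daily_dose_max)


def filter_and_classify(records: pd.DataFrame, products: pd.DataFrame,
                        log: dict | None = None) -> pd.DataFrame:
    """Remove excluded-product issues and attach product metadata.

    ``products`` is indexed by product_id (see :mod:`opioid_trends.products`).
    Raises :class:`DrugPreparationError` listing any unknown product ids.
    """
    if records.empty:
        out = records.copy()
        for c in ("strength_mg", "mme_factor", "potency_class", "action_class"):
            out[c] = pd.Series(dtype=products[c].dtype if c in products else object)
        return out
    unknown = sorted(set(records["product_id"]) - set(products.index))
    if unknown:
        raise DrugPreparationError(f"unknown product ids: {unknown}")
    meta = products[["strength_mg", "mme_factor", "potency_class",
                     "action_class", "excluded_flag"]]
    out = records.merge(meta, left_on="product_id", right_index=True, how="left")
    n_excluded = int(out["excluded_flag"].sum())
    if log is not None:
        log["n_excluded_product"] = n_excluded
    return out.loc[~out["excluded_flag"]].drop(columns="excluded_flag") \
              .reset_index(drop=True)


def impute_missing_fields(records: pd.DataFrame, products: pd.DataFrame,
                          bounds: PlausibilityBounds | None = None,
                          log: dict | None = None) -> pd.DataFrame:
    """Fill missing/implausible quantity and daily dose; flag what was imputed.

    Product-level medians are computed over plausible observed values; a
    product with none falls back to the formulary's typical quantity and
    daily units.  Rows that still cannot be completed are dropped with a
    logged count.  Idempotent, order-preserving.
    """
    bounds = bounds or PlausibilityBounds()
    out = records.copy()
    if out.empty:
        out["imputed_quantity"] = pd.Series(dtype=bool)
        out["imputed_daily_dose"] = pd.Series(dtype=bool)
        return out
    q = pd.to_numeric(out["quantity"], errors="coerce")
    d = pd.to_numeric(out["daily_dose_units"], errors="coerce")
    ok_q = _plausible_quantity(q, bounds)
    ok_d = _plausible_daily_dose(d, bounds)

    med_q = q.where(ok_q).groupby(out["product_id"]).median()
    med_d = d.where(ok_d).groupby(out["product_id"]).median()
    fb_q = products["typical_daily_units"] * products["typical_supply_days"]
    fb_d = products["typical_daily_units"]
    fill_q = med_q.reindex(out["product_id"]).to_numpy()
    fill_d = med_d.reindex(out["product_id"]).to_numpy()
    fill_q = np.where(np.isnan(fill_q),
                      fb_q.reindex(out["product_id"]).to_numpy(), fill_q)
    fill_d = np.where(np.isnan(fill_d),
                      fb_d.reindex(out["product_id"]).to_numpy(), fill_d)

    out["quantity"] = np.where(ok_q, q, fill_q)
    out["daily_dose_units"] = np.where(ok_d, d, fill_d)
    # OR with any flags from a previous pass so the operation is idempotent
    prev_q = out["imputed_quantity"].to_numpy() if "imputed_quantity" in out \
        else False
    prev_d = out["imputed_daily_dose"].to_numpy() if "imputed_daily_dose" in out \
        else False
    out["imputed_quantity"] = (~ok_q).to_numpy() | prev_q
    out["imputed_daily_dose"] = (~ok_d).to_numpy() | prev_d

    still_bad = out["quantity"].isna() | out["daily_dose_units"].isna() \
        | (out["daily_dose_units"] <= 0)
    if log is not None:
        log["n_imputed_quantity"] = int((~ok_q & ~still_bad).sum())
        log["n_imputed_daily_dose"] = int((~ok_d & ~still_bad).sum())
        log["n_dropped_unimputable"] = int(still_bad.sum())
    return out.loc[~still_bad].reset_index(drop=True)


def derive_supply_days(records: pd.DataFrame,
                       bounds: PlausibilityBounds | None = None) -> pd.Series:
    """Supply days per issue: explicit plausible duration wins, else
    ceil(quantity / daily dose), clamped to [1, max_supply_days]."""
    bounds = bounds or PlausibilityBounds()
    d = pd.to_numeric(records["daily_dose_units"], errors="coerce")
    if (d.isna() | (d <= 0)).any():
        raise DrugPreparationError("daily_dose_units must be imputed before "
                                   "deriving supply days")
    derived = np.ceil(pd.to_numeric(records["quantity"]) / d)
    if "duration_days" in records:
        dur = pd.to_numeric(records["duration_days"], errors="coerce")
        use_dur = dur.notna() & (dur >= bounds.duration_min) & (dur <= bounds.duration_max)
        derived = derived.where(~use_dur, dur)
    return derived.clip(1, bounds.max_supply_days).astype(int)


def compute_daily_mme(records: pd.DataFrame) -> pd.Series:
    """Daily dose in oral morphine milligram equivalents (requires the
    product metadata columns attached by :func:`filter_and_classify`)."""
    mme = (pd.to_numeric(records["daily_dose_units"])
           * records["strength_mg"] * records["mme_factor"])
    if not np.isfinite(mme).all() or (mme <= 0).any():
        raise DrugPreparationError("non-positive or non-finite daily MME")
    return mme


def clean_prescriptions(records: pd.DataFrame, products: pd.DataFrame,
                        bounds: PlausibilityBounds | None = None,
                        log: dict | None = None) -> pd.DataFrame:
    """Full cleaning pipeline: exclusion filter -> imputation -> supply/MME.

    Returns one row per analysable prescription with closed supply intervals
    and imputation flags.  ``log`` (optional dict) accumulates removal and
    imputation counts.
    """
    bounds = bounds or PlausibilityBounds()
    log = log if log is not None else {}
    log["n_input"] = len(records)
    kept = filter_and_classify(records, products, log=log)
    kept = impute_missing_fields(kept, products, bounds, log=log)
    if kept.empty:
        return pd.DataFrame({c: pd.Series(dtype="datetime64[ns]"
                                          if "supply" in c and c != "supply_days"
                                          else object)
                             for c in CLEAN_COLUMNS})
    supply_days = derive_supply_days(kept, bounds)
    out = pd.DataFrame({
        "patient_id": kept["patient_id"],
        "supply_start": pd.to_datetime(kept["issue_date"]),
        "supply_days": supply_days,
        "daily_mme": compute_daily_mme(kept),
        "product_id": kept["product_id"],
        "potency_class": kept["potency_class"],
        "action_class": kept["action_class"],
        "imputed_quantity": kept["imputed_quantity"],
        "imputed_daily_dose": kept["imputed_daily_dose"],
    })
    out["supply_end"] = out["supply_start"] + pd.to_timedelta(
        out["supply_days"] - 1, unit="D")
    log["n_output"] = len(out)
    return out[CLEAN_COLUMNS].sort_values(
        ["patient_id", "supply_start", "product_id"], kind="mergesort",
    ).reset_index(drop=True)
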