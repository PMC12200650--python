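"""Opioid product metadata: strength, morphine-equivalence, potency and duration classes.

Doses are standardised to oral morphine milligram equivalents (MME) with
per-product conversion factors: ``daily MME = units/day x strength_mg x
mme_factor``.  Methadone and sublingual buprenorphine are excluded from all
analyses because their primary indication is opioid-dependence treatment
rather than analgesia; the transdermal buprenorphine formulation is a
distinct product and is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

WEAK = "weak"
STRONG = "strong"
SHORT_ACTING = "short-acting"
LONG_ACTING = "long-acting"


@dataclass(frozen=True)
class Product:
    """One opioid product with conversion metadata.

    ``typical_daily_units`` and ``typical_supply_days`` are the formulary
    defaults used by the synthetic generator and as imputation fallbacks when
    a product has no observed plausible records at all.
    """

    product_id: str
    name: str
    strength_mg: float
    mme_factor: float
    potency_class: str
    action_class: str
    excluded_flag: bool = False
    typical_daily_units: float = 2.0
    typical_supply_days: int = 28

    def __post_init__(self) -> None:
        if self.strength_mg <= 0:
            raise ValueError(f"{self.product_id}: strength_mg must be > 0")
        if self.mme_factor <= 0:
            raise ValueError(f"{self.product_id}: mme_factor must be > 0")

    @property
    def typical_quantity(self) -> float:
        return self.typical_daily_units * self.typical_supply_days

    @property
    def daily_mme(self) -> float:
        """Daily MME at the typical daily dose."""
        return self.typical_daily_units * self.strength_mg * self.mme_factor


# Synthetic formulary. Conversion factors follow the standard oral-MME tables
# (codeine/dihydrocodeine/tramadol 0.1, morphine 1.0, oxycodone 1.5);
# the weights with which the generator samples these products are chosen so
# that the mean daily dose of the synthetic long-term-therapy cohort lands
# near 20 MME mg/day, the magnitude seen in UK primary-care CNCP cohorts.
DEFAULT_FORMULARY: tuple[Product, ...] = (
    Product("codeine30", "codeine 30mg tab", 30.0, 0.1, WEAK, SHORT_ACTING,
            typical_daily_units=6),
    Product("codeine15", "codeine 15mg tab", 15.0, 0.1, WEAK, SHORT_ACTING,
            typical_daily_units=8),
    Product("tramadol50", "tramadol 50mg cap", 50.0, 0.1, WEAK, SHORT_ACTING,
            typical_daily_units=4),
    Product("dhc30", "dihydrocodeine 30mg tab", 30.0, 0.1, WEAK, SHORT_ACTING,
            typical_daily_units=6),
    Product("morphine10", "morphine MR 10mg tab", 10.0, 1.0, STRONG, LONG_ACTING,
            typical_daily_units=2),
    Product("oxycodone5", "oxycodone 5mg cap", 5.0, 1.5, STRONG, SHORT_ACTING,
            typical_daily_units=4),
    Product("bup_td10", "buprenorphine 10ug/h transdermal patch", 0.24, 100.0,
            STRONG, LONG_ACTING, typical_daily_units=1),
    # dependence-treatment products: present in raw data, excluded from analysis
    Product("methadone5", "methadone 5mg tab", 5.0, 4.7, STRONG, LONG_ACTING,
            excluded_flag=True, typical_daily_units=4),
    Product("bup_sl2", "buprenorphine 2mg sublingual tab", 2.0, 30.0, STRONG,
            SHORT_ACTING, excluded_flag=True, typical_daily_units=4),
)

# Generator sampling weights over the non-excluded formulary (episode level).
DEFAULT_PRODUCT_WEIGHTS: dict[str, float] = {
    "codeine30": 0.30,
    "codeine15": 0.11,
    "tramadol50": 0.25,
    "dhc30": 0.15,
    "morphine10": 0.08,
    "oxycodone5": 0.06,
    "bup_td10": 0.05,
}

PRODUCT_COLUMNS = [
    "product_id", "name", "strength_mg", "mme_factor", "potency_class",
    "action_class", "excluded_flag", "typical_daily_units", "typical_supply_days",
]


def products_to_frame(products: tuple[Product, ...] | list[Product]) -> pd.DataFrame:
    """Product metadata as a DataFrame indexed by product_id."""
    df = pd.DataFrame([asdict(p) for p in products], columns=PRODUCT_COLUMNS)
    return df.set_index("product_id", drop=False)


def write_products_csv(products, path: str | Path) -> None:
    products_to_frame(products).to_csv(path, index=False)


def read_products_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["excluded_flag"] = df["excluded_flag"].astype(bool)
    return df.set_index("product_id", drop=False)
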