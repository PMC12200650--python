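"""Packaged reference data.

``load_reference_counts`` returns the published annual counts of incident
opioid users, L-TOT users and L-TOT discontinuers (with their denominators
and printed percentage rates) for UK primary care, 2009-2019.  The counts
are inputs to the statistical layer, letting the segmented regressions be
exercised and checked independently of the synthetic pipeline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_FIXTURE = "uk_annual_opioid_counts.csv"


def load_reference_counts() -> pd.DataFrame:
    """Annual series table: year, n_registered, n_incident, n_ltot,
    n_discontinuers plus the published percent rates."""
    with resources.files("opioid_trends.data").joinpath(_FIXTURE).open() as fh:
        return pd.read_csv(fh)
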