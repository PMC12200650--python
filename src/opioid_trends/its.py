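"""Segmented count regression for annual opioid-utilisation rates.

Each annual series (numerator count, denominator count per calendar year)
is modelled as an interrupted time series around a fixed breakpoint with a
log-link count regression and offset ln(denominator):

    ln mu_y = b0 + b1*t + b2*I + b3*X + ln(denominator_y)

with t = y - first_year, I = 1 iff y > break_year, and
X = (y - (break_year+1)) * I.  exp(b1) is the annual pre-break rate ratio,
exp(b2) the observed-vs-projected level ratio in the first post-break year
(the centering of X makes this exact), and exp(b3) the post- vs pre-break
annual slope ratio.  The break year itself is excluded from the primary
fit; a sensitivity fit keeps it in the pre-break segment.

The primary family is NB2 negative binomial (variance mu + alpha*mu^2)
with MLE dispersion; when the dispersion estimate collapses to zero or the
NB likelihood fails to converge the model is refitted as Poisson and
flagged.  Confidence intervals are Wald on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.discrete.discrete_model import NegativeBinomial, Poisson

from .config import ConfigurationError, SegmentedModelSpec

COEF_NAMES = ["intercept", "time", "indicator", "interaction"]
ALPHA_FLOOR = 1e-8


class FitError(RuntimeError):
    pass


@dataclass
class SegmentedFitResult:
    """Coefficients and Wald inference for one segmented count regression."""

    params: np.ndarray            # b0..b3 on the log scale
    bse: np.ndarray
    dispersion: float
    family: str                   # family actually used
    converged: bool
    loglik: float
    nobs: int
    ci_level: float = 0.95
    years: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def irr(self) -> np.ndarray:
        return np.exp(self.params)

    @property
    def ci(self) -> np.ndarray:
        z = stats.norm.ppf(0.5 + self.ci_level / 2)
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return np.column_stack([lo, hi])

    @property
    def pvalues(self) -> np.ndarray:
        z = self.params / self.bse
        return 2 * stats.norm.sf(np.abs(z))

    def summary_frame(self) -> pd.DataFrame:
        ci = self.ci
        return pd.DataFrame({
            "coefficient": COEF_NAMES,
            "beta": self.params,
            "se": self.bse,
            "irr": self.irr,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": self.pvalues,
            "significant": self.pvalues < 0.05,
            "family": self.family,
            "dispersion": self.dispersion,
        })


def compute_yearly_rates(series: pd.DataFrame, numerator: str = "numerator",
                         denominator: str = "denominator") -> pd.Series:
    """Percent rates = 100 * numerator / denominator, 2-decimal rounding."""
    den = series[denominator]
    if (den <= 0).any():
        bad = series.loc[den <= 0, "year"].tolist()
        raise ConfigurationError(f"zero/negative denominator in years {bad}")
    return (100.0 * series[numerator] / den).round(2)


def build_design(years, spec: SegmentedModelSpec,
                 apply_exclusions: bool = True) -> pd.DataFrame:
    """Design rows (t, I, X) for the retained years."""
    years = np.asarray(sorted(years))
    if apply_exclusions:
        years = years[~np.isin(years, list(spec.excluded_years))]
    if years.size == 0:
        raise ConfigurationError("all years excluded from the design")
    t = years - spec.first_year
    I = (years > spec.break_year).astype(float)
    X = (years - (spec.break_year + 1)) * I
    return pd.DataFrame({"year": years, "t": t.astype(float), "I": I, "X": X})


def _fit_poisson(y, X, offset):
    res = Poisson(y, X, offset=offset).fit(disp=0, maxiter=200)
    return res


def _fit_nb(y, X, offset, start):
    """NB2 MLE with a Poisson warm start.

    Newton steps diverge on the dispersion when the series is nearly
    equidispersed, so optimise with Nelder-Mead first and polish with BFGS.
    """
    model = NegativeBinomial(y, X, offset=offset, loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(start_params=np.append(start, 0.01), method="nm",
                        maxiter=5000, disp=0)
        converged = bool(res.mle_retvals.get("converged", False))
        polished = model.fit(start_params=res.params, method="bfgs",
                             maxiter=500, disp=0)
    if np.isfinite(polished.llf) and polished.llf >= res.llf:
        res, converged = polished, converged or bool(
            polished.mle_retvals.get("converged", False))
    return res, converged


def fit_segmented(series: pd.DataFrame, spec: SegmentedModelSpec | None = None
                  ) -> SegmentedFitResult:
    """Fit the segmented count model to one annual series.

    ``series`` needs columns year, numerator, denominator.  Requires >= 6
    retained years.  Family per ``spec.family`` with the NB -> Poisson
    fallback described in the module docstring.
    """
    spec = spec or SegmentedModelSpec()
    df = series.sort_values("year").reset_index(drop=True)
    design = build_design(df["year"], spec)
    df = df.merge(design, on="year")
    if len(df) < 6:
        raise ConfigurationError("need >= 6 retained years to fit")
    if (df["numerator"] < 0).any():
        raise ConfigurationError("negative numerators")
    if (df["denominator"] <= 0).any():
        raise ConfigurationError("non-positive denominators")

    y = df["numerator"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), df["t"], df["I"], df["X"]])
    offset = np.log(df["denominator"].to_numpy(dtype=float))

    pois = _fit_poisson(y, X, offset)
    if spec.family == "poisson":
        return SegmentedFitResult(
            params=pois.params.copy(), bse=pois.bse.copy(), dispersion=0.0,
            family="poisson", converged=bool(pois.mle_retvals.get("converged", True)),
            loglik=float(pois.llf), nobs=len(df), ci_level=spec.ci_level,
            years=df["year"].to_numpy())

    try:
        nb, nb_conv = _fit_nb(y, X, offset, pois.params)
        alpha = float(nb.params[-1])
        usable = (nb_conv and alpha >= ALPHA_FLOOR
                  and np.all(np.isfinite(nb.bse[:4])) and np.all(nb.bse[:4] > 0))
    except Exception:
        usable = False
    if not usable:
        if not bool(pois.mle_retvals.get("converged", True)):
            raise FitError("neither negative-binomial nor Poisson converged")
        return SegmentedFitResult(
            params=pois.params.copy(), bse=pois.bse.copy(), dispersion=0.0,
            family="poisson", converged=True, loglik=float(pois.llf),
            nobs=len(df), ci_level=spec.ci_level, years=df["year"].to_numpy())
    return SegmentedFitResult(
        params=nb.params[:4].copy(), bse=nb.bse[:4].copy(), dispersion=alpha,
        family="negative_binomial", converged=True, loglik=float(nb.llf),
        nobs=len(df), ci_level=spec.ci_level, years=df["year"].to_numpy())


def project_counterfactual(fit: SegmentedFitResult, years,
                           spec: SegmentedModelSpec | None = None) -> pd.Series:
    """Pre-break linear projection (b0, b1 only) on the percent scale."""
    spec = spec or SegmentedModelSpec()
    years = np.asarray(list(years))
    t = years - spec.first_year
    rate = np.exp(fit.params[0] + fit.params[1] * t) * 100.0
    return pd.Series(rate, index=years, name="projected_rate_percent")


def fitted_rates(fit: SegmentedFitResult, spec: SegmentedModelSpec | None = None
                 ) -> pd.Series:
    """Model-fitted rates (percent) for the retained years."""
    spec = spec or SegmentedModelSpec()
    design = build_design(fit.years, spec)
    lin = (fit.params[0] + fit.params[1] * design["t"]
           + fit.params[2] * design["I"] + fit.params[3] * design["X"])
    return pd.Series(np.exp(lin.to_numpy()) * 100.0,
                     index=design["year"].to_numpy(),
                     name="fitted_rate_percent")


def run_sensitivity(series: pd.DataFrame, spec: SegmentedModelSpec | None = None
                    ) -> dict[str, SegmentedFitResult]:
    """(a) refit with the break year retained in the pre-break segment;
    (b) Poisson fit with the default exclusion."""
    spec = spec or SegmentedModelSpec()
    include = SegmentedModelSpec(
        first_year=spec.first_year, last_year=spec.last_year,
        break_year=spec.break_year, excluded_years=frozenset(),
        family=spec.family, ci_level=spec.ci_level)
    poisson = SegmentedModelSpec(
        first_year=spec.first_year, last_year=spec.last_year,
        break_year=spec.break_year, excluded_years=spec.excluded_years,
        family="poisson", ci_level=spec.ci_level)
    return {"include_break_year": fit_segmented(series, include),
            "poisson": fit_segmented(series, poisson)}


def structural_break_scan(series: pd.DataFrame, candidate_years,
                          min_side_years: int = 3) -> pd.DataFrame:
    """Likelihood-ratio scan for the breakpoint.

    For each candidate b: segmented Poisson model (break at b, no year
    excluded) against the single-trend Poisson model; statistic
    2*(ll_seg - ll_null) on 2 df.  Returns the statistic table with the
    argmax flagged; a chi-square p-value indicates whether the best break
    improves at all on the single trend.
    """
    df = series.sort_values("year").reset_index(drop=True)
    years = df["year"].to_numpy()
    y = df["numerator"].to_numpy(dtype=float)
    offset = np.log(df["denominator"].to_numpy(dtype=float))
    t = (years - years[0]).astype(float)
    X0 = np.column_stack([np.ones(len(df)), t])
    ll0 = float(_fit_poisson(y, X0, offset).llf)

    rows = []
    for b in candidate_years:
        n_pre = int((years <= b).sum())
        n_post = int((years > b).sum())
        if n_pre < min_side_years or n_post < min_side_years:
            raise ConfigurationError(
                f"candidate {b} leaves < {min_side_years} years on one side")
        I = (years > b).astype(float)
        X = np.column_stack([np.ones(len(df)), t, I, (years - (b + 1)) * I])
        ll1 = float(_fit_poisson(y, X, offset).llf)
        lr = max(0.0, 2 * (ll1 - ll0))
        rows.append({"candidate_year": int(b), "lr_statistic": lr,
                     "p_value": float(stats.chi2.sf(lr, df=2))})
    out = pd.DataFrame(rows)
    best = out["lr_statistic"].idxmax()
    out["selected"] = False
    out.loc[best, "selected"] = True
    out.attrs["selected_year"] = int(out.loc[best, "candidate_year"])
    out.attrs["significant"] = bool(out.loc[best, "p_value"] < 0.05)
    return out


def fit_all_series(table: pd.DataFrame, spec: SegmentedModelSpec | None = None
                   ) -> dict[str, SegmentedFitResult]:
    """Fit the three standard series from a wide annual table
    (columns n_registered, n_incident, n_ltot, n_discontinuers)."""
    spec = spec or SegmentedModelSpec()
    pairs = {"incident": ("n_incident", "n_registered"),
             "ltot": ("n_ltot", "n_incident"),
             "discontinuers": ("n_discontinuers", "n_ltot")}
    out = {}
    for name, (num, den) in pairs.items():
        series = table.rename(columns={num: "numerator", den: "denominator"})[
            ["year", "numerator", "denominator"]]
        out[name] = fit_segmented(series, spec)
    return out


def results_table(fits: dict[str, SegmentedFitResult]) -> pd.DataFrame:
    """Stack per-series summaries into one long results table."""
    frames = []
    for name, fit in fits.items():
        f = fit.summary_frame()
        f.insert(0, "series", name)
        frames.append(f.loc[f["coefficient"] != "intercept"])
    return pd.concat(frames, ignore_index=True)
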