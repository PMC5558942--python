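"""Per-species temporal trend estimation.

For each species, body mass is regressed on the year of collection with
absolute latitude, longitude and sex as covariates (ordinary least
squares). The trend statistic is the partial correlation between mass and
year given the covariates,

    r_year = t / sqrt(t^2 + df_resid),

where ``t`` is the year coefficient's t-statistic — algebraically equal to
the Pearson correlation between the residuals of mass and of year after
each is regressed on the remaining covariates. Species are classified as
increasing/decreasing when the year effect is significant at ``alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .records import RecordTable, SpeciesMeta


@dataclass(frozen=True)
class SpeciesTrend:
    """Per-species trend summary."""

    species_id: str
    n: int
    slope_year: float        # grams per year
    r_year: float            # partial correlation, [-1, 1]
    p_year: float            # two-sided
    df_resid: int
    trend_class: str         # increase | none | decrease
    dropped_covariates: tuple = ()


def partial_r_from_t(t: float, df_resid: float) -> float:
    """Partial correlation from a coefficient t-statistic and residual df."""
    if df_resid <= 0:
        raise ValueError("residual df must be positive")
    return float(t / np.sqrt(t * t + df_resid))


def classify_trend(slope: float, p: float, alpha: float = 0.05) -> str:
    """"increase"/"decrease" when p < alpha (strict), otherwise "none"."""
    if p < alpha:
        return "increase" if slope > 0 else "decrease"
    return "none"


def _design(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Year + covariate design matrix; constant covariates are dropped."""
    X = pd.DataFrame({
        "year": df["year"].astype(float),
        "abs_latitude": df["latitude"].abs().astype(float),
        "longitude": df["longitude"].astype(float),
        "sex_male": (df["sex"] == "male").astype(float),
    })
    dropped = [c for c in ("abs_latitude", "longitude", "sex_male")
               if X[c].nunique() <= 1]
    return X.drop(columns=dropped), dropped


class SpeciesTrendModel(BaseEstimator):
    """OLS of body mass on year, |latitude|, longitude and sex for one species.

    Parameters
    ----------
    alpha : float
        Two-sided significance level for the trend classification.

    Attributes (after ``fit``)
    --------------------------
    result_ : statsmodels RegressionResults
    slope_year_, r_year_, p_year_, df_resid_, trend_class_
    dropped_covariates_ : tuple of covariates removed as constant/collinear
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, df, y=None):  # noqa: ARG002 - sklearn API
        df = getattr(df, "df", df)  # accept a RecordTable or a DataFrame
        X, dropped = _design(df)
        if df["year"].nunique() <= 1:
            raise ValueError("year is constant; no trend is estimable")
        n, k = X.shape
        if n <= k + 1:
            raise ValueError(
                f"need more records ({n}) than parameters ({k + 1})")
        if dropped:
            warnings.warn(
                f"dropping constant covariates {dropped}", stacklevel=2)
        res = sm.OLS(df["mass"].astype(float), sm.add_constant(X)).fit()
        self.result_ = res
        self.dropped_covariates_ = tuple(dropped)
        self.slope_year_ = float(res.params["year"])
        self.df_resid_ = int(res.df_resid)
        self.r_year_ = partial_r_from_t(float(res.tvalues["year"]),
                                        res.df_resid)
        self.p_year_ = float(res.pvalues["year"])
        self.trend_class_ = classify_trend(self.slope_year_, self.p_year_,
                                           self.alpha)
        return self

    def predict(self, df) -> np.ndarray:
        df = getattr(df, "df", df)
        X, _ = _design(df)
        X = X[[c for c in X.columns if c in self.result_.params.index]]
        return np.asarray(self.result_.predict(sm.add_constant(X, has_constant="add")))

    def summary(self, species_id: str = "") -> SpeciesTrend:
        return SpeciesTrend(
            species_id=species_id, n=int(self.result_.nobs),
            slope_year=self.slope_year_, r_year=self.r_year_,
            p_year=self.p_year_, df_resid=self.df_resid_,
            trend_class=self.trend_class_,
            dropped_covariates=self.dropped_covariates_)


def fit_species_model(df: pd.DataFrame, alpha: float = 0.05) -> SpeciesTrendModel:
    """Fit the per-species trend model to one species' records."""
    return SpeciesTrendModel(alpha=alpha).fit(df)


def fit_species_trends(records: RecordTable, alpha: float = 0.05,
                       min_n: int = 10) -> pd.DataFrame:
    """Per-species trend table over every species in ``records``.

    Species with fewer than ``min_n`` records (or an otherwise unfittable
    design) get NaN statistics and trend_class "unavailable".
    """
    rows = []
    for sp, df in records.df.groupby("species_id"):
        if len(df) < min_n:
            rows.append({"species_id": sp, "n": len(df), "slope_year": np.nan,
                         "r_year": np.nan, "p_year": np.nan,
                         "df_resid": np.nan, "trend_class": "unavailable"})
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t = fit_species_model(df, alpha=alpha).summary(sp)
        except ValueError:
            rows.append({"species_id": sp, "n": len(df), "slope_year": np.nan,
                         "r_year": np.nan, "p_year": np.nan,
                         "df_resid": np.nan, "trend_class": "unavailable"})
            continue
        rows.append({"species_id": sp, "n": t.n, "slope_year": t.slope_year,
                     "r_year": t.r_year, "p_year": t.p_year,
                     "df_resid": t.df_resid, "trend_class": t.trend_class})
    return pd.DataFrame(rows).set_index("species_id").sort_index()


def trend_class_counts(trends: pd.DataFrame) -> dict[str, int]:
    """Counts of increase / none / decrease over the fitted species."""
    vc = trends["trend_class"].value_counts()
    return {k: int(vc.get(k, 0)) for k in ("increase", "none", "decrease")}


def trend_covariate_correlations(trends: pd.DataFrame,
                                 meta: dict[str, SpeciesMeta],
                                 records: RecordTable) -> pd.DataFrame:
    """Pearson correlation of r_year with species-level covariates.

    Covariates: sample size, series length, mean body mass, and latitudinal
    extent of the records (a proxy for the breadth of the species'
    distribution). Constant covariates yield NaN, flagged in the table.
    """
    df = trends.dropna(subset=["r_year"])
    if len(df) < 3:
        raise ValueError("need at least 3 species with estimable trends")
    sp = df.index
    grp = records.df.groupby("species_id")
    mean_mass = grp["mass"].mean()
    lat_extent = grp["latitude"].apply(lambda s: s.abs().max() - s.abs().min())
    covs = pd.DataFrame({
        "n_records": [meta[s].n_records for s in sp],
        "series_length": [meta[s].series_length for s in sp],
        "mean_mass": mean_mass.reindex(sp).to_numpy(),
        "lat_extent": lat_extent.reindex(sp).to_numpy(),
    }, index=sp)
    rows = []
    for name, x in covs.items():
        if np.ptp(x.to_numpy(float)) == 0 or np.ptp(df["r_year"].to_numpy()) == 0:
            rows.append({"covariate": name, "r": np.nan, "p": np.nan,
                         "flag": "constant"})
        else:
            r, p = stats.pearsonr(df["r_year"], x)
            rows.append({"covariate": name, "r": float(r), "p": float(p),
                         "flag": ""})
    return pd.DataFrame(rows).set_index("covariate")
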