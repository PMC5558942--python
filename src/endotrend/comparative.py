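"""Cross-species classical statistics on the per-species trend values.

Once each species has an ``r_year``, the questions become comparative: do
birds and mammals differ, do aquatic and terrestrial species differ, and
did the trend change between the first and second half of the 20th
century? These are answered with a two-way main-effects ANOVA (Type III
sums of squares, sum-to-zero coding — the design is unbalanced), an
ANCOVA adding series length as a covariate with a parallelism
(homogeneity-of-slopes) check, standard assumption tests, a split of each
species' records at 1950, and a paired t-test on the per-period r_year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .records import RecordTable, SpeciesMeta
from .trends import fit_species_trends


@dataclass
class AnovaResult:
    """F tests per effect from an ANOVA/ANCOVA fit."""

    effects: pd.DataFrame            # index effect; columns F, df_num, df_den, p
    ss_type: str = "III (sum-to-zero coding)"
    model: object = None             # fitted statsmodels results
    parallelism: dict | None = None  # {"F":, "df_num":, "df_den":, "p":}

    def __getitem__(self, effect: str) -> pd.Series:
        return self.effects.loc[effect]


def _trend_frame(r_values, taxo_class, habitat, covariate=None) -> pd.DataFrame:
    d = pd.DataFrame({"r_year": np.asarray(r_values, float),
                      "taxo_class": list(taxo_class),
                      "habitat": list(habitat)})
    if covariate is not None:
        d["covariate"] = np.asarray(covariate, float)
    cells = d.groupby(["taxo_class", "habitat"]).size()
    if (cells < 2).any():
        bad = cells[cells < 2].index.tolist()
        raise ValueError(f"cells with fewer than 2 species: {bad}")
    return d


def _typ3(fit, label_map: dict[str, str]) -> pd.DataFrame:
    tab = sm.stats.anova_lm(fit, typ=3)
    df_den = int(fit.df_resid)
    rows = []
    for raw, name in label_map.items():
        rows.append({"effect": name, "F": float(tab.loc[raw, "F"]),
                     "df_num": int(tab.loc[raw, "df"]), "df_den": df_den,
                     "p": float(tab.loc[raw, "PR(>F)"])})
    return pd.DataFrame(rows).set_index("effect")


def two_way_anova(r_values, taxo_class, habitat) -> AnovaResult:
    """Two-way ANOVA of r_year on taxonomic class and habitat.

    Full factorial model (class, habitat, class x habitat) with Type III
    sums of squares and sum-to-zero effects coding, appropriate for the
    unbalanced 2x2 species design; with n species the residual df is
    n - 4 (40 for 44 species).
    """
    d = _trend_frame(r_values, taxo_class, habitat)
    fit = smf.ols("r_year ~ C(taxo_class, Sum) * C(habitat, Sum)", d).fit()
    eff = _typ3(fit, {"C(taxo_class, Sum)": "taxo_class",
                      "C(habitat, Sum)": "habitat",
                      "C(taxo_class, Sum):C(habitat, Sum)": "interaction"})
    return AnovaResult(effects=eff, model=fit)


def ancova(r_values, taxo_class, habitat, covariate) -> AnovaResult:
    """ANCOVA adding a species-level covariate (series length) to the ANOVA.

    Also runs the parallelism test: a joint F test of the
    factor x covariate interactions against the additive model; a
    significant result means the covariate's slope differs between groups
    and the ANCOVA adjustment is suspect.
    """
    cov = np.asarray(covariate, float)
    if np.ptp(cov) == 0:
        raise ValueError("covariate is constant")
    d = _trend_frame(r_values, taxo_class, habitat, cov)
    fit = smf.ols(
        "r_year ~ C(taxo_class, Sum) * C(habitat, Sum) + covariate", d).fit()
    eff = _typ3(fit, {"C(taxo_class, Sum)": "taxo_class",
                      "C(habitat, Sum)": "habitat",
                      "C(taxo_class, Sum):C(habitat, Sum)": "interaction",
                      "covariate": "covariate"})
    full = smf.ols(
        "r_year ~ C(taxo_class, Sum) * C(habitat, Sum) + covariate"
        " + C(taxo_class, Sum):covariate + C(habitat, Sum):covariate", d).fit()
    cmp = sm.stats.anova_lm(fit, full)
    parallelism = {"F": float(cmp.loc[1, "F"]),
                   "df_num": int(cmp.loc[1, "df_diff"]),
                   "df_den": int(full.df_resid),
                   "p": float(cmp.loc[1, "Pr(>F)"])}
    return AnovaResult(effects=eff, model=fit, parallelism=parallelism)


def assumption_tests(residuals, groups) -> dict[str, float]:
    """Kolmogorov-Smirnov normality and Levene homogeneity-of-variance p-values.

    The KS test is one-sample against a normal with the residuals' own
    mean and standard deviation; Levene uses absolute deviations from
    group means (``center="mean"``).
    """
    resid = np.asarray(residuals, float)
    if len(resid) < 3:
        raise ValueError("need at least 3 residuals")
    ks = stats.kstest(resid, "norm", args=(resid.mean(), resid.std(ddof=1)))
    groups = pd.Series(list(groups))
    samples = [resid[(groups == g).to_numpy()] for g in groups.unique()]
    lev = stats.levene(*samples, center="mean")
    return {"ks_p": float(ks.pvalue), "levene_p": float(lev.pvalue),
            "ks_stat": float(ks.statistic), "levene_stat": float(lev.statistic)}


@dataclass
class PeriodSplit:
    """Records and trend tables for the pre/post boundary periods."""

    boundary: int
    records_pre: RecordTable
    records_post: RecordTable
    trends_pre: pd.DataFrame = field(default=None)
    trends_post: pd.DataFrame = field(default=None)

    def paired_r(self) -> pd.DataFrame:
        """Species with an estimable r_year in both periods, aligned."""
        pre = self.trends_pre["r_year"].rename("r_pre")
        post = self.trends_post["r_year"].rename("r_post")
        return pd.concat([pre, post], axis=1).dropna()


def split_periods(records: RecordTable, boundary: int = 1950,
                  alpha: float = 0.05, min_n: int = 10) -> PeriodSplit:
    """Partition records at a boundary year and fit per-period trends.

    A record collected in the boundary year itself belongs to the first
    period (the split is "through 1950" / "from 1951 on"). Species too
    sparse in a period are flagged "unavailable" in that period's table.
    """
    pre = records.subset(records.df["year"] <= boundary)
    post = records.subset(records.df["year"] > boundary)
    split = PeriodSplit(boundary=boundary, records_pre=pre, records_post=post)
    split.trends_pre = (fit_species_trends(pre, alpha=alpha, min_n=min_n)
                        if len(pre) else pd.DataFrame(columns=["r_year"]))
    split.trends_post = (fit_species_trends(post, alpha=alpha, min_n=min_n)
                         if len(post) else pd.DataFrame(columns=["r_year"]))
    return split


def paired_t(r_period1, r_period2) -> dict:
    """Paired t-test for dependent samples on aligned per-species r_year.

    Returns t, df, p and per-period means/sds; ``degenerate`` is True when
    the differences have zero variance (t undefined).
    """
    x = np.asarray(r_period1, float)
    y = np.asarray(r_period2, float)
    if x.shape != y.shape:
        raise ValueError("periods must be aligned by species")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise ValueError("need at least 2 species with both periods")
    out = {"n_pairs": int(len(x)), "df": int(len(x) - 1),
           "mean_1": float(x.mean()), "sd_1": float(x.std(ddof=1)),
           "mean_2": float(y.mean()), "sd_2": float(y.std(ddof=1)),
           "mean_diff": float((x - y).mean())}
    if np.std(x - y, ddof=1) == 0:
        out.update(t=np.nan, p=np.nan, degenerate=True)
        return out
    t = stats.ttest_rel(x, y)
    out.update(t=float(t.statistic), p=float(t.pvalue), degenerate=False)
    return out


def period_comparison(records: RecordTable, meta: dict[str, SpeciesMeta],
                      taxo_class: str = "bird", habitat: str = "terrestrial",
                      boundary: int = 1950, alpha: float = 0.05,
                      min_n: int = 10) -> dict:
    """Full before/after comparison for one class-habitat group.

    Restricts the records to the requested group (the group with even
    temporal coverage across the century), splits at the boundary, fits
    per-period trends, and runs the paired t-test on species present in
    both periods.
    """
    keep = [s for s, m in meta.items()
            if m.taxo_class == taxo_class and m.habitat == habitat]
    sub = records.subset(records.df["species_id"].isin(keep))
    split = split_periods(sub, boundary=boundary, alpha=alpha, min_n=min_n)
    paired = split.paired_r()
    test = paired_t(paired["r_pre"], paired["r_post"])
    return {"split": split, "paired": paired, "t_test": test}
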