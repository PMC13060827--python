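"""Validation metrics: batch-effect removal, biological preservation, retention.

Batch-effect removal is quantified two ways.  The cohort R² increment is the
gain in OLS R² when cohort indicators are added to a biological baseline of a
degree-3 age polynomial (centred age, raw powers) plus sex; it measures
residual mean-level cohort variance.  The mean pairwise KS statistic first
residualises the feature on the same pooled biological model, then takes the
exact two-sample Kolmogorov–Smirnov statistic for every unique cohort pair
and averages; it is sensitive to residual differences in spread and shape,
not just location.  Per-cohort residualisation is available as an option.

Biological preservation uses Spearman rank correlation with age (robust to
non-Gaussian marginals and monotone transforms) and Cohen's d for sex
differences with the pooled standard deviation, Welch two-sample t-tests and
Benjamini–Hochberg FDR across features.  The d sign convention is
reference minus other, with the reference being the lexicographically
smaller sex label.

Between-cohort moment differences (absolute log SD ratio, absolute delta
skewness, absolute delta excess kurtosis) describe pre-existing
distributional divergence; the log SD ratio is scale-invariant so features
with different units are comparable.

Retention counts records that were valid before harmonisation but missing
afterwards; these reconcile exactly with the harmonisation-stage QC flags.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetricError",
    "cohort_r2_increment",
    "mean_pairwise_ks",
    "moment_differences",
    "spearman_age",
    "sex_effect",
    "retention_report",
    "harmonised_wide",
    "ValidationReport",
    "validation_report",
]


class MetricError(ValueError):
    """A metric is undefined for the given data (single cohort, zero variance, ...)."""


def _age_design(age: np.ndarray, sex01: np.ndarray, model: str) -> np.ndarray:
    a = age - age.mean()
    if model == "linear":
        return np.column_stack([np.ones_like(a), a, sex01])
    if model == "poly3":
        return np.column_stack([np.ones_like(a), a, a ** 2, a ** 3, sex01])
    raise ValueError(f"unknown age model {model!r}")


def _sex01(sex) -> np.ndarray:
    levels = sorted(pd.unique(sex), key=str)
    return (np.asarray(sex) != levels[0]).astype(float)


def _r2(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise MetricError("response has zero variance")
    return 1.0 - float(resid @ resid) / sst


def _complete(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    return table.loc[np.isfinite(pd.to_numeric(table[value_col], errors="coerce"))]


def cohort_r2_increment(table: pd.DataFrame, value_col: str,
                        age_model: str = "poly3") -> float:
    """Gain in OLS R² from adding cohort indicators to the age+sex baseline."""
    d = _complete(table, value_col)
    cohorts = pd.Categorical(d["cohort"])
    if len(cohorts.categories) < 2:
        raise MetricError("cohort R^2 increment requires at least two cohorts")
    y = d[value_col].to_numpy(dtype=float)
    Xb = _age_design(d["age"].to_numpy(dtype=float), _sex01(d["sex"]), age_model)
    Z = pd.get_dummies(cohorts).to_numpy(dtype=float)[:, 1:]  # drop reference level
    Xe = np.column_stack([Xb, Z])
    if len(y) <= Xe.shape[1]:
        raise MetricError("too few rows for the extended cohort model")
    inc = _r2(Xe, y) - _r2(Xb, y)
    return max(float(inc), 0.0)


def _residualise(d: pd.DataFrame, value_col: str, mode: str,
                 age_model: str = "poly3") -> pd.Series:
    y = d[value_col].to_numpy(dtype=float)
    if mode == "pooled":
        X = _age_design(d["age"].to_numpy(dtype=float), _sex01(d["sex"]), age_model)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return pd.Series(y - X @ beta, index=d.index)
    if mode == "per_cohort":
        out = pd.Series(np.nan, index=d.index)
        for _, grp in d.groupby("cohort", observed=True):
            X = _age_design(grp["age"].to_numpy(dtype=float), _sex01(grp["sex"]),
                            age_model)
            yy = grp[value_col].to_numpy(dtype=float)
            beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
            out.loc[grp.index] = yy - X @ beta
        return out
    raise ValueError(f"unknown residualisation mode {mode!r}")


def mean_pairwise_ks(table: pd.DataFrame, value_col: str,
                     residualisation: str = "pooled",
                     age_model: str = "poly3") -> float:
    """Mean exact two-sample KS statistic over all unique cohort pairs of
    age/sex-residualised values.  Pairs with fewer than 2 usable residuals on
    either side are skipped."""
    d = _complete(table, value_col)
    levels = pd.unique(d["cohort"])
    if len(levels) < 2:
        raise MetricError("mean pairwise KS requires at least two cohorts")
    resid = _residualise(d, value_col, residualisation, age_model)
    groups = {lev: resid[d["cohort"] == lev].to_numpy() for lev in levels}
    stats_out = []
    for a, b in itertools.combinations(levels, 2):
        xa, xb = groups[a], groups[b]
        if len(xa) < 2 or len(xb) < 2:
            continue
        stats_out.append(stats.ks_2samp(xa, xb, method="asymp").statistic)
    if not stats_out:
        raise MetricError("no cohort pair had enough residuals for a KS statistic")
    return float(np.mean(stats_out))


def moment_differences(table: pd.DataFrame, value_col: str, cohort_pair) -> tuple:
    """(|log SD ratio|, |Δ skewness|, |Δ excess kurtosis|) between two cohorts."""
    d = _complete(table, value_col)
    a, b = cohort_pair
    xa = d.loc[d["cohort"] == a, value_col].to_numpy(dtype=float)
    xb = d.loc[d["cohort"] == b, value_col].to_numpy(dtype=float)
    if len(xa) < 4 or len(xb) < 4:
        raise MetricError("moment differences need >= 4 observations per cohort")
    sd_a, sd_b = np.std(xa, ddof=1), np.std(xb, ddof=1)
    if sd_a == 0.0 or sd_b == 0.0:
        raise MetricError("zero standard deviation in a cohort")
    return (abs(float(np.log(sd_a / sd_b))),
            abs(float(stats.skew(xa) - stats.skew(xb))),
            abs(float(stats.kurtosis(xa) - stats.kurtosis(xb))))


def spearman_age(table: pd.DataFrame, features) -> pd.DataFrame:
    """Spearman rank correlation of each feature with age, with BH-FDR q
    across features."""
    rows = []
    for feat in features:
        d = _complete(table, feat)
        if d["age"].nunique() < 3:
            raise MetricError(f"{feat}: fewer than 3 distinct age values")
        y = d[feat].to_numpy(dtype=float)
        if np.std(y) == 0.0:
            raise MetricError(f"{feat}: constant feature")
        rho, p = stats.spearmanr(d["age"].to_numpy(dtype=float), y)
        rows.append({"feature": feat, "spearman_rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def sex_effect(table: pd.DataFrame, features) -> pd.DataFrame:
    """Cohen's d (pooled SD, reference-minus-other), Welch two-sided p and
    BH-FDR q per feature."""
    rows = []
    for feat in features:
        d = _complete(table, feat)
        levels = sorted(pd.unique(d["sex"]), key=str)
        if len(levels) != 2:
            raise MetricError(f"{feat}: need exactly two sex groups")
        g0 = d.loc[d["sex"] == levels[0], feat].to_numpy(dtype=float)
        g1 = d.loc[d["sex"] == levels[1], feat].to_numpy(dtype=float)
        if len(g0) < 2 or len(g1) < 2:
            raise MetricError(f"{feat}: each sex group needs >= 2 observations")
        n0, n1 = len(g0), len(g1)
        pooled = np.sqrt(((n0 - 1) * np.var(g0, ddof=1)
                          + (n1 - 1) * np.var(g1, ddof=1)) / (n0 + n1 - 2))
        if pooled == 0.0:
            d_val, p = 0.0, 1.0
        else:
            d_val = float((g0.mean() - g1.mean()) / pooled)
            p = float(stats.ttest_ind(g0, g1, equal_var=False).pvalue)
            if not np.isfinite(p):
                p = 1.0
        rows.append({"feature": feat, "cohens_d": d_val, "p": p,
                     "n_ref": n0, "n_other": n1})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def harmonised_wide(long_output: pd.DataFrame,
                    value: str = "y_harmonised") -> pd.DataFrame:
    """Pivot the long harmonisation output back to one column per feature,
    preserving row order within feature blocks."""
    parts = {}
    meta = None
    for feat, grp in long_output.groupby("feature", sort=False):
        grp = grp.reset_index(drop=True)
        parts[feat] = grp[value].to_numpy()
        if meta is None:
            meta = grp[["subject_id", "cohort", "age", "sex"]]
    wide = meta.copy()
    for feat, vals in parts.items():
        wide[feat] = vals
    return wide


def retention_report(pre_table: pd.DataFrame, post_table: pd.DataFrame,
                     features) -> pd.DataFrame:
    """Lost records per feature: valid before harmonisation, missing after."""
    if len(pre_table) != len(post_table):
        raise MetricError("pre and post tables must cover the same rows")
    rows = []
    for feat in features:
        pre_valid = np.isfinite(pd.to_numeric(pre_table[feat], errors="coerce").to_numpy())
        post_valid = np.isfinite(pd.to_numeric(post_table[feat], errors="coerce").to_numpy())
        lost = int(np.sum(pre_valid & ~post_valid))
        n_valid = int(pre_valid.sum())
        rows.append({"feature": feat, "valid_pre": n_valid, "lost": lost,
                     "loss_rate": lost / n_valid if n_valid else np.nan})
    out = pd.DataFrame(rows)
    total_valid = int(out["valid_pre"].sum())
    total_lost = int(out["lost"].sum())
    out.attrs["overall"] = {"valid_pre": total_valid, "lost": total_lost,
                            "loss_rate": total_lost / total_valid if total_valid else np.nan}
    return out


@dataclass
class ValidationReport:
    """Tidy per-feature metrics for the pre- and post-harmonisation states."""

    table: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def validation_report(pre_table: pd.DataFrame, post_table: pd.DataFrame,
                      features, age_model: str = "poly3",
                      residualisation: str = "pooled") -> ValidationReport:
    """Compute the full metric suite on aligned pre/post tables (wide format,
    one column per feature)."""
    rows = []
    for state, tab in (("pre", pre_table), ("post", post_table)):
        sp = spearman_age(tab, features).set_index("feature")
        sx = sex_effect(tab, features).set_index("feature")
        for feat in features:
            rows.append({
                "feature": feat, "state": state,
                "cohort_r2_increment": cohort_r2_increment(tab, feat, age_model),
                "mean_pairwise_ks": mean_pairwise_ks(tab, feat, residualisation,
                                                     age_model),
                "spearman_rho_age": sp.loc[feat, "spearman_rho"],
                "spearman_q": sp.loc[feat, "q"],
                "cohens_d_sex": sx.loc[feat, "cohens_d"],
                "welch_p": sx.loc[feat, "p"],
                "sex_q": sx.loc[feat, "q"],
            })
    table = pd.DataFrame(rows)
    retention = retention_report(pre_table, post_table, features)
    summary = {
        "median_r2_increment": {
            state: float(table.loc[table["state"] == state,
                                   "cohort_r2_increment"].median())
            for state in ("pre", "post")},
        "median_mean_pairwise_ks": {
            state: float(table.loc[table["state"] == state,
                                   "mean_pairwise_ks"].median())
            for state in ("pre", "post")},
        "mean_abs_cohens_d": {
            state: float(table.loc[table["state"] == state,
                                   "cohens_d_sex"].abs().mean())
            for state in ("pre", "post")},
        "retention": retention.attrs["overall"],
    }
    report = ValidationReport(table=table, summary=summary)
    report.retention = retention
    return report
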