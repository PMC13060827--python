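"""Quantile-mapping harmonisation and normative z-scores from a fitted GAMLSS.

Harmonised values are produced in three steps: (1) each observation's centile
is computed from the CDF of its cohort-specific fitted distribution,
including all cohort random effects; (2) harmonised distributional parameters
are obtained by setting every cohort random intercept to zero on its link
scale (subtraction on the log scale for sigma and tau, direct subtraction for
mu and nu) — parameters without a fitted cohort effect pass through
unchanged; (3) the quantile function of the fitted family is evaluated at
the original centile under the harmonised parameters, returning a value on
the native measurement scale.  The same centile yields the normative
deviation z-score through the probit transform.

No numerical clipping is applied anywhere on this path: centiles that
saturate to 0 or 1 in floating point must reach the quality-control stage
untouched so the open-interval rule can fire.  QC applies three rules in
order, and a record failing an earlier rule is not evaluated by later ones:

1. centile outside the open interval (0, 1)  -> harmonised value and z-score
   missing (``cdf_out_of_range``);
2. harmonised value negative (for features declared non-negative) or
   non-finite -> harmonised value missing (``negative_harmonised`` /
   ``nonfinite_harmonised``);
3. non-finite z-score -> z missing (``nonfinite_z``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .distributions import ParamVector, cdf, quantile
from .model_fit import (
    FitConfig,
    FittedModel,
    fit_with_fallback,
    predict_parameters,
)

__all__ = [
    "QC_FLAGS",
    "compute_centiles",
    "remove_cohort_effects",
    "quantile_map",
    "centile_to_z",
    "postprocess_qc",
    "harmonise_feature",
    "harmonise_table",
    "HarmonisationResult",
]

QC_FLAGS = ("ok", "cdf_out_of_range", "negative_harmonised",
            "nonfinite_harmonised", "nonfinite_z")

_RANDOM_PARAMS = ("mu", "sigma", "nu", "tau")


def compute_centiles(model: FittedModel, table: pd.DataFrame) -> np.ndarray:
    """Centile (probability-integral-transform) score of each observation
    under its own cohort's fitted conditional distribution."""
    y = table[model.response].to_numpy(dtype=float)
    pv, _ = predict_parameters(model, table["age"], table["sex"], table["cohort"])
    return np.asarray(cdf(y, model.family_used, pv), dtype=float)


def remove_cohort_effects(model: FittedModel, table: pd.DataFrame) -> ParamVector:
    """Distributional parameters with every cohort random intercept zeroed on
    the link scale; parameters without a fitted cohort effect are carried
    forward without modification."""
    pv, _ = predict_parameters(model, table["age"], table["sex"], table["cohort"],
                               zero_random=_RANDOM_PARAMS)
    return pv


def quantile_map(centiles: np.ndarray, harmonised_params: ParamVector,
                 family) -> np.ndarray:
    """Back-transform centiles to the native scale under harmonised
    parameters.  Centiles outside (0, 1) yield NaN here and are flagged by
    QC downstream."""
    c = np.asarray(centiles, dtype=float)
    out = np.full(c.shape, np.nan)
    valid = (c > 0.0) & (c < 1.0)
    if np.any(valid):
        def _take(x):
            if x is None:
                return None
            x = np.asarray(x, dtype=float)
            return x[valid] if x.ndim else x
        pv = ParamVector(_take(harmonised_params.mu), _take(harmonised_params.sigma),
                         _take(harmonised_params.nu), _take(harmonised_params.tau))
        out[valid] = quantile(c[valid], family, pv)
    return out


def centile_to_z(centiles: np.ndarray) -> np.ndarray:
    """Probit transform of the centile: the normative deviation z-score.
    Saturated centiles map to +/-inf and are handled by QC."""
    c = np.asarray(centiles, dtype=float)
    with np.errstate(invalid="ignore"):
        return special.ndtri(c)


def postprocess_qc(y_raw: np.ndarray, centiles: np.ndarray,
                   y_harmonised: np.ndarray, z_scores: np.ndarray,
                   non_negative: bool = True) -> pd.DataFrame:
    """Apply the three QC rules in order and return the final output fields.

    The comparison with the open interval is exact floating-point (c <= 0 or
    c >= 1 fails); no epsilon widening is applied.
    """
    c = np.asarray(centiles, dtype=float)
    yh = np.asarray(y_harmonised, dtype=float).copy()
    z = np.asarray(z_scores, dtype=float).copy()
    n = len(c)
    flags = np.full(n, "ok", dtype=object)

    rule1 = ~((c > 0.0) & (c < 1.0))
    flags[rule1] = "cdf_out_of_range"
    yh[rule1] = np.nan
    z[rule1] = np.nan

    todo = ~rule1
    negative = todo & non_negative & (yh < 0)
    flags[negative] = "negative_harmonised"
    yh[negative] = np.nan
    todo &= ~negative
    nonfinite = todo & ~np.isfinite(yh)
    flags[nonfinite] = "nonfinite_harmonised"
    yh[nonfinite] = np.nan
    todo &= ~nonfinite

    bad_z = todo & ~np.isfinite(z)
    flags[bad_z] = "nonfinite_z"
    z[bad_z] = np.nan

    return pd.DataFrame({"y_raw": np.asarray(y_raw, dtype=float),
                         "centile": c, "y_harmonised": yh,
                         "z_score": z, "qc_flag": flags})


@dataclass
class HarmonisationResult:
    model: FittedModel
    output: pd.DataFrame
    qc_counts: dict = field(default_factory=dict)


def harmonise_feature(table: pd.DataFrame, feature: str,
                      config: FitConfig = FitConfig(), seed: int = 0,
                      non_negative: bool = True,
                      max_iterations: int = 200,
                      model: FittedModel = None) -> HarmonisationResult:
    """Fit (with the fallback hierarchy) and harmonise one feature.

    Passing a pre-fitted ``model`` skips refitting, e.g. when the model was
    deserialised from its JSON sidecar.  Deterministic given data, config
    and seed.
    """
    y_all = pd.to_numeric(table[feature], errors="coerce").to_numpy(dtype=float)
    usable = np.isfinite(y_all)
    sub = table.loc[usable]
    if model is None:
        model = fit_with_fallback(sub, feature, config, seed=seed,
                                  max_iterations=max_iterations)
    c_sub = compute_centiles(model, sub)
    harm_pv = remove_cohort_effects(model, sub)
    y_tilde_sub = quantile_map(c_sub, harm_pv, model.family_used)
    z_sub = centile_to_z(c_sub)

    n = len(table)
    c = np.full(n, np.nan); c[usable] = c_sub
    y_tilde = np.full(n, np.nan); y_tilde[usable] = y_tilde_sub
    z = np.full(n, np.nan); z[usable] = z_sub
    out = postprocess_qc(y_all, c, y_tilde, z, non_negative=non_negative)
    # rows whose input was already missing are upstream exclusions, not QC losses
    out.loc[~usable, "qc_flag"] = "excluded_input"
    out.insert(0, "subject_id", table["subject_id"].to_numpy()
               if "subject_id" in table else np.arange(len(table)))
    for col in ("cohort", "age", "sex"):
        out.insert(out.columns.get_loc("y_raw"), col, table[col].to_numpy())
    out.insert(out.columns.get_loc("y_raw"), "feature", feature)
    out["family_used"] = model.family_used.name
    counts = out["qc_flag"].value_counts().to_dict()
    qc = {flag: int(counts.get(flag, 0)) for flag in QC_FLAGS}
    qc["excluded_input"] = int(counts.get("excluded_input", 0))
    qc["n_modelled"] = int(usable.sum())
    qc["n"] = n
    qc["retention_rate"] = float(qc["ok"] / max(int(usable.sum()), 1))
    return HarmonisationResult(model=model, output=out, qc_counts=qc)


def harmonise_table(table: pd.DataFrame, features: list,
                    config: FitConfig = FitConfig(), seed: int = 0,
                    non_negative=True) -> tuple:
    """Harmonise several features of one table.

    Returns ``(long_output, models, qc_summary)`` where ``long_output``
    stacks the per-feature records, ``models`` maps feature name to its
    fitted model, and ``qc_summary`` maps feature name to QC flag counts.
    Randomness (none in the fit itself, but reserved for stochastic
    extensions) is drawn from per-feature substreams of ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(features))]
    outputs, models, qc_summary = [], {}, {}
    for feat, sub_seed in zip(features, child_seeds):
        nn = non_negative if isinstance(non_negative, bool) else non_negative.get(feat, True)
        res = harmonise_feature(table, feat, config, seed=sub_seed, non_negative=nn)
        outputs.append(res.output)
        models[feat] = res.model
        qc_summary[feat] = res.qc_counts
    return pd.concat(outputs, ignore_index=True), models, qc_summary
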