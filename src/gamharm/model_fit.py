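"""Penalised maximum-likelihood fitting of hierarchical GAMLSS models.

Each distributional parameter of the response family gets its own linear
predictor on the link scale:

* location ``mu`` and log-scale ``sigma``: intercept + sex fixed effect +
  penalised B-spline smooth of age + cohort random intercept;
* shape parameters ``nu`` (skewness) and ``log tau`` (tail weight): intercept
  plus an optional cohort random intercept.

Estimation is an RS-type backfitting scheme: the outer loop cycles over the
distributional parameters, and each parameter is updated by a penalised
iteratively reweighted least-squares step built from per-observation first and
second derivatives of the log-likelihood with respect to that parameter's
linear predictor (obtained by central differences, so the same machinery
serves every family).  Cohort random intercepts are ridge-penalised
coefficients whose prior variance is re-estimated by an EM-type local
maximum-likelihood update inside the cycle; the P-spline smoothing parameter
is updated the same way through the mixed-model representation of the
second-order difference penalty.  Because the age-smooth basis is centred and
the intercept is unpenalised, the fitted random intercepts sum to zero at the
optimum, matching their zero-mean normal formulation.

The response is standardised internally (affine for SHASH/Normal, pure
scaling for the positive-support generalised gamma); all reported
coefficients, offsets and predictions are transformed back to the natural
scale of the feature.

Convergence rule: a fit converges iff the absolute change in global deviance
is below ``dev_tol`` (default 1e-3) for two consecutive outer cycles within
``max_iterations`` (default 200), every coefficient is finite, and no
full Newton step in the final two cycles was rejected for violating the
shape-parameter bounds.  Non-convergence is reported through the
``converged`` flag, never as an exception — the fallback hierarchy consumes
it: SHASH with cohort intercepts on both shape parameters, then on the
skewness only, then on the tail weight only, then intercept-only shapes,
then generalised gamma, then Normal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.interpolate import BSpline

from .distributions import (
    FamilySpec,
    ParameterDomainError,
    ParamVector,
    get_family,
    invert_link,
    logpdf,
)

__all__ = [
    "DataError",
    "CohortTooSmallError",
    "DegenerateDesignError",
    "UnseenCohortError",
    "FitError",
    "ModelSpec",
    "FitConfig",
    "SmoothTerm",
    "RandomEffectTerm",
    "ParamSubmodel",
    "AttemptRecord",
    "FittedModel",
    "build_design",
    "fit_gamlss",
    "fit_with_fallback",
    "predict_parameters",
    "FALLBACK_HIERARCHY",
]

REQUIRED_COLUMNS = ("age", "sex", "cohort")

# bounds on shape linear predictors (internal standardised scale); a full
# Newton step landing outside marks the attempt as ill-behaved
_ETA_BOUNDS = {"mu": 1e6, "sigma": 12.0, "nu": 8.0, "tau": 4.0}


class DataError(ValueError):
    """Input data violate a precondition of the model."""


class CohortTooSmallError(DataError):
    def __init__(self, cohort, n, minimum):
        self.cohort, self.n, self.minimum = cohort, n, minimum
        super().__init__(
            f"cohort {cohort!r} has {n} rows, below the minimum of {minimum} "
            f"required for a cohort random intercept"
        )


class DegenerateDesignError(DataError):
    """The design matrix is rank-deficient (e.g. constant age)."""


class UnseenCohortError(DataError):
    """Prediction requested for a cohort level absent from the fitted model."""


class FitError(RuntimeError):
    """Every specification in the fallback hierarchy failed to converge."""


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Structure of a single GAMLSS specification.

    ``shape_random`` lists which shape parameters ("nu", "tau") carry a
    cohort random intercept; location and scale always carry one, together
    with the age smooth and the sex fixed effect.
    """

    family: str = "SHASH"
    shape_random: tuple = ("nu", "tau")
    subject_random: bool = False
    max_iterations: int = 200

    def label(self) -> str:
        sr = "+".join(self.shape_random) if self.shape_random else "none"
        return f"{self.family}(shape_re={sr})"


@dataclass(frozen=True)
class FitConfig:
    """Numerical controls for the backfitting algorithm."""

    n_inner_knots: int = 20
    degree: int = 3
    penalty_order: int = 2
    min_cohort_size: int = 10
    dev_tol: float = 1e-3
    hyper_update_cycles: int = 20
    deriv_step: float = 1e-4


FALLBACK_HIERARCHY: tuple = (
    ModelSpec("SHASH", ("nu", "tau")),
    ModelSpec("SHASH", ("nu",)),
    ModelSpec("SHASH", ("tau",)),
    ModelSpec("SHASH", ()),
    ModelSpec("GG", ()),
    ModelSpec("NORMAL", ()),
)


# ---------------------------------------------------------------------------
# Fitted-model containers
# ---------------------------------------------------------------------------

@dataclass
class SmoothTerm:
    """A penalised B-spline smooth with centred basis and linear extrapolation."""

    knots: np.ndarray           # full knot vector with repeated boundaries
    degree: int
    penalty_order: int
    coefficients: np.ndarray
    smoothing_parameter: float
    col_means: np.ndarray       # training-sample column means (centering)
    lo: float
    hi: float

    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    def design(self, x: np.ndarray) -> tuple:
        """Centred basis rows at ``x``; boundary-linear outside [lo, hi].

        Returns ``(rows, extrapolated)`` where ``extrapolated`` flags rows
        evaluated outside the training age range.
        """
        x = np.asarray(x, dtype=float)
        rows = np.empty((x.size, self.n_basis()))
        inside = (x >= self.lo) & (x <= self.hi)
        if np.any(inside):
            rows[inside] = _bspline_design(x[inside], self.knots, self.degree)
        for bound, mask in ((self.lo, x < self.lo), (self.hi, x > self.hi)):
            if np.any(mask):
                b = np.array([bound])
                base = _bspline_design(b, self.knots, self.degree)
                slope = _bspline_deriv_design(b, self.knots, self.degree)
                rows[mask] = base + slope * (x[mask] - bound)[:, None]
        return rows - self.col_means, ~inside

    def value(self, x: np.ndarray) -> np.ndarray:
        rows, _ = self.design(x)
        return rows @ self.coefficients


@dataclass
class RandomEffectTerm:
    """Per-cohort offsets on the link scale, estimated under a zero-mean normal prior."""

    levels: tuple
    offsets: np.ndarray
    variance: float

    def offset_for(self, labels) -> np.ndarray:
        index = {lev: i for i, lev in enumerate(self.levels)}
        try:
            idx = np.array([index[l] for l in np.asarray(labels, dtype=object)])
        except KeyError as exc:
            raise UnseenCohortError(f"cohort level {exc.args[0]!r} not in fitted model") from None
        return self.offsets[idx]


@dataclass
class ParamSubmodel:
    link: str
    intercept: float
    sex_coef: Optional[float]
    smooth: Optional[SmoothTerm]
    cohort_re: Optional[RandomEffectTerm]


@dataclass
class AttemptRecord:
    spec_label: str
    family: str
    converged: bool
    n_iterations: int
    deviance: float
    message: str = ""


@dataclass
class FittedModel:
    """A fitted per-feature hierarchical GAMLSS on the internal standardised scale."""

    response: str
    spec: ModelSpec
    family_used: FamilySpec
    submodels: dict
    converged: bool
    n_iterations: int
    global_deviance: float
    sex_levels: tuple
    cohort_levels: tuple
    internal_loc: float
    internal_scale: float
    deviance_history: list = field(default_factory=list)
    pen_ll_history: list = field(default_factory=list)
    hyper_frozen_at: Optional[int] = None
    fallback_path: list = field(default_factory=list)

    # -- natural-scale summaries ------------------------------------------
    def cohort_offsets(self, param: str) -> dict:
        """Fitted cohort random intercepts on the natural link scale of ``param``."""
        sub = self.submodels[param]
        if sub.cohort_re is None:
            return {lev: 0.0 for lev in self.cohort_levels}
        off = sub.cohort_re.offsets.copy()
        if param == "mu":
            off = off * self.internal_scale
        return dict(zip(sub.cohort_re.levels, off))

    def fixed_effects(self) -> dict:
        """Intercepts and sex coefficients per parameter, natural link scale."""
        out = {}
        s = self.internal_scale
        for param, sub in self.submodels.items():
            icpt, sexc = sub.intercept, sub.sex_coef
            if param == "mu":
                icpt = self.internal_loc + s * icpt
                sexc = None if sexc is None else s * sexc
            elif param == "sigma" and self.family_used.name != "GG":
                icpt = icpt + np.log(s)
            out[param] = {"intercept": float(icpt),
                          "sex": None if sexc is None else float(sexc)}
        return out

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        def _smooth(s):
            if s is None:
                return None
            d = asdict(s)
            for k in ("knots", "coefficients", "col_means"):
                d[k] = np.asarray(d[k]).tolist()
            return d

        subs = {}
        for p, sub in self.submodels.items():
            re = None
            if sub.cohort_re is not None:
                re = {"levels": list(sub.cohort_re.levels),
                      "offsets": np.asarray(sub.cohort_re.offsets).tolist(),
                      "variance": float(sub.cohort_re.variance)}
            subs[p] = {"link": sub.link, "intercept": float(sub.intercept),
                       "sex_coef": None if sub.sex_coef is None else float(sub.sex_coef),
                       "smooth": _smooth(sub.smooth), "cohort_re": re}
        return {
            "response": self.response,
            "spec": {"family": self.spec.family,
                     "shape_random": list(self.spec.shape_random),
                     "subject_random": self.spec.subject_random,
                     "max_iterations": self.spec.max_iterations},
            "family_used": self.family_used.name,
            "submodels": subs,
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "global_deviance": float(self.global_deviance),
            "sex_levels": [_jsonable(v) for v in self.sex_levels],
            "cohort_levels": [_jsonable(v) for v in self.cohort_levels],
            "internal_loc": float(self.internal_loc),
            "internal_scale": float(self.internal_scale),
            "hyper_frozen_at": self.hyper_frozen_at,
            "fallback_path": [asdict(a) for a in self.fallback_path],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        def _smooth(s):
            if s is None:
                return None
            return SmoothTerm(
                knots=np.asarray(s["knots"], float), degree=int(s["degree"]),
                penalty_order=int(s["penalty_order"]),
                coefficients=np.asarray(s["coefficients"], float),
                smoothing_parameter=float(s["smoothing_parameter"]),
                col_means=np.asarray(s["col_means"], float),
                lo=float(s["lo"]), hi=float(s["hi"]))

        subs = {}
        for p, sd in d["submodels"].items():
            re = sd["cohort_re"]
            re_t = None
            if re is not None:
                re_t = RandomEffectTerm(tuple(re["levels"]),
                                        np.asarray(re["offsets"], float),
                                        float(re["variance"]))
            subs[p] = ParamSubmodel(sd["link"], float(sd["intercept"]),
                                    sd["sex_coef"], _smooth(sd["smooth"]), re_t)
        spec = ModelSpec(d["spec"]["family"], tuple(d["spec"]["shape_random"]),
                         d["spec"]["subject_random"], d["spec"]["max_iterations"])
        return cls(
            response=d["response"], spec=spec,
            family_used=get_family(d["family_used"]), submodels=subs,
            converged=d["converged"], n_iterations=d["n_iterations"],
            global_deviance=d["global_deviance"],
            sex_levels=tuple(d["sex_levels"]), cohort_levels=tuple(d["cohort_levels"]),
            internal_loc=d["internal_loc"], internal_scale=d["internal_scale"],
            hyper_frozen_at=d.get("hyper_frozen_at"),
            fallback_path=[AttemptRecord(**a) for a in d.get("fallback_path", [])])

    @classmethod
    def from_json(cls, source) -> "FittedModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


# ---------------------------------------------------------------------------
# B-spline basis helpers
# ---------------------------------------------------------------------------

def _knot_vector(lo: float, hi: float, n_inner: int, degree: int) -> np.ndarray:
    # uniformly extended knots (Eilers-Marx convention): the difference
    # penalty's null space then corresponds exactly to polynomials in age
    n_seg = n_inner + 1
    d = (hi - lo) / n_seg
    core = np.linspace(lo, hi, n_seg + 1)  # exact endpoints
    left = lo - d * np.arange(degree, 0, -1)
    right = hi + d * np.arange(1, degree + 1)
    return np.concatenate([left, core, right])


def _bspline_design(x: np.ndarray, t: np.ndarray, k: int) -> np.ndarray:
    return BSpline.design_matrix(np.asarray(x, float), t, k).toarray()


def _bspline_deriv_design(x: np.ndarray, t: np.ndarray, k: int) -> np.ndarray:
    """Rows of first derivatives of each degree-k basis function at x."""
    B1 = BSpline.design_matrix(np.asarray(x, float), t, k - 1).toarray()
    K = len(t) - k - 1
    out = np.zeros((len(np.atleast_1d(x)), K))
    for j in range(K):
        d1 = t[j + k] - t[j]
        d2 = t[j + k + 1] - t[j + 1]
        if d1 > 0:
            out[:, j] += k / d1 * B1[:, j]
        if d2 > 0:
            out[:, j] -= k / d2 * B1[:, j + 1]
    return out


def _difference_penalty(n_coef: int, order: int) -> np.ndarray:
    D = np.diff(np.eye(n_coef), n=order, axis=0)
    return D.T @ D


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

@dataclass
class _ParamDesign:
    """Stacked design matrix for one distributional parameter with slice map."""

    X: np.ndarray
    fixed_idx: slice
    smooth_idx: Optional[slice]
    random_idx: Optional[slice]
    penalty_smooth: Optional[np.ndarray]   # unscaled D'D on the smooth block
    smooth_meta: Optional[dict]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class DesignSet:
    """Everything the backfitting loop needs, on the internal response scale."""

    y: np.ndarray                 # standardised response
    designs: dict                 # param -> _ParamDesign
    sex_levels: tuple
    cohort_levels: tuple
    cohort_index: np.ndarray
    internal_loc: float
    internal_scale: float
    n: int


def _validate_columns(data: pd.DataFrame, response: str) -> None:
    missing = [c for c in (*REQUIRED_COLUMNS, response) if c not in data.columns]
    if missing:
        raise DataError(f"missing required columns: {missing}")
    for c in ("age", response):
        if not np.all(np.isfinite(pd.to_numeric(data[c], errors="coerce"))):
            raise DataError(f"column {c!r} contains missing or non-numeric values")
    if data[["sex", "cohort"]].isna().any().any():
        raise DataError("sex/cohort contain missing values")


def build_design(data: pd.DataFrame, response: str, spec: ModelSpec,
                 config: FitConfig = FitConfig()) -> DesignSet:
    """Materialise the per-parameter design matrices for one feature.

    Location and scale receive ``[1, sex, B-spline(age), cohort one-hot]``;
    shape parameters receive ``[1]`` plus the cohort block when the model
    specification requests a random intercept for them.
    """
    _validate_columns(data, response)
    family = get_family(spec.family)
    age = data["age"].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    n = len(data)

    cohorts = pd.Categorical(data["cohort"])
    levels = tuple(cohorts.categories)
    counts = pd.Series(cohorts).value_counts()
    for lev in levels:
        if counts.get(lev, 0) < config.min_cohort_size:
            raise CohortTooSmallError(lev, int(counts.get(lev, 0)), config.min_cohort_size)
    cohort_index = np.asarray(cohorts.codes, dtype=int)
    Z = np.zeros((n, len(levels)))
    Z[np.arange(n), cohort_index] = 1.0

    sex_levels = tuple(sorted(pd.unique(data["sex"]), key=str))
    if len(sex_levels) > 2:
        raise DataError(f"sex must be binary, found levels {sex_levels}")
    x_sex = (data["sex"].to_numpy() != sex_levels[0]).astype(float)

    lo, hi = float(age.min()), float(age.max())
    if not hi > lo or len(np.unique(age)) <= config.degree + 1:
        raise DegenerateDesignError(
            "age column has too few distinct values for a B-spline basis")
    t = _knot_vector(lo, hi, config.n_inner_knots, config.degree)
    B = _bspline_design(age, t, config.degree)
    col_means = B.mean(axis=0)
    Bc = B - col_means
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), age])) < 2:
        raise DegenerateDesignError("age column is constant")

    # internal standardisation: affine for real-support families, pure
    # scaling for the positive-support generalised gamma
    s = float(np.std(y))
    if s == 0.0:
        raise DataError(f"response {response!r} is constant; no distribution can be fitted")
    if family.name == "GG":
        if np.any(y <= 0):
            raise DataError("GG family requires strictly positive responses")
        loc, scale = 0.0, float(np.mean(y))
    else:
        loc, scale = float(np.mean(y)), s
    y_int = (y - loc) / scale

    smooth_meta = {"knots": t, "degree": config.degree,
                   "penalty_order": config.penalty_order,
                   "col_means": col_means, "lo": lo, "hi": hi}
    K = B.shape[1]
    P_s = _difference_penalty(K, config.penalty_order)

    designs = {}
    for param in family.param_names:
        if param in ("mu", "sigma"):
            X = np.column_stack([np.ones(n), x_sex, Bc, Z])
            designs[param] = _ParamDesign(
                X, slice(0, 2), slice(2, 2 + K), slice(2 + K, 2 + K + len(levels)),
                P_s, smooth_meta)
        else:
            with_re = param in spec.shape_random
            if with_re:
                X = np.column_stack([np.ones(n), Z])
                designs[param] = _ParamDesign(X, slice(0, 1), None,
                                              slice(1, 1 + len(levels)), None, None)
            else:
                designs[param] = _ParamDesign(np.ones((n, 1)), slice(0, 1),
                                              None, None, None, None)

    return DesignSet(y_int, designs, sex_levels, levels, cohort_index, loc, scale, n)


# ---------------------------------------------------------------------------
# Backfitting engine
# ---------------------------------------------------------------------------

def _loglik_vec(y, family: FamilySpec, etas: dict) -> np.ndarray:
    params = {p: invert_link(etas[p], family.links[p]) for p in family.param_names}
    pv = ParamVector(params["mu"], params["sigma"],
                     params.get("nu"), params.get("tau"))
    try:
        return logpdf(y, family, pv)
    except ParameterDomainError:
        # a perturbed/proposed eta left the parameter domain; treat as an
        # impossible configuration so step-halving backs off
        return np.full(np.shape(y), -np.inf)


def _eta_derivs(y, family, etas, param, h):
    """Per-observation first/second derivatives of loglik w.r.t. one eta."""
    base = etas[param]
    step = h * (1.0 + np.abs(base))
    up = dict(etas); up[param] = base + step
    dn = dict(etas); dn[param] = base - step
    l0 = _loglik_vec(y, family, etas)
    lp = _loglik_vec(y, family, up)
    lm = _loglik_vec(y, family, dn)
    u = (lp - lm) / (2.0 * step)
    d2 = (lp - 2.0 * l0 + lm) / (step * step)
    return l0, u, d2


def fit_gamlss(data: pd.DataFrame, response: str, spec: ModelSpec,
               config: FitConfig = FitConfig(), seed: int = 0) -> FittedModel:
    """Fit one GAMLSS specification to one feature.

    The fit is deterministic given the data and configuration; ``seed`` is
    accepted for interface uniformity with the stochastic stages of the
    pipeline.  Non-convergence is reported via ``converged=False``.
    """
    del seed  # deterministic algorithm
    ds = build_design(data, response, spec, config)
    family = get_family(spec.family)
    y = ds.y
    n = ds.n

    # -- starting values ---------------------------------------------------
    beta = {}
    etas = {}
    for param, pdn in ds.designs.items():
        beta[param] = np.zeros(pdn.p)
    mu_design = ds.designs["mu"]
    A0 = mu_design.X.T @ mu_design.X + 1e-6 * np.eye(mu_design.p)
    beta["mu"] = np.linalg.solve(A0, mu_design.X.T @ y)
    if family.name == "GG":
        mu0 = mu_design.X @ beta["mu"]
        if np.any(mu0 <= 0):
            beta["mu"] = np.zeros(mu_design.p)
            beta["mu"][0] = float(np.mean(y))
    resid = y - mu_design.X @ beta["mu"]
    sd0 = max(float(np.std(resid)), 1e-3)
    beta["sigma"][0] = np.log(sd0)
    if family.name == "GG":
        beta["nu"][0] = 1.0
        beta["sigma"][0] = np.log(max(sd0 / max(float(np.mean(y)), 1e-12), 1e-3))
    for param, pdn in ds.designs.items():
        etas[param] = pdn.X @ beta[param]

    lam_smooth = {p: 1.0 for p in family.param_names
                  if ds.designs[p].smooth_idx is not None}
    lam_random = {p: 1.0 for p in family.param_names
                  if ds.designs[p].random_idx is not None}

    def penalty_matrix(param):
        pdn = ds.designs[param]
        P = np.zeros((pdn.p, pdn.p))
        if pdn.smooth_idx is not None:
            P[pdn.smooth_idx, pdn.smooth_idx] = lam_smooth[param] * pdn.penalty_smooth
        if pdn.random_idx is not None:
            ridx = np.arange(pdn.p)[pdn.random_idx]
            P[ridx, ridx] += lam_random[param]
        return P

    def penalised_ll(ll_sum, which_beta):
        pen = 0.0
        for param in family.param_names:
            pdn = ds.designs[param]
            b = which_beta[param]
            if pdn.smooth_idx is not None:
                th = b[pdn.smooth_idx]
                pen += 0.5 * lam_smooth[param] * float(th @ pdn.penalty_smooth @ th)
            if pdn.random_idx is not None:
                br = b[pdn.random_idx]
                pen += 0.5 * lam_random[param] * float(br @ br)
        return ll_sum - pen

    dev_history: list = []
    pen_ll_history: list = []
    hyper_frozen_at: Optional[int] = None
    bound_hit_cycles: list = []
    n_cycles = 0

    for cycle in range(spec.max_iterations):
        n_cycles = cycle + 1
        update_hyper = cycle < config.hyper_update_cycles
        if not update_hyper and hyper_frozen_at is None:
            hyper_frozen_at = cycle
        cycle_hit_bound = False

        for param in family.param_names:
            pdn = ds.designs[param]
            l0, u, d2 = _eta_derivs(y, family, etas, param, config.deriv_step)
            if not np.all(np.isfinite(l0)):
                break
            w = np.where(d2 < -1e-12, -d2, np.maximum(u * u, 1e-4))
            w = np.clip(w, 1e-10, 1e10)
            # observations whose perturbed likelihood left the domain get
            # negligible weight and no pull on the working response
            bad = ~(np.isfinite(u) & np.isfinite(w))
            u = np.where(bad, 0.0, u)
            w = np.where(bad, 1e-10, w)
            zwork = etas[param] + u / w
            P = penalty_matrix(param)
            XtW = pdn.X.T * w
            A = XtW @ pdn.X + P + 1e-10 * np.eye(pdn.p)
            try:
                cf = linalg.cho_factor(A)
            except linalg.LinAlgError:
                A = A + 1e-6 * np.eye(pdn.p)
                try:
                    cf = linalg.cho_factor(A)
                except linalg.LinAlgError:
                    cycle_hit_bound = True
                    continue
            beta_prop = linalg.cho_solve(cf, XtW @ zwork)

            # bound check on the full Newton step
            eta_prop = pdn.X @ beta_prop
            if np.max(np.abs(eta_prop)) > _ETA_BOUNDS[param] or not np.all(
                    np.isfinite(eta_prop)):
                cycle_hit_bound = True

            # step-halving against the penalised log-likelihood
            pen_old = penalised_ll(float(np.sum(l0)), beta)
            accepted = False
            step = 1.0
            for _ in range(30):
                cand = beta[param] + step * (beta_prop - beta[param])
                trial = dict(beta); trial[param] = cand
                eta_c = pdn.X @ cand
                if np.max(np.abs(eta_c)) <= _ETA_BOUNDS[param]:
                    etas_c = dict(etas); etas_c[param] = eta_c
                    if family.name == "GG" and param == "mu" and np.any(eta_c <= 0):
                        ok = False
                    else:
                        ll_c = _loglik_vec(y, family, etas_c)
                        ok = np.all(np.isfinite(ll_c)) and (
                            penalised_ll(float(np.sum(ll_c)), trial)
                            >= pen_old - 1e-10)
                    if ok:
                        beta[param] = cand
                        etas[param] = eta_c
                        accepted = True
                        break
                step *= 0.5
            if not accepted:
                continue  # keep previous coefficients for this parameter

            # -- EM-type hyperparameter updates ----------------------------
            if update_hyper and (pdn.random_idx is not None
                                 or pdn.smooth_idx is not None):
                Ainv = linalg.cho_solve(cf, np.eye(pdn.p))
                if pdn.random_idx is not None:
                    br = beta[param][pdn.random_idx]
                    Cbb = Ainv[pdn.random_idx, pdn.random_idx]
                    q = len(br)
                    s2 = (float(br @ br) + float(np.trace(Cbb))) / q
                    lam_random[param] = float(np.clip(1.0 / max(s2, 1e-10), 1e-8, 1e8))
                if pdn.smooth_idx is not None:
                    th = beta[param][pdn.smooth_idx]
                    Css = Ainv[pdn.smooth_idx, pdn.smooth_idx]
                    Ps = pdn.penalty_smooth
                    rank = Ps.shape[0] - config.penalty_order
                    s2 = (float(th @ Ps @ th) + float(np.trace(Ps @ Css))) / rank
                    lam_smooth[param] = float(np.clip(1.0 / max(s2, 1e-12), 1e-6, 1e12))

        ll = _loglik_vec(y, family, etas)
        dev = -2.0 * float(np.sum(ll))
        dev_history.append(dev)
        pen_ll_history.append(penalised_ll(float(np.sum(ll)), beta))
        if cycle_hit_bound:
            bound_hit_cycles.append(cycle)
        if not np.isfinite(dev):
            break
        if (len(dev_history) >= 3
                and abs(dev_history[-1] - dev_history[-2]) < config.dev_tol
                and abs(dev_history[-2] - dev_history[-3]) < config.dev_tol):
            break

    final_dev = dev_history[-1] if dev_history else np.inf
    all_finite = all(np.all(np.isfinite(b)) for b in beta.values()) and np.isfinite(final_dev)
    met_rule = (len(dev_history) >= 3
                and abs(dev_history[-1] - dev_history[-2]) < config.dev_tol
                and abs(dev_history[-2] - dev_history[-3]) < config.dev_tol)
    recent_bound = any(c >= n_cycles - 2 for c in bound_hit_cycles)
    converged = bool(met_rule and all_finite and not recent_bound
                     and n_cycles <= spec.max_iterations)

    submodels = {}
    for param in family.param_names:
        pdn = ds.designs[param]
        b = beta[param]
        sex_coef = float(b[1]) if (pdn.fixed_idx.stop - pdn.fixed_idx.start) == 2 else None
        smooth = None
        if pdn.smooth_idx is not None:
            m = pdn.smooth_meta
            smooth = SmoothTerm(m["knots"], m["degree"], m["penalty_order"],
                                b[pdn.smooth_idx].copy(), float(lam_smooth[param]),
                                m["col_means"], m["lo"], m["hi"])
        re = None
        if pdn.random_idx is not None:
            re = RandomEffectTerm(ds.cohort_levels, b[pdn.random_idx].copy(),
                                  float(1.0 / lam_random[param]))
        submodels[param] = ParamSubmodel(family.links[param], float(b[0]),
                                         sex_coef, smooth, re)

    return FittedModel(
        response=response, spec=spec, family_used=family, submodels=submodels,
        converged=converged, n_iterations=n_cycles, global_deviance=final_dev,
        sex_levels=ds.sex_levels, cohort_levels=ds.cohort_levels,
        internal_loc=ds.internal_loc, internal_scale=ds.internal_scale,
        deviance_history=dev_history, pen_ll_history=pen_ll_history,
        hyper_frozen_at=hyper_frozen_at)


# ---------------------------------------------------------------------------
# Fallback hierarchy
# ---------------------------------------------------------------------------

def fit_with_fallback(data: pd.DataFrame, response: str,
                      config: FitConfig = FitConfig(), seed: int = 0,
                      max_iterations: int = 200) -> FittedModel:
    """Fit the prespecified hierarchy and return the first converged model.

    Order: SHASH with cohort intercepts on both shape parameters, on the
    skewness only, on the tail weight only, with intercept-only shapes; then
    generalised gamma; then Normal.  Every attempt is recorded on the
    returned model's ``fallback_path``.
    """
    path: list = []
    for base_spec in FALLBACK_HIERARCHY:
        spec = ModelSpec(base_spec.family, base_spec.shape_random,
                         base_spec.subject_random, max_iterations)
        try:
            model = fit_gamlss(data, response, spec, config, seed)
        except DataError as exc:
            path.append(AttemptRecord(spec.label(), spec.family, False, 0,
                                      float("nan"), f"data error: {exc}"))
            continue
        path.append(AttemptRecord(spec.label(), spec.family, model.converged,
                                  model.n_iterations, model.global_deviance,
                                  "" if model.converged else "did not converge"))
        if model.converged:
            model.fallback_path = path
            return model
    raise FitError(
        f"no specification in the fallback hierarchy converged for {response!r}; "
        "attempts: " + "; ".join(f"{a.spec_label}: {a.message or 'failed'}" for a in path))


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_parameters(model: FittedModel, age, sex, cohort,
                       zero_random: Sequence[str] = ()) -> tuple:
    """Evaluate the fitted distributional parameters at new covariates.

    Returns ``(ParamVector, extrapolated)`` on the natural feature scale.
    ``zero_random`` names parameters whose cohort random intercept is set to
    zero on the link scale (the harmonisation operation).
    """
    age = np.atleast_1d(np.asarray(age, dtype=float))
    sex = np.atleast_1d(np.asarray(sex, dtype=object))
    cohort = np.atleast_1d(np.asarray(cohort, dtype=object))
    n = max(len(age), len(sex), len(cohort))
    age, sex, cohort = (np.broadcast_to(a, (n,)) for a in (age, sex, cohort))

    known = set(model.cohort_levels)
    for lev in pd.unique(cohort):
        if lev not in known:
            raise UnseenCohortError(f"cohort level {lev!r} not in fitted model")
    unknown_sex = [s for s in pd.unique(sex) if s not in model.sex_levels]
    if unknown_sex:
        raise DataError(f"unseen sex levels {unknown_sex}")
    x_sex = np.array([0.0 if s == model.sex_levels[0] else 1.0 for s in sex])

    extrapolated = np.zeros(n, dtype=bool)
    natural = {}
    for param, sub in model.submodels.items():
        eta = np.full(n, sub.intercept, dtype=float)
        if sub.sex_coef is not None:
            eta = eta + sub.sex_coef * x_sex
        if sub.smooth is not None:
            rows, extra = sub.smooth.design(age)
            eta = eta + rows @ sub.smooth.coefficients
            extrapolated |= extra
        if sub.cohort_re is not None and param not in zero_random:
            eta = eta + sub.cohort_re.offset_for(cohort)
        natural[param] = invert_link(eta, sub.link)

    loc, s = model.internal_loc, model.internal_scale
    mu = loc + s * natural["mu"]
    # SHASH/Normal sigma is in feature units; the GG sigma is a dimensionless
    # shape quantity invariant under rescaling of y, so only mu is scaled
    if model.family_used.name == "GG":
        sigma = natural["sigma"]
    else:
        sigma = s * natural["sigma"]
    pv = ParamVector(mu, sigma, natural.get("nu"), natural.get("tau"))
    return pv, extrapolated
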