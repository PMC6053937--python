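"""Hypothesis-testing model suite for alarm-call information content and response.

Two experiments feed two model families:

* **M1** (predator-model presentations): logistic regression of alarm-call
  occurrence on focal species, the focal species' vulnerability to the
  presented predator, their interaction, distance to the model, group size
  and presence of young.  A positive vulnerability coefficient supports the
  hypothesis that species preferentially alarm at predators that prefer them.
* **M2 suite** (playbacks): a preliminary logistic model with call type
  (conspecific / heterospecific / control) establishes that alarm playbacks
  outperform the control sound, after which control trials are removed.
  The heterospecific-response models then share one covariate set — receiver
  body size, body-size ratio (linear + quadratic) and their interactions,
  caller consistency, call reliability, acoustic similarity, caller
  abundance, and five environmental covariates — with a per-receiver random
  intercept: M2.1 response probability (binomial-logit GLMM), M2.2 latency,
  M2.3 duration, M2.4 head-lift speed (log-linear mixed models), M2.5
  head-ups and M2.6 scratches (negative-binomial GLMMs).

Model selection is all-subsets under marginality constraints, ranked by
AICc.  Fixed-effect-only binomial/NB fits delegate to statsmodels GLM;
random-intercept binomial/NB fits use the quadrature ML fitter in
``alarmnet.glmm``; Gaussian mixed models delegate to statsmodels MixedLM.
Per-term inference is Wald by default, with likelihood-ratio tests
available via :func:`term_lrt`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import DESIGN_TERMS, build_playback_design
from .glmm import fit_binomial_glmm, fit_negbin_glmm
from .indices import DerivedIndices

FAMILIES = ("binomial", "lognormal", "negbin")

# Marginality parents of the canonical playback design columns.
PLAYBACK_TERM_PARENTS = {
    "size_ratio_sq": {"size_ratio"},
    "rbs_x_ratio": {"receiver_size", "size_ratio"},
    "rbs_x_ratio_sq": {"receiver_size", "size_ratio_sq"},
}

__all__ = [
    "ModelSpec", "FitResult", "standardize_covariates", "aicc",
    "term_parents", "build_candidate_set", "fit_model", "select_model",
    "term_lrt", "fit_alarm_model_M1", "preliminary_calltype_model",
    "fit_response_models", "wilcoxon_control_check", "response_model_spec",
]


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, family, fixed terms, random intercept."""

    response: str
    family: str
    fixed_terms: tuple
    random_intercept: str | None = None
    data_filter: str | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))


@dataclass
class FitResult:
    """Coefficients plus fit metadata for one fitted model."""

    spec: ModelSpec
    coefficients: pd.DataFrame      # index: term; estimate, se, statistic, p
    loglik: float
    k: int
    n: int
    converged: bool
    sigma: float | None = None      # random-intercept SD (mixed fits)
    alpha: float | None = None      # NB2 dispersion
    extra: dict = field(default_factory=dict)

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)


def standardize_covariates(table: pd.DataFrame, variables) -> tuple[pd.DataFrame, dict]:
    """Mean-centre and SD-scale the named columns (sample SD, ddof=1).

    Returns the transformed table and a {name: (mean, sd)} map for
    back-transformation.  A zero-SD column is an error.
    """
    out = table.copy()
    params = {}
    for v in variables:
        col = out[v].astype(float)
        mu, sd = col.mean(), col.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"standardize_covariates: column {v!r} has zero SD")
        out[v] = (col - mu) / sd
        params[v] = (mu, sd)
    return out, params


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: -2 loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"aicc: correction undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def term_parents(term: str, parents: dict | None = None) -> set:
    """Marginality parents of a term.

    Composite names are parsed: ``a:b`` requires ``a`` and ``b``; ``a^2``
    requires ``a``; ``a:b^2`` requires ``a`` and ``b^2``.  An explicit
    ``parents`` map (e.g. PLAYBACK_TERM_PARENTS for precomputed columns)
    takes precedence.
    """
    if parents and term in parents:
        return set(parents[term])
    if ":" in term:
        return set(term.split(":"))
    if term.endswith("^2"):
        return {term[:-2]}
    return set()


def _closed_under_marginality(subset: set, all_terms, parents) -> bool:
    return all(term_parents(t, parents) <= subset for t in subset)


def build_candidate_set(full_spec: ModelSpec, parents: dict | None = None,
                        max_models: int = 100_000) -> list[ModelSpec]:
    """All-subsets candidate enumeration respecting marginality.

    Interactions never appear without their main effects and quadratics
    never without their linear terms; the random intercept is always
    retained.  Raises if the enumeration would exceed ``max_models``.
    """
    terms = list(full_spec.fixed_terms)
    if 2 ** len(terms) > max_models:
        raise ValueError(
            f"build_candidate_set: 2^{len(terms)} subsets exceeds cap {max_models}; "
            "reduce the term list or raise max_models")
    out = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            if _closed_under_marginality(set(combo), terms, parents):
                out.append(replace(full_spec, fixed_terms=combo))
    return out


def _term_column(data: pd.DataFrame, term: str) -> np.ndarray:
    if term in data.columns:
        return data[term].to_numpy(dtype=float)
    if ":" in term:
        cols = [_term_column(data, t) for t in term.split(":")]
        return np.prod(cols, axis=0)
    if term.endswith("^2"):
        return _term_column(data, term[:-2]) ** 2
    raise KeyError(f"unknown model term {term!r}")


def _design(data: pd.DataFrame, terms) -> pd.DataFrame:
    X = pd.DataFrame(index=data.index)
    X["intercept"] = 1.0
    for t in terms:
        X[t] = _term_column(data, t)
    return X


def _coef_frame(names, est, se) -> pd.DataFrame:
    est = np.asarray(est, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"estimate": est, "se": se, "statistic": z, "p": p}, index=list(names))


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit one ModelSpec on a prepared data table.

    The table must contain the response column, every column a term refers
    to, and the random-intercept grouping column if one is named.  Log-normal
    responses are log-transformed before linear fitting.
    """
    X = _design(data, spec.fixed_terms)
    y = data[spec.response].to_numpy(dtype=float)
    groups = data[spec.random_intercept] if spec.random_intercept else None

    if spec.family == "binomial":
        return _fit_binomial(spec, X, y, groups)
    if spec.family == "negbin":
        return _fit_negbin(spec, X, y, groups)
    return _fit_lognormal(spec, X, y, groups)


def _fit_binomial(spec, X, y, groups) -> FitResult:
    glm = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm_fit = glm.fit()
    separation = bool(np.any(np.abs(glm_fit.params) > 15))
    if groups is None:
        coef = _coef_frame(X.columns, glm_fit.params, glm_fit.bse)
        return FitResult(spec, coef, float(glm_fit.llf), X.shape[1], len(y),
                         converged=glm_fit.converged,
                         extra={"separation": separation})
    res = fit_binomial_glmm(X.to_numpy(), y, groups.to_numpy(),
                            start_beta=np.clip(glm_fit.params, -10, 10))
    coef = _coef_frame(X.columns, res.params, res.se)
    return FitResult(spec, coef, res.loglik, res.k, res.n, res.converged,
                     sigma=res.sigma, extra={"separation": separation,
                                             "sigma_se": res.sigma_se})


def _fit_negbin(spec, X, y, groups) -> FitResult:
    if groups is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nb = sm.NegativeBinomial(y, X.to_numpy()).fit(disp=0)
        coef = _coef_frame(X.columns, nb.params[:-1], nb.bse[:-1])
        return FitResult(spec, coef, float(nb.llf), X.shape[1] + 1, len(y),
                         converged=bool(nb.mle_retvals.get("converged", True)),
                         alpha=float(nb.params[-1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.GLM(y, X.to_numpy(), family=sm.families.Poisson()).fit()
    res = fit_negbin_glmm(X.to_numpy(), y, groups.to_numpy(),
                          start_beta=np.clip(pois.params, -10, 10))
    alpha = res.alpha
    if alpha is not None and alpha > 1e3:
        warnings.warn("negative-binomial dispersion diverged; "
                      "interpret as Poisson", RuntimeWarning)
    coef = _coef_frame(X.columns, res.params, res.se)
    return FitResult(spec, coef, res.loglik, res.k, res.n, res.converged,
                     sigma=res.sigma, alpha=alpha)


def _fit_lognormal(spec, X, y, groups) -> FitResult:
    if np.any(y <= 0) or np.any(~np.isfinite(y)):
        raise ValueError(
            f"fit_model: log-normal response {spec.response!r} must be positive "
            "and finite (filter undefined rows first)")
    ylog = np.log(y)
    if groups is None:
        ols = sm.OLS(ylog, X.to_numpy()).fit()
        coef = _coef_frame(X.columns, ols.params, ols.bse)
        return FitResult(spec, coef, float(ols.llf), X.shape[1] + 1, len(y),
                         converged=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mm = sm.MixedLM(ylog, X.to_numpy(), groups=np.asarray(groups))
        fit = mm.fit(reml=False)
    p = X.shape[1]
    sigma = float(np.sqrt(max(np.asarray(fit.cov_re)[0, 0], 0.0)))
    if not np.isfinite(fit.llf) or sigma < 1e-8:
        # ML landed on the sigma_u = 0 boundary: the model degenerates to a
        # fixed-effects fit, which is then the correct (and finite) ML answer
        ols = sm.OLS(ylog, X.to_numpy()).fit()
        coef = _coef_frame(X.columns, ols.params, ols.bse)
        return FitResult(spec, coef, float(ols.llf), p + 1, len(y),
                         converged=True, sigma=0.0,
                         extra={"re_boundary": True})
    coef = _coef_frame(X.columns, fit.params[:p], fit.bse[:p])
    return FitResult(spec, coef, float(fit.llf), p + 2, len(y),
                     converged=bool(fit.converged), sigma=sigma)


def select_model(candidates, data: pd.DataFrame) -> tuple[FitResult, pd.DataFrame]:
    """Fit every candidate, rank by AICc, return the best and the full table.

    Ties are broken by fewer parameters and then by lexicographic term
    order, which makes selection deterministic.  Candidates that fail to
    converge are ranked but never selected unless nothing converged.
    """
    if not candidates:
        raise ValueError("select_model: empty candidate list")
    fits, rows = [], []
    for spec in candidates:
        fit = fit_model(spec, data)
        fits.append(fit)
        rows.append({
            "terms": " + ".join(spec.fixed_terms) or "(intercept only)",
            "k": fit.k, "loglik": fit.loglik, "aicc": fit.aicc,
            "converged": fit.converged,
        })
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(fits)),
        key=lambda i: (not fits[i].converged, fits[i].aicc, fits[i].k,
                       fits[i].spec.fixed_terms),
    )
    table = table.iloc[order].reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    best = fits[order[0]]
    if not best.converged:
        raise RuntimeError("select_model: no candidate converged; "
                           f"best diagnostic table:\n{table.head()}")
    return best, table


def term_lrt(spec: ModelSpec, data: pd.DataFrame, term: str) -> tuple[float, float]:
    """Likelihood-ratio test for one term (dropping dependants with it)."""
    keep = tuple(
        t for t in spec.fixed_terms
        if t != term and term not in term_parents(t, PLAYBACK_TERM_PARENTS))
    full = fit_model(spec, data)
    red = fit_model(replace(spec, fixed_terms=keep), data)
    df = full.k - red.k
    lr = 2.0 * (full.loglik - red.loglik)
    return lr, float(stats.chi2.sf(max(lr, 0.0), df))


# ---------------------------------------------------------------------------
# Experiment-specific model builders


def fit_alarm_model_M1(trials: pd.DataFrame, epsilon: pd.DataFrame,
                       include_interaction: bool = True) -> FitResult:
    """Alarm-occurrence model for the predator-presentation experiment.

    Logistic regression of ``alarm_given`` on focal species, the focal
    species' vulnerability to the presented predator (``epsilon[focal,
    predator]``), optionally their interaction, distance to the model,
    group size and presence of young.  Control trials are excluded (the
    preliminary predator-vs-control contrast is a separate model).  With
    ``include_interaction=False`` the model estimates the community-wide
    vulnerability slope directly.
    """
    pred = trials[trials["model_kind"] == "predator"].copy()
    if len(pred) == 0:
        raise ValueError("fit_alarm_model_M1: no predator trials")
    pred["vulnerability"] = [
        epsilon.loc[s, p] for s, p in zip(pred["focal_species"], pred["predator_id"])]
    species = sorted(pred["focal_species"].unique())
    X = pd.DataFrame(index=pred.index)
    X["intercept"] = 1.0
    for s in species[1:]:
        X[f"species[{s}]"] = (pred["focal_species"] == s).astype(float)
    X["vulnerability"] = pred["vulnerability"].to_numpy()
    if include_interaction:
        for s in species[1:]:
            X[f"species[{s}]:vulnerability"] = (
                X[f"species[{s}]"] * X["vulnerability"])
    X["distance_m"] = pred["distance_m"].astype(float).to_numpy()
    X["group_size"] = pred["group_size"].astype(float).to_numpy()
    X["young_present"] = pred["young_present"].astype(float).to_numpy()
    y = pred["alarm_given"].astype(float).to_numpy()
    glm = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = glm.fit()
    separation = bool(np.any(np.abs(fit.params) > 15))
    spec = ModelSpec("alarm_given", "binomial", tuple(X.columns[1:]))
    coef = _coef_frame(X.columns, fit.params, fit.bse)
    return FitResult(spec, coef, float(fit.llf), X.shape[1], len(y),
                     converged=fit.converged, extra={"separation": separation})


def preliminary_calltype_model(
    playbacks: pd.DataFrame,
    include_interaction: bool = True,
) -> tuple[FitResult, pd.DataFrame]:
    """Call-type model on the full playback set; returns (fit, filtered data).

    Binomial model of ``responded`` on receiver species, call type with the
    control sound as reference level (so the reported conspecific and
    heterospecific coefficients are contrasts against control), optionally
    their interaction, plus the environmental covariates.  The returned
    table has all control trials removed, ready for the M2 suite.
    """
    kinds = set(playbacks["call_kind"].unique())
    missing = {"control", "conspecific", "heterospecific"} - kinds
    if missing:
        raise ValueError(f"preliminary_calltype_model: call types absent: {sorted(missing)}")
    dat = playbacks.copy()
    species = sorted(dat["receiver_species"].unique())
    X = pd.DataFrame(index=dat.index)
    X["intercept"] = 1.0
    for s in species[1:]:
        X[f"receiver[{s}]"] = (dat["receiver_species"] == s).astype(float)
    for kind in ("conspecific", "heterospecific"):
        X[kind] = (dat["call_kind"] == kind).astype(float)
    if include_interaction:
        for s in species[1:]:
            for kind in ("conspecific", "heterospecific"):
                X[f"receiver[{s}]:{kind}"] = X[f"receiver[{s}]"] * X[kind]
    for col in ("grass_height", "cover_proximity", "speaker_distance",
                "wind_speed", "group_size"):
        v = dat[col].astype(float)
        X[col] = ((v - v.mean()) / v.std(ddof=1)).to_numpy()
    y = dat["responded"].astype(float).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial()).fit()
    spec = ModelSpec("responded", "binomial", tuple(X.columns[1:]))
    coef = _coef_frame(X.columns, fit.params, fit.bse)
    result = FitResult(spec, coef, float(fit.llf), X.shape[1], len(y),
                       converged=fit.converged)
    filtered = playbacks[playbacks["call_kind"] != "control"].reset_index(drop=True)
    return result, filtered


def response_model_spec(response: str, family: str) -> ModelSpec:
    """Canonical full ModelSpec for one playback response variable."""
    return ModelSpec(response, family, tuple(DESIGN_TERMS),
                     random_intercept="receiver_species")


def prepare_playback_table(playbacks: pd.DataFrame, indices: DerivedIndices,
                           masses: pd.Series,
                           include_conspecific: bool = False) -> pd.DataFrame:
    """Join coded playback trials with their model covariates.

    Control trials are dropped; conspecific trials are dropped too unless
    requested (the heterospecific-response models target heterospecific
    information use).
    """
    dat = playbacks[playbacks["call_kind"] != "control"]
    if not include_conspecific:
        dat = dat[dat["call_kind"] == "heterospecific"]
    dat = dat.reset_index(drop=True)
    X = build_playback_design(dat, indices, masses)
    keep = [c for c in dat.columns if c not in X.columns]
    return pd.concat([dat[keep], X], axis=1)


RESPONSE_FAMILIES = {
    "responded": "binomial",
    "latency_s": "lognormal",
    "duration_s": "lognormal",
    "headlift_speed": "lognormal",
    "n_head_ups": "negbin",
    "n_scratches": "negbin",
}


def fit_response_models(playbacks: pd.DataFrame, indices: DerivedIndices,
                        masses: pd.Series,
                        include_conspecific: bool = False,
                        responses=None) -> dict[str, FitResult]:
    """Fit the six playback response models on their appropriate subsets.

    Binary response uses every (heterospecific) trial; latency, duration,
    head-lift speed and the two counts are fitted only on trials where a
    response occurred (they are undefined otherwise), and duration
    additionally drops censored trials.  Non-convergence is reported on the
    FitResult, not raised.
    """
    table = prepare_playback_table(playbacks, indices, masses,
                                   include_conspecific=include_conspecific)
    out = {}
    for resp in (responses or RESPONSE_FAMILIES):
        family = RESPONSE_FAMILIES[resp]
        sub = table
        if resp != "responded":
            sub = sub[sub["responded"]]
            if resp == "duration_s":
                sub = sub[~sub["duration_censored"] & sub["duration_s"].notna()]
            if family == "lognormal":
                sub = sub[sub[resp].notna() & (sub[resp] > 0)]
            sub = sub.reset_index(drop=True)
        out[resp] = fit_model(response_model_spec(resp, family), sub)
    return out


@dataclass
class WilcoxonResult:
    V: float          # sum of ranks of positive differences (R's V)
    p: float
    n_nonzero: int
    degenerate: bool = False


def wilcoxon_control_check(control_rates, baseline_rates) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test of control-playback vs baseline rates.

    Tests whether per-subject head-up rates during control playbacks differ
    from undisturbed foraging; a non-significant result supports treating
    the control sound as neutral.  ``V`` is the sum of ranks of the positive
    differences (zero differences dropped), matching R's convention; the
    p-value is exact for small samples without ties.
    """
    x = np.asarray(control_rates, dtype=float)
    y = np.asarray(baseline_rates, dtype=float)
    if x.shape != y.shape:
        raise ValueError("wilcoxon_control_check: unequal lengths")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("wilcoxon_control_check: rates must be nonnegative")
    d = x - y
    nz = d[d != 0]
    if len(nz) == 0:
        return WilcoxonResult(V=0.0, p=1.0, n_nonzero=0, degenerate=True)
    ranks = stats.rankdata(np.abs(nz))
    V = float(ranks[nz > 0].sum())
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                         method="auto")
    return WilcoxonResult(V=V, p=float(res.pvalue), n_nonzero=len(nz))
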