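"""Linear mixed-effects modelling with LRT-driven backward selection.

Dyad-level tables are modelled with linear mixed models (random
intercepts for dyads, optionally crossed with video valence and video
index).  Model comparison uses likelihood-ratio tests on ML fits;
the backward-stepwise procedure first orders candidate fixed effects by
their LRT contribution, prunes from the bottom if the full model fails
to converge, then repeatedly removes the term whose deletion has the
largest LRT p-value until every remaining fixed effect is significant,
never removing a main effect while one of its interactions remains.

Fitting is delegated to ``statsmodels`` MixedLM; crossed random
intercepts are expressed as variance components within a single
all-encompassing group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests


@dataclass
class ModelSpec:
    """Declarative mixed-model specification.

    ``fixed`` lists fixed-effect terms in formula syntax (main effects
    and ``a:b`` interactions; string/categorical columns get treatment
    coding).  ``random_intercepts`` lists grouping columns — one column
    uses the ordinary grouped-intercept parameterization, several are
    crossed via variance components.  ``estimation`` is ``"REML"`` for
    reporting or ``"ML"`` for model comparison.
    """

    response: str
    fixed: list = field(default_factory=list)
    random_intercepts: list = field(default_factory=lambda: ["dyad"])
    random_slopes: list = field(default_factory=list)
    estimation: str = "REML"

    def __post_init__(self) -> None:
        if self.estimation not in ("REML", "ML"):
            raise ValueError("estimation must be 'REML' or 'ML'")
        if not self.random_intercepts:
            raise ValueError("at least one random-intercept grouping is required")

    @property
    def formula(self) -> str:
        rhs = " + ".join(["1"] + list(self.fixed))
        return f"{self.response} ~ {rhs}"

    def columns_used(self) -> list:
        cols = {self.response}
        for term in list(self.fixed) + list(self.random_slopes):
            for part in term.split(":"):
                cols.add(part.replace("C(", "").replace(")", "").strip())
        cols.update(self.random_intercepts)
        return sorted(cols)

    def without(self, term: str) -> "ModelSpec":
        if term not in self.fixed:
            raise ValueError(f"term {term!r} not in the model")
        return replace(self, fixed=[t for t in self.fixed if t != term])


@dataclass
class ModelFit:
    """Fitted mixed model with the usual reporting quantities."""

    spec: ModelSpec
    method: str
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    llf: float
    n_fixed_params: int
    nobs: int
    sigma2: float
    tau00: float
    icc: float
    r2_marginal: float
    r2_conditional: float
    converged: bool
    result: object = None


def standardize_predictors(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """z-score the named continuous columns (sample SD, ddof=1).

    Centring and scaling around the experimental-sample mean makes
    coefficients comparable and interaction terms interpretable.
    Categorical columns are left untouched.
    """
    out = table.copy()
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        out[col] = (x - x.mean()) / sd
    return out


def fit_lmm(spec: ModelSpec, table: pd.DataFrame) -> ModelFit:
    """Fit a linear mixed model by (RE)ML.

    Complete cases only; with zero random variance in the data the
    fixed effects coincide with ordinary least squares.  Singular or
    non-converged optimizations are reported through the ``converged``
    flag, never silently.
    """
    data = table.dropna(subset=[c for c in spec.columns_used() if c in table.columns])
    data = data.reset_index(drop=True)
    if data.empty:
        raise ValueError("no complete cases for the model columns")

    kwargs = {}
    if len(spec.random_intercepts) == 1 and not spec.random_slopes:
        kwargs["groups"] = data[spec.random_intercepts[0]].astype(str)
        kwargs["re_formula"] = "1"
    elif len(spec.random_intercepts) == 1:
        kwargs["groups"] = data[spec.random_intercepts[0]].astype(str)
        kwargs["re_formula"] = "1 + " + " + ".join(spec.random_slopes)
    else:
        data = data.assign(_one=1)
        kwargs["groups"] = data["_one"]
        vc = {g: f"0 + C({g})" for g in spec.random_intercepts}
        if spec.random_slopes:
            g0 = spec.random_intercepts[0]
            for s in spec.random_slopes:
                vc[f"slope_{s}"] = f"0 + C({g0}):{s}"
        kwargs["vc_formula"] = vc
        kwargs["re_formula"] = "0"

    model = MixedLM.from_formula(spec.formula, data, **kwargs)
    result = None
    last_exc = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                result = model.fit(reml=(spec.estimation == "REML"), method=method)
                break
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
    if result is None:
        raise RuntimeError(f"mixed-model fit failed: {last_exc}") from last_exc
    converged = bool(getattr(result, "converged", True) and np.isfinite(result.llf))

    fe = result.fe_params
    k_fe = fe.size
    bse = result.bse_fe
    ci = pd.DataFrame({"lower": fe - 1.96 * bse, "upper": fe + 1.96 * bse})
    z = fe / bse
    pvals = pd.Series(2.0 * sstats.norm.sf(np.abs(z)), index=fe.index)

    sigma2 = float(result.scale)
    tau00 = 0.0
    if result.cov_re is not None and result.cov_re.size:
        tau00 += float(np.trace(np.atleast_2d(result.cov_re)))
    if getattr(result, "vcomp", None) is not None and np.size(result.vcomp):
        tau00 += float(np.sum(result.vcomp))
    icc = tau00 / (tau00 + sigma2) if (tau00 + sigma2) > 0 else float("nan")

    fitted_fixed = np.asarray(result.model.exog) @ np.asarray(fe)
    var_f = float(np.var(fitted_fixed))
    denom = var_f + tau00 + sigma2
    r2m = var_f / denom if denom > 0 else float("nan")
    r2c = (var_f + tau00) / denom if denom > 0 else float("nan")

    return ModelFit(spec=spec, method=spec.estimation, params=fe, bse=bse,
                    conf_int=ci, pvalues=pvals, llf=float(result.llf),
                    n_fixed_params=int(k_fe), nobs=int(result.nobs),
                    sigma2=sigma2, tau00=tau00, icc=icc,
                    r2_marginal=r2m, r2_conditional=r2c,
                    converged=converged, result=result)


def likelihood_ratio_test(fit_nested: ModelFit, fit_full: ModelFit):
    """LRT between nested ML fits: (chi2, df, p).

    chi2 = 2·(ll_full − ll_nested); df is the fixed-parameter-count
    difference; REML log-likelihoods are not comparable across fixed
    effects and are rejected.
    """
    if fit_nested.method != "ML" or fit_full.method != "ML":
        raise ValueError("LRT requires ML fits (REML log-likelihoods are not comparable)")
    if not set(fit_nested.spec.fixed).issubset(set(fit_full.spec.fixed)):
        raise ValueError("models are not nested: the reduced model has extra terms")
    chi2 = max(0.0, 2.0 * (fit_full.llf - fit_nested.llf))
    df = fit_full.n_fixed_params - fit_nested.n_fixed_params
    if df <= 0:
        return chi2, 0, 1.0
    return chi2, df, float(sstats.chi2.sf(chi2, df))


def _components(term: str) -> frozenset:
    return frozenset(p.strip() for p in term.split(":"))


def _droppable(terms: Sequence[str]) -> list:
    """Terms removable without violating marginality (no main effect is
    dropped while one of its interactions remains)."""
    comps = {t: _components(t) for t in terms}
    out = []
    for t in terms:
        if any(comps[t] < comps[u] for u in terms if u != t):
            continue
        out.append(t)
    return out


@dataclass
class SelectionStep:
    action: str
    term: Optional[str]
    chi2: float
    df: int
    p: float


@dataclass
class SelectionTrace:
    """Replayable record of the backward-stepwise elimination."""

    ordering: list
    steps: list
    final_spec: ModelSpec
    final_fit: ModelFit
    dropped_for_convergence: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ordering": self.ordering,
            "dropped_for_convergence": self.dropped_for_convergence,
            "steps": [vars(s) for s in self.steps],
            "final_fixed": list(self.final_spec.fixed),
        }


def backward_stepwise(full_spec: ModelSpec, table: pd.DataFrame,
                      alpha_keep: float = 0.05) -> SelectionTrace:
    """LRT-driven backward elimination of fixed effects.

    1. rank candidate terms by their single-term LRT contribution to
       the full model; 2. if the full model does not converge, drop the
       least-contributing droppable terms until it does; 3. repeatedly
       remove the droppable term with the largest deletion-LRT p-value
       while that p-value exceeds ``alpha_keep``.  All comparison fits
       use ML; the returned final fit as well (so its log-likelihood is
       comparable in post hoc nesting tests).
    """
    spec = replace(full_spec, estimation="ML")
    fit = fit_lmm(spec, table)

    # step 1: contribution ordering (largest deletion p = least contribution)
    ordering = []
    for term in _droppable(spec.fixed):
        reduced = fit_lmm(spec.without(term), table)
        chi2, df, p = likelihood_ratio_test(reduced, fit)
        ordering.append((term, p, chi2, df))
    ordering.sort(key=lambda item: item[1])
    ordered_terms = [t for t, _, _, _ in ordering]

    # step 2: convergence-driven pruning from the least-contributing end
    dropped_conv = []
    while not fit.converged and spec.fixed:
        droppable = _droppable(spec.fixed)
        if not droppable:
            break
        victims = [t for t in reversed(ordered_terms) if t in droppable]
        victim = victims[0] if victims else droppable[-1]
        spec = spec.without(victim)
        dropped_conv.append(victim)
        fit = fit_lmm(spec, table)
    if not fit.converged and not spec.fixed:
        raise RuntimeError("intercept-only model failed to converge")

    # step 3: backward elimination by deletion LRT
    steps = []
    while spec.fixed:
        candidates = []
        for term in _droppable(spec.fixed):
            reduced_fit = fit_lmm(spec.without(term), table)
            chi2, df, p = likelihood_ratio_test(reduced_fit, fit)
            candidates.append((p, term, chi2, df, reduced_fit))
        if not candidates:
            break
        candidates.sort(key=lambda item: -item[0])
        p, term, chi2, df, reduced_fit = candidates[0]
        if p <= alpha_keep:
            break
        steps.append(SelectionStep(action="drop", term=term, chi2=chi2, df=df, p=p))
        spec, fit = reduced_fit.spec, reduced_fit

    return SelectionTrace(ordering=[t for t, *_ in ordering], steps=steps,
                          final_spec=spec, final_fit=fit,
                          dropped_for_convergence=dropped_conv)


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def nonparametric_posthoc(table: pd.DataFrame, comparisons: Sequence[tuple],
                          adjust: bool = True) -> pd.DataFrame:
    """Spearman correlations and Wilcoxon–Mann–Whitney group tests.

    ``comparisons`` is a list of ``("spearman", col_x, col_y)`` or
    ``("mannwhitney", value_col, group_col)`` tuples forming one Holm
    family.  Effect sizes are Pearson-style r (rho itself for Spearman,
    the normal-approximation Z/sqrt(n) for Mann–Whitney; ties handled
    by midranks).
    """
    rows = []
    for comp in comparisons:
        kind, a, b = comp
        if kind == "spearman":
            x = table[a].dropna()
            y = table[b].dropna()
            joined = table[[a, b]].dropna()
            if len(joined) < 4:
                raise ValueError(f"spearman({a}, {b}): need n >= 4")
            rho, p = sstats.spearmanr(joined[a], joined[b])
            rows.append({"test": "spearman", "a": a, "b": b,
                         "statistic": float(rho), "p": float(p),
                         "effect_r": float(rho), "n": len(joined)})
        elif kind == "mannwhitney":
            sub = table[[a, b]].dropna()
            levels = sorted(sub[b].unique())
            if len(levels) != 2:
                raise ValueError(f"mannwhitney({a}, {b}): need exactly 2 groups")
            g1 = sub.loc[sub[b] == levels[0], a]
            g2 = sub.loc[sub[b] == levels[1], a]
            n = len(g1) + len(g2)
            if n < 4:
                raise ValueError(f"mannwhitney({a}, {b}): need n >= 4")
            u, p = sstats.mannwhitneyu(g1, g2, alternative="two-sided")
            mu = len(g1) * len(g2) / 2.0
            # tie-corrected variance for the normal approximation
            ranks = sstats.rankdata(np.concatenate([g1, g2]))
            _, counts = np.unique(ranks, return_counts=True)
            tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1))
            var_u = len(g1) * len(g2) / 12.0 * (n + 1 - tie_term)
            z = (u - mu) / np.sqrt(var_u) if var_u > 0 else 0.0
            rows.append({"test": "mannwhitney", "a": a, "b": b,
                         "statistic": float(u), "p": float(p),
                         "effect_r": float(z / np.sqrt(n)), "n": n})
        else:
            raise ValueError(f"unknown comparison kind {kind!r}")
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["p_holm"] = holm_adjust(out["p"].to_numpy())
    return out


def shapiro_normality(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Shapiro–Wilk normality screen used to motivate nonparametric tests."""
    rows = []
    for col in columns:
        x = table[col].dropna().to_numpy(dtype=float)
        stat, p = sstats.shapiro(x)
        rows.append({"column": col, "W": float(stat), "p": float(p), "n": x.size})
    return pd.DataFrame(rows)
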