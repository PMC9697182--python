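"""Statistical stages: age grouping, mixed-model likelihood-ratio tests,
group-vs-adult RDM permutation tests, and the RDM-score/completion-score
correlation.

Mixed models are fit by maximum likelihood (not REML) so that likelihood-
ratio tests of nested fixed effects are valid; the test statistic is
chi2 = 2 * (loglik_full - loglik_reduced), clamped at zero, with df equal to
the fixed-parameter difference.  The group-vs-adult comparison uses a paired
sign-flip permutation on the RDMs' off-diagonal entries because those entries
are not independent, which rules out naive two-sample tests.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rsa import RDM

__all__ = [
    "AGE_GROUP_BOUNDS",
    "AgeGroupAssignment",
    "LRTResult",
    "CorrelationResult",
    "ConvergenceError",
    "assign_age_groups",
    "age_group_of",
    "lrt_fixed_effect",
    "compare_group_to_adult_rdm",
    "correlate_rdm_completion",
]

#: inclusive upper bounds (months) of age groups 1-3; group 4 is open-ended
AGE_GROUP_BOUNDS = (44, 58, 67)


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class AgeGroupAssignment:
    child_id: str
    age_months: int
    group: int


@dataclass(frozen=True)
class LRTResult:
    term: str
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    p: float


def age_group_of(age_months: int) -> int:
    """Group 1: <= 44 mo; group 2: 45-58; group 3: 59-67; group 4: > 67."""
    for g, bound in enumerate(AGE_GROUP_BOUNDS, start=1):
        if age_months <= bound:
            return g
    return 4


def assign_age_groups(children) -> list:
    """Children may be agents (``.child_id``/``.age_months``), mappings, or a
    DataFrame; entries without an age are excluded."""
    if isinstance(children, pd.DataFrame):
        children = children.to_dict("records")
    out = []
    for c in children:
        child_id = getattr(c, "child_id", None) or c["child_id"]
        age = getattr(c, "age_months", None)
        if age is None:
            age = c.get("age_months")
        if age is None or (isinstance(age, float) and np.isnan(age)):
            continue
        out.append(AgeGroupAssignment(child_id, int(age), age_group_of(int(age))))
    return out


def _fit_mixed(data: pd.DataFrame, response: str, fixed: list, random_terms: list):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rhs = " + ".join(fixed) if fixed else "1"
    formula = f"{response} ~ {rhs}"
    usable = [t for t in random_terms if data[t].nunique() >= 2]
    for t in set(random_terms) - set(usable):
        warnings.warn(f"random term {t!r} has < 2 levels; dropped", UserWarning, stacklevel=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if not usable:
            model = smf.ols(formula, data=data)
            return model.fit()
        if len(usable) == 1:
            model = smf.mixedlm(formula, data=data, groups=data[usable[0]])
        else:
            # crossed random intercepts as variance components on one trivial group
            df = data.copy()
            df["_one"] = 1
            vc = {t: f"0 + C({t})" for t in usable}
            model = smf.mixedlm(formula, data=df, groups=df["_one"], vc_formula=vc)
        # the default optimizer can stall in poor optima for variance-component
        # models; refine with Powell and keep the best finite log-likelihood
        candidates = []
        try:
            candidates.append(model.fit(reml=False, maxiter=500))
        except Exception:
            pass
        try:
            candidates.append(model.fit(reml=False, method="powell", maxiter=2000))
        except Exception:
            pass
        usable_fits = [r for r in candidates if np.isfinite(r.llf)]
        if not usable_fits:
            raise ConvergenceError("mixed-model fit failed with all optimizers")
        return max(usable_fits, key=lambda r: r.llf)


def lrt_fixed_effect(
    data: pd.DataFrame,
    response: str,
    fixed_terms: list,
    test_term: str,
    random_terms: list,
) -> LRTResult:
    """Chi-squared likelihood-ratio test of one fixed effect in a linear mixed
    model, comparing the full model (all fixed terms) against the model
    without ``test_term``.  Both fits use maximum likelihood."""
    for col in [response, *random_terms]:
        if col not in data.columns:
            raise KeyError(f"column {col!r} not in data")
    if test_term not in fixed_terms:
        raise ValueError(f"test_term {test_term!r} must be among fixed_terms")
    if test_term in data.columns and data[test_term].nunique() <= 1:
        warnings.warn(
            f"test term {test_term!r} is constant; full and reduced models coincide",
            UserWarning,
            stacklevel=2,
        )
        return LRTResult(test_term, 0.0, 1, 1.0)

    reduced_terms = [t for t in fixed_terms if t != test_term]
    full = _fit_mixed(data, response, fixed_terms, random_terms)
    reduced = _fit_mixed(data, response, reduced_terms, random_terms)
    for name, res in (("full", full), ("reduced", reduced)):
        if hasattr(res, "converged") and not res.converged:
            raise ConvergenceError(
                f"{name} model did not converge "
                f"(method={getattr(res, 'method', '?')}, llf={res.llf})"
            )
    df = int(np.asarray(full.fe_params if hasattr(full, "fe_params") else full.params).size
             - np.asarray(reduced.fe_params if hasattr(reduced, "fe_params") else reduced.params).size)
    if df <= 0:
        raise ValueError("models are not properly nested")
    chi2 = 2.0 * (full.llf - reduced.llf)
    if chi2 < 0:
        warnings.warn(
            f"negative LRT statistic ({chi2:.3g}) clamped to 0 (optimizer noise)",
            UserWarning,
            stacklevel=2,
        )
        chi2 = 0.0
    p = float(stats.chi2.sf(chi2, df))
    return LRTResult(test_term, float(chi2), df, p)


def compare_group_to_adult_rdm(
    group_rdm: RDM, adult_rdm: RDM, n_perm: int = 1000, rng=None
) -> float:
    """Paired sign-flip permutation test on the two RDMs' off-diagonal entries.

    Statistic: absolute mean of the paired entry differences.  Null: each
    paired difference has a symmetric distribution around zero, simulated by
    random sign flips.  Returns the plus-one permutation p-value
    (1 + #{null >= observed}) / (1 + n_perm), never below 1/(1 + n_perm).
    """
    if group_rdm.labels != adult_rdm.labels:
        raise ValueError("RDM label mismatch between group and adult matrices")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    diffs = group_rdm.off_diagonal() - adult_rdm.off_diagonal()
    observed = abs(float(diffs.mean()))
    signs = rng.choice((-1.0, 1.0), size=(n_perm, diffs.size))
    null = np.abs((signs * diffs).mean(axis=1))
    return float((1 + int(np.sum(null >= observed))) / (1 + n_perm))


def correlate_rdm_completion(rdm_scores, completion_scores) -> CorrelationResult:
    """Pearson correlation between per-child RDM scores and completion scores,
    with the two-sided t-transform p-value on n-2 df."""
    x = np.asarray(rdm_scores, dtype=np.float64)
    y = np.asarray(completion_scores, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-d score vectors required")
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant score vector; correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), x.size - 2, float(res.pvalue))
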