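"""Statistical layer: linear mixed models, Tukey-adjusted least-squares
means, Fisher omnibus combination, Cohen's kappa and backward stepwise
elimination.

Mixed models are maximum-likelihood fits (not REML) with random intercepts
per individual; the call-rate models carry crossed random intercepts for the
two individuals of a dyad, implemented as variance components.  Per-term
ANOVA tables use Wald F tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "EffectTest", "LmeFit", "fit_lme", "pairwise_lsmeans", "fisher_omnibus",
    "cohens_kappa", "backward_eliminate", "simulate_rate_dataset",
]


@dataclass(frozen=True)
class EffectTest:
    term: str
    statistic: float
    df: float
    p_value: float
    kind: str = "wald_F"

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0


@dataclass
class LmeFit:
    """A fitted linear mixed model plus its per-term Wald tests.

    ``df_resid_eff`` is the effective residual degrees of freedom
    n - k_fe - edf(random effects), where the random-effect contribution is
    the sum of per-level shrinkage factors; the per-term F tests and the
    Tukey comparisons use it as denominator df together with the matching
    rescaling of the ML Wald statistic, which keeps their size close to
    nominal at small n (plug-in ML covariances are otherwise
    anti-conservative).
    """

    formula: str
    result: "object"  # MixedLMResults
    effect_tests: list[EffectTest]
    df_resid_eff: float = np.inf
    singular: bool = False
    warnings_: list[str] = field(default_factory=list)

    @property
    def fe_params(self) -> pd.Series:
        return self.result.fe_params

    @property
    def llf(self) -> float:
        return float(self.result.llf)

    def anova(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.effect_tests])

    def summary(self) -> str:
        head = f"LME (ML): {self.formula}" + ("   [singular fit]" if self.singular else "")
        return head + "\n" + self.anova().to_string(index=False)


def _term_contrast(result, term: str) -> np.ndarray:
    di = result.model.data.design_info
    sl = di.term_name_slices[term]
    k = len(result.params)
    R = np.zeros((sl.stop - sl.start, k))
    for i, j in enumerate(range(sl.start, sl.stop)):
        R[i, j] = 1.0
    return R


def _random_effect_edf(result, data: pd.DataFrame,
                       factors: list[str]) -> float:
    """Degrees of freedom absorbed by the shrunken random intercepts:
    sum over levels of n_l * v / (n_l * v + sigma^2)."""
    scale = float(result.scale)
    if scale <= 0:
        return 0.0
    variances: list[tuple[str, float]] = []
    vcomp = np.atleast_1d(getattr(result, "vcomp", np.array([])))
    if len(factors) == 1 and vcomp.size == 0:
        cov_re = np.atleast_2d(result.cov_re)
        variances.append((factors[0], float(cov_re[0, 0])))
    else:
        for f, v in zip(factors, vcomp):
            variances.append((f, float(v)))
    edf = 0.0
    for f, v in variances:
        if v <= 0:
            continue
        for n_l in data[f].value_counts():
            edf += n_l * v / (n_l * v + scale)
    return edf


def _wald_term_tests(result, df_resid_eff: float) -> list[EffectTest]:
    di = result.model.data.design_info
    nobs = result.model.exog.shape[0]
    tests = []
    for term in di.term_names:
        if term == "Intercept":
            continue
        R = _term_contrast(result, term)
        J = R.shape[0]
        try:
            wt = result.wald_test(R, use_f=False, scalar=True)
            # rescale the ML Wald chi2 into an F with effective residual df
            f_stat = float(wt.statistic) / J * df_resid_eff / nobs
            p = float(np.clip(sps.f.sf(f_stat, J, df_resid_eff), 0.0, 1.0))
        except (ValueError, np.linalg.LinAlgError):
            # degenerate covariance (e.g. constant response): no evidence
            f_stat, p = 0.0, 1.0
        tests.append(EffectTest(term=term, statistic=f_stat, df=float(J),
                                p_value=p))
    return tests


def fit_lme(data: pd.DataFrame, response: str, fixed_terms: list[str] | str,
            random_intercepts: list[str] | str) -> LmeFit:
    """ML-fit a linear mixed model with random intercepts.

    ``fixed_terms`` may be a list of term strings (joined by '+') or a
    ready-made right-hand side; ``random_intercepts`` names one grouping
    column (classic random intercept) or several (crossed random
    intercepts via variance components).  Singular / non-converged fits are
    reported on the returned object, not silently ignored.
    """
    if isinstance(fixed_terms, (list, tuple)):
        rhs = " + ".join(fixed_terms) if fixed_terms else "1"
    else:
        rhs = fixed_terms
    if isinstance(random_intercepts, str):
        random_intercepts = [random_intercepts]
    if not random_intercepts:
        raise ValueError("at least one random-intercept factor is required")
    for col in [response, *random_intercepts]:
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    formula = f"{response} ~ {rhs}"
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        if len(random_intercepts) == 1:
            model = MixedLM.from_formula(formula, data=data,
                                         groups=data[random_intercepts[0]])
        else:
            vc = {g: f"0 + C({g})" for g in random_intercepts}
            model = MixedLM.from_formula(
                formula, data=data.assign(_one=1), groups="_one", vc_formula=vc)
        result = model.fit(reml=False)
        caught = [str(w.message) for w in wlist]
    singular = any("singular" in m.lower() or "converge" in m.lower()
                   or "boundary" in m.lower() for m in caught)
    nobs = result.model.exog.shape[0]
    k_fe = len(result.fe_params)
    edf = _random_effect_edf(result, data, random_intercepts)
    df_resid_eff = max(float(nobs - k_fe - edf), 3.0)
    fit = LmeFit(formula=formula, result=result,
                 effect_tests=_wald_term_tests(result, df_resid_eff),
                 df_resid_eff=df_resid_eff,
                 singular=singular, warnings_=caught)
    if singular:
        warnings.warn(f"LME fit for {formula!r} is singular or did not "
                      "converge cleanly; interpret with care")
    return fit


def pairwise_lsmeans(fit: LmeFit, factor: str,
                     data: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tukey-adjusted pairwise comparisons of least-squares means.

    Least-squares means are model predictions with the target factor set to
    each level and all other model columns held at their observed values,
    averaged over the data (i.e. predictions on balanced copies of the
    dataset).  The adjusted p-value uses the studentized range with the
    number of levels and the residual degrees of freedom.
    """
    result = fit.result
    frame = data if data is not None else result.model.data.frame
    levels = sorted(pd.unique(frame[factor].dropna()))
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    di = result.model.data.design_info
    cov = np.asarray(result.cov_params())[:len(result.fe_params), :len(result.fe_params)]
    beta = np.asarray(result.fe_params)

    from patsy import dmatrix
    rows = {}
    for lv in levels:
        mod = frame.copy()
        mod[factor] = lv
        X = np.asarray(dmatrix(di, mod, return_type="matrix"))
        rows[lv] = X.mean(axis=0)

    dof = max(fit.df_resid_eff, 3.0)
    k = len(levels)
    recs = []
    for i in range(k):
        for j in range(i + 1, k):
            c = rows[levels[i]] - rows[levels[j]]
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            t = est / se if se > 0 else np.inf
            p_raw = 2.0 * sps.t.sf(abs(t), dof)
            p_adj = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, dof))
            recs.append({
                "contrast": f"{levels[i]} - {levels[j]}",
                "estimate": est, "se": se, "t": t, "df": dof,
                "p_unadjusted": min(1.0, p_raw),
                "p_tukey": min(1.0, p_adj),
            })
    return pd.DataFrame(recs)


def fisher_omnibus(p_values) -> tuple[float, int, float]:
    """Fisher's omnibus combination of independent p-values.

    ``chi2 = -2 sum ln p_i`` on ``2k`` degrees of freedom; the combined p
    comes from the chi-square survival function.  Zero p-values are rejected
    (infinite statistic).
    """
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * len(p)
    return chi2, df, float(sps.chi2.sf(chi2, df))


def cohens_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa: ``(p_o - p_e) / (1 - p_e)`` with chance agreement from
    the marginal products."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label sequences differ in length")
    if len(a) == 0:
        raise ValueError("empty label sequences")
    cats = np.unique(np.concatenate([a, b]))
    idx = {c: i for i, c in enumerate(cats)}
    conf = np.zeros((len(cats), len(cats)))
    for x, y in zip(a, b):
        conf[idx[x], idx[y]] += 1
    n = conf.sum()
    p_o = np.trace(conf) / n
    p_e = float((conf.sum(axis=1) / n) @ (conf.sum(axis=0) / n))
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass
class EliminationStep:
    dropped: str
    p_value: float
    wald_comparison_p: float


def backward_eliminate(data: pd.DataFrame, response: str,
                       main_terms: list[str], interaction_terms: list[str],
                       random_intercepts: list[str] | str,
                       alpha: float = 0.05) -> tuple[LmeFit, list[EliminationStep]]:
    """Backward stepwise elimination of interaction terms.

    Starting from the full model, the interaction term with the highest
    non-significant Wald p-value is removed at each step; after each removal
    the dropped block is also assessed as a Wald comparison of the nested
    models.  Elimination stops when only main terms remain, when every
    remaining interaction is significant, or when a removal would
    significantly change the model.  Returns the minimum adequate model and
    the elimination log.
    """
    current = list(interaction_terms)
    log: list[EliminationStep] = []
    fit = fit_lme(data, response, main_terms + current, random_intercepts)
    while current:
        pvals = {}
        for term in current:
            test = next((t for t in fit.effect_tests
                         if _same_term(t.term, term)), None)
            if test is None:
                raise ValueError(f"interaction term {term!r} not found in the "
                                 "fitted model; non-nested comparison")
            pvals[term] = test.p_value
        worst = max(pvals, key=pvals.get)
        if pvals[worst] < alpha:
            break  # all remaining interactions significant
        # the Wald comparison of full vs reduced equals the block test of
        # the dropped coefficients in the fuller model
        comparison_p = pvals[worst]
        current.remove(worst)
        log.append(EliminationStep(dropped=worst, p_value=pvals[worst],
                                   wald_comparison_p=comparison_p))
        fit = fit_lme(data, response, main_terms + current, random_intercepts)
    return fit, log


def _same_term(a: str, b: str) -> bool:
    return set(a.split(":")) == set(b.split(":"))


def simulate_rate_dataset(n_experiments: int = 48, seed: int = 0,
                          mf_chirp_boost: float = 0.0,
                          housing_effect: float = 0.0,
                          interaction_effect: float = 0.0,
                          sd_individual: float = 0.3,
                          sd_residual: float = 0.5,
                          baseline: float = 2.0) -> pd.DataFrame:
    """Simulate a per-experiment call-rate table for the dyad design.

    Experiments balance sex composition (MM/FF/MF) x familiarity x housing
    type; each dyad pairs two individuals who recur across roughly three
    experiments in the same dyad role (mirroring repeated confrontation
    testing) and both contribute a random intercept.  Role-consistent
    recurrence keeps the two individual variance components identifiable --
    a factor whose levels appear once cannot be separated from the residual.
    ``mf_chirp_boost`` raises the rate of MF dyads, ``housing_effect`` the
    rate of pair-housed dyads, and ``interaction_effect`` adds a
    sex-by-housing interaction; all in calls/min on the response scale.
    """
    rng = np.random.default_rng(seed)
    sexes = ("MM", "FF", "MF")
    fams = ("familiar", "unfamiliar")
    houses = ("pair", "same_sex_group")
    pool = max(2, n_experiments // 6)   # per role: ~3 experiments each
    b1 = rng.normal(0.0, sd_individual, pool)
    b2 = rng.normal(0.0, sd_individual, pool)
    rows = []
    for e in range(n_experiments):
        sex = sexes[e % 3]
        fam = fams[(e // 3) % 2]
        house = houses[(e // 6) % 2]
        i1 = int(rng.integers(pool))
        i2 = int(rng.integers(pool))
        mu = baseline
        if sex == "MF":
            mu += mf_chirp_boost
        if house == "pair":
            mu += housing_effect
        if sex == "MF" and house == "pair":
            mu += interaction_effect
        rate = mu + b1[i1] + b2[i2] + rng.normal(0.0, sd_residual)
        rows.append({
            "experiment_id": f"sim{e:03d}", "sex_composition": sex,
            "familiarity": fam, "housing_type": house,
            "individual_1": f"a{i1:03d}", "individual_2": f"b{i2:03d}",
            "rate_per_min": rate,
        })
    return pd.DataFrame(rows)
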