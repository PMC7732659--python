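"""Two-level mixed models for event- vs. time-based PAS responses.

Measurement occasions (level 1) are nested in persons (level 2).  The
outcome is the PAS angle in degrees (how offended the participant felt,
0-90).  Two level-1 dummies code the occasion type: ``single_chat`` (message
ignored by a single recipient) and ``group_chat`` (ignored by a group);
baseline prompts have both at 0.  The saturated model is

    y_ti = b00 + b10*single_ti + b20*group_ti
           + r0i + r1i*single_ti + r2i*group_ti + e_ti

with random intercept r0i and random slopes r1i, r2i per person.  By
default the three random effects are modelled as independent (a diagonal
covariance); a full covariance is available by flag.  Estimation is REML
via :class:`statsmodels.regression.mixed_linear_model.MixedLM` (ML is
togglable for model comparison).

The intercept-only null model yields the intraclass correlation
ICC = var_between / (var_between + var_residual), and explained variance is
summarised by Omega^2 = 1 - resid_var(full)/resid_var(null), a generalized
R^2 for linear mixed models.

Person-level covariates (sex, age, self-esteem, Big Five, text-message
dependency, narcissism, collective self-esteem re: online groups) enter the
intercept equation grand-mean centered — all except sex, which keeps the
study's 1 = female / 2 = male coding so intercepts are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import EstimationError, InputError, LinkageError, UndefinedStatisticError
from .protocol import ResponseBurst, Category

__all__ = [
    "LEVEL2_COVARIATES",
    "MixedModelFit",
    "occasions_from_bursts",
    "center_level2",
    "fit_null",
    "fit_saturated",
    "omega_squared",
    "contrast_group_vs_single",
    "moderation_scan",
    "VarianceAssumptions",
    "estimate_power",
    "power_min_n",
]

#: Person-level covariates of the saturated model, in reporting order.
LEVEL2_COVARIATES = [
    "sex",
    "age",
    "self_esteem",
    "extraversion",
    "neuroticism",
    "openness",
    "agreeableness",
    "conscientiousness",
    "text_msg_dependency",
    "narcissism",
    "cse_og",
]

#: Covariates that stay on their raw coding (sex keeps 1=female / 2=male).
UNCENTERED = {"sex"}

# order matters: statsmodels' default optimizer (with its internal retries)
# first, then progressively more robust fallbacks
_FIT_METHODS = (None, "bfgs", "cg", "powell")


@dataclass
class MixedModelFit:
    """A fitted two-level model in report-ready form.

    ``fixed`` has one row per fixed effect (estimate, se, tvalue, pvalue);
    ``re_sd`` maps random-effect names to their SDs; ``resid_var`` is the
    level-1 residual variance; ``icc`` is set for intercept-only fits.
    ``fe_cov`` is the sampling covariance of the fixed effects (used by the
    group-vs-single contrast).  ``standardized`` optionally carries
    standardized coefficients (see :func:`fit_saturated`).
    """

    fixed: pd.DataFrame
    fe_cov: pd.DataFrame
    re_sd: dict[str, float]
    resid_var: float
    n_obs: int
    n_groups: int
    method: str
    converged: bool
    formula: str
    icc: float | None = None
    standardized: pd.DataFrame | None = None
    notes: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        out = self.fixed.copy()
        if self.standardized is not None:
            out.insert(0, "beta", self.standardized["estimate"].reindex(out.index))
        return out


def occasions_from_bursts(bursts: Sequence[ResponseBurst]) -> pd.DataFrame:
    """Build the occasion-level analysis table from classified bursts.

    One row per kept burst: the device id serves as person id, the burst's
    first-press angle as the offendedness outcome, and the category is
    dummy-coded (baseline = both dummies 0).
    """
    rows = []
    for b in bursts:
        if b.category not in (Category.SINGLE_CHAT, Category.GROUP_CHAT, Category.BASELINE):
            continue
        rows.append(
            {
                "person_id": b.device_id,
                "offendedness": b.angle,
                "single_chat": int(b.category is Category.SINGLE_CHAT),
                "group_chat": int(b.category is Category.GROUP_CHAT),
                "timestamp": b.timestamp,
            }
        )
    return pd.DataFrame(rows)


def center_level2(persons: pd.DataFrame, covariates: Sequence[str] | None = None) -> pd.DataFrame:
    """Grand-mean center person-level covariates (all except sex)."""
    covs = list(covariates) if covariates is not None else [
        c for c in LEVEL2_COVARIATES if c in persons.columns
    ]
    out = persons.copy()
    for c in covs:
        if c in UNCENTERED:
            continue
        out[c] = out[c] - out[c].mean()
    return out


def _validate_occasions(occasions: pd.DataFrame, need_dummies: bool) -> pd.DataFrame:
    required = {"person_id", "offendedness"} | ({"single_chat", "group_chat"} if need_dummies else set())
    missing = required - set(occasions.columns)
    if missing:
        raise InputError(f"occasions table lacks columns: {sorted(missing)}")
    df = occasions.copy()
    if need_dummies:
        s = df["single_chat"].astype(float)
        g = df["group_chat"].astype(float)
        if not set(np.unique(s)) <= {0.0, 1.0} or not set(np.unique(g)) <= {0.0, 1.0}:
            raise InputError("single_chat/group_chat must be 0/1 dummies")
        if (s * g).any():
            raise InputError("an occasion cannot be both single-chat and group-chat")
    sizes = df.groupby("person_id").size()
    if len(sizes) < 2 or (sizes < 2).all():
        raise EstimationError(
            "need at least two persons and repeated occasions to separate "
            "between- from within-person variance",
            diagnostics={"persons": len(sizes), "occasions": int(sizes.sum())},
        )
    return df


def _fit_mixedlm(model, reml: bool):
    best = None
    last_exc = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in _FIT_METHODS:
            try:
                if method is None:
                    res = model.fit(reml=reml, maxiter=2000)
                else:
                    res = model.fit(reml=reml, method=method, maxiter=2000)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if res.converged:
                return res
            # keep the best non-converged candidate by the (restricted)
            # likelihood in case no optimizer reports convergence
            if best is None or res.llf > best.llf:
                best = res
    if best is not None:
        return best  # caller records converged=False
    raise EstimationError(f"mixed-model optimisation failed: {last_exc!r}", diagnostics=last_exc)


def _package_fit(res, *, formula: str, method: str, slope_names: Sequence[str]) -> MixedModelFit:
    fe = res.fe_params
    bse = res.bse_fe
    fixed = pd.DataFrame(
        {
            "estimate": fe,
            "se": bse,
            "tvalue": fe / bse,
            "pvalue": 2 * st.norm.sf(np.abs(fe / bse)),
        }
    )
    k = len(fe)
    fe_cov = pd.DataFrame(
        np.asarray(res.cov_params())[:k, :k], index=fe.index, columns=fe.index
    )
    re_sd: dict[str, float] = {}
    cov_re = pd.DataFrame(res.cov_re)
    for name in cov_re.index:
        key = "intercept" if name in ("Group", "Intercept", "1") else str(name)
        re_sd[key] = float(np.sqrt(max(cov_re.loc[name, name], 0.0)))
    vc_names = list(res.model.exog_vc.names) if getattr(res.model, "exog_vc", None) else []
    for name, v in zip(vc_names, np.asarray(res.vcomp, dtype=float)):
        re_sd[str(name)] = float(np.sqrt(max(v, 0.0)))
    _ = slope_names  # names come from the model; kept for signature clarity
    return MixedModelFit(
        fixed=fixed,
        fe_cov=fe_cov,
        re_sd=re_sd,
        resid_var=float(res.scale),
        n_obs=int(res.model.nobs),
        n_groups=int(res.model.n_groups),
        method=method,
        converged=bool(res.converged),
        formula=formula,
    )


def fit_null(occasions: pd.DataFrame, *, reml: bool = True) -> MixedModelFit:
    """Intercept-only (null) model; sets the fit's ``icc``.

    ICC = between-person variance / (between + residual): the share of
    outcome variance attributable to stable differences between persons.
    """
    df = _validate_occasions(occasions, need_dummies=False)
    if df["offendedness"].var(ddof=1) == 0:
        raise EstimationError(
            "outcome is constant; variance components are degenerate",
            diagnostics={"value": float(df['offendedness'].iloc[0])},
        )
    formula = "offendedness ~ 1"
    model = smf.mixedlm(formula, df, groups=df["person_id"])
    res = _fit_mixedlm(model, reml)
    fit = _package_fit(res, formula=formula, method="reml" if reml else "ml", slope_names=[])
    tau0 = fit.re_sd.get("intercept", 0.0) ** 2
    fit.icc = tau0 / (tau0 + fit.resid_var)
    return fit


def fit_saturated(
    occasions: pd.DataFrame,
    persons: pd.DataFrame | None = None,
    *,
    include_level2: bool | None = None,
    random_slopes: bool = True,
    correlated_re: bool = False,
    reml: bool = True,
    standardize: bool = False,
    extra_terms: Sequence[str] = (),
) -> MixedModelFit:
    """Fit the random-intercept, random-slope ostracism model.

    With ``persons`` supplied (and ``include_level2`` not disabled), the
    person-level covariates enter the intercept equation after grand-mean
    centering (sex stays on its 1/2 coding).  ``random_slopes=False`` drops
    r1i/r2i; ``correlated_re=True`` frees the full 3x3 random-effect
    covariance instead of the default diagonal.  ``standardize=True``
    additionally refits on z-scored outcome and non-dummy predictors and
    stores the coefficients in ``fit.standardized`` (standardization
    convention: dummies left raw; see docs).

    ``extra_terms`` appends fixed-effect terms verbatim (used by
    :func:`moderation_scan` for cross-level interactions).
    """
    df = _validate_occasions(occasions, need_dummies=True)
    if df["single_chat"].sum() == 0 or df["group_chat"].sum() == 0:
        raise EstimationError(
            "both event types must occur at least once to estimate their effects",
            diagnostics={
                "n_single": int(df["single_chat"].sum()),
                "n_group": int(df["group_chat"].sum()),
            },
        )
    covs: list[str] = []
    if include_level2 is None:
        include_level2 = persons is not None
    if include_level2:
        if persons is None:
            raise InputError("include_level2 requires a persons table")
        covs = [c for c in LEVEL2_COVARIATES if c in persons.columns]
        if not covs:
            raise InputError("persons table carries no known level-2 covariates")
        centered = center_level2(persons, covs)
        merged = df.merge(centered[["person_id"] + covs], on="person_id", how="left", validate="many_to_one")
        unmatched = merged[covs].isna().any(axis=1)
        if unmatched.any():
            bad = sorted(merged.loc[unmatched, "person_id"].unique())
            raise LinkageError(f"persons table lacks covariates for: {bad[:5]}")
        df = merged
        _check_rank(df, covs)

    terms = ["single_chat", "group_chat"] + covs + list(extra_terms)
    formula = "offendedness ~ " + " + ".join(terms)
    vc, re_formula = None, "1"
    if random_slopes:
        if correlated_re:
            re_formula = "1 + single_chat + group_chat"
        else:
            vc = {"single_chat": "0 + single_chat", "group_chat": "0 + group_chat"}
    model = smf.mixedlm(formula, df, groups=df["person_id"], re_formula=re_formula, vc_formula=vc)
    res = _fit_mixedlm(model, reml)
    fit = _package_fit(
        res, formula=formula, method="reml" if reml else "ml",
        slope_names=["single_chat", "group_chat"] if random_slopes else [],
    )
    if standardize:
        fit.standardized = _standardized_fixed(df, terms, covs, random_slopes, correlated_re, reml)
        fit.notes["standardization"] = (
            "outcome and non-dummy predictors z-scored before refit; "
            "single_chat/group_chat/sex dummies left raw"
        )
    return fit


def _check_rank(df: pd.DataFrame, covs: Sequence[str]) -> None:
    X = df[list(covs)].drop_duplicates().to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify a minimal offending set by greedy elimination
        bad = []
        cols = list(covs)
        for c in list(cols):
            rest = [cc for cc in cols if cc != c]
            Xr = np.column_stack(
                [np.ones(len(X))] + [df[cc].drop_duplicates(ignore_index=True) for cc in rest]
            ) if rest else np.ones((len(X), 1))
            if np.linalg.matrix_rank(Xr) == np.linalg.matrix_rank(X):
                bad.append(c)
                cols = rest
        raise EstimationError(
            f"level-2 design is rank deficient; collinear covariates: {bad or list(covs)}",
            diagnostics={"collinear": bad},
        )


def _standardized_fixed(df, terms, covs, random_slopes, correlated_re, reml) -> pd.DataFrame:
    z = df.copy()
    dummy_like = {"single_chat", "group_chat", "sex"}
    z["offendedness"] = (z["offendedness"] - z["offendedness"].mean()) / z["offendedness"].std(ddof=1)
    for c in covs:
        if c in dummy_like:
            continue
        sd = z[c].std(ddof=1)
        if sd > 0:
            z[c] = (z[c] - z[c].mean()) / sd
    formula = "offendedness ~ " + " + ".join(terms)
    vc, re_formula = None, "1"
    if random_slopes:
        if correlated_re:
            re_formula = "1 + single_chat + group_chat"
        else:
            vc = {"single_chat": "0 + single_chat", "group_chat": "0 + group_chat"}
    model = smf.mixedlm(formula, z, groups=z["person_id"], re_formula=re_formula, vc_formula=vc)
    res = _fit_mixedlm(model, reml)
    fe = res.fe_params
    return pd.DataFrame({"estimate": fe, "se": res.bse_fe})


def omega_squared(full: MixedModelFit, null: MixedModelFit) -> float:
    """Omega^2 = 1 - resid_var(full) / resid_var(null).

    A generalized R^2 for linear mixed models (conventional anchors: 0.01
    small, 0.09 medium, 0.25 large).  Both fits must be to the same
    occasions.  A negative value (full model fits worse) is floored at 0
    with a warning.
    """
    if full.n_obs != null.n_obs:
        raise InputError(
            f"models fit to different data (n={full.n_obs} vs n={null.n_obs})"
        )
    if null.resid_var <= 0:
        raise UndefinedStatisticError("null model has no residual variance")
    val = 1.0 - full.resid_var / null.resid_var
    if val < 0:
        warnings.warn("Omega^2 negative; floored at 0", stacklevel=2)
        return 0.0
    return float(val)


@dataclass
class ContrastResult:
    estimate: float
    se: float
    statistic: float
    pvalue: float


def contrast_group_vs_single(fit: MixedModelFit) -> ContrastResult:
    """Wald test of b20 - b10 = 0 (is group ostracism worse than single?)."""
    for term in ("single_chat", "group_chat"):
        if term not in fit.fixed.index:
            raise InputError(f"fit lacks the {term!r} fixed effect")
    b10 = fit.fixed.loc["single_chat", "estimate"]
    b20 = fit.fixed.loc["group_chat", "estimate"]
    v = (
        fit.fe_cov.loc["group_chat", "group_chat"]
        + fit.fe_cov.loc["single_chat", "single_chat"]
        - 2 * fit.fe_cov.loc["group_chat", "single_chat"]
    )
    est = float(b20 - b10)
    se = float(np.sqrt(v))
    z = est / se if se > 0 else np.inf * np.sign(est)
    return ContrastResult(est, se, float(z), float(2 * st.norm.sf(abs(z))))


def moderation_scan(
    occasions: pd.DataFrame,
    persons: pd.DataFrame,
    covariates: Sequence[str] | None = None,
    *,
    reml: bool = True,
) -> pd.DataFrame:
    """Cross-level moderation: does a person-level trait predict the slopes?

    One model per covariate, adding its main effect plus interactions with
    both event dummies; returns a table of the interaction estimates, SEs
    and p-values.  A constant covariate cannot moderate anything and raises
    :class:`~paskit.errors.UndefinedStatisticError`.
    """
    covs = list(covariates) if covariates is not None else [
        c for c in LEVEL2_COVARIATES if c in persons.columns
    ]
    if not covs:
        raise InputError("no level-2 covariates to scan")
    rows = []
    for c in covs:
        if persons[c].std(ddof=1) == 0 or persons[c].isna().all():
            raise UndefinedStatisticError(f"moderator {c!r} has no variance")
        single = persons[["person_id", c]]
        fit = fit_saturated(
            occasions,
            single,
            include_level2=True,
            reml=reml,
            extra_terms=[f"{c}:single_chat", f"{c}:group_chat"],
        )
        for dummy in ("single_chat", "group_chat"):
            term = f"{c}:{dummy}"
            if term not in fit.fixed.index:  # pragma: no cover
                continue
            r = fit.fixed.loc[term]
            rows.append(
                {
                    "moderator": c,
                    "dummy": dummy,
                    "estimate": r["estimate"],
                    "se": r["se"],
                    "pvalue": r["pvalue"],
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monte-Carlo power analysis for the two-level event design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceAssumptions:
    """Generative assumptions for the power simulation (residual SD = 1 scale).

    ``icc`` fixes the random-intercept variance via icc/(1-icc);
    ``slope_sd`` is the SD of the person-specific event effect;
    ``event_prob`` the per-occasion probability of an event (vs. baseline).
    The effect size passed to the power routines is the standardized mean
    event effect in residual-SD units (0.3 ~ a medium effect).
    """

    icc: float = 0.089
    slope_sd: float = 0.3
    event_prob: float = 0.5

    def intercept_sd(self) -> float:
        return float(np.sqrt(self.icc / (1.0 - self.icc)))


def estimate_power(
    n_persons: int,
    effect_size: float,
    *,
    alpha: float = 0.05,
    obs_per_person: int = 14,
    assumptions: VarianceAssumptions | None = None,
    n_sims: int = 400,
    rng=None,
) -> float:
    """Monte-Carlo rejection rate of the event effect at the given design.

    The test statistic is the one-sample t over person-specific mean event
    vs. baseline differences — an exact level-alpha test under this
    generative model, fast enough to vectorise over thousands of simulated
    studies.  Persons lacking both occasion types drop out of a replicate.
    """
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    if n_persons < 3 or obs_per_person < 2:
        raise InputError("need at least 3 persons and 2 occasions each")
    a = assumptions or VarianceAssumptions()
    rng = rng if rng is not None else np.random.default_rng(0)
    shape = (n_sims, n_persons, obs_per_person)
    x = rng.random(shape) < a.event_prob
    r0 = rng.standard_normal((n_sims, n_persons, 1)) * a.intercept_sd()
    r1 = rng.standard_normal((n_sims, n_persons, 1)) * a.slope_sd
    y = r0 + (effect_size + r1) * x + rng.standard_normal(shape)
    n1 = x.sum(axis=2)
    n0 = obs_per_person - n1
    ok = (n1 > 0) & (n0 > 0)
    m1 = np.where(x, y, 0.0).sum(axis=2) / np.maximum(n1, 1)
    m0 = np.where(~x, y, 0.0).sum(axis=2) / np.maximum(n0, 1)
    d = np.where(ok, m1 - m0, np.nan)
    k = ok.sum(axis=1)
    mean_d = np.nanmean(d, axis=1)
    sd_d = np.nanstd(d, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd_d / np.sqrt(k))
    crit = st.t.ppf(1 - alpha / 2, df=np.maximum(k - 1, 1))
    valid = k >= 3
    return float(np.mean(np.abs(t[valid]) > crit[valid]))


def power_min_n(
    effect_size: float,
    alpha: float = 0.05,
    obs_per_person: int = 14,
    power_target: float = 0.8,
    variance_assumptions: VarianceAssumptions | None = None,
    rng_seed: int = 0,
    *,
    n_min: int = 4,
    n_cap: int = 512,
    n_sims: int = 400,
) -> dict:
    """Smallest N whose Monte-Carlo power reaches ``power_target``.

    Doubles N from ``n_min`` until the target is met, then binary-searches
    the interval; each candidate N uses its own deterministic RNG stream
    derived from ``rng_seed``.  Raises
    :class:`~paskit.errors.EstimationError` if the target is unreachable
    below ``n_cap``.  Returns the chosen N together with every assumption
    that produced it.
    """
    if effect_size <= 0:
        raise InputError("effect_size must be > 0")
    a = variance_assumptions or VarianceAssumptions()

    def power_at(n: int) -> float:
        rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), int(n)]))
        return estimate_power(
            n, effect_size, alpha=alpha, obs_per_person=obs_per_person,
            assumptions=a, n_sims=n_sims, rng=rng,
        )

    lo, hi = n_min, n_min
    p = power_at(hi)
    while p < power_target:
        if hi >= n_cap:
            raise EstimationError(
                f"power target {power_target} unreachable below N={n_cap}",
                diagnostics={"power_at_cap": p},
            )
        lo, hi = hi, min(hi * 2, n_cap)
        p = power_at(hi)
    while lo < hi:  # invariant: power(hi) >= target, power(lo-ish) unknown/below
        mid = (lo + hi) // 2
        if mid == lo:
            break
        if power_at(mid) >= power_target:
            hi = mid
        else:
            lo = mid
    return {
        "min_n": int(hi),
        "power": power_at(hi),
        "effect_size": effect_size,
        "alpha": alpha,
        "obs_per_person": obs_per_person,
        "power_target": power_target,
        "assumptions": a,
        "n_sims": n_sims,
        "rng_seed": rng_seed,
    }
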