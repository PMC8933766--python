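"""The cohort statistics chain.

Welch two-sample tests, PCA with loading reports, a permutation PERMANOVA
on Euclidean distances, metabolite-behaviour linear regressions, and
collinearity-screened multiple regression with Bonferroni adjustment --
the sequence used to compare groups and relate neurochemistry to motor
performance and clinical covariates.

PERMANOVA is computed from the distance-partition definition (pseudo-F on
squared Euclidean distances, p-value by permuting factor labels with the
observed statistic included in the reference set). The univariate case
reduces exactly to classical one-way ANOVA, which the test suite uses as
an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "WelchResult",
    "PcaResult",
    "PermanovaResult",
    "RegressionResult",
    "welch_t",
    "run_pca",
    "permanova",
    "screen_collinearity",
    "fit_group_age_sex_model",
    "regress_behaviour",
    "adjust_bonferroni",
    "aic_univariate",
]


@dataclass
class WelchResult:
    statistic: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float


@dataclass
class PcaResult:
    scores: np.ndarray
    loadings: pd.DataFrame          # variables x components, orthonormal columns
    variance_explained: np.ndarray  # percent, non-increasing
    variables: list[str]
    scaled: bool

    def top_loadings(self, component: int = 0, n: int = 5) -> pd.DataFrame:
        """Variables most correlated with a component, by |loading|."""
        col = self.loadings.iloc[:, component]
        order = col.abs().sort_values(ascending=False).index[:n]
        return self.loadings.loc[order, [self.loadings.columns[component]]]


@dataclass
class PermanovaResult:
    pseudo_F: float
    permutation_p: float
    n_permutations: int
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int


@dataclass
class RegressionResult:
    terms: pd.DataFrame             # term, beta, se, t, p_raw, p_adj
    r_squared: float
    n: int
    retained: list[str] = field(default_factory=list)
    dropped: pd.DataFrame | None = None
    stratum_slopes: pd.DataFrame | None = None
    adjustment: str = "bonferroni"


def welch_t(sample_a, sample_b) -> WelchResult:
    """Unpaired t test with Welch's correction (Satterthwaite df)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each sample needs n >= 2, got {a.size} and {b.size}")
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        statistic=float(res.statistic), df=float(res.df), p_value=float(res.pvalue),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
    )


def run_pca(table: pd.DataFrame, variables: list[str], scale: bool = True) -> PcaResult:
    """PCA of the selected variables via SVD of the (scaled) centred data.

    ``scale=True`` (default) standardizes each variable to unit variance,
    i.e. a correlation-matrix PCA, appropriate when the metabolite panel
    mixes units and scales. Scores are the projections of each subject on
    the orthonormal loading vectors; variance explained is reported in
    percent, non-increasing.
    """
    if len(variables) < 2:
        raise ValueError("PCA needs at least 2 variables")
    X = table[list(variables)].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 subjects")
    if np.isnan(X).any():
        bad = [v for v in variables if table[v].isna().any()]
        raise ValueError(f"missing values in {bad}; filter or impute explicitly before PCA")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            zero = [v for v, s in zip(variables, sd) if s == 0]
            raise ValueError(f"zero-variance variables cannot be scaled: {zero}")
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    eigvals = S**2 / (X.shape[0] - 1)
    var_pct = 100.0 * eigvals / eigvals.sum()
    comps = [f"PC{k + 1}" for k in range(Vt.shape[0])]
    loadings = pd.DataFrame(Vt.T, index=list(variables), columns=comps)
    return PcaResult(
        scores=Xc @ Vt.T, loadings=loadings, variance_explained=var_pct,
        variables=list(variables), scaled=scale,
    )


def permanova(
    table: pd.DataFrame,
    response_variables: list[str],
    factor: str,
    n_permutations: int = 9999,
    seed: int = 0,
    scale: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances of the response variables.

    The pseudo-F statistic partitions the total sum of squared distances
    into between- and within-group components; the p-value is the fraction
    of label permutations (observed statistic included) whose statistic is
    at least as large as the observed one.
    """
    sub = table[[factor, *response_variables]].dropna()
    Y = sub[list(response_variables)].to_numpy(dtype=float)
    labels, counts = np.unique(sub[factor].to_numpy(), return_counts=True)
    if labels.size < 2 or counts.min() < 2:
        raise ValueError("factor needs >= 2 levels with >= 2 subjects each")
    if scale:
        sd = Y.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance response cannot be scaled")
        Y = (Y - Y.mean(axis=0)) / sd
    n = Y.shape[0]
    a = labels.size
    sq = ((Y[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)  # squared distances
    if not np.any(sq > 0):
        raise ValueError("all responses are constant; distances are degenerate")
    ss_total = sq.sum() / (2 * n)

    codes = np.searchsorted(labels, sub[factor].to_numpy())

    def ss_within_of(perm_codes: np.ndarray) -> float:
        ssw = 0.0
        for g in range(a):
            idx = np.flatnonzero(perm_codes == g)
            ssw += sq[np.ix_(idx, idx)].sum() / (2 * idx.size)
        return ssw

    def f_of(perm_codes: np.ndarray) -> float:
        ssw = ss_within_of(perm_codes)
        ssb = ss_total - ssw
        return (ssb / (a - 1)) / (ssw / (n - a))

    f_obs = f_of(codes)
    rng = np.random.default_rng(seed)
    hits = 1  # the observed statistic belongs to the reference set
    for _ in range(n_permutations):
        if f_of(rng.permutation(codes)) >= f_obs:
            hits += 1
    ssw = ss_within_of(codes)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        permutation_p=hits / (n_permutations + 1),
        n_permutations=n_permutations,
        ss_between=float(ss_total - ssw),
        ss_within=float(ssw),
        ss_total=float(ss_total),
        df_between=a - 1,
        df_within=n - a,
    )


def aic_univariate(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """AIC and slope p-value of the univariate Gaussian regression y ~ x.

    AIC is ``n * log(RSS / n) + 2k`` with k = 2 (intercept and slope).
    """
    n = x.size
    res = sps.linregress(x, y)
    rss = float(np.sum((y - (res.intercept + res.slope * x)) ** 2))
    aic = n * np.log(rss / n) + 2 * 2
    return float(aic), float(res.pvalue)


def screen_collinearity(
    table: pd.DataFrame,
    candidates: list[str],
    outcome: str,
    r_threshold: float = 0.7,
) -> tuple[list[str], pd.DataFrame]:
    """Resolve collinear predictor pairs before multiple regression.

    For every candidate pair with |r| above the threshold, only the member
    whose univariate model on the outcome has the lower AIC is kept (ties
    broken by lower p-value, then by name order). Returns the retained
    variables and a drop log recording r, both AICs and p-values, and
    whether the AIC and p-value preferences disagreed.
    """
    if len(candidates) < 2:
        raise ValueError("screening needs >= 2 candidate variables")
    sub = table[[outcome, *candidates]].dropna()
    uni: dict[str, tuple[float, float]] = {}
    for v in candidates:
        x = sub[v].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"candidate {v!r} has zero variance")
        uni[v] = aic_univariate(x, sub[outcome].to_numpy(dtype=float))

    retained = sorted(candidates)
    log_rows = []
    for i, vi in enumerate(sorted(candidates)):
        for vj in sorted(candidates)[i + 1:]:
            if vi not in retained or vj not in retained:
                continue
            r = float(np.corrcoef(sub[vi], sub[vj])[0, 1])
            if abs(r) <= r_threshold:
                continue
            (aic_i, p_i), (aic_j, p_j) = uni[vi], uni[vj]
            if aic_i != aic_j:
                drop = vj if aic_i < aic_j else vi
            elif p_i != p_j:
                drop = vj if p_i < p_j else vi
            else:
                drop = vj  # alphabetical tie-break: later name dropped
            conflict = (aic_i < aic_j) != (p_i < p_j) and p_i != p_j
            retained.remove(drop)
            kept = vi if drop == vj else vj
            log_rows.append({
                "kept": kept, "dropped": drop, "r": r,
                "aic_kept": uni[kept][0], "aic_dropped": uni[drop][0],
                "p_kept": uni[kept][1], "p_dropped": uni[drop][1],
                "aic_p_conflict": bool(conflict),
            })
    drop_log = pd.DataFrame(
        log_rows,
        columns=["kept", "dropped", "r", "aic_kept", "aic_dropped", "p_kept", "p_dropped", "aic_p_conflict"],
    )
    return retained, drop_log


def _design(df: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = {"const": np.ones(len(df))}
    g = (df["group"] == "MJD").to_numpy(float)
    s = (df["sex"] == "M").to_numpy(float)
    age = df["_age"].to_numpy(float)
    base = {"group": g, "age": age, "sex": s,
            "group:age": g * age, "group:sex": g * s, "age:sex": age * s,
            "group:age:sex": g * age * s}
    for t in terms:
        cols[t] = base[t]
    return np.column_stack(list(cols.values()))


_HIERARCHY = {
    "group:age": {"group:age:sex"},
    "group:sex": {"group:age:sex"},
    "age:sex": {"group:age:sex"},
    "age": {"group:age", "age:sex", "group:age:sex"},
    "sex": {"group:sex", "age:sex", "group:age:sex"},
    "group:age:sex": set(),
}


def fit_group_age_sex_model(
    table: pd.DataFrame,
    outcome: str,
    alpha: float = 0.05,
) -> RegressionResult:
    """Multiple regression of an outcome on group, age, sex and interactions.

    Starts from the full factorial ``outcome ~ group * age * sex`` and
    removes non-significant covariate terms backward, one at a time (the
    least significant removable term first, respecting marginality: a term
    is only removable while no retained higher-order interaction contains
    it). The group effect is always retained. Bonferroni adjustment is
    applied across the non-intercept terms of the final model, and
    per-stratum age slopes (per group, split by sex when a sex-age
    interaction survives) are reported as linear contrasts of the final
    coefficients.
    """
    cols = ["group", "sex", outcome]
    age_col = "age_years" if "age_years" in table.columns else "age_months"
    sub = table[cols + [age_col]].dropna().rename(columns={age_col: "_age"})
    n = len(sub)
    if n < 10:
        raise ValueError(f"need >= 10 subjects with complete data, got {n}")

    terms = ["group", "age", "sex", "group:age", "group:sex", "age:sex", "group:age:sex"]
    while True:
        X = _design(sub, terms)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                "rank-deficient design: a factor level or interaction is empty "
                f"(terms {terms}, n = {n}); check group/sex balance"
            )
        fit = sm.OLS(sub[outcome].to_numpy(float), X).fit()
        pvals = dict(zip(["const"] + terms, fit.pvalues))
        removable = [
            t for t in terms
            if t != "group" and not (_HIERARCHY.get(t, set()) & set(terms))
        ]
        worst = max(removable, key=lambda t: pvals[t], default=None)
        if worst is None or pvals[worst] <= alpha:
            break
        terms.remove(worst)

    names = ["const"] + terms
    p_raw = np.asarray(fit.pvalues)
    m = len(terms)  # tested terms (intercept not counted)
    p_adj = np.concatenate([[p_raw[0]], adjust_bonferroni(p_raw[1:], m)])
    term_table = pd.DataFrame({
        "term": names, "beta": fit.params, "se": fit.bse,
        "t": fit.tvalues, "p_raw": p_raw, "p_adj": p_adj,
    })

    strata = None
    if "age" in terms or "group:age" in terms:
        V = fit.cov_params()
        rows = []
        sex_split = bool({"age:sex", "group:age:sex"} & set(terms))
        for grp_name, g in (("control", 0.0), ("MJD", 1.0)):
            # the marginal (sex-averaged) slope plus per-sex slopes when a
            # sex-age interaction survived the retention rule
            in_grp = (sub["group"] == "MJD") == bool(g)
            s_bar = float((sub.loc[in_grp, "sex"] == "M").mean())
            levels = [("all", s_bar)] + ([("M", 1.0), ("F", 0.0)] if sex_split else [])
            for sex_name, s in levels:
                c = np.zeros(len(names))
                for k, t in enumerate(names):
                    if t == "age":
                        c[k] = 1.0
                    elif t == "group:age":
                        c[k] = g
                    elif t == "age:sex":
                        c[k] = s
                    elif t == "group:age:sex":
                        c[k] = g * s
                beta = float(c @ fit.params)
                se = float(np.sqrt(c @ V @ c))
                tval = beta / se
                p = 2 * sps.t.sf(abs(tval), fit.df_resid)
                rows.append({"group": grp_name, "sex": sex_name, "age_slope": beta,
                             "se": se, "t": tval, "p": p})
        strata = pd.DataFrame(rows)

    return RegressionResult(
        terms=term_table, r_squared=float(fit.rsquared), n=n,
        retained=terms, stratum_slopes=strata,
    )


def regress_behaviour(table: pd.DataFrame, metabolite: str, behaviour: str) -> RegressionResult:
    """Ordinary least squares of a behavioural score on a metabolite level."""
    sub = table[[metabolite, behaviour]].dropna()
    if len(sub) < 3:
        raise ValueError(f"need >= 3 paired observations, got {len(sub)}")
    x = sub[metabolite].to_numpy(float)
    y = sub[behaviour].to_numpy(float)
    if np.std(x) == 0:
        raise ValueError(f"predictor {metabolite!r} has zero variance")
    res = sps.linregress(x, y)
    terms = pd.DataFrame({
        "term": ["const", metabolite],
        "beta": [res.intercept, res.slope],
        "se": [res.intercept_stderr, res.stderr],
        "t": [res.intercept / res.intercept_stderr if res.intercept_stderr else np.nan,
              res.slope / res.stderr if res.stderr else np.inf],
        "p_raw": [np.nan, res.pvalue],
        "p_adj": [np.nan, res.pvalue],
    })
    return RegressionResult(terms=terms, r_squared=float(res.rvalue**2), n=len(sub),
                            retained=[metabolite], adjustment="none")


def adjust_bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p * m clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(p * m, 1.0)
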