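"""The study's statistical battery over cohort tables.

Four operations: omnibus group comparison with a normality gate and
post-hoc tests, covariate-adjusted partial Spearman correlation, the
longitudinal group-by-time mixed model, and product-of-coefficients
mediation with a percentile bootstrap.

Every operation is complete-case over its own variables, mirroring the
per-analysis Ns of observational cohort studies, and bit-reproducible
given (data, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .errors import ModelError, ValidationError


def _sex_numeric(values: pd.Series | np.ndarray) -> np.ndarray:
    """Map F/M labels to 0/1; numeric input passes through."""
    arr = np.asarray(values)
    if arr.dtype.kind in "OUS":
        mapping = {"F": 0.0, "M": 1.0}
        try:
            return np.array([mapping[str(v)] for v in arr])
        except KeyError as exc:
            raise ValidationError(f"unknown sex label {exc.args[0]!r}") from exc
    return arr.astype(float)


# ---------------------------------------------------------------------------
# group comparison


@dataclass
class GroupComparisonResult:
    test_name: str  # "anova" | "kruskal"
    statistic: float
    pvalue: float
    posthoc: pd.DataFrame  # columns: group1, group2, statistic, p_adjusted
    posthoc_name: str
    normality_p: dict[str, float] = dc_field(default_factory=dict)


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-sum z tests with tie correction, Holm-adjusted."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for g in labels:
        k = groups[g].size
        mean_rank[g] = float(ranks[start : start + k].mean())
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for g1, g2 in combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / groups[g1].size + 1.0 / groups[g2].size))
        z = (mean_rank[g1] - mean_rank[g2]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "statistic": float(z), "p_raw": p})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(table["p_raw"], method="holm")[1]
    return table


def _tukey_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    labels = list(groups)
    res = sps.tukey_hsd(*(groups[g] for g in labels))
    rows = []
    for i, j in combinations(range(len(labels)), 2):
        rows.append(
            {
                "group1": labels[i],
                "group2": labels[j],
                "statistic": float(res.statistic[i, j]),
                "p_raw": float(res.pvalue[i, j]),
                "p_adjusted": float(res.pvalue[i, j]),  # Tukey is already familywise
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    values: Sequence[float],
    labels: Sequence,
    normality_alpha: float = 0.05,
    force: str | None = None,
) -> GroupComparisonResult:
    """Omnibus comparison with a Shapiro-Wilk normality gate.

    If every group passes Shapiro-Wilk at ``normality_alpha``, one-way
    ANOVA with Tukey HSD post-hoc; otherwise Kruskal-Wallis with Dunn
    post-hoc (Holm-adjusted). ``force`` ("anova"/"kruskal") overrides the
    gate so either branch is computable on demand.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    keep = ~np.isnan(v)
    v, lab = v[keep], lab[keep]
    groups = {str(g): v[lab == g] for g in pd.unique(lab)}
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    for g, arr in groups.items():
        if arr.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 observations")

    normality_p = {
        g: (float(sps.shapiro(arr).pvalue) if arr.size >= 3 else 0.0)
        for g, arr in groups.items()
    }
    parametric = all(p > normality_alpha for p in normality_p.values())
    if force is not None:
        if force not in ("anova", "kruskal"):
            raise ValidationError(f"force must be 'anova' or 'kruskal', got {force!r}")
        parametric = force == "anova"

    if parametric:
        stat, p = sps.f_oneway(*groups.values())
        posthoc = _tukey_posthoc(groups)
        name, ph_name = "anova", "tukey_hsd"
    else:
        stat, p = sps.kruskal(*groups.values())
        posthoc = _dunn_posthoc(groups)
        name, ph_name = "kruskal", "dunn"
    return GroupComparisonResult(
        test_name=name,
        statistic=float(stat),
        pvalue=float(p),
        posthoc=posthoc,
        posthoc_name=ph_name,
        normality_p=normality_p,
    )


# ---------------------------------------------------------------------------
# partial Spearman


@dataclass
class PartialCorrelationResult:
    rho: float
    pvalue: float
    n_used: int
    covariates: tuple[str, ...]


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | pd.DataFrame | None = None,
    covariate_names: Sequence[str] = (),
) -> PartialCorrelationResult:
    """Partial Spearman correlation of x and y given covariates.

    All variables are rank-transformed (average ranks on ties), ranked x
    and y are residualized on the ranked covariates (plus intercept) by
    least squares, and rho is the Pearson correlation of the residuals.
    The p-value uses the t reference with n - 2 - k degrees of freedom.
    With no covariates this reduces exactly to ordinary Spearman rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((x.size, 0))
    else:
        if isinstance(covariates, pd.DataFrame):
            covariate_names = covariate_names or tuple(covariates.columns)
            cov = covariates.to_numpy(dtype=float)
        else:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
    keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(cov).any(axis=1))
    x, y, cov = x[keep], y[keep], cov[keep]
    n, k = x.size, cov.shape[1]
    if n < k + 4:
        raise ValidationError(f"need at least covariates+4 complete rows, have {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant x or y after listwise deletion")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rc = np.column_stack([sps.rankdata(c) for c in cov.T]) if k else np.empty((n, 0))
    X = np.column_stack([np.ones(n), rc])
    ex = rx - X @ np.linalg.lstsq(X, rx, rcond=None)[0]
    ey = ry - X @ np.linalg.lstsq(X, ry, rcond=None)[0]
    denom = np.sqrt((ex @ ex) * (ey @ ey))
    if denom == 0:
        raise ValidationError("degenerate residuals: correlation undefined")
    rho = float((ex @ ey) / denom)
    df = n - 2 - k
    rho_c = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrelationResult(
        rho=rho, pvalue=p, n_used=n, covariates=tuple(covariate_names)
    )


# ---------------------------------------------------------------------------
# longitudinal group x time model


@dataclass
class LongitudinalModelResult:
    coefficients: pd.DataFrame  # index: term; columns: estimate, se, pvalue
    interaction_beta: float  # PD_poor x time coefficient
    interaction_p: float
    n_subjects: int
    n_observations: int
    converged: bool

    def term(self, name: str) -> float:
        return float(self.coefficients.loc[name, "estimate"])


def fit_group_time_model(
    cohort: pd.DataFrame,
    outcome: str = "alps_mean",
    covariates: Sequence[str] = ("age", "sex"),
    reference_group: str = "HC",
    poor_group: str = "PD_poor",
) -> LongitudinalModelResult:
    """Linear mixed model: outcome ~ group * time + covariates + (1|subject).

    Time is the session coded 0, 1(, 2); estimation is restricted maximum
    likelihood. The reported beta is the ``poor_group`` x time interaction —
    the extra per-session change of the poor-outcome group relative to the
    reference. A classical repeated-measures ANOVA cross-check lives in
    :func:`rm_anova_crosscheck`.
    """
    cols = ["subject_id", "group", "session", outcome, *covariates]
    data = cohort[cols].dropna().copy()
    data["time"] = data["session"].astype(int) - 1
    if "sex" in covariates:
        data["sex"] = _sex_numeric(data["sex"])
    groups_present = data.groupby("time")["group"].unique()
    all_groups = set(data["group"])
    for t, present in groups_present.items():
        missing = all_groups - set(present)
        if missing:
            raise ModelError(
                f"singular design: group(s) {sorted(missing)} absent at time {t}"
            )
    if data.groupby("subject_id")["time"].nunique().max() < 2:
        raise ModelError("no subject has more than one session; time effect inestimable")

    cov_terms = " + ".join(covariates)
    formula = (
        f"{outcome} ~ C(group, Treatment('{reference_group}')) * time"
        + (f" + {cov_terms}" if cov_terms else "")
    )
    model = smf.mixedlm(formula, data, groups=data["subject_id"])
    with np.errstate(all="ignore"):
        try:
            fit = model.fit(reml=True, method="lbfgs")
        except Exception as exc:
            raise ModelError(f"mixed model failed: {exc}") from exc

    coef = pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "pvalue": fit.pvalues}
    ).drop(index=[i for i in fit.params.index if i == "Group Var"])
    inter = f"C(group, Treatment('{reference_group}'))[T.{poor_group}]:time"
    if inter not in coef.index:
        raise ModelError(f"interaction term {inter!r} missing from the design")
    return LongitudinalModelResult(
        coefficients=coef,
        interaction_beta=float(coef.loc[inter, "estimate"]),
        interaction_p=float(coef.loc[inter, "pvalue"]),
        n_subjects=int(data["subject_id"].nunique()),
        n_observations=len(data),
        converged=bool(fit.converged),
    )


def rm_anova_crosscheck(
    cohort: pd.DataFrame, outcome: str = "alps_mean"
) -> pd.DataFrame:
    """Classical two-way repeated-measures ANOVA (group x session) on
    balanced complete cases; returns the mixed-design ANOVA table.

    Subjects missing any session are dropped. Serves as a cross-check of
    the mixed model's interaction inference, not as the primary estimator.
    """
    data = cohort[["subject_id", "group", "session", outcome]].dropna().copy()
    n_sessions = data["session"].nunique()
    complete = data.groupby("subject_id")["session"].nunique() == n_sessions
    keep = complete[complete].index
    data = data[data["subject_id"].isin(keep)]
    wide = data.pivot(index="subject_id", columns="session", values=outcome)
    groups = data.groupby("subject_id")["group"].first().loc[wide.index]

    # mixed-design (split-plot) decomposition by hand: between = group,
    # within = session and group x session, subject nested in group
    y = wide.to_numpy()
    n_sub, n_ses = y.shape
    grand = y.mean()
    subj_mean = y.mean(axis=1)
    ses_mean = y.mean(axis=0)
    g_labels = groups.to_numpy()
    uniq = pd.unique(g_labels)
    cell = {
        (g, s): y[g_labels == g, s].mean() for g in uniq for s in range(n_ses)
    }
    g_mean = {g: y[g_labels == g].mean() for g in uniq}
    n_g = {g: int((g_labels == g).sum()) for g in uniq}

    ss_group = n_ses * sum(n_g[g] * (g_mean[g] - grand) ** 2 for g in uniq)
    ss_subj = n_ses * sum(
        (subj_mean[i] - g_mean[g_labels[i]]) ** 2 for i in range(n_sub)
    )
    ss_ses = n_sub * float(((ses_mean - grand) ** 2).sum())
    ss_inter = sum(
        n_g[g] * (cell[(g, s)] - g_mean[g] - ses_mean[s] + grand) ** 2
        for g in uniq
        for s in range(n_ses)
    )
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_group - ss_subj - ss_ses - ss_inter

    df_group = len(uniq) - 1
    df_subj = n_sub - len(uniq)
    df_ses = n_ses - 1
    df_inter = df_group * df_ses
    df_err = df_subj * df_ses
    rows = []
    for name, ss, df, err_ss, err_df in (
        ("group", ss_group, df_group, ss_subj, df_subj),
        ("session", ss_ses, df_ses, ss_err, df_err),
        ("group:session", ss_inter, df_inter, ss_err, df_err),
    ):
        ms, ms_err = ss / df, err_ss / err_df
        f = ms / ms_err
        rows.append(
            {
                "term": name,
                "F": float(f),
                "df1": df,
                "df2": err_df,
                "pvalue": float(sps.f.sf(f, df, err_df)),
            }
        )
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    total: float  # c : y ~ x
    direct: float  # c': y ~ x + m
    indirect: float  # a*b
    a: float
    b: float
    ci_total: tuple[float, float]
    ci_direct: tuple[float, float]
    ci_indirect: tuple[float, float]
    n_used: int
    n_boot: int
    seed: int


def _paths(x, m, y, cov) -> tuple[float, float, float, float]:
    one = np.ones_like(x)
    Xa = np.column_stack([one, x, cov])
    a = np.linalg.lstsq(Xa, m, rcond=None)[0][1]
    Xb = np.column_stack([one, x, m, cov])
    beta = np.linalg.lstsq(Xb, y, rcond=None)[0]
    cprime, b = beta[1], beta[2]
    c = np.linalg.lstsq(Xa, y, rcond=None)[0][1]
    return float(c), float(cprime), float(a), float(b)


def mediation(
    x: Sequence[float],
    m: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | pd.DataFrame | None = None,
    n_boot: int = 5000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationResult:
    """Linear product-of-coefficients mediation with percentile bootstrap.

    Paths: a from ``m ~ x + cov``; b and the direct effect c' from
    ``y ~ x + m + cov``; total effect c from ``y ~ x + cov``. The indirect
    effect is a*b, and c = c' + a*b holds exactly on the point estimates.
    Confidence intervals are percentile over ``n_boot`` seeded case
    resamples.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((x.size, 0))
    else:
        cov = (
            covariates.to_numpy(dtype=float)
            if isinstance(covariates, pd.DataFrame)
            else np.asarray(covariates, dtype=float)
        )
        if cov.ndim == 1:
            cov = cov[:, None]
    keep = ~(np.isnan(x) | np.isnan(m) | np.isnan(y) | np.isnan(cov).any(axis=1))
    x, m, y, cov = x[keep], m[keep], y[keep], cov[keep]
    n = x.size
    if n < 10:
        raise ValidationError(f"mediation needs >= 10 complete rows, have {n}")
    if np.ptp(m) == 0:
        raise ValidationError("zero-variance mediator")

    c, cprime, a, b = _paths(x, m, y, cov)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 3))  # c, c', a*b
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        ci_, cpi, ai, bi = _paths(x[idx], m[idx], y[idx], cov[idx])
        boots[i] = (ci_, cpi, ai * bi)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha], axis=0)
    return MediationResult(
        total=c,
        direct=cprime,
        indirect=a * b,
        a=a,
        b=b,
        ci_total=(float(lo[0]), float(hi[0])),
        ci_direct=(float(lo[1]), float(hi[1])),
        ci_indirect=(float(lo[2]), float(hi[2])),
        n_used=n,
        n_boot=n_boot,
        seed=seed,
    )


# kept importable for users who want the plain OLS tables behind the model
__all__ = [
    "GroupComparisonResult",
    "PartialCorrelationResult",
    "LongitudinalModelResult",
    "MediationResult",
    "compare_groups",
    "partial_spearman",
    "fit_group_time_model",
    "rm_anova_crosscheck",
    "mediation",
    "sm",
]
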