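"""Cohort statistics: repeated-measures ANOVA over the four WMH region
categories, Ryan's sequentially-rejective pairwise procedure, and log-link
generalized linear models of cognition on age + WMH + rCBF predictors.

The ANOVA is one-way within-subject: each of the n subjects contributes a
volume in each of the k = 4 region categories, F = MS_condition /
MS_(condition x subject) with df = (k-1, (k-1)(n-1)) — with n = 29 and
k = 4 this is the familiar F(3, 84).

Ryan's procedure orders the k condition means and tests the pair spanning
m ordered means at the adjusted level alpha'(m) = 2*alpha / (k*(m-1)),
rejecting a pair only if every encompassing (wider) pair was rejected.

The GLMs use a log link, so exponentiated coefficients are multiplicative
effects on the outcome mean (ratios), reported with Wald 95% CIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from ._exceptions import FitError, ValidationError

__all__ = [
    "AnovaResult",
    "PairwiseTable",
    "RegressionResult",
    "rm_anova",
    "ryan_pairwise",
    "ryan_adjusted_alpha",
    "fit_glm_log",
    "analyze_cohort",
    "CohortReport",
    "PREDICTOR_COLUMNS",
    "OUTCOME_COLUMNS",
]

PREDICTOR_COLUMNS = ["age", "pvh_a", "pvh_p", "dwmh_a", "dwmh_p",
                     "cbf_parietal", "cbf_temporal", "cbf_post_cingulate"]

# outcome column -> (pretty name, default family)
OUTCOME_COLUMNS = {
    "mmse": ("MMSE", "poisson"),
    "rcpm_score": ("RCPM (score)", "poisson"),
    "rcpm_time_s": ("RCPM (time, s)", "gamma"),
    "rbmt_sps": ("RBMT (SPS)", "poisson"),
    "rbmt_ss": ("RBMT (SS)", "poisson"),
    "tmt_a_s": ("TMT A (s)", "gamma"),
    "wf_category": ("WF (category, /min)", "poisson"),
    "wf_letter": ("WF (letter, /min)", "poisson"),
    "construction_cube": ("Construction (cube)", "poisson"),
    "construction_necker": ("Construction (Necker cube)", "poisson"),
}


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA summary."""

    F: float
    df1: int
    df2: int
    p: float
    condition_means: np.ndarray
    condition_names: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return (f"F({self.df1},{self.df2}) = {self.F:.3f}, "
                f"p = {self.p:.4f}")


@dataclass
class PairwiseTable:
    """All-pairs results of Ryan's sequentially-rejective procedure.

    ``table`` columns: cond_i, cond_j (original condition indices with
    mean_i <= mean_j), span, t, p_raw, alpha_adj, significant.
    """

    table: pd.DataFrame
    alpha: float
    k: int

    def significant_pairs(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


@dataclass
class RegressionResult:
    """Log-link GLM fit reported on the ratio scale.

    ``table`` columns: predictor, ratio (= exp(beta)), ci_low, ci_high, p.
    """

    response: str
    family: str
    link: str
    table: pd.DataFrame
    n_obs: int
    converged: bool

    def ratio(self, predictor: str) -> float:
        row = self.table.loc[self.table["predictor"] == predictor]
        if row.empty:
            raise KeyError(predictor)
        return float(row["ratio"].iloc[0])

    def summary(self) -> pd.DataFrame:
        out = self.table.copy()
        out["cell"] = [
            f"{r.ratio:.2f} ({r.ci_low:.2f}−{r.ci_high:.2f})"
            + _stars(r.p) for r in out.itertuples()]
        return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova(data: np.ndarray | pd.DataFrame,
             condition_names: list[str] | None = None) -> AnovaResult:
    """One-way within-subject ANOVA on an n x k matrix.

    Rows are subjects, columns the k within-subject conditions.
    F = MS_condition / MS_(condition x subject); df = (k-1, (k-1)(n-1)).
    Missing cells are a validation error (complete cases required).
    """
    if isinstance(data, pd.DataFrame):
        if condition_names is None:
            condition_names = list(map(str, data.columns))
        data = data.to_numpy(dtype=float)
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValidationError("data must be an n x k matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValidationError("need n >= 2 subjects and k >= 2 conditions")
    if np.isnan(x).any():
        raise ValidationError("missing cells: repeated-measures ANOVA "
                              "requires complete data")

    grand = x.mean()
    subj_means = x.mean(axis=1)
    cond_means = x.mean(axis=0)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        F = 0.0 if ms_cond <= 0 else np.inf
    else:
        F = ms_cond / ms_err
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    if condition_names is None:
        condition_names = [f"cond_{j}" for j in range(k)]
    return AnovaResult(float(F), df1, df2, p, cond_means,
                       list(condition_names))


# ---------------------------------------------------------------------------
# Ryan's sequentially-rejective pairwise procedure
# ---------------------------------------------------------------------------

def ryan_adjusted_alpha(alpha: float, k: int, span: int) -> float:
    """alpha'(m) = 2*alpha / (k*(m-1)) for a pair spanning m ordered means."""
    if span < 2 or span > k:
        raise ValidationError("span must be in [2, k]")
    return 2.0 * alpha / (k * (span - 1))


def _paired_t_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        return (0.0, 1.0) if np.allclose(d, 0) else (np.inf, 0.0)
    t = d.mean() / (sd / np.sqrt(n))
    return float(t), float(2.0 * sps.t.sf(abs(t), n - 1))


def ryan_pairwise(data: np.ndarray | pd.DataFrame, alpha: float = 0.05,
                  condition_names: list[str] | None = None) -> PairwiseTable:
    """All-pairs paired t-tests under Ryan's stepwise adjustment.

    Conditions are ordered by mean; the pair of ordered positions (a, b)
    spans m = b - a + 1 means and is significant iff its paired-t p-value
    is <= alpha'(m) = 2*alpha/(k*(m-1)) AND every encompassing pair
    (a' <= a, b' >= b, wider span) is significant.
    """
    if isinstance(data, pd.DataFrame):
        if condition_names is None:
            condition_names = list(map(str, data.columns))
        data = data.to_numpy(dtype=float)
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("need an n x k matrix with k >= 2")
    if np.isnan(x).any():
        raise ValidationError("missing cells not allowed")
    n, k = x.shape
    if condition_names is None:
        condition_names = [f"cond_{j}" for j in range(k)]

    order = np.argsort(x.mean(axis=0), kind="stable")  # ascending means
    rows = {}
    for a, b in combinations(range(k), 2):
        i, j = int(order[a]), int(order[b])
        span = b - a + 1
        t, p = _paired_t_p(x[:, j], x[:, i])
        rows[(a, b)] = {
            "cond_i": i, "cond_j": j,
            "name_i": condition_names[i], "name_j": condition_names[j],
            "span": span, "t": t, "p_raw": p,
            "alpha_adj": ryan_adjusted_alpha(alpha, k, span),
        }

    # sequential rejection, widest spans first
    sig: dict[tuple[int, int], bool] = {}
    for a, b in sorted(rows, key=lambda ab: ab[1] - ab[0], reverse=True):
        r = rows[(a, b)]
        own = r["p_raw"] <= r["alpha_adj"]
        gate = all(sig[(a2, b2)] for (a2, b2) in rows
                   if a2 <= a and b2 >= b and (b2 - a2) > (b - a))
        sig[(a, b)] = bool(own and gate)
        rows[(a, b)]["significant"] = sig[(a, b)]
    table = pd.DataFrame([rows[ab] for ab in sorted(rows)])
    return PairwiseTable(table, alpha, k)


# ---------------------------------------------------------------------------
# Log-link GLM
# ---------------------------------------------------------------------------

_FAMILIES = {
    "gamma": lambda: sm.families.Gamma(link=sm.families.links.Log()),
    "poisson": lambda: sm.families.Poisson(link=sm.families.links.Log()),
    "gaussian-log": lambda: sm.families.Gaussian(
        link=sm.families.links.Log()),
}


def fit_glm_log(response: pd.Series | np.ndarray,
                predictors: pd.DataFrame,
                family: str = "gamma",
                max_iter: int = 100) -> RegressionResult:
    """Multivariate GLM with log link; coefficients on the ratio scale.

    Fits by IRLS, returns exp(beta) with Wald 95% CIs
    exp(beta +- 1.96*SE) and two-sided Wald p-values per predictor
    (intercept included as 'intercept').  Rows with a missing response or
    predictor are dropped (complete case per response).
    """
    if family not in _FAMILIES:
        raise ValidationError(f"unknown family {family!r}")
    y = pd.Series(np.asarray(response, dtype=float)).reset_index(drop=True)
    X = predictors.reset_index(drop=True).astype(float)
    ok = y.notna() & X.notna().all(axis=1)
    y, X = y[ok], X.loc[ok]
    n, p = X.shape
    if n <= p + 1:
        raise ValidationError(f"n = {n} too small for {p} predictors")
    if family == "poisson":
        if (y < 0).any():
            raise ValidationError("counts must be >= 0")
    elif (y <= 0).any():
        raise ValidationError("response must be positive for a log link")

    design = sm.add_constant(X, prepend=True, has_constant="add")
    # scale-invariant collinearity check on correlation structure
    Xs = design.to_numpy()
    norms = np.linalg.norm(Xs, axis=0)
    if np.any(norms == 0) or \
            np.linalg.cond(Xs / norms) > 1e10:
        raise ValidationError("collinear design (condition number > 1e10)")

    model = sm.GLM(y.to_numpy(), design, family=_FAMILIES[family]())
    try:
        fit = model.fit(maxiter=max_iter)
    except Exception as exc:
        raise FitError(f"GLM fit failed: {exc}") from exc
    if not fit.converged:
        raise FitError(f"GLM did not converge in {max_iter} iterations")

    beta = fit.params
    se = fit.bse
    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    names = ["intercept"] + list(X.columns)
    table = pd.DataFrame({
        "predictor": names,
        "ratio": np.exp(beta),
        "ci_low": np.exp(beta - 1.96 * se),
        "ci_high": np.exp(beta + 1.96 * se),
        "p": pvals,
    })
    resp_name = response.name if isinstance(response, pd.Series) else "y"
    return RegressionResult(str(resp_name), family, "log", table, int(n),
                            bool(fit.converged))


# ---------------------------------------------------------------------------
# Cohort report (descriptives + region ANOVA + per-outcome GLMs)
# ---------------------------------------------------------------------------

@dataclass
class CohortReport:
    """The three report tables plus the underlying result objects."""

    table1: pd.DataFrame
    table2a: pd.DataFrame
    anova: AnovaResult
    pairwise: PairwiseTable
    table3: pd.DataFrame
    regressions: dict[str, RegressionResult]
    warnings: list[str] = field(default_factory=list)


REGION_CATEGORY_COLUMNS = ["pvh_a", "pvh_p", "dwmh_a", "dwmh_p"]


def derive_analysis_columns(records: pd.DataFrame) -> pd.DataFrame:
    """Add anterior/posterior predictor columns summed over hemispheres.

    pvh_a = pvh_ra + pvh_la, etc.  Columns already present are kept.
    """
    out = records.copy()
    for cls in ("pvh", "dwmh"):
        for ap in ("a", "p"):
            col = f"{cls}_{ap}"
            if col not in out.columns:
                out[col] = out[f"{cls}_r{ap}"] + out[f"{cls}_l{ap}"]
    return out


def analyze_cohort(records: pd.DataFrame,
                   alpha: float = 0.05,
                   families: dict[str, str] | None = None,
                   outcomes: list[str] | None = None) -> CohortReport:
    """Run the full statistical layer on a fused cohort table.

    Produces (i) a descriptive table of means/SD and prevalences,
    (ii) the four region-category volume means with the repeated-measures
    ANOVA and Ryan pairwise comparisons, and (iii) one ratio-scale GLM per
    cognitive outcome on age + WMH + rCBF predictors.  Outcomes with too
    few complete records are skipped with a warning.
    """
    if len(records) < 3:
        raise ValidationError("need at least 3 records")
    df = derive_analysis_columns(records)
    warns: list[str] = []

    # Table 1: descriptives
    rows1 = []
    for col in df.columns:
        if col == "subject_id":
            continue
        v = pd.to_numeric(df[col], errors="coerce")
        if v.notna().sum() == 0:
            continue
        vals = v.dropna()
        if set(vals.unique()) <= {0.0, 1.0}:
            rows1.append({"variable": col, "mean": np.nan, "sd": np.nan,
                          "prevalence_n": int(vals.sum()),
                          "prevalence_pct": 100.0 * vals.mean()})
        else:
            rows1.append({"variable": col, "mean": vals.mean(),
                          "sd": vals.std(ddof=1),
                          "prevalence_n": np.nan, "prevalence_pct": np.nan})
    table1 = pd.DataFrame(rows1)

    # Table 2a: region volumes + RM-ANOVA + Ryan
    mat = df[REGION_CATEGORY_COLUMNS].dropna()
    anova = rm_anova(mat, REGION_CATEGORY_COLUMNS)
    pairwise = ryan_pairwise(mat, alpha, REGION_CATEGORY_COLUMNS)
    table2a = pd.DataFrame({
        "region": REGION_CATEGORY_COLUMNS,
        "mean_cc": mat.mean(axis=0).to_numpy(),
        "sd_cc": mat.std(axis=0, ddof=1).to_numpy(),
    })

    # Table 3: per-outcome GLMs
    if outcomes is None:
        outcomes = [c for c in OUTCOME_COLUMNS if c in df.columns]
    families = families or {}
    regressions: dict[str, RegressionResult] = {}
    cells = {}
    for out in outcomes:
        fam = families.get(out, OUTCOME_COLUMNS.get(out, (out, "gamma"))[1])
        try:
            res = fit_glm_log(df[out].rename(out), df[PREDICTOR_COLUMNS],
                              family=fam)
        except (ValidationError, FitError) as exc:
            warns.append(f"{out}: skipped ({exc})")
            continue
        regressions[out] = res
        cells[out] = {r.predictor: f"{r.ratio:.2f} "
                      f"({r.ci_low:.2f}−{r.ci_high:.2f}){_stars(r.p)}"
                      for r in res.table.itertuples()}
    table3 = pd.DataFrame(cells).reindex(
        ["intercept"] + PREDICTOR_COLUMNS)
    table3.index.name = "predictor"
    return CohortReport(table1, table2a, anova, pairwise, table3,
                        regressions, warns)
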