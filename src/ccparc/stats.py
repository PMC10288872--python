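"""Group-comparison statistics.

Linear models of callosal / cortical parcel areas with diagnosis, sex,
age and total cortical surface as covariates; eta-squared effect sizes;
Benjamini-Hochberg FDR; and the descriptive two-group tests (Welch t,
Yates-corrected chi-squared, Fisher exact).

Conventions, fixed package-wide:

* the diagnosis coefficient is tested one-tailed (lower: a deficit),
  all other coefficients two-tailed;
* eta-squared is the single-df type-III sum of squares of the diagnosis
  term over the total sum of squares, equivalently t^2 (1 - R^2) / df;
* two-sample t-tests are Welch (unpooled) with Welch-Satterthwaite df;
* the 2x2 chi-squared applies the Yates continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .formats_io import GROUPS, PARCEL_NAMES, SURFACES, ccps_column, cxps_column

DEFAULT_AFFECTED = frozenset({"FAS", "NS-FASD"})


@dataclass
class ModelFit:
    """An OLS fit of one of the three group models."""

    model: int
    surface: str
    response: str
    n: int
    df_resid: int
    coef: dict[str, float]
    se: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]          # DIAG one-tailed lower; others two-tailed
    eta2_diag: float
    r2: float

    @property
    def p_diag(self) -> float:
        return self.p["DIAG"]


@dataclass
class TestResult:
    statistic: float
    df: float | tuple[float, float] | None
    p: float
    q: float | None = None


def _design(df: pd.DataFrame, model: int, surface: str,
            affected_groups: frozenset[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    unknown = set(affected_groups) - set(GROUPS)
    if unknown:
        raise ValidationError(f"unknown affected groups: {sorted(unknown)}")
    sub = df[df["group"].isin({"control"} | set(affected_groups))]
    diag = sub["group"].isin(affected_groups).astype(float).to_numpy()
    if diag.sum() < 2 or (1 - diag).sum() < 2:
        raise ValidationError("need >= 2 subjects per diagnosis level")
    cols = ["DIAG", "SEX", "AGE", "TCxS"]
    X = [diag, sub["sex"].to_numpy(float), sub["age_years"].to_numpy(float),
         sub["tcxs_cm2"].to_numpy(float)]
    if model == 1 or model == 3:
        y = sub[ccps_column(surface)].to_numpy(float)
        if model == 3:
            if surface == "total":
                raise ValidationError("model 3 is defined per parcel, not for total")
            pct = 100.0 * sub[cxps_column(surface)].to_numpy(float) \
                / sub["tcxs_cm2"].to_numpy(float)
            X.append(pct)
            cols.append("pctCxPS")
    elif model == 2:
        if surface == "total":
            raise ValidationError("model 2 is defined per parcel, not for total")
        y = 100.0 * sub[cxps_column(surface)].to_numpy(float) \
            / sub["tcxs_cm2"].to_numpy(float)
    else:
        raise ValidationError(f"model must be 1, 2 or 3, got {model}")
    X.append(np.ones(len(sub)))
    cols.append("const")
    return np.column_stack(X), y, cols


def ols(X: np.ndarray, y: np.ndarray, names: list[str]):
    """Plain OLS with coefficient standard errors; checks full rank."""
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # Name the offending columns via near-zero diagonal of R in a QR.
        r = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [names[i] for i in np.nonzero(r < 1e-8 * max(r.max(), 1.0))[0]]
        raise ValidationError(f"design matrix is rank deficient (columns: {bad})")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = n - k
    if df_resid <= 0:
        raise ValidationError("not enough observations for the model")
    mse = float(resid @ resid) / df_resid
    cov = mse * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return beta, se, resid, df_resid, mse


def fit_model(df: pd.DataFrame, model: int, surface: str,
              affected_groups: frozenset[str] | set[str] = DEFAULT_AFFECTED
              ) -> ModelFit:
    """Fit group model 1, 2 or 3 for one surface.

    Model 1: CcPS ~ DIAG + SEX + AGE + TCxS.
    Model 2: %CxPS ~ DIAG + SEX + AGE + TCxS.
    Model 3: CcPS ~ DIAG + SEX + AGE + TCxS + %CxPS (same parcel).
    """
    if surface not in SURFACES:
        raise ValidationError(f"unknown surface {surface!r}")
    X, y, names = _design(df, model, surface, frozenset(affected_groups))
    beta, se, resid, df_resid, mse = ols(X, y, names)
    tvals = beta / se
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValidationError("response has zero variance")
    p = {}
    for name, t in zip(names, tvals):
        if name == "DIAG":
            p[name] = float(sps.t.cdf(t, df_resid))          # one-tailed lower
        else:
            p[name] = float(2 * sps.t.sf(abs(t), df_resid))  # two-tailed
    r2 = 1.0 - float(resid @ resid) / sst
    i = names.index("DIAG")
    eta2 = float(tvals[i] ** 2) * mse / sst   # type-III single-df SS / SS_total
    response = {1: "CcPS", 2: "pctCxPS", 3: "CcPS"}[model]
    return ModelFit(
        model=model, surface=surface, response=response, n=len(y),
        df_resid=df_resid,
        coef={n_: float(b) for n_, b in zip(names, beta)},
        se={n_: float(s) for n_, s in zip(names, se)},
        t={n_: float(t) for n_, t in zip(names, tvals)},
        p=p, eta2_diag=min(max(eta2, 0.0), 1.0), r2=r2,
    )


def eta_squared(fit: ModelFit) -> float:
    """Diagnosis effect size: t^2 (1 - R^2) / df_resid."""
    return fit.eta2_diag


def diag_p_value(t: float, df: int) -> float:
    """Lower-tailed Student-t p-value of the diagnosis coefficient."""
    return float(sps.t.cdf(t, df))


# ---------------------------------------------------------------------------
# Multiple comparisons
# ---------------------------------------------------------------------------

def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    q(k) = min over k' >= k of p(k') * m / k' on the ascending sort,
    clamped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be a 1D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Descriptive two-group tests
# ---------------------------------------------------------------------------

def welch_t_summary(mean1: float, sd1: float, n1: int,
                    mean2: float, sd2: float, n2: int) -> TestResult:
    """Welch two-sample t-test from summary statistics, two-tailed."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("standard deviations must be > 0")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = float(2 * sps.t.sf(abs(t), df))
    return TestResult(statistic=float(t), df=float(df), p=p)


def welch_t(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Welch two-sample t-test on raw vectors, two-tailed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return welch_t_summary(x.mean(), x.std(ddof=1), len(x),
                           y.mean(), y.std(ddof=1), len(y))


def yates_chi2(a: int, b: int, c: int, d: int) -> TestResult:
    """Continuity-corrected chi-squared test of a 2x2 table [[a,b],[c,d]]."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValidationError("table entries must be nonnegative integers")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValidationError("all table margins must be > 0")
    x2 = n * max(abs(a * d - b * c) - n / 2, 0.0) ** 2 / np.prod(
        [float(m) for m in margins]
    )
    return TestResult(statistic=float(x2), df=1.0, p=float(sps.chi2.sf(x2, 1)))


def fisher_exact(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test of a 2x2 table [[a,b],[c,d]].

    Sums hypergeometric point probabilities no larger than the observed
    table's, margins fixed.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValidationError("table entries must be nonnegative integers")
    stat, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult(statistic=float(stat), df=None, p=float(p))


def compare_groups_raw(df: pd.DataFrame, surfaces: list[str] | None = None,
                       affected_groups: frozenset[str] | set[str] = DEFAULT_AFFECTED,
                       use_cxps: bool = False) -> pd.DataFrame:
    """Per-surface Welch t-tests on raw areas, BH-corrected across surfaces."""
    surfaces = list(surfaces) if surfaces is not None else list(SURFACES)
    is_ctrl = df["group"] == "control"
    is_pat = df["group"].isin(set(affected_groups))
    if not is_ctrl.any() or not is_pat.any():
        raise ValidationError("both control and affected subjects are required")
    rows = []
    for s in surfaces:
        col = cxps_column(s) if use_cxps and s != "total" else ccps_column(s)
        res = welch_t(df.loc[is_ctrl, col], df.loc[is_pat, col])
        rows.append({"surface": s, "t": res.statistic, "df": res.df, "p": res.p})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def model_table(df: pd.DataFrame,
                affected_groups: frozenset[str] | set[str] = DEFAULT_AFFECTED
                ) -> pd.DataFrame:
    """Fit all three models over all surfaces; BH within each model column.

    Model 1 spans total + 7 parcels; models 2 and 3 span the 7 parcels.
    """
    rows = []
    for model in (1, 2, 3):
        surfaces = list(SURFACES) if model == 1 else list(PARCEL_NAMES)
        fits = [fit_model(df, model, s, affected_groups) for s in surfaces]
        q = bh_fdr(np.array([f.p_diag for f in fits]))
        for f, qv in zip(fits, q):
            row = {"model": model, "surface": f.surface, "response": f.response,
                   "n": f.n, "df_resid": f.df_resid, "eta2_pct": 100 * f.eta2_diag,
                   "t_diag": f.t["DIAG"], "p_diag": f.p_diag, "q_diag": float(qv),
                   "r2": f.r2}
            for name, b in f.coef.items():
                row[f"b_{name}"] = b
            rows.append(row)
    return pd.DataFrame(rows)
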