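"""Association-analysis chain for mobility outcomes and multi-domain covariates.

Stage order (``run_association_analysis``):

1. square-root transform of the spatial outcomes,
2. normality screening (Lilliefors-corrected Kolmogorov–Smirnov, α=0.10),
3. Tukey fence outlier filtering (flagged cells set to missing),
4. Little's MCAR test on the missingness pattern,
5. column-mean imputation,
6. Spearman rank correlation screening (α=0.05),
7. per-outcome stepwise multiple regression (p-to-enter 0.05,
   p-to-remove 0.10) with standardized coefficients, adjusted R²,
   variance-inflation factors and a Shapiro–Wilk residual check.

The stepwise selector and Little's test are implemented here; standard
distributions and the Shapiro–Wilk / Lilliefors statistics come from
scipy/statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

DEFAULT_SQRT_COLUMNS = ("life_space_area_km2", "path_distance_km", "action_range_km")


class InsufficientDataError(ValueError):
    """Raised when a statistic is requested on too few observations."""


@dataclass
class AnalysisConfig:
    """Thresholds and switches for the association chain."""

    alpha: float = 0.05
    alpha_ks: float = 0.10
    p_enter: float = 0.05
    p_remove: float = 0.10
    tukey_k: float = 1.5
    sqrt_columns: tuple[str, ...] = DEFAULT_SQRT_COLUMNS
    outlier_mode: str = "cell"          # "cell": value→missing; "case": drop row
    ks_lilliefors: bool = True
    bh_correction: bool = False         # off by default: mirrors uncorrected screening

    def __post_init__(self) -> None:
        if not (0 < self.p_enter <= self.p_remove < 1):
            raise ValueError("require 0 < p_enter <= p_remove < 1")
        if self.tukey_k <= 0:
            raise ValueError("tukey_k must be positive")
        if self.outlier_mode not in ("cell", "case"):
            raise ValueError(f"unknown outlier_mode {self.outlier_mode!r}")


@dataclass
class StepwiseResult:
    """Final stepwise model for one outcome."""

    outcome: str
    predictors: list[str]
    std_betas: dict[str, float]
    pvalues: dict[str, float]
    adj_r2: float
    r2: float
    n: int
    max_vif: float
    shapiro_p: float
    trace: list[tuple[str, str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictors": list(self.predictors),
            "std_betas": dict(self.std_betas),
            "pvalues": dict(self.pvalues),
            "adj_r2": self.adj_r2,
            "r2": self.r2,
            "n": self.n,
            "max_vif": self.max_vif,
            "shapiro_p": self.shapiro_p,
            "trace": [list(t) for t in self.trace],
        }


# ---------------------------------------------------------------------------
# elementwise transforms & filters
# ---------------------------------------------------------------------------

def sqrt_transform(column: pd.Series) -> pd.Series:
    """Element-wise square root; missing propagates; negatives are errors."""
    bad = column.dropna() < 0
    if bad.any():
        raise ValueError(
            f"negative value in column {column.name!r} at rows "
            f"{list(bad[bad].index[:5])}"
        )
    return np.sqrt(column)


def ks_normality(column: pd.Series, alpha: float = 0.10,
                 lilliefors: bool = True) -> tuple[float, float, bool]:
    """Kolmogorov–Smirnov normality check with estimated mean/sd.

    Uses the Lilliefors small-sample correction by default (parameters are
    estimated from the data).  Returns ``(statistic, p, passed)``; a
    zero-variance column is reported as a failure with p=0.
    """
    x = np.asarray(column.dropna(), dtype=float)
    if x.size < 5:
        raise InsufficientDataError("KS normality needs >= 5 non-missing values")
    if np.std(x) == 0:
        return float("nan"), 0.0, False
    if lilliefors:
        stat, p = _lilliefors(x, dist="norm")
    else:
        stat, p = stats.kstest(x, "norm", args=(np.mean(x), np.std(x, ddof=1)))
    return float(stat), float(p), bool(p > alpha)


def tukey_fences(values: np.ndarray, k: float = 1.5) -> tuple[float, float]:
    """Lower/upper Tukey fences with type-7 (linear interpolation) quartiles."""
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def tukey_outlier_filter(column: pd.Series, k: float = 1.5) -> pd.Series:
    """Boolean flags for values outside the Tukey fences (inclusive bounds).

    Missing cells are never flagged.
    """
    obs = column.dropna().astype(float)
    if obs.size < 4:
        raise InsufficientDataError("Tukey filter needs >= 4 non-missing values")
    lo, hi = tukey_fences(obs.to_numpy(), k)
    flags = (column < lo) | (column > hi)
    return flags.fillna(False)


def mean_impute(table: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing cell with its column's observed mean."""
    out = table.copy()
    for col in out.columns:
        if not pd.api.types.is_numeric_dtype(out[col]):
            continue
        if out[col].isna().all():
            raise ValueError(f"column {col!r} is fully missing; cannot impute")
        out[col] = out[col].fillna(out[col].mean())
    return out


# ---------------------------------------------------------------------------
# Little's MCAR test
# ---------------------------------------------------------------------------

def _em_mvnorm(y: np.ndarray, max_iter: int = 200, tol: float = 1e-7
               ) -> tuple[np.ndarray, np.ndarray]:
    """ML mean/covariance of a multivariate normal with missing values (EM)."""
    n, p = y.shape
    mu = np.nanmean(y, axis=0)
    # available-case covariance, regularised to be safely PD as a start
    resid = np.where(np.isnan(y), 0.0, y - mu)
    sigma = (resid.T @ resid) / n
    sigma[np.diag_indices_from(sigma)] = np.nanvar(y, axis=0) + 1e-8

    miss = np.isnan(y)
    pattern_ids = {}
    for i in range(n):
        pattern_ids.setdefault(miss[i].tobytes(), []).append(i)

    for _ in range(max_iter):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for key, rows in pattern_ids.items():
            m = np.frombuffer(key, dtype=bool)
            o = ~m
            yo = y[np.ix_(rows, o)]
            k = len(rows)
            if not m.any():
                s1[o] += yo.sum(axis=0)
                s2[np.ix_(o, o)] += yo.T @ yo
                continue
            soo = sigma[np.ix_(o, o)]
            smo = sigma[np.ix_(m, o)]
            smm = sigma[np.ix_(m, m)]
            coef = np.linalg.solve(soo, smo.T).T          # Σ_mo Σ_oo⁻¹
            ym = mu[m] + (yo - mu[o]) @ coef.T            # conditional means
            cond_cov = smm - coef @ smo.T
            s1[o] += yo.sum(axis=0)
            s1[m] += ym.sum(axis=0)
            s2[np.ix_(o, o)] += yo.T @ yo
            s2[np.ix_(o, m)] += yo.T @ ym
            s2[np.ix_(m, o)] += ym.T @ yo
            s2[np.ix_(m, m)] += ym.T @ ym + k * cond_cov
        mu_new = s1 / n
        sigma_new = s2 / n - np.outer(mu_new, mu_new)
        sigma_new = (sigma_new + sigma_new.T) / 2
        shift = max(np.max(np.abs(mu_new - mu)),
                    np.max(np.abs(sigma_new - sigma)))
        mu, sigma = mu_new, sigma_new
        if shift < tol:
            break
    return mu, sigma


def little_mcar_test(table: pd.DataFrame) -> tuple[float, int, float]:
    """Little's chi-square test of Missing-Completely-At-Random.

    The statistic sums, over missingness patterns j, the Mahalanobis
    distance n_j (ȳ_j − μ̂_j)' Σ̂_j⁻¹ (ȳ_j − μ̂_j) between the pattern's
    observed-variable means and the EM grand estimates; df = Σ_j p_j − p.

    Returns ``(statistic, df, p)``.  A table with a single missingness
    pattern (e.g. fully observed) degenerates to ``(0.0, 0, 1.0)``.
    """
    num = table.select_dtypes(include=[np.number])
    y = num.to_numpy(dtype=float)
    # drop rows with every value missing: they carry no pattern information
    y = y[~np.isnan(y).all(axis=1)]
    n, p = y.shape
    miss = np.isnan(y)
    patterns: dict[bytes, list[int]] = {}
    for i in range(n):
        patterns.setdefault(miss[i].tobytes(), []).append(i)
    if len(patterns) < 2:
        return 0.0, 0, 1.0
    if n <= p:
        raise InsufficientDataError("need more rows than variables for MCAR test")

    mu, sigma = _em_mvnorm(y)
    d2 = 0.0
    df = -p
    for key, rows in patterns.items():
        m = np.frombuffer(key, dtype=bool)
        o = ~m
        po = int(o.sum())
        if po == 0:
            continue
        df += po
        ybar = y[np.ix_(rows, o)].mean(axis=0)
        dev = ybar - mu[o]
        soo = sigma[np.ix_(o, o)]
        d2 += len(rows) * float(dev @ np.linalg.solve(soo, dev))
    if df <= 0:
        return 0.0, 0, 1.0
    return float(d2), int(df), float(stats.chi2.sf(d2, df))


# ---------------------------------------------------------------------------
# correlation screening
# ---------------------------------------------------------------------------

def spearman_rho_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (mid-ranks) with two-sided t-approximation p-value."""
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 5:
        raise InsufficientDataError("Spearman needs >= 5 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def spearman_matrix(predictors: pd.DataFrame, outcomes: pd.DataFrame
                    ) -> pd.DataFrame:
    """Pairwise Spearman correlations between predictors and outcomes.

    Returns a long-format frame with columns
    ``predictor, outcome, rho, p, n`` (rho/p are NaN for constant columns).
    """
    rows = []
    for pred in predictors.columns:
        for out in outcomes.columns:
            x = predictors[pred].to_numpy(dtype=float)
            y = outcomes[out].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            rho, p = spearman_rho_p(x, y)
            rows.append({"predictor": pred, "outcome": out,
                         "rho": rho, "p": p, "n": int(ok.sum())})
    return pd.DataFrame(rows)


def select_candidates(corr: pd.DataFrame, outcome: str,
                      alpha: float = 0.05) -> list[str]:
    """Predictors significantly correlated with ``outcome``, input order."""
    sub = corr[corr["outcome"] == outcome]
    return [r.predictor for r in sub.itertuples() if r.p < alpha]


# ---------------------------------------------------------------------------
# regression machinery
# ---------------------------------------------------------------------------

def _ols(y: np.ndarray, x: np.ndarray) -> dict:
    """Least squares with intercept; returns coefs, p-values, R², residuals."""
    n = y.size
    xd = np.column_stack([np.ones(n), x]) if x.size else np.ones((n, 1))
    k = xd.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(xd, y, rcond=None)
    resid = y - xd @ beta
    dof = n - k
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if dof > 0 and rank == k:
        sigma2 = rss / dof
        xtx_inv = np.linalg.inv(xd.T @ xd)
        se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = beta / se
        pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    else:
        se = np.full(k, np.nan)
        pvals = np.full(k, np.nan)
    return {"beta": beta, "se": se, "p": pvals, "r2": r2,
            "resid": resid, "dof": dof}


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 − (1 − R²)(n − 1)/(n − p − 1)."""
    if n <= p + 1:
        raise ValueError("adjusted R² undefined for n <= p + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def vif(x: np.ndarray) -> np.ndarray:
    """Variance inflation factor per column: 1/(1 − R²_k) regressing k on rest.

    Perfectly collinear columns report ``inf``.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if n <= p:
        raise ValueError("VIF needs more rows than predictors")
    out = np.empty(p)
    for k in range(p):
        others = np.delete(x, k, axis=1)
        r2 = _ols(x[:, k], others)["r2"]
        out[k] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def shapiro_wilk(residuals: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk statistic and p (AS R94 via scipy); 3 <= n <= 5000."""
    r = np.asarray(residuals, dtype=float)
    r = r[~np.isnan(r)]
    if r.size < 3:
        raise InsufficientDataError("Shapiro-Wilk needs n >= 3")
    if r.size > 5000:
        raise ValueError("Shapiro-Wilk p-value unreliable beyond n = 5000")
    stat, p = stats.shapiro(r)
    return float(stat), float(p)


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant column")
    return (a - a.mean()) / sd


def stepwise_regression(
    y: pd.Series,
    candidates: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    outcome_name: Optional[str] = None,
) -> StepwiseResult:
    """Forward-stepwise OLS with backward removal (SPSS-style thresholds).

    At each step the excluded candidate with the smallest partial-F p-value
    enters if it is below ``p_enter``; afterwards any included variable
    whose p-value exceeds ``p_remove`` is removed (worst first).  All
    variables (outcome included) are z-scored, so the reported coefficients
    are standardized betas.  The entry/removal trace is logged, and a
    variable removed straight after entering an otherwise unchanged model
    is barred from re-entry so termination is guaranteed.
    """
    names = list(candidates.columns)
    n = len(y)
    if n <= len(names) + 2:
        raise InsufficientDataError("need n > candidates + 2 for stepwise fit")
    yz = _zscore(y.to_numpy(dtype=float))
    xz = {c: _zscore(candidates[c].to_numpy(dtype=float)) for c in names}

    included: list[str] = []
    barred: set[str] = set()
    trace: list[tuple[str, str, float]] = []

    def model_matrix(cols: Sequence[str]) -> np.ndarray:
        return (np.column_stack([xz[c] for c in cols])
                if cols else np.empty((n, 0)))

    while True:
        changed = False
        # --- entry step
        best_name, best_p = None, np.inf
        for cand in names:
            if cand in included or cand in barred:
                continue
            fit = _ols(yz, model_matrix(included + [cand]))
            pval = fit["p"][-1]
            if np.isnan(pval):
                continue
            if pval < best_p:
                best_name, best_p = cand, pval
        entered = None
        if best_name is not None and best_p < p_enter:
            included.append(best_name)
            trace.append(("enter", best_name, float(best_p)))
            entered = best_name
            changed = True
        # --- removal sweep
        while len(included) > 0:
            fit = _ols(yz, model_matrix(included))
            pvals = fit["p"][1:]
            worst = int(np.nanargmax(pvals))
            if pvals[worst] > p_remove:
                victim = included.pop(worst)
                trace.append(("remove", victim, float(pvals[worst])))
                if victim == entered:
                    barred.add(victim)   # cycle guard
                changed = True
            else:
                break
        if not changed:
            break

    fit = _ols(yz, model_matrix(included))
    p_model = len(included)
    betas = {c: float(b) for c, b in zip(included, fit["beta"][1:])}
    pvals = {c: float(v) for c, v in zip(included, fit["p"][1:])}
    max_vif = float(np.max(vif(model_matrix(included)))) if p_model >= 2 else 1.0
    try:
        _, sw_p = shapiro_wilk(fit["resid"])
    except (InsufficientDataError, ValueError):
        sw_p = float("nan")
    return StepwiseResult(
        outcome=outcome_name or (y.name or "y"),
        predictors=list(included),
        std_betas=betas,
        pvalues=pvals,
        adj_r2=adjusted_r2(fit["r2"], n, p_model) if n > p_model + 1 else float("nan"),
        r2=fit["r2"],
        n=n,
        max_vif=max_vif,
        shapiro_p=sw_p,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_association_analysis(
    table: pd.DataFrame,
    outcome_columns: Sequence[str],
    predictor_columns: Sequence[str],
    config: Optional[AnalysisConfig] = None,
) -> dict:
    """Run the full chain on a participants × (outcomes + covariates) table.

    Returns a structured report dict with keys ``config``, ``normality``,
    ``outliers``, ``mcar``, ``correlations`` and ``models``.  A failure in
    one outcome's model is recorded under that outcome without halting the
    others.
    """
    cfg = config or AnalysisConfig()
    work = table[list(outcome_columns) + list(predictor_columns)].astype(float).copy()

    for col in cfg.sqrt_columns:
        if col in work.columns:
            work[col] = sqrt_transform(work[col])

    normality = {}
    for col in work.columns:
        try:
            stat, p, ok = ks_normality(work[col], cfg.alpha_ks, cfg.ks_lilliefors)
            normality[col] = {"statistic": stat, "p": p, "normal": ok}
        except InsufficientDataError:
            normality[col] = {"statistic": None, "p": None, "normal": None}

    n_flagged = 0
    dropped_rows: set = set()
    for col in work.columns:
        try:
            flags = tukey_outlier_filter(work[col], cfg.tukey_k)
        except InsufficientDataError:
            continue
        n_flagged += int(flags.sum())
        if cfg.outlier_mode == "cell":
            work.loc[flags, col] = np.nan
        else:
            dropped_rows.update(work.index[flags])
    if cfg.outlier_mode == "case" and dropped_rows:
        work = work.drop(index=list(dropped_rows))
    outlier_rate = n_flagged / float(work.size) if work.size else 0.0

    try:
        mcar_stat, mcar_df, mcar_p = little_mcar_test(work)
    except (InsufficientDataError, np.linalg.LinAlgError):
        mcar_stat, mcar_df, mcar_p = float("nan"), 0, float("nan")
    imputed = mean_impute(work)

    corr = spearman_matrix(imputed[list(predictor_columns)],
                           imputed[list(outcome_columns)])
    if cfg.bh_correction:
        corr = corr.assign(p=_benjamini_hochberg(corr["p"].to_numpy()))

    models: dict[str, dict] = {}
    for out in outcome_columns:
        cand = select_candidates(corr, out, cfg.alpha)
        if not cand:
            models[out] = {"note": "no candidates", "predictors": []}
            continue
        try:
            res = stepwise_regression(imputed[out], imputed[cand],
                                      cfg.p_enter, cfg.p_remove, outcome_name=out)
            models[out] = res.to_dict()
        except (InsufficientDataError, ValueError) as exc:
            models[out] = {"error": f"stepwise regression failed: {exc}",
                           "predictors": []}

    return {
        "config": {
            "alpha": cfg.alpha, "alpha_ks": cfg.alpha_ks,
            "p_enter": cfg.p_enter, "p_remove": cfg.p_remove,
            "tukey_k": cfg.tukey_k, "sqrt_columns": list(cfg.sqrt_columns),
            "outlier_mode": cfg.outlier_mode,
            "ks_lilliefors": cfg.ks_lilliefors,
            "threshold_convention":
                "entry/removal limits applied to the probability of F",
        },
        "n": int(len(work)),
        "normality": normality,
        "outliers": {"n_flagged": n_flagged, "rate": outlier_rate,
                     "mode": cfg.outlier_mode},
        "mcar": {"statistic": mcar_stat, "df": mcar_df, "p": mcar_p},
        "correlations": corr.to_dict(orient="records"),
        "models": models,
    }


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional multiplicity control, off by default)."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    prev = 1.0
    for rank, idx in enumerate(order[::-1]):
        k = m - rank
        prev = min(prev, p[idx] * m / k)
        adj[idx] = prev
    return adj
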