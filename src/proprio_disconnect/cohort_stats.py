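"""Cohort-level statistics linking lesion metrics to APM Task Scores.

The battery comprises:

* an ANCOVA comparing Task Scores between left- and right-lesioned
  participants with lesion volume as covariate;
* a 2x2 Pearson chi-square of ipsilesional motor impairment x hemisphere;
* per-tract multivariate regressions of Task Score on tract lesion load,
  lesion side and grey-matter lesion volume (all variables standardised to
  zero mean, unit sample SD), with Benjamini-Hochberg FDR over the pooled
  family of coefficient tests (3 coefficients x tracts);
* a principal-component regression: PCA of the standardised predictor block
  (tract loads + grey-matter lesion volume), components retained up to 95%
  cumulative variance, their scores regressed on Task Score with FDR over
  the retained components.

Effect sizes are Cohen's f^2 = R^2 / (1 - R^2).  Sample (n-1) SDs are used
throughout so standardisation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "standardize",
    "ancova_side",
    "chi_square_2x2",
    "tract_regression",
    "tract_regression_battery",
    "bh_fdr",
    "pca_predictors",
    "pc_regression",
    "RegressionResult",
    "PCAResult",
    "PCRegressionResult",
    "cohens_f2",
]


class DegenerateDataError(ValueError):
    pass


def standardize(values) -> np.ndarray:
    """Zero mean, unit sample (n-1) SD."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("standardize expects a 1D array")
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateDataError("constant input cannot be standardized")
    return (x - x.mean()) / sd


def cohens_f2(r2: float) -> float:
    if not 0 <= r2 <= 1:
        raise ValueError("R^2 must be in [0, 1]")
    if r2 == 1.0:
        return float("inf")  # perfect fit
    return r2 / (1.0 - r2)


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS via statsmodels with exact small-sample t tests."""
    import statsmodels.api as sm

    n, p = X.shape
    if n <= p:
        raise DegenerateDataError("more parameters than observations")
    cond = np.linalg.cond(X.T @ X)
    if not np.isfinite(cond) or cond > 1e12:
        raise DegenerateDataError("rank-deficient (collinear) design")
    fit = sm.OLS(y, X).fit()
    return (
        np.asarray(fit.params),
        np.asarray(fit.bse),
        np.asarray(fit.tvalues),
        np.asarray(fit.pvalues),
        float(fit.rsquared),
        int(fit.df_resid),
    )


@dataclass
class AncovaResult:
    F: float
    p: float
    df_num: int
    df_den: int


def ancova_side(task_scores, lesion_side, lesion_volume) -> AncovaResult:
    """One-way ANCOVA of Task Score by lesion side, covarying lesion volume.

    ``lesion_side`` may be 0/1 codes or "left"/"right" labels (left=0,
    right=1).  The F statistic is the type-III (partial) test of side in
    ``score ~ side + volume``; with two levels it equals t^2.
    """
    y = np.asarray(task_scores, dtype=float)
    side = _side_codes(lesion_side)
    vol = np.asarray(lesion_volume, dtype=float)
    if len({len(y), len(side), len(vol)}) != 1:
        raise ValueError("inputs must have equal length")
    if side.min() == side.max():
        raise DegenerateDataError("both lesion sides must be present")
    X = np.column_stack([np.ones_like(y), side, vol])
    _, _, t, _, _, dfden = _ols(X, y)
    F = float(t[1] ** 2)
    p = float(sps.f.sf(F, 1, dfden))
    return AncovaResult(F=F, p=p, df_num=1, df_den=dfden)


def _side_codes(lesion_side) -> np.ndarray:
    arr = np.asarray(lesion_side)
    if arr.dtype.kind in "OUS":
        mapping = {"left": 0.0, "right": 1.0}
        try:
            return np.array([mapping[str(v).lower()] for v in arr])
        except KeyError as exc:
            raise ValueError(f"unknown lesion side label: {exc}") from exc
    return arr.astype(float)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) of a 2x2 count table.

    ``chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``, p from chi2 with 1 df.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise DegenerateDataError("zero margin: chi-square undefined")
    chi2 = float(n * (a * d - b * c) ** 2 / margins)
    return chi2, float(sps.chi2.sf(chi2, df=1))


@dataclass
class RegressionResult:
    """One tract's standardized multivariate regression."""

    coefficients: pd.DataFrame  # index: predictor; columns: coef, se, t, p
    r2: float
    f2: float
    df_resid: int


def tract_regression(
    task_scores,
    tract_loads,
    lesion_side,
    gm_volume=None,
    standardize_inputs: bool = True,
) -> RegressionResult:
    """OLS of Task Score on one tract's lesion load plus covariates.

    All variables (outcome included) are standardised to zero mean and unit
    sample SD, so coefficients are in SD units.  ``gm_volume=None``
    reproduces the uncontrolled variant without the grey-matter covariate.
    """
    y = np.asarray(task_scores, dtype=float)
    n = len(y)
    if n <= 10:
        raise DegenerateDataError("tract regression needs n > 10")
    cols: dict[str, np.ndarray] = {
        "tract_load": np.asarray(tract_loads, dtype=float),
        "side": _side_codes(lesion_side),
    }
    if gm_volume is not None:
        cols["gm_volume"] = np.asarray(gm_volume, dtype=float)
    if standardize_inputs:
        y = standardize(y)
        cols = {k: standardize(v) for k, v in cols.items()}
    names = list(cols)
    X = np.column_stack([np.ones(n)] + [cols[k] for k in names])
    beta, se, t, pvals, r2, dfr = _ols(X, y)
    coef = pd.DataFrame(
        {"coef": beta[1:], "se": se[1:], "t": t[1:], "p": pvals[1:]}, index=names
    )
    return RegressionResult(
        coefficients=coef, r2=r2, f2=cohens_f2(r2), df_resid=dfr
    )


def tract_regression_battery(
    task_scores,
    loads: pd.DataFrame,
    tracts: list[str],
    lesion_side,
    gm_volume=None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-tract regressions with BH-FDR pooled over all coefficient tests.

    The FDR family pools every coefficient of every tract model (3 per tract
    when the grey-matter covariate is present), matching a family size of
    3 x n_tracts.  Returns a long table with one row per (tract, predictor).
    """
    rows = []
    for tract in tracts:
        res = tract_regression(
            task_scores, loads[tract].to_numpy(), lesion_side, gm_volume
        )
        for pred, r in res.coefficients.iterrows():
            rows.append(
                {
                    "tract": tract,
                    "predictor": pred,
                    "coef": r["coef"],
                    "se": r["se"],
                    "t": r["t"],
                    "p": r["p"],
                    "r2": res.r2,
                    "f2": res.f2,
                }
            )
    out = pd.DataFrame(rows)
    reject, p_adj = bh_fdr(out["p"].to_numpy(), q=q)
    out["p_fdr"] = p_adj
    out["significant"] = reject
    return out


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection flags, adjusted p-values)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# Principal component regression


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # predictors x components (eigenvectors)
    eigenvalues: np.ndarray  # non-increasing
    pct_variance: np.ndarray  # sums to 100 over all components
    n_selected: int  # smallest k with cumulative variance >= threshold
    scores: np.ndarray  # (n, n_components) component scores
    variance_threshold: float


def pca_predictors(
    predictors: pd.DataFrame, variance_threshold: float = 95.0
) -> PCAResult:
    """PCA of the standardised predictor block (correlation eigenstructure).

    Columns are standardised (sample SD), the correlation matrix is
    eigendecomposed, components are ordered by decreasing eigenvalue, and
    the smallest k whose cumulative explained variance reaches the threshold
    (percent) is selected.  Eigenvector signs are fixed so each component's
    largest-magnitude loading is positive.
    """
    X = np.column_stack([standardize(predictors[c].to_numpy()) for c in predictors])
    n, m = X.shape
    corr = (X.T @ X) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    for j in range(m):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    pct = 100.0 * eigval / eigval.sum()
    cum = np.cumsum(pct)
    n_selected = int(np.searchsorted(cum, variance_threshold - 1e-9) + 1)
    n_selected = min(n_selected, m)
    comp_names = [f"PC{j + 1}" for j in range(m)]
    loadings = pd.DataFrame(eigvec, index=list(predictors.columns), columns=comp_names)
    return PCAResult(
        loadings=loadings,
        eigenvalues=eigval,
        pct_variance=pct,
        n_selected=n_selected,
        scores=X @ eigvec,
        variance_threshold=variance_threshold,
    )


@dataclass
class PCRegressionResult:
    table: pd.DataFrame  # per component: coef, se, t, p, p_fdr, significant
    r2: float
    f2: float
    pca: PCAResult


def pc_regression(
    pca: PCAResult, task_scores, q: float = 0.05, standardize_outcome: bool = True
) -> PCRegressionResult:
    """OLS of Task Score on the selected component scores, FDR over the k
    component coefficient tests."""
    if pca.n_selected < 1:
        raise DegenerateDataError("no components selected")
    y = np.asarray(task_scores, dtype=float)
    if standardize_outcome:
        y = standardize(y)
    S = pca.scores[:, : pca.n_selected]
    X = np.column_stack([np.ones(len(y)), S])
    beta, se, t, pvals, r2, _ = _ols(X, y)
    reject, p_adj = bh_fdr(pvals[1:], q=q)
    table = pd.DataFrame(
        {
            "coef": beta[1:],
            "se": se[1:],
            "t": t[1:],
            "p": pvals[1:],
            "p_fdr": p_adj,
            "significant": reject,
        },
        index=[f"PC{j + 1}" for j in range(pca.n_selected)],
    )
    return PCRegressionResult(table=table, r2=r2, f2=cohens_f2(r2), pca=pca)
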