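"""Association testing and meta-analysis for glycan traits.

The association layer follows the standard population-glycomics recipe:

* rank-based inverse normal transformation (RINT) of glycan traits and
  quantitative phenotypes, making effects comparable across traits and
  cohorts (binary phenotypes stay 0/1, males coded 1);
* ordinary least squares of the (transformed) glycan trait on the phenotype
  plus covariates (age, sex and optionally BMI), complete cases per pair;
* partial (covariate-adjusted residual) Pearson correlation where a
  correlation rather than a regression slope is wanted;
* inverse-variance fixed-effects meta-analysis across cohorts;
* Benjamini–Hochberg step-up FDR control within each analysis family.

The public surface is a pair of statsmodels-style objects:
:class:`GlycanAssociationModel` (built from data, ``fit()`` returns
:class:`AssociationResults`) and :class:`FixedEffectsMeta` (combines
per-cohort results, ``fit()`` returns :class:`MetaResults`); both results
objects carry tidy tables and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, t as t_dist

__all__ = [
    "rint", "bh_adjust", "meta_fixed", "fit_association", "adjusted_correlation",
    "sex_stratified_smoother", "AssociationRecord", "MetaRecord",
    "GlycanAssociationModel", "AssociationResults", "FixedEffectsMeta", "MetaResults",
]


# ---------------------------------------------------------------------------
# Elementary transforms
# ---------------------------------------------------------------------------

def rint(values) -> np.ndarray:
    """Rank-based inverse normal transform, Phi^-1((r - 0.5)/n).

    Average ranks for ties; missing values are preserved in place; at least
    3 non-missing, non-constant values are required.
    """
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = np.isfinite(arr)
    x = arr[ok]
    if x.size < 3:
        raise ValueError("rint needs at least 3 non-missing values")
    if np.all(x == x[0]):
        raise ValueError("rint undefined for a constant vector")
    ranks = rankdata(x, method="average")
    out[ok] = norm.ppf((ranks - 0.5) / x.size)
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Missing entries are dropped from the family and restored as NaN.
    """
    arr = np.asarray(pvals, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = np.isfinite(arr)
    p = arr[ok]
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if m == 0:
        return out
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[ok] = restored
    return out


def _is_binary(x: np.ndarray) -> bool:
    vals = np.unique(x[np.isfinite(x)])
    return vals.size <= 2


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class AssociationRecord:
    """One (glycan trait x phenotype x cohort) regression result."""

    glycan: str
    trait: str
    cohort: str | None
    df: int
    effect: float
    se: float
    p_value: float
    p_adjusted: float | None = None


@dataclass
class MetaRecord:
    """Inverse-variance fixed-effects combination of cohort results."""

    glycan: str
    trait: str
    effect: float
    se: float
    z: float
    p_value: float
    p_adjusted: float | None = None
    cohorts: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Core fits
# ---------------------------------------------------------------------------

def _ols(y: np.ndarray, X: np.ndarray, names: list[str]):
    """Plain OLS with collinearity check; returns (beta, se, df_resid)."""
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # identify an offending column by leave-one-out rank
        for j in range(k):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                raise ValueError(f"collinear design; offending column: {names[j]!r}")
        raise ValueError("collinear design")
    if n < k + 1:
        raise ValueError(f"too few complete cases ({n}) for {k} predictors")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return beta, se, df


def fit_association(
    y, x, covariates=None, glycan: str = "y", trait: str = "x",
    cohort: str | None = None, transform: bool = True,
) -> AssociationRecord:
    """OLS association of a glycan trait (outcome) with a phenotype.

    ``y`` and quantitative ``x`` are RINT-transformed (binary ``x`` is left
    0/1); covariates enter untransformed.  Complete cases only; the reported
    effect/SE/p belong to ``x``; DF = n_complete - (predictors + 1).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if covariates is None:
        C = np.empty((y.size, 0))
        cov_names: list[str] = []
    else:
        C = pd.DataFrame(covariates)
        cov_names = [str(c) for c in C.columns]
        C = C.to_numpy(dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    if C.shape[1]:
        ok &= np.all(np.isfinite(C), axis=1)
    n = int(ok.sum())
    if n < C.shape[1] + 3:
        raise ValueError(f"too few complete cases ({n})")
    yy, xx, CC = y.copy(), x.copy(), C
    if transform:
        yy = np.where(ok, yy, np.nan)
        yy = rint(yy)
        if not _is_binary(xx):
            xx = np.where(ok, xx, np.nan)
            xx = rint(xx)
    X = np.column_stack([np.ones(n), xx[ok]] + ([CC[ok]] if CC.shape[1] else []))
    names = ["const", trait] + cov_names
    beta, se, df = _ols(yy[ok], X, names)
    tval = beta[1] / se[1]
    p = float(2 * t_dist.sf(abs(tval), df))
    return AssociationRecord(glycan=glycan, trait=trait, cohort=cohort,
                             df=df, effect=float(beta[1]), se=float(se[1]), p_value=p)


def adjusted_correlation(y, x, covariates=None) -> tuple[float, float]:
    """Pearson correlation of covariate-residualized y and x, with t-test p.

    ``y`` (and ``x`` when quantitative) are residualized on the covariates by
    OLS; binary ``x`` is correlated as-is against residualized ``y``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        C = np.empty((y.size, 0))
    else:
        C = pd.DataFrame(covariates).to_numpy(dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    if C.shape[1]:
        ok &= np.all(np.isfinite(C), axis=1)
    n = int(ok.sum())
    if n < C.shape[1] + 3:
        raise ValueError(f"too few complete cases ({n})")
    X = np.column_stack([np.ones(n)] + ([C[ok]] if C.shape[1] else []))

    def _resid(v):
        beta, _, _, _ = np.linalg.lstsq(X, v, rcond=None)
        return v - X @ beta

    ry = _resid(y[ok])
    rx = x[ok] - x[ok].mean() if _is_binary(x) else _resid(x[ok])
    if ry.std() == 0 or rx.std() == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(ry, rx)[0, 1])
    df = n - 2 - C.shape[1]
    tval = r * np.sqrt(df / max(1e-300, 1 - r ** 2))
    p = float(2 * t_dist.sf(abs(tval), df))
    return r, p


def meta_fixed(records: list[AssociationRecord]) -> MetaRecord:
    """Inverse-variance fixed-effects combination of per-cohort estimates.

    Weights are 1/SE^2; the combined p comes from the Normal z statistic.
    Records with missing effect or SE are dropped; a single surviving record
    passes through unchanged (same effect and SE).
    """
    usable = [r for r in records
              if r is not None and np.isfinite(r.effect) and np.isfinite(r.se)]
    if not usable:
        raise ValueError("no usable cohort records to combine")
    if any(r.se <= 0 for r in usable):
        raise ValueError("standard errors must be positive")
    w = np.array([1.0 / r.se ** 2 for r in usable])
    e = np.array([r.effect for r in usable])
    effect = float((w * e).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    z = effect / se
    p = float(2 * norm.sf(abs(z)))
    first = usable[0]
    return MetaRecord(glycan=first.glycan, trait=first.trait, effect=effect,
                      se=se, z=z, p_value=p,
                      cohorts=tuple(r.cohort for r in usable if r.cohort))


# ---------------------------------------------------------------------------
# Sex-stratified age smoother
# ---------------------------------------------------------------------------

def sex_stratified_smoother(
    age, value, sex, span: float = 0.75, n_grid: int = 50,
    min_stratum: int = 30,
) -> dict[str, pd.DataFrame]:
    """Locally weighted linear regression of a trait on age, per sex.

    Tricube weights over the ``span`` nearest fraction of points, evaluated
    on a fixed age grid; the pointwise 95% CI comes from the local weighted
    least-squares standard error.  Strata below ``min_stratum`` points are
    skipped with a warning.
    """
    import warnings

    age = np.asarray(age, dtype=float)
    value = np.asarray(value, dtype=float)
    sex = np.asarray(sex)
    out: dict[str, pd.DataFrame] = {}
    for s in pd.unique(sex[pd.notna(sex)]):
        mask = (sex == s) & np.isfinite(age) & np.isfinite(value)
        a, v = age[mask], value[mask]
        if a.size < min_stratum:
            warnings.warn(f"stratum {s!r} has only {a.size} points; skipped")
            continue
        grid = np.linspace(a.min(), a.max(), n_grid)
        k = max(int(np.ceil(span * a.size)), 3)
        fit = np.empty(n_grid)
        se = np.empty(n_grid)
        for i, x0 in enumerate(grid):
            d = np.abs(a - x0)
            h = np.sort(d)[k - 1]
            if h == 0:
                h = np.finfo(float).eps
            w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
            use = w > 0
            W = w[use]
            X = np.column_stack([np.ones(use.sum()), a[use] - x0])
            WX = X * W[:, None]
            XtWX = X.T @ WX
            beta = np.linalg.solve(XtWX, WX.T @ v[use])
            resid = v[use] - X @ beta
            sigma2 = float((W * resid ** 2).sum() / max(W.sum() - 2.0, 1.0))
            # variance of the local intercept (the fitted value at x0)
            inv = np.linalg.inv(XtWX)
            var_fit = sigma2 * float((inv @ (X.T @ (W[:, None] ** 2 * X)) @ inv)[0, 0])
            fit[i] = beta[0]
            se[i] = np.sqrt(max(var_fit, 0.0))
        out[str(s)] = pd.DataFrame({
            "age": grid, "fit": fit, "se": se,
            "lo": fit - 1.96 * se, "hi": fit + 1.96 * se,
        })
    return out


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class GlycanAssociationModel:
    """Regression of every glycan trait on every phenotype within one cohort.

    Parameters
    ----------
    glycans
        Samples x glycan-traits DataFrame (any monotone scale; RINT is
        applied per trait).
    phenotypes
        Samples x phenotypes DataFrame, aligned by index.
    covariates
        Samples x covariates DataFrame (e.g. age, sex 0/1, BMI).  A
        phenotype that is itself a covariate is dropped from its own
        covariate set.
    cohort
        Label carried into the result table.
    """

    def __init__(self, glycans: pd.DataFrame, phenotypes: pd.DataFrame,
                 covariates: pd.DataFrame | None = None,
                 cohort: str | None = None, transform: bool = True):
        idx = glycans.index
        if not phenotypes.index.equals(idx):
            phenotypes = phenotypes.reindex(idx)
        if covariates is not None and not covariates.index.equals(idx):
            covariates = covariates.reindex(idx)
        self.glycans = glycans
        self.phenotypes = phenotypes
        self.covariates = covariates
        self.cohort = cohort
        self.transform = transform

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, glycan_cols, phenotype_cols,
                       covariate_cols=(), **kw) -> "GlycanAssociationModel":
        return cls(df[list(glycan_cols)], df[list(phenotype_cols)],
                   df[list(covariate_cols)] if covariate_cols else None, **kw)

    def fit(self, fdr_family: str = "all") -> "AssociationResults":
        records = []
        for ph in self.phenotypes.columns:
            if self.covariates is not None and ph in self.covariates.columns:
                cov = self.covariates.drop(columns=[ph])
            else:
                cov = self.covariates
            for gl in self.glycans.columns:
                try:
                    rec = fit_association(
                        self.glycans[gl], self.phenotypes[ph], cov,
                        glycan=gl, trait=ph, cohort=self.cohort,
                        transform=self.transform,
                    )
                except ValueError:
                    rec = AssociationRecord(glycan=gl, trait=ph, cohort=self.cohort,
                                            df=0, effect=np.nan, se=np.nan,
                                            p_value=np.nan)
                records.append(rec)
        table = pd.DataFrame([vars(r) for r in records])
        table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
        return AssociationResults(table=table, model=self)


class AssociationResults:
    """Tidy per-(glycan, phenotype) regression table with BH-adjusted p."""

    def __init__(self, table: pd.DataFrame, model: GlycanAssociationModel | None = None):
        self.table = table
        self.model = model

    @property
    def cohort(self):
        vals = self.table["cohort"].dropna().unique()
        return vals[0] if len(vals) else None

    def records(self) -> list[AssociationRecord]:
        return [AssociationRecord(**{k: row[k] for k in (
            "glycan", "trait", "cohort", "df", "effect", "se", "p_value", "p_adjusted")})
            for _, row in self.table.iterrows()]

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adjusted"] <= alpha]

    def summary(self, max_rows: int = 25) -> str:
        t = self.table.sort_values("p_value").head(max_rows)
        lines = [
            f"Glycan trait associations — cohort: {self.cohort or 'n/a'}",
            f"pairs tested: {len(self.table)}, "
            f"BH-significant at 0.05: {int((self.table['p_adjusted'] <= 0.05).sum())}",
            "",
            t.to_string(index=False,
                        float_format=lambda v: f"{v:.4g}",
                        columns=["glycan", "trait", "df", "effect", "se",
                                 "p_value", "p_adjusted"]),
        ]
        return "\n".join(lines)


class FixedEffectsMeta:
    """Inverse-variance fixed-effects meta-analysis across cohorts."""

    def __init__(self, results: list[AssociationResults]):
        if not results:
            raise ValueError("need at least one cohort's results")
        self.results = results

    def fit(self) -> "MetaResults":
        keyed: dict[tuple[str, str], list[AssociationRecord]] = {}
        order: list[tuple[str, str]] = []
        for res in self.results:
            for rec in res.records():
                key = (rec.glycan, rec.trait)
                if key not in keyed:
                    keyed[key] = []
                    order.append(key)
                keyed[key].append(rec)
        rows = []
        for key in order:
            recs = keyed[key]
            try:
                mr = meta_fixed(recs)
            except ValueError:
                mr = MetaRecord(glycan=key[0], trait=key[1], effect=np.nan,
                                se=np.nan, z=np.nan, p_value=np.nan)
            rows.append(vars(mr))
        table = pd.DataFrame(rows)
        table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
        return MetaResults(table=table, meta=self)


class MetaResults:
    """Combined-effect table mirroring the per-cohort layout."""

    def __init__(self, table: pd.DataFrame, meta: FixedEffectsMeta | None = None):
        self.table = table
        self.meta = meta

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adjusted"] <= alpha]

    def summary(self, max_rows: int = 25) -> str:
        t = self.table.sort_values("p_value").head(max_rows)
        lines = [
            "Fixed-effects meta-analysis (inverse-variance weights)",
            f"pairs: {len(self.table)}, "
            f"BH-significant at 0.05: {int((self.table['p_adjusted'] <= 0.05).sum())}",
            "",
            t.to_string(index=False,
                        float_format=lambda v: f"{v:.4g}",
                        columns=["glycan", "trait", "effect", "se", "z",
                                 "p_value", "p_adjusted"]),
        ]
        return "\n".join(lines)
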