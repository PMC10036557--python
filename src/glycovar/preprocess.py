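"""Normalization, log transform, batch correction and QC estimators.

The preprocessing chain for compositional chromatographic glycan data:

1. total-area normalization: each sample's peak areas are expressed as a
   percentage of that sample's total integrated area, removing injection-
   amount differences;
2. natural-log transform: percent areas are right-skewed and plate (batch)
   effects act multiplicatively, so both are handled on the log scale;
3. location-only empirical-Bayes batch correction: per (plate, peak) mean
   shifts are estimated, shrunk across peaks within a plate toward a
   moment-matched Normal prior, and subtracted.  This is the parametric,
   location-only variant of the ComBat family; estimated effects are
   *subtracted*, never rescaled (a location+scale mode exists behind a
   flag and is off by default).

Measurement-error estimators quantify technical noise from internal
standards (variance ratio against cohort samples) and sample duplicates
(one minus the replicate correlation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaktable import PeakTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Normalization and log transform
# ---------------------------------------------------------------------------

def normalize_total_area(raw: PeakTable) -> PeakTable:
    """Convert raw areas to percent-of-total-area per sample.

    Samples whose total area is zero (e.g. blanks) are excluded with a
    logged warning.
    """
    if raw.scale != "raw_area":
        raise ValueError(f"expected raw_area table, got {raw.scale!r}")
    totals = raw.values.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        excluded = list(raw.values.index[zero])
        logger.warning(
            "normalize_total_area: excluding %d all-zero sample(s): %s",
            len(excluded), excluded[:10],
        )
        raw = raw.subset(raw.values.index[~zero])
        totals = totals[~zero]
    pct = raw.values.div(totals, axis=0) * 100.0
    return raw.with_values(pct, "percent_area")


def log_transform(pt: PeakTable, zero_policy: str = "half_min") -> PeakTable:
    """Natural-log transform of percent areas.

    Zeros are replaced by half the smallest positive value of the same peak
    (``zero_policy='half_min'``, standard compositional practice) or raise
    (``zero_policy='error'``).  Negative values always raise.
    """
    if pt.scale != "percent_area":
        raise ValueError(f"expected percent_area table, got {pt.scale!r}")
    vals = pt.values.copy()
    if (vals.to_numpy() < 0).any():
        raise ValueError("negative percent areas")
    n_zero = int((vals.to_numpy() == 0).sum())
    if n_zero:
        if zero_policy == "error":
            raise ValueError(f"{n_zero} zero value(s); cannot log-transform")
        logger.info("log_transform: imputing %d zero value(s) as half-minimum", n_zero)
        for col in vals.columns:
            col_vals = vals[col]
            if (col_vals == 0).any():
                pos = col_vals[col_vals > 0]
                if pos.empty:
                    raise ValueError(f"peak {col!r} is zero in every sample")
                vals.loc[col_vals == 0, col] = pos.min() / 2.0
    return pt.with_values(np.log(vals), "log")


# ---------------------------------------------------------------------------
# Empirical-Bayes batch correction
# ---------------------------------------------------------------------------

@dataclass
class BatchModel:
    """Fitted batch-correction model.

    ``gamma_hat``/``gamma_star`` are (batch x peak) DataFrames of raw and
    EB-shrunk location effects; ``prior_mean``/``prior_var`` the per-batch
    moment-matched Normal prior parameters.  The sample-size-weighted mean
    of raw effects is 0 for every peak (identifiability), and shrunk effects
    lie between the raw estimate and the prior mean.
    """

    gamma_hat: pd.DataFrame
    gamma_star: pd.DataFrame
    prior_mean: pd.Series
    prior_var: pd.Series
    batch_sizes: pd.Series
    batches: list = field(default_factory=list)
    scale_applied: bool = False

    def to_json(self, path) -> None:
        import json

        payload = {
            "gamma_hat": self.gamma_hat.to_dict(orient="split"),
            "gamma_star": self.gamma_star.to_dict(orient="split"),
            "prior_mean": self.prior_mean.to_dict(),
            "prior_var": self.prior_var.to_dict(),
            "batch_sizes": self.batch_sizes.to_dict(),
            "batches": list(self.batches),
            "scale_applied": self.scale_applied,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, default=str)


def correct_batch_effects(
    pt: PeakTable,
    batches: pd.Series | None = None,
    adjust_scale: bool = False,
    shrink: bool = True,
) -> tuple[PeakTable, BatchModel]:
    """Subtract empirical-Bayes-shrunk per-(batch, peak) location effects.

    For each peak the grand mean is preserved exactly: the shrunk effects are
    re-centered (sample-size weighted) before subtraction.  Batches with a
    single sample are warned about and left uncorrected.  With a single
    batch the input is returned unchanged.
    """
    if pt.scale not in ("log", "log_batch_corrected"):
        raise ValueError("batch correction operates on log-scale tables")
    if batches is None:
        batches = pt.batches
    if batches is None:
        raise ValueError("no batch labels available")
    batches = pd.Series(batches).reindex(pt.values.index)
    if batches.isna().any():
        raise ValueError("batch labels missing for some samples")

    X = pt.values
    labels = list(pd.unique(batches))
    n_i = batches.value_counts()
    if len(labels) < 2:
        model = BatchModel(
            gamma_hat=pd.DataFrame(0.0, index=labels, columns=X.columns),
            gamma_star=pd.DataFrame(0.0, index=labels, columns=X.columns),
            prior_mean=pd.Series(0.0, index=labels),
            prior_var=pd.Series(0.0, index=labels),
            batch_sizes=n_i, batches=labels,
        )
        return pt.with_values(X.copy(), "log_batch_corrected"), model

    singletons = [b for b in labels if n_i[b] < 2]
    if singletons:
        logger.warning("correct_batch_effects: singleton batch(es) %s left uncorrected",
                       singletons)

    grand = X.mean(axis=0)  # per-peak grand mean (= size-weighted batch-mean mean)
    batch_means = X.groupby(batches).mean()
    gamma_hat = batch_means.sub(grand, axis=1).reindex(labels)

    # pooled within-batch residual variance per peak -> sampling variance of
    # each batch-mean deviation
    resid = X - batch_means.loc[batches].set_axis(X.index)
    dof = max(len(X) - len(labels), 1)
    sigma2 = (resid ** 2).sum(axis=0) / dof

    prior_mean = gamma_hat.mean(axis=1)
    prior_var = pd.Series(0.0, index=gamma_hat.index)
    gamma_star = gamma_hat.copy()
    for b in labels:
        if n_i[b] < 2:
            gamma_star.loc[b] = 0.0
            gamma_hat.loc[b] = 0.0
            continue
        s2 = sigma2 / n_i[b]  # sampling variance per peak
        # moment-matched Normal prior across peaks within this batch
        tau2 = max(float(gamma_hat.loc[b].var(ddof=1) - s2.mean()), 0.0)
        prior_var[b] = tau2
        if shrink:
            w = tau2 / (tau2 + s2)  # 0 when tau2 == 0
            gamma_star.loc[b] = w * gamma_hat.loc[b] + (1 - w) * prior_mean[b]
        else:
            gamma_star.loc[b] = gamma_hat.loc[b]

    # re-center so the per-peak grand mean is untouched
    weights = n_i.reindex(gamma_star.index).to_numpy()[:, None] / n_i.sum()
    offset = (gamma_star * weights).sum(axis=0)
    applied = gamma_star.sub(offset, axis=1)

    corrected = X - applied.loc[batches].set_axis(X.index)

    if adjust_scale:
        # optional location+scale mode: rescale within-batch spread to pooled
        batch_sd = resid.groupby(batches).std(ddof=1)
        pooled_sd = np.sqrt(sigma2)
        for b in labels:
            if n_i[b] < 2:
                continue
            idx = batches[batches == b].index
            ratio = pooled_sd / batch_sd.loc[b].replace(0.0, np.nan)
            ratio = ratio.fillna(1.0)
            center = corrected.loc[idx].mean(axis=0)
            corrected.loc[idx] = (corrected.loc[idx] - center) * ratio + center

    model = BatchModel(
        gamma_hat=gamma_hat, gamma_star=gamma_star,
        prior_mean=prior_mean, prior_var=prior_var,
        batch_sizes=n_i, batches=labels, scale_applied=adjust_scale,
    )
    return pt.with_values(corrected, "log_batch_corrected"), model


def apply_batch_model(pt: PeakTable, model: BatchModel,
                      batches: pd.Series | None = None) -> PeakTable:
    """Correct a table (e.g. internal standards) with effects estimated on
    another table (the cohort samples)."""
    if batches is None:
        batches = pt.batches
    if batches is None:
        raise ValueError("no batch labels available")
    batches = pd.Series(batches).reindex(pt.values.index)
    known = batches.isin(model.gamma_star.index)
    if not known.all():
        missing = sorted(set(batches[~known]))
        logger.warning("apply_batch_model: batches %s not in model; left uncorrected",
                       missing[:5])
    weights = model.batch_sizes.reindex(model.gamma_star.index).to_numpy()[:, None]
    offset = (model.gamma_star * (weights / weights.sum())).sum(axis=0)
    applied = model.gamma_star.sub(offset, axis=1)
    shift = pd.DataFrame(0.0, index=pt.values.index, columns=pt.values.columns)
    ok = batches[known]
    shift.loc[ok.index] = applied.loc[ok].to_numpy()
    return pt.with_values(pt.values - shift, "log_batch_corrected")


# ---------------------------------------------------------------------------
# Measurement-error / QC estimators
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-peak measurement-error summary.

    ``error_standards``: 100 * Var(standards) / Var(cohort) per peak;
    ``error_replicates``: 100 * (1 - replicate correlation) per peak;
    ``cv_standards``: coefficient of variation (%) of standards on the
    percent scale (NaN when unavailable).
    """

    error_standards: pd.Series
    error_replicates: pd.Series
    cv_standards: pd.Series
    n_standards: int
    n_replicate_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "error_standards_pct": self.error_standards,
            "error_replicates_pct": self.error_replicates,
            "cv_standards_pct": self.cv_standards,
        })

    def to_json(self, path) -> None:
        import json

        payload = self.to_frame().to_dict(orient="split")
        payload["n_standards"] = self.n_standards
        payload["n_replicate_pairs"] = self.n_replicate_pairs
        with open(path, "w") as fh:
            json.dump(payload, fh, default=str)


def measurement_error_standards(standards: PeakTable, cohort: PeakTable) -> pd.Series:
    """Technical-variance share per peak: 100 * Var(standards)/Var(cohort).

    Standards are biologically identical aliquots, so their variance is pure
    measurement noise; cohort variance is biology plus noise.  Both tables
    must be on the same scale.  Zero cohort variance yields NaN.
    """
    if standards.scale != cohort.scale:
        raise ValueError("standards and cohort tables must share a scale")
    if standards.n_samples < 3 or cohort.n_samples < 3:
        raise ValueError("need at least 3 standards and 3 cohort samples")
    vs = standards.values.var(ddof=1)
    vc = cohort.values.var(ddof=1)
    out = 100.0 * vs / vc.replace(0.0, np.nan)
    out.name = "error_standards_pct"
    return out


def measurement_error_replicates(first: pd.DataFrame, second: pd.DataFrame) -> pd.Series:
    """Replicate-based error per peak: 100 * (1 - Pearson r across pairs)."""
    if first.shape != second.shape:
        raise ValueError("replicate members must align")
    if len(first) < 3:
        raise ValueError("need at least 3 replicate pairs")
    out = {}
    for col in first.columns:
        a = first[col].to_numpy(dtype=float)
        b = second[col].to_numpy(dtype=float)
        if a.std() == 0 or b.std() == 0:
            out[col] = np.nan
        else:
            out[col] = 100.0 * (1.0 - np.corrcoef(a, b)[0, 1])
    return pd.Series(out, name="error_replicates_pct")


def cv(values) -> float:
    """Coefficient of variation, 100 * SD / mean (sample SD, n-1)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    m = arr.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / m)


def qc_report(
    standards: PeakTable,
    cohort: PeakTable,
    replicate_first: pd.DataFrame | None = None,
    replicate_second: pd.DataFrame | None = None,
    standards_percent: PeakTable | None = None,
) -> QCReport:
    """Assemble the per-peak QC report from standards and replicate pairs."""
    err_std = measurement_error_standards(standards, cohort)
    if replicate_first is not None and len(replicate_first) >= 3:
        err_rep = measurement_error_replicates(replicate_first, replicate_second)
        n_pairs = len(replicate_first)
    else:
        err_rep = pd.Series(np.nan, index=standards.peak_ids, name="error_replicates_pct")
        n_pairs = 0
    if standards_percent is not None:
        cvs = pd.Series({c: cv(standards_percent.values[c]) for c in standards_percent.peak_ids},
                        name="cv_standards_pct")
    else:
        cvs = pd.Series(np.nan, index=standards.peak_ids, name="cv_standards_pct")
    return QCReport(
        error_standards=err_std, error_replicates=err_rep, cv_standards=cvs,
        n_standards=standards.n_samples, n_replicate_pairs=n_pairs,
    )
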