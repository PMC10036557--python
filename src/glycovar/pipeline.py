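"""End-to-end orchestration: simulate -> preprocess -> traits -> associate -> meta.

One declarative configuration drives the whole synthetic study: generate two
cohorts, total-area normalize, log-transform, batch-correct (per cohort,
standards corrected with cohort-derived effects), compute derived traits and
run them through the same correction chain, assemble the QC report,
regress every trait on every phenotype with age/sex(/BMI) covariates within
each cohort, combine cohorts by inverse-variance fixed-effects
meta-analysis, and control FDR by Benjamini–Hochberg.  Deterministic given
the seed; every output table carries the config hash and seed in a header
comment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import config_hash, write_peak_table, write_table
from .peaktable import PeakTable, phenotype_columns, replicate_pairs, split_roles
from .preprocess import (apply_batch_model, correct_batch_effects, log_transform,
                         normalize_total_area, qc_report)
from .stats import AssociationResults, FixedEffectsMeta, GlycanAssociationModel
from .synthetic import CohortConfig, generate_cohort, korcula_config, viking_config
from .traits import default_annotation, derive_traits

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration of the full synthetic study."""

    cohorts: list[CohortConfig] = field(
        default_factory=lambda: [korcula_config(), viking_config()])
    panel: str = "Tf"
    covariates: tuple[str, ...] = ("age", "sex")   # or ("age", "sex", "bmi")
    phenotypes: tuple[str, ...] | None = None      # default: all generated
    fdr_level: float = 0.05
    seed: int = 0
    include_peaks: bool = False  # associate single peaks as well as derived traits

    def __post_init__(self) -> None:
        if not (0 < self.fdr_level < 1):
            raise ValueError("FDR level must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "cohorts": [c.to_dict() for c in self.cohorts],
            "panel": self.panel,
            "covariates": list(self.covariates),
            "phenotypes": list(self.phenotypes) if self.phenotypes else None,
            "fdr_level": self.fdr_level,
            "seed": self.seed,
            "include_peaks": self.include_peaks,
        }

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = json.load(fh)
        cohorts = []
        for c in payload.pop("cohorts", []):
            c = dict(c)
            from .synthetic import Effect
            c["effect_table"] = tuple(Effect(**e) for e in c.get("effect_table", []))
            c.pop("baseline_composition", None)
            c.pop("phenotypes", None)
            c["age_range"] = tuple(c.get("age_range", (18.0, 90.0)))
            cohorts.append(CohortConfig(**c))
        kw = {k: payload[k] for k in
              ("panel", "fdr_level", "seed", "include_peaks") if k in payload}
        if payload.get("covariates"):
            kw["covariates"] = tuple(payload["covariates"])
        if payload.get("phenotypes"):
            kw["phenotypes"] = tuple(payload["phenotypes"])
        return cls(cohorts=cohorts or None, **kw) if cohorts else cls(**kw)


@dataclass
class CohortResult:
    """Per-cohort artifacts of one pipeline run."""

    config: CohortConfig
    samples: pd.DataFrame
    raw: PeakTable
    percent: PeakTable
    corrected: PeakTable          # cohort samples, log batch-corrected peaks
    trait_percent: pd.DataFrame
    trait_corrected: pd.DataFrame
    qc: object
    truth: object
    age_sex: AssociationResults
    associations: AssociationResults


@dataclass
class PipelineResult:
    """Everything a full run produces."""

    config: PipelineConfig
    cohorts: list[CohortResult]
    meta: object
    log: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = f"glycovar {__version__} config_hash={config_hash(self.config.to_dict())} seed={self.config.seed}"
        for cr in self.cohorts:
            cid = cr.config.cohort_id
            write_peak_table(outdir / f"{cid}_raw.csv", cr.samples, cr.raw, comment=tag)
            write_peak_table(outdir / f"{cid}_corrected.csv",
                             cr.samples, cr.corrected, comment=tag)
            write_table(outdir / f"{cid}_traits.csv",
                        cr.trait_corrected.reset_index(names="sample_id"), comment=tag)
            write_table(outdir / f"{cid}_qc.csv",
                        cr.qc.to_frame().reset_index(names="peak_id"), comment=tag)
            write_table(outdir / f"{cid}_associations.csv", cr.associations.table,
                        comment=tag)
            write_table(outdir / f"{cid}_age_sex.csv", cr.age_sex.table, comment=tag)
        write_table(outdir / "meta_associations.csv", self.meta.table, comment=tag)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(self.log, fh, indent=2, default=str)


def encode_covariates(samples: pd.DataFrame, names) -> pd.DataFrame:
    """Numeric covariate matrix: sex coded M=1/F=0, others passed through."""
    cols = {}
    for name in names:
        if name == "sex":
            cols["sex"] = (samples["sex"] == "M").astype(float)
        else:
            cols[name] = pd.to_numeric(samples[name], errors="coerce")
    return pd.DataFrame(cols, index=samples.index)


def preprocess_cohort(config: CohortConfig, samples: pd.DataFrame,
                      raw: PeakTable) -> dict:
    """Normalize -> log -> batch-correct one cohort; traits get the same chain.

    Batch effects are estimated on cohort + replicate samples only;
    standards are corrected with the cohort-derived effects.
    """
    percent = normalize_total_area(raw)       # drops blanks (zero rows)
    logged = log_transform(percent)
    parts = split_roles(samples, logged)
    bio = pd.concat([parts[r].values for r in ("cohort", "replicate") if r in parts])
    bio_pt = PeakTable(bio, scale="log", batches=logged.batches.reindex(bio.index))
    bio_corr, model = correct_batch_effects(bio_pt)
    corrected = {r: bio_corr.subset(parts[r].sample_ids)
                 for r in ("cohort", "replicate") if r in parts}
    if "standard" in parts:
        corrected["standard"] = apply_batch_model(parts["standard"], model)

    ann = config.annotation
    tr_pct = derive_traits(percent, ann)
    # derived traits are strictly positive sums of percent areas (but not a
    # composition: families overlap), so they take the same log +
    # location-correction chain directly rather than via log_transform
    tr_logged = PeakTable(np.log(tr_pct), scale="log", batches=percent.batches)
    bio_tr = tr_logged.subset(tr_logged.sample_ids.intersection(bio.index))
    tr_corr, tr_model = correct_batch_effects(bio_tr)
    return {
        "percent": percent, "logged": logged, "batch_model": model,
        "corrected": corrected, "trait_percent": tr_pct,
        "trait_corrected_all": tr_corr, "trait_model": tr_model,
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full synthetic study; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    cohort_results: list[CohortResult] = []
    log: dict = {"glycovar_version": __version__, "seed": config.seed,
                 "config_hash": config_hash(config.to_dict()), "stages": []}
    for cfg in config.cohorts:
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        try:
            samples, raw, truth = generate_cohort(cfg, seed=sub_seed)
            pre = preprocess_cohort(cfg, samples, raw)
            cohort_ids = samples.index[samples["role"] == "cohort"]
            corrected = pre["corrected"]["cohort"]
            trait_corr = pre["trait_corrected_all"].subset(
                pre["trait_corrected_all"].sample_ids.intersection(cohort_ids))

            rep1, rep2 = replicate_pairs(
                samples,
                PeakTable(pd.concat([c.values for c in pre["corrected"].values()]),
                          scale="log_batch_corrected"))
            std_pct = (pre["percent"].subset(
                pre["percent"].sample_ids.intersection(
                    samples.index[samples["role"] == "standard"])))
            qc = qc_report(pre["corrected"].get("standard"), corrected,
                           rep1 if len(rep1) else None,
                           rep2 if len(rep2) else None,
                           standards_percent=std_pct if std_pct.n_samples else None)

            cov = encode_covariates(samples.loc[cohort_ids], config.covariates)
            pheno_names = (list(config.phenotypes) if config.phenotypes
                           else list(cfg.phenotypes))
            phenos = samples.loc[cohort_ids, pheno_names].apply(
                pd.to_numeric, errors="coerce")
            glycans = trait_corr.values
            if config.include_peaks:
                glycans = pd.concat([glycans, corrected.values], axis=1)

            # age/sex analysis: each of primary interest, the other adjusted
            as_cov = encode_covariates(samples.loc[cohort_ids], ("age", "sex"))
            age_sex_model = GlycanAssociationModel(
                glycans, as_cov.copy(), as_cov, cohort=cfg.cohort_id)
            age_sex_res = age_sex_model.fit()

            model = GlycanAssociationModel(glycans, phenos, cov,
                                           cohort=cfg.cohort_id)
            assoc = model.fit()
            cohort_results.append(CohortResult(
                config=cfg, samples=samples, raw=raw, percent=pre["percent"],
                corrected=corrected, trait_percent=pre["trait_percent"],
                trait_corrected=trait_corr.values, qc=qc, truth=truth,
                age_sex=age_sex_res, associations=assoc,
            ))
            log["stages"].append({
                "cohort": cfg.cohort_id, "seed": sub_seed,
                "n_samples": int(cfg.n_samples),
                "n_plates": int(cfg.n_plates),
                "n_standards": int(qc.n_standards),
                "n_replicate_pairs": int(qc.n_replicate_pairs),
                "n_pairs_tested": int(len(assoc.table)),
            })
        except Exception as exc:  # noqa: BLE001 - stage-named abort
            raise RuntimeError(f"pipeline failed in cohort {cfg.cohort_id!r}: {exc}") from exc

    try:
        meta = FixedEffectsMeta([cr.associations for cr in cohort_results]).fit()
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline failed in meta-analysis: {exc}") from exc
    log["stages"].append({"stage": "meta", "n_pairs": int(len(meta.table))})
    return PipelineResult(config=config, cohorts=cohort_results, meta=meta, log=log)
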