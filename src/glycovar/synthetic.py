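"""Synthetic two-cohort glycomics study generator.

Individual-level cohort glycomics data are rarely releasable, so this module
generates cohorts with the statistical structure the downstream analysis
assumes: a fixed baseline glycan composition, covariate effects injected on
derived-trait groups, per-plate multiplicative batch effects, log-normal
technical noise, per-sample injection-scale factors, and the quality-control
scaffolding of a 96-well workflow (internal standards, blanks and sample
duplicates on every plate, plate assignment blocked on sex and age).

The generative model, per sample i and peak k (log scale):

    log a_ik = log b_k + sum_g in G(k) d_gi + u_ik * s_peak
               + gamma_{p(i),k} + e_ik * s_noise + c_i

where b is the baseline composition, d_gi the shared latent of trait group g
(carrying the configured standardized covariate effects), u idiosyncratic
biological variation, gamma the plate x peak batch offset, e technical noise
and c_i a per-sample scale removed by total-area normalization.  For a
targeted group g with effects {(c, beta_gc)}:

    d_gi = s_trait * ( sum_c beta_gc z_ci + sqrt(1 - sum_c beta_gc^2) eps_gi )

with z_c the standardized covariate, so corr(z_c, d_g) = beta_gc exactly and
the noiseless derived trait carries the configured standardized effect (up
to the mild log/closure nonlinearity).

Everything injected is kept in a :class:`TruthRecord` for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import ceil

import numpy as np
import pandas as pd
from scipy.stats import norm

from .peaktable import PeakTable, validate_sample_frame
from .traits import TraitAnnotation, default_annotation, derive_traits


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Effect:
    """Standardized effect of a covariate on a derived trait (or peak)."""

    target: str      # derived trait name or peak id
    covariate: str   # 'age', 'sex', BMI ('bmi') or a phenotype name
    beta: float      # standardized (correlation-scale) effect


@dataclass
class PhenotypeSpec:
    """Marginal distribution and age/sex/BMI correlation of one phenotype.

    Continuous phenotypes are Gaussian (or log-normal) with the given median
    and IQR; binary phenotypes threshold the latent Gaussian at the given
    prevalence, and effects on them are specified on the latent scale.
    """

    median: float = 0.0
    iqr: tuple[float, float] = (-0.6745, 0.6745)
    log_scale: bool = False
    rho_age: float = 0.0
    rho_sex: float = 0.0
    rho_bmi: float = 0.0
    binary: bool = False
    prevalence: float = 0.5


DEFAULT_PHENOTYPES: dict[str, PhenotypeSpec] = {
    "hdl": PhenotypeSpec(1.50, (1.30, 1.70), rho_age=0.05, rho_sex=-0.25, rho_bmi=-0.25),
    "insulin": PhenotypeSpec(6.2, (4.3, 9.0), log_scale=True, rho_age=0.10, rho_bmi=0.45),
    "triglyc": PhenotypeSpec(1.20, (0.90, 1.60), log_scale=True,
                             rho_age=0.15, rho_sex=0.10, rho_bmi=0.35),
    "tot_chol": PhenotypeSpec(5.70, (5.00, 6.70), rho_age=0.30),
    "fibrinogen": PhenotypeSpec(3.30, (2.80, 3.90), rho_age=0.25, rho_bmi=0.20),
    "uric": PhenotypeSpec(300.0, (250.0, 360.0), rho_sex=0.40, rho_bmi=0.25),
    "hba1c": PhenotypeSpec(5.30, (5.00, 5.60), rho_age=0.35, rho_bmi=0.20),
    "waist": PhenotypeSpec(92.0, (83.0, 101.0), rho_sex=0.30, rho_bmi=0.75),
    "arth_sr": PhenotypeSpec(binary=True, prevalence=0.05, rho_age=0.30, rho_sex=-0.15),
}

#: default injected effects for the transferrin preset: the strongest
#: age/sex associations and one biochemical association at their reported
#: correlation magnitudes (sex coded M=1, so "higher in females" is negative)
DEFAULT_TF_EFFECTS = (
    Effect("A4", "age", 0.278),
    Effect("S1", "age", -0.262),
    Effect("B", "sex", -0.331),
    Effect("S2", "hdl", -0.129),
)

_TF_BASELINE = {
    "Tf_GP1": 0.7, "Tf_GP2": 0.5, "Tf_GP3": 0.4, "Tf_GP4": 0.5, "Tf_GP5": 0.4,
    "Tf_GP6": 0.6, "Tf_GP7": 0.4, "Tf_GP8": 0.4, "Tf_GP9": 1.2, "Tf_GP10": 0.6,
    "Tf_GP11": 0.3, "Tf_GP12": 0.8, "Tf_GP13": 9.0, "Tf_GP14": 3.0, "Tf_GP15": 1.2,
    "Tf_GP16": 0.3, "Tf_GP17": 14.0, "Tf_GP18": 3.0, "Tf_GP19": 28.0, "Tf_GP20": 10.0,
    "Tf_GP21": 2.5, "Tf_GP22": 0.8, "Tf_GP23": 2.0, "Tf_GP24": 2.5, "Tf_GP25": 1.2,
    "Tf_GP26": 2.5, "Tf_GP27": 2.0, "Tf_GP28": 1.2, "Tf_GP29": 2.0, "Tf_GP30": 2.0,
    "Tf_GP31": 1.0, "Tf_GP32": 0.8, "Tf_GP33": 1.5, "Tf_GP34": 1.5, "Tf_GP35": 1.2,
}

_IGG_BASELINE = {
    "IgG_GP1": 4.0, "IgG_GP2": 1.0, "IgG_GP3": 0.5, "IgG_GP4": 20.0, "IgG_GP5": 0.3,
    "IgG_GP6": 4.0, "IgG_GP7": 0.3, "IgG_GP8": 5.0, "IgG_GP9": 18.0, "IgG_GP10": 2.0,
    "IgG_GP11": 4.0, "IgG_GP12": 1.0, "IgG_GP13": 0.5, "IgG_GP14": 16.0, "IgG_GP15": 2.0,
    "IgG_GP16": 1.0, "IgG_GP17": 1.5, "IgG_GP18": 9.0, "IgG_GP19": 2.0, "IgG_GP20": 1.0,
    "IgG_GP21": 1.0, "IgG_GP22": 0.5, "IgG_GP23": 4.0, "IgG_GP24": 1.4,
}


@dataclass
class CohortConfig:
    """Full specification of one synthetic cohort."""

    cohort_id: str = "COHORT"
    n_samples: int = 500
    panel: str = "Tf"
    plate_size: int = 96
    standards_per_plate: int = 6
    blanks_per_plate: int = 1
    replicate_fraction: float = 0.0
    replicate_same_plate: bool = True
    age_range: tuple[float, float] = (18.0, 90.0)
    sex_ratio: float = 0.6           # proportion female
    baseline_composition: pd.Series | None = None
    effect_table: tuple[Effect, ...] = ()
    trait_sd: float = 0.15           # log-scale SD of each targeted trait group
    peak_sd: float = 0.05            # idiosyncratic biological log-SD per peak
    batch_sd: float = 0.10           # per-(plate, peak) multiplicative effect, log SD
    noise_sd: float = 0.05           # technical log-SD per measurement
    sample_scale_sd: float = 0.30    # per-sample injection-amount log-SD
    missing_rate: float = 0.02       # phenotype missingness (cohort rows)
    phenotypes: dict[str, PhenotypeSpec] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPES))
    annotation: TraitAnnotation | None = None

    def __post_init__(self) -> None:
        if self.annotation is None:
            self.annotation = default_annotation(self.panel)
        if self.baseline_composition is None:
            table = _TF_BASELINE if self.panel.lower() in ("tf", "transferrin") else _IGG_BASELINE
            self.baseline_composition = pd.Series(table, dtype=float)
        else:
            self.baseline_composition = pd.Series(self.baseline_composition, dtype=float)
            if list(self.baseline_composition.index) != list(self.annotation.peak_ids):
                self.baseline_composition.index = self.annotation.peak_ids
        base = self.baseline_composition
        if (base <= 0).any():
            raise ValueError("baseline composition entries must be positive")
        if abs(base.sum() - 100.0) > 1e-9:
            raise ValueError(f"baseline composition must sum to 100 (got {base.sum()!r})")
        if not (0 <= self.replicate_fraction < 0.5):
            raise ValueError("replicate_fraction must be in [0, 0.5)")
        if not (4 <= self.standards_per_plate <= 6):
            raise ValueError("standards_per_plate must be in [4, 6]")
        overhead = self.standards_per_plate + self.blanks_per_plate
        if self.plate_size < overhead + 1:
            raise ValueError("plate_size too small for standards + blanks + 1 sample")
        for eff in self.effect_table:
            self._resolve_target(eff.target)
        for target, effs in self._grouped_effects().items():
            ssq = sum(e.beta ** 2 for e in effs)
            if ssq > 1.0:
                raise ValueError(
                    f"effects on target {target!r} imply correlation > 1 (sum beta^2 = {ssq:.3f})")

    @property
    def n_peaks(self) -> int:
        return self.annotation.n_peaks

    def _resolve_target(self, target: str) -> list[str]:
        """Peak ids a trait- or peak-level effect acts on."""
        if target in self.annotation.peak_ids:
            return [target]
        try:
            members = self.annotation.members(target)
        except KeyError:
            raise ValueError(
                f"effect target {target!r} is neither a peak id nor a derived trait")
        if not members:
            raise ValueError(f"derived trait {target!r} has no member peaks")
        return members

    def _grouped_effects(self) -> dict[str, list[Effect]]:
        groups: dict[str, list[Effect]] = {}
        for eff in self.effect_table:
            groups.setdefault(eff.target, []).append(eff)
        return groups

    @property
    def n_replicates(self) -> int:
        return int(round(self.replicate_fraction * self.n_samples))

    @property
    def n_plates(self) -> int:
        capacity = self.plate_size - self.standards_per_plate - self.blanks_per_plate
        return ceil((self.n_samples + self.n_replicates) / capacity)

    def to_dict(self) -> dict:
        d = {
            "cohort_id": self.cohort_id, "n_samples": self.n_samples,
            "panel": self.panel, "plate_size": self.plate_size,
            "standards_per_plate": self.standards_per_plate,
            "blanks_per_plate": self.blanks_per_plate,
            "replicate_fraction": self.replicate_fraction,
            "replicate_same_plate": self.replicate_same_plate,
            "age_range": list(self.age_range), "sex_ratio": self.sex_ratio,
            "trait_sd": self.trait_sd, "peak_sd": self.peak_sd,
            "batch_sd": self.batch_sd, "noise_sd": self.noise_sd,
            "sample_scale_sd": self.sample_scale_sd,
            "missing_rate": self.missing_rate,
            "effect_table": [asdict(e) for e in self.effect_table],
            "baseline_composition": self.baseline_composition.to_dict(),
            "phenotypes": {k: asdict(v) for k, v in self.phenotypes.items()},
        }
        return d


def korcula_config(**overrides) -> CohortConfig:
    """Discovery-cohort preset: 927 samples, 96-well plates, ~10% duplicates.

    replicate_fraction 0.115 yields 107 duplicate pairs and 12 plates with
    6 standards each (72 standards), matching the published QC layout.
    """
    kw = dict(cohort_id="KOR", n_samples=927, panel="Tf", plate_size=96,
              standards_per_plate=6, blanks_per_plate=1, replicate_fraction=0.115,
              sex_ratio=0.65, effect_table=DEFAULT_TF_EFFECTS)
    kw.update(overrides)
    return CohortConfig(**kw)


def viking_config(**overrides) -> CohortConfig:
    """Replication-cohort preset: 958 samples, 60-well batches, no duplicates."""
    kw = dict(cohort_id="VIK", n_samples=958, panel="Tf", plate_size=60,
              standards_per_plate=4, blanks_per_plate=1, replicate_fraction=0.0,
              sex_ratio=0.60, effect_table=DEFAULT_TF_EFFECTS)
    kw.update(overrides)
    return CohortConfig(**kw)


# ---------------------------------------------------------------------------
# Truth record
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Everything injected by the generator, for recovery tests."""

    config: dict
    covariate_z: pd.DataFrame       # standardized covariates/latents, cohort samples
    group_deltas: pd.DataFrame      # per-sample latent of each targeted group
    true_log: pd.DataFrame          # noiseless log abundances (cohort+std+replicates)
    batch_offsets: pd.DataFrame     # plates x peaks
    true_percent: pd.DataFrame      # noiseless percent areas, cohort samples

    def true_traits(self, annotation: TraitAnnotation) -> pd.DataFrame:
        pt = PeakTable(self.true_percent, scale="percent_area")
        return derive_traits(pt, annotation)

    def to_json(self, path) -> None:
        payload = {
            "config": self.config,
            "covariate_z": self.covariate_z.to_dict(orient="split"),
            "group_deltas": self.group_deltas.to_dict(orient="split"),
            "true_log": self.true_log.to_dict(orient="split"),
            "batch_offsets": self.batch_offsets.to_dict(orient="split"),
            "true_percent": self.true_percent.to_dict(orient="split"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# Plate assignment
# ---------------------------------------------------------------------------

def assign_plates(
    samples: pd.DataFrame,
    plate_size: int,
    blocking: tuple[str, ...] = ("sex", "age"),
    n_plates: int | None = None,
    reserved_per_plate: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Distribute cohort samples over plates, blocked on the given covariates.

    Stratifies on the blocking covariates (categorical columns by level,
    numeric columns by tertile), shuffles within strata and deals samples
    round-robin across plates, so per-plate sex proportions and age means
    are balanced by construction.  ``reserved_per_plate`` wells are kept free
    for standards/blanks when computing the default plate count.
    """
    if reserved_per_plate + 1 > plate_size:
        raise ValueError("plate_size smaller than standards + blanks + 1")
    missing = [c for c in blocking if c not in samples.columns]
    if missing:
        raise ValueError(f"blocking covariates not present: {missing}")
    capacity = plate_size - reserved_per_plate
    if n_plates is None:
        n_plates = ceil(len(samples) / capacity)
    rng = rng if rng is not None else np.random.default_rng(0)

    strata = pd.Series("", index=samples.index)
    for col in blocking:
        vals = samples[col]
        if vals.dtype.kind in "fiu" and vals.nunique() > 3:
            binned = pd.qcut(vals, 3, labels=False, duplicates="drop").astype(str)
        else:
            binned = vals.astype(str)
        strata = strata + "|" + binned

    order: list = []
    for _, idx in samples.groupby(strata).groups.items():
        idx = list(idx)
        rng.shuffle(idx)
        order.extend(idx)
    assignment = pd.Series(
        [i % n_plates for i in range(len(order))], index=order, dtype=int
    ).reindex(samples.index)
    return assignment


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _phenotype_latents(
    spec: PhenotypeSpec, z_age: np.ndarray, z_sex: np.ndarray, z_bmi: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    ssq = spec.rho_age ** 2 + spec.rho_sex ** 2 + spec.rho_bmi ** 2
    if ssq > 1:
        raise ValueError("phenotype correlations with age/sex/BMI imply variance > 1")
    resid = np.sqrt(1.0 - ssq)
    return (spec.rho_age * z_age + spec.rho_sex * z_sex + spec.rho_bmi * z_bmi
            + resid * rng.standard_normal(z_age.shape))


def _phenotype_value(spec: PhenotypeSpec, latent: np.ndarray) -> np.ndarray:
    if spec.binary:
        return (latent > norm.ppf(1.0 - spec.prevalence)).astype(float)
    q1, q3 = spec.iqr
    if spec.log_scale:
        sd = (np.log(q3) - np.log(q1)) / (2 * norm.ppf(0.75))
        return np.exp(np.log(spec.median) + sd * latent)
    sd = (q3 - q1) / (2 * norm.ppf(0.75))
    return spec.median + sd * latent


def generate_cohort(
    config: CohortConfig, seed: int
) -> tuple[pd.DataFrame, PeakTable, TruthRecord]:
    """Generate one cohort: sample frame, raw-area peak table and truth.

    Fully deterministic given ``(config, seed)``.
    """
    rng = np.random.default_rng(seed)
    ann = config.annotation
    peaks = list(ann.peak_ids)
    n = config.n_samples
    ids = [f"{config.cohort_id}_S{i + 1:04d}" for i in range(n)]

    # --- demographics ----------------------------------------------------
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n)
    male = rng.random(n) >= config.sex_ratio          # M coded 1
    z_age = (age - age.mean()) / age.std()
    z_sex = (male - male.mean()) / male.std() if 0 < male.mean() < 1 else np.zeros(n)
    z_bmi_lat = 0.2 * z_age + np.sqrt(1 - 0.04) * rng.standard_normal(n)
    bmi = np.exp(np.log(26.6) + 0.16 * z_bmi_lat)

    covariate_z = pd.DataFrame({"age": z_age, "sex": z_sex, "bmi": z_bmi_lat}, index=ids)
    samples = pd.DataFrame({
        "cohort_id": config.cohort_id,
        "role": "cohort",
        "replicate_of": pd.NA,
        "age": age,
        "sex": np.where(male, "M", "F"),
        "bmi": bmi,
    }, index=pd.Index(ids, name="sample_id"))

    # --- phenotypes -------------------------------------------------------
    for name, spec in config.phenotypes.items():
        latent = _phenotype_latents(spec, z_age, z_sex, z_bmi_lat, rng)
        covariate_z[name] = latent
        samples[name] = _phenotype_value(spec, latent)

    # --- group latents carrying the injected effects ----------------------
    grouped = config._grouped_effects()
    deltas = pd.DataFrame(index=ids, dtype=float)
    for target, effs in grouped.items():
        lin = np.zeros(n)
        ssq = 0.0
        for e in effs:
            z = covariate_z[e.covariate].to_numpy()
            lin = lin + e.beta * z
            ssq += e.beta ** 2
        eps = rng.standard_normal(n)
        deltas[target] = config.trait_sd * (lin + np.sqrt(max(1.0 - ssq, 0.0)) * eps)

    # --- noiseless log abundances (cohort) --------------------------------
    log_base = np.log(config.baseline_composition.to_numpy())
    true_log = np.tile(log_base, (n, 1))
    for target in deltas.columns:
        members = config._resolve_target(target)
        cols = [peaks.index(p) for p in members]
        true_log[:, cols] += deltas[target].to_numpy()[:, None]
    if config.peak_sd > 0:
        true_log += config.peak_sd * rng.standard_normal((n, len(peaks)))
    true_log_df = pd.DataFrame(true_log, index=ids, columns=peaks)

    # --- replicates and plates --------------------------------------------
    n_rep = config.n_replicates
    rep_sources = list(rng.choice(ids, size=n_rep, replace=False)) if n_rep else []
    overhead = config.standards_per_plate + config.blanks_per_plate
    plates = assign_plates(
        samples, config.plate_size,
        blocking=("sex", "age"),
        n_plates=config.n_plates,
        reserved_per_plate=overhead,
        rng=rng,
    )
    samples["plate_id"] = plates
    n_plates = config.n_plates
    capacity = config.plate_size - overhead
    load = plates.value_counts().reindex(range(n_plates), fill_value=0)

    rows = [samples]
    extra_z = {}
    rep_plate = {}
    for j, src in enumerate(rep_sources):
        rid = f"{config.cohort_id}_R{j + 1:04d}"
        plate = int(samples.loc[src, "plate_id"])
        if (not config.replicate_same_plate) or load[plate] >= capacity:
            plate = int(load.idxmin())
        load[plate] += 1
        rep_plate[rid] = plate
        row = samples.loc[[src]].copy()
        row.index = [rid]
        row["role"] = "replicate"
        row["replicate_of"] = src
        row["plate_id"] = plate
        rows.append(row)

    std_ids, blank_ids, tech_plate = [], [], {}
    for p in range(n_plates):
        for s in range(config.standards_per_plate):
            sid = f"{config.cohort_id}_STD_P{p:02d}_{s + 1}"
            std_ids.append(sid)
            tech_plate[sid] = p
        for b in range(config.blanks_per_plate):
            bid = f"{config.cohort_id}_BLK_P{p:02d}_{b + 1}"
            blank_ids.append(bid)
            tech_plate[bid] = p
    tech = pd.DataFrame({
        "cohort_id": config.cohort_id,
        "role": ["standard"] * len(std_ids) + ["blank"] * len(blank_ids),
        "replicate_of": pd.NA,
        "age": np.nan, "sex": pd.NA, "bmi": np.nan,
        "plate_id": [tech_plate[i] for i in std_ids + blank_ids],
    }, index=pd.Index(std_ids + blank_ids, name="sample_id"))
    for name in config.phenotypes:
        tech[name] = np.nan
    samples = pd.concat(rows + [tech])
    samples["plate_id"] = samples["plate_id"].astype(int)

    # --- phenotype missingness -------------------------------------------
    if config.missing_rate > 0:
        for name in config.phenotypes:
            mask = rng.random(n) < config.missing_rate
            samples.loc[np.array(ids)[mask], name] = np.nan

    # --- measurement model -------------------------------------------------
    batch_offsets = pd.DataFrame(
        rng.normal(0.0, config.batch_sd, size=(n_plates, len(peaks))),
        index=pd.RangeIndex(n_plates, name="plate_id"), columns=peaks,
    )

    # true log for replicates (copy of source) and standards (baseline pool)
    all_true = [true_log_df]
    rep_ids = [f"{config.cohort_id}_R{j + 1:04d}" for j in range(n_rep)]
    if rep_ids:
        rep_true = true_log_df.loc[rep_sources].copy()
        rep_true.index = rep_ids
        all_true.append(rep_true)
    if std_ids:
        std_true = pd.DataFrame(np.tile(log_base, (len(std_ids), 1)),
                                index=std_ids, columns=peaks)
        all_true.append(std_true)
    true_all = pd.concat(all_true)

    measured = samples.index[samples["role"] != "blank"]
    m = len(measured)
    plate_of = samples.loc[measured, "plate_id"].to_numpy()
    log_meas = (
        true_all.loc[measured].to_numpy()
        + batch_offsets.to_numpy()[plate_of, :]
        + config.noise_sd * rng.standard_normal((m, len(peaks)))
        + config.sample_scale_sd * rng.standard_normal((m, 1))
    )
    raw = pd.DataFrame(0.0, index=samples.index, columns=peaks)
    raw.loc[measured] = np.exp(log_meas)

    table = PeakTable(values=raw, scale="raw_area",
                      batches=samples["plate_id"])
    validate_sample_frame(samples, plate_size=config.plate_size)

    pct = np.exp(true_log)
    pct = 100.0 * pct / pct.sum(axis=1, keepdims=True)
    truth = TruthRecord(
        config=config.to_dict(),
        covariate_z=covariate_z,
        group_deltas=deltas,
        true_log=true_all,
        batch_offsets=batch_offsets,
        true_percent=pd.DataFrame(pct, index=ids, columns=peaks),
    )
    return samples, table, truth
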