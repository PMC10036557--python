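"""Core in-memory containers for glycan peak data.

A :class:`PeakTable` is a samples x peaks matrix of chromatographic peak
quantities together with a scale tag recording where in the preprocessing
chain the values sit (``raw_area`` -> ``percent_area`` -> ``log`` ->
``log_batch_corrected``) and a per-sample batch (plate) label.

Sample metadata (age, sex, BMI, biochemical phenotypes, sample role) live in
a plain :class:`pandas.DataFrame` indexed by sample id — the "sample frame".
Helper functions here validate and split it rather than wrapping it in a
custom class, so users keep the full pandas API.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: allowed value scales, in pipeline order
SCALES = ("raw_area", "percent_area", "log", "log_batch_corrected")

#: allowed sample roles
ROLES = ("cohort", "standard", "replicate", "blank")

#: sample-frame columns that are not phenotypes
META_COLUMNS = ("cohort_id", "role", "replicate_of", "plate_id", "age", "sex", "bmi")


@dataclass
class PeakTable:
    """Samples x peaks matrix of glycan peak quantities.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with one column per peak id.
    scale
        One of :data:`SCALES`.
    batches
        Optional per-sample batch (plate) labels aligned with ``values``.
    """

    values: pd.DataFrame
    scale: str = "raw_area"
    batches: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate peak ids: {dups}")
        if self.batches is not None:
            self.batches = pd.Series(self.batches)
            if not self.batches.index.equals(self.values.index):
                self.batches = self.batches.reindex(self.values.index)
                if self.batches.isna().any():
                    missing = self.batches.index[self.batches.isna()].tolist()
                    raise ValueError(f"batch labels missing for samples: {missing[:5]}")
        self.validate()

    # -- basic protocol ----------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def peak_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return len(self.values.index)

    @property
    def n_peaks(self) -> int:
        return len(self.values.columns)

    def validate(self) -> None:
        """Check the invariants implied by the scale tag."""
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("peak table contains non-finite values")
        if self.scale in ("raw_area", "percent_area") and (arr < 0).any():
            raise ValueError(f"negative values not allowed on scale {self.scale!r}")
        if self.scale == "percent_area":
            sums = arr.sum(axis=1)
            if not np.allclose(sums, 100.0, atol=1e-6):
                bad = self.values.index[~np.isclose(sums, 100.0, atol=1e-6)]
                raise ValueError(
                    f"percent-area rows must sum to 100; offending samples: {list(bad[:5])}"
                )

    def with_values(self, values: pd.DataFrame, scale: str) -> "PeakTable":
        """Return a new table sharing this table's batch labels."""
        batches = None
        if self.batches is not None:
            batches = self.batches.reindex(values.index)
        return PeakTable(values=values, scale=scale, batches=batches)

    def subset(self, sample_ids: Iterable) -> "PeakTable":
        ids = pd.Index(sample_ids)
        return PeakTable(
            values=self.values.loc[ids],
            scale=self.scale,
            batches=None if self.batches is None else self.batches.loc[ids],
        )


def validate_sample_frame(samples: pd.DataFrame, plate_size: int | None = None) -> None:
    """Validate a sample frame against the container contract.

    Checks roles, replicate back-references, absence of phenotypes on
    standards/blanks and (optionally) per-plate well counts.
    """
    if samples.index.has_duplicates:
        dups = samples.index[samples.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    unknown = set(samples["role"]) - set(ROLES)
    if unknown:
        raise ValueError(f"unknown sample roles: {sorted(unknown)}")
    reps = samples[samples["role"] == "replicate"]
    cohort_ids = set(samples.index[samples["role"] == "cohort"])
    for sid, src in reps["replicate_of"].items():
        if src not in cohort_ids:
            raise ValueError(f"replicate {sid!r} references unknown cohort sample {src!r}")
        if samples.loc[src, "cohort_id"] != samples.loc[sid, "cohort_id"]:
            raise ValueError(f"replicate {sid!r} crosses cohorts")
    pheno_cols = phenotype_columns(samples)
    tech = samples[samples["role"].isin(["standard", "blank"])]
    if pheno_cols and len(tech) and tech[pheno_cols].notna().any().any():
        raise ValueError("standards/blanks must not carry phenotype values")
    if plate_size is not None:
        counts = samples.groupby("plate_id").size()
        if (counts > plate_size).any():
            bad = counts[counts > plate_size].index.tolist()
            raise ValueError(f"plates over capacity {plate_size}: {bad}")


def phenotype_columns(samples: pd.DataFrame) -> list[str]:
    """Columns of a sample frame that hold biochemical/physiological traits."""
    return [c for c in samples.columns if c not in META_COLUMNS]


def split_roles(
    samples: pd.DataFrame, table: PeakTable
) -> dict[str, PeakTable]:
    """Split a peak table into per-role sub-tables keyed by role name."""
    out = {}
    for role in ROLES:
        ids = samples.index[samples["role"] == role]
        ids = ids.intersection(table.sample_ids)
        if len(ids):
            out[role] = table.subset(ids)
    return out


def replicate_pairs(
    samples: pd.DataFrame, table: PeakTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align replicate measurements with their source measurements.

    Returns two DataFrames (first member, second member) with identical shape,
    one row per replicate pair, columns = peak ids.
    """
    reps = samples[samples["role"] == "replicate"]
    reps = reps[reps.index.isin(table.sample_ids) & reps["replicate_of"].isin(table.sample_ids)]
    if reps.empty:
        empty = pd.DataFrame(columns=table.peak_ids)
        return empty, empty.copy()
    first = table.values.loc[reps["replicate_of"].to_numpy()]
    second = table.values.loc[reps.index]
    first.index = reps.index
    return first, second
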