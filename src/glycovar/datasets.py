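"""Small published reference datasets shipped with the package.

``TABLE2_ROWS`` holds the published age-, sex- and BMI-adjusted association
estimates of derived transferrin N-glycome traits with biochemical and
physiological phenotypes in the two cohorts (discovery: Korcula;
replication: VIKING), as printed: per-cohort standardized effect and
standard error, and the reported inverse-variance fixed-effects combination.
Rows where the discovery cohort lacked the phenotype carry ``None`` and the
meta column equals the replication cohort.  These printed pairs are the
worked examples for the meta-analysis routine: the combination is fully
determined by the per-cohort (effect, SE) inputs.

Phenotype keys follow the published spelling (including ``fbrinogen`` in
one row).
"""

from __future__ import annotations

from typing import NamedTuple


class Table2Row(NamedTuple):
    glycan: str
    phenotype: str
    korcula: tuple[float, float] | None   # (effect, SE) or None when unavailable
    viking: tuple[float, float] | None
    meta: tuple[float, float]             # printed combined (effect, SE)


TABLE2_ROWS: list[Table2Row] = [
    Table2Row("S2", "insulin", None, (0.248, 0.034), (0.248, 0.034)),
    Table2Row("S1", "insulin", None, (-0.234, 0.034), (-0.234, 0.034)),
    Table2Row("G2", "hdl", (-0.203, 0.035), (-0.114, 0.037), (-0.162, 0.025)),
    Table2Row("A2", "hdl", (-0.204, 0.035), (-0.112, 0.037), (-0.160, 0.025)),
    Table2Row("A3", "hdl", (0.181, 0.036), (0.127, 0.036), (0.155, 0.026)),
    Table2Row("G3", "hdl", (0.181, 0.036), (0.127, 0.036), (0.155, 0.026)),
    Table2Row("S1", "fbrinogen", (-0.103, 0.033), (-0.151, 0.032), (-0.128, 0.023)),
    Table2Row("S2", "hdl", (-0.106, 0.035), (-0.150, 0.033), (-0.129, 0.024)),
    Table2Row("S2", "hba1c", (0.158, 0.035), (0.086, 0.034), (0.121, 0.024)),
    Table2Row("S0", "insulin", None, (-0.178, 0.036), (-0.178, 0.036)),
    Table2Row("S3", "tot_chol", (0.109, 0.036), (0.124, 0.035), (0.117, 0.025)),
    Table2Row("F", "fibrinogen", (0.109, 0.035), (0.120, 0.035), (0.114, 0.025)),
    Table2Row("S3", "hdl", (0.142, 0.037), (0.094, 0.037), (0.118, 0.026)),
    Table2Row("HM", "insulin", None, (-0.162, 0.036), (-0.162, 0.036)),
    Table2Row("S0", "triglyc", (-0.094, 0.035), (-0.118, 0.034), (-0.106, 0.024)),
    Table2Row("A4", "fibrinogen", (0.114, 0.033), (0.087, 0.035), (0.102, 0.024)),
    Table2Row("G4", "fibrinogen", (0.114, 0.033), (0.087, 0.035), (0.102, 0.024)),
    Table2Row("G2", "uric", (0.192, 0.040), (0.045, 0.041), (0.120, 0.029)),
    Table2Row("S1", "hba1c", (-0.129, 0.036), (-0.077, 0.034), (-0.102, 0.025)),
    Table2Row("G1", "triglyc", (-0.093, 0.034), (-0.105, 0.034), (-0.099, 0.024)),
    Table2Row("G1", "arth_sr", (0.380, 0.130), (0.316, 0.115), (0.344, 0.086)),
    Table2Row("A2", "uric", (0.187, 0.041), (0.040, 0.041), (0.115, 0.029)),
    Table2Row("S0", "waist", (-0.120, 0.060), (-0.250, 0.071), (-0.175, 0.046)),
]
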