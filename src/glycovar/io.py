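"""CSV dialect for sample frames, peak tables and result bundles.

One flat CSV per table: UTF-8, comma-separated, header row, samples as rows.
Sample metadata columns are prefixed ``meta_`` (``meta_role``, ``meta_age``,
...); every unprefixed column after ``sample_id`` is a peak.  Missing values
are empty fields.  Leading ``#`` lines are comments; writers stamp a comment
carrying the config hash and seed so every output is traceable to its run.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json

import numpy as np
import pandas as pd

from .peaktable import PeakTable

META_PREFIX = "meta_"


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_peak_table(path, samples: pd.DataFrame, table: PeakTable,
                     comment: str | None = None) -> None:
    """Write samples x peaks CSV with ``meta_``-prefixed metadata columns."""
    meta = samples.loc[table.sample_ids].copy()
    meta.columns = [META_PREFIX + c for c in meta.columns]
    out = pd.concat([meta, table.values], axis=1)
    out.index.name = "sample_id"
    with open(path, "w", newline="") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(f"# scale={table.scale}\n")
        out.to_csv(fh)


def read_peak_table(path) -> tuple[pd.DataFrame, PeakTable]:
    """Read the peak-table CSV dialect back into (sample frame, PeakTable).

    Errors name the offending row/column: duplicated sample ids, malformed
    header (no ``sample_id``), and non-numeric peak cells all raise.
    """
    scale = "raw_area"
    with open(path) as fh:
        head = []
        for line in fh:
            if line.startswith("#"):
                if "scale=" in line:
                    scale = line.split("scale=")[1].strip()
                continue
            head.append(line)
            break
        df = pd.read_csv(_stdio.StringIO("".join(head) + fh.read()), dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError("malformed header: missing 'sample_id' column")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate sample_id: {dup.iloc[0]!r}")
    df = df.set_index("sample_id")
    meta_cols = [c for c in df.columns if c.startswith(META_PREFIX)]
    peak_cols = [c for c in df.columns if not c.startswith(META_PREFIX)]
    samples = df[meta_cols].copy()
    samples.columns = [c[len(META_PREFIX):] for c in samples.columns]
    for col in ("age", "bmi"):
        if col in samples.columns:
            samples[col] = pd.to_numeric(samples[col], errors="coerce")
    if "plate_id" in samples.columns:
        samples["plate_id"] = pd.to_numeric(samples["plate_id"],
                                            errors="coerce").astype("Int64")
    pheno_cols = [c for c in samples.columns
                  if c not in ("cohort_id", "role", "replicate_of", "plate_id",
                               "age", "sex", "bmi")]
    for col in pheno_cols:
        samples[col] = pd.to_numeric(samples[col], errors="coerce")
    values = pd.DataFrame(index=df.index)
    for col in peak_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-numeric peak value at row {row!r}, column {col!r}: "
                f"{df.loc[row, col]!r}")
        values[col] = converted
    values = values.fillna(0.0)
    batches = None
    if "plate_id" in samples.columns and samples["plate_id"].notna().all():
        batches = samples["plate_id"].astype(int)
    table = PeakTable(values=values, scale=scale, batches=batches)
    return samples, table


def validate_panel_width(table: PeakTable, panel: str) -> None:
    """Check the peak count against the declared panel (Tf: 35, IgG: 24)."""
    expected = {"tf": 35, "igg": 24}[panel.lower()]
    if table.n_peaks != expected:
        raise ValueError(
            f"{panel} panel expects {expected} peak columns, found {table.n_peaks}")


def write_table(path, df: pd.DataFrame, comment: str | None = None,
                index: bool = False) -> None:
    """Write a tidy result table with an optional traceability comment."""
    with open(path, "w", newline="") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, index=index)


def read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


def write_windows_csv(path, windows) -> None:
    rows = [{"peak_id": w.peak_id, "start_gu": w.start, "end_gu": w.end,
             "structure": w.structure or ""} for w in windows]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_windows_csv(path):
    from .chromatography import PeakWindow

    df = pd.read_csv(path, comment="#")
    need = {"peak_id", "start_gu", "end_gu"}
    if not need.issubset(df.columns):
        raise ValueError(f"window CSV must have columns {sorted(need)}")
    return [PeakWindow(peak_id=r.peak_id, start=float(r.start_gu),
                       end=float(r.end_gu),
                       structure=getattr(r, "structure", None) or None)
            for r in df.itertuples()]


def read_ladder_csv(path):
    from .chromatography import DextranLadder

    df = pd.read_csv(path, comment="#")
    need = {"gu", "retention_time"}
    if not need.issubset(df.columns):
        raise ValueError(f"ladder CSV must have columns {sorted(need)}")
    return DextranLadder([(int(r.gu), float(r.retention_time))
                          for r in df.itertuples()])


def read_chromatogram_csv(path):
    from .chromatography import Chromatogram

    df = pd.read_csv(path, comment="#")
    need = {"time_min", "signal_eu"}
    if not need.issubset(df.columns):
        raise ValueError(f"chromatogram CSV must have columns {sorted(need)}")
    return Chromatogram(time=df["time_min"].to_numpy(),
                        signal=df["signal_eu"].to_numpy())


def write_chromatogram_csv(path, chrom) -> None:
    pd.DataFrame({"time_min": chrom.time, "signal_eu": chrom.signal}).to_csv(
        path, index=False)
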