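"""Structural peak annotation and derived glycosylation traits.

Each chromatographic peak of a HILIC-UHPLC glycan profile is dominated by one
glycan structure, characterized by branching (antennarity), galactosylation,
sialylation (with sialic-acid linkage), core fucosylation, bisecting GlcNAc
and the high-mannose class.  Derived traits are sums of percent areas over
peaks sharing a feature: they track the activity of individual
glycosyltransferases more directly than single peaks do.

The default transferrin panel (35 peaks) and IgG panel (24 peaks) shipped
here pin the dominant structures reported for the major transferrin peaks
(M5 in GP1, A2G2S[6]1 in GP13, A2G2S[3,6]2 in GP17, A2G2S[6,6]2 in GP19,
FA2G2S[6,6]2 in GP20, F2A4G4S[3,3]2 in GP33); the remaining assignments are
plausible placeholders and both panels are fully overridable via CSV.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaktable import PeakTable

#: the fifteen standard derived traits
DERIVED_TRAIT_NAMES = (
    "A2", "A3", "A4", "HM",
    "G0", "G1", "G2", "G3", "G4",
    "F", "B",
    "S0", "S1", "S2", "S3",
)

#: families of traits that partition the peak set (each plus HM covers all peaks)
PARTITION_FAMILIES = {
    "antennarity": ("A2", "A3", "A4", "HM"),
    "galactosylation": ("G0", "G1", "G2", "G3", "G4", "HM"),
    "sialylation": ("S0", "S1", "S2", "S3", "HM"),
}

ANNOTATION_COLUMNS = [
    "peak_id", "antennae", "gal", "sia", "sia_linkages", "fucose",
    "bisecting", "high_mannose", "structure", "hex", "hexnac", "dhex", "neuac",
]


@dataclass
class TraitAnnotation:
    """Per-peak structural features and the derived-trait membership map.

    ``table`` is indexed by peak id with columns as in
    :data:`ANNOTATION_COLUMNS` (minus ``peak_id``).  High-mannose peaks carry
    ``antennae = 0`` internally and are excluded from the complex-type trait
    classes.
    """

    table: pd.DataFrame
    user_traits: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate peak ids in annotation: {dups}")
        hm = t["high_mannose"].astype(bool)
        bad = t.index[hm & ((t["sia"] != 0) | (t["gal"] != 0))].tolist()
        if bad:
            raise ValueError(f"high-mannose peaks must have 0 sialic acids and 0 galactoses: {bad}")
        complex_rows = t[~hm]
        bad = complex_rows.index[complex_rows["gal"] > complex_rows["antennae"]].tolist()
        if bad:
            raise ValueError(f"galactose count exceeds antennae for peaks: {bad}")
        if not set(complex_rows["antennae"]).issubset({2, 3, 4}):
            raise ValueError("complex-type antennarity must be 2, 3 or 4")

    @property
    def peak_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_peaks(self) -> int:
        return len(self.table)

    def members(self, trait: str) -> list[str]:
        """Peak ids contributing to a derived trait."""
        t = self.table
        hm = t["high_mannose"].astype(bool)
        if trait in self.user_traits:
            return list(self.user_traits[trait])
        if trait == "HM":
            mask = hm
        elif trait.startswith("A"):
            mask = ~hm & (t["antennae"] == int(trait[1]))
        elif trait.startswith("G"):
            mask = ~hm & (t["gal"] == int(trait[1]))
        elif trait.startswith("S"):
            mask = ~hm & (t["sia"] == int(trait[1]))
        elif trait == "F":
            mask = t["fucose"].astype(bool)
        elif trait == "B":
            mask = t["bisecting"].astype(bool)
        else:
            raise KeyError(f"unknown derived trait {trait!r}")
        return list(t.index[mask])

    def trait_names(self) -> list[str]:
        return list(DERIVED_TRAIT_NAMES) + list(self.user_traits)

    def membership_matrix(self, traits: list[str] | None = None) -> pd.DataFrame:
        """Indicator matrix (peaks x traits) used by :func:`derive_traits`."""
        traits = traits if traits is not None else self.trait_names()
        mat = pd.DataFrame(0.0, index=self.table.index, columns=traits)
        for tr in traits:
            mat.loc[self.members(tr), tr] = 1.0
        return mat

    def to_csv(self, path) -> None:
        out = self.table.reset_index(names="peak_id")
        out.to_csv(path, index=False)


def load_annotation(source) -> TraitAnnotation:
    """Read a peak annotation from CSV (path, file object or string).

    Expected columns: ``peak_id, antennae, gal, sia, sia_linkages, fucose,
    bisecting, high_mannose, structure, hex, hexnac, dhex, neuac``.
    """
    if isinstance(source, str) and "\n" in source:
        source = _io.StringIO(source)
    df = pd.read_csv(source)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if df["peak_id"].isna().any():
        raise ValueError("annotation has rows with missing peak_id")
    df = df.set_index("peak_id")
    df["sia_linkages"] = df["sia_linkages"].fillna("")
    for col in ("fucose", "bisecting", "high_mannose"):
        df[col] = df[col].astype(bool)
    for col in ("antennae", "gal", "sia", "hex", "hexnac", "dhex", "neuac"):
        df[col] = df[col].astype(int)
    return TraitAnnotation(df)


def derive_traits(pt: PeakTable, ann: TraitAnnotation,
                  traits: list[str] | None = None) -> pd.DataFrame:
    """Compute derived traits as shared-feature sums of percent areas.

    Returns a samples x traits DataFrame on the percent scale.  Every peak id
    in the table must be annotated.
    """
    if pt.scale != "percent_area":
        raise ValueError("derived traits are defined on the percent_area scale")
    unmatched = [p for p in pt.peak_ids if p not in ann.peak_ids]
    if unmatched:
        raise ValueError(f"peaks missing from annotation: {unmatched}")
    mat = ann.membership_matrix(traits).loc[pt.peak_ids]
    return pt.values @ mat


# ---------------------------------------------------------------------------
# Default panels
# ---------------------------------------------------------------------------

def _row(peak, structure, ant, gal, sia, link, fuc, bis, hm, dhex=None):
    """Build one annotation row; composition derived from the feature counts."""
    if hm:
        # high-mannose M(n): hex = n, hexnac = 2
        n_man = int(structure[1:])
        hexose, hexnac = n_man, 2
        ant = 0
        dhex = 0
    else:
        hexose = 3 + gal
        hexnac = 2 + ant + (1 if bis else 0)
        if dhex is None:
            dhex = 1 if fuc else 0
    return dict(
        peak_id=peak, antennae=ant, gal=gal, sia=sia, sia_linkages=link,
        fucose=bool(fuc), bisecting=bool(bis), high_mannose=bool(hm),
        structure=structure, hex=hexose, hexnac=hexnac, dhex=dhex, neuac=sia,
    )


_TF_ROWS = [
    # peak, structure, antennae, gal, sia, linkages, fucose, bisecting, HM
    _row("Tf_GP1", "M5", 0, 0, 0, "", 0, 0, 1),
    _row("Tf_GP2", "A2G0", 2, 0, 0, "", 0, 0, 0),
    _row("Tf_GP3", "FA2G0", 2, 0, 0, "", 1, 0, 0),
    _row("Tf_GP4", "FA2BG0", 2, 0, 0, "", 1, 1, 0),
    _row("Tf_GP5", "M6", 0, 0, 0, "", 0, 0, 1),
    _row("Tf_GP6", "A2G1", 2, 1, 0, "", 0, 0, 0),
    _row("Tf_GP7", "FA2G1", 2, 1, 0, "", 1, 0, 0),
    _row("Tf_GP8", "A2BG1", 2, 1, 0, "", 0, 1, 0),
    _row("Tf_GP9", "A2G2", 2, 2, 0, "", 0, 0, 0),
    _row("Tf_GP10", "FA2G2", 2, 2, 0, "", 1, 0, 0),
    _row("Tf_GP11", "M7", 0, 0, 0, "", 0, 0, 1),
    _row("Tf_GP12", "A2G1S[3]1", 2, 1, 1, "a2,3", 0, 0, 0),
    _row("Tf_GP13", "A2G2S[6]1", 2, 2, 1, "a2,6", 0, 0, 0),
    _row("Tf_GP14", "FA2G2S[6]1", 2, 2, 1, "a2,6", 1, 0, 0),
    _row("Tf_GP15", "A2BG2S[6]1", 2, 2, 1, "a2,6", 0, 1, 0),
    _row("Tf_GP16", "M8", 0, 0, 0, "", 0, 0, 1),
    _row("Tf_GP17", "A2G2S[3,6]2", 2, 2, 2, "a2,3;a2,6", 0, 0, 0),
    _row("Tf_GP18", "FA2G2S[3,6]2", 2, 2, 2, "a2,3;a2,6", 1, 0, 0),
    _row("Tf_GP19", "A2G2S[6,6]2", 2, 2, 2, "a2,6;a2,6", 0, 0, 0),
    _row("Tf_GP20", "FA2G2S[6,6]2", 2, 2, 2, "a2,6;a2,6", 1, 0, 0),
    _row("Tf_GP21", "A2BG2S[6,6]2", 2, 2, 2, "a2,6;a2,6", 0, 1, 0),
    _row("Tf_GP22", "A3G3S[3]1", 3, 3, 1, "a2,3", 0, 0, 0),
    _row("Tf_GP23", "A3G3S[3,3]2", 3, 3, 2, "a2,3;a2,3", 0, 0, 0),
    _row("Tf_GP24", "A3G3S[3,6]2", 3, 3, 2, "a2,3;a2,6", 0, 0, 0),
    _row("Tf_GP25", "FA3G3S[3,6]2", 3, 3, 2, "a2,3;a2,6", 1, 0, 0),
    _row("Tf_GP26", "A3G3S[6,6]2", 3, 3, 2, "a2,6;a2,6", 0, 0, 0),
    _row("Tf_GP27", "A3G3S[3,3,3]3", 3, 3, 3, "a2,3;a2,3;a2,3", 0, 0, 0),
    _row("Tf_GP28", "FA3G3S[3,3,6]3", 3, 3, 3, "a2,3;a2,3;a2,6", 1, 0, 0),
    _row("Tf_GP29", "A4G4S[3,3]2", 4, 4, 2, "a2,3;a2,3", 0, 0, 0),
    _row("Tf_GP30", "A4G4S[3,3,3]3", 4, 4, 3, "a2,3;a2,3;a2,3", 0, 0, 0),
    _row("Tf_GP31", "FA4G4S[3,3,3]3", 4, 4, 3, "a2,3;a2,3;a2,3", 1, 0, 0),
    _row("Tf_GP32", "A4G3S[3,3]2", 4, 3, 2, "a2,3;a2,3", 0, 0, 0),
    _row("Tf_GP33", "F2A4G4S[3,3]2", 4, 4, 2, "a2,3;a2,3", 1, 0, 0, dhex=2),
    _row("Tf_GP34", "A4G4S[3,3,6]3", 4, 4, 3, "a2,3;a2,3;a2,6", 0, 0, 0),
    _row("Tf_GP35", "FA4G4S[3,3,6]3", 4, 4, 3, "a2,3;a2,3;a2,6", 1, 0, 0),
]

_IGG_ROWS = [
    _row("IgG_GP1", "FA2G0", 2, 0, 0, "", 1, 0, 0),
    _row("IgG_GP2", "A2G0", 2, 0, 0, "", 0, 0, 0),
    _row("IgG_GP3", "A2BG0", 2, 0, 0, "", 0, 1, 0),
    _row("IgG_GP4", "FA2G0b", 2, 0, 0, "", 1, 0, 0),
    _row("IgG_GP5", "M5", 0, 0, 0, "", 0, 0, 1),
    _row("IgG_GP6", "FA2BG0", 2, 0, 0, "", 1, 1, 0),
    _row("IgG_GP7", "M6", 0, 0, 0, "", 0, 0, 1),
    _row("IgG_GP8", "A2G1", 2, 1, 0, "", 0, 0, 0),
    _row("IgG_GP9", "FA2G1", 2, 1, 0, "", 1, 0, 0),
    _row("IgG_GP10", "FA2G1b", 2, 1, 0, "", 1, 0, 0),
    _row("IgG_GP11", "FA2BG1", 2, 1, 0, "", 1, 1, 0),
    _row("IgG_GP12", "A2G2", 2, 2, 0, "", 0, 0, 0),
    _row("IgG_GP13", "A2BG2", 2, 2, 0, "", 0, 1, 0),
    _row("IgG_GP14", "FA2G2", 2, 2, 0, "", 1, 0, 0),
    _row("IgG_GP15", "FA2BG2", 2, 2, 0, "", 1, 1, 0),
    _row("IgG_GP16", "A2G1S[6]1", 2, 1, 1, "a2,6", 0, 0, 0),
    _row("IgG_GP17", "A2G2S[6]1", 2, 2, 1, "a2,6", 0, 0, 0),
    _row("IgG_GP18", "FA2G2S[6]1", 2, 2, 1, "a2,6", 1, 0, 0),
    _row("IgG_GP19", "FA2BG2S[6]1", 2, 2, 1, "a2,6", 1, 1, 0),
    _row("IgG_GP20", "FA2G1S[6]1", 2, 1, 1, "a2,6", 1, 0, 0),
    _row("IgG_GP21", "A2G2S[6,6]2", 2, 2, 2, "a2,6;a2,6", 0, 0, 0),
    _row("IgG_GP22", "A2BG2S[6,6]2", 2, 2, 2, "a2,6;a2,6", 0, 1, 0),
    _row("IgG_GP23", "FA2G2S[6,6]2", 2, 2, 2, "a2,6;a2,6", 1, 0, 0),
    _row("IgG_GP24", "FA2BG2S[6,6]2", 2, 2, 2, "a2,6;a2,6", 1, 1, 0),
]


def _build(rows) -> TraitAnnotation:
    df = pd.DataFrame(rows).set_index("peak_id")
    return TraitAnnotation(df)


def default_tf_annotation() -> TraitAnnotation:
    """Default 35-peak transferrin panel (synthetic placeholder assignments
    except the pinned major peaks; override via :func:`load_annotation`)."""
    return _build(_TF_ROWS)


def default_igg_annotation() -> TraitAnnotation:
    """Default 24-peak IgG panel (synthetic placeholder assignments)."""
    return _build(_IGG_ROWS)


def default_annotation(panel: str) -> TraitAnnotation:
    if panel.lower() in ("tf", "transferrin"):
        return default_tf_annotation()
    if panel.lower() == "igg":
        return default_igg_annotation()
    raise KeyError(f"unknown panel {panel!r}; expected 'Tf' or 'IgG'")
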