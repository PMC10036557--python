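"""Glycan composition masses and tolerance-based candidate matching.

Released N-glycan compositions are written as counts of hexose (Hex),
N-acetylhexosamine (HexNAc), deoxyhexose (dHex, fucose) and N-acetyl-
neuraminic acid (Neu5Ac).  The neutral mass of a composition is the sum of
residue monoisotopic masses plus one water (the reducing end); fluorescently
labeled, sodiated species carry an additional lump adduct constant
(2-AB label + Na, 143 Da by default) exactly as used in GlycoMod-style
searches.  After linkage-specific sialic-acid derivatization by ethyl
esterification, each alpha-2,6-linked Neu5Ac gains an ethyl ester
(+C2H4, +28.0313 Da) and each alpha-2,3-linked Neu5Ac forms a lactone
(-H2O, -18.0106 Da), which is what makes the two linkages mass-resolvable.

Candidate matching enumerates the bounded composition space exhaustively
and returns every composition within the mass tolerance, ordered by
|mass error| then lexicographically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

#: residue monoisotopic masses (Da); residue = monosaccharide minus water
RESIDUE_MASSES = {
    "hex": 162.0528,
    "hexnac": 203.0794,
    "dhex": 146.0579,
    "neuac": 291.0954,
}

WATER = 18.0106           # Da, reducing-end water
ETHYL_ESTER_SHIFT = 28.0313   # +C2H4 on alpha-2,6 Neu5Ac
LACTONE_SHIFT = -18.0106      # -H2O on alpha-2,3 Neu5Ac


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide composition of one glycan species.

    ``neuac_26``/``neuac_23`` split sialic acids by linkage; with
    ``derivatized=False`` the split is irrelevant for mass (both weigh as
    underivatized Neu5Ac).  ``label`` is ``"2AB"`` or ``"none"``.
    """

    hex: int = 0
    hexnac: int = 0
    dhex: int = 0
    neuac_26: int = 0
    neuac_23: int = 0
    label: str = "2AB"
    derivatized: bool = False

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "dhex", "neuac_26", "neuac_23"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name} count")
        if self.label not in ("none", "2AB"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def neuac(self) -> int:
        return self.neuac_26 + self.neuac_23

    @property
    def total_residues(self) -> int:
        return self.hex + self.hexnac + self.dhex + self.neuac

    def short_name(self) -> str:
        parts = []
        for sym, n in (("Hex", self.hex), ("HexNAc", self.hexnac),
                       ("dHex", self.dhex), ("Neu5Ac", self.neuac)):
            if n:
                parts.append(f"{sym}{n}")
        return "".join(parts) or "empty"


@dataclass
class MassMatchConfig:
    """Matching parameters: tolerance, adduct constant, composition bounds."""

    tolerance: float = 0.5       # Da
    adduct_mass: float = 143.0   # lump 2-AB + Na constant, Da
    max_hex: int = 12
    max_hexnac: int = 8
    max_dhex: int = 3
    max_neuac: int = 4
    residue_masses: dict = field(default_factory=lambda: dict(RESIDUE_MASSES))

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        for b in (self.max_hex, self.max_hexnac, self.max_dhex, self.max_neuac):
            if b < 0:
                raise ValueError("composition bounds must be non-negative")


def composition_mass(comp: GlycanComposition,
                     cfg: MassMatchConfig | None = None) -> float:
    """Monoisotopic mass (Da) of a composition under the given config.

    mass = sum(count * residue mass) + water
           + adduct constant (when labeled)
           + derivatization shifts (when derivatized).
    """
    cfg = cfg if cfg is not None else MassMatchConfig()
    rm = cfg.residue_masses
    mass = (comp.hex * rm["hex"] + comp.hexnac * rm["hexnac"]
            + comp.dhex * rm["dhex"] + comp.neuac * rm["neuac"] + WATER)
    if comp.label == "2AB":
        mass += cfg.adduct_mass
    if comp.derivatized:
        mass += comp.neuac_26 * ETHYL_ESTER_SHIFT + comp.neuac_23 * LACTONE_SHIFT
    return mass


def match_composition(observed_mass: float,
                      cfg: MassMatchConfig | None = None,
                      label: str = "2AB",
                      derivatized: bool = False) -> list[tuple[GlycanComposition, float]]:
    """All compositions within tolerance of an observed mass.

    Exhaustively enumerates hex <= max_hex, hexnac <= max_hexnac,
    dhex <= max_dhex, neuac <= max_neuac (total residues >= 1) and returns
    ``(composition, delta_mass)`` pairs sorted by |delta| then by counts.
    For derivatized searches every alpha-2,3/alpha-2,6 split of each sialic
    acid count is enumerated (the splits differ in mass).
    """
    if observed_mass <= 0:
        raise ValueError("observed mass must be positive")
    cfg = cfg if cfg is not None else MassMatchConfig()
    if cfg.max_hex + cfg.max_hexnac + cfg.max_dhex + cfg.max_neuac == 0:
        raise ValueError("empty composition bounds")
    hits: list[tuple[GlycanComposition, float]] = []
    for h, n, d, s in itertools.product(
            range(cfg.max_hex + 1), range(cfg.max_hexnac + 1),
            range(cfg.max_dhex + 1), range(cfg.max_neuac + 1)):
        if h + n + d + s == 0:
            continue
        splits = [(s, 0)] if not derivatized else [(s26, s - s26) for s26 in range(s + 1)]
        for s26, s23 in splits:
            comp = GlycanComposition(hex=h, hexnac=n, dhex=d,
                                     neuac_26=s26, neuac_23=s23,
                                     label=label, derivatized=derivatized)
            delta = composition_mass(comp, cfg) - observed_mass
            if abs(delta) <= cfg.tolerance:
                hits.append((comp, delta))
    hits.sort(key=lambda cd: (abs(cd[1]), cd[0].hex, cd[0].hexnac,
                              cd[0].dhex, cd[0].neuac_26, cd[0].neuac_23))
    return hits
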