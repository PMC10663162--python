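"""Monoisotopic mass arithmetic and cleavable cross-linker chemistry.

Cross-linking MS encodes spatial proximity as covalent lysine-lysine
bridges.  For an MS-cleavable linker such as DSSO (disuccinimidyl
sulfoxide) the sulfoxide bridge fragments in the collision cell, leaving
one of three remnants on each peptide: alkene (C3H2O), thiol (C3H2SO) or
sulfenic acid (C3H4O2S).  The alkene/sulfenic-acid pair reconstitutes the
intact bridge; the thiol is the sulfenic acid minus water.  All masses
here are monoisotopic and positive-mode.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

# Monoisotopic atomic masses, IUPAC/CIAAW 2021 (Da).  Embedded so results
# do not drift with library versions.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Se": 79.9165213,
}

#: Mass of a proton (positive-mode charge carrier), Da.
PROTON_MASS = 1.0072765

_WATER = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]

# Amino-acid residue formulas (residue = amino acid minus water).
_RESIDUE_FORMULA: dict[str, str] = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ChemistryError(ValueError):
    """Invalid formula, residue or charge."""


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count map; all counts non-negative, at least one positive."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for element, n in self.counts.items():
            if element not in ATOMIC_MASS:
                raise ChemistryError(f"unknown element symbol: {element!r}")
            if n < 0:
                raise ChemistryError(f"negative count for element {element}")
        if not any(n > 0 for n in self.counts.values()):
            raise ChemistryError("empty formula: all element counts are zero")
        object.__setattr__(self, "counts", dict(self.counts))

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse Hill-style text such as ``"C3H2SO"`` (implicit count 1)."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ChemistryError(f"cannot parse formula {text!r}")
            pos = match.end()
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        if pos != len(text):
            raise ChemistryError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n != 1 else ''}" for el, n in sorted(self.counts.items()) if n
        )


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass of an elemental formula, Da."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    return sum(ATOMIC_MASS[el] * n for el, n in formula.counts.items())


WATER_MASS = monoisotopic_mass("H2O")

RESIDUE_MASS: dict[str, float] = {
    aa: monoisotopic_mass(f) for aa, f in _RESIDUE_FORMULA.items()
}


@dataclass(frozen=True)
class Modification:
    """A mass modification on a residue or terminus.

    ``mod_class`` distinguishes search-engine bookkeeping classes:
    ``fixed``/``variable`` for ordinary modifications, ``remnant`` for
    cleaved cross-linker fragments, ``dead_end`` for the hydrolyzed
    monolink.
    """

    name: str
    delta_mass: float
    site: str = "K"
    mod_class: str = "variable"
    formula: ElementalFormula | None = None

    def __post_init__(self) -> None:
        if self.mod_class not in {"fixed", "variable", "remnant", "dead_end"}:
            raise ChemistryError(f"unknown modification class {self.mod_class!r}")
        if self.formula is not None:
            expected = monoisotopic_mass(self.formula)
            if abs(expected - self.delta_mass) > 1e-4:
                raise ChemistryError(
                    f"modification {self.name}: delta_mass {self.delta_mass} "
                    f"disagrees with formula mass {expected:.5f}"
                )


@dataclass(frozen=True)
class CrossLinker:
    """Chemical definition of a lysine-reactive cross-linker.

    ``bridge_mass`` is the intact mass added between the two linked
    lysines; for a cleavable linker the remnant modifications are the
    gas-phase cleavage products and ``signature_delta`` is the spacing of
    the MS2 signature doublet (thiol minus alkene for DSSO).
    ``max_ca_distance`` is the Calpha-Calpha restraint used in structure
    mapping.
    """

    name: str
    bridge_mass: float
    remnant_mods: tuple[Modification, ...]
    dead_end_mass: float
    reactive_residue: str = "K"
    max_ca_distance: float = 20.0
    cleavable: bool = False
    signature_delta: float | None = None

    def remnant(self, name: str) -> Modification:
        for mod in self.remnant_mods:
            if mod.name == name:
                return mod
        raise KeyError(f"{self.name} has no remnant named {name!r}")

    @property
    def dead_end_mod(self) -> Modification:
        return Modification(
            name=f"{self.name}-deadend",
            delta_mass=self.dead_end_mass,
            site=self.reactive_residue,
            mod_class="dead_end",
        )

    def known_mods(self) -> tuple[Modification, ...]:
        """Remnants plus the dead-end, for search-result delta matching."""
        return self.remnant_mods + (self.dead_end_mod,)


def _build_dsso() -> CrossLinker:
    alkene = Modification(
        "alkene", monoisotopic_mass("C3H2O"), "K", "remnant",
        ElementalFormula.parse("C3H2O"),
    )
    thiol = Modification(
        "thiol", monoisotopic_mass("C3H2SO"), "K", "remnant",
        ElementalFormula.parse("C3H2SO"),
    )
    sulfenic = Modification(
        "sulfenic_acid", monoisotopic_mass("C3H4O2S"), "K", "remnant",
        ElementalFormula.parse("C3H4O2S"),
    )
    bridge = alkene.delta_mass + sulfenic.delta_mass
    return CrossLinker(
        name="DSSO",
        bridge_mass=bridge,
        remnant_mods=(alkene, thiol, sulfenic),
        # Hydrolyzed NHS-ester monolink: bridge + water.
        dead_end_mass=bridge + WATER_MASS,
        reactive_residue="K",
        max_ca_distance=20.0,
        cleavable=True,
        signature_delta=thiol.delta_mass - alkene.delta_mass,
    )


DSSO = _build_dsso()

# PhoX (non-cleavable, IMAC-enrichable phosphonate linker).  Bridge
# composition C8H3O5P; the Calpha distance default is an implementer
# choice (the linker is shorter than DSSO, commonly capped near 25 A).
PHOX = CrossLinker(
    name="PhoX",
    bridge_mass=monoisotopic_mass("C8H3O5P"),
    remnant_mods=(),
    dead_end_mass=monoisotopic_mass("C8H3O5P") + WATER_MASS,
    reactive_residue="K",
    max_ca_distance=25.0,
    cleavable=False,
)

BUILTIN_LINKERS: dict[str, CrossLinker] = {"DSSO": DSSO, "PHOX": PHOX}


def get_linker(name: str) -> CrossLinker:
    try:
        return BUILTIN_LINKERS[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown cross-linker {name!r}; built-ins: "
            + ", ".join(sorted(BUILTIN_LINKERS))
        ) from None


def load_linkers(path: str | Path) -> dict[str, CrossLinker]:
    """Load cross-linker definitions from a YAML config.

    One stanza per linker::

        linkers:
          DSSO:
            reactive_residue: K
            max_ca_distance: 20.0
            cleavable: true
            remnants:
              alkene: C3H2O
              thiol: C3H2SO
              sulfenic_acid: C3H4O2S
            bridge: [alkene, sulfenic_acid]   # or bridge_mass: <Da>
    """
    spec = yaml.safe_load(Path(path).read_text())
    linkers: dict[str, CrossLinker] = {}
    for name, stanza in (spec.get("linkers") or {}).items():
        residue = stanza.get("reactive_residue", "K")
        remnants = tuple(
            Modification(mod_name, monoisotopic_mass(f), residue, "remnant",
                         ElementalFormula.parse(f))
            for mod_name, f in (stanza.get("remnants") or {}).items()
        )
        by_name = {m.name: m for m in remnants}
        if "bridge_mass" in stanza:
            bridge = float(stanza["bridge_mass"])
        elif "bridge_formula" in stanza:
            bridge = monoisotopic_mass(stanza["bridge_formula"])
        else:
            bridge = sum(by_name[n].delta_mass for n in stanza["bridge"])
        cleavable = bool(stanza.get("cleavable", bool(remnants)))
        signature = None
        if cleavable and "signature" in stanza:
            hi, lo = stanza["signature"]
            signature = by_name[hi].delta_mass - by_name[lo].delta_mass
        linkers[name] = CrossLinker(
            name=name,
            bridge_mass=bridge,
            remnant_mods=remnants,
            dead_end_mass=float(stanza.get("dead_end_mass", bridge + WATER_MASS)),
            reactive_residue=residue,
            max_ca_distance=float(stanza.get("max_ca_distance", 20.0)),
            cleavable=cleavable,
            signature_delta=signature,
        )
    return linkers


@dataclass
class Peptide:
    """A search-result peptide with positioned modifications.

    ``mods`` holds ``(position, Modification)`` pairs with 1-based
    positions ("nterm"/"cterm" accepted for termini).  ``start_position``
    is the 1-based protein coordinate of residue 1, when known.
    """

    sequence: str
    mods: list[tuple[int | str, Modification]] = field(default_factory=list)
    protein_accession: str = ""
    start_position: int | None = None
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ChemistryError("empty peptide sequence")
        for pos, _ in self.mods:
            if isinstance(pos, int) and not 1 <= pos <= len(self.sequence):
                raise ChemistryError(
                    f"modification position {pos} outside 1..{len(self.sequence)}"
                )

    def mods_of_class(self, mod_class: str) -> list[tuple[int | str, Modification]]:
        return [(p, m) for p, m in self.mods if m.mod_class == mod_class]

    def residue_positions(self, residue: str) -> list[int]:
        return [i + 1 for i, aa in enumerate(self.sequence) if aa == residue]


def peptide_mass(
    peptide: Peptide,
    include_mod_classes: Iterable[str] = ("fixed", "variable", "remnant", "dead_end"),
) -> float:
    """Neutral monoisotopic peptide mass, Da.

    Sums residue masses plus water plus the deltas of modifications whose
    class is in ``include_mod_classes``; excluding a class (e.g. the
    cross-linker remnants before the precursor mass-sum test) removes
    exactly those deltas.
    """
    classes = set(include_mod_classes)
    total = WATER_MASS
    for aa in peptide.sequence:
        try:
            total += RESIDUE_MASS[aa]
        except KeyError:
            raise ChemistryError(f"unknown residue letter: {aa!r}") from None
    for _, mod in peptide.mods:
        if mod.mod_class in classes:
            total += mod.delta_mass
    return total


def neutral_mass_from_mz(mz: float, charge: int) -> float:
    """Neutral mass from an observed m/z at a given positive charge."""
    if charge <= 0:
        raise ChemistryError(f"charge must be a positive integer, got {charge}")
    if mz <= 0:
        raise ChemistryError(f"m/z must be positive, got {mz}")
    return charge * mz - charge * PROTON_MASS


def mz_from_neutral_mass(mass: float, charge: int) -> float:
    if charge <= 0:
        raise ChemistryError(f"charge must be a positive integer, got {charge}")
    return (mass + charge * PROTON_MASS) / charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ChemistryError(f"theoretical mass must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6
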