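"""Spectral-group classification and cross-linked spectrum match validation.

Each spectral group is assigned exactly one category by a fixed decision
tree:

1. A confident MS2 assignment whose peptide carries no cross-linker
   modification on a lysine is a **SINGLE** (ordinary linear peptide).
2. A confident MS2 assignment with a hydrolyzed (dead-end) linker mass on
   an internal lysine is a **MONOLINK**.
3. Otherwise the MS3 assignments are evaluated: those above the
   probability threshold that carry a linker-remnant-modified lysine are
   candidate cross-linked peptides.  If two candidate peptide masses
   (remnant deltas stripped) plus the intact bridge mass reconstruct the
   precursor neutral mass within the ppm tolerance, the group is a
   **CSM**; candidates that never sum correctly leave an
   **INCOMPLETE_CSM**.
4. Groups with one or zero qualifying MS3 assignments are **UNKNOWN**.

Stripping the remnant deltas before the mass-sum makes the test
independent of which remnant pair (alkene/thiol vs alkene/sulfenic acid)
the search engine reported.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .chem import (
    CrossLinker,
    DSSO,
    Peptide,
    neutral_mass_from_mz,
    peptide_mass,
    ppm_error,
)
from .grouping import SpectralGroup
from .msio import SearchHit

logger = logging.getLogger(__name__)

SINGLE = "SINGLE"
MONOLINK = "MONOLINK"
CSM_CATEGORY = "CSM"
INCOMPLETE_CSM = "INCOMPLETE_CSM"
UNKNOWN = "UNKNOWN"
LOOPLINK = "LOOPLINK"

CATEGORIES = (SINGLE, MONOLINK, CSM_CATEGORY, INCOMPLETE_CSM, UNKNOWN)

_NON_REMNANT_CLASSES = ("fixed", "variable", "dead_end")


@dataclass
class ClassifierConfig:
    """Thresholds and chemistry for the decision tree.

    ``probability_threshold`` gates assignments strictly above the value;
    ``precursor_tol_ppm`` bounds the mass-sum error;
    ``charge_range_for_unknown`` is the charge hypothesis range tried when
    the instrument did not report a precursor charge (acquisition selects
    4+ and above for cross-linked precursors).
    """

    linker: CrossLinker = field(default_factory=lambda: DSSO)
    probability_threshold: float = 0.8
    precursor_tol_ppm: float = 20.0
    require_remnant_on_ms3: bool = True
    charge_range_for_unknown: tuple[int, int] = (4, 8)
    allow_looplink: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.probability_threshold < 1.0:
            raise ValueError("probability_threshold must be in (0, 1)")
        if self.precursor_tol_ppm <= 0:
            raise ValueError("precursor_tol_ppm must be positive")


@dataclass
class CSM:
    """A validated cross-linked spectrum match."""

    peptide_a: Peptide
    peptide_b: Peptide
    link_pos_a: int
    link_pos_b: int
    theoretical_mass: float
    observed_mass: float
    mass_error: float
    probability_a: float
    probability_b: float
    inferred_charge: int = 0

    @property
    def combined_probability(self) -> float:
        return self.probability_a * self.probability_b

    @property
    def decoy_class(self) -> str:
        n_decoy = int(self.peptide_a.is_decoy) + int(self.peptide_b.is_decoy)
        return ("TT", "TD", "DD")[n_decoy]


@dataclass
class ClassifiedGroup:
    group: SpectralGroup
    category: str
    csm: CSM | None = None

    def __post_init__(self) -> None:
        if (self.category == CSM_CATEGORY) != (self.csm is not None):
            raise ValueError("csm must be present exactly when category is CSM")


@dataclass(frozen=True, order=True)
class ResidueLink:
    """A lysine-lysine cross-link in protein coordinates (1-based)."""

    accession_a: str
    residue_a: int
    accession_b: str
    residue_b: int
    mapped: bool = True

    def canonical(self) -> "ResidueLink":
        a = (self.accession_a, self.residue_a)
        b = (self.accession_b, self.residue_b)
        if b < a:
            a, b = b, a
        return ResidueLink(a[0], a[1], b[0], b[1], self.mapped)


def _linker_mod_positions(peptide: Peptide, linker: CrossLinker) -> dict[str, list[int]]:
    """Positions of linker-derived modifications on reactive residues."""
    out: dict[str, list[int]] = {"remnant": [], "dead_end": []}
    for pos, mod in peptide.mods:
        if not isinstance(pos, int):
            continue
        if peptide.sequence[pos - 1] != linker.reactive_residue:
            continue
        if mod.mod_class in out:
            out[mod.mod_class].append(pos)
    return out


def _has_internal(positions: list[int], peptide: Peptide) -> bool:
    # A cross-linked lysine blocks trypsin, so a genuine dead-end site is a
    # missed-cleavage K, i.e. not the C-terminal residue.
    return any(pos < len(peptide.sequence) for pos in positions)


def _remnant_candidates(
    group: SpectralGroup, config: ClassifierConfig
) -> list[SearchHit]:
    candidates = []
    for hit in group.ms3_hits:
        if hit.probability <= config.probability_threshold:
            continue
        if config.require_remnant_on_ms3:
            if not _linker_mod_positions(hit.assigned_peptide, config.linker)["remnant"]:
                continue
        candidates.append(hit)
    return candidates


def validate_interlink(
    candidates: list[SearchHit],
    precursor_neutral_mass: float,
    config: ClassifierConfig,
) -> CSM | None:
    """Run the precursor mass-sum test over all candidate peptide pairs.

    For every unordered pair of candidates from distinct MS3 scans the
    theoretical precursor mass is the two peptide masses with remnant
    deltas stripped plus the intact bridge mass.  The best passing pair
    (smallest absolute ppm error, ties broken by larger combined
    probability then lexicographic peptide order) is returned; ``None``
    if no pair passes.
    """
    best: CSM | None = None
    best_key: tuple | None = None
    for hit_a, hit_b in itertools.combinations(candidates, 2):
        if hit_a.scan_id == hit_b.scan_id:
            continue
        pep_a, pep_b = hit_a.assigned_peptide, hit_b.assigned_peptide
        theoretical = (
            peptide_mass(pep_a, _NON_REMNANT_CLASSES)
            + peptide_mass(pep_b, _NON_REMNANT_CLASSES)
            + config.linker.bridge_mass
        )
        error = ppm_error(precursor_neutral_mass, theoretical)
        if abs(error) > config.precursor_tol_ppm:
            continue
        link_a = _linker_mod_positions(pep_a, config.linker)["remnant"]
        link_b = _linker_mod_positions(pep_b, config.linker)["remnant"]
        pos_a = link_a[0] if link_a else 0
        pos_b = link_b[0] if link_b else 0
        # Canonical peptide order for stable output.
        if (pep_b.sequence, pep_b.protein_accession) < (
            pep_a.sequence, pep_a.protein_accession
        ):
            pep_a, pep_b = pep_b, pep_a
            pos_a, pos_b = pos_b, pos_a
            hit_a, hit_b = hit_b, hit_a
        csm = CSM(
            peptide_a=pep_a,
            peptide_b=pep_b,
            link_pos_a=pos_a,
            link_pos_b=pos_b,
            theoretical_mass=theoretical,
            observed_mass=precursor_neutral_mass,
            mass_error=error,
            probability_a=hit_a.probability,
            probability_b=hit_b.probability,
        )
        key = (
            abs(error),
            -csm.combined_probability,
            pep_a.sequence,
            pep_b.sequence,
        )
        if best_key is None or key < best_key:
            best, best_key = csm, key
    return best


def classify_group(group: SpectralGroup, config: ClassifierConfig) -> ClassifiedGroup:
    """Apply the decision tree to one spectral group."""
    linker = config.linker
    ms2 = group.ms2_hit
    if ms2 is not None and ms2.probability > config.probability_threshold:
        peptide = ms2.assigned_peptide
        linked = _linker_mod_positions(peptide, linker)
        if not linked["remnant"] and not linked["dead_end"]:
            if config.allow_looplink and _has_bridge_mod(peptide, linker):
                return ClassifiedGroup(group, LOOPLINK)
            return ClassifiedGroup(group, SINGLE)
        if _has_internal(linked["dead_end"], peptide):
            return ClassifiedGroup(group, MONOLINK)
        # Remnant-modified MS2 peptide: part of a cross-link, keep going.

    candidates = _remnant_candidates(group, config)
    if len({h.scan_id for h in candidates}) >= 2:
        csm = _validate_with_charge_hypotheses(group, candidates, config)
        if csm is not None:
            return ClassifiedGroup(group, CSM_CATEGORY, csm)
        return ClassifiedGroup(group, INCOMPLETE_CSM)
    return ClassifiedGroup(group, UNKNOWN)


def _has_bridge_mod(peptide: Peptide, linker: CrossLinker) -> bool:
    return any(
        abs(mod.delta_mass - linker.bridge_mass) < 0.01 for _, mod in peptide.mods
    )


def _validate_with_charge_hypotheses(
    group: SpectralGroup, candidates: list[SearchHit], config: ClassifierConfig
) -> CSM | None:
    if group.precursor_neutral_mass is not None:
        csm = validate_interlink(candidates, group.precursor_neutral_mass, config)
        if csm is not None:
            csm.inferred_charge = group.precursor_charge
        return csm
    # Unknown charge: test each hypothesis in the configured range and keep
    # the smallest-error acceptance.
    lo, hi = config.charge_range_for_unknown
    best: CSM | None = None
    for charge in range(lo, hi + 1):
        mass = neutral_mass_from_mz(group.ms2_scan.selected_ion_mz, charge)
        csm = validate_interlink(candidates, mass, config)
        if csm is not None and (best is None or abs(csm.mass_error) < abs(best.mass_error)):
            csm.inferred_charge = charge
            best = csm
    return best


def classify_all(
    groups: list[SpectralGroup], config: ClassifierConfig
) -> list[ClassifiedGroup]:
    return [classify_group(group, config) for group in groups]


@dataclass
class FdrEstimate:
    tt: int
    td: int
    dd: int

    @property
    def fdr(self) -> float:
        # Conservative: decoy-containing matches over target-target
        # matches; zero CSMs reports 0.
        return (self.td + self.dd) / max(self.tt, 1)


def estimate_fdr(results: list[ClassifiedGroup]) -> FdrEstimate:
    """Target-decoy FDR over validated CSMs (estimator, not a filter)."""
    counts = {"TT": 0, "TD": 0, "DD": 0}
    for result in results:
        if result.csm is not None:
            counts[result.csm.decoy_class] += 1
    if sum(counts.values()) == 0:
        logger.warning("no CSMs found; FDR reported as 0")
    return FdrEstimate(counts["TT"], counts["TD"], counts["DD"])


def to_residue_links(results: list[ClassifiedGroup]) -> list[ResidueLink]:
    """Project CSM link sites onto protein coordinates and deduplicate.

    Protein position = peptide start position + link position - 1.
    Peptides without a start position (e.g. decoys that do not locate in
    the database) yield links flagged ``mapped=False`` carrying the
    peptide-relative positions.
    """
    links: set[ResidueLink] = set()
    for result in results:
        csm = result.csm
        if csm is None:
            continue
        mapped = (
            csm.peptide_a.start_position is not None
            and csm.peptide_b.start_position is not None
            and csm.link_pos_a > 0
            and csm.link_pos_b > 0
        )
        if mapped:
            link = ResidueLink(
                csm.peptide_a.protein_accession,
                csm.peptide_a.start_position + csm.link_pos_a - 1,
                csm.peptide_b.protein_accession,
                csm.peptide_b.start_position + csm.link_pos_b - 1,
            )
        else:
            link = ResidueLink(
                csm.peptide_a.protein_accession,
                max(csm.link_pos_a, 1),
                csm.peptide_b.protein_accession,
                max(csm.link_pos_b, 1),
                mapped=False,
            )
        links.add(link.canonical())
    return sorted(links)


def summarize(results: list[ClassifiedGroup]) -> str:
    """Human-readable run summary: category counts, FDR block, link roll-up."""
    counts = {cat: 0 for cat in CATEGORIES + (LOOPLINK,)}
    for result in results:
        counts[result.category] = counts.get(result.category, 0) + 1
    fdr = estimate_fdr(results)
    links = [l for l in to_residue_links(results) if l.mapped]
    pairs: dict[tuple[str, str], int] = {}
    for link in links:
        key = tuple(sorted((link.accession_a, link.accession_b)))
        pairs[key] = pairs.get(key, 0) + 1
    lines = ["Spectral group classification summary", "=" * 37]
    total = len(results)
    for cat in CATEGORIES:
        lines.append(f"{cat:>15}: {counts[cat]}")
    if counts.get(LOOPLINK):
        lines.append(f"{LOOPLINK:>15}: {counts[LOOPLINK]}")
    lines.append(f"{'total groups':>15}: {total}")
    lines.append("")
    lines.append(
        f"CSM decoy composition: TT={fdr.tt} TD={fdr.td} DD={fdr.dd} "
        f"(FDR estimate {fdr.fdr:.4f})"
    )
    lines.append(f"Unique residue links: {len(links)}")
    for (acc_a, acc_b), n in sorted(pairs.items()):
        lines.append(f"  {acc_a} -- {acc_b}: {n} link(s)")
    return "\n".join(lines)
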