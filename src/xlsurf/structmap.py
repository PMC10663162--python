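"""Mapping residue-level cross-links onto 3D structures.

A cross-link constrains the Calpha-Calpha distance of its two lysines
(<20 A for DSSO).  Mapping identified links onto a crystal structure and
flagging violations is how an alternative in-situ conformation is
detected: a link that cannot be satisfied on the deposited model implies
the protein adopts a different arrangement on the cell surface.

Protein (UniProt-style) 1-based coordinates are used throughout; the
structure's author numbering is reached only through an explicit
:class:`ChainMapping`, because silently equating the two numbering
schemes is the classic source of wrong distances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.PDB import MMCIFParser, PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .classify import ResidueLink

logger = logging.getLogger(__name__)

SATISFIED = "SATISFIED"
VIOLATED = "VIOLATED"
UNRESOLVED = "UNRESOLVED"


@dataclass
class StructureResidue:
    number: int
    icode: str
    name: str
    ca: np.ndarray | None  # Calpha coordinates (A), or None if absent

    @property
    def one_letter(self) -> str:
        return protein_letters_3to1.get(self.name.upper(), "X")


@dataclass
class StructureModel:
    """First model of a structure: ordered residues per chain, Calpha only."""

    chains: dict[str, list[StructureResidue]]

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chains[chain_id])

    def find_residue(self, chain_id: str, number: int) -> StructureResidue | None:
        """Residue by author number; None when absent or icode-ambiguous."""
        matches = [r for r in self.chains.get(chain_id, []) if r.number == number]
        if len(matches) == 1:
            return matches[0]
        if len(matches) > 1:
            blank = [r for r in matches if not r.icode.strip()]
            if len(blank) == 1:
                return blank[0]
            logger.warning(
                "residue %s%d is insertion-code ambiguous; left unresolved",
                chain_id, number,
            )
        return None


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Model 1 only; waters and heteroatoms excluded; for disordered atoms
    the highest-occupancy altloc is kept (Biopython's default selection).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty structure file: {path}")
    parser = (
        MMCIFParser(QUIET=True)
        if path.suffix.lower() in {".cif", ".mmcif"}
        else PDBParser(QUIET=True)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            structure = parser.get_structure(path.stem, str(path))
        except Exception as exc:  # noqa: BLE001 - re-raise with file context
            raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    try:
        model = next(iter(structure))
    except StopIteration:
        raise ValueError(f"structure file {path} contains no models") from None
    chains: dict[str, list[StructureResidue]] = {}
    for chain in model:
        residues = []
        for residue in chain:
            hetflag, number, icode = residue.id
            if hetflag.strip():  # skip waters and heteroatoms
                continue
            ca = None
            if "CA" in residue:
                coord = np.asarray(residue["CA"].coord, dtype=float)
                if not np.all(np.isfinite(coord)):
                    raise ValueError(
                        f"non-finite Calpha coordinates at {chain.id}{number}"
                    )
                ca = coord
            residues.append(
                StructureResidue(number=number, icode=icode, name=residue.resname, ca=ca)
            )
        if residues:
            chains[chain.id] = residues
    if not chains:
        raise ValueError(f"no polymer residues found in {path}")
    return StructureModel(chains)


@dataclass
class ChainMapping:
    """Protein-coordinate to structure-author-number translation.

    Either a constant ``offset`` (author number = protein position +
    offset) or an alignment-derived per-residue ``residue_map``.
    """

    accession: str
    chain_id: str
    offset: int | None = None
    residue_map: dict[int, int] | None = None
    source: str = "explicit"

    def author_number(self, position: int) -> int | None:
        if self.residue_map is not None:
            return self.residue_map.get(position)
        if self.offset is not None:
            return position + self.offset
        return None


class MappingError(ValueError):
    """Sequence-to-chain mapping could not be established."""


def resolve_mapping(
    accession: str,
    sequence: str,
    model: StructureModel,
    hint: ChainMapping | None = None,
    min_matches: int = 20,
) -> ChainMapping:
    """Map a protein sequence onto the best-matching structure chain.

    An explicit ``hint`` is used verbatim.  Otherwise the sequence is
    locally aligned (match +1, mismatch -1, gap -2) against every chain's
    residue sequence; the highest-scoring chain wins and a per-residue
    map is emitted.  A tie between chains (e.g. a homodimer) raises a
    :class:`MappingError` naming the candidates rather than guessing, as
    does failure to reach ``min_matches`` identical aligned residues.
    """
    if hint is not None:
        return hint
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    scored: list[tuple[float, str]] = []
    alignments: dict[str, object] = {}
    for chain_id in model.chains:
        chain_seq = model.chain_sequence(chain_id)
        if not chain_seq:
            continue
        result = aligner.align(sequence, chain_seq)
        if result.score <= 0:
            continue
        try:
            alignment = result[0]
        except IndexError:
            continue
        scored.append((result.score, chain_id))
        alignments[chain_id] = alignment
    if not scored:
        raise MappingError(f"{accession}: structure has no usable chains")
    scored.sort(reverse=True)
    best_score, best_chain = scored[0]
    ties = [cid for score, cid in scored if score == best_score]
    if len(ties) > 1:
        raise MappingError(
            f"{accession}: ambiguous chain mapping, chains {sorted(ties)} "
            f"tie at alignment score {best_score:.0f}"
        )
    alignment = alignments[best_chain]
    residues = model.chains[best_chain]
    residue_map: dict[int, int] = {}
    matches = 0
    for (q_start, q_end), (t_start, t_end) in zip(*alignment.aligned):
        for offset in range(q_end - q_start):
            q_pos = q_start + offset  # 0-based in protein sequence
            t_pos = t_start + offset  # 0-based in chain residue list
            residue = residues[t_pos]
            if sequence[q_pos] == residue.one_letter:
                matches += 1
            else:
                logger.warning(
                    "%s: residue type mismatch at protein position %d "
                    "(%s vs chain %s %s%d)",
                    accession, q_pos + 1, sequence[q_pos], best_chain,
                    residue.one_letter, residue.number,
                )
            residue_map[q_pos + 1] = residue.number
    if matches < min_matches:
        raise MappingError(
            f"{accession}: best chain {best_chain} aligns only {matches} "
            f"identical residues (< {min_matches})"
        )
    return ChainMapping(
        accession=accession,
        chain_id=best_chain,
        residue_map=residue_map,
        source="alignment",
    )


def ca_distance(p, q) -> float:
    """Euclidean Calpha-Calpha distance in Angstrom."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(p - q))


@dataclass
class DistanceRecord:
    link: ResidueLink
    chain_a: str = ""
    author_res_a: int | None = None
    chain_b: str = ""
    author_res_b: int | None = None
    ca_distance: float | None = None
    status: str = UNRESOLVED
    threshold_used: float = 20.0


def _resolve_end(
    accession: str,
    position: int,
    model: StructureModel,
    mappings: dict[str, ChainMapping],
) -> tuple[str, int, np.ndarray] | None:
    mapping = mappings.get(accession)
    if mapping is None:
        return None
    number = mapping.author_number(position)
    if number is None:
        return None
    residue = model.find_residue(mapping.chain_id, number)
    if residue is None or residue.ca is None:
        return None
    return mapping.chain_id, number, residue.ca


def map_links(
    links: list[ResidueLink],
    model: StructureModel,
    mappings: list[ChainMapping],
    threshold: float = 20.0,
) -> list[DistanceRecord]:
    """Resolve links on the structure and test the distance constraint.

    Every link yields one record.  A link is SATISFIED when its
    Calpha-Calpha distance is strictly below ``threshold`` (the linker
    geometry constraint, 20 A for DSSO) and VIOLATED otherwise; ends that
    cannot be resolved (no mapping, residue absent, no Calpha, insertion
    -code ambiguity) leave the record UNRESOLVED.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    by_accession = {m.accession: m for m in mappings}
    records = []
    for link in sorted(links):
        record = DistanceRecord(link=link, threshold_used=threshold)
        end_a = _resolve_end(link.accession_a, link.residue_a, model, by_accession)
        end_b = _resolve_end(link.accession_b, link.residue_b, model, by_accession)
        if link.mapped and end_a is not None and end_b is not None:
            record.chain_a, record.author_res_a, ca_a = end_a
            record.chain_b, record.author_res_b, ca_b = end_b
            record.ca_distance = ca_distance(ca_a, ca_b)
            record.status = SATISFIED if record.ca_distance < threshold else VIOLATED
        records.append(record)
    return records


def distance_report(records: list[DistanceRecord]) -> dict:
    """Per-status counts plus the maximum violated distance."""
    counts = {SATISFIED: 0, VIOLATED: 0, UNRESOLVED: 0}
    max_violated = None
    for record in records:
        counts[record.status] += 1
        if record.status == VIOLATED:
            if max_violated is None or record.ca_distance > max_violated:
                max_violated = record.ca_distance
    return {"counts": counts, "max_violated_distance": max_violated}


def write_distance_table(records: list[DistanceRecord], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "accession_a": r.link.accession_a,
            "residue_a": r.link.residue_a,
            "chain_a": r.chain_a,
            "author_res_a": "" if r.author_res_a is None else r.author_res_a,
            "accession_b": r.link.accession_b,
            "residue_b": r.link.residue_b,
            "chain_b": r.chain_b,
            "author_res_b": "" if r.author_res_b is None else r.author_res_b,
            "ca_distance": "" if r.ca_distance is None else round(r.ca_distance, 3),
            "status": r.status,
            "threshold": r.threshold_used,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "accession_a", "residue_a", "chain_a", "author_res_a",
            "accession_b", "residue_b", "chain_b", "author_res_b",
            "ca_distance", "status", "threshold",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_viz_script(
    records: list[DistanceRecord], path: str | Path, dialect: str = "pymol"
) -> None:
    """Emit a PyMOL or ChimeraX script drawing one object per resolved link.

    Satisfied links are drawn green, violated links red; ordering is
    deterministic (sorted by link).
    """
    if dialect not in {"pymol", "chimerax"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = []
    resolved = [r for r in sorted(records, key=lambda r: r.link) if r.status != UNRESOLVED]
    for index, record in enumerate(resolved, start=1):
        color = "green" if record.status == SATISFIED else "red"
        name = f"xl{index:03d}"
        if dialect == "pymol":
            sel_a = f"chain {record.chain_a} and resi {record.author_res_a} and name CA"
            sel_b = f"chain {record.chain_b} and resi {record.author_res_b} and name CA"
            lines.append(f"distance {name}, ({sel_a}), ({sel_b})")
            lines.append(f"color {color}, {name}")
        else:
            lines.append(
                f"distance /{record.chain_a}:{record.author_res_a}@CA "
                f"/{record.chain_b}:{record.author_res_b}@CA "
                f"color {color}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
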