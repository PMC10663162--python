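"""Ground-truthed synthetic fixtures for the whole cross-linking pipeline.

The generator emulates what the classifier actually consumes from a
cleavable-XL acquisition: random protein sequences, tryptic peptides with
remnant-modified lysines, precursor ions whose neutral mass obeys the
DSSO mass-sum relation (two stripped peptide masses plus the intact
bridge), MS2 signature doublets spaced by the thiol-alkene difference,
high/low assignment probabilities around the 0.8 gate, and decoy
assignments at a controlled rate.  It does not model isotope envelopes,
retention time, or fragment-ion ladders — the database search itself is
out of scope and its output is what we synthesize.

The same seed always produces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import msio
from .chem import (
    CrossLinker,
    DSSO,
    Modification,
    Peptide,
    mz_from_neutral_mass,
    peptide_mass,
)
from .classify import (
    CSM_CATEGORY,
    INCOMPLETE_CSM,
    MONOLINK,
    ResidueLink,
    SINGLE,
    UNKNOWN,
)
from .msio import SearchHit, SpectrumRecord
from .structmap import ChainMapping, StructureModel, StructureResidue

_AMINO_ACIDS = "ACDEFGHILMNPQRSTVWY"  # K handled separately to force density
_STRIP = ("fixed", "variable", "dead_end")


@dataclass
class SimulationConfig:
    """Counts and noise model for one synthetic acquisition.

    Defaults follow the stated acquisition/search behaviour: confident
    assignments at probability 0.99, wrong ones at 0.10, exact precursor
    masses (0 ppm noise) and cross-link precursor charges 4-6.
    """

    seed: int = 0
    n_proteins: int = 20
    n_interlinks: int = 0
    n_monolinks: int = 0
    n_singles: int = 0
    n_incomplete: int = 0
    n_unknown: int = 0
    prob_true: float = 0.99
    prob_false: float = 0.10
    mass_noise_ppm: float = 0.0
    decoy_fraction: float = 0.0
    precursor_charges: tuple[int, ...] = (4, 5, 6)
    linker: CrossLinker = field(default_factory=lambda: DSSO)

    def __post_init__(self) -> None:
        counts = (self.n_interlinks, self.n_monolinks, self.n_singles,
                  self.n_incomplete, self.n_unknown)
        if any(c < 0 for c in counts):
            raise ValueError("group counts must be non-negative")
        for frac in (self.prob_true, self.prob_false, self.decoy_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be within [0, 1]")

    @property
    def total_groups(self) -> int:
        return (self.n_interlinks + self.n_monolinks + self.n_singles
                + self.n_incomplete + self.n_unknown)


@dataclass
class GroundTruth:
    """What was planted, for asserting recovery downstream."""

    categories: dict[int, str]               # MS2 scan number -> category
    links: list[ResidueLink]                 # planted interlinks (protein coords)
    n_ms3_assignments: int = 0
    n_decoy_ms3: int = 0
    group_peptides: dict[int, list[str]] = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    spectra: list[SpectrumRecord]
    ms2_hits: list[SearchHit]
    ms3_hits: list[SearchHit]
    proteins: dict[str, str]
    truth: GroundTruth


def _random_protein(rng: np.random.Generator, length: int) -> str:
    # Uniform over 19 residues with K overlaid at >=5% so tryptic peptides
    # with internal lysines always exist; extra R supplies cleavage sites.
    letters = []
    for _ in range(length):
        roll = rng.random()
        if roll < 0.08:
            letters.append("K")
        elif roll < 0.14:
            letters.append("R")
        else:
            letters.append(_AMINO_ACIDS[rng.integers(len(_AMINO_ACIDS))])
    return "".join(letters)


def tryptic_peptides(
    sequence: str, max_missed: int = 3, min_len: int = 6, max_len: int = 30
) -> list[tuple[int, str]]:
    """(1-based start, peptide) for tryptic peptides with missed cleavages.

    Cleavage after K/R except before P, up to ``max_missed`` missed sites.
    """
    cut_after = [
        i for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    boundaries = [0] + [i + 1 for i in cut_after] + [len(sequence)]
    peptides = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(boundaries))):
            start, end = boundaries[i], boundaries[j]
            if min_len <= end - start <= max_len:
                peptides.append((start + 1, sequence[start:end]))
    return peptides


def _internal_k_positions(peptide: str) -> list[int]:
    return [i + 1 for i, aa in enumerate(peptide[:-1]) if aa == "K"]


def _shuffled_decoy(
    rng: np.random.Generator, sequence: str, keep: int
) -> str:
    """Shuffle all residues except position ``keep`` (1-based) and the
    C-terminus, preserving composition (hence mass) and the linked lysine."""
    fixed = {keep - 1, len(sequence) - 1}
    movable = [i for i in range(len(sequence)) if i not in fixed]
    residues = list(sequence)
    for attempt in range(10):
        order = rng.permutation(len(movable))
        shuffled = list(residues)
        for slot, src in zip(movable, order):
            shuffled[slot] = residues[movable[src]]
        if shuffled != residues:
            return "".join(shuffled)
    return "".join(reversed(sequence[:-1])) + sequence[-1]


class _PeptidePool:
    def __init__(self, rng: np.random.Generator, proteins: dict[str, str]):
        self.rng = rng
        self.linkable: list[tuple[str, int, str]] = []  # (acc, start, seq)
        self.plain: list[tuple[str, int, str]] = []
        for accession, sequence in proteins.items():
            for start, pep in tryptic_peptides(sequence):
                entry = (accession, start, pep)
                if _internal_k_positions(pep):
                    self.linkable.append(entry)
                else:
                    self.plain.append(entry)

    def draw_linkable(self) -> tuple[str, int, str]:
        return self.linkable[self.rng.integers(len(self.linkable))]

    def draw_plain(self) -> tuple[str, int, str]:
        pool = self.plain or self.linkable
        return pool[self.rng.integers(len(pool))]


def simulate_groups(config: SimulationConfig) -> SimulatedDataset:
    """Generate the in-memory spectra and search hits for one acquisition."""
    if config.total_groups == 0:
        raise ValueError("configuration plants zero spectral groups")
    rng = np.random.default_rng(config.seed)
    linker = config.linker
    alkene = linker.remnant("alkene") if linker.cleavable else None
    thiol = linker.remnant("thiol") if linker.cleavable else None

    proteins = {
        f"SP{i + 1:04d}": _random_protein(rng, int(rng.integers(200, 400)))
        for i in range(config.n_proteins)
    }
    pool = _PeptidePool(rng, proteins)
    if not pool.linkable:
        raise ValueError("no linkable tryptic peptides; increase n_proteins")

    spectra: list[SpectrumRecord] = [
        SpectrumRecord(scan_id="scan=1", ms_level=1, peaks=[(400.0, 1000.0)])
    ]
    ms2_hits: list[SearchHit] = []
    ms3_hits: list[SearchHit] = []
    truth = GroundTruth(categories={}, links=[])
    scan = 1

    def next_scan() -> int:
        nonlocal scan
        scan += 1
        return scan

    def random_peaks(n: int = 5) -> list[tuple[float, float]]:
        mzs = rng.uniform(300.0, 1500.0, size=n)
        intensities = rng.uniform(1e3, 1e5, size=n)
        return [(float(m), float(i)) for m, i in zip(mzs, intensities)]

    def ppm_jitter(mass: float) -> float:
        if config.mass_noise_ppm == 0:
            return mass
        u = float(rng.uniform(-config.mass_noise_ppm, config.mass_noise_ppm))
        return mass * (1.0 + u * 1e-6)

    def maybe_decoy(
        accession: str, sequence: str, link_pos: int
    ) -> tuple[str, str, bool]:
        if config.decoy_fraction > 0 and rng.random() < config.decoy_fraction:
            return (
                msio.DEFAULT_DECOY_PREFIX + accession,
                _shuffled_decoy(rng, sequence, link_pos),
                True,
            )
        return accession, sequence, False

    def emit_pair_group(category: str) -> None:
        """Interlink-shaped group: CSM, INCOMPLETE_CSM or UNKNOWN."""
        acc_a, start_a, seq_a = pool.draw_linkable()
        while True:
            acc_b, start_b, seq_b = pool.draw_linkable()
            if (acc_b, start_b, seq_b) != (acc_a, start_a, seq_a):
                break
        pos_a = _internal_k_positions(seq_a)[0]
        pos_b = _internal_k_positions(seq_b)[0]
        stripped_a = peptide_mass(Peptide(seq_a))
        stripped_b = peptide_mass(Peptide(seq_b))
        true_mass = stripped_a + stripped_b + linker.bridge_mass
        observed = true_mass + (5.0 if category == INCOMPLETE_CSM else 0.0)
        observed = ppm_jitter(observed)
        charge = int(config.precursor_charges[
            rng.integers(len(config.precursor_charges))
        ])
        ms2_num = next_scan()
        # Signature doublets: singly protonated alkene/thiol fragment pair
        # per peptide, spaced exactly thiol - alkene.
        peaks = random_peaks()
        for stripped in (stripped_a, stripped_b):
            low = mz_from_neutral_mass(stripped + alkene.delta_mass, 1)
            peaks.append((low, 5e4))
            peaks.append((low + linker.signature_delta, 4e4))
        peaks.sort()
        spectra.append(SpectrumRecord(
            scan_id=f"scan={ms2_num}",
            ms_level=2,
            precursor_scan_id="scan=1",
            selected_ion_mz=mz_from_neutral_mass(observed, charge),
            precursor_charge=charge,
            peaks=peaks,
        ))
        prob = (
            config.prob_false if category == UNKNOWN else config.prob_true
        )
        for seq, acc, link_pos, remnant, pep_start in (
            (seq_a, acc_a, pos_a, alkene, start_a),
            (seq_b, acc_b, pos_b, thiol, start_b),
        ):
            ms3_num = next_scan()
            spectra.append(SpectrumRecord(
                scan_id=f"scan={ms3_num}",
                ms_level=3,
                precursor_scan_id=f"scan={ms2_num}",
                selected_ion_mz=mz_from_neutral_mass(
                    peptide_mass(Peptide(seq)) + remnant.delta_mass, 2
                ),
                precursor_charge=2,
                peaks=random_peaks(3),
            ))
            hit_acc, hit_seq, is_decoy = maybe_decoy(acc, seq, link_pos)
            truth.n_ms3_assignments += 1
            truth.n_decoy_ms3 += int(is_decoy)
            ms3_hits.append(SearchHit(
                scan_id=f"scan={ms3_num}",
                assigned_peptide=Peptide(
                    sequence=hit_seq,
                    mods=[(link_pos, remnant)],
                    protein_accession=hit_acc,
                    is_decoy=is_decoy,
                ),
                probability=prob,
            ))
        truth.categories[ms2_num] = category
        truth.group_peptides[ms2_num] = [seq_a, seq_b]
        if category == CSM_CATEGORY:
            truth.links.append(ResidueLink(
                acc_a, start_a + pos_a - 1, acc_b, start_b + pos_b - 1
            ).canonical())

    def emit_ms2_group(category: str) -> None:
        """MS2-identified group: SINGLE or MONOLINK (no MS3 children)."""
        if category == MONOLINK:
            acc, start, seq = pool.draw_linkable()
            mods = [(_internal_k_positions(seq)[0], linker.dead_end_mod)]
        else:
            acc, start, seq = pool.draw_plain()
            mods = []
        peptide = Peptide(sequence=seq, mods=mods, protein_accession=acc)
        mass = ppm_jitter(peptide_mass(peptide))
        charge = int(config.precursor_charges[
            rng.integers(len(config.precursor_charges))
        ])
        ms2_num = next_scan()
        spectra.append(SpectrumRecord(
            scan_id=f"scan={ms2_num}",
            ms_level=2,
            precursor_scan_id="scan=1",
            selected_ion_mz=mz_from_neutral_mass(mass, charge),
            precursor_charge=charge,
            peaks=random_peaks(),
        ))
        ms2_hits.append(SearchHit(
            scan_id=f"scan={ms2_num}",
            assigned_peptide=peptide,
            probability=config.prob_true,
        ))
        truth.categories[ms2_num] = category
        truth.group_peptides[ms2_num] = [seq]

    # Emission order is deterministic and interleaving-free; shuffled input
    # order is a grouping-layer concern exercised separately in tests.
    for _ in range(config.n_interlinks):
        emit_pair_group(CSM_CATEGORY)
    for _ in range(config.n_monolinks):
        emit_ms2_group(MONOLINK)
    for _ in range(config.n_singles):
        emit_ms2_group(SINGLE)
    for _ in range(config.n_incomplete):
        emit_pair_group(INCOMPLETE_CSM)
    for _ in range(config.n_unknown):
        emit_pair_group(UNKNOWN)

    return SimulatedDataset(spectra, ms2_hits, ms3_hits, proteins, truth)


def simulate_dataset(
    config: SimulationConfig, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Write a full synthetic fixture set: FASTA, mzML, two PepXML, truth TSV.

    Returns the file paths and the ground truth.  Identical configs
    (including seed) produce byte-identical files.
    """
    data = simulate_groups(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "mzml": outdir / "spectra.mzML",
        "pepxml_ms2": outdir / "search_ms2.pep.xml",
        "pepxml_ms3": outdir / "search_ms3.pep.xml",
        "truth": outdir / "ground_truth.tsv",
    }
    rng = np.random.default_rng(config.seed + 1)
    with paths["fasta"].open("w") as handle:
        for accession, sequence in data.proteins.items():
            handle.write(f">{accession} synthetic\n{sequence}\n")
        for accession, sequence in data.proteins.items():
            decoy = "".join(
                np.array(list(sequence))[rng.permutation(len(sequence))]
            )
            handle.write(
                f">{msio.DEFAULT_DECOY_PREFIX}{accession} synthetic decoy\n"
                f"{decoy}\n"
            )
    msio.write_mzml(data.spectra, paths["mzml"])
    msio.write_pepxml(data.ms2_hits, paths["pepxml_ms2"])
    msio.write_pepxml(data.ms3_hits, paths["pepxml_ms3"])
    with paths["truth"].open("w") as handle:
        handle.write("ms2_scan\tcategory\tpeptides\n")
        for num in sorted(data.truth.categories):
            peptides = ";".join(data.truth.group_peptides.get(num, []))
            handle.write(f"{num}\t{data.truth.categories[num]}\t{peptides}\n")
    return paths, data.truth


def _quantize(x: float) -> float:
    # PDB coordinate fields carry 3 decimals; quantizing up front keeps the
    # on-disk structure exactly equal to the in-memory one.
    return round(x, 3)


def simulate_structure(
    links: list[ResidueLink],
    distances: list[float],
    seed: int = 0,
) -> tuple[StructureModel, list[ChainMapping], str]:
    """Build a toy structure realizing each link at a requested distance.

    Each linked Calpha pair is placed axis-aligned exactly at its
    requested distance (quantized to the 0.001-A PDB precision);
    non-linked residues sit on a distant non-clashing trace.  Returns the
    model, explicit offset-0 chain mappings, and the PDB text.  Requests
    that place one residue at two inconsistent positions raise
    ``ValueError``.
    """
    if len(links) != len(distances):
        raise ValueError("need exactly one distance per link")
    if any(d <= 0 for d in distances):
        raise ValueError("distances must be positive")
    accessions = sorted(
        {l.accession_a for l in links} | {l.accession_b for l in links}
    )
    chain_ids = {acc: chr(ord("A") + i) for i, acc in enumerate(accessions)}
    placed: dict[tuple[str, int], np.ndarray] = {}
    for index, (link, dist) in enumerate(zip(links, distances)):
        dist = _quantize(dist)
        key_a = (link.accession_a, link.residue_a)
        key_b = (link.accession_b, link.residue_b)
        if key_a in placed and key_b in placed:
            have = float(np.linalg.norm(placed[key_a] - placed[key_b]))
            if abs(have - dist) > 1e-6:
                raise ValueError(
                    f"inconsistent constraints: {key_a}-{key_b} already at "
                    f"{have:.3f} A, requested {dist:.3f} A"
                )
            continue
        if key_a not in placed and key_b not in placed:
            placed[key_a] = np.array([_quantize(100.0 * index), 0.0, 0.0])
        anchor, free = (key_a, key_b) if key_a in placed else (key_b, key_a)
        placed[free] = placed[anchor] + np.array([dist, 0.0, 0.0])
    # Backbone trace for context residues, far from the planted pairs.
    chains: dict[str, list[StructureResidue]] = {}
    max_residue = {
        acc: max(
            [l.residue_a for l in links if l.accession_a == acc]
            + [l.residue_b for l in links if l.accession_b == acc]
        )
        for acc in accessions
    }
    for chain_index, acc in enumerate(accessions):
        residues = []
        for number in range(1, max_residue[acc] + 3):
            key = (acc, number)
            if key in placed:
                coord = placed[key]
                name = "LYS"
            else:
                coord = np.array([
                    _quantize(4.0 * number),
                    _quantize(1000.0 + 100.0 * chain_index),
                    0.0,
                ])
                name = "ALA"
            residues.append(StructureResidue(number, " ", name, coord))
        chains[chain_ids[acc]] = residues
    model = StructureModel(chains)
    mappings = [
        ChainMapping(accession=acc, chain_id=chain_ids[acc], offset=0)
        for acc in accessions
    ]
    return model, mappings, _to_pdb(model)


def _to_pdb(model: StructureModel) -> str:
    lines = []
    serial = 0
    for chain_id in sorted(model.chains):
        for residue in model.chains[chain_id]:
            if residue.ca is None:
                continue
            serial += 1
            x, y, z = residue.ca
            lines.append(
                f"ATOM  {serial:5d}  CA  {residue.name:>3s} {chain_id}"
                f"{residue.number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"  1.00  0.00           C"
            )
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
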