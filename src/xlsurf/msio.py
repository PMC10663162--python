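"""Readers and writers for mzML spectra, PepXML search results and TSV reports.

Only the subset of each format that the spectral-group classifier consumes
is handled: scan hierarchy and precursor metadata from mzML (peak arrays
optional), rank/peptide/modification/probability from PepXML.  Parsing is
stdlib ``xml.etree`` based and tolerant of namespaced or namespace-free
documents.
"""

from __future__ import annotations

import base64
import logging
import re
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
from xml.etree import ElementTree as ET

import pandas as pd
from Bio import SeqIO

from .chem import (
    Modification,
    Peptide,
    RESIDUE_MASS,
    neutral_mass_from_mz,
)

logger = logging.getLogger(__name__)

DEFAULT_DECOY_PREFIX = "DECOY_"

# mzML controlled-vocabulary accessions.
_CV_MS_LEVEL = "MS:1000511"
_CV_SELECTED_MZ = "MS:1000744"
_CV_CHARGE_STATE = "MS:1000041"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"
_CV_64BIT = "MS:1000523"
_CV_32BIT = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_NO_COMPRESSION = "MS:1000576"


@dataclass
class SpectrumRecord:
    """One spectrum with its place in the MS1/MS2/MS3 scan hierarchy."""

    scan_id: str
    ms_level: int
    precursor_scan_id: str = ""
    selected_ion_mz: float = 0.0
    precursor_charge: int = 0
    peaks: list[tuple[float, float]] = field(default_factory=list)
    precursor_missing: bool = False

    def __post_init__(self) -> None:
        if self.ms_level not in (1, 2, 3):
            raise ValueError(f"ms_level must be 1-3, got {self.ms_level}")
        if self.ms_level >= 2 and self.selected_ion_mz <= 0:
            raise ValueError(
                f"MS{self.ms_level} spectrum {self.scan_id!r} lacks a "
                "positive selected ion m/z"
            )

    @property
    def scan_number(self) -> int | None:
        return scan_number(self.scan_id)


@dataclass
class SearchHit:
    """A peptide-spectrum assignment with its posterior probability."""

    scan_id: str
    assigned_peptide: Peptide
    probability: float
    hit_rank: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")

    @property
    def scan_number(self) -> int | None:
        return scan_number(self.scan_id)


_SCAN_RE = re.compile(r"scan[=_ ]?(\d+)", re.IGNORECASE)


def scan_number(scan_id: str) -> int | None:
    """Extract the scan number from a native id or a PepXML spectrum name.

    Handles ``scan=123``, Thermo-style ``controllerType=0 ... scan=123``
    and dotted TPP names like ``run.123.123.4`` (start-scan field).  Run
    prefixes are ignored so MS2 and MS3 result files from the same run
    join on the number alone.
    """
    m = _SCAN_RE.search(scan_id)
    if m:
        return int(m.group(1))
    parts = scan_id.split(".")
    if len(parts) >= 3 and parts[-3].isdigit():
        return int(parts[-3])
    digits = re.findall(r"\d+", scan_id)
    return int(digits[-1]) if digits else None


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element: ET.Element) -> dict[str, str]:
    out = {}
    for child in element:
        if _local(child.tag) == "cvParam":
            out[child.get("accession", "")] = child.get("value", "")
    return out


def _decode_binary(array_el: ET.Element) -> list[float]:
    accessions = {c.get("accession") for c in array_el if _local(c.tag) == "cvParam"}
    binary = next((c for c in array_el if _local(c.tag) == "binary"), None)
    if binary is None or not (binary.text or "").strip():
        return []
    raw = base64.b64decode(binary.text.strip())
    if _CV_ZLIB in accessions:
        raw = zlib.decompress(raw)
    fmt = "f" if _CV_32BIT in accessions else "d"
    width = 4 if fmt == "f" else 8
    return list(struct.unpack(f"<{len(raw) // width}{fmt}", raw))


def read_mzml(path: str | Path, with_peaks: bool = True) -> list[SpectrumRecord]:
    """Read an mzML file into spectrum records with resolved parent links.

    Precursor linkage prefers the explicit ``spectrumRef``; when absent
    the nearest preceding scan one MS level down is used.  An MS3 scan
    whose reference cannot be resolved is kept and flagged
    (``precursor_missing``) with a logged warning.  Set
    ``with_peaks=False`` for a metadata-only pass on large runs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SpectrumRecord] = []
    last_at_level: dict[int, str] = {}
    seen_ids: set[str] = set()
    for _, spectrum in _iter_spectra(path):
        scan_id = spectrum.get("id", "")
        params = _cv_params(spectrum)
        ms_level = int(params.get(_CV_MS_LEVEL, "1"))
        selected_mz = 0.0
        charge = 0
        precursor_ref = ""
        missing = False
        for child in spectrum.iter():
            if _local(child.tag) == "precursor":
                precursor_ref = child.get("spectrumRef", "")
            elif _local(child.tag) == "selectedIon":
                ion = _cv_params(child)
                selected_mz = float(ion.get(_CV_SELECTED_MZ, 0.0) or 0.0)
                charge = int(ion.get(_CV_CHARGE_STATE, 0) or 0)
        peaks: list[tuple[float, float]] = []
        if with_peaks:
            arrays: dict[str, list[float]] = {}
            for child in spectrum.iter():
                if _local(child.tag) == "binaryDataArray":
                    acc = {
                        c.get("accession")
                        for c in child
                        if _local(c.tag) == "cvParam"
                    }
                    key = "mz" if _CV_MZ_ARRAY in acc else (
                        "intensity" if _CV_INTENSITY_ARRAY in acc else ""
                    )
                    if key:
                        arrays[key] = _decode_binary(child)
            peaks = list(zip(arrays.get("mz", []), arrays.get("intensity", [])))
        if ms_level >= 2:
            if precursor_ref and precursor_ref not in seen_ids:
                logger.warning(
                    "spectrum %s references missing precursor scan %s",
                    scan_id, precursor_ref,
                )
                missing = True
            elif not precursor_ref:
                fallback = last_at_level.get(ms_level - 1, "")
                if fallback:
                    precursor_ref = fallback
                else:
                    logger.warning(
                        "spectrum %s (MS%d) has no resolvable precursor",
                        scan_id, ms_level,
                    )
                    missing = True
        records.append(
            SpectrumRecord(
                scan_id=scan_id,
                ms_level=ms_level,
                precursor_scan_id=precursor_ref,
                selected_ion_mz=selected_mz,
                precursor_charge=charge,
                peaks=peaks,
                precursor_missing=missing,
            )
        )
        seen_ids.add(scan_id)
        last_at_level[ms_level] = scan_id
    return records


def _iter_spectra(path: Path):
    for event, element in ET.iterparse(str(path), events=("end",)):
        if _local(element.tag) == "spectrum":
            yield event, element
            element.clear()


def write_mzml(records: Sequence[SpectrumRecord], path: str | Path) -> None:
    """Serialize spectrum records as minimal centroid mzML."""
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '  <run id="run1">',
        f'    <spectrumList count="{len(records)}">',
    ]
    for index, rec in enumerate(records):
        lines.append(
            f'      <spectrum index="{index}" id="{rec.scan_id}" '
            f'defaultArrayLength="{len(rec.peaks)}">'
        )
        lines.append(
            f'        <cvParam cvRef="MS" accession="{_CV_MS_LEVEL}" '
            f'name="ms level" value="{rec.ms_level}"/>'
        )
        if rec.ms_level >= 2:
            ref = (
                f' spectrumRef="{rec.precursor_scan_id}"'
                if rec.precursor_scan_id
                else ""
            )
            lines.append('        <precursorList count="1">')
            lines.append(f"          <precursor{ref}>")
            lines.append('            <selectedIonList count="1">')
            lines.append("              <selectedIon>")
            lines.append(
                f'                <cvParam cvRef="MS" accession="{_CV_SELECTED_MZ}" '
                f'name="selected ion m/z" value="{rec.selected_ion_mz:.10f}"/>'
            )
            if rec.precursor_charge:
                lines.append(
                    f'                <cvParam cvRef="MS" accession="{_CV_CHARGE_STATE}" '
                    f'name="charge state" value="{rec.precursor_charge}"/>'
                )
            lines.append("              </selectedIon>")
            lines.append("            </selectedIonList>")
            lines.append("          </precursor>")
            lines.append("        </precursorList>")
        lines.append('        <binaryDataArrayList count="2">')
        for accession, name, values in (
            (_CV_MZ_ARRAY, "m/z array", [p[0] for p in rec.peaks]),
            (_CV_INTENSITY_ARRAY, "intensity array", [p[1] for p in rec.peaks]),
        ):
            encoded = base64.b64encode(
                struct.pack(f"<{len(values)}d", *values)
            ).decode("ascii")
            lines.append(
                f'          <binaryDataArray encodedLength="{len(encoded)}">'
            )
            lines.append(
                f'            <cvParam cvRef="MS" accession="{_CV_64BIT}" '
                'name="64-bit float"/>'
            )
            lines.append(
                f'            <cvParam cvRef="MS" accession="{_CV_NO_COMPRESSION}" '
                'name="no compression"/>'
            )
            lines.append(
                f'            <cvParam cvRef="MS" accession="{accession}" '
                f'name="{name}"/>'
            )
            lines.append(f"            <binary>{encoded}</binary>")
            lines.append("          </binaryDataArray>")
        lines.append("        </binaryDataArrayList>")
        lines.append("      </spectrum>")
    lines += ["    </spectrumList>", "  </run>", "</mzML>", ""]
    Path(path).write_text("\n".join(lines))


def read_pepxml(
    path: str | Path,
    known_mods: Iterable[Modification] = (),
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
    all_ranks: bool = False,
    mod_match_tol: float = 0.01,
) -> list[SearchHit]:
    """Read PepXML search results into :class:`SearchHit` records.

    One hit per rank-1 ``search_hit`` (``all_ranks=True`` keeps all).
    Modification masses (PepXML reports residue+delta totals) are mapped
    to the nearest configured :class:`~xlsurf.chem.Modification` within
    ``mod_match_tol`` Da; unmatched deltas are kept as ``unknown``
    variable modifications with a logged warning.  Decoy status comes
    from the accession prefix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mods = list(known_mods)
    hits: list[SearchHit] = []
    for _, query in _iter_elements(path, "spectrum_query"):
        scan_id = query.get("native_id") or query.get("spectrum", "")
        for hit_el in query.iter():
            if _local(hit_el.tag) != "search_hit":
                continue
            rank = int(hit_el.get("hit_rank", "1"))
            if not all_ranks and rank != 1:
                continue
            sequence = hit_el.get("peptide", "")
            protein = hit_el.get("protein", "")
            pep_mods: list[tuple[int | str, Modification]] = []
            probability = 0.0
            for child in hit_el.iter():
                tag = _local(child.tag)
                if tag == "mod_aminoacid_mass":
                    position = int(child.get("position"))
                    total = float(child.get("mass"))
                    residue = sequence[position - 1]
                    delta = total - RESIDUE_MASS.get(residue, 0.0)
                    pep_mods.append(
                        (position, _match_mod(delta, residue, mods, mod_match_tol))
                    )
                elif tag == "peptideprophet_result":
                    probability = float(child.get("probability", "0"))
                elif tag == "search_score" and probability == 0.0:
                    # Fallback when no PeptideProphet block is present.
                    if child.get("name") in {"probability", "prob"}:
                        probability = float(child.get("value", "0"))
            peptide = Peptide(
                sequence=sequence,
                mods=pep_mods,
                protein_accession=protein,
                is_decoy=protein.startswith(decoy_prefix),
            )
            hits.append(
                SearchHit(
                    scan_id=scan_id,
                    assigned_peptide=peptide,
                    probability=probability,
                    hit_rank=rank,
                )
            )
    return hits


def _match_mod(
    delta: float, residue: str, mods: list[Modification], tol: float
) -> Modification:
    best: Modification | None = None
    best_err = tol
    for mod in mods:
        err = abs(mod.delta_mass - delta)
        if err <= best_err:
            best, best_err = mod, err
    if best is None:
        logger.warning(
            "unmatched modification delta %+.4f Da on %s; recording as unknown",
            delta, residue,
        )
        return Modification("unknown", delta, residue, "variable")
    return best


def _iter_elements(path: Path, local_name: str):
    for event, element in ET.iterparse(str(path), events=("end",)):
        if _local(element.tag) == local_name:
            yield event, element
            element.clear()


def write_pepxml(hits: Sequence[SearchHit], path: str | Path,
                 precursor_info: dict[str, tuple[float, int]] | None = None) -> None:
    """Serialize hits as minimal TPP-style PepXML.

    ``precursor_info`` optionally maps scan ids to
    ``(precursor_neutral_mass, assumed_charge)``.
    """
    from .chem import peptide_mass  # local import to avoid cycle at module load

    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<msms_pipeline_analysis '
        'xmlns="http://regis-web.systemsbiology.net/pepXML">',
        '  <msms_run_summary base_name="run1" raw_data=".mzML">',
    ]
    by_scan: dict[str, list[SearchHit]] = {}
    for hit in hits:
        by_scan.setdefault(hit.scan_id, []).append(hit)
    for scan_id, scan_hits in by_scan.items():
        number = scan_number(scan_id) or 0
        mass, charge = (precursor_info or {}).get(scan_id, (0.0, 0))
        lines.append(
            f'    <spectrum_query spectrum="run1.{number}.{number}.{charge}" '
            f'native_id="{scan_id}" start_scan="{number}" end_scan="{number}" '
            f'precursor_neutral_mass="{mass:.6f}" assumed_charge="{charge}">'
        )
        lines.append("      <search_result>")
        for hit in scan_hits:
            pep = hit.assigned_peptide
            lines.append(
                f'        <search_hit hit_rank="{hit.hit_rank}" '
                f'peptide="{pep.sequence}" protein="{pep.protein_accession}" '
                f'calc_neutral_pep_mass="{peptide_mass(pep):.6f}">'
            )
            positional = [(p, m) for p, m in pep.mods if isinstance(p, int)]
            if positional:
                lines.append("          <modification_info>")
                for pos, mod in positional:
                    total = RESIDUE_MASS[pep.sequence[pos - 1]] + mod.delta_mass
                    lines.append(
                        f'            <mod_aminoacid_mass position="{pos}" '
                        f'mass="{total:.6f}"/>'
                    )
                lines.append("          </modification_info>")
            lines.append(
                '          <analysis_result analysis="peptideprophet">'
            )
            lines.append(
                f'            <peptideprophet_result '
                f'probability="{hit.probability:.4f}"/>'
            )
            lines.append("          </analysis_result>")
            lines.append("        </search_hit>")
        lines.append("      </search_result>")
        lines.append("    </spectrum_query>")
    lines += ["  </msms_run_summary>", "</msms_pipeline_analysis>", ""]
    Path(path).write_text("\n".join(lines))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Accession -> sequence map (first whitespace-delimited token of header)."""
    return {
        record.id: str(record.seq) for record in SeqIO.parse(str(path), "fasta")
    }


def locate_peptides(hits: Iterable[SearchHit], sequences: dict[str, str]) -> None:
    """Fill in peptide protein start positions by substring lookup.

    Peptides whose accession or sequence cannot be located (typical for
    randomized decoys) keep ``start_position=None``.
    """
    for hit in hits:
        pep = hit.assigned_peptide
        protein = sequences.get(pep.protein_accession)
        if protein is None:
            continue
        index = protein.find(pep.sequence)
        if index >= 0:
            pep.start_position = index + 1


CSM_COLUMNS = [
    "ms2_scan", "category", "charge",
    "peptide_a", "protein_a", "start_a", "link_pos_a", "decoy_a", "prob_a",
    "peptide_b", "protein_b", "start_b", "link_pos_b", "decoy_b", "prob_b",
    "observed_mass", "theoretical_mass", "ppm_error",
    "combined_probability", "decoy_class",
]


def write_csm_table(results, path: str | Path) -> None:
    """Write classified spectral groups as a TSV, one row per group.

    Rows are ordered by MS2 scan number so repeated runs are
    byte-identical; non-CSM categories leave the pair columns empty.
    """
    rows = []
    for cg in sorted(results, key=lambda r: (r.group.scan_number or 0,
                                             r.group.ms2_scan.scan_id)):
        row = dict.fromkeys(CSM_COLUMNS, "")
        row["ms2_scan"] = cg.group.ms2_scan.scan_id
        row["category"] = cg.category
        row["charge"] = cg.group.precursor_charge or ""
        if cg.csm is not None:
            csm = cg.csm
            row.update(
                peptide_a=csm.peptide_a.sequence,
                protein_a=csm.peptide_a.protein_accession,
                start_a=csm.peptide_a.start_position or "",
                link_pos_a=csm.link_pos_a,
                decoy_a=csm.peptide_a.is_decoy,
                prob_a=round(csm.probability_a, 4),
                peptide_b=csm.peptide_b.sequence,
                protein_b=csm.peptide_b.protein_accession,
                start_b=csm.peptide_b.start_position or "",
                link_pos_b=csm.link_pos_b,
                decoy_b=csm.peptide_b.is_decoy,
                prob_b=round(csm.probability_b, 4),
                observed_mass=round(csm.observed_mass, 6),
                theoretical_mass=round(csm.theoretical_mass, 6),
                ppm_error=round(csm.mass_error, 3),
                combined_probability=round(csm.combined_probability, 6),
                decoy_class=csm.decoy_class,
            )
        rows.append(row)
    frame = pd.DataFrame(rows, columns=CSM_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_csm_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
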