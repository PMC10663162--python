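"""Assembly of spectral groups from the MS1/MS2/MS3 scan hierarchy.

A spectral group is one MS2 precursor scan together with its MS2 search
result (if any) and the search results of all MS3 scans that were
acquired from that precursor.  It is the unit on which the cross-link
classifier operates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .chem import neutral_mass_from_mz
from .msio import SearchHit, SpectrumRecord, scan_number

logger = logging.getLogger(__name__)


@dataclass
class SpectralGroup:
    ms2_scan: SpectrumRecord
    precursor_charge: int
    precursor_neutral_mass: float | None
    ms2_hit: SearchHit | None = None
    ms3_hits: list[SearchHit] = field(default_factory=list)
    ms3_scans: list[SpectrumRecord] = field(default_factory=list)

    @property
    def scan_number(self) -> int | None:
        return scan_number(self.ms2_scan.scan_id)


def build_spectral_groups(
    spectra: list[SpectrumRecord],
    ms2_hits: list[SearchHit],
    ms3_hits: list[SearchHit],
    diagnostics: dict | None = None,
) -> list[SpectralGroup]:
    """Group spectra and search hits by their MS2 precursor scan.

    One group is produced for every MS2 scan that has at least one child
    MS3 scan or an MS2 search hit.  MS3 hits whose scan or parent MS2
    scan is absent from ``spectra`` are dropped with a warning and
    counted in ``diagnostics`` (keys ``orphan_ms2_hits`` /
    ``orphan_ms3_hits``).  Output order follows the MS2 scan number, so
    the result is independent of input shuffling.
    """
    tally = {"orphan_ms2_hits": 0, "orphan_ms3_hits": 0}

    by_number: dict[int, SpectrumRecord] = {}
    for spectrum in spectra:
        num = spectrum.scan_number
        if num is not None:
            by_number[num] = spectrum
    by_id = {s.scan_id: s for s in spectra}

    children: dict[str, list[SpectrumRecord]] = {}
    for spectrum in spectra:
        if spectrum.ms_level == 3 and spectrum.precursor_scan_id:
            children.setdefault(spectrum.precursor_scan_id, []).append(spectrum)

    ms2_hit_by_scan: dict[str, SearchHit] = {}
    for hit in ms2_hits:
        num = hit.scan_number
        spectrum = by_number.get(num) if num is not None else None
        if spectrum is None or spectrum.ms_level != 2:
            tally["orphan_ms2_hits"] += 1
            logger.warning("MS2 hit for unknown scan %s dropped", hit.scan_id)
            continue
        # Keep the best-rank (then highest-probability) hit per scan.
        current = ms2_hit_by_scan.get(spectrum.scan_id)
        if current is None or (hit.hit_rank, -hit.probability) < (
            current.hit_rank, -current.probability
        ):
            ms2_hit_by_scan[spectrum.scan_id] = hit

    ms3_hits_by_parent: dict[str, list[SearchHit]] = {}
    for hit in ms3_hits:
        num = hit.scan_number
        spectrum = by_number.get(num) if num is not None else None
        if spectrum is None or spectrum.ms_level != 3:
            tally["orphan_ms3_hits"] += 1
            logger.warning("MS3 hit for unknown scan %s dropped", hit.scan_id)
            continue
        parent = by_id.get(spectrum.precursor_scan_id)
        if parent is None or parent.ms_level != 2:
            tally["orphan_ms3_hits"] += 1
            logger.warning(
                "MS3 hit %s has no resolvable MS2 parent; dropped", hit.scan_id
            )
            continue
        ms3_hits_by_parent.setdefault(parent.scan_id, []).append(hit)

    groups: list[SpectralGroup] = []
    for spectrum in spectra:
        if spectrum.ms_level != 2:
            continue
        kids = children.get(spectrum.scan_id, [])
        hit = ms2_hit_by_scan.get(spectrum.scan_id)
        hits3 = ms3_hits_by_parent.get(spectrum.scan_id, [])
        if not kids and hit is None and not hits3:
            continue
        charge = spectrum.precursor_charge
        mass = (
            neutral_mass_from_mz(spectrum.selected_ion_mz, charge)
            if charge > 0
            else None
        )
        groups.append(
            SpectralGroup(
                ms2_scan=spectrum,
                precursor_charge=charge,
                precursor_neutral_mass=mass,
                ms2_hit=hit,
                ms3_hits=sorted(
                    hits3, key=lambda h: (h.scan_number or 0, h.hit_rank)
                ),
                ms3_scans=sorted(kids, key=lambda s: s.scan_number or 0),
            )
        )
    groups.sort(key=lambda g: (g.scan_number or 0, g.ms2_scan.scan_id))
    if diagnostics is not None:
        diagnostics.update(tally)
    return groups
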