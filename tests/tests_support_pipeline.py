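"""Shared test helpers: pipeline shortcut and an independent naive classifier.

The naive classifier is the brute-force oracle for the decision tree: it
re-states the classification rules as plain loops over all hits and all
peptide pairs, independent of the production implementation's candidate
filtering, pair enumeration and tie-breaking structure.
"""

import itertools

from xlsurf import msio
from xlsurf.chem import DSSO, peptide_mass
from xlsurf.classify import ClassifierConfig, classify_all
from xlsurf.grouping import build_spectral_groups


def classify_fixture(paths, config=None):
    linker = (config or ClassifierConfig()).linker
    spectra = msio.read_mzml(paths["mzml"])
    known = linker.known_mods()
    ms2_hits = msio.read_pepxml(paths["pepxml_ms2"], known)
    ms3_hits = msio.read_pepxml(paths["pepxml_ms3"], known)
    sequences = msio.read_fasta(paths["fasta"])
    msio.locate_peptides(ms2_hits, sequences)
    msio.locate_peptides(ms3_hits, sequences)
    groups = build_spectral_groups(spectra, ms2_hits, ms3_hits)
    return classify_all(groups, config or ClassifierConfig())


def _linker_k_mods(peptide, linker):
    out = []
    for pos, mod in peptide.mods:
        if not isinstance(pos, int):
            continue
        if peptide.sequence[pos - 1] != linker.reactive_residue:
            continue
        if mod.mod_class in ("remnant", "dead_end"):
            out.append((pos, mod))
    return out


def naive_classify(group, config):
    """Brute-force reference: every rule written out longhand."""
    linker = config.linker
    threshold = config.probability_threshold

    hit = group.ms2_hit
    if hit is not None and hit.probability > threshold:
        peptide = hit.assigned_peptide
        k_mods = _linker_k_mods(peptide, linker)
        if not k_mods:
            return "SINGLE"
        internal_dead_end = [
            pos for pos, mod in k_mods
            if mod.mod_class == "dead_end" and pos < len(peptide.sequence)
        ]
        if internal_dead_end:
            return "MONOLINK"

    candidates = []
    for ms3 in group.ms3_hits:
        if ms3.probability <= threshold:
            continue
        has_remnant = any(
            mod.mod_class == "remnant"
            for _, mod in _linker_k_mods(ms3.assigned_peptide, linker)
        )
        if has_remnant:
            candidates.append(ms3)
    if len({c.scan_id for c in candidates}) < 2:
        return "UNKNOWN"

    if group.precursor_neutral_mass is not None:
        observed_masses = [group.precursor_neutral_mass]
    else:
        lo, hi = config.charge_range_for_unknown
        observed_masses = [
            z * group.ms2_scan.selected_ion_mz - z * 1.0072765
            for z in range(lo, hi + 1)
        ]
    strip = ("fixed", "variable", "dead_end")
    for a, b in itertools.combinations(candidates, 2):
        if a.scan_id == b.scan_id:
            continue
        theoretical = (
            peptide_mass(a.assigned_peptide, strip)
            + peptide_mass(b.assigned_peptide, strip)
            + linker.bridge_mass
        )
        for observed in observed_masses:
            error_ppm = (observed - theoretical) / theoretical * 1e6
            if abs(error_ppm) <= config.precursor_tol_ppm:
                return "CSM"
    return "INCOMPLETE_CSM"
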