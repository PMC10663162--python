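# Methods

## Chemistry model

All masses are monoisotopic, computed from an embedded IUPAC/CIAAW 2021
atomic-mass table (`xlsurf.chem.ATOMIC_MASS`) so results do not depend
on third-party library versions. The proton mass is fixed at
1.0072765 Da and all charges are positive-mode.

DSSO is defined by its remnant formulas rather than hard-coded masses:
alkene C₃H₂O (54.01056 Da), thiol C₃H₂SO (85.98264 Da), sulfenic acid
C₃H₄O₂S (103.99320 Da). Derived quantities follow by construction:

- intact bridge = alkene + sulfenic acid = 158.00377 Da,
- signature doublet spacing = thiol − alkene = 31.97207 Da (the mass of
  S, since thiol = alkene + S),
- dead-end (hydrolyzed monolink) = bridge + H₂O = 176.01433 Da. No
  literature value is printed for this quantity; bridge + water is the
  standard NHS-ester hydrolysis product and is an implementer-supplied
  choice.

PhoX ships as a non-cleavable built-in with bridge C₈H₃O₅P
(209.97181 Da) and a 25 Å Cα–Cα default — both implementer-supplied,
configurable via the YAML linker config (`chem.load_linkers`).

## Classification

The decision tree is applied to each spectral group exactly once, in
order: confident MS² assignment → `SINGLE` / `MONOLINK`; otherwise
qualifying MS³ assignments → mass-sum validation → `CSM` /
`INCOMPLETE_CSM`; else `UNKNOWN`. Conventions:

- **Probability gate.** Strictly greater than the threshold (default
  0.8), matching the published ">0.8" rule. The probability is the
  PeptideProphet-style posterior from PepXML.
- **"Internal" lysine.** A modified lysine not at the peptide
  C-terminus. A cross-linked or dead-end lysine blocks trypsin, so a
  genuine site appears as a missed cleavage; a C-terminal dead-end
  assignment is treated as unreliable and falls through the tree.
- **Mass-sum convention.** Remnant deltas are stripped from both
  peptides and the intact bridge mass is added once:
  `M_A^stripped + M_B^stripped + M_bridge`. This makes validation
  independent of whether the search reported the alkene/thiol or
  alkene/sulfenic-acid remnant pair (thiol and sulfenic acid differ by
  water, which would otherwise shift the sum).
- **Pair enumeration.** All unordered candidate pairs from *distinct*
  MS³ scans are tested; the accepted pair is the one with the smallest
  absolute ppm error, ties broken by larger combined probability, then
  lexicographic peptide order — fixed so outputs are bit-stable.
- **Unknown precursor charge.** When the instrument reported no charge,
  the mass-sum test is repeated for each charge hypothesis in 4–8 (the
  acquisition selects ≥4+ precursors for cross-links) and the
  smallest-error acceptance wins, annotated with the inferred charge.
- **Combined probability.** The product of the two assignment
  probabilities; the quantity is not defined upstream and is used only
  for tie-breaking and reporting.
- **Loop-links.** An optional sixth category (`allow_looplink`), off by
  default, for single MS² peptides carrying the intact +bridge mass.

**FDR.** Among CSMs, TT/TD/DD counts by decoy flags (accession prefix,
default `DECOY_`), and `FDR = (TD + DD) / max(TT, 1)` — a conservative
estimator, reported rather than used as a filter. With zero CSMs the
FDR is reported as 0 with a warning.

## File handling

mzML and PepXML are parsed with the stdlib `xml.etree` event parser
(namespace-agnostic; 32/64-bit float peak arrays, zlib or uncompressed).
Precursor linkage prefers the explicit `spectrumRef` and falls back to
the nearest preceding scan one MS level down; unresolvable MS³ parents
are kept, flagged and logged. MS² and MS³ results may arrive in separate
PepXML files; scans are joined on the scan *number* extracted from
native ids or TPP dotted names, ignoring run prefixes. Modification
masses are matched to the configured set by nearest delta within
0.01 Da; unmatched deltas are kept as `unknown`. PepXML carries no
protein start coordinate, so peptide start positions are resolved by
substring lookup against the FASTA (`msio.locate_peptides`); randomized
decoy peptides generally do not locate and their links are flagged
unmapped.

## Structure mapping

Protein positions are 1-based throughout; structure author numbering is
reached only through an explicit `ChainMapping` (constant offset or an
alignment-derived per-residue map; local alignment match +1, mismatch
−1, gap −2, with a 20-identical-residue floor and a hard error on chain
ties such as homodimers — ambiguity is surfaced, never guessed). Model 1
only; waters/heteroatoms excluded; highest-occupancy altloc. Residues
are keyed by (author number, insertion code); links address the number
only and resolve to `UNRESOLVED` on insertion-code ambiguity.

A link is `SATISFIED` when its Cα–Cα distance is strictly below the
threshold (default 20 Å for DSSO, per the published "<20 Å" constraint;
the strict inequality matters only exactly at the boundary) and
`VIOLATED` otherwise; ends that cannot be resolved leave the record
`UNRESOLVED` rather than guessed.

## Synthetic data

`simulate_dataset` emulates exactly what the classifier consumes:
random proteins (uniform residues with lysine density ≥ 5% and arginine
~6% so tryptic peptides with internal lysines always exist), tryptic
digestion with ≤ 3 missed cleavages, and per planted category:

- **interlink**: two remnant-modified peptides (alkene/thiol), precursor
  neutral mass = stripped masses + bridge (± `mass_noise_ppm`, default
  0), charge from {4, 5, 6}, MS² signature doublet pair per peptide
  spaced exactly thiol − alkene, two MS³ children with assignments at
  `prob_true` (default 0.99);
- **monolink**: MS² peptide with the dead-end mass on an internal
  lysine; **single**: unmodified MS² peptide; both at `prob_true`;
- **incomplete**: interlink-shaped with the precursor shifted +5 Da so
  no pair sums; **unknown**: interlink-shaped with assignments at
  `prob_false` (default 0.10).

Decoy assignments are injected per MS³ assignment at `decoy_fraction`
by shuffling the peptide (fixing the linked lysine and the C-terminal
residue), which preserves composition — hence mass — so decoy CSMs
still validate, as randomized-decoy database hits do in practice. The
same seed yields byte-identical files.

The generator does **not** model isotope envelopes, retention time,
chromatographic coelution, fragment-ion ladders or search-engine score
distributions; a green recovery test therefore establishes the
correctness of grouping, mass arithmetic and the decision tree, not
robustness to real search-engine error modes.

`simulate_structure` places each linked Cα pair axis-aligned at exactly
the requested distance and context residues on a distant trace.
Coordinates are quantized to 0.001 Å (the PDB field precision) up
front, so the in-memory model realizes planted distances to better than
1e-6 Å; the written PDB file round-trips at format/parser precision
(~1e-4 Å, Biopython stores coordinates as float32).

## Numerical choices

- Formula/mass invariants are enforced at 1e-4 Da; mass arithmetic is
  reproducible to 1e-5 Da.
- The mzML writer emits selected-ion m/z at 10 decimals so noiseless
  fixtures survive a file round trip at sub-1e-6-ppm precision; peak
  arrays are exact little-endian float64.
- Group and table ordering is always by MS² scan number; all tie-breaks
  are total orders, so outputs are deterministic under input shuffling.

## Known limitations

- Fragment-ion level verification of MS³ assignments is out of scope
  (the search engine's job); the doublet peaks in simulated MS² spectra
  exist for detection tests, not for rescoring.
- The FDR block estimates, it does not filter; a production workflow
  would typically threshold CSM lists at ≤1% estimated FDR downstream.
- The structure worked example (integrin αL/β₂, PDB 5E6R) requires the
  deposited structure file, which must be fetched once; without it the
  corresponding acceptance test reports the missing input explicitly.
- No SASD (solvent-accessible surface distance) computation; distances
  are straight-line Cα–Cα.
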