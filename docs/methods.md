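# Methods

## The analytical problem

LC-ESI-MS of glycopeptides reports neutral monoisotopic masses, from which
only a monosaccharide *composition* (HexN HexNAcM dHexK PentL) can be read:
glucose and mannose are isobaric hexoses. ER glycan biology, however, turns
on structure — a single α1,3-glucose on the A-branch tip is the binding
determinant of the calnexin/calreticulin (CNX/CRT) chaperone cycle, and a
terminal α1,6-mannose on the C-branch is the OS9 degradation signal. The
package therefore keeps two representations: trees for enzymology and
structure inference, compositions for identification and quantification, and
makes the mapping between them explicit.

## Glycan trees and canonical structures

A glycan is a rooted tree of residues (sugar, linkage, branch label,
parent); the reducing-end GlcNAc is the unique root. The Glc3Man9GlcNAc2
precursor topology is hardcoded once — GlcNAc-β1,4-GlcNAc-β1,4-Man with the
α1,3 arm carrying the A-branch (two α1,2-Man, triglucose cap
Glcα1,2-Glcα1,3-Glcα1,3) and the α1,6 arm carrying the B-branch
(Manα1,2-Manα1,3) and C-branch (Manα1,2-Manα1,6). Branch labels are fixed by
position in this topology and propagated through edits, never recomputed
from geometry; every other registry structure (Glc2/Glc1/Man9, Glc1Man8,
Glc1Man7, the three Man8 isomers named by the branch whose tip is missing)
is *derived* from the precursor by enzyme-rule applications, so each carries
its derivation as provenance.

Tree identity is canonical-string equality: the formatter orders children
a1-2 < a1-3 < a1-6 < b1-4, prints the highest-sorted child inline and the
rest bracketed, which makes the string a canonical form for rooted-tree
isomorphism and gives the parser/formatter an exact round trip.

## Masses

All masses are neutral monoisotopic, computed from elemental formulas
(Hex C6H10O5, HexNAc C8H13NO5, dHex C6H10O4, Pent C5H8O4 — residue forms,
one water less than the free sugar) through pyteomics' atomic-mass table, so
the matching tolerance (ppm-scale on kDa species) is never limited by
constant precision. Peptide masses add one water per chain and a fixed
carbamidomethyl (C2H3NO, +57.02146 Da) per cysteine; variable modifications
are out of scope. Released (PNGase-type) glycans add one water. The test
suite checks every mass path against an independent hand-frozen
atomic-mass/residue-formula oracle to 1e-4 Da (reference values to 1e-5),
and composition mass is exactly additive by construction.

## Enzyme rules

Each enzyme is a deterministic rewrite with an explicit structural guard;
applying a rule to a non-substrate raises rather than silently no-ops, and
every removal reports the released fragments so residue balance
(product + released = input) is checkable everywhere:

* **GCSI** — removes the single terminal α1,2-Glc of the cap.
* **GCSII** — removes one terminal α1,3-Glc per application.
* **UGGT** — adds one α1,3-Glc to the A-branch tip, only when the glycan is
  glucose-free and the A-branch is intact (three mannoses, terminal tip);
  EndoM's removal of the tip mannose therefore permanently abolishes
  reglucosylation, as observed.
* **MNS4/MNS5** — removes the C-tip α1,2-Man, exposing the α1,6-Man that the
  tree reports as `os9_signal_exposed` (a computed predicate: the C-stem
  α1,6-mannose is terminal). Whether the B-tip mannose is also removed by
  MNS4/MNS5 or by another mannosidase is genuinely open; both behaviours are
  exposed via the `extended` flag, and nothing downstream depends on the
  attribution.
* **EndoM** — removes the Glcα1,3-Man disaccharide from the A-tip; restricted
  to glycans with exactly one glucose because its action on di/triglucosylated
  species is disputed — such inputs are rejected as non-substrates.
* **JBM** — per iteration removes *all* currently terminal α-linked mannoses
  simultaneously; β-linked core mannose and glucose are never substrates, so
  a glucose-capped A-branch is fully protected. Simultaneous rounds (rather
  than one residue per step) make partial-digestion series deterministic and
  reproduce the Hex5–Hex8 intermediate band seen in partial digests of
  monoglucosylated substrates; the limit digest is a fixpoint and idempotent.

`reachable_structures` is a breadth-first closure over single rule
applications, deduplicated by canonical string; state spaces are small
(≲ 30 states under the ER rule set) and bounded by residue count, so the
closure terminates. `infer_isomer` filters the ER-reachable set (from the
precursor, under GCSI/GCSII/UGGT/generic α1,2-mannosidase/MNS4-5 sub-rules)
by observed composition, then by diagnostic evidence — predicted JBM limit
composition, EndoM susceptibility — and ranks glucose count descending, then
name, a deterministic order that also places glucosylated candidates first
when the species elutes apart from glucose-free standards. Glucosylation is
bounded at Glc ≤ 1 by default (GCSI/II act co-translationally); the bound is
a parameter. An observed Hex7HexNAc2 in a trimming-deficient background has
no registered canonical assignment and is deliberately left to the generic
reachable set.

## Glycopeptide annotation

Sequons are N-X-S/T with X ≠ P (overlaps reported, 1-based positions);
tryptic digestion cleaves after K/R except before P, with a configurable
missed-cleavage count — both are small regex scans because coordinates are
part of the contract. Glycoform enumeration is the Cartesian product over
per-class ranges (defaults HexNAc 1–2, Hex 0–12, dHex 0–1, Pent 0–1 — the
plant N-glycan repertoire on a tryptic peptide), dropping HexNAc-free
compositions since any N-glycan remnant retains the innermost GlcNAc.

Peak matching assigns each peak to the candidate with minimal |ppm error|
within tolerance (default 10 ppm, Orbitrap-class), ties to the lower
candidate mass; each candidate keeps only its best peak, and displaced peaks
stay unassigned rather than being rerouted, which keeps assignments
order-independent and monotone in the tolerance. The implementation is
checked against an all-pairs brute-force oracle on randomized spectra.
Hexose-ladder detection grows chains of peaks spaced by 162.0528 Da (up to
`max_gap` missing rungs) greedily from the lowest unused peak — a screening
aid, not part of quantification.

## Quantification

Relative abundance of composition c at a site = 100 · I(c) / Σ I over
*assigned* compositions; peaks matching no candidate are excluded from the
denominator, so columns sum to exactly 100 (to accumulation error), are
invariant under intensity rescaling and under injection of unassignable
peaks. Multiple peaks assigned to one composition are summed first. Report
TSVs round to one decimal (matching how such tables are published); full
precision stays in memory. The bundled measurement table
(`data/subex_site_glycoforms.tsv`) carries the per-site relative amounts for
the SUBEX-C57Y substrate from the *os9* and *mns4 mns5* backgrounds, with
isomer annotations Hex8→Glc1Man7GlcNAc2 (*os9*) and Hex9→Glc1Man8GlcNAc2
(*mns4 mns5*); `monoglucosylated_fraction` averages the annotated glycoform
over selected columns (its as-printed column sums run 99.9–100.1, inside the
±0.5 validation band).

## Synthetic spectra

The generator draws, in fixed order from one seeded stream (NumPy
`default_rng`): per-glycoform mass errors ~ Normal(0, ppm_sd), lognormal
intensity noise with unit mean and given CV (lognormal keeps intensities
positive), then decoys uniform over the glycoform mass span ± 200 Da,
rejection-sampled (bounded retries) to stay ≥ 50 ppm from *every*
theoretical mass of the default enumeration, so decoys are unassignable at
working tolerances. Defaults — ppm_sd 3 (a third of the 10 ppm tolerance),
CV 0.2, 25 decoys, 1e7 total intensity — describe a routine Orbitrap-class
deconvoluted spectrum. Ground truth records per-peak provenance and true
fractions. Digestion series convert the JBM product composition at each
iteration depth to its released-glycan mass with intensity proportional to
the given weights.

What the generator does *not* emulate: chromatographic elution, isotope
envelopes, charge states, in-source fragmentation, coeluting peptide
backgrounds. Passing recovery tests therefore demonstrates correctness of
the mass/matching/normalization chain under calibrated noise, not robustness
to real-world interference.

## Statistical checks and problem sizes

Stochastic tests run at fixed seed lists, making them deterministic.
Assignment completeness: at ppm_sd 3 and 10 ppm tolerance the per-peak miss
probability is the normal tail ≈ 8.6e-4, so a five-glycoform spectrum keeps
all true peaks in ≈ 99.6% of replicates; 1000 seeded replicates are checked
against a 99% floor (a ten-glycoform spectrum would sit within one binomial
standard deviation of that floor and was not used for this reason).
Parameter recovery: over 100 seeds, the mean recovered fraction per
glycoform must lie within 3·CV/√100 (relative) of truth — the standard-error
form of a 3σ bound; a per-seed 3·CV bound would be a ≈2.8σ test repeated
1000 times and fail by construction. The brute-force matching oracle runs on
1000 random spectra. The whole suite completes in a few seconds on one CPU.

## Known limitations

No MS/MS (oxonium/Y-ion) evidence, no FDR against decoy peptides, no
charge-state or isotope handling, one glycan per peptide (multi-sequon
peptides are flagged, their compositions reported per peptide), no enzyme
kinetics or competition (the processing "timer" is outside scope), no
O-glycans or phospho/sulfo modifications, and no GlycoCT/WURCS interchange.
Structure inference is only as complete as the ER rule set: glycoforms
produced by Golgi processing would need additional rules before
`infer_isomer` could name them.
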