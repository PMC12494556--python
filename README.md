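# glycotrim

Site-specific N-glycopeptide annotation and quantification from deconvoluted
LC-ESI-MS peak lists, combined with a deterministic rule engine for the
endoplasmic-reticulum (ER) N-glycan processing enzymes. It is aimed at
glycoproteomics practitioners studying ER quality control and ERAD
(ER-associated degradation), where the central analytical problem is that MS
sees only compositions — HexN HexNAcM — while the biology is decided by
structure: an observed Hex8HexNAc2 peak can be glucose-free Man8GlcNAc2 or
the monoglucosylated Glc1Man7GlcNAc2, and only the latter binds the lectin
chaperone calnexin.

## What it computes

**Glycan model.** The unprocessed N-glycan Glc3Man9GlcNAc2 is a rooted tree:
chitobiose core, β1,4-mannose, the A-branch (α1,3 arm,
Man-α1,2-Man-α1,2 + Glcα1,3-Glcα1,3-Glcα1,2 cap) and the B- and C-branches
(α1,3/α1,6 on the α1,6 arm). Trees collapse to compositions for MS work;
a condensed structure-string dialect
(`Glc(a1-3)Man(a1-2)...Man(b1-4)GlcNAc(b1-4)GlcNAc`) round-trips them.

**Enzyme rules** (each a rewrite on the tree, conserving residues):
GCSI (−α1,2-Glc), GCSII (−α1,3-Glc), UGGT (+α1,3-Glc on an intact A-branch
tip), MNS4/MNS5 (−C-tip α1,2-Man, exposing the α1,6-Man OS9 degradation
signal; extended mode also trims the B-tip), EndoM (−Glcα1,3-Man
disaccharide) and jack bean α-mannosidase (JBM), which iteratively removes
every terminal α-Man. A glucose cap protects the A-branch from JBM, so the
limit digest discriminates isobaric structures: Man8GlcNAc2 → Hex1HexNAc2
but Glc1Man7GlcNAc2 → Hex5HexNAc2. `infer_isomer` searches the ER-reachable
structure space and ranks candidates against such digestion evidence.

**Glycoproteomics.** Sequon detection (N-X-S/T, X ≠ P), tryptic digestion
(cleave after K/R, not before P), theoretical neutral monoisotopic masses of
peptide + glycan (fixed carbamidomethyl-Cys), hexose-ladder detection, and
ppm-tolerance matching of deconvoluted peaks. Relative glycoform abundance
at a site is assigned intensity over summed assigned intensity (columns sum
to exactly 100%); unassigned peaks never enter the denominator.

**Synthetic data.** A seeded generator emulates deconvoluted spectra of
tryptic glycopeptides — theoretical masses with normal ppm error, lognormal
intensity noise, decoy peaks kept ≥ 50 ppm from every theoretical candidate —
so every pipeline stage is testable against known ground truth.

## Worked example

Digest the monoglucosylated, mannose-trimmed glycan with JBM and interpret
the observed composition:

```
$ glycotrim glycan-digest --structure Glc1Man7GlcNAc2 --enzyme jbm --mode limit
structure	composition	released	steps
Glc(a1-3)Man(a1-2)Man(a1-2)Man(a1-3)Man(b1-4)GlcNAc(b1-4)GlcNAc	Hex5HexNAc2	Hex3	JBM:round1:-2Man;JBM:round2:-1Man

$ glycotrim infer --observed Hex8HexNAc2 --jbm-product Hex5HexNAc2
rank	structure	glc	jbm_limit	evidence
1	Glc1Man7GlcNAc2	1	Hex5HexNAc2	JBM limit Hex5HexNAc2; EndoM-sensitive
```

The limit digest strips three mannoses (B-tip/C-stem arm) but stops at
Hex5HexNAc2 because the glucose cap protects the A-branch — so a Hex8HexNAc2
peak whose JBM product is Hex5, not Hex1, must be Glc1Man7GlcNAc2, i.e. the
protein still carries the calnexin-binding monoglucosylated glycan.

End-to-end on synthetic data (noise-free here, so the table equals the
generator truth):

```
$ glycotrim simulate --spec spec.yaml --out peaks.tsv
$ glycotrim run --fasta prot.fasta --peaks peaks.tsv:site2:synthetic:NLSLSSNR --outdir out
$ cat out/glycoform_table.tsv
composition	site2_synthetic
HexNAc1	10.0
Hex8HexNAc2	60.0
Hex9HexNAc2	30.0
total	100.0
```

Library use mirrors the CLI: `build_canonical`, `jbm_digest`, `infer_isomer`,
`theoretical_masses`, `match_peaks`, `quantify_site`, `simulate_spectrum`.

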