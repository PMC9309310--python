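# Methods

This note records the models the package implements, the defaults it
ships, and the numerical choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Residue numbering and alignment

All tuning-site arithmetic uses bovine rod opsin numbering
(NP_001014890, 348 residues; the protein is shipped as packaged data).
Queries are mapped by global pairwise protein alignment (Biopython
`PairwiseAligner`, BLOSUM62, gap open/extend −10/−0.5). Opsins are
full-length class-A GPCRs and align end to end, so a global,
end-gap-penalized alignment is appropriate; the gap parameters are
conventional protein-alignment defaults and are exposed in the aligner
helper rather than hard-coded into callers. Queries under 100 residues
are mapped but flagged unreliable. Nucleotide identity for probe
screening uses a global DNA alignment (match 5, mismatch −4, gap
−10/−0.5), with identity = matches / alignment columns, internal gap
columns counted as mismatches; a codon-aware mode threads the protein
alignment back onto codons when both inputs are coding sequences.

The cross-hybridization flag has three bands: ≥ 90% identity
(a riboprobe will bind paralogues), ≤ 65% (class-specific), and an
uncertain band in between. The band boundaries deliberately bracket the
~87% within-class paralogue identity at which cross-hybridization is
empirically likely, rather than pretending to a sharper threshold.

## Site rules

* **SWS1.** Site 86 controls UV versus violet sensitivity; F86 yields a
  numeric 360 nm call, any other residue a qualitative violet-shifted
  call with no number. An unalignable site 86 is an error, not a guess.
* **LWS five-sites rule.** Base 560 nm for the ancestral
  S164/H181/Y261/T269/A292 state with additive shifts −7 (S164A), −28
  (H181Y), −8 (Y261F), −15 (T269A), −27 (A292S) nm. The shift table is
  packaged as TSV and overridable; the defaults are the standard
  literature values and are consistent with the 560/553/546 nm outputs
  of the salmon repertoire. Unalignable sites are skipped and flag the
  prediction `incomplete`; unexpected residues are skipped with a
  warning note. Additivity and monotonicity are property-tested by
  brute-force enumeration of all 2^5 residue combinations.
* **RH1.** 27 rod tuning sites are reported with literature annotations
  for the recognised substitutions (D83N, E122Q, A292S, ...). A numeric
  estimate (500 nm base plus registered deltas) is returned but always
  flagged `approximate`: no complete additive rule set exists for rods,
  so the estimate is a reading aid, not a claim.
* **RH2.** Only the qualitative E122Q call is made from sequence
  (E ⇒ green-shifted > 495 nm, Q ⇒ blue-shifted < 495 nm, ~15 nm
  swing); numeric RH2 values come from the dynamics regression.

## Chromophore descriptors

Trajectories are ordered atom sets (lysine backbone/side chain plus
retinal C1..C20 in a fixed canonical order) with per-frame coordinates
in Å. Descriptors:

* Dihedrals use the atan2-on-plane-normals construction. The sign
  convention is fixed by the reference case
  ((0,0,0),(1,0,0),(1,1,0),(1,1,1)) → −90°; reversing atom order
  preserves the value, mirroring negates it, range (−180°, 180°].
* "Angle 3" (C3–C7–C8) names non-bonded atoms; it is implemented
  literally as the geometric angle with vertex C7.
* Medians of dihedral series are circular-aware: values are re-branched
  around the circular mean before the ordinary median, so distributions
  straddling ±180° (e.g. alternating ±179°) give 180°, not 0°. Bond
  angle series use the plain median (they live in [0°, 180°]).
* RMSF is computed after least-squares rigid superposition of every
  frame onto the mean structure of the selected atoms themselves,
  iterated to self-consistency (the fit uses scipy's Kabsch solver). The
  reference is the chromophore's own mean because the package ingests
  chromophore-only trajectories; a user-supplied reference frame is
  accepted. An independent cross-check against MDAnalysis's RMSF on the
  same aligned ensemble is part of the test suite.
* The RMSF curve area is a trapezoidal integral over atom index with
  unit spacing, atoms in the canonical lysine→retinal order. The
  integration scheme is a package choice; the published curve-area
  magnitudes (~0.76–1.12) are consistent with a short atom series at
  unit spacing.

## Regression models and templates

The two printed models are shipped as JSON (swappable coefficient
sets). The SWS2 model is evaluated as
2677.5348 + (−17.052·Angle3) + 5.1634·Torsion3 + 2.3642·Torsion12: the
source prints the first term as a double negative, which evaluated
literally gives a physically impossible ~4900 nm for the published
inputs; the adopted sign is the only reading consistent with the
published output (420.04 nm), and the resolution is pinned by tests.
Raw model evaluations far outside the class's physical window are
returned with an `out_of_range` flag rather than clipped — the models
are affine fits valid only near their training descriptor ranges.

Dark spectra use the Govardovskii A1 template with its published
alpha-band constants (A = 69.7, B = 28, C = −14.9, D = 0.674,
b = 0.922, c = 1.104, and the λ_max-dependent exponent
a = 0.8795 + 0.0459·exp(−(λ_max−300)²/11940)). Output is rescaled so
the on-grid maximum is exactly 1. The beta band (amplitude 0.26,
λ_mβ = 189 + 0.315·λ_max, width −40.5 + 0.195·λ_max) is implemented but
**off by default**: adding it always produces a secondary short-wave
maximum below ~400 nm, and the package's default contract is a unimodal
normalized dark spectrum over the 300–700 nm grid. Callers wanting the
two-band spectrum real pigments show pass `include_beta=True`.

## ORF integrity

A candidate CDS is globally aligned to an intact reference CDS. Gap
runs in the query row are deletions, in the reference row insertions;
frame effect is length mod 3. Indel coordinates are canonicalized by
left-alignment (as VCF normalization does) because alignment-equivalent
placements in repeat context would otherwise make coordinates
incomparable between tools. Premature stops are found by translating
the query in the shared reading frame and are reported in reference
codon coordinates via the alignment. Verdicts: ≥ 1 frameshift or
premature stop ⇒ `pseudogene`; otherwise a ≥ 30 nt in-frame deletion ⇒
`nonfunctional_suspect`, flagged specially when it overlaps an
annotated transmembrane helix (TM boundaries of the bovine reference,
mapped through the numbering alignment; a TM3 hit guts the
retinal-binding pocket). Queries under 50% of the reference length are
truncated beyond rescue and forced to `pseudogene`. The 30 nt and 50%
thresholds generalize single observed cases and are overridable; they
are package choices, not published constants.

## Expression

Depth normalization scales every sample column by
min(depth)/depth — the "normalize to the lowest-read sample"
convention — which preserves within-sample proportions exactly. The
heatmap matrix is log2(normalized count + 1) by default; because
"log-fold" is ambiguous, a second mode computes
log2((c+1)/(c_ref+1)) against a reference stage (earliest by default).
Full precision is kept internally; rounding happens only at report
time.

## Synthetic data

The generator controls only the statistics the pipeline measures.

* **Trajectories** start from an idealized lysine+retinal scaffold
  built from internal coordinates (generic bond lengths/angles, an
  11-*cis* kink at C11=C12). Targeted torsions (torsion15, torsion3,
  torsion12 — the ones whose terminal methyl can rotate about the
  central bond) are set frame by frame to wrapped-normal draws by
  rotating that leaf atom; requesting a non-rotatable spec is an error.
  Isotropic Gaussian jitter and optional per-frame random rigid motion
  are added on top. The ground-truth sidecar records target medians and
  a *linearized* expectation of the post-superposition RMSF curve: each
  atom's covariance (jitter plus the leaf's tangential circular
  variance ρ²(1−e^(−s²))) minus the variance absorbed by the 6
  rigid-body modes, computed exactly in the small-displacement limit.
  Default torsional spread is 8°, a typical room-temperature width for
  a ring-adjacent torsion; jitter amplitudes of 0.01–0.05 Å reproduce
  the published RMSF-area magnitudes. Jitter ≥ ~0.1 Å leaves the
  linearized regime: coordinate noise then biases dihedral medians
  through the nonlinearity, which is a known limitation, not a bug.
  The generator emulates no force field, no anharmonicity, and no
  correlated backbone motion, so descriptor-recovery tests demonstrate
  estimator correctness, not realism of molecular dynamics.
* **Sequences** are built from an intact synthetic reference — the
  bovine rod opsin protein back-translated with cycling synonymous
  codons (avoiding repeats that would make indel placement ambiguous)
  plus class-typical tuning residues. Site edits are codon
  replacements at bovine-numbered positions; lesions (deletions,
  insertions, engineered stops) are applied right-to-left at known
  codon positions. The sidecar records both the planted and the
  canonical (left-aligned) coordinates; tests compare canonical
  coordinates because that is the only placement an aligner can be
  expected to reproduce.
* **Count tables** are negative-binomial (size 20, moderate bulk
  RNA-seq overdispersion) over 4 stages × 4 replicates by default, with
  log-normal gene abundances, per-gene stage trajectories, and library
  depths drawn from a range so normalization has real work to do. A
  planted fold change is imposed on the gene's *relative* abundance
  per stage, since depth normalization can only recover relative
  ratios.

## Problem sizes

Descriptor-recovery runs use 5,000-frame trajectories of the 29-atom
chromophore moiety (medians then recover planted locations to well
under 0.5° and curve areas to a few percent); count tables are 11
genes × 16 samples. These sizes make the whole suite run in well under
a minute while leaving the statistical checks meaningful.

## Known limitations

* The RH1 numeric estimate is not a validated additive model; it is
  flagged `approximate` and should be read as an annotation summary.
* The regression models are used strictly as published; no re-fitting
  is attempted (their training data lives in prior work), and
  evaluations outside the training descriptor range are flagged, not
  trusted.
* Chromophore trajectories are consumed, never produced: molecular
  dynamics production runs and homology modelling are out of scope.
* The A1 template only; no A2 (3,4-didehydroretinal) shift is
  modelled.
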