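# Methods

This note documents the models and procedures implemented in
`vartriage`, the parameters that matter, the numerical choices, and what
the synthetic test corpus does and does not establish.

## Solvent-accessible surface area

SASA is computed with the Shrake–Rupley method: each heavy atom carries a
quasi-uniform lattice of points on its solvent-expanded sphere (van der
Waals radius + probe radius), and a point counts as accessible when it
lies outside every neighbouring atom's expanded sphere. The atom's area
is the accessible fraction of 4π(r + probe)².

* **Probe radius**: 1.4 Å (water) by default.
* **Radii**: NACCESS convention — C 1.87 Å (backbone carbonyl C 1.76 Å),
  N 1.65 Å, O 1.40 Å, S 1.85 Å — chosen for continuity with
  NACCESS-configured FreeSASA runs; the `RadiiSet` is swappable and
  accepts per-(residue, atom) overrides and an optional fallback radius
  for exotic elements.
* **Sampling**: a deterministic golden-spiral (Fibonacci) lattice,
  default 960 points per atom; there is no stochastic variation between
  runs. Doubling the density changes per-residue areas by well under 1%.
* **Lattice orientation**: the lattice is expressed in a per-atom frame
  built from the directions to the atom's two nearest neighbours. Because
  that frame co-rotates with the molecule, SASA is *exactly* invariant
  under rigid-body rotation and translation, not merely to sampling
  noise. The cost is that deleting an atom can reorient the frames of its
  former nearest neighbours, so per-atom areas of unrelated atoms may
  fluctuate by ~1 Å² of resampling noise under edits; occlusion
  monotonicity holds exactly wherever the neighbour pair is unchanged,
  and in aggregate everywhere.
* **Neighbour search**: a k-d tree query with radius r_i + r_max +
  2·probe, exactly equivalent to the all-pairs scan (verified by oracle
  tests).
* **Exclusions**: hydrogens and hetero records (waters, ligands) are
  excluded from all geometric computations, matching the hydrogen-free
  crystal and predicted structures this tool targets; hetero inclusion is
  configurable.

## Relative solvent accessibility

RSA of a residue is 100 · SASA / SASA_max, where SASA_max is the area of
residue type X inside an extended (φ = −120°, ψ = 120°) Ala-X-Ala
tripeptide built from ideal geometry — alanine neighbours impose minimal
steric hindrance, so this approximates the maximum attainable exposure.
The reference table is computed with the same radii, probe and lattice as
the query structure (self-consistent normalization); values can exceed
100% at termini or in distorted geometry. A published-constants table can
be substituted for literature comparisons. Exposure is called at the 20%
threshold, with exposure defined strictly as RSA > 20% — the boundary
value classifies as buried.

Computed SASA_max values range from ≈ 82 Å² (Gly) to ≈ 262 Å² (Trp),
with the expected ordering of side-chain sizes.

## Structural definition at mutation sites

A mutation site's 5 Å neighbourhood contains every residue with a heavy
atom within 5 Å of any heavy atom of the site (minimum heavy-atom
distance, not Cα–Cα, which under-counts long side chains). The site's
structural-definition label classifies the neighbourhood mean of:

* **B-factor** (experimental structures; per-residue value = mean over
  heavy atoms): < 30 Å² High, 30–60 Å² Medium, > 60 Å² Low;
* **pLDDT** (predicted models; constant per residue): > 70 High, 50–70
  Medium, < 50 Low.

Boundary values classify as Medium in both bases. The neighbourhood mean
includes the centre; the reported census of individual labels pools the
*surrounding* residues of all sites, deduplicated across overlapping
neighbourhoods and excluding the centres, so both conventions are
inspectable. High definition means a rigid or confidently predicted
context in which structure-based reasoning about the variant is
reliable.

Per-substitution pathogenicity matrices (19 alternative residues per
position, scores in [0, 1]) are reduced to per-residue means for
structure colouring; empty positions are skipped with a warning.

## NMD susceptibility

For a nonsense variant the premature termination codon (PTC) is the
variant codon itself. For a frameshift, the edit (duplication, deletion
or insertion parsed from a c.-notation subset) is applied to the spliced
transcript and the coding region is re-translated in the shifted frame
from the start codon through the transcript end; the first stop codon
encountered is the PTC. A shifted frame that reaches the transcript end
without a stop yields a low-confidence call — no PTC can be placed.

The decay rule is the canonical 50-nt boundary rule: a PTC escapes NMD
when it lies in the last exon or within 50 nt of the final exon–exon
junction (boundary inclusive); single-exon transcripts always escape.
Start-proximal escape (< 150 nt) is available behind a flag but off by
default. The summary percentage divides NMD calls by the confident
protein-level denominator (NMD + escape + missense; low-confidence
frameshifts and unknown-effect variants excluded); a second convention
keeping low-confidence frameshifts in the denominator is also reported,
as the missense share of all protein-level variants. Feasibility flags:
≤ 33% High, ≥ 66% Low, Medium between, boundaries to Medium (the bands
are claimed strictly by their sources, leaving the boundary values
unassigned; Medium is the conservative choice).

## Interface contacts

Detection is distance-only on heavy atoms because crystal structures and
predicted models carry no hydrogens:

* **Salt bridge**: side-chain basic nitrogen (Arg NE/NH1/NH2, Lys NZ,
  His ND1/NE2) within 4.0 Å of a side-chain acidic oxygen (Asp OD1/OD2,
  Glu OE1/OE2). Histidine's protonation is unknown, so it counts as basic
  and records involving it are flagged for optional filtering.
* **Hydrogen bond**: donor–acceptor N/O (and S) pairs within 3.5 Å, from
  a fixed per-residue donor/acceptor table plus backbone N (donor) and O
  (acceptor). No angle term is applied. Backbone–backbone pairs between
  sequence-adjacent residues are excluded — at that separation the O···N
  distance is fixed by the peptide bond, not by an interaction — and
  records crossing only backbone atoms are flagged so interface analyses
  can separate them from side-chain contacts.

One record is emitted per residue pair and kind, carrying the
closest realizing atom pair. Cutoffs are configurable; the defaults are
common literature conventions. Wild-type/mutant comparison is a set
difference keyed by (residue pair, kind); residue numbering must agree
except at declared mutation sites.

## Triage thresholds

* Pathogenicity consensus: the MutPred2-style score votes pathogenic at
  ≥ 0.80 (a conservative bound reducing false positives) and leans
  pathogenic in [0.50, 0.80); the E-SNPs&GO-style probability votes
  pathogenic at ≥ 0.50. Two pathogenic votes → pathogenic; two clean
  benign votes → benign; anything else → discordant.
* Disorder: score ≥ 0.50 places the site in an intrinsically disordered
  region.
* Stability: the variant is highly destabilizing ("over threshold") if
  any of up to three independent ΔΔG predictions is ≤ −1.5 kcal/mol
  (negative = destabilizing).
* **Ligandability gate**: exposed ∧ not highly destabilizing. This is the
  minimal rule consistent with the worked example's outcomes;
  pathogenicity, conservation and disorder are reported as context
  because they inform interpretation (e.g. discordant low scores at
  interface residues suggest an interaction-breaking rather than
  fold-breaking mechanism) but do not gate.

## The feasibility report

Four target-level criteria, each High / Medium / Low:

1. **Literature** — publication count with provisional half-open bands
   (< 100 Low, < 500 Medium, else High; configuration-exposed, since only
   the low band is anchored by the worked example).
2. **NMD** — the percentage flag above.
3. **Structure** — majority label over per-site definition labels, ties
   broken toward the more pessimistic label.
4. **Interactome** — < 3 interactors Low (Medium when the protein sits in
   ≥ 1 annotated pathway), > 3 High; exactly 3 is unclaimed by the source
   rule and maps to Medium.

Missing criteria produce a partial report with explicit "not assessed"
markers. Publication, interactor and pathway counts are inputs; the
toolkit does not query PubMed, STRING or KEGG.

## Compound pre-filter

Molecular weight is summed from IUPAC standard average atomic weights
over a Hill-notation formula (reported to 2 decimals). The screening
window keeps compounds with weight in the closed interval [100, 1000] Da,
strictly fewer than 13 rotatable bonds, drug group among
approved/nutraceutical, and no manual-exclusion flag; every rejection
carries its failed predicates. Rotatable-bond counts are accepted
precomputed so the core has no cheminformatics dependency; an optional
backend computes them from SMILES when RDKit is importable.

## Synthetic fixtures

Peptides are built by NeRF chain extension from ideal backbone internal
coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; helix φ/ψ =
−57°/−47°, extended −120°/120°), with side chains superimposed from the
chemical component dictionary's ideal coordinates in a fixed default
rotamer and the carbonyl oxygen placed in the peptide plane anti to the
next nitrogen (which reproduces the helical O(i)···N(i+4) ladder at
≈ 3.1 Å). Dimers place a second copy under a caller-specified rotation
and translation; Gaussian coordinate jitter is seeded and reproducible.

The 25-variant class-composition fixture uses a three-exon transcript
whose CDS is built from CAC repeats — a codon with no stop in any reading
frame — so stops exist only where planted: the terminator, and one
+1-frame TAA motif. Duplications upstream of the motif therefore decay
(PTC far upstream of the last junction), single-base deletions never meet
a stop (low confidence), and the engineered accounting — 10 NMD of 17
confident calls, 4 low-confidence, 7 missense = 33.3% of 21 — is
verified by a self-check at construction.

What passing on this corpus shows: the geometry, rules and bookkeeping
are implemented correctly and agree with independent oracles (a second
SASA implementation, brute-force neighbourhood and contact scans, a
translation oracle). What it does not show: performance on real
structures — synthetic peptides lack the packing heterogeneity, missing
atoms, alternate conformations and surface topography of crystal and
predicted models, and the transcript fixture's stop landscape is far
simpler than a real gene's. The two acceptance tests that analyse the
AP4M1 AlphaFold entry close part of that gap but require fetching the
database entry.

## Problem sizes

Default test and acceptance runs use peptides of 3–60 residues (50 for
cross-implementation SASA agreement at 2000 lattice points), transcripts
of 30–60 codons with 100-transcript oracle sweeps, and a 200-compound
synthetic library — sizes at which every brute-force oracle is exact and
the full suite completes in well under a minute per module.

## Known limitations

* Nucleic acids, anisotropic B-factors and crystallographic symmetry are
  out of scope; only the first model of multi-model files is read, and
  altloc collapse keeps the highest-occupancy conformer.
* H-bond detection has no angular term; with hydrogens absent the
  distance criterion over-counts marginal geometries.
* The 50-nt rule is a documented approximation to dedicated NMD
  predictors; exact concordance with any external server on edge cases
  is not promised.
* RSA reference values depend on the radii set and the tripeptide
  conformation; comparisons against tables computed with other
  conventions can differ by a few percentage points.
* The NeRF fixture builder uses a single default rotamer per residue;
  side-chain packing in fixtures is idealized, not energy-minimized.
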