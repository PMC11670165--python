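# vartriage

Structure-aware triage of missense variants and drug-repurposing
feasibility assessment for rare-disease protein targets.

## The problem

For most rare diseases no therapy exists, and developing one from scratch
is rarely viable. Repurposing an approved small molecule is attractive —
but only for the right kind of variant. A candidate mutation must produce
a protein at all (transcripts carrying a premature termination codon far
upstream of the last exon–exon junction are degraded by nonsense-mediated
decay and leave nothing to drug), must sit in a region of the structure
that is defined well enough to model, and must be *ligandable*: solvent-
exposed rather than buried in the fold, and not so destabilizing that the
protein never folds in the first place. Variants that pass these gates —
typically interface residues whose substitution breaks a specific
protein–protein contact — are the ones a "molecular glue" compound could
plausibly rescue.

`vartriage` implements this triage as a reusable toolkit, developed
around the worked example of AP4M1, the medium subunit of the adapter
protein complex 4 (AP-4), whose bi-allelic loss-of-function mutations
cause spastic paraplegia type 50.

## What it computes

* **Solvent accessibility** — Shrake–Rupley SASA on a deterministic
  golden-spiral lattice with NACCESS-style radii, and relative solvent
  accessibility RSA = 100 · SASA / SASA_max, where SASA_max is computed
  on an extended Ala-X-Ala tripeptide of the same residue type. RSA > 20%
  calls a site solvent-exposed.
* **Structural context** — 5 Å neighborhoods around mutation sites;
  mean B-factor (experimental structures) or pLDDT (predicted models)
  classified High / Medium / Low (B < 30 Å² High, > 60 Å² Low;
  pLDDT > 70 High, < 50 Low); per-residue averaging of AlphaMissense-style
  19-substitution pathogenicity matrices; variant-to-structure mapping
  with wild-type verification.
* **NMD susceptibility** — premature-stop placement for nonsense and
  frameshift variants (frameshifts are re-translated in the shifted
  frame) and the canonical 50-nt boundary rule; the percentage of
  variants predicted to undergo decay feeds the feasibility report.
* **Interface contacts** — geometric salt-bridge (basic N – acidic O
  ≤ 4.0 Å) and hydrogen-bond (donor–acceptor N/O ≤ 3.5 Å) detection, and
  wild-type vs mutant contact diffs that expose bridges lost upon a
  substitution.
* **Ligandability consensus** — per-variant calls from external predictor
  scores (pathogenicity ≥ 0.80 MutPred2-style / ≥ 0.50 E-SNPs&GO-style;
  disorder ≥ 0.50; any ΔΔG ≤ −1.5 kcal/mol = highly destabilizing);
  ligandable ⟺ exposed ∧ not highly destabilizing.
* **Feasibility (four-criterion) report** — literature volume, NMD
  percentage (≤ 33% High, ≥ 66% Low), structural definition at mutation
  sites, and interactome size, each flagged High / Medium / Low.
* **Screening pre-filter** — molecular weight from a Hill formula and the
  100–1000 Da / < 13 rotatable bonds / approved-or-nutraceutical window.

Synthetic generators (`vartriage.fixtures`) produce every input class —
ideal-geometry peptides and dimers, confidence-profiled structures,
transcripts with engineered stop landscapes, score tables, compound
libraries — so the full pipeline runs and is tested with zero downloads.

## Worked example

```python
from vartriage.fixtures import make_table2_fixture, make_mutation_class_fixture
from vartriage.nmd import call_variant, nmd_summary
from vartriage.triage import call_ligandable

for rec in make_table2_fixture():
    c = call_ligandable(rec)
    print(rec.variant.label, c.pathogenicity_call, c.disorder_call,
          c.exposure_call, c.stability_call, c.ligandable)

tx, variants = make_mutation_class_fixture()
s = nmd_summary([call_variant(tx, v) for v in variants])
print(f"{s.n_nmd}/{s.n_confident} = {s.percentage:.1f}% NMD -> {s.flag}")
```

prints

```
E193K pathogenic structured buried tolerated False
R227H benign structured exposed tolerated True
Y284S pathogenic structured buried over_threshold False
G307A benign structured exposed tolerated True
C319R discordant structured buried over_threshold False
C319Y discordant structured buried tolerated False
R367Q discordant idr exposed tolerated True
10/17 = 58.8% NMD -> Medium
```

Of the seven missense variants, exactly three (R227H, G307A, R367Q) are
solvent-exposed and tolerably destabilizing, hence ligandable; the NMD
accounting over the 25-variant set excludes the four frameshifts without
a placeable stop and the four unknown-effect variants, leaving 10 of 17
confident calls predicted to undergo decay — a Medium feasibility flag.

The same operations are available from the shell:

```sh
vartriage fixtures --kind table2 --out table2.tsv
vartriage triage --scores table2.tsv
vartriage rsa --structure model.pdb --residues R227,G307,R367
vartriage contacts --structure complex.pdb --sel-a chain=B --sel-b chain=M
```

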