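"""Deterministic synthetic fixtures for every input class.

Three generators cover the full pipeline without any download:

* :func:`make_table2_fixture` — the worked-example predictor-score table
  for the seven AP4M1 missense variants (scores as published for the
  SPG50 variant set), the default triage test corpus;
* :func:`make_mutation_class_fixture` — a synthetic transcript plus a
  25-variant set with the published class composition (7 nonsense, 7
  frameshift, 7 missense, 4 unknown-effect), engineered so the NMD module
  reproduces the published accounting: 4 frameshifts yield no in-frame
  stop (low confidence), the 10 remaining nonsense/frameshift variants
  all undergo decay, and the 7 missense pass through;
* :func:`make_scored_structure` — a peptide fixture carrying a prescribed
  per-residue pLDDT/B-factor profile for structural-context tests.

Every generator is pure and deterministic: the same arguments always
produce identical objects (and byte-identical files when written).
"""

from __future__ import annotations

from typing import Literal, Sequence

from .nmd import CodingVariant, TranscriptModel, call_variant
from .structmodel import StructureModel, VariantRecord, build_fixture
from .triage import PredictorScoreRecord

__all__ = [
    "make_table2_fixture",
    "make_mutation_class_fixture",
    "make_scored_structure",
    "TABLE2_VARIANTS",
]

# Published predictor outputs for the seven SPG50-associated AP4M1
# missense variants: (label, mutpred, esnpgo, consurf grade, disorder,
# rsa %, (ddg1, ddg2, ddg3) kcal/mol).
_TABLE2_ROWS: list[tuple[str, float, float, int, float, float,
                         tuple[float, float, float]]] = [
    ("E193K", 0.92, 0.93, 9, 0.16, 0.1, (-0.96, -1.37, 0.17)),
    ("R227H", 0.40, 0.27, 7, 0.13, 33.7, (-1.28, -1.09, -0.59)),
    ("Y284S", 0.93, 0.95, 8, 0.22, 3.1, (-3.63, -2.25, -2.27)),
    ("G307A", 0.48, 0.02, 1, 0.17, 98.0, (-0.41, 0.43, 0.00)),
    ("C319R", 0.86, 0.47, 7, 0.15, 0.4, (-0.77, -1.91, -1.53)),
    ("C319Y", 0.89, 0.42, 7, 0.15, 0.4, (-0.82, -1.30, -1.29)),
    ("R367Q", 0.61, 0.05, 7, 0.60, 57.2, (-0.26, -0.95, -0.35)),
]

TABLE2_VARIANTS = [row[0] for row in _TABLE2_ROWS]


def make_table2_fixture() -> list[PredictorScoreRecord]:
    """The seven-variant predictor-score table of the worked example."""
    records = []
    for label, mutpred, esnpgo, consurf, disorder, rsa, ddg in _TABLE2_ROWS:
        records.append(PredictorScoreRecord(
            variant=VariantRecord.from_label(label),
            mutpred=mutpred, esnpgo=esnpgo, consurf_grade=consurf,
            disorder=disorder, rsa=rsa, ddg=ddg,
        ))
    return records


def _build_fixture_transcript() -> TranscriptModel:
    """Three-exon synthetic transcript with a controlled stop landscape.

    The CDS is built from CAC repeats, which contain no stop codon in any
    reading frame, so stops appear only where planted: the in-frame
    terminator at the end, and a single +1-frame TAA motif roughly a third
    of the way in.  Duplications upstream of the motif therefore terminate
    at it, while single-base deletions (a -1 shift) never meet a stop and
    run through to the transcript end.
    """
    # codon list: ATG + CAC... with a +1-frame stop motif + final TAA
    codons = ["ATG"] + ["CAC"] * 120 + ["TAA"]
    # Plant "TAA" readable in the +1 frame: bases 2-4 of codon pair
    # (c.3k+2 .. 3k+4).  "CTA"+"ACA" gives ...C | TAA | CA... at offset +1.
    motif_codon = 45                       # 0-based codon index
    codons[motif_codon] = "CTA"
    codons[motif_codon + 1] = "ACA"
    cds = "".join(codons)                  # length 366, 122 codons

    utr5 = "GGCAGGCAGG"                    # 10 nt, no ATG, no stop issues
    utr3 = "GCCA" * 20                     # 80 nt
    seq = utr5 + cds + utr3                # total 456 nt
    # exon layout: last junction at transcript position 356, leaving the
    # final 100 nt as the last exon
    exons = [(1, 120), (121, 356), (357, len(seq))]
    return TranscriptModel(
        id="synthetic-tx-25", exons=exons,
        cds_start=len(utr5) + 1, cds_end=len(utr5) + len(cds),
        sequence=seq,
    )


def make_mutation_class_fixture() -> tuple[TranscriptModel, list[CodingVariant]]:
    """Transcript plus 25 variants with the published class composition.

    Composition: 7 nonsense (all with a premature stop well upstream of
    the last junction), 7 frameshift (three +1 duplications that reach the
    planted shifted-frame stop, four single-base deletions whose shifted
    frame has no stop at all), 7 missense, 4 unknown-effect.
    """
    tx = _build_fixture_transcript()
    variants: list[CodingVariant] = []

    # Nonsense: CAC -> TAC? No: nonsense means new stop at that codon.  The
    # c. position is the first base of the stop codon.
    nonsense_positions = [22, 43, 64, 85, 106, 127, 148]
    for p in nonsense_positions:
        variants.append(CodingVariant(label=f"c.{p}C>T(nonsense)",
                                      c_position=p, kind="nonsense"))

    # Frameshift duplications upstream of the +1-frame stop motif
    for p in (10, 40, 70):
        variants.append(CodingVariant(label=f"c.{p}dup", c_position=p,
                                      kind="frameshift", frame_offset=1))
    # Frameshift deletions: -1 shift never meets a stop in this CDS
    for p in (15, 50, 90, 200):
        variants.append(CodingVariant(label=f"c.{p}del", c_position=p,
                                      kind="frameshift", frame_offset=-1,
                                      deleted_len=1))

    # Missense and unknown-effect (intronic) variants: protein-level
    # pass-through and upstream exclusion respectively.
    for i, p in enumerate((30, 60, 95, 130, 160, 190, 220)):
        variants.append(CodingVariant(label=f"c.{p}A>G(missense{i})",
                                      c_position=p, kind="missense"))
    for i, p in enumerate((12, 55, 110, 180)):
        variants.append(CodingVariant(label=f"c.{p}+5G>A(intronic{i})",
                                      c_position=p, kind="unknown"))

    # construction self-check: the engineered accounting must hold
    calls = [call_variant(tx, v) for v in variants
             if v.kind in ("nonsense", "frameshift")]
    n_nmd = sum(1 for c in calls if c.verdict == "nmd")
    n_low = sum(1 for c in calls if c.verdict == "low_confidence")
    if n_nmd != 10 or n_low != 4:
        raise AssertionError(
            f"fixture self-check failed: {n_nmd} nmd / {n_low} low-confidence")
    return tx, variants


def make_scored_structure(
    n_residues: int,
    profile: Sequence[float] | Sequence[tuple[int, float]],
    kind: Literal["helix", "extended"] = "helix",
    source_kind: Literal["experimental", "predicted"] = "predicted",
    seed: int | None = None,
    jitter: float = 0.0,
) -> StructureModel:
    """Peptide fixture with a prescribed per-residue score profile.

    ``profile`` is either one value per residue or a piecewise list of
    (count, value) segments whose counts sum to ``n_residues``.  The score
    is written to every atom of the residue (the pLDDT convention).
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    values: list[float]
    if profile and isinstance(profile[0], tuple):
        values = []
        for count, value in profile:   # type: ignore[misc]
            values.extend([float(value)] * int(count))
    else:
        values = [float(v) for v in profile]   # type: ignore[arg-type]
    if len(values) != n_residues:
        raise ValueError(
            f"profile covers {len(values)} residues, model has {n_residues}")

    model = build_fixture(kind, "A" * n_residues, seed=seed, jitter=jitter,
                          identifier=f"scored-{kind}-{n_residues}")
    model.source_kind = source_kind
    for res, value in zip(model.residues(), values):
        for atom in res.atoms:
            atom.bfactor = value
    return model
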