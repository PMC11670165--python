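"""Nonsense-mediated decay (NMD) susceptibility from a transcript model.

A premature termination codon (PTC) generally triggers NMD when it lies
more than 50 nt upstream of the last exon-exon junction; PTCs in the last
exon or within 50 nt of that junction escape.  For nonsense variants the
PTC is the variant position itself; for frameshifts the edited CDS is
re-translated in the shifted frame to find the first in-frame stop.  A
frameshift whose shifted frame reaches the annotated transcript end
without a stop cannot be placed and is reported as low-confidence.

The summary statistic is the percentage of protein-level variants
predicted to undergo NMD, flagged High (≤33%), Medium or Low (≥66%) for
drug-repurposing feasibility: a high NMD fraction means mutant protein is
mostly never made, leaving little for a small molecule to rescue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Sequence

__all__ = [
    "TranscriptModel",
    "CodingVariant",
    "NmdCall",
    "NmdSummary",
    "locate_ptc",
    "predict_nmd",
    "nmd_summary",
    "parse_c_notation",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class TranscriptModel:
    """Exon layout and CDS bounds in transcript coordinates (1-based,
    inclusive).  ``sequence`` is the spliced transcript; required for
    frameshift analysis."""

    id: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.exons:
            if start != prev_end + 1:
                raise ValueError(
                    f"{self.id}: exons must tile transcript space contiguously; "
                    f"exon starts at {start}, expected {prev_end + 1}")
            if end < start:
                raise ValueError(f"{self.id}: exon ({start},{end}) inverted")
            prev_end = end
        if not self.cds_start < self.cds_end:
            raise ValueError(f"{self.id}: cds_start must precede cds_end")
        if self.cds_end > prev_end:
            raise ValueError(f"{self.id}: CDS extends past the last exon")
        if self.sequence is not None:
            self.sequence = self.sequence.upper().replace("U", "T")
            if len(self.sequence) != prev_end:
                raise ValueError(
                    f"{self.id}: sequence length {len(self.sequence)} does not "
                    f"match exon span {prev_end}")
            if (self.cds_end - self.cds_start + 1) % 3 != 0:
                raise ValueError(f"{self.id}: CDS length not a multiple of 3")

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def last_junction_tx(self) -> int | None:
        """Transcript coordinate of the last exon-exon junction (the final
        nucleotide of the penultimate exon), or None for single-exon
        transcripts."""
        if len(self.exons) < 2:
            return None
        return self.exons[-2][1]

    def cds_to_tx(self, c_pos: int) -> int:
        return self.cds_start + c_pos - 1

    def cds_sequence(self) -> str:
        if self.sequence is None:
            raise ValueError(f"{self.id}: no sequence attached")
        return self.sequence[self.cds_start - 1:self.cds_end]


@dataclass(frozen=True)
class CodingVariant:
    """A coding variant in HGVS-like c. coordinates."""

    label: str
    c_position: int
    kind: Literal["nonsense", "frameshift", "missense", "unknown"]
    frame_offset: int = 0          # net inserted - deleted bases
    inserted_seq: str = ""
    deleted_len: int = 0

    def __post_init__(self) -> None:
        if self.c_position < 1:
            raise ValueError(f"{self.label}: c. position must be >= 1")
        if self.kind == "frameshift" and self.frame_offset % 3 == 0:
            raise ValueError(f"{self.label}: frameshift with in-frame offset")


@dataclass(frozen=True)
class NmdCall:
    label: str
    kind: str
    ptc_c_position: int | None
    verdict: Literal["nmd", "escape", "low_confidence", "not_applicable"]


@dataclass
class NmdSummary:
    """NMD bookkeeping over a variant set.

    ``percentage`` is 100 × (NMD calls) / (confident protein-level calls):
    NMD + escape + missense, excluding low-confidence frameshifts and
    unknown-effect variants.  ``percentage_protein_level`` keeps the
    low-confidence frameshifts in the denominator, which is the convention
    under which missense variants account for their share of all
    protein-level mutations.
    """

    n_nmd: int
    n_escape: int
    n_missense: int
    n_low_confidence: int
    n_unknown: int
    flag: Literal["High", "Medium", "Low"]

    @property
    def n_confident(self) -> int:
        return self.n_nmd + self.n_escape + self.n_missense

    @property
    def percentage(self) -> float:
        return 100.0 * self.n_nmd / self.n_confident

    @property
    def n_protein_level(self) -> int:
        return self.n_confident + self.n_low_confidence

    @property
    def missense_percentage(self) -> float:
        """Missense share of all protein-level variants (low-confidence
        frameshifts included, unknown-effect excluded)."""
        return 100.0 * self.n_missense / self.n_protein_level


_C_NONSENSE = re.compile(r"^c\.(\d+)(?:[ACGT]>[ACGT])?(?:\s*\(?p?\.?.*)?$")
_C_DUP = re.compile(r"^c\.(\d+)(?:_(\d+))?dup([ACGT]*)$")
_C_DEL = re.compile(r"^c\.(\d+)(?:_(\d+))?del([ACGT]*)$")
_C_INS = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")


def parse_c_notation(notation: str,
                     kind: Literal["nonsense", "frameshift", "missense",
                                   "unknown"] | None = None) -> CodingVariant:
    """Parse a small HGVS c. subset: substitutions (c.850C>T), duplications
    (c.218dupA), deletions (c.100delG, c.100_103del), insertions
    (c.100_101insTT).  ``kind`` may be given explicitly; dups/dels/ins with
    a net out-of-frame length are frameshifts by construction."""
    s = notation.strip().replace(" ", "")
    m = _C_DUP.match(s)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        length = max(end - start + 1, len(m.group(3)) or 1)
        offset = length
        return CodingVariant(label=notation, c_position=start,
                             kind=kind or ("frameshift" if offset % 3 else "unknown"),
                             frame_offset=offset,
                             inserted_seq=m.group(3), deleted_len=0)
    m = _C_DEL.match(s)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        length = end - start + 1
        return CodingVariant(label=notation, c_position=start,
                             kind=kind or ("frameshift" if length % 3 else "unknown"),
                             frame_offset=-length, deleted_len=length)
    m = _C_INS.match(s)
    if m:
        ins = m.group(3)
        return CodingVariant(label=notation, c_position=int(m.group(1)),
                             kind=kind or ("frameshift" if len(ins) % 3 else "unknown"),
                             frame_offset=len(ins), inserted_seq=ins)
    m = _C_NONSENSE.match(s)
    if m:
        return CodingVariant(label=notation, c_position=int(m.group(1)),
                             kind=kind or "nonsense")
    raise ValueError(f"cannot parse c. notation {notation!r}")


def locate_ptc(transcript: TranscriptModel, variant: CodingVariant) -> int | None:
    """CDS coordinate of the premature termination codon, or None.

    Nonsense: the variant position itself (its codon).  Frameshift: apply
    the edit to the CDS, translate downstream in the shifted frame and
    return the position of the first stop codon encountered (reported as
    the CDS coordinate of the stop's first base in the edited sequence,
    mapped back to pre-edit coordinates where possible).  Returns None if
    the shifted frame runs to the end of the transcript without a stop.
    """
    if not 1 <= variant.c_position <= transcript.cds_length:
        raise ValueError(
            f"{variant.label}: c.{variant.c_position} outside CDS "
            f"(length {transcript.cds_length})")
    if variant.kind == "nonsense":
        return variant.c_position
    if variant.kind != "frameshift":
        raise ValueError(f"{variant.label}: no PTC concept for kind {variant.kind}")
    if transcript.sequence is None:
        raise ValueError(f"{variant.label}: frameshift analysis requires a sequence")

    # Build the edited read-through sequence from the CDS start through the
    # transcript end (the shifted frame may run into the 3' UTR).
    seq = transcript.sequence
    edit_tx = transcript.cds_to_tx(variant.c_position)
    if variant.frame_offset > 0 and variant.deleted_len == 0 and not variant.inserted_seq:
        # duplication: a copy of seq[start .. start+len-1] goes in after it
        length = variant.frame_offset
        dup = seq[edit_tx - 1: edit_tx - 1 + length]
        edited = seq[:edit_tx - 1 + length] + dup + seq[edit_tx - 1 + length:]
    elif variant.frame_offset > 0 and variant.deleted_len == 0 \
            and len(variant.inserted_seq) == variant.frame_offset \
            and variant.label.find("dup") >= 0:
        # dup with explicit letters, e.g. c.218dupA: insert after the base
        edited = seq[:edit_tx - 1 + len(variant.inserted_seq)] \
            + variant.inserted_seq + seq[edit_tx - 1 + len(variant.inserted_seq):]
    else:
        # deletion and/or plain insertion at the position
        edited = seq[:edit_tx - 1] + variant.inserted_seq \
            + seq[edit_tx - 1 + variant.deleted_len:]
    coding = edited[transcript.cds_start - 1:]
    for frame_pos in range(0, len(coding) - 2, 3):
        codon = coding[frame_pos:frame_pos + 3]
        if codon in STOP_CODONS:
            ptc_edited_c = frame_pos + 1
            if ptc_edited_c <= variant.c_position:
                return ptc_edited_c
            # map back to pre-edit CDS coordinates
            return ptc_edited_c - variant.frame_offset
    return None


def predict_nmd(transcript: TranscriptModel,
                ptc_c_position: int,
                start_proximal_escape: bool = False,
                start_proximal_nt: int = 150) -> Literal["nmd", "escape"]:
    """50-nt boundary rule: a PTC escapes NMD when it lies in the last exon
    or no more than 50 nt upstream of the final exon-exon junction.

    ``start_proximal_escape`` additionally lets PTCs within
    ``start_proximal_nt`` of the start codon escape (re-initiation);
    off by default.
    """
    if ptc_c_position < 1:
        raise ValueError("PTC position must be >= 1")
    if start_proximal_escape and ptc_c_position <= start_proximal_nt:
        return "escape"
    ptc_tx = transcript.cds_to_tx(ptc_c_position)
    if ptc_tx > transcript.exons[-1][1]:
        raise ValueError(
            f"PTC at transcript position {ptc_tx} beyond transcript end")
    junction = transcript.last_junction_tx
    if junction is None:
        return "escape"
    if ptc_tx > junction:
        return "escape"
    return "escape" if junction - ptc_tx <= 50 else "nmd"


def call_variant(transcript: TranscriptModel, variant: CodingVariant) -> NmdCall:
    """Full per-variant call: PTC placement then the 50-nt rule."""
    if variant.kind == "missense":
        return NmdCall(variant.label, variant.kind, None, "not_applicable")
    if variant.kind == "unknown":
        return NmdCall(variant.label, variant.kind, None, "not_applicable")
    ptc = locate_ptc(transcript, variant)
    if ptc is None:
        return NmdCall(variant.label, variant.kind, None, "low_confidence")
    return NmdCall(variant.label, variant.kind, ptc, predict_nmd(transcript, ptc))


def nmd_summary(calls: Sequence[NmdCall],
                include_missense_count: int = 0) -> NmdSummary:
    """Summarise NMD calls into the feasibility percentage and flag.

    ``include_missense_count`` adds missense variants (which by definition
    escape transcript degradation at the protein level) to the confident
    denominator; missense NmdCalls in ``calls`` are counted the same way.
    Unknown-effect variants never enter any denominator.
    """
    n_nmd = sum(1 for c in calls if c.verdict == "nmd")
    n_escape = sum(1 for c in calls if c.verdict == "escape")
    n_low = sum(1 for c in calls if c.verdict == "low_confidence")
    n_missense = include_missense_count + sum(
        1 for c in calls if c.kind == "missense")
    n_unknown = sum(1 for c in calls if c.kind == "unknown")
    denominator = n_nmd + n_escape + n_missense
    if denominator == 0:
        raise ValueError("no confident protein-level calls to summarise")
    pct = 100.0 * n_nmd / denominator
    # boundaries belong to Medium: the High/Low bands are claimed strictly
    flag: Literal["High", "Medium", "Low"]
    if pct < 33.0:
        flag = "High"
    elif pct > 66.0:
        flag = "Low"
    else:
        flag = "Medium"
    return NmdSummary(n_nmd=n_nmd, n_escape=n_escape, n_missense=n_missense,
                      n_low_confidence=n_low, n_unknown=n_unknown, flag=flag)
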