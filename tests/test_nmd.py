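"""PTC placement, the 50-nt decay rule, c. notation parsing and summaries.

The frameshift scan is cross-checked against a brute-force oracle that
independently applies the edit and walks the edited coding sequence codon
by codon.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from vartriage.fixtures import make_mutation_class_fixture
from vartriage.nmd import (
    STOP_CODONS,
    CodingVariant,
    NmdCall,
    TranscriptModel,
    call_variant,
    locate_ptc,
    nmd_summary,
    parse_c_notation,
    predict_nmd,
)


def toy_transcript(cds: str, utr5: str = "GGGG", utr3: str = "GGGGGGGG",
                   exons=None) -> TranscriptModel:
    seq = utr5 + cds + utr3
    if exons is None:
        exons = [(1, len(seq))]
    return TranscriptModel(id="toy", exons=exons, cds_start=len(utr5) + 1,
                           cds_end=len(utr5) + len(cds), sequence=seq)


def oracle_frameshift_stop(seq: str, cds_start: int, edited: str) -> int | None:
    """Independent scan: first stop codon in the edited coding frame,
    1-based position within the edited CDS-through-end region."""
    coding = edited[cds_start - 1:]
    for i in range(0, len(coding) - 2, 3):
        if coding[i:i + 3] in ("TAA", "TAG", "TGA"):
            return i + 1
    return None


def apply_edit_oracle(seq: str, tx_pos: int, variant: CodingVariant) -> str:
    """Independent reconstruction of the edited transcript."""
    if variant.deleted_len:
        return seq[:tx_pos - 1] + variant.inserted_seq + seq[tx_pos - 1 + variant.deleted_len:]
    if variant.label.find("dup") >= 0 or (variant.frame_offset > 0
                                          and not variant.inserted_seq):
        length = variant.frame_offset
        segment = variant.inserted_seq or seq[tx_pos - 1:tx_pos - 1 + length]
        return seq[:tx_pos - 1 + length] + segment + seq[tx_pos - 1 + length:]
    return seq[:tx_pos - 1] + variant.inserted_seq + seq[tx_pos - 1:]


class TestParseCNotation:
    @pytest.mark.parametrize("notation,pos,kind,offset", [
        ("c.850C>T", 850, "nonsense", 0),
        ("c.218dupA", 218, "frameshift", 1),
        ("c.100delG", 100, "frameshift", -1),
        ("c.100_102del", 100, "unknown", -3),
        ("c.50_51insTT", 50, "frameshift", 2),
    ])
    def test_subset(self, notation, pos, kind, offset):
        v = parse_c_notation(notation)
        assert (v.c_position, v.kind, v.frame_offset) == (pos, kind, offset)

    def test_garbage(self):
        with pytest.raises(ValueError):
            parse_c_notation("p.R367Q")


class TestLocatePtc:
    def test_nonsense_is_its_own_ptc(self):
        tx = toy_transcript("ATG" + "CAC" * 40 + "TAA")
        v = CodingVariant(label="c.100C>T", c_position=100, kind="nonsense")
        assert locate_ptc(tx, v) == 100

    def test_manual_duplication_hand_translation(self):
        # CDS ATG AAT AAG TAA; +1 dup of c.4 (A) edits the coding region
        # to ATGA[A]ATAAGTAA, which hand-translates ATG AAA TAA: the
        # shifted frame stops at edited position 7, pre-edit coordinate 6
        tx = toy_transcript("ATGAATAAGTAA")
        v = CodingVariant(label="c.4dup", c_position=4, kind="frameshift",
                          frame_offset=1)
        assert locate_ptc(tx, v) == 6

    def test_frameshift_without_stop_is_none(self):
        tx = toy_transcript("ATG" + "CAC" * 20 + "TAA", utr3="CACCACCAC")
        v = CodingVariant(label="c.5del", c_position=5, kind="frameshift",
                          frame_offset=-1, deleted_len=1)
        assert locate_ptc(tx, v) is None

    def test_outside_cds_rejected(self):
        tx = toy_transcript("ATGCACTAA")
        with pytest.raises(ValueError):
            locate_ptc(tx, CodingVariant(label="c.99C>T", c_position=99,
                                         kind="nonsense"))

    def test_frameshift_requires_sequence(self):
        tx = TranscriptModel(id="noseq", exons=[(1, 100)], cds_start=1,
                             cds_end=99)
        v = CodingVariant(label="c.10del", c_position=10, kind="frameshift",
                          frame_offset=-1, deleted_len=1)
        with pytest.raises(ValueError, match="sequence"):
            locate_ptc(tx, v)

    def test_agrees_with_translation_oracle_on_random_transcripts(self):
        rng = np.random.default_rng(12345)
        bases = np.array(list("ACGT"))
        n_checked = 0
        for _ in range(100):
            n_codons = int(rng.integers(20, 60))
            cds = "ATG" + "".join(rng.choice(bases, size=3 * n_codons)) + "TAA"
            utr3 = "".join(rng.choice(bases, size=int(rng.integers(10, 40))))
            tx = toy_transcript(cds, utr3=utr3)
            c_pos = int(rng.integers(4, len(cds) - 3))
            if rng.uniform() < 0.5:
                v = CodingVariant(label=f"c.{c_pos}dup", c_position=c_pos,
                                  kind="frameshift", frame_offset=1)
            else:
                v = CodingVariant(label=f"c.{c_pos}del", c_position=c_pos,
                                  kind="frameshift", frame_offset=-1,
                                  deleted_len=1)
            tx_pos = tx.cds_to_tx(c_pos)
            edited = apply_edit_oracle(tx.sequence, tx_pos, v)
            expected_edited = oracle_frameshift_stop(tx.sequence, tx.cds_start,
                                                     edited)
            got = locate_ptc(tx, v)
            if expected_edited is None:
                assert got is None
            else:
                mapped = (expected_edited if expected_edited <= c_pos
                          else expected_edited - v.frame_offset)
                assert got == mapped, (v.label, cds)
            n_checked += 1
        assert n_checked == 100


class TestPredictNmd:
    def three_exon_tx(self):
        # junctions after 150 and 300; CDS 11..400; total 460
        seq = "A" * 460
        return TranscriptModel(id="t3", exons=[(1, 150), (151, 300), (301, 460)],
                               cds_start=11, cds_end=400, sequence=None)

    def test_far_upstream_ptc_decays(self):
        tx = self.three_exon_tx()
        # PTC at transcript 100 -> 200 nt upstream of junction at 300
        assert predict_nmd(tx, 100 - 10) == "nmd"

    def test_last_exon_escapes(self):
        tx = self.three_exon_tx()
        assert predict_nmd(tx, 350 - 10) == "escape"

    def test_boundary_50nt_escapes(self):
        tx = self.three_exon_tx()
        # exactly 50 nt upstream of the final junction
        assert predict_nmd(tx, 250 - 10) == "escape"
        assert predict_nmd(tx, 249 - 10) == "nmd"

    def test_single_exon_always_escapes(self):
        tx = TranscriptModel(id="mono", exons=[(1, 300)], cds_start=11,
                             cds_end=250)
        assert predict_nmd(tx, 5) == "escape"

    def test_upstream_shift_never_flips_nmd_to_escape(self):
        tx = self.three_exon_tx()
        verdicts = [predict_nmd(tx, c) for c in range(1, 380)]
        # once a downstream-moving PTC reaches escape it stays escape
        first_escape = verdicts.index("escape")
        assert all(v == "escape" for v in verdicts[first_escape:])


class TestNmdSummary:
    def make_calls(self, n_nmd, n_escape, n_low):
        calls = []
        for i in range(n_nmd):
            calls.append(NmdCall(f"n{i}", "nonsense", 10, "nmd"))
        for i in range(n_escape):
            calls.append(NmdCall(f"e{i}", "nonsense", 400, "escape"))
        for i in range(n_low):
            calls.append(NmdCall(f"l{i}", "frameshift", None, "low_confidence"))
        return calls

    def test_worked_example_accounting(self):
        # 10 decayed, 7 missense pass-through, 4 low-confidence excluded
        s = nmd_summary(self.make_calls(10, 0, 4), include_missense_count=7)
        assert s.n_confident == 17
        assert s.percentage == pytest.approx(100 * 10 / 17)
        assert s.flag == "Medium"
        # missense share of the 21 protein-level variants
        assert s.missense_percentage == pytest.approx(100 * 7 / 21)

    def test_zero_nmd_is_high(self):
        s = nmd_summary(self.make_calls(0, 5, 0), include_missense_count=2)
        assert s.percentage == 0.0
        assert s.flag == "High"

    def test_all_nmd_is_low(self):
        s = nmd_summary(self.make_calls(8, 0, 0))
        assert s.percentage == 100.0
        assert s.flag == "Low"

    @pytest.mark.parametrize("pct,flag", [(33.0, "Medium"), (66.0, "Medium"),
                                          (32.9, "High"), (66.5, "Low")])
    def test_boundaries_to_medium(self, pct, flag):
        # craft integer counts approximating the percentage on n=1000
        n_nmd = round(pct * 10)
        s = nmd_summary(self.make_calls(n_nmd, 1000 - n_nmd, 0))
        assert s.flag == flag

    def test_order_invariance(self):
        calls = self.make_calls(3, 2, 1)
        fwd = nmd_summary(calls, include_missense_count=2)
        rev = nmd_summary(list(reversed(calls)), include_missense_count=2)
        assert fwd.percentage == rev.percentage

    def test_empty_denominator(self):
        with pytest.raises(ValueError):
            nmd_summary(self.make_calls(0, 0, 3))


class TestMutationClassFixture:
    def test_class_composition(self):
        _tx, variants = make_mutation_class_fixture()
        kinds = [v.kind for v in variants]
        assert len(variants) == 25
        assert kinds.count("nonsense") == 7
        assert kinds.count("frameshift") == 7
        assert kinds.count("missense") == 7
        assert kinds.count("unknown") == 4

    def test_full_accounting(self):
        tx, variants = make_mutation_class_fixture()
        calls = [call_variant(tx, v) for v in variants]
        summary = nmd_summary(calls)
        assert summary.n_nmd == 10
        assert summary.n_low_confidence == 4
        assert summary.n_confident == 17
        assert summary.flag == "Medium"
        assert summary.missense_percentage > 33.0
        assert math.isclose(summary.percentage, 100 * 10 / 17)


class TestStartProximalEscape:
    def test_flag_off_by_default(self):
        tx = TestPredictNmd().three_exon_tx()
        assert predict_nmd(tx, 60) == "nmd"

    def test_flag_enables_reinitiation_escape(self):
        tx = TestPredictNmd().three_exon_tx()
        assert predict_nmd(tx, 60, start_proximal_escape=True) == "escape"
        assert predict_nmd(tx, 200, start_proximal_escape=True) == "nmd"
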