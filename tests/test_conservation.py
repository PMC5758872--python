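"""Orthologue scanning, motif-region alignment, and consensus reliability."""

import numpy as np
import pytest

from dlekit.conservation import (
    align_motif_regions,
    consensus_structure,
    progressive_align,
    scan_orthologues,
)
from dlekit.dle_scan import STRICT
from dlekit.rna_thermo import pair_probability_matrix
from dlekit.seqio import AlignmentSet, Transcript, ValidationError
from dlekit.synthetic_data import (
    SimConfig,
    gen_orthologue_family,
    select_homologous_matches,
)

FAMILY_SEED = 17


@pytest.fixture(scope="module")
def family():
    return gen_orthologue_family(SimConfig(seed=FAMILY_SEED, utr_length=60))


class TestScanOrthologues:
    def test_species_without_match_absent(self):
        with_dle = Transcript(id="a", seq="GCACUUGGGAAAAACCCAAA")
        without = Transcript(id="b", seq="A" * 20)
        out = scan_orthologues([with_dle, without], STRICT, cds_context=0)
        assert {m.transcript_id for m in out} == {"a"}

    def test_cds_context_extends_scan_window(self):
        # element straddles the CDS/UTR boundary: only visible with context
        seq = "GCACUUGGGAAAAACCCAAA"
        t = Transcript(id="c", seq=seq, utr_start=10)
        assert scan_orthologues([t], STRICT, cds_context=0) == []
        [m] = scan_orthologues([t], STRICT, cds_context=100)
        assert m.anchor.start == 0  # all available CDS used when < 100 nt

    def test_family_matches_at_homologous_positions(self, family):
        fam, truth = family
        out = scan_orthologues(fam, STRICT, cds_context=0)
        anchors = {m.transcript_id for m in out if m.anchor.start == truth.anchor_start}
        assert anchors == {t.id for t in fam}


class TestProgressiveAlign:
    def test_identical_sequences_align_gapless(self):
        aln = progressive_align([("a", "GCACUUGGG"), ("b", "GCACUUGGG")])
        assert aln.rows[0][1] == aln.rows[1][1] == "GCACUUGGG"

    def test_single_sequence_trivial_alignment(self):
        aln = progressive_align([("only", "ACGU")])
        assert aln.rows == [("only", "ACGU")]

    def test_insertion_gives_one_gap_run(self):
        a = "GCACUUGGGAAACCC"
        b = "GCACUUGGGCGAAACCC"  # 2-nt insertion after the stem arm
        aln = progressive_align([("a", a), ("b", b)])
        row_a = aln.rows[0][1]
        assert row_a.count("-") == 2
        gap_start = row_a.index("-")
        assert row_a[gap_start:gap_start + 2] == "--"
        assert "-" not in row_a.replace("--", "", 1)  # single run only
        assert aln.rows[1][1].replace("-", "") == b

    def test_family_anchor_columns_gapless(self, family):
        fam, truth = family
        matches = select_homologous_matches(fam, truth, STRICT)
        aln = align_motif_regions(matches, fam, flanks=10)
        assert len({len(r) for _, r in aln.rows}) == 1
        # anchors occupy the same gapless columns in every row
        off = matches[0].anchor.start - max(0, matches[0].anchor.start - 10)
        for _, row in aln.rows:
            assert row[off:off + 4] == "GCAC"


class TestConsensusStructure:
    def test_single_row_equals_own_pair_probabilities(self, simple_model):
        seq = "GCACUUGGGAAAAACCC"
        aln = AlignmentSet(rows=[("one", seq)])
        cs = consensus_structure(aln, simple_model)
        P = pair_probability_matrix(seq, simple_model)
        assert np.allclose(cs.pair_reliability, P)

    def test_two_identical_rows_idempotent(self, simple_model):
        seq = "GCACUUGGGAAAAACCC"
        one = consensus_structure(AlignmentSet(rows=[("a", seq)]), simple_model)
        two = consensus_structure(
            AlignmentSet(rows=[("a", seq), ("b", seq)]), simple_model
        )
        assert np.allclose(one.pair_reliability, two.pair_reliability)
        assert one.dot_bracket == two.dot_bracket

    def test_empty_alignment_rejected(self, simple_model):
        with pytest.raises(ValidationError):
            consensus_structure(AlignmentSet(rows=[]), simple_model)

    def test_reliabilities_bounded_and_dot_bracket_balanced(self, family, simple_model):
        fam, truth = family
        matches = select_homologous_matches(fam, truth, STRICT)
        aln = align_motif_regions(matches, fam, flanks=10)
        cs = consensus_structure(aln, simple_model)
        assert np.all(cs.pair_reliability >= 0) and np.all(cs.pair_reliability <= 1)
        assert np.all(cs.single_reliability >= 0) and np.all(cs.single_reliability <= 1)
        depth = 0
        for c in cs.dot_bracket:
            depth += {"(": 1, ")": -1}.get(c, 0)
            assert depth >= 0
        assert depth == 0
        # per-column occupancy never exceeds the averaged normalization
        occupancy = (
            cs.single_reliability
            + cs.pair_reliability.sum(axis=0)
            + cs.pair_reliability.sum(axis=1)
        )
        assert np.all(occupancy <= 1 + 1e-9)

    def test_all_gap_column_contributes_nothing(self, simple_model):
        seq = "GCACUUGGGAAAAACCC"
        base = consensus_structure(AlignmentSet(rows=[("a", seq)]), simple_model)
        padded = consensus_structure(
            AlignmentSet(rows=[("a", seq), ("gap", "-" * len(seq))]), simple_model
        )
        # the gap row halves every reliability, never increases one
        assert np.allclose(padded.pair_reliability, base.pair_reliability / 2)

    def test_compensatory_family_recovers_planted_stem(self, family, simple_model):
        """Planted stem column pairs out-rank all others and enter the consensus.

        Uses the generator's ground-truth (indel-free) alignment, the
        synthetic analogue of a curated alignment, so the check isolates
        the consensus scoring from aligner jitter in low-complexity flanks.
        """
        from dlekit.synthetic_data import truth_alignment

        fam, truth = family
        assert len(select_homologous_matches(fam, truth, STRICT)) == len(fam)
        aln, off = truth_alignment(fam, truth, flanks=10)
        cs = consensus_structure(aln, simple_model)
        planted = {(i - off, j - off) for i, j in truth.stem_pairs}
        rel = cs.pair_reliability
        worst_planted = min(rel[i, j] for i, j in planted)
        best_other = max(
            rel[i, j]
            for i in range(cs.columns)
            for j in range(i + 1, cs.columns)
            if (i, j) not in planted
        )
        assert worst_planted > best_other
        assert planted <= set(cs.consensus_pairs())

    def test_compensatory_beats_pairing_breaking_divergence(self, simple_model):
        """At equal divergence, compensatory families keep stem reliability."""
        cfg_c = SimConfig(seed=FAMILY_SEED, utr_length=60, compensatory=True)
        cfg_r = SimConfig(seed=FAMILY_SEED, utr_length=60, compensatory=False)
        rels = {}
        for name, cfg in (("comp", cfg_c), ("rand", cfg_r)):
            fam, truth = gen_orthologue_family(cfg)
            rows = [(t.id, t.seq) for t in fam]  # truth alignment: no indels
            cs = consensus_structure(AlignmentSet(rows=rows), simple_model)
            rels[name] = np.mean([
                cs.pair_reliability[i, j] for i, j in truth.stem_pairs
            ])
        assert rels["comp"] > rels["rand"]

    def test_format_block_has_tracks(self, family, simple_model):
        fam, truth = family
        matches = select_homologous_matches(fam, truth, STRICT)
        aln = align_motif_regions(matches, fam, flanks=10)
        cs = consensus_structure(aln, simple_model)
        block = cs.format_block(aln)
        assert "conservation" in block and "reliab_paired" in block
        assert cs.dot_bracket in block
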