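import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as stnum

from splicesense.annotation import SkippingEvent
from splicesense.features import (
    MotifTable,
    count_motifs,
    feature_vector,
    ppt_score,
    predict_branch_point,
    revcomp,
    splice_site_sequences,
)
from splicesense.models import PositionWeightModel, default_branch_model


def motif_table(entries):
    return MotifTable.from_frame(
        pd.DataFrame(entries, columns=["factor", "motif", "score"])
    )


class TestSpliceSiteSequences:
    def _genome(self, seq):
        return {"chr1": seq}

    def test_plus_strand_windows_match_hand_slicing(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 800)])
        ev = SkippingEvent("e", "g", "chr1", "+", 150, 400, 470, 650)
        s = splice_site_sequences(ev, self._genome(seq))
        assert s.donor == seq[467:476]          # 3 exonic + 6 intronic
        assert s.acceptor == seq[380:403]       # 20 intronic + 3 exonic
        assert s.ppt_window == seq[300:400]     # last 100 nt of upstream intron
        assert s.donor_upstream_intron == seq[147:156]
        assert s.acceptor_downstream_intron == seq[630:653]
        assert s.exon == seq[400:470]
        assert not s.truncated

    def test_minus_strand_is_reverse_complement_of_mirror(self):
        rng = np.random.default_rng(1)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 800)])
        ev = SkippingEvent("e", "g", "chr1", "-", 150, 400, 470, 650)
        s = splice_site_sequences(ev, self._genome(seq))
        assert s.exon == revcomp(seq[400:470])
        assert s.donor == revcomp(seq[394:403])
        assert s.acceptor == revcomp(seq[467:490])
        assert s.ppt_window == revcomp(seq[470:570])

    def test_short_intron_truncates_window(self):
        seq = "ACGT" * 300
        ev = SkippingEvent("e", "g", "chr1", "+", 340, 400, 470, 650)
        s = splice_site_sequences(ev, self._genome(seq))
        assert len(s.ppt_window) == 60
        assert s.truncated

    def test_strand_consistency_under_genome_mirroring(self):
        """Reverse-complementing the genome and flipping strands leaves the
        extracted sequences unchanged."""
        rng = np.random.default_rng(2)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 900)])
        L = len(seq)
        ev = SkippingEvent("e", "g", "chr1", "+", 150, 400, 470, 650)
        mirrored = SkippingEvent(
            "e", "g", "chr1", "-", L - 650, L - 470, L - 400, L - 150
        )
        s1 = splice_site_sequences(ev, self._genome(seq))
        s2 = splice_site_sequences(mirrored, self._genome(revcomp(seq)))
        assert s1 == s2


class TestScoreSpliceSite:
    def test_uniform_model_scores_zero(self):
        m = PositionWeightModel.uniform(9)
        assert m.score("CAGGTAAGT") == pytest.approx(0.0)
        assert m.score("AAAAAAAAA") == pytest.approx(0.0)

    def test_twofold_consensus_model(self):
        cons = "CAGGTAAGT"
        probs = np.full((9, 4), 1 / 6)
        for i, b in enumerate(cons):
            probs[i, "ACGT".index(b)] = 0.5
        m = PositionWeightModel(probs)
        assert m.score(cons) == pytest.approx(9.0)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            PositionWeightModel.uniform(9).score("CAGGTAAG")

    def test_tsv_round_trip(self, tmp_path):
        m = default_branch_model()
        m.to_tsv(tmp_path / "m.tsv")
        m2 = PositionWeightModel.from_tsv(tmp_path / "m.tsv")
        assert m2.score("GGCTAAC") == pytest.approx(m.score("GGCTAAC"), abs=1e-4)


class TestCountMotifs:
    def test_overlapping_occurrences_counted(self):
        table = motif_table([("f", "GAAGAA", 1.0)])
        assert count_motifs("GAAGAAGAA", table) == (2, 0)

    def test_no_hits(self):
        table = motif_table([("f", "GAAGAA", 1.0)])
        assert count_motifs("CCCCCCCC", table) == (0, 0)

    def test_negative_score_counts_as_ess(self):
        table = motif_table([("f", "TTTAGG", -2.0)])
        assert count_motifs("CCTTTAGGCC", table) == (0, 1)

    def test_empty_table(self):
        assert count_motifs("ACGT", MotifTable([])) == (0, 0)

    def test_additive_over_disjoint_tables(self):
        t1 = motif_table([("a", "GAAGAA", 1.0)])
        t2 = motif_table([("b", "GGGTTT", -1.0)])
        both = motif_table([("a", "GAAGAA", 1.0), ("b", "GGGTTT", -1.0)])
        seq = "GAAGAAGGGTTTGAAGAA"
        e1, s1 = count_motifs(seq, t1)
        e2, s2 = count_motifs(seq, t2)
        assert count_motifs(seq, both) == (e1 + e2, s1 + s2)


class TestBranchPoint:
    def test_consensus_heptamer_wins(self):
        window = "TTTTTCTAACTTTTTTTTTTTTTTTTTAG"
        bp = predict_branch_point(window)
        assert bp is not None
        pos, score = bp
        assert pos == 8  # the 3'-most A of CTAAC
        assert window[pos] == "A"
        # exhaustive scan agrees
        model = default_branch_model()
        best = max(
            (
                (model.score(window[i:i + 7]), i)
                for i in range(len(window) - 6)
                if window[i + 5] == "A"
            ),
        )
        assert (score, pos - 5) == pytest.approx(best)

    def test_no_adenosine_gives_none(self):
        assert predict_branch_point("TTTTTTTTTTCCCCCCCGGG") is None

    def test_short_window_gives_none(self):
        assert predict_branch_point("CTAAC") is None

    def test_tie_breaks_to_three_prime(self):
        # two identical candidate heptamers; the 3'-most must win
        window = "GGCTAACGGG" + "GGCTAACGGG"
        pos, _ = predict_branch_point(window)
        assert pos == 15


class TestPptScore:
    def test_all_purine_region(self):
        assert ppt_score("AGGGGGGGGGGCAG", 0) == 0

    def test_uniform_pyrimidine_run(self):
        assert ppt_score("AATTTTTTTTTTCAG", 1) == 20

    def test_mixed_region(self):
        # region TCAGTT: 4 pyrimidines, longest run 2
        assert ppt_score("ATCAGTTCAG", 0) == 6

    def test_empty_region(self):
        assert ppt_score("ACAG", 0) == 0

    @given(stnum.integers(0, 3))
    @settings(max_examples=20, deadline=None)
    def test_monotone_under_pyrimidine_substitution(self, idx):
        base = "AGAGAGAGAGACAG"
        score0 = ppt_score(base, 0)
        swapped = list(base)
        swapped[2 + idx * 2] = "T"  # purine -> pyrimidine inside the region
        assert ppt_score("".join(swapped), 0) >= score0


class TestFeatureVector:
    def _toy_event(self):
        up_exon = "A" * 50
        up_intron = "GTAAGT" + "G" * 40 + "GGCTAAC" + "G" * 2 + "T" * 7 + "CAG"
        exon = "CC" + "GGAAGA" + "CC" + "GGGTTT" + "CC" * 24  # 64 nt
        down_intron = "GTAAGT" + "G" * 60 + "TTTTTTTCAG"
        down_exon = "G" * 50
        seq = up_exon + up_intron + exon + down_intron + down_exon
        c1 = 50
        c2 = c1 + len(up_intron)
        c3 = c2 + len(exon)
        c4 = c3 + len(down_intron)
        ev = SkippingEvent("e", "g", "chr1", "+", c1, c2, c3, c4)
        return ev, {"chr1": seq}, exon, up_intron

    def test_fields_match_hand_computation(self):
        ev, genome, exon, up_intron = self._toy_event()
        table = motif_table(
            [("e1", "GGAAGA", 5.0), ("s1", "GGGTTT", -4.0)]
        )
        fv = feature_vector(ev, genome, table)
        assert fv.exon_length == len(exon) == 64
        assert fv.n_ese == 1 and fv.n_ess == 1
        assert fv.upstream_intron_length == len(up_intron)
        # branch A inside GGCTAAC; region = C + GG + TTTTTTT -> 8 py + run 7
        assert fv.ppt_score == 15
        assert fv.branch_score is not None
        assert fv.window_truncated  # 58-nt upstream intron < 100

    def test_missing_branch_point_flags_ppt_missing(self):
        ev, genome, *_ = self._toy_event()
        # genome with no adenosine in the upstream intron window
        seq = genome["chr1"]
        window = seq[ev.coord2 - (ev.coord2 - ev.coord1):ev.coord2]
        doctored = seq[:ev.coord1] + window.replace("A", "G") + seq[ev.coord2:]
        fv = feature_vector(ev, {"chr1": doctored}, MotifTable([]))
        assert fv.ppt_score is None and fv.branch_score is None
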