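import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stnum

from splicesense.quantify import (
    classify_response,
    compute_psi,
    delta_psi_distribution,
    extract_junctions,
    passes_expression_filter,
    rpk30m,
    strict_skip_call,
)

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:10000\n"


def sam_line(name, flag, pos, cigar):
    return f"{name}\t{flag}\tchr1\t{pos}\t60\t{cigar}\t*\t0\t0\t*\t*\n"


class TestExtractJunctions:
    def test_anchor_filter_and_library_size(self, tmp_path):
        sam = tmp_path / "reads.sam"
        sam.write_text(
            SAM_HEADER
            + sam_line("short_anchor", 0, 101, "7M100N50M")   # 7 < 8: dropped
            + sam_line("exact_anchor", 0, 101, "8M100N8M")     # counted
            + sam_line("unspliced", 0, 101, "50M")             # no junction
            + sam_line("unmapped", 4, 0, "*")
        )
        jc = extract_junctions(sam, min_anchor=8)
        counts = jc.counts["sample"]
        assert counts == {("chr1", 108, 208, "+"): 1}
        assert jc.library_sizes["sample"] == 3  # mapped reads only

    def test_two_junction_read_needs_anchors_on_each(self, tmp_path):
        sam = tmp_path / "reads.sam"
        # middle block 20 nt anchors both junctions; trailing block only 5 nt
        sam.write_text(SAM_HEADER + sam_line("r", 0, 1, "10M50N20M50N5M"))
        jc = extract_junctions(sam)
        assert jc.counts["sample"] == {("chr1", 10, 60, "+"): 1}


class TestRpk30m:
    @pytest.mark.parametrize(
        "count, length, lib, expected",
        [(3, 300, 30_000_000, 10.0), (0, 300, 30_000_000, 0.0),
         (3, 300, 60_000_000, 5.0)],
    )
    def test_values(self, count, length, lib, expected):
        assert rpk30m(count, length, lib) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpk30m(1, 0, 100)
        with pytest.raises(ValueError):
            rpk30m(1, 100, 0)


class TestComputePsi:
    @pytest.mark.parametrize(
        "up, down, skip, expected",
        [(10, 10, 0, 1.0), (0, 0, 7, 0.0), (6, 4, 5, 0.5)],
    )
    def test_values(self, up, down, skip, expected):
        assert compute_psi(up, down, skip) == pytest.approx(expected)

    def test_undefined_when_all_zero(self):
        assert compute_psi(0, 0, 0) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_psi(-1, 0, 0)

    @given(
        up=stnum.integers(0, 1000),
        down=stnum.integers(0, 1000),
        skip=stnum.integers(0, 1000),
        scale=stnum.integers(1, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_scale_invariance(self, up, down, skip, scale):
        psi = compute_psi(up, down, skip)
        if psi is None:
            assert (up, down, skip) == (0, 0, 0)
        else:
            assert 0.0 <= psi <= 1.0
            scaled = compute_psi(up * scale, down * scale, skip * scale)
            assert scaled == pytest.approx(psi)

    def test_monotone_in_skip_and_inclusion(self):
        base = compute_psi(10, 10, 5)
        assert compute_psi(10, 10, 6) < base
        assert compute_psi(12, 10, 5) > base


class TestExpressionFilter:
    def test_gene_low_everywhere_fails(self):
        gene = {s: 15.0 for s in "abcd"}
        junc = {s: 10.0 for s in "abcd"}
        assert not passes_expression_filter(gene, junc)

    def test_boundary_gene_expression_passes(self):
        gene = {"a": 16.0, "b": 1.0, "c": 1.0, "d": 1.0}
        junc = {s: 4.0 for s in "abcd"}
        assert passes_expression_filter(gene, junc)

    def test_single_low_junction_replicate_fails(self):
        gene = {s: 100.0 for s in "abcd"}
        junc = {"a": 3.9, "b": 10.0, "c": 10.0, "d": 10.0}
        assert not passes_expression_filter(gene, junc)

    def test_missing_samples_rejected(self):
        with pytest.raises(ValueError):
            passes_expression_filter({"a": 20.0}, {"b": 5.0})


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "deltas, expected",
        [
            ((-0.06, -0.02), "skip"),
            ((-0.06, 0.01), "others:inconsistent"),
            ((0.00, 0.04), "no_change"),
            ((0.06, 0.02), "inclusion"),
            ((0.05, 0.00), "others:inconsistent"),
            ((-0.05, -0.001), "skip"),
        ],
    )
    def test_rules(self, deltas, expected):
        psi = (0.5, 0.5, 0.5, 0.5)
        assert classify_response(deltas, psi) == expected

    def test_psi_too_low(self):
        assert (
            classify_response((0.0, 0.0), (0.03, 0.03, 0.03, 0.03))
            == "others:psi_too_low"
        )

    def test_no_expression_takes_precedence(self):
        assert (
            classify_response((None, 0.0), (None, 0.5, 0.5, 0.5))
            == "others:no_expression"
        )

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            classify_response((0.1,), (0.5, 0.5))

    @given(
        d1=stnum.floats(-1, 1, allow_nan=False),
        d2=stnum.floats(-1, 1, allow_nan=False),
        p=stnum.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=300, deadline=None)
    def test_totality(self, d1, d2, p):
        """Every Δψ pair falls in exactly one response class."""
        cls = classify_response((d1, d2), (p, p, p, p))
        assert cls in {
            "skip", "inclusion", "no_change", "others:no_expression",
            "others:inconsistent", "others:psi_too_low",
        }


class TestStrictSkipCall:
    def test_clear_shift_called(self):
        assert strict_skip_call([0.80, 0.82], [0.50, 0.52]) is True

    def test_small_shift_rejected(self):
        assert strict_skip_call([0.80, 0.82], [0.70, 0.72]) is False

    def test_identical_values_rejected(self):
        assert strict_skip_call([0.8, 0.8], [0.8, 0.8]) is False

    def test_zero_variance_shift_called(self):
        assert strict_skip_call([0.9, 0.9], [0.5, 0.5]) is True

    def test_matches_hand_t_test(self):
        # t = dpsi / sqrt(sp2 * (1/2 + 1/2)), df = 2
        ctrl, treat = [0.80, 0.84], [0.50, 0.56]
        sp2 = (np.var(ctrl, ddof=1) + np.var(treat, ddof=1)) / 2
        t = (np.mean(treat) - np.mean(ctrl)) / math.sqrt(sp2)
        from scipy.stats import t as tdist
        p = 2 * tdist.sf(abs(t), df=2)
        assert strict_skip_call(ctrl, treat) == bool(p < 0.05)

    def test_requires_replicates(self):
        with pytest.raises(ValueError):
            strict_skip_call([0.8], [0.5, 0.5])


class TestDeltaPsiDistribution:
    def test_flat_events(self):
        df = delta_psi_distribution(
            [{"event_id": "e", "psi_ctrl": (0.6, 0.6), "psi_treat": (0.6, 0.6)}]
        )
        assert df["delta_psi_avg"].iloc[0] == 0.0
        assert df["baseline"].iloc[0] == 0.0

    def test_skip_enhanced_counted(self):
        df = delta_psi_distribution(
            [{"event_id": "e", "psi_ctrl": (0.6, 0.6), "psi_treat": (0.4, 0.5)}]
        )
        assert df["delta_psi_avg"].iloc[0] == pytest.approx(-0.15)
        assert df.attrs["n_skip_enhanced"] == 1
        assert df.attrs["n_inclusion_enhanced"] == 0

    def test_empty_input(self):
        df = delta_psi_distribution([])
        assert len(df) == 0
        assert df.attrs["n_skip_enhanced"] == 0
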