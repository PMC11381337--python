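"""Known-site caller: quality filter, thresholds, blacklist, pooling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edicall.formats import NT_CODE, PileupColumn
from edicall.known_sites import (
    EDITED,
    NOT_EDITED,
    NOT_EXPRESSED,
    EditingConfig,
    NucCounts,
    build_adar_blacklist,
    call_known_site,
    editing_matrix,
    gene_level_editing,
    merge_replicates,
    quality_filter_column,
)


def column(ref="A", bases="", quals=None, chrom="chrI", pos=100):
    """Build a column from a base string like 'AAAG' (all forward)."""
    codes = [NT_CODE[b] for b in bases]
    quals = [40] * len(bases) if quals is None else quals
    return PileupColumn(chrom, pos, ref, codes, [True] * len(bases), quals)


def counts_from(ref="A", chrom="chrI", pos=100, **nt_counts) -> NucCounts:
    nc = NucCounts(chrom, pos, ref)
    for nt, n in nt_counts.items():
        nc.mat[NT_CODE[nt], 0] = n
    return nc


class TestQualityFilter:
    def test_worked_fixture_hand_tallied(self):
        # the decoded "..,,GGg." / "IIIII#II" column: 5xA, 3xG, one G at Q2
        col = PileupColumn(
            "chrI", 1005, "A",
            [0, 0, 0, 0, 2, 2, 2, 0],
            [True, True, False, False, True, True, False, True],
            [40, 40, 40, 40, 40, 2, 40, 40],
        )
        nc = quality_filter_column(col, q_min=25)
        assert nc.count("A") == 5 and nc.count("G") == 2
        assert nc.depth == 7
        # strand-resolved counts preserved
        assert nc.as_dict() == {("A", "+"): 3, ("A", "-"): 2, ("G", "+"): 1, ("G", "-"): 1}

    def test_all_passing_is_identity(self):
        col = column(bases="AAGG", quals=[40, 40, 40, 40])
        nc = quality_filter_column(col, 25)
        assert nc.depth == 4 and nc.count("G") == 2

    def test_all_below_threshold_empties_column(self):
        col = column(bases="AAGG", quals=[20, 20, 20, 20])
        assert quality_filter_column(col, 25).depth == 0

    def test_boundary_phred_24_out_25_in(self):
        col = column(bases="GG", quals=[24, 25])
        nc = quality_filter_column(col, 25)
        assert nc.depth == 1 and nc.count("G") == 1


class TestCallKnownSite:
    def test_both_thresholds_at_boundary_is_edited(self):
        # depth 200: target 2 (1.0%), others 2 (1.0%) -> edited at level 0.01
        nc = counts_from(A=196, G=2, C=1, T=1)
        call = call_known_site(nc, "A")
        assert call.status == EDITED
        assert call.record.level == pytest.approx(0.01)
        assert call.record.n_target == 2 and call.record.n_other == 2

    def test_excess_other_changes_rejects(self):
        nc = counts_from(A=195, G=2, C=3)  # others 1.5% > 1%
        assert call_known_site(nc, "A").status == NOT_EDITED

    def test_simple_five_percent_site(self):
        nc = counts_from(A=95, G=5)
        call = call_known_site(nc, "A")
        assert call.status == EDITED and call.record.level == pytest.approx(0.05)

    def test_zero_depth_is_not_expressed(self):
        assert call_known_site(NucCounts("chrI", 1, "A"), "A").status == NOT_EXPRESSED

    def test_t_to_c_reverse_strand_signature(self):
        nc = counts_from(ref="T", T=90, C=10)
        call = call_known_site(nc, "T")
        assert call.status == EDITED
        assert call.record.change == "T>C" and call.record.strand == "-"

    def test_sub_one_percent_target_not_edited(self):
        nc = counts_from(A=199, G=1)  # 0.5%
        assert call_known_site(nc, "A").status == NOT_EDITED

    def test_per_change_other_mode(self):
        # others split 0.75%+0.75%: aggregate 1.5% fails, per-change passes
        nc = counts_from(A=381, G=13, C=3, T=3)
        assert call_known_site(nc, "A").status == NOT_EDITED
        cfg = EditingConfig(aggregate_other=False)
        assert call_known_site(nc, "A", cfg).status == EDITED

    def test_non_a_t_reference_rejected(self):
        with pytest.raises(ValueError):
            call_known_site(counts_from(ref="G", G=10), "G")


class TestBlacklist:
    def site(self):
        return [("chrI", 500, "A")]

    def test_exactly_three_percent_retained(self):
        adar = {("chrI", 500): counts_from(pos=500, A=970, G=30)}
        black, gray = build_adar_blacklist(adar, self.site(), 0.03)
        assert black == set() and gray == set()

    def test_above_three_percent_blacklisted(self):
        adar = {("chrI", 500): counts_from(pos=500, A=969, G=31)}
        black, _ = build_adar_blacklist(adar, self.site(), 0.03)
        assert black == {("chrI", 500)}

    def test_zero_coverage_unassessable_but_retained(self):
        black, gray = build_adar_blacklist({}, self.site(), 0.03)
        assert black == set() and gray == {("chrI", 500)}


class TestMergeReplicates:
    def test_depth_additive(self):
        cols = [column(bases="A" * n) for n in (10, 12, 8)]
        assert merge_replicates(cols).depth == 30

    def test_ref_disagreement_rejected(self):
        with pytest.raises(ValueError, match="disagreement"):
            merge_replicates([column(ref="A"), column(ref="G")])

    def test_single_column_identity(self):
        col = column(bases="AAG")
        assert merge_replicates([col]) == col

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        per_rep=st.lists(
            st.tuples(st.integers(0, 50), st.integers(0, 50)),
            min_size=1,
            max_size=5,
        )
    )
    def test_pooled_fraction_is_weighted_mean(self, per_rep):
        """Pooled G fraction equals sum(G_i)/sum(depth_i) exactly."""
        cols = [column(bases="A" * a + "G" * g) for a, g in per_rep]
        pooled = merge_replicates(cols)
        nc = quality_filter_column(pooled, 25)
        total = sum(a + g for a, g in per_rep)
        if total:
            assert nc.count("G") == sum(g for _, g in per_rep)
            assert nc.depth == total


class TestGeneLevel:
    def test_pooling_arithmetic(self):
        sites = [
            (counts_from(A=98, G=2), "A"),
            (counts_from(A=92, G=8), "A"),
        ]
        summary = gene_level_editing("g1", sites)
        assert (summary.n_target, summary.n_total) == (10, 200)
        assert summary.level == pytest.approx(0.05)

    def test_single_site_equals_site_level(self):
        summary = gene_level_editing("g1", [(counts_from(A=95, G=5), "A")])
        assert summary.level == pytest.approx(0.05)

    def test_unedited_gene_is_zero(self):
        summary = gene_level_editing("g1", [(counts_from(A=50), "A")])
        assert summary.level == 0.0

    def test_unexpressed_gene_level_undefined(self):
        assert gene_level_editing("g1", [(NucCounts(), "A")]).level is None


class TestEditingMatrix:
    def test_unthresholded_levels_and_flags(self):
        sites = [("chrI", 10, "A"), ("chrI", 20, "A")]
        per_sample = {
            "s1": {("chrI", 10): counts_from(pos=10, A=49, G=1)},
            "s2": {("chrI", 20): counts_from(pos=20, A=10)},
        }
        mat = editing_matrix(per_sample, sites)
        assert mat.levels.shape == (2, 2)
        assert mat.levels.loc["chrI:10", "s1"] == pytest.approx(0.02)
        assert mat.expressed.loc["chrI:10", "s1"]
        # depth 0: unexpressed, level NaN (undefined, not zero)
        assert not mat.expressed.loc["chrI:10", "s2"]
        assert np.isnan(mat.levels.loc["chrI:10", "s2"])
        assert mat.levels.loc["chrI:20", "s2"] == 0.0


# ---------------------------------------------------------------------------
# oracle equivalence and monotonicity
# ---------------------------------------------------------------------------


def oracle_known_decision(n_a, n_c, n_g, n_t, ref="A"):
    """Brute-force evaluation of the printed criteria in integer arithmetic."""
    depth = n_a + n_c + n_g + n_t
    if depth == 0:
        return NOT_EXPRESSED
    target = n_g if ref == "A" else n_c
    other = depth - target - (n_a if ref == "A" else n_t)
    # >=1% target and <=1% other, scaled to integers
    if target * 100 >= depth and other * 100 <= depth:
        return EDITED
    return NOT_EDITED


class TestOracleEquivalence:
    def test_exhaustive_small_depth(self):
        for depth in range(0, 9):
            for n_c, n_g, n_t in itertools.product(range(depth + 1), repeat=3):
                if n_c + n_g + n_t > depth:
                    continue
                n_a = depth - n_c - n_g - n_t
                nc = counts_from(A=n_a, C=n_c, G=n_g, T=n_t)
                assert call_known_site(nc, "A").status == oracle_known_decision(
                    n_a, n_c, n_g, n_t
                ), (n_a, n_c, n_g, n_t)


class TestMonotonicity:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        quals=st.lists(st.integers(0, 60), min_size=0, max_size=40),
        q1=st.integers(0, 60),
        q2=st.integers(0, 60),
    )
    def test_raising_qmin_never_increases_depth(self, quals, q1, q2):
        lo, hi = min(q1, q2), max(q1, q2)
        col = column(bases="A" * len(quals), quals=quals)
        assert quality_filter_column(col, hi).depth <= quality_filter_column(col, lo).depth

    def test_raising_theta_site_shrinks_edited_set(self):
        rng = np.random.default_rng(0)
        cols = [
            counts_from(A=int(a), G=int(g), C=int(c))
            for a, g, c in zip(
                rng.integers(50, 200, 50), rng.integers(0, 12, 50), rng.integers(0, 3, 50)
            )
        ]
        def edited_set(theta):
            cfg = EditingConfig(theta_site=theta)
            return {
                i for i, nc in enumerate(cols)
                if call_known_site(nc, "A", cfg).status == EDITED
            }
        sets = [edited_set(t) for t in (0.01, 0.03, 0.05, 0.1)]
        for a, b in zip(sets, sets[1:]):
            assert b <= a

    def test_raising_theta_mut_grows_retained_set(self):
        rng = np.random.default_rng(1)
        sites = [("chrI", int(p), "A") for p in range(50)]
        adar = {
            ("chrI", i): counts_from(pos=i, A=100 - int(g), G=int(g))
            for i, g in enumerate(rng.integers(0, 10, 50))
        }
        def retained(theta):
            black, _ = build_adar_blacklist(adar, sites, theta)
            return {s[:2] for s in sites} - black
        sets = [retained(t) for t in (0.0, 0.03, 0.05, 0.08)]
        for a, b in zip(sets, sets[1:]):
            assert a <= b
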