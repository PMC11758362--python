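"""Per-site coverage, P/M/C statistics, and the paralogy matrix."""

import numpy as np
import pandas as pd
import pytest

from hybvet.assembly import (
    CoverageProfile,
    build_paralogy_matrix,
    filter_hits,
    flag_missing,
    flag_outlier_samples,
    flag_paralogs,
    length_ratio_flag,
    paralogy_stats,
    refine_superset,
    site_coverage,
)

from _helpers import (
    make_hit,
    oracle_outlier_samples,
    oracle_paralogy,
    oracle_site_coverage,
    random_hit_instance,
)


class TestFilterHits:
    @pytest.mark.parametrize(
        "alen, ident, kept",
        [
            (149, 99.0, False),  # below length boundary
            (150, 70.0, True),  # both exactly at boundary: kept
            (500, 69.9, False),
            (150, 69.9, False),
        ],
    )
    def test_boundaries_are_kept_not_removed(self, alen, ident, kept):
        hit = make_hit(ident=ident, alen=alen)
        assert (filter_hits([hit]) == [hit]) is kept

    def test_mixed_list_keeps_survivors_in_order(self):
        hits = [
            make_hit(query="a", alen=200, ident=90),
            make_hit(query="b", alen=100, ident=90),
            make_hit(query="c", alen=200, ident=50),
            make_hit(query="d", alen=151, ident=70),
            make_hit(query="e", alen=1000, ident=100),
        ]
        assert [h.query_id for h in filter_hits(hits)] == ["a", "d", "e"]


class TestSiteCoverage:
    def test_single_hit_covers_its_interval(self):
        profile = site_coverage([make_hit(s=(1, 10))], 20)
        assert profile.c.tolist() == [1] * 10 + [0] * 10

    def test_overlapping_hits_from_one_contig_count_once(self):
        hits = [make_hit(s=(1, 10)), make_hit(s=(5, 15))]
        profile = site_coverage(hits, 20)
        assert profile.c.tolist() == [1] * 15 + [0] * 5

    def test_two_contigs_stack(self):
        hits = [make_hit(query="A", s=(1, 10)), make_hit(query="B", s=(6, 20))]
        profile = site_coverage(hits, 20)
        assert profile.c.tolist() == [1] * 5 + [2] * 5 + [1] * 10
        assert profile.c.tolist() == oracle_site_coverage(hits, 20)

    def test_minus_strand_hits_cover_the_same_interval(self):
        plus = site_coverage([make_hit(s=(6, 20))], 25)
        minus = site_coverage([make_hit(s=(20, 6))], 25)
        assert plus.c.tolist() == minus.c.tolist()

    def test_hit_beyond_target_length_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            site_coverage([make_hit(s=(5, 30))], 20)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            hits, L = random_hit_instance(rng)
            profile = site_coverage(hits, L)
            assert profile.c.tolist() == oracle_site_coverage(hits, L)

    def test_adding_a_new_contig_never_decreases_coverage(self):
        # c_i and l_ge2 never decrease, M never increases; P itself is
        # guaranteed non-decreasing only when the new hit stays within
        # already-covered sites (new coverage also grows P's denominator)
        rng = np.random.default_rng(7)
        checked_p = 0
        for _ in range(40):
            hits, L = random_hit_instance(rng, max_hits=10)
            before = site_coverage(hits, L).c
            lo = int(rng.integers(1, L + 1))
            hi = int(rng.integers(lo, L + 1))
            extra = make_hit(query="brand_new_contig", s=(lo, hi))
            after = site_coverage(hits + [extra], L).c
            assert (after >= before).all()
            prof_before = CoverageProfile("t1", before)
            prof_after = CoverageProfile("t1", after)
            assert prof_after.l_ge2 >= prof_before.l_ge2
            s_before = paralogy_stats(prof_before)
            s_after = paralogy_stats(prof_after)
            assert s_after.M <= s_before.M
            if s_before.P is not None and (before[lo - 1 : hi] >= 1).all():
                assert s_after.P >= s_before.P
                checked_p += 1
        assert checked_p > 0


class TestParalogyStats:
    def test_uniform_single_coverage(self):
        s = paralogy_stats(CoverageProfile("t", np.ones(10, dtype=int)))
        assert (s.P, s.M, s.C) == (0.0, 0.0, 1.0)

    def test_mixed_profile_counts(self):
        c = [0, 0, 1, 1, 1, 2, 2, 3, 0, 1]
        s = paralogy_stats(CoverageProfile("t", np.array(c)))
        assert s.P == pytest.approx(3 / 7)
        assert s.M == pytest.approx(0.3)
        assert s.C == pytest.approx(11 / 7)

    def test_fully_missing_target_has_undefined_p_and_c(self):
        s = paralogy_stats(CoverageProfile("t", np.zeros(8, dtype=int)))
        assert (s.P, s.C) == (None, None)
        assert s.M == 1.0

    def test_conservation_and_oracle_on_random_profiles(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            c = rng.integers(0, 4, size=int(rng.integers(1, 200)))
            profile = CoverageProfile("t", c)
            assert profile.l_0 + profile.l_1 + profile.l_ge2 == profile.L
            s = paralogy_stats(profile)
            P, M, C = oracle_paralogy(c.tolist())
            assert s.M == pytest.approx(M)
            for got, want in ((s.P, P), (s.C, C)):
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(want)

    def test_same_hits_give_same_p_whatever_the_reference_label(self):
        hits, L = random_hit_instance(np.random.default_rng(11), max_hits=20)
        a = paralogy_stats(site_coverage(hits, L), "s")
        b = paralogy_stats(site_coverage(list(hits), L), "s")
        assert a.P == b.P


def stats_cell(target, sample, p, m=0.0):
    from hybvet.assembly import ParalogyStats

    return ParalogyStats(target, sample, p, m, 1.0 if p is not None else None)


class TestParalogyMatrix:
    def test_means_over_fully_defined_matrix(self):
        stats = [
            stats_cell("t1", "s1", 0.2),
            stats_cell("t2", "s1", 0.4),
            stats_cell("t1", "s2", 0.4),
            stats_cell("t2", "s2", 0.0),
        ]
        matrix = build_paralogy_matrix(stats)
        assert matrix.mean_p()["t1"] == pytest.approx(0.3)
        assert matrix.mean_p()["t2"] == pytest.approx(0.2)

    def test_undefined_cell_is_excluded_from_the_mean(self):
        stats = [
            stats_cell("t1", "s1", None, m=1.0),
            stats_cell("t1", "s2", 0.6),
        ]
        matrix = build_paralogy_matrix(stats)
        assert matrix.mean_p()["t1"] == pytest.approx(0.6)

    def test_duplicate_sample_target_pair_is_an_error(self):
        stats = [stats_cell("t1", "s1", 0.2), stats_cell("t1", "s1", 0.3)]
        with pytest.raises(ValueError, match="duplicate"):
            build_paralogy_matrix(stats)

    def test_three_by_three_means_match_hand_computation(self):
        rng = np.random.default_rng(5)
        values = rng.random((3, 3))
        stats = [
            stats_cell(f"t{j}", f"s{i}", float(values[i, j]))
            for i in range(3)
            for j in range(3)
        ]
        matrix = build_paralogy_matrix(stats)
        for j in range(3):
            assert matrix.mean_p()[f"t{j}"] == pytest.approx(values[:, j].mean())


class TestFlags:
    def matrix_with_mean_p(self, mean_by_target):
        stats = [
            stats_cell(t, s, p) for t, p in mean_by_target.items() for s in ("s1", "s2")
        ]
        return build_paralogy_matrix(stats)

    def test_mean_p_at_threshold_is_not_flagged(self):
        matrix = self.matrix_with_mean_p({"t1": 0.40, "t2": 0.41})
        assert flag_paralogs(matrix, matrix) == {"t2"}

    def test_flag_if_either_matrix_exceeds(self):
        low = self.matrix_with_mean_p({"t1": 0.1, "t2": 0.1})
        high = self.matrix_with_mean_p({"t1": 0.41, "t2": 0.1})
        assert flag_paralogs(low, high) == {"t1"}
        assert flag_paralogs(low) == set()

    def test_threshold_outside_unit_interval_is_an_error(self):
        matrix = self.matrix_with_mean_p({"t1": 0.1})
        with pytest.raises(ValueError):
            flag_paralogs(matrix, threshold=1.5)

    def test_flag_missing_boundary(self):
        stats = [
            stats_cell("t1", "s1", 0.0, m=0.40),
            stats_cell("t2", "s1", 0.0, m=0.400001),
            stats_cell("t3", "s1", 0.0, m=0.1),
        ]
        matrix = build_paralogy_matrix(stats)
        assert flag_missing(matrix) == {"t2"}


class TestRefineSuperset:
    def test_disjoint_flag_sets_subtract(self):
        targets = [f"t{i}" for i in range(303)]
        result = refine_superset(targets, targets[:13], targets[13:18])
        assert len(result.retained) == 285
        assert result.n_removed == 18

    def test_overlapping_flags_not_double_counted(self):
        targets = ["a", "b", "c", "d"]
        result = refine_superset(targets, {"a", "b"}, {"b", "c"})
        assert result.retained == ["d"]
        assert result.n_removed == 3

    def test_no_flags_is_identity(self):
        targets = ["a", "b"]
        assert refine_superset(targets, set(), set()).retained == targets


class TestOutlierSamples:
    def test_shifted_sample_is_flagged(self):
        # one sample sits ~0.47 above every per-target mean (a ploidy
        # shift signature); everyone else is at baseline
        stats = []
        for s in range(9):
            for t in range(6):
                stats.append(stats_cell(f"t{t}", f"s{s}", 0.05))
        for t in range(6):
            stats.append(stats_cell(f"t{t}", "odd", 0.52))
        matrix = build_paralogy_matrix(stats)
        assert flag_outlier_samples(matrix) == {"odd"}

    def test_identical_samples_are_never_flagged(self):
        stats = [
            stats_cell(f"t{t}", f"s{s}", 0.3) for s in range(4) for t in range(5)
        ]
        assert flag_outlier_samples(build_paralogy_matrix(stats)) == set()

    def test_matches_brute_force_oracle_on_random_matrix(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            P = {
                f"s{i}": {
                    f"t{j}": (None if rng.random() < 0.15 else float(rng.random()))
                    for j in range(6)
                }
                for i in range(4)
            }
            stats = [
                stats_cell(t, s, p, m=1.0 if p is None else 0.0)
                for s, row in P.items()
                for t, p in row.items()
            ]
            matrix = build_paralogy_matrix(stats)
            assert flag_outlier_samples(matrix, 0.2) == oracle_outlier_samples(P, 0.2)


class TestLengthRatioFlag:
    @pytest.mark.parametrize(
        "lengths, flagged",
        [
            ([1000, 800], True),
            ([1000, 750], False),  # 750 > 750 is false
            ([1000], False),
            ([], False),
            ([800, 1000, 100], True),  # order-free
        ],
    )
    def test_second_longest_rule(self, lengths, flagged):
        assert length_ratio_flag(lengths) is flagged

    def test_negative_length_is_an_error(self):
        with pytest.raises(ValueError):
            length_ratio_flag([100, -1])
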