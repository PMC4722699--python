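"""Core consensus algorithms against closed forms and brute-force oracles."""

import numpy as np
import pytest
from helpers import (
    brute_force_sdc,
    brute_force_standout,
    brute_force_usc,
    brute_force_vsdc,
    make_correlated_tables,
    make_table,
)
from hypothesis import given, settings
from hypothesis import strategies as st

from sdcons.consensus import (
    rank_molecules,
    sdc,
    standardize,
    standout_set,
    top_n,
    usc,
    venn_partition,
    venn_to_frame,
    vsdc,
)
from sdcons.consensus import StandoutSet
from sdcons.errors import (
    ConfigurationError,
    DegenerateDistributionError,
    InfeasibleConsensusError,
)


class TestStandardize:
    def test_closed_form_sample_sd(self):
        t = make_table([("a", -1.0), ("b", 0.0), ("c", 1.0)], direction="higher_better")
        std = standardize(t)
        # sample SD of (-1, 0, 1) is exactly 1
        assert np.allclose(std.z, [-1.0, 0.0, 1.0])
        assert std.mean == 0.0 and std.sd == 1.0

    def test_lower_better_flips_sign(self):
        hi = standardize(make_table([("a", -1.0), ("b", 0.0), ("c", 1.0)],
                                    direction="higher_better"))
        lo = standardize(make_table([("a", -1.0), ("b", 0.0), ("c", 1.0)],
                                    direction="lower_better"))
        assert np.allclose(lo.z, -hi.z)

    def test_z_moments(self, rng):
        t = make_table([(f"m{i}", s) for i, s in enumerate(rng.normal(5, 3, 500))])
        std = standardize(t)
        assert abs(std.z.mean()) < 1e-9
        assert abs(std.z.std(ddof=1) - 1) < 1e-9

    def test_normal_tail_fraction(self, rng):
        t = make_table(
            [(f"m{i}", s) for i, s in enumerate(rng.standard_normal(10_000))],
            direction="higher_better",
        )
        frac = np.mean(standardize(t).z >= 2)
        assert frac == pytest.approx(0.0228, abs=0.006)

    def test_constant_scores_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            standardize(make_table([("a", 3.0), ("b", 3.0), ("c", 3.0)]))


class TestStandoutSet:
    def test_extremes(self, rng):
        t = make_table([(f"m{i}", s) for i, s in enumerate(rng.normal(size=50))])
        std = standardize(t)
        assert standout_set(std, 1e9).members == frozenset()
        assert standout_set(std, float(std.z.min()) - 1).members == t.id_set()

    def test_matches_brute_force(self, rng):
        t = make_table([(f"m{i}", s) for i, s in enumerate(rng.normal(size=500))],
                       direction="higher_better")
        got = standout_set(standardize(t), 2.0).members
        assert got == brute_force_standout(t, 2.0)

    def test_cutoff_in_score_units(self):
        t = make_table([(f"m{i}", float(i)) for i in range(10)])
        std = standardize(t)
        s = standout_set(std, 2.0)
        assert s.cutoff_c == pytest.approx(2.0 * std.sd)

    @given(x1=st.floats(-3, 3), x2=st.floats(-3, 3))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_x(self, x1, x2):
        rng = np.random.default_rng(7)
        t = make_table([(f"m{i}", s) for i, s in enumerate(rng.normal(size=80))])
        std = standardize(t)
        lo, hi = min(x1, x2), max(x1, x2)
        assert standout_set(std, hi).members <= standout_set(std, lo).members


class TestSdc:
    def test_self_intersection(self, rng):
        pairs = [(f"m{i}", s) for i, s in enumerate(rng.normal(size=200))]
        t1 = make_table(pairs, program="A")
        t2 = make_table(pairs, program="B")
        res = sdc([t1, t2], x=2.0)
        assert set(res.members) == brute_force_standout(t1, 2.0)

    def test_empty_standout_absorbs(self, rng):
        # a flat 10-point grid never reaches z >= 2 (max z ~ 1.49)
        flat = make_table([(f"m{i}", float(i)) for i in range(10)], program="flat")
        other = make_table(
            [(f"m{i}", s) for i, s in enumerate(rng.normal(size=10))], program="B"
        )
        assert sdc([flat, other]).nCM == 0

    def test_matches_brute_force_intersection(self, rng):
        for trial in range(10):
            tables, _ = make_correlated_tables(rng, n=300, k=4, w=0.5)
            res = sdc(tables, x=1.5)
            assert set(res.members) == brute_force_sdc(tables, 1.5)

    def test_members_ordered_by_summed_z(self, rng):
        tables, _ = make_correlated_tables(rng, n=300, k=3, w=0.6)
        res = sdc(tables, x=1.0)
        stds = [standardize(t) for t in tables]
        sums = [sum(s.z_of(m) for s in stds) for m in res.members]
        assert sums == sorted(sums, reverse=True)

    def test_needs_two_tables(self, rng):
        t = make_table([(f"m{i}", s) for i, s in enumerate(rng.normal(size=10))])
        with pytest.raises(ConfigurationError):
            sdc([t])


class TestVsdc:
    def test_single_table_degenerates_to_top_n(self, rng):
        t = make_table([(f"m{i}", s) for i, s in enumerate(rng.normal(size=100))])
        res = vsdc([t], n_test=7)
        assert res.members == top_n(t, 7).members

    def test_infeasible_reports_ceiling(self, rng):
        pairs = [(f"m{i}", s) for i, s in enumerate(rng.normal(size=20))]
        t1 = make_table(pairs[:15], program="A")
        t2 = make_table(pairs[5:], program="B")
        with pytest.warns(UserWarning, match="not shared"):
            with pytest.raises(InfeasibleConsensusError) as exc:
                vsdc([t1, t2], n_test=11)
        assert exc.value.max_achievable == 10

    def test_matches_grid_scan_oracle(self, rng):
        tables, _ = make_correlated_tables(rng, n=30, k=3, w=0.5)
        res = vsdc(tables, n_test=5, trim=False)
        x_oracle, members_oracle = brute_force_vsdc(tables, 5)
        assert res.x_used == x_oracle
        assert set(res.members) == members_oracle

    def test_trim_keeps_best_summed_z(self, rng):
        tables, _ = make_correlated_tables(rng, n=120, k=2, w=0.8)
        raw = vsdc(tables, n_test=6, trim=False)
        trimmed = vsdc(tables, n_test=6, trim=True)
        assert len(trimmed.members) == 6
        assert set(trimmed.members) <= set(raw.members)
        assert trimmed.members == raw.members[:6]
        assert trimmed.trimmed or raw.nCM == 6

    def test_x_used_non_increasing_in_n_test(self, rng):
        tables, _ = make_correlated_tables(rng, n=400, k=3, w=0.4)
        xs = [vsdc(tables, n).x_used for n in (1, 3, 5, 10, 20, 40)]
        assert all(a >= b for a, b in zip(xs, xs[1:]))

    def test_members_standout_in_every_program(self, rng):
        tables, _ = make_correlated_tables(rng, n=250, k=4, w=0.5)
        res = vsdc(tables, n_test=8, trim=False)
        stds = [standardize(t) for t in tables]
        for m in res.members:
            assert all(s.z_of(m) >= res.x_used for s in stds)

    def test_identical_tables_reduce_to_top_n(self, rng):
        pairs = [(f"m{i}", s) for i, s in enumerate(rng.normal(size=150))]
        tables = [make_table(pairs, program=p) for p in "ABC"]
        res = vsdc(tables, n_test=9)
        assert res.members == top_n(tables[0], 9).members

    def test_bad_n_test(self, rng):
        tables, _ = make_correlated_tables(rng, n=30, k=2)
        with pytest.raises(ConfigurationError):
            vsdc(tables, n_test=0)


class TestUsc:
    def test_disjoint_top_lists_take_equal_shares(self):
        tables = [
            make_table([(f"{p}{i}", float(i)) for i in range(10)], program=p)
            for p in "ABCD"
        ]
        res = usc(tables, 8)
        assert res.nCM == 8
        for p in "ABCD":
            assert sum(m.startswith(p) for m in res.members) == 2

    def test_identical_rankings_top_up_to_top_n(self, rng):
        pairs = [(f"m{i}", s) for i, s in enumerate(rng.normal(size=50))]
        t1, t2 = make_table(pairs, program="A"), make_table(pairs, program="B")
        res = usc([t1, t2], 10)
        assert res.members == top_n(t1, 10).members

    def test_matches_reimplementation_oracle(self, rng):
        for trial in range(10):
            tables, _ = make_correlated_tables(rng, n=60, k=4, w=0.6)
            n_test = int(rng.integers(4, 20))
            assert usc(tables, n_test).members == brute_force_usc(tables, n_test)

    def test_size_is_min_of_n_test_and_pool(self, rng):
        tables, _ = make_correlated_tables(rng, n=12, k=3, w=0.3)
        assert usc(tables, 9).nCM == 9
        assert usc(tables, 12).nCM == 12

    def test_n_test_below_k_rejected(self, rng):
        tables, _ = make_correlated_tables(rng, n=20, k=4)
        with pytest.raises(ConfigurationError):
            usc(tables, 3)


class TestVennPartition:
    @staticmethod
    def _sets(members_by_program):
        return [
            StandoutSet(p, 2.0, float("nan"), frozenset(m))
            for p, m in members_by_program.items()
        ]

    def test_disjoint_sets(self):
        v = venn_partition(self._sets({"A": {"a1", "a2"}, "B": {"b1"}}))
        assert v.region_counts[frozenset({"A"})] == 2
        assert v.region_counts[frozenset({"B"})] == 1
        assert v.region_counts[frozenset({"A", "B"})] == 0

    def test_identical_sets(self):
        v = venn_partition(self._sets({"A": {"x", "y"}, "B": {"x", "y"}}))
        assert v.region_counts[frozenset({"A", "B"})] == 2
        assert v.common_to(["A", "B"]) == 2

    def test_conservation_per_program(self, rng):
        tables, _ = make_correlated_tables(rng, n=400, k=4, w=0.5)
        sets = [standout_set(standardize(t), 1.0) for t in tables]
        v = venn_partition(sets)
        for s in sets:
            assert v.set_size(s.program_name) == len(s.members)
        assert sum(v.region_counts.values()) == len(
            frozenset().union(*[s.members for s in sets])
        )

    def test_frame_export(self):
        v = venn_partition(self._sets({"A": {"x"}, "B": {"x", "y"}}))
        df = venn_to_frame(v)
        assert set(df.columns) == {"region", "n_programs", "count"}
        assert df[df.region == "A+B"]["count"].item() == 1


class TestRanking:
    def test_rank_examples(self):
        t = make_table([("a", -9.0), ("b", -7.0)])
        assert rank_molecules(t) == [("a", 1), ("b", 2)]
        tie = make_table([("b", 5.0), ("a", 5.0)], direction="higher_better")
        assert rank_molecules(tie) == [("a", 1), ("b", 2)]

    def test_matches_argsort_oracle(self, rng):
        scores = rng.normal(size=1000)
        t = make_table([(f"m{i:04d}", s) for i, s in enumerate(scores)],
                       direction="higher_better")
        got = dict(rank_molecules(t))
        order = np.argsort(-scores, kind="stable")  # ids are already sorted
        for rank, idx in enumerate(order, start=1):
            assert got[f"m{idx:04d}"] == rank

    def test_top_n_boundaries(self, rng):
        t = make_table([(f"m{i}", s) for i, s in enumerate(rng.normal(size=9))])
        assert top_n(t, 9).nCM == 9
        assert top_n(t, 1).members == [rank_molecules(t)[0][0]]
        with pytest.raises(ConfigurationError):
            top_n(t, 10)
        with pytest.raises(ConfigurationError):
            top_n(t, 0)

    def test_top_n_on_permuted_table(self, rng):
        scores = rng.permutation(30).astype(float)
        t = make_table([(f"m{i:02d}", s) for i, s in enumerate(scores)])
        expected = [f"m{i:02d}" for i in np.argsort(scores, kind="stable")[:9]]
        assert top_n(t, 9).members == expected


class TestConsensusMonotonicity:
    def test_sdc_size_non_increasing_in_x(self, rng):
        tables, _ = make_correlated_tables(rng, n=300, k=3, w=0.6)
        sizes = [sdc(tables, x=x).nCM for x in (0.5, 1.0, 1.5, 2.0, 2.5)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
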