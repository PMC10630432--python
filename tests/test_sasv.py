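import datetime as dt

import numpy as np
import pandas as pd
import pytest

import sasvtrace as st
from conftest import make_climatology
from sasvtrace.sasv import DIRECT_MONTH


def water_sample(sid, depth, date, rep=None):
    return st.SampleRecord(sid, "water", depth, date, replicate=rep)


class TestMonthlyClimatology:
    def test_two_years_averaged_per_month(self):
        # March 2015 = 0.4, March 2016 = 0.6 for ASV a at 5 m -> mean 0.5
        data = pd.DataFrame({
            "w15": [0.4, 0.6], "w16": [0.6, 0.4]}, index=["a", "b"])
        m = st.AbundanceMatrix(data, mode="relative")
        samples = [water_sample("w15", 5, dt.date(2015, 3, 10)),
                   water_sample("w16", 5, dt.date(2016, 3, 12))]
        clim = st.monthly_climatology(m, samples)
        vec = clim.vector(5, 3)
        assert vec["a"] == pytest.approx(0.5)
        assert clim.n_years[(5.0, 3)] == 2

    def test_single_year_month_unchanged(self):
        data = pd.DataFrame({"w": [0.3, 0.7]}, index=["a", "b"])
        m = st.AbundanceMatrix(data, mode="relative")
        clim = st.monthly_climatology(
            m, [water_sample("w", 25, dt.date(2015, 7, 2))])
        assert np.allclose(clim.vector(25, 7), [0.3, 0.7])

    def test_replicates_averaged_before_years(self):
        # 2015: replicates 0.2/0.4 -> 0.3; 2016: 0.5 -> March mean 0.4
        data = pd.DataFrame({"r1": [0.2, 0.8], "r2": [0.4, 0.6],
                             "y2": [0.5, 0.5]}, index=["a", "b"])
        m = st.AbundanceMatrix(data, mode="relative")
        samples = [water_sample("r1", 5, dt.date(2015, 3, 10), "a"),
                   water_sample("r2", 5, dt.date(2015, 3, 10), "b"),
                   water_sample("y2", 5, dt.date(2016, 3, 11))]
        clim = st.monthly_climatology(m, samples)
        assert clim.vector(5, 3)["a"] == pytest.approx(0.4)

    def test_mean_of_normalized_vectors_stays_normalized(self):
        rng = np.random.default_rng(0)
        cols = {f"w{i}": rng.dirichlet(np.ones(6)) for i in range(4)}
        m = st.AbundanceMatrix(
            pd.DataFrame(cols, index=[f"a{j}" for j in range(6)]),
            mode="relative")
        samples = [water_sample(f"w{i}", 75, dt.date(2013 + i, 6, 5))
                   for i in range(4)]
        clim = st.monthly_climatology(m, samples)
        clim.validate(tol=1e-12)


class TestInterpolateMissingMonths:
    def test_adjacent_month_mean(self):
        clim = make_climatology({
            (5.0, 8): {"a": 0.3, "b": 0.7},
            (5.0, 10): {"a": 0.5, "b": 0.5},
        })
        out = st.interpolate_missing_months(clim, months=[8, 9, 10])
        assert out.vector(5, 9)["a"] == pytest.approx(0.4)
        assert (5.0, 9) in out.interpolated

    def test_no_missing_months_is_identity(self):
        clim = make_climatology({(5.0, m): {"a": 1.0} for m in range(1, 13)})
        out = st.interpolate_missing_months(clim)
        assert set(out.data) == set(clim.data)
        assert not out.interpolated

    def test_december_january_are_adjacent(self):
        clim = make_climatology({
            (5.0, 12): {"a": 0.2, "b": 0.8},
            (5.0, 2): {"a": 0.6, "b": 0.4},
        })
        out = st.interpolate_missing_months(clim, months=[1, 2, 12])
        assert out.vector(5, 1)["a"] == pytest.approx(0.4)

    def test_strict_mode_names_unfillable_entries(self):
        clim = make_climatology({(75.0, 7): {"a": 1.0}})
        with pytest.raises(ValueError, match=r"75.*8|8.*75"):
            st.interpolate_missing_months(clim, months=[7, 8, 9])

    def test_allow_nearest_fallback(self):
        clim = make_climatology({(75.0, 7): {"a": 1.0}})
        out = st.interpolate_missing_months(clim, months=[7, 9],
                                            allow_nearest=True)
        assert out.vector(75, 9)["a"] == pytest.approx(1.0)


def sasv_setup(trap_abund, water_abund, seqs):
    clim = make_climatology({(75.0, 3): water_abund})
    trap_col = pd.Series(trap_abund, name="trap1")
    asvs = {k: st.AsvRecord(k, v) for k, v in seqs.items()}
    return trap_col, clim, asvs


class TestIdentifySasvs:
    SEQS = {"A": "AAAA", "B": "CCCC", "C": "GGGG", "D": "TTTT"}

    def test_shared_set_is_nonzero_intersection(self):
        trap_col, clim, asvs = sasv_setup(
            {"A": 0.2, "B": 0.3, "C": 0.5, "D": 0.0},
            {"A": 0.0, "B": 0.4, "C": 0.3, "D": 0.3}, self.SEQS)
        ss = st.identify_sasvs(trap_col, clim, 75, 3, asvs)
        assert ss.asv_ids == frozenset({"B", "C"})

    def test_disjoint_presence_gives_empty_set(self):
        trap_col, clim, asvs = sasv_setup(
            {"A": 1.0, "B": 0.0, "C": 0.0, "D": 0.0},
            {"A": 0.0, "B": 0.5, "C": 0.5, "D": 0.0}, self.SEQS)
        ss = st.identify_sasvs(trap_col, clim, 75, 3, asvs)
        assert not ss.asv_ids
        assert st.water_fraction(ss, clim) == 0.0

    def test_sequence_identity_not_id_identity(self):
        # trap id t1 shares its exact sequence with water id w1
        seqs = {"t1": "ACGT", "w1": "ACGT", "w2": "AAAA"}
        clim = make_climatology({(75.0, 3): {"w1": 0.6, "w2": 0.4}})
        trap_col = pd.Series({"t1": 1.0}, name="trap1")
        asvs = {k: st.AsvRecord(k, v) for k, v in seqs.items()}
        ss = st.identify_sasvs(trap_col, clim, 75, 3, asvs)
        assert ss.water_asv_ids == frozenset({"w1"})
        assert ss.trap_asv_ids == frozenset({"t1"})

    def test_masked_position_needs_wildcard_flag(self):
        # sequences differ only at one position where one has an N
        seqs = {"t1": "ACNT", "w1": "ACGT"}
        clim = make_climatology({(75.0, 3): {"w1": 1.0}})
        trap_col = pd.Series({"t1": 1.0}, name="trap1")
        asvs = {k: st.AsvRecord(k, v) for k, v in seqs.items()}
        strict = st.identify_sasvs(trap_col, clim, 75, 3, asvs)
        assert not strict.asv_ids
        loose = st.identify_sasvs(trap_col, clim, 75, 3, asvs,
                                  n_wildcard=True)
        assert loose.water_asv_ids == frozenset({"w1"})

    def test_missing_climatology_entry_errors(self):
        trap_col, clim, asvs = sasv_setup(
            {"A": 1.0}, {"A": 1.0}, {"A": "AAAA"})
        with pytest.raises(KeyError, match="month 12"):
            st.identify_sasvs(trap_col, clim, 75, 12, asvs)


class TestFractions:
    def water_set(self, ids):
        return st.SasvSet("t", 75.0, 3, frozenset(ids), frozenset(ids))

    def test_water_fraction_sums_climatology(self):
        clim = make_climatology({(75.0, 3): {"B": 0.2, "C": 0.1, "D": 0.7}})
        assert st.water_fraction(self.water_set({"B", "C"}), clim) == \
            pytest.approx(0.3)

    def test_water_fraction_complete_when_all_shared(self):
        clim = make_climatology({(75.0, 3): {"B": 0.2, "C": 0.1, "D": 0.7}})
        assert st.water_fraction(self.water_set({"B", "C", "D"}), clim) == \
            pytest.approx(1.0, abs=1e-9)

    def test_trap_fraction_sums_trap_column(self):
        col = pd.Series({"B": 0.05, "C": 0.15, "E": 0.8})
        assert st.trap_fraction(self.water_set({"B", "C"}), col) == \
            pytest.approx(0.20)

    def test_multi_depth_asv_counts_fully_at_each_depth(self):
        col = pd.Series({"B": 0.25, "E": 0.75})
        s100 = st.SasvSet("t", 100.0, 3, frozenset({"B"}), frozenset({"B"}))
        s200 = st.SasvSet("t", 200.0, 3, frozenset({"B"}), frozenset({"B"}))
        assert st.trap_fraction(s100, col) == st.trap_fraction(s200, col) == \
            pytest.approx(0.25)

    def test_fractions_monotone_under_adding_asvs(self):
        clim = make_climatology({(75.0, 3): {"A": 0.5, "B": 0.3, "C": 0.2}})
        col = pd.Series({"A": 0.6, "B": 0.1, "C": 0.3})
        small = self.water_set({"A"})
        big = self.water_set({"A", "B"})
        assert st.water_fraction(big, clim) >= st.water_fraction(small, clim)
        assert st.trap_fraction(big, col) >= st.trap_fraction(small, col)


class TestProfileOverTime:
    def test_singleton_interval(self):
        df = pd.DataFrame({"interval_id": ["i1"], "depth_m": [75.0],
                           "water_fraction": [0.42]})
        prof = st.profile_over_time(df).to_frame()
        row = prof.iloc[0]
        assert (row["mean"], row["sd"], row["n"]) == (0.42, 0.0, 1)

    def test_sample_sd_of_two_values(self):
        # {0.2, 0.4}: mean 0.3, sample sd sqrt(0.02) = 0.14142...
        df = pd.DataFrame({"interval_id": ["i1", "i2"],
                           "depth_m": [75.0, 75.0],
                           "water_fraction": [0.2, 0.4]})
        row = st.profile_over_time(df).to_frame().iloc[0]
        assert row["mean"] == pytest.approx(0.3)
        assert row["sd"] == pytest.approx(np.sqrt(0.02), abs=1e-12)

    def test_interval_order_irrelevant(self):
        df = pd.DataFrame({"interval_id": ["i1", "i2", "i3"],
                           "depth_m": [75.0] * 3,
                           "water_fraction": [0.1, 0.5, 0.3]})
        a = st.profile_over_time(df).to_frame()
        b = st.profile_over_time(df.iloc[::-1]).to_frame()
        pd.testing.assert_frame_equal(a, b)


class TestRichness:
    def make(self, depth, ids):
        return st.SasvSet("t", depth, 3, frozenset(ids), frozenset(ids))

    def test_union_of_sets(self):
        sets = [self.make(75, {"A", "B"}), self.make(75, {"B", "C"})]
        assert st.sasv_richness_by_depth(sets, 75) == 3

    def test_empty_sets(self):
        assert st.sasv_richness_by_depth([self.make(75, set())], 75) == 0

    def test_duplicate_interval_idempotent(self):
        s = self.make(75, {"A", "B"})
        assert st.sasv_richness_by_depth([s, s], 75) == 2

    def test_other_depths_not_counted(self):
        sets = [self.make(75, {"A"}), self.make(150, {"B", "C"})]
        assert st.sasv_richness_by_depth(sets, 75) == 1


class TestNoiselessRecovery:
    def test_water_fraction_equals_planted_curve(self, noiseless_products,
                                                 noiseless_sim):
        frac = noiseless_products["fractions"]
        cfg = noiseless_sim.config
        for depth, g in frac.groupby("depth_m"):
            expect = st.expected_shared_fraction(cfg, depth)
            assert np.allclose(g["water_fraction"], expect, atol=1e-12)

    def test_climatology_normalized_after_interpolation(self,
                                                        noiseless_products):
        noiseless_products["climatology"].validate(tol=1e-9)
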