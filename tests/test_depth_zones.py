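import numpy as np
import pandas as pd
import pytest
from scipy.signal import find_peaks as scipy_find_peaks

import sasvtrace as st
from sasvtrace.depth_zones import (DepthZoneMap, assignment_counts,
                                   find_depth_maxima, zone_composition)
from sasvtrace.synthetic import DEFAULT_DEPTH_GRID, planted_zone_profiles

GRID = [float(z) for z in DEFAULT_DEPTH_GRID]


def profile_frame(rows: dict[str, list[float]], depths=None):
    depths = depths or GRID[: len(next(iter(rows.values())))]
    return pd.DataFrame(rows, index=depths).T


class TestSelectAbundant:
    def test_threshold_boundary_inclusive(self):
        prof = profile_frame({
            "keep": [0.001, 0.0, 0.0],
            "drop": [0.0005, 0.0004, 0.0],
        })
        kept = st.select_abundant(prof)
        assert list(kept.index) == ["keep"]

    def test_zero_threshold_keeps_all(self):
        prof = profile_frame({"a": [1e-9, 0, 0], "b": [0, 0, 0]})
        assert len(st.select_abundant(prof, threshold=0.0)) == 2


class TestFindDepthMaxima:
    def test_interior_maximum(self):
        assert find_depth_maxima([75, 100, 125], [1, 3, 2]) == [100.0]

    def test_monotone_profile_edge_convention(self):
        depths, vals = [75, 100, 125, 150], [5, 4, 3, 2]
        assert find_depth_maxima(depths, vals, edge_peaks=True) == [75.0]
        assert find_depth_maxima(depths, vals, edge_peaks=False) == []

    def test_bimodal(self):
        depths = [75, 100, 125, 150, 175]
        assert find_depth_maxima(depths, [1, 5, 2, 6, 1]) == [100.0, 150.0]

    def test_plateau_reported_at_shallowest_depth(self):
        depths = [75, 100, 125, 150, 175]
        assert find_depth_maxima(depths, [1, 4, 4, 4, 2]) == [100.0]

    def test_plateau_not_flanked_by_smaller_is_not_a_peak(self):
        depths = [75, 100, 125]
        assert find_depth_maxima(depths, [2.0, 2.0, 2.0]) == []

    def test_deep_edge_peak(self):
        assert find_depth_maxima([75, 100, 125], [1, 2, 5]) == [125.0]

    def test_too_few_depths_errors(self):
        with pytest.raises(ValueError, match=">= 3"):
            find_depth_maxima([75, 100], [1, 2])

    @pytest.mark.parametrize("seed", range(5))
    def test_interior_peaks_agree_with_scipy(self, seed):
        # independent cross-check on strictly-distinct-valued profiles
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(1.0, 16.0))
        depths = np.arange(15, dtype=float) + 1
        ours = find_depth_maxima(depths, vals, edge_peaks=False)
        theirs = depths[scipy_find_peaks(vals)[0]].tolist()
        assert ours == theirs


class TestZoneMap:
    def test_default_covers_study_grid(self):
        zm = DepthZoneMap.default()
        for z in GRID:
            zm.zone_for_depth(z, strict=True)

    def test_gap_depth_goes_to_nearest_zone_midpoint(self):
        zm = DepthZoneMap.default()
        # 85 m: Surface midpoint 40, DCM midpoint 125 -> DCM is nearer
        assert zm.zone_for_depth(85.0) == "DCM"
        with pytest.raises(ValueError, match="85"):
            zm.zone_for_depth(85.0, strict=True)

    def test_overlapping_bounds_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DepthZoneMap.from_dict({"A": (5, 100), "B": (75, 200)})


class TestClassify:
    def classify_one(self, values, depths=GRID):
        prof = pd.DataFrame({"x": values}, index=depths).T
        return st.classify_and_assign(prof)[0]

    def test_single_peak_assigned_to_its_zone(self):
        vals = [0.0] * len(GRID)
        vals[GRID.index(770.0)] = 0.05
        a = self.classify_one(vals)
        assert a.retained and a.zone == "LowerMesopelagic"

    def test_bimodal_same_zone_retained(self):
        # peaks at 100 m and 150 m, both DCM
        vals = [0.0] * len(GRID)
        vals[GRID.index(100.0)] = 0.05
        vals[GRID.index(150.0)] = 0.04
        a = self.classify_one(vals)
        assert a.n_peaks == 2 and a.retained and a.zone == "DCM"

    def test_bimodal_single_dominant_peak_retained(self):
        # 25 m peak above the depth-averaged mean, 770 m peak below it
        vals = [0.0] * len(GRID)
        vals[GRID.index(25.0)] = 0.10
        vals[GRID.index(770.0)] = 0.003
        a = self.classify_one(vals)
        assert a.retained and a.zone == "Surface"
        assert vals[GRID.index(770.0)] < a.depth_averaged_mean

    def test_bimodal_both_dominant_excluded(self):
        vals = [0.0] * len(GRID)
        vals[GRID.index(25.0)] = 0.10
        vals[GRID.index(770.0)] = 0.09
        a = self.classify_one(vals)
        assert not a.retained and a.reason == "bimodal_ambiguous"

    def test_three_peaks_excluded_as_multimodal(self):
        vals = [0.0] * len(GRID)
        for z in (25.0, 300.0, 3000.0):
            vals[GRID.index(z)] = 0.05
        a = self.classify_one(vals)
        assert not a.retained and a.reason == "multimodal"

    def test_count_conservation_on_random_profiles(self):
        rng = np.random.default_rng(4)
        prof = pd.DataFrame(rng.random((50, len(GRID))) * 0.01,
                            index=[f"a{i}" for i in range(50)], columns=GRID)
        counts = assignment_counts(st.classify_and_assign(prof))
        assert (counts["n_single"] + counts["n_bimodal"]
                + counts["n_multimodal"] + counts["n_no_peak"]
                == counts["n_abundant"] == 50)
        assert counts["n_retained"] + counts["n_excluded"] == 50

    def test_classification_scale_invariant(self):
        prof, _ = planted_zone_profiles(n_unimodal=10, n_bimodal_rule1=3,
                                        n_bimodal_rule2=2,
                                        n_bimodal_ambiguous=2, seed=1)
        a = st.classify_and_assign(prof)
        b = st.classify_and_assign(prof * 37.5)
        assert [(x.retained, x.zone, x.peak_depths_m) for x in a] == \
               [(x.retained, x.zone, x.peak_depths_m) for x in b]


class TestPlantedRecovery:
    def test_planted_zones_recovered_exactly(self):
        prof, truth = planted_zone_profiles(seed=3)
        abundant = st.select_abundant(prof)
        assignments = st.classify_and_assign(abundant)
        counts = assignment_counts(assignments)
        assert counts["n_single"] == 100
        assert counts["n_bimodal"] == 20
        assert counts["n_retained"] == 115
        assert counts["n_excluded"] == 5
        for a in assignments:
            if truth[a.asv_id] is None:
                assert not a.retained
            else:
                assert a.retained and a.zone == truth[a.asv_id]

    def test_simulated_ecotype_zones_recovered(self, noiseless_products,
                                               noiseless_sim):
        truth = noiseless_sim.truth
        by_id = {a.asv_id: a for a in noiseless_products["assignments"]}
        for asv_id, zone in truth.ecotype_zone.items():
            assert by_id[asv_id].retained
            assert by_id[asv_id].zone == zone


class TestZoneComposition:
    def test_taxon_aggregation(self):
        vals = {"s1": [0.02] + [0.0] * (len(GRID) - 1),
                "s2": [0.03] + [0.0] * (len(GRID) - 1)}
        prof = profile_frame(vals, depths=GRID)
        assignments = st.classify_and_assign(prof)
        taxonomy = {"s1": "Prochlorococcus", "s2": "Prochlorococcus"}
        comp, cov = zone_composition(assignments, taxonomy, prof)
        surface = comp[comp["zone"] == "Surface"]
        assert len(surface) == 1
        # mean over the 4 Surface grid depths: (0.02 + 0.03) / 4
        assert surface["abundance"].iloc[0] == pytest.approx(0.05 / 4)

    def test_coverage_is_one_when_all_retained(self):
        prof, _ = planted_zone_profiles(n_unimodal=12, n_bimodal_rule1=0,
                                        n_bimodal_rule2=0,
                                        n_bimodal_ambiguous=0, seed=2)
        assignments = st.classify_and_assign(prof)
        assert all(a.retained for a in assignments)
        comp, cov = zone_composition(assignments, {}, prof)
        occupied = cov[cov["n_retained"] > 0]
        assert np.allclose(occupied["coverage"], 1.0)

    def test_missing_taxonomy_becomes_unknown(self):
        vals = {"s1": [0.02] + [0.0] * (len(GRID) - 1)}
        prof = profile_frame(vals, depths=GRID)
        assignments = st.classify_and_assign(prof)
        comp, _ = zone_composition(assignments, {}, prof)
        assert set(comp["taxon"]) == {"Unknown"}
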