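import math

import numpy as np
import pandas as pd
import pytest

from ibdshare import (
    SharingMatrix,
    SimilarityResult,
    distance_table,
    haversine_km,
    mean_between,
    mean_within,
    network_edges,
    similarity_S,
)
from ibdshare.sharing import aggregate_pair_sharing
from conftest import make_panel, make_segment
from _oracles import (
    brute_L_between,
    brute_L_within,
    brute_S,
    random_panel_and_segments,
)


class TestMeanWithin:
    def test_single_pair_mean_equals_sum(self):
        panel = make_panel({"X": ["a", "b"]})
        segs = [make_segment("a", "b", length_cm=4.0),
                make_segment("a", "b", start_cm=40.0, length_cm=6.0)]
        L, N = mean_within(segs, panel, "X")
        assert L == pytest.approx(10.0)
        assert N == pytest.approx(2.0)

    def test_three_individuals_printed_formula(self):
        # pair sums {3, 6, 0} -> L = 2/(3*2) * 9 = 3.0
        panel = make_panel({"X": ["a", "b", "c"]})
        segs = [make_segment("a", "b", length_cm=3.0),
                make_segment("a", "c", length_cm=6.0)]
        L, N = mean_within(segs, panel, "X")
        assert L == pytest.approx(3.0)
        assert N == pytest.approx(2 / 3)

    def test_no_segments_zero(self):
        panel = make_panel({"X": ["a", "b"]})
        assert mean_within([], panel, "X") == (0.0, 0.0)

    def test_singleton_group_undefined(self):
        panel = make_panel({"X": ["a"], "Y": ["b", "c"]})
        L, N = mean_within([], panel, "X")
        assert math.isnan(L) and math.isnan(N)

    def test_hbd_excluded_from_within(self):
        panel = make_panel({"X": ["a", "b"]})
        segs = [make_segment("a", "a", length_cm=5.0, hap_a=1, hap_b=2)]
        assert mean_within(segs, panel, "X")[0] == 0.0


class TestMeanBetween:
    def test_one_by_one(self, two_group_panel):
        panel = make_panel({"X": ["a"], "Y": ["b"]})
        segs = [make_segment("a", "b", length_cm=5.0)]
        L, N = mean_between(segs, panel, "X", "Y")
        assert L == pytest.approx(5.0) and N == pytest.approx(1.0)

    def test_two_by_three(self):
        panel = make_panel({"X": ["a", "b"], "Y": ["c", "d", "e"]})
        segs = [make_segment("a", "c", length_cm=7.0),
                make_segment("b", "e", length_cm=5.0)]
        L, _ = mean_between(segs, panel, "X", "Y")
        assert L == pytest.approx(12.0 / 6.0)

    def test_symmetry_and_no_sharing(self):
        panel = make_panel({"X": ["a", "b"], "Y": ["c", "d"]})
        segs = [make_segment("a", "c", length_cm=7.0)]
        assert mean_between(segs, panel, "X", "Y") == mean_between(segs, panel, "Y", "X")
        assert mean_between([], panel, "X", "Y") == (0.0, 0.0)


class TestSimilarity:
    def make_sharing(self, lx, ly, lxy):
        L = pd.DataFrame([[lx, lxy], [lxy, ly]], index=["X", "Y"], columns=["X", "Y"])
        N = L / 2.0
        return SharingMatrix(L=L, N=N)

    def test_structure_free_sharing_gives_one(self):
        assert similarity_S(self.make_sharing(7.0, 7.0, 7.0), "X", "Y") == pytest.approx(1.0)

    def test_no_between_sharing_gives_zero(self):
        assert similarity_S(self.make_sharing(4.0, 6.0, 0.0), "X", "Y") == 0.0

    def test_hand_value(self):
        assert similarity_S(self.make_sharing(4.0, 6.0, 2.5), "X", "Y") == pytest.approx(0.5)

    def test_zero_denominator_is_missing_not_zero(self):
        s = similarity_S(self.make_sharing(0.0, 0.0, 0.0), "X", "Y")
        assert math.isnan(s)

    def test_diagonal_is_one_by_convention(self):
        sim = SimilarityResult.from_sharing(self.make_sharing(4.0, 6.0, 2.5))
        assert sim.S.loc["X", "X"] == 1.0


class TestMatrixProperties:
    def segments(self):
        return [
            make_segment("a", "b", length_cm=4.0),
            make_segment("a", "c", chrom="2", length_cm=6.0),
            make_segment("b", "d", length_cm=2.0),
            make_segment("c", "d", chrom="3", length_cm=3.0),
        ]

    def panel(self):
        return make_panel({"X": ["a", "b"], "Y": ["c", "d"]})

    def test_scale_invariance_of_S(self):
        panel = self.panel()
        segs = self.segments()
        scaled = [make_segment(s.sample_a, s.sample_b, chrom=s.chrom,
                               start_cm=s.start_cm, length_cm=3.0 * s.length_cm,
                               hap_a=s.hap_a, hap_b=s.hap_b)
                  for s in segs]
        sh1 = SharingMatrix.from_segments(segs, panel)
        sh2 = SharingMatrix.from_segments(scaled, panel)
        assert sh2.L.loc["X", "Y"] == pytest.approx(3.0 * sh1.L.loc["X", "Y"])
        assert similarity_S(sh2, "X", "Y") == pytest.approx(similarity_S(sh1, "X", "Y"))

    def test_within_group_relabelling_invariance(self):
        panel = self.panel()
        swapped = [
            make_segment({"a": "b", "b": "a"}.get(s.sample_a, s.sample_a),
                         {"a": "b", "b": "a"}.get(s.sample_b, s.sample_b),
                         chrom=s.chrom, start_cm=s.start_cm, length_cm=s.length_cm)
            for s in self.segments()
        ]
        sh1 = SharingMatrix.from_segments(self.segments(), panel)
        sh2 = SharingMatrix.from_segments(swapped, panel)
        pd.testing.assert_frame_equal(sh1.L, sh2.L)
        pd.testing.assert_frame_equal(sh1.N, sh2.N)

    def test_chromosome_additivity(self):
        panel = self.panel()
        agg = aggregate_pair_sharing(self.segments(), panel, by_chrom=True)
        total = SharingMatrix.from_aggregate(agg, panel)
        direct = SharingMatrix.from_segments(self.segments(), panel)
        pd.testing.assert_frame_equal(total.L, direct.L)
        # summing the per-chromosome sums reproduces the global sums
        assert agg.groupby(["group_a", "group_b"])["sum_cm"].sum().sum() == pytest.approx(
            sum(s.length_cm for s in self.segments())
        )

    def test_brute_force_oracle_small_random_panels(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            panel, segs = random_panel_and_segments(rng)
            sharing = SharingMatrix.from_segments(segs, panel)
            sim = SimilarityResult.from_sharing(sharing)
            for gx in panel.group_names:
                lx, nx = brute_L_within(segs, panel, gx)
                if math.isnan(lx):
                    assert math.isnan(sharing.L.loc[gx, gx])
                else:
                    assert sharing.L.loc[gx, gx] == pytest.approx(lx, rel=1e-12, abs=1e-12)
                    assert sharing.N.loc[gx, gx] == pytest.approx(nx, rel=1e-12, abs=1e-12)
                for gy in panel.group_names:
                    if gy <= gx:
                        continue
                    lxy, nxy = brute_L_between(segs, panel, gx, gy)
                    assert sharing.L.loc[gx, gy] == pytest.approx(lxy, rel=1e-12, abs=1e-12)
                    s_expect = brute_S(segs, panel, gx, gy)
                    s_got = sim.S.loc[gx, gy]
                    if math.isnan(s_expect):
                        assert math.isnan(s_got)
                    else:
                        assert s_got == pytest.approx(s_expect, rel=1e-12, abs=1e-12)

    def test_unknown_individual_rejected(self):
        with pytest.raises(KeyError, match="zzz"):
            SharingMatrix.from_segments(
                [make_segment("zzz", "a")], make_panel({"X": ["a", "b"]})
            )


class TestNetwork:
    def sharing(self, n_xy):
        L = pd.DataFrame([[5.0, 2.0], [2.0, 5.0]], index=["X", "Y"], columns=["X", "Y"])
        N = pd.DataFrame([[1.0, n_xy], [n_xy, 1.0]], index=["X", "Y"], columns=["X", "Y"])
        return SharingMatrix(L=L, N=N, bin_label="1-5cM")

    def test_edge_kept_at_mean_count_above_half(self):
        edges = network_edges(self.sharing(0.6))
        assert len(edges) == 1
        assert edges.iloc[0]["mean_sum_cm"] == pytest.approx(2.0)

    def test_edge_dropped_below_half(self):
        assert len(network_edges(self.sharing(0.4))) == 0

    def test_boundary_kept(self):
        assert len(network_edges(self.sharing(0.5))) == 1

    def test_empty_matrix(self):
        empty = SharingMatrix(
            L=pd.DataFrame(dtype=float), N=pd.DataFrame(dtype=float)
        )
        assert len(network_edges(empty)) == 0


class TestGeography:
    def test_identical_coordinates_zero(self):
        assert haversine_km(-8.0, 151.0, -8.0, 151.0) == 0.0

    def test_antipodal_half_circumference(self):
        assert haversine_km(0.0, 0.0, 0.0, 180.0) == pytest.approx(
            math.pi * 6371.0, rel=1e-6
        )

    def test_distance_table_classes_and_missing_coords(self):
        panel = make_panel(
            {"K1": ["a", "b"], "K2": ["c", "d"], "N1": ["e", "f"], "O1": ["g", "h"]},
            K1=("Massim", "northern", "kula", -8.5, 151.0),
            K2=("Massim", "northern", "kula", -9.0, 152.0),
            N1=("Massim", "southern", "non_kula", -11.0, 153.0),
            O1=("Bismarck", None, None, None, None),  # no coordinates
        )
        segs = [make_segment("a", "b", length_cm=4.0),
                make_segment("c", "d", length_cm=4.0),
                make_segment("e", "f", length_cm=4.0),
                make_segment("a", "c", length_cm=2.0)]
        sim = SimilarityResult.from_sharing(SharingMatrix.from_segments(segs, panel))
        table = distance_table(sim, panel)
        # O1 lacks coordinates: only pairs among K1, K2, N1 remain
        assert set(zip(table.group_a, table.group_b)) == {
            ("K1", "K2"), ("K1", "N1"), ("K2", "N1")
        }
        classes = dict(zip(zip(table.group_a, table.group_b), table.pair_class))
        assert classes[("K1", "K2")] == "kula-kula"
        assert classes[("K1", "N1")] == "mixed"
        assert (table.distance_km > 0).all()
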