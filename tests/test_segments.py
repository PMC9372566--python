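import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ibdshare import (
    AncestryTractSet,
    GeneticMap,
    LengthBins,
    PhasedGenotypes,
    ancestry_partition,
    bin_segments,
    merge_segments,
    within_group_ibd_summary,
)
from ibdshare.io import AncestryTract
from conftest import make_panel, make_segment
from _oracles import grid_ancestry_lengths


class TestMerge:
    def test_gap_below_threshold_merges(self):
        segs = [make_segment("I1", "I2", start_cm=10.0, length_cm=10.0),
                make_segment("I1", "I2", start_cm=20.5, length_cm=9.5)]
        (merged,) = merge_segments(segs, gap_cm=0.6)
        assert merged.start_cm == pytest.approx(10.0)
        assert merged.end_cm == pytest.approx(30.0)
        assert merged.length_cm == pytest.approx(20.0)

    def test_gap_at_threshold_does_not_merge(self):
        segs = [make_segment("I1", "I2", start_cm=10.0, length_cm=10.0),
                make_segment("I1", "I2", start_cm=20.7, length_cm=9.3)]
        assert len(merge_segments(segs, gap_cm=0.6)) == 2

    @pytest.mark.parametrize("start2, n_expected", [(2.599, 1), (2.6, 2)])
    def test_strict_boundary(self, start2, n_expected):
        # gaps of 0.599 and 0.600 cM around the strict 0.6 cM threshold
        segs = [make_segment("I1", "I2", start_cm=0.0, length_cm=2.0),
                make_segment("I1", "I2", start_cm=start2, length_cm=5.0)]
        assert len(merge_segments(segs, gap_cm=0.6)) == n_expected

    def test_transitive_merge_spans_all_three(self):
        segs = [make_segment("I1", "I2", start_cm=10.0, length_cm=5.0),
                make_segment("I1", "I2", start_cm=15.2, length_cm=5.0),
                make_segment("I1", "I2", start_cm=20.5, length_cm=5.0)]
        (merged,) = merge_segments(segs, gap_cm=0.6)
        assert merged.start_cm == pytest.approx(10.0)
        assert merged.end_cm == pytest.approx(25.5)

    def test_lod_is_max_of_parts(self):
        segs = [make_segment("I1", "I2", start_cm=10.0, length_cm=5.0, lod=4.0),
                make_segment("I1", "I2", start_cm=15.1, length_cm=5.0, lod=9.0)]
        (merged,) = merge_segments(segs)
        assert merged.lod == 9.0

    def test_distinct_hap_pairs_and_chromosomes_kept_apart(self):
        segs = [make_segment("I1", "I2", start_cm=10.0, length_cm=5.0, hap_a=1),
                make_segment("I1", "I2", start_cm=15.1, length_cm=5.0, hap_a=2),
                make_segment("I1", "I2", start_cm=15.1, length_cm=5.0, chrom="2")]
        assert len(merge_segments(segs)) == 3

    def test_hbd_blocks_merge_like_ibd(self):
        segs = [make_segment("I1", "I1", start_cm=10.0, length_cm=5.0, hap_a=1, hap_b=2),
                make_segment("I1", "I1", start_cm=15.3, length_cm=5.0, hap_a=1, hap_b=2)]
        (merged,) = merge_segments(segs)
        assert merged.is_hbd and merged.length_cm == pytest.approx(10.3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(0.0, 90.0), st.floats(0.5, 8.0)),
            min_size=0, max_size=12,
        )
    )
    def test_merge_idempotent_monotone(self, intervals):
        segs = [make_segment("I1", "I2", start_cm=round(s, 3), length_cm=round(l, 3))
                for s, l in intervals]
        once = merge_segments(segs)
        twice = merge_segments(once)
        assert once == twice
        assert len(once) <= len(segs)
        assert sum(s.length_cm for s in once) >= max(
            (s.length_cm for s in segs), default=0.0
        )


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length=200000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tI1\tI2
"""


def write_vcf(path, records):
    body = "".join(
        f"1\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t{g1}\t{g2}\n" for pos, g1, g2 in records
    )
    path.write_text(VCF_HEADER + body)


class TestGenotypeConsistentMerge:
    # segments I1/h1 - I2/h1 at 10-20 cM and 20.5-30 cM on the 1 cM/Mb map;
    # the gap spans bp ~20,000,001-20,500,001
    def segs(self):
        return [make_segment("I1", "I2", start_cm=10.0, length_cm=10.0),
                make_segment("I1", "I2", start_cm=20.5, length_cm=9.5)]

    def test_two_discordant_sites_block_the_merge(self, tmp_path):
        vcf = tmp_path / "g.vcf"
        # hap1 of I1 is 0, hap1 of I2 is 1 at two gap sites -> 2 discordances
        write_vcf(vcf, [(20_100_000, "0|0", "1|0"), (20_300_000, "0|0", "1|0")])
        gts = PhasedGenotypes.read(vcf)
        out = merge_segments(self.segs(), genotypes=gts, max_discordant=1)
        assert len(out) == 2

    def test_one_discordant_site_allows_the_merge(self, tmp_path):
        vcf = tmp_path / "g.vcf"
        write_vcf(vcf, [(20_100_000, "0|0", "1|0"), (20_300_000, "1|0", "1|0")])
        gts = PhasedGenotypes.read(vcf)
        out = merge_segments(self.segs(), genotypes=gts, max_discordant=1)
        assert len(out) == 1

    def test_discordance_counted_inside_blocks_too(self, tmp_path):
        vcf = tmp_path / "g.vcf"
        # one mismatch in the gap, one inside the left block
        write_vcf(vcf, [(15_000_000, "0|0", "1|0"), (20_300_000, "0|0", "1|0")])
        gts = PhasedGenotypes.read(vcf)
        assert len(merge_segments(self.segs(), genotypes=gts, max_discordant=1)) == 2


class TestBins:
    def test_half_open_binning(self):
        bins = LengthBins((1.0, 5.0, 10.0))
        segs = [make_segment("I1", "I2", length_cm=l) for l in (1.0, 4.99, 5.0, 12.0)]
        binned = bin_segments(segs, bins)
        assert {k: len(v) for k, v in binned.items()} == {
            "1-5cM": 2, "5-10cM": 1, ">10cM": 1,
        }

    def test_below_first_edge_dropped(self):
        bins = LengthBins((1.0, 5.0, 10.0))
        binned = bin_segments([make_segment("I1", "I2", length_cm=0.8)], bins)
        assert all(len(v) == 0 for v in binned.values())

    def test_empty_input(self):
        binned = bin_segments([], LengthBins((1.0, 5.0)))
        assert set(binned) == {"1-5cM", ">5cM"}
        assert all(v == [] for v in binned.values())

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.1, 30.0), max_size=30))
    def test_binning_partitions_lengths_above_first_edge(self, lengths):
        bins = LengthBins((1.0, 5.0, 10.0))
        segs = [make_segment("I1", "I2", length_cm=round(l, 4)) for l in lengths]
        binned = bin_segments(segs, bins)
        assert sum(len(v) for v in binned.values()) == sum(
            1 for s in segs if s.length_cm >= 1.0
        )

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError):
            LengthBins((5.0, 1.0))


class TestWithinGroupSummary:
    def test_single_pair_summed_length(self):
        panel = make_panel({"X": ["a", "b"]})
        segs = [make_segment("a", "b", length_cm=3.0)]
        per_group, _ = within_group_ibd_summary(segs, panel, min_cm=2.0)
        assert per_group.loc["X", "mean_sum_cm"] == pytest.approx(3.0)
        assert per_group.loc["X", "mean_count"] == pytest.approx(1.0)

    def test_short_blocks_filtered(self):
        panel = make_panel({"X": ["a", "b"]})
        segs = [make_segment("a", "b", length_cm=1.5)]
        per_group, _ = within_group_ibd_summary(segs, panel, min_cm=2.0)
        assert per_group.loc["X", "mean_sum_cm"] == 0.0

    def test_roh_totals_per_individual(self):
        panel = make_panel({"X": ["a", "b"]})
        segs = [
            make_segment("a", "a", length_cm=4.0, hap_a=1, hap_b=2),
            make_segment("a", "a", start_cm=40.0, length_cm=6.0, hap_a=1, hap_b=2),
        ]
        _, roh = within_group_ibd_summary(segs, panel)
        assert roh["a"] == pytest.approx(10.0)
        assert roh["b"] == 0.0

    def test_singleton_group_reported_missing(self):
        panel = make_panel({"X": ["a"], "Y": ["b", "c"]})
        per_group, _ = within_group_ibd_summary([], panel)
        assert np.isnan(per_group.loc["X", "mean_sum_cm"])
        assert per_group.loc["Y", "mean_sum_cm"] == 0.0


def tract_set(pieces):
    """pieces: {(ind, hap): [(start_bp, end_bp, ancestry, posterior), ...]} on chrom 1."""
    return AncestryTractSet(
        {(ind, hap, "1"): [AncestryTract(*p) for p in items]
         for (ind, hap), items in pieces.items()},
    )


class TestAncestryPartition:
    def test_identity_case_both_fully_an(self, toy_map):
        seg = make_segment("I1", "I2", start_cm=10.0, length_cm=8.0)
        tr = tract_set({
            ("I1", 1): [(1, 200_000_000, "AN", 0.99)],
            ("I2", 1): [(1, 200_000_000, "AN", 0.99)],
        })
        (sub,) = ancestry_partition(seg, tr, toy_map)
        assert sub.ancestry == "AN"
        assert sub.length_cm == pytest.approx(seg.length_cm, rel=1e-3)
        assert (sub.start_bp, sub.end_bp) == (seg.start_bp, seg.end_bp)

    def test_half_switch_intersection(self, toy_map):
        # segment 10-20 cM; hap I1/1 is AN until 15 cM then PAP; I2/1 AN all along
        seg = make_segment("I1", "I2", start_cm=10.0, length_cm=10.0)
        mid = int(1 + 15.0 * 1e6)
        tr = tract_set({
            ("I1", 1): [(1, mid, "AN", 0.99), (mid + 1, 200_000_000, "PAP", 0.99)],
            ("I2", 1): [(1, 200_000_000, "AN", 0.99)],
        })
        (sub,) = ancestry_partition(seg, tr, toy_map, min_sub_cm=1.0)
        assert sub.ancestry == "AN"
        assert sub.length_cm == pytest.approx(5.0, abs=0.01)

    def test_label_mismatch_yields_nothing(self, toy_map):
        seg = make_segment("I1", "I2", start_cm=10.0, length_cm=10.0)
        tr = tract_set({
            ("I1", 1): [(1, 200_000_000, "AN", 0.99)],
            ("I2", 1): [(1, 200_000_000, "PAP", 0.99)],
        })
        assert ancestry_partition(seg, tr, toy_map) == []

    def test_missing_coverage_yields_nothing(self, toy_map):
        seg = make_segment("I1", "I2", start_cm=10.0, length_cm=10.0)
        assert ancestry_partition(seg, tract_set({}), toy_map) == []

    def test_low_posterior_treated_as_unknown(self, toy_map):
        seg = make_segment("I1", "I2", start_cm=10.0, length_cm=10.0)
        tr = tract_set({
            ("I1", 1): [(1, 200_000_000, "UNKNOWN", 0.90)],  # masked at load time
            ("I2", 1): [(1, 200_000_000, "AN", 0.99)],
        })
        assert ancestry_partition(seg, tr, toy_map) == []

    def test_short_subsegments_dropped(self, toy_map):
        seg = make_segment("I1", "I2", start_cm=10.0, length_cm=10.0)
        mid = int(1 + 10.5 * 1e6)  # AN piece of only 0.5 cM
        tr = tract_set({
            ("I1", 1): [(1, mid, "AN", 0.99), (mid + 1, 200_000_000, "PAP", 0.99)],
            ("I2", 1): [(1, 200_000_000, "AN", 0.99)],
        })
        assert ancestry_partition(seg, tr, toy_map, min_sub_cm=1.0) == []

    def test_conservation_and_grid_oracle_on_random_mosaics(self, toy_map):
        rng = np.random.default_rng(7)
        for _ in range(20):
            start = rng.uniform(0, 60)
            length = rng.uniform(2, 30)
            seg = make_segment("I1", "I2", start_cm=round(start, 2),
                               length_cm=round(length, 2))
            pieces = {}
            for ind, hap in (("I1", 1), ("I2", 1)):
                cuts = np.sort(rng.uniform(0, 100, size=rng.integers(0, 4)))
                bounds = [0.0, *cuts, 100.0]
                items = []
                prev_bp = 0
                for lo, hi in zip(bounds, bounds[1:]):
                    anc = rng.choice(["AN", "PAP", "UNKNOWN"])
                    s_bp = prev_bp + 1
                    e_bp = int(1 + hi * 1e6)
                    if e_bp >= s_bp:
                        items.append((s_bp, e_bp, anc, 0.99))
                        prev_bp = e_bp
                pieces[(ind, hap)] = items
            tr = tract_set(pieces)
            subs = ancestry_partition(seg, tr, toy_map, min_sub_cm=0.0)
            total = sum(s.length_cm for s in subs)
            assert total <= seg.length_cm + 1e-9
            oracle = grid_ancestry_lengths(seg, tr, toy_map)
            for anc in ("AN", "PAP"):
                got = sum(s.length_cm for s in subs if s.ancestry == anc)
                assert got == pytest.approx(oracle.get(anc, 0.0), abs=0.03)
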