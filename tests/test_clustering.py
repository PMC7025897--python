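"""Pre-filtering, clustering and footprint tests."""

import math

import numpy as np
import pytest
from scipy import stats

from svrearrange.clustering import (
    BALANCED_OVERLAP,
    CANDIDATE_SHORT_INSERTION,
    ClusterModel,
    PLAIN,
    cluster_junctions,
    filter_foldback_artefacts,
    refine_clusters,
    remove_segment_bypassing,
    resolve_balanced_overlaps,
)
from svrearrange.genome_model import (
    Breakend,
    CNSegment,
    GenomeBuild,
    Junction,
    LEFT,
    RIGHT,
    SVSet,
)


def J(jid, c1, p1, s1, c2, p2, s2, sample="s"):
    return Junction(jid, sample, Breakend(c1, p1, s1), Breakend(c2, p2, s2))


class TestSegmentBypassing:
    def cn(self):
        return [
            CNSegment("s", "chrA", 0, 200_000, 2.0),
            CNSegment("s", "chrA", 200_000, 400_000, 1.0),
        ]

    def test_bypassed_junction_removed(self):
        j1 = J("J1", "chrA", 100_010, LEFT, "chrA", 200_000, RIGHT)
        j2 = J("J2", "chrA", 200_000, LEFT, "chrA", 299_995, RIGHT)
        j3 = J("J3", "chrA", 100_000, LEFT, "chrA", 300_000, RIGHT)
        kept, log = remove_segment_bypassing([j1, j2, j3], self.cn(), tol_bp=50)
        assert [j.id for j in kept] == ["J1", "J2"]
        assert log[0]["junction"] == "J3"
        assert set(log[0]["bypassed_by"]) == {"J1", "J2"}

    def test_distant_breakends_not_bypassed(self):
        j1 = J("J1", "chrA", 100_010, LEFT, "chrA", 200_000, RIGHT)
        j2 = J("J2", "chrA", 200_000, LEFT, "chrA", 299_995, RIGHT)
        j3 = J("J3", "chrA", 105_000, LEFT, "chrA", 305_000, RIGHT)
        kept, log = remove_segment_bypassing([j1, j2, j3], self.cn(), tol_bp=50)
        assert len(kept) == 3 and not log

    def test_random_junctions_untouched(self):
        """Brute-force oracle: with well-separated random junctions no pair of
        junction ends coincides, so no bypass path can exist."""
        rng = np.random.default_rng(5)
        junctions = [
            J(f"R{k}", "chrA", int(a), LEFT if rng.random() < 0.5 else RIGHT,
              "chrA", int(b), RIGHT)
            for k, (a, b) in enumerate(
                np.sort(rng.choice(10**8, size=(50, 2), replace=False), axis=1)
            )
        ]
        # independent check: no two breakends from different junctions within tol
        ends = [(j, bk) for j in junctions for bk in j.breakends]
        coincident = [
            (j1.id, j2.id)
            for i, (j1, b1) in enumerate(ends)
            for (j2, b2) in ends[i + 1:]
            if j1 is not j2 and abs(b1.pos - b2.pos) <= 50
        ]
        assert not coincident
        kept, log = remove_segment_bypassing(junctions, self.cn(), tol_bp=50)
        assert kept == junctions and not log


class TestFoldbackFilter:
    def test_flat_cn_foldback_removed(self, build, flat_cn):
        j = J("F", "chr1", 1_000_000, LEFT, "chr1", 1_000_400, LEFT)
        assert filter_foldback_artefacts([j], flat_cn()) == []

    def test_cn_step_retains_foldback(self, build):
        cn = [
            CNSegment("s", "chr1", 0, 1_000_200, 2.0),
            CNSegment("s", "chr1", 1_000_200, 50_000_000, 3.0),
        ]
        j = J("F", "chr1", 1_000_000, LEFT, "chr1", 1_000_400, LEFT)
        assert filter_foldback_artefacts([j], cn) == [j]

    def test_wide_inversion_junction_retained(self, build, flat_cn):
        j = J("W", "chr1", 1_000_000, LEFT, "chr1", 3_000_000, LEFT)
        assert filter_foldback_artefacts([j], flat_cn()) == [j]


class TestBalancedOverlaps:
    def test_reciprocal_translocation_tagged(self):
        j1 = J("J1", "chrA", 1000, LEFT, "chrB", 5000, RIGHT)
        j2 = J("J2", "chrA", 1020, RIGHT, "chrB", 4990, LEFT)
        tags = resolve_balanced_overlaps([j1, j2])
        assert tags == {"J1": BALANCED_OVERLAP, "J2": BALANCED_OVERLAP}

    def test_short_insertion_candidate(self):
        # 25-bp segment of chrB inserted into chrA
        j1 = J("J1", "chrA", 1000, LEFT, "chrB", 5000, RIGHT)
        j2 = J("J2", "chrB", 5025, LEFT, "chrA", 1001, RIGHT)
        tags = resolve_balanced_overlaps([j1, j2])
        assert tags["J1"] == CANDIDATE_SHORT_INSERTION
        assert tags["J2"] == CANDIDATE_SHORT_INSERTION

    def test_isolated_junction_plain(self):
        j = J("J1", "chrA", 1000, LEFT, "chrA", 90_000, RIGHT)
        assert resolve_balanced_overlaps([j]) == {"J1": PLAIN}


class TestClusterModel:
    def test_merge_probability_closed_form(self):
        # 10 junctions -> 20 breakpoints on G = 1e8
        model = ClusterModel(20, 1e8, 1e-3)
        assert model.merge_p(1000) == pytest.approx(1 - math.exp(-2e-7 * 1000))
        assert model.merge_p(1000) < 1e-3
        assert model.merge_p(10_000_000) == pytest.approx(0.8647, abs=1e-3)


class TestClustering:
    def _sv(self, junctions, build_len=10**8):
        build = GenomeBuild("g", (("chrA", build_len),))
        cn = [CNSegment("s", "chrA", 0, build_len, 2.0)]
        return SVSet("s", junctions, cn, build, 2.0)

    def _ten_junctions(self, gap, spread=10_000_000):
        """8 far-apart junctions plus one pair with nearest breakends `gap` apart."""
        js = [
            J(f"B{k}", "chrA", 5_000_000 + k * spread, LEFT,
              "chrA", 5_000_000 + k * spread + 2_000_000, RIGHT)
            for k in range(8)
        ]
        js.append(J("N1", "chrA", 90_000_000, LEFT, "chrA", 92_000_000, RIGHT))
        js.append(J("N2", "chrA", 92_000_000 + gap, LEFT, "chrA", 95_000_000, RIGHT))
        return js

    def test_nearby_junctions_merge(self):
        sv = self._sv(self._ten_junctions(gap=1000))
        clusters = cluster_junctions(sv, p_merge=1e-3, callable_size=1e8)
        by_id = {j.id: c.id for c in clusters for j in c.junctions}
        assert by_id["N1"] == by_id["N2"]

    def test_distant_junctions_stay_singletons(self):
        sv = self._sv(self._ten_junctions(gap=10_000_000 - 3_000_000))
        clusters = cluster_junctions(sv, p_merge=1e-3, callable_size=1e8)
        by_id = {j.id: c.id for c in clusters for j in c.junctions}
        assert by_id["N1"] != by_id["N2"]

    def test_large_deletion_one_cluster_two_footprints(self):
        """The intra-junction span is excluded from the merge statistic."""
        j = J("D", "chrA", 5_000_000, LEFT, "chrA", 10_000_000, RIGHT)
        sv = self._sv([j])
        (c,) = cluster_junctions(sv, p_merge=1e-3, callable_size=1e8)
        assert c.n_junctions == 1
        assert len(c.footprints) == 2
        assert all(f.n_breakends == 1 for f in c.footprints)

    def test_partition_property(self, small_genome):
        """Every junction in exactly one cluster; every breakend in one footprint."""
        sv, _ = small_genome
        clusters = cluster_junctions(sv)
        seen = {}
        for c in clusters:
            for j in c.junctions:
                assert j.id not in seen
                seen[j.id] = c.id
        assert len(seen) == len(sv.junctions)
        for c in clusters:
            n_fp_bends = sum(f.n_breakends for f in c.footprints)
            assert n_fp_bends == 2 * c.n_junctions

    def test_scale_invariance(self):
        """Doubling G and all coordinates leaves the clustering identical."""
        js = self._ten_junctions(gap=1500)
        sv1 = self._sv(js)
        js2 = [
            J(j.id, "chrA", j.a.pos * 2, j.a.side, "chrA", j.b.pos * 2, j.b.side)
            for j in js
        ]
        sv2 = self._sv(js2, build_len=2 * 10**8)
        c1 = cluster_junctions(sv1, callable_size=1e8)
        c2 = cluster_junctions(sv2, callable_size=2e8)
        part1 = sorted(tuple(sorted(j.id for j in c.junctions)) for c in c1)
        part2 = sorted(tuple(sorted(j.id for j in c.junctions)) for c in c2)
        assert part1 == part2

    def test_empty_input(self, build, flat_cn):
        sv = SVSet("s", [], flat_cn(), build, 2.0)
        assert cluster_junctions(sv) == []


class TestCalibration:
    def test_uniform_junctions_merge_at_null_rate(self):
        """Spurious merges among uniform junctions occur at ~p_merge per
        adjacent breakend gap (binomial test must not reject)."""
        from svrearrange.simulator import simulate_uniform_junctions

        build = GenomeBuild("cal", (("chr1", 10**8),))
        merges = gaps = 0
        for rep in range(30):
            sv = simulate_uniform_junctions(200, build, seed=2000 + rep)
            clusters = cluster_junctions(sv, p_merge=1e-3, callable_size=1e8)
            merges += sum(c.n_junctions - 1 for c in clusters)
            gaps += 2 * 200 - 1
        p = stats.binomtest(merges, gaps, 1e-3).pvalue
        assert p > 0.01


class TestRefinement:
    def test_independent_deletions_split(self, build):
        # two deletions whose left breakends are 2 kb apart
        j1 = J("D1", "chr1", 1_000_000, LEFT, "chr1", 1_050_000, RIGHT)
        j2 = J("D2", "chr1", 1_052_000, LEFT, "chr1", 1_102_000, RIGHT)
        cn = [
            CNSegment("s", "chr1", 0, 1_000_001, 2.0),
            CNSegment("s", "chr1", 1_000_001, 1_050_000, 1.0),
            CNSegment("s", "chr1", 1_050_000, 1_052_001, 2.0),
            CNSegment("s", "chr1", 1_052_001, 1_102_000, 1.0),
            CNSegment("s", "chr1", 1_102_000, 50_000_000, 2.0),
        ]
        sv = SVSet("s", [j1, j2], cn, build, 2.0)
        clusters = cluster_junctions(sv, p_merge=1e-3, callable_size=1.35e8)
        assert any(c.n_junctions == 2 for c in clusters)  # co-clustered first
        refined = refine_clusters(clusters, cn, 2.0, d_crit=60_000)
        assert sorted(c.n_junctions for c in refined) == [1, 1]

    def test_templated_cycle_not_split(self, build):
        """Oracle: exhaustive bipartitions of the cycle all leave a part that is
        not an independently CN-consistent simple event."""
        j1 = J("C1", "chr1", 2_010_000, LEFT, "chr2", 5_000_000, RIGHT)
        j2 = J("C2", "chr2", 5_050_000, LEFT, "chr1", 2_000_000, RIGHT)
        cn = [
            CNSegment("s", "chr1", 0, 2_000_000, 2.0),
            CNSegment("s", "chr1", 2_000_000, 2_010_001, 3.0),
            CNSegment("s", "chr1", 2_010_001, 50_000_000, 2.0),
            CNSegment("s", "chr2", 0, 5_000_000, 2.0),
            CNSegment("s", "chr2", 5_000_000, 5_050_001, 3.0),
            CNSegment("s", "chr2", 5_050_001, 50_000_000, 2.0),
            CNSegment("s", "chr3", 0, 50_000_000, 2.0),
        ]
        sv = SVSet("s", [j1, j2], cn, build, 2.0)
        clusters = cluster_junctions(sv, p_merge=1e-3, callable_size=1.35e8)
        refined = refine_clusters(clusters, cn, 2.0, d_crit=60_000)
        assert any(
            {j.id for j in c.junctions} == {"C1", "C2"} for c in refined
        )

    def test_overlapping_footprint_clusters_merge(self, build, flat_cn):
        j1 = J("A1", "chr1", 1_000_000, LEFT, "chr2", 9_000_000, RIGHT)
        j2 = J("A2", "chr1", 1_000_000, RIGHT, "chr3", 30_000_000, LEFT)
        c1 = cluster_junctions(
            SVSet("s", [j1], flat_cn(), build, 2.0), callable_size=1.35e8
        )
        c2 = cluster_junctions(
            SVSet("s", [j2], flat_cn(), build, 2.0), callable_size=1.35e8
        )
        merged = refine_clusters(c1 + c2, flat_cn(), 2.0, d_crit=60_000)
        assert any(c.n_junctions == 2 for c in merged)
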