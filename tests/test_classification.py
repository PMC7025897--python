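"""Cluster classification tests: segment graph, templated-insertion paths,
the replay oracle, and the full decision tree."""

from collections import Counter

import numpy as np
import pytest

from svrearrange.classification import (
    Classification,
    EVENT_CLASSES,
    build_segment_graph,
    classify_all,
    classify_cluster,
    find_templated_insertion_path,
    path_replay_consistent,
)
from svrearrange.clustering import Cluster, _build_footprints
from svrearrange.genome_model import (
    Breakend,
    CNSegment,
    Junction,
    LEFT,
    RIGHT,
    SVSet,
    toy_build,
)
from tests.conftest import cn_profile


def J(jid, c1, p1, s1, c2, p2, s2):
    return Junction(jid, "s", Breakend(c1, p1, s1), Breakend(c2, p2, s2))


def make_cluster(junctions, d_crit=100_000):
    c = Cluster("s.c1", "s", list(junctions))
    c.footprints = _build_footprints(c, d_crit)
    return c


@pytest.fixture(scope="module")
def build():
    return toy_build()


# The two-junction cycle and bridge fixtures: host chrA, template on chrB.
def cycle_fixture(build):
    j1 = J("J1", "chr1", 2_010_000, LEFT, "chr2", 5_000_000, RIGHT)
    j2 = J("J2", "chr2", 5_050_000, LEFT, "chr1", 2_000_000, RIGHT)
    cn = (
        cn_profile(build, "s", "chr1", [2_000_000, 2_010_001], [2.0, 3.0, 2.0])[:3]
        + cn_profile(build, "s", "chr2", [5_000_000, 5_050_001], [2.0, 3.0, 2.0])
    )
    cn = [s for s in cn if not (s.chrom == "chr1" and s.total_cn == 2.0 and s.start == 0 and s.end == build.lengths["chr1"])]
    return make_cluster([j1, j2]), cn


def bridge_fixture(build):
    j1 = J("J1", "chr1", 2_000_000, LEFT, "chr2", 5_000_000, RIGHT)
    j2 = J("J2", "chr2", 5_050_000, LEFT, "chr1", 2_010_000, RIGHT)
    cn = (
        cn_profile(build, "s", "chr1", [2_000_001, 2_010_000], [2.0, 1.0, 2.0])[:3]
        + cn_profile(build, "s", "chr2", [5_000_000, 5_050_001], [2.0, 3.0, 2.0])
    )
    cn = [s for s in cn if not (s.chrom == "chr1" and s.total_cn == 2.0 and s.start == 0 and s.end == build.lengths["chr1"])]
    return make_cluster([j1, j2]), cn


class TestSegmentGraph:
    def test_deletion_graph(self, build):
        cluster = make_cluster(
            [J("D", "chr1", 999_999, LEFT, "chr1", 1_100_000, RIGHT)]
        )
        cn = cn_profile(build, "s", "chr1", [1_000_000, 1_100_000], [2.0, 1.0, 2.0])
        g = build_segment_graph(cluster, cn, 2.0)
        assert g.gain_between("chr1", 999_999, 1_100_000) == -1

    def test_cycle_graph_two_gained_nodes(self, build):
        cluster, cn = cycle_fixture(build)
        g = build_segment_graph(cluster, cn, 2.0)
        assert g.gain_between("chr1", 2_000_000, 2_010_000) == 1
        assert g.gain_between("chr2", 5_000_000, 5_050_000) == 1

    def test_flat_inversion_all_zero(self, build, flat_cn=None):
        js = [
            J("I1", "chr1", 999_999, LEFT, "chr1", 1_499_999, LEFT),
            J("I2", "chr1", 1_000_000, RIGHT, "chr1", 1_500_000, RIGHT),
        ]
        cn = cn_profile(build, "s", "chr1", [], [2.0])
        g = build_segment_graph(make_cluster(js), cn, 2.0)
        assert all(v == 0 for v in g.gains.values())


class TestTemplatedInsertionPaths:
    def test_cycle_detected_and_replays(self, build):
        cluster, cn = cycle_fixture(build)
        g = build_segment_graph(cluster, cn, 2.0)
        path = find_templated_insertion_path(g, cn)
        assert path is not None and path.topology == "cycle"
        assert path.host_chrom == "chr1"
        assert len(path.templates) == 1
        assert path.templates[0][:3] == ("chr2", 5_000_000, 5_050_000)
        assert path_replay_consistent(path, cluster, cn, 2.0, build)

    def test_bridge_detected_and_replays(self, build):
        cluster, cn = bridge_fixture(build)
        g = build_segment_graph(cluster, cn, 2.0)
        path = find_templated_insertion_path(g, cn)
        assert path is not None and path.topology == "bridge"
        assert path_replay_consistent(path, cluster, cn, 2.0, build)

    def test_chain_ends_on_two_chromosomes(self, build):
        j1 = J("J1", "chr1", 2_000_000, LEFT, "chr2", 5_000_000, RIGHT)
        j2 = J("J2", "chr2", 5_050_000, LEFT, "chr3", 9_000_000, RIGHT)
        cn = (
            cn_profile(build, "s", "chr1", [2_000_001], [2.0, 1.0])[:2]
            + cn_profile(build, "s", "chr2", [5_000_000, 5_050_001], [2.0, 3.0, 2.0])[:3]
            + cn_profile(build, "s", "chr3", [9_000_000], [1.0, 2.0])
        )
        g = build_segment_graph(make_cluster([j1, j2]), cn, 2.0)
        path = find_templated_insertion_path(g, cn)
        assert path is not None and path.topology == "chain"

    def test_flat_cluster_has_no_path(self, build):
        js = [
            J("B1", "chr1", 1_000_000, LEFT, "chr2", 5_000_000, RIGHT),
            J("B2", "chr2", 5_000_000, LEFT, "chr3", 9_000_000, RIGHT),
        ]
        cn = cn_profile(build, "s", "chr1", [], [2.0]) \
            + [CNSegment("s", "chr2", 0, build.lengths["chr2"], 2.0)][:0]
        cn = [CNSegment("s", c, 0, l, 2.0) for c, l in build.chromosomes]
        g = build_segment_graph(make_cluster(js), cn, 2.0)
        assert find_templated_insertion_path(g, cn) is None


class TestClassifyCluster:
    def test_deletion(self, build):
        cluster = make_cluster([J("D", "chr1", 999_999, LEFT, "chr1", 1_100_000, RIGHT)])
        cn = cn_profile(build, "s", "chr1", [1_000_000, 1_100_000], [2.0, 1.0, 2.0])
        out = classify_cluster(cluster, cn, 2.0, build=build)
        assert out.event_class == "deletion"

    def test_deletion_orientation_with_flat_cn_is_not_a_deletion(self, build):
        cluster = make_cluster([J("D", "chr1", 999_999, LEFT, "chr1", 1_100_000, RIGHT)])
        cn = [CNSegment("s", c, 0, l, 2.0) for c, l in build.chromosomes]
        out = classify_cluster(cluster, cn, 2.0, build=build)
        assert out.event_class != "deletion"

    def test_cycle_fixture_classified(self, build):
        cluster, cn = cycle_fixture(build)
        out = classify_cluster(cluster, cn, 2.0, build=build)
        assert out.event_class == "templated_insertion_cycle"
        assert out.details["replay_consistent"]

    def test_chromoplexy(self, build):
        js = [
            J("P1", "chr1", 1_000_000, LEFT, "chr2", 5_000_000, RIGHT),
            J("P2", "chr2", 4_999_999, LEFT, "chr3", 9_000_000, RIGHT),
            J("P3", "chr3", 8_999_999, LEFT, "chr1", 1_000_001, RIGHT),
        ]
        cn = [CNSegment("s", c, 0, l, 2.0) for c, l in build.chromosomes]
        out = classify_cluster(make_cluster(js), cn, 2.0, build=build)
        assert out.event_class == "chromoplexy"

    def test_chromothripsis_like(self, build):
        """12 deletion-type junctions with oscillating two-state CN over a
        multi-megabase region."""
        js, bounds, vals = [], [], []
        pos = 2_000_000
        vals.append(2.0)
        for k in range(12):
            lost_lo, lost_hi = pos + 100_000, pos + 250_000
            js.append(J(f"K{k}", "chr1", lost_lo - 1, LEFT, "chr1", lost_hi, RIGHT))
            bounds += [lost_lo, lost_hi]
            vals += [1.0, 2.0]
            pos += 300_000
        cn = cn_profile(build, "s", "chr1", bounds, vals)
        out = classify_cluster(make_cluster(js, d_crit=500_000), cn, 2.0, build=build)
        assert out.event_class == "chromothripsis_like"
        assert out.details["oscillations"] >= 10

    def test_missing_cn_never_crashes(self, build):
        cluster = make_cluster([J("D", "chr1", 999_999, LEFT, "chr1", 1_100_000, RIGHT)])
        out = classify_cluster(cluster, [], 2.0, build=build)
        assert out.event_class == "complex_unclassified"
        assert out.details.get("flag") == "missing_cn"

    def test_mutual_exclusivity(self, small_genome):
        sv, _ = small_genome
        classifications, counts, _ = classify_all(sv)
        assert sum(counts.values()) == len(classifications)
        assert all(c.event_class in EVENT_CLASSES for c in classifications)


class TestGenerativeRecovery:
    def test_recovery_on_simulated_genome(self, small_genome):
        """Class labels recover the simulator truth for simple and templated-
        insertion events; topology is exact on this noise-free input."""
        from svrearrange.simulator import SIMPLE_CLASSES, TEMPLATED_CLASSES

        sv, truths = small_genome
        classifications, _, _ = classify_all(sv)
        jmap = {
            j.id: c.event_class
            for c in classifications for j in c.cluster.junctions
        }
        simple = [t for t in truths if t.event_class in SIMPLE_CLASSES]
        ti = [t for t in truths if t.event_class in TEMPLATED_CLASSES]
        ok_simple = sum(
            {jmap.get(j) for j in t.junction_ids} == {t.event_class} for t in simple
        )
        ok_ti = sum(
            {jmap.get(j) for j in t.junction_ids} == {t.event_class} for t in ti
        )
        assert ok_simple / len(simple) >= 0.9
        assert ok_ti / len(ti) >= 0.9
        # topology exactness: no cycle/bridge confusion on noise-free input
        for t in ti:
            got = {jmap.get(j) for j in t.junction_ids}
            if got <= set(TEMPLATED_CLASSES):
                assert got == {t.event_class}

    def test_replay_oracle_all_paths(self, small_genome):
        """Every classified templated-insertion path replays exactly."""
        sv, _ = small_genome
        classifications, _, _ = classify_all(sv)
        ti = [c for c in classifications
              if c.event_class.startswith("templated_insertion")]
        assert ti, "expected templated-insertion calls in the fixture genome"
        assert all(c.details["replay_consistent"] for c in ti)

    def test_empty_svset(self, build):
        sv = SVSet("s", [], [CNSegment("s", c, 0, l, 2.0) for c, l in build.chromosomes],
                   build, 2.0)
        classifications, counts, bp = classify_all(sv)
        assert classifications == [] and sum(counts.values()) == 0 and bp == []

    def test_two_jump_recovery(self, build):
        """Each simulated local 2-jump subtype classifies as itself."""
        from svrearrange.simulator import SimConfig, simulate_genome

        cfg = SimConfig(
            seed=23, build=build, cn_noise_sd=0.0,
            intensities={
                "local_2jump_dup_trp_dup": 6,
                "local_2jump_inverted_dups": 6,
                "local_2jump_del_invdup": 6,
            },
        )
        sv, truths = simulate_genome(cfg)
        classifications, _, _ = classify_all(sv)
        jmap = {j.id: c.event_class
                for c in classifications for j in c.cluster.junctions}
        agree = Counter()
        for t in truths:
            got = {jmap.get(j) for j in t.junction_ids}
            agree[got == {t.event_class}] += 1
        assert agree[True] >= 0.9 * sum(agree.values())
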