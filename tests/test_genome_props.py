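"""Pixel grid, property-association, permutation-enrichment and
microhomology-regime tests."""

import numpy as np
import pytest
from scipy import stats

from svrearrange.genome_model import GenomeBuild, ParseError, toy_build
from svrearrange.genome_props import (
    association_suite,
    fit_microhomology_regimes,
    footprint_connectivity,
    partner_permutation_enrichment,
    property_quantile_test,
    read_track,
    tile_genome,
    track_from_array,
)
from svrearrange.simulator import RTModel


class TestTiling:
    def test_toy_partial_bin(self):
        grid = tile_genome(GenomeBuild("t", (("c1", 2500),)), 1000)
        assert grid.total_bins == 3

    def test_exact_division(self):
        grid = tile_genome(GenomeBuild("t", (("c1", 1000),)), 1000)
        assert grid.total_bins == 1

    def test_pixel_conservation(self, build):
        grid = tile_genome(build, 1000)
        assert grid.total_bins == sum(grid.n_bins.values())
        # last bin covers the chromosome end exactly once
        for chrom, length in build.chromosomes:
            assert grid.pixel_index(chrom, length - 1) == (
                grid.offsets[chrom] + grid.n_bins[chrom] - 1
            )


class TestReadTrack:
    def test_constant_track(self, tmp_path):
        grid = tile_genome(GenomeBuild("t", (("c1", 3000),)), 1000)
        p = tmp_path / "t.bedgraph"
        p.write_text("c1\t0\t3000\t5.0\n")
        tr = read_track(p, grid)
        assert np.allclose(tr.values, 5.0)

    def test_coverage_weighted_mean(self, tmp_path):
        grid = tile_genome(GenomeBuild("t", (("c1", 1000),)), 1000)
        p = tmp_path / "t.bedgraph"
        p.write_text("c1\t0\t500\t0\nc1\t500\t1000\t10\n")
        tr = read_track(p, grid)
        assert tr.values[0] == pytest.approx(5.0)

    def test_empty_file_all_missing(self, tmp_path):
        grid = tile_genome(GenomeBuild("t", (("c1", 3000),)), 1000)
        p = tmp_path / "t.bedgraph"
        p.write_text("")
        tr = read_track(p, grid)
        assert np.isnan(tr.values).all()

    def test_non_numeric_value_errors(self, tmp_path):
        grid = tile_genome(GenomeBuild("t", (("c1", 3000),)), 1000)
        p = tmp_path / "t.bedgraph"
        p.write_text("c1\t0\t100\thigh\n")
        with pytest.raises(ParseError, match=":1"):
            read_track(p, grid)


class TestQuantileTest:
    def test_extreme_low_enrichment(self, build):
        """All observed breakpoints in the minimum-value pixel."""
        grid = tile_genome(build)
        rng = np.random.default_rng(0)
        vals = rng.random(grid.total_bins)
        vals[grid.pixel_index("chr1", 5_000_000)] = -10.0
        tr = track_from_array("x", grid, vals)
        pos = [("chr1", 5_000_000)] * 30
        r = property_quantile_test(pos, tr, grid, n_random=10_000, seed=1)
        assert r.median_quantile < 0.01
        assert r.p < 1e-6
        assert r.ks_statistic < 0  # enriched at low values

    def test_null_calibration(self, build):
        """Uniform observed positions give ~uniform p; the fraction below 0.05
        stays inside its binomial 99% interval over replicates."""
        grid = tile_genome(build)
        tr = RTModel(build).track(grid)
        rng = np.random.default_rng(0)
        chroms = [c for c, _ in build.chromosomes]
        n_rep, hits = 100, 0
        for rep in range(n_rep):
            pos = [
                (chroms[rng.integers(0, len(chroms))], int(rng.integers(0, 50_000_000)))
                for _ in range(100)
            ]
            r = property_quantile_test(pos, tr, grid, n_random=5_000, seed=rep)
            hits += r.p < 0.05
        lo, hi = stats.binom.interval(0.99, n_rep, 0.05)
        assert lo <= hits <= hi

    def test_constant_track_not_significant(self, build):
        grid = tile_genome(build)
        tr = track_from_array("c", grid, np.ones(grid.total_bins))
        pos = [("chr1", int(p)) for p in np.linspace(0, 4e7, 50)]
        r = property_quantile_test(pos, tr, grid, n_random=5_000, seed=0)
        assert r.p > 0.5
        assert r.median_quantile == pytest.approx(0.5, abs=0.01)

    def test_underpowered_flag(self, build):
        grid = tile_genome(build)
        tr = RTModel(build).track(grid)
        r = property_quantile_test([("chr1", 100)], tr, grid, n_random=1_000, seed=0)
        assert r.underpowered


class TestAssociationSuite:
    def test_bookkeeping_and_by_with_m1(self, build):
        grid = tile_genome(build)
        tr = RTModel(build).track(grid)
        rng = np.random.default_rng(1)
        by_class = {
            cls: [("chr1", int(p)) for p in rng.integers(0, 5e7, 40)]
            for cls in ("a", "b", "c")
        }
        res = association_suite(by_class, [tr, tr], grid, n_random=2_000, seed=0)
        assert len(res) == 6
        single = association_suite({"a": by_class["a"]}, [tr], grid, n_random=2_000, seed=0)
        assert single[0].q == pytest.approx(single[0].p)  # BY with m=1

    def test_planted_enrichment_flagged(self, build):
        """Deletions planted at low replication timing are detected; a null
        class on the same track is not."""
        grid = tile_genome(build)
        tr = RTModel(build).track(grid)
        rt = RTModel(build)
        rng = np.random.default_rng(2)
        low, nulls = [], []
        while len(low) < 60:
            p = int(rng.integers(0, 5e7))
            if rt.value("chr1", p) < 0.2:
                low.append(("chr1", p))
        nulls = [("chr2", int(p)) for p in rng.integers(0, 5e7, 60)]
        res = association_suite(
            {"deletion": low, "other": nulls}, [tr], grid, n_random=10_000, seed=0
        )
        by_class = {r.event_class: r for r in res}
        assert by_class["deletion"].q < 0.01
        assert by_class["deletion"].median_quantile < 0.5
        assert by_class["other"].q > 0.01


class TestPartnerPermutation:
    def test_homotypic_pairing_enriched(self):
        rng = np.random.default_rng(0)
        labels = [("X", "X")] * 30 + [
            tuple(rng.choice(["Y", "Z"], 2)) for _ in range(60)
        ]
        res = partner_permutation_enrichment(labels, n_perm=300, seed=1)
        xx = next(r for r in res if r.pair == ("X", "X"))
        assert xx.fold_change > 1
        assert xx.z > 3

    def test_random_pairing_unenriched(self):
        rng = np.random.default_rng(3)
        labels = [tuple(rng.choice(["A", "B", "C"], 2)) for _ in range(200)]
        res = partner_permutation_enrichment(labels, n_perm=300, seed=2)
        calm = [r for r in res if abs(r.z) < 3]
        assert len(calm) / len(res) >= 0.95

    def test_exchangeability_mean_z_near_zero(self):
        """Averaged over replicate random datasets, z is centred on zero."""
        rng = np.random.default_rng(4)
        zs = []
        for rep in range(30):
            labels = [tuple(rng.choice(["A", "B"], 2)) for _ in range(100)]
            res = partner_permutation_enrichment(labels, n_perm=200, seed=rep)
            zs.extend(r.z for r in res)
        assert abs(np.mean(zs)) < 0.25

    def test_single_junction_degenerate(self):
        res = partner_permutation_enrichment([("A", "B")], n_perm=100, seed=0)
        assert all(r.degenerate for r in res)


class TestFootprintConnectivity:
    def test_homotypic_connectivity_enriched(self):
        """Footprints of the same structure always joined -> strong enrichment."""
        from svrearrange.clustering import Cluster, Footprint
        from svrearrange.genome_model import Breakend, Junction, LEFT, RIGHT

        clusters = []
        for k in range(40):
            # same-type pairs: both breakends left-side (pattern 'L'-'L')
            side = LEFT if k < 20 else RIGHT
            a = Breakend("chr1", 10_000 * (k + 1), side)
            b = Breakend("chr2", 10_000 * (k + 1), side)
            j = Junction(f"j{k}", "s", a, b)
            c = Cluster(f"c{k}", "s", [j])
            c.footprints = [
                Footprint(f"c{k}.f1", a.chrom, a.pos, a.pos, [(a, j)]),
                Footprint(f"c{k}.f2", b.chrom, b.pos, b.pos, [(b, j)]),
            ]
            clusters.append(c)
        res = footprint_connectivity(clusters, n_perm=300, seed=5)
        ll = next(r for r in res if r.pair == ("L", "L"))
        assert ll.fold_change >= 1.5 and ll.z > 3

    def test_single_type_degenerate(self):
        from svrearrange.clustering import Cluster, Footprint
        from svrearrange.genome_model import Breakend, Junction, LEFT

        clusters = []
        for k in range(5):
            a = Breakend("chr1", 10_000 * (k + 1), LEFT)
            b = Breakend("chr2", 10_000 * (k + 1), LEFT)
            j = Junction(f"j{k}", "s", a, b)
            c = Cluster(f"c{k}", "s", [j])
            c.footprints = [
                Footprint(f"c{k}.f1", a.chrom, a.pos, a.pos, [(a, j)]),
                Footprint(f"c{k}.f2", b.chrom, b.pos, b.pos, [(b, j)]),
            ]
            clusters.append(c)
        res = footprint_connectivity(clusters, n_perm=100, seed=0)
        assert all(r.degenerate for r in res)


def three_regime_counts(b1=2, b2=10, length=31,
                        params=((5.0, -1.2), (4.0, -0.3), (2.5, -0.05))):
    """Counts whose log10(count+1) is exactly piecewise-linear."""
    x = np.arange(length, dtype=float)
    y = np.empty(length)
    (a0, s0), (a1, s1), (a2, s2) = params
    y[:b1] = a0 + s0 * x[:b1]
    y[b1:b2] = a1 + s1 * x[b1:b2]
    y[b2:] = a2 + s2 * x[b2:]
    return 10.0**y - 1.0


class TestMicrohomology:
    def test_exact_recovery_noise_free(self):
        counts = three_regime_counts()
        fit = fit_microhomology_regimes(counts)
        assert (fit.b1, fit.b2) == (2, 10)
        assert fit.slopes["NHEJ"] == pytest.approx(-1.2, abs=1e-9)
        assert fit.slopes["MMEJ"] == pytest.approx(-0.3, abs=1e-9)
        assert fit.slopes["SSA"] == pytest.approx(-0.05, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_constant_counts_tie_rule(self):
        fit = fit_microhomology_regimes(np.full(31, 7.0))
        assert (fit.b1, fit.b2) == (1, 8)  # first grid values on ties
        assert all(abs(s) < 1e-12 for s in fit.slopes.values())

    def test_poisson_noise_recovery(self):
        """Changepoints within +-1 bp in >= 90% of noisy replicates."""
        counts = three_regime_counts()
        rng = np.random.default_rng(6)
        ok = 0
        n_rep = 50
        for _ in range(n_rep):
            noisy = rng.poisson(counts)
            fit = fit_microhomology_regimes(noisy)
            ok += abs(fit.b1 - 2) <= 1 and abs(fit.b2 - 10) <= 1
        assert ok / n_rep >= 0.9

    def test_short_histogram_errors(self):
        with pytest.raises(ValueError):
            fit_microhomology_regimes(np.ones(5))

    def test_regime_labels(self):
        fit = fit_microhomology_regimes(three_regime_counts())
        assert fit.regime_of(0) == "NHEJ"
        assert fit.regime_of(5) == "MMEJ"
        assert fit.regime_of(25) == "SSA"
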