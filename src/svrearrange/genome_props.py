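"""Genome-property associations, partner-permutation enrichment, footprint
connectivity, and the junction-microhomology regime fit.

The genome is tiled into fixed-size pixels (1 kb by default) and each
property track is averaged into that grid.  Breakpoint-vs-property
association compares the property quantiles at observed breakpoints against
uniform random positions from the callable (non-missing) genome: observed
and random values are pooled, rank-transformed to [0, 1] with mid-ranks, and
the observed quantiles are tested against uniformity with a one-sided
Kolmogorov-Smirnov test (reporting the larger one-sided direction, signed).
Benjamini-Yekutieli correction controls the FDR across the suite of tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .genome_model import GenomeBuild, Junction, ParseError

DEFAULT_BIN_SIZE = 1_000


@dataclass
class PixelGrid:
    """Fixed-size tiling of a genome build; the final partial bin counts."""

    build: GenomeBuild
    bin_size: int = DEFAULT_BIN_SIZE
    offsets: dict[str, int] = field(default_factory=dict)
    n_bins: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        acc = 0
        for chrom, length in self.build.chromosomes:
            n = -(-length // self.bin_size)  # ceil
            self.offsets[chrom] = acc
            self.n_bins[chrom] = n
            acc += n
        self.total_bins = acc

    def pixel_index(self, chrom: str, pos: int) -> int:
        return self.offsets[chrom] + pos // self.bin_size


def tile_genome(build: GenomeBuild, bin_size: int = DEFAULT_BIN_SIZE) -> PixelGrid:
    return PixelGrid(build, bin_size)


@dataclass
class PropertyTrack:
    """Per-pixel values of one genome property; NaN marks missing pixels."""

    name: str
    grid: PixelGrid
    values: np.ndarray

    def __post_init__(self):
        if len(self.values) != self.grid.total_bins:
            raise ValueError("track length does not match grid")

    @property
    def covered(self) -> np.ndarray:
        return ~np.isnan(self.values)


def read_track(path, grid: PixelGrid, name: Optional[str] = None) -> PropertyTrack:
    """Coverage-weighted average of a bedGraph / 4-column BED onto the grid."""
    sums = np.zeros(grid.total_bins)
    cov = np.zeros(grid.total_bins)
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if chrom not in grid.offsets:
                continue
            n_rows += 1
            b0 = start // grid.bin_size
            b1 = -(-end // grid.bin_size)
            for b in range(b0, min(b1, grid.n_bins[chrom])):
                lo = b * grid.bin_size
                hi = lo + grid.bin_size
                ov = min(end, hi) - max(start, lo)
                if ov > 0:
                    idx = grid.offsets[chrom] + b
                    sums[idx] += ov * value
                    cov[idx] += ov
    if n_rows == 0:
        import logging

        logging.getLogger(__name__).warning("%s: empty track; all pixels missing", path)
    values = np.full(grid.total_bins, np.nan)
    mask = cov > 0
    values[mask] = sums[mask] / cov[mask]
    return PropertyTrack(name or str(path), grid, values)


def track_from_array(name: str, grid: PixelGrid, values: np.ndarray) -> PropertyTrack:
    return PropertyTrack(name, grid, np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# Quantile association test


@dataclass
class AssociationResult:
    event_class: str
    property: str
    n_obs: int
    ks_statistic: float  # signed: positive = enriched at high property values
    p: float
    q: Optional[float]
    median_quantile: float
    underpowered: bool = False


def _one_position_per_junction(
    junctions: Sequence[Junction], rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Randomly choose one side of each junction to reduce dependence."""
    out = []
    for j in junctions:
        bk = j.a if rng.random() < 0.5 else j.b
        out.append((bk.chrom, bk.pos))
    return out


def property_quantile_test(
    breakpoints: Sequence[tuple[str, int]],
    track: PropertyTrack,
    grid: PixelGrid,
    n_random: int = 1_000_000,
    seed: int = 0,
    event_class: str = "",
) -> AssociationResult:
    """Rank-based KS test of breakpoint property values against random positions.

    Observed pixel values are pooled with *n_random* uniform draws from the
    covered pixels, jointly rank-transformed to [0, 1] (mid-ranks for ties),
    and the observed quantiles compared to Uniform(0, 1) with the larger of
    the two one-sided KS statistics, reported with a sign (positive when
    breakpoints sit at high property values).
    """
    rng = np.random.default_rng(seed)
    covered_idx = np.flatnonzero(track.covered)
    if len(covered_idx) == 0:
        raise ValueError("track has no covered pixels")
    obs_idx = [grid.pixel_index(c, p) for c, p in breakpoints]
    obs_vals = track.values[obs_idx]
    keep = ~np.isnan(obs_vals)
    obs_vals = obs_vals[keep]
    rand_vals = track.values[rng.choice(covered_idx, size=n_random, replace=True)]

    pooled = np.concatenate([obs_vals, rand_vals])
    ranks = stats.rankdata(pooled, method="average")
    quantiles = (ranks - 0.5) / len(pooled)
    obs_q = quantiles[: len(obs_vals)]

    if len(obs_q) == 0:
        return AssociationResult(event_class, track.name, 0, 0.0, 1.0, None, 0.5, True)
    if np.ptp(pooled) == 0:  # constant track: every quantile is the mid-rank 0.5
        return AssociationResult(
            event_class, track.name, len(obs_q), 0.0, 1.0, None, 0.5,
            len(obs_q) < 10,
        )
    res_greater = stats.ks_1samp(obs_q, stats.uniform.cdf, alternative="greater")
    res_less = stats.ks_1samp(obs_q, stats.uniform.cdf, alternative="less")
    # D+ (alternative="greater") is large when the observed quantiles pile up
    # LOW; D- (alternative="less") when they pile up HIGH.  Sign: positive =
    # enriched at high property values.
    if res_greater.statistic >= res_less.statistic:
        stat, p = res_greater.statistic, res_greater.pvalue
        signed = -stat
    else:
        stat, p = res_less.statistic, res_less.pvalue
        signed = stat
    # the direction was chosen from the data: correct the one-sided p for the
    # two-way selection so the reported p is calibrated under the null
    p = min(1.0, 2.0 * p)
    return AssociationResult(
        event_class=event_class,
        property=track.name,
        n_obs=len(obs_q),
        ks_statistic=float(signed),
        p=float(p),
        q=None,
        median_quantile=float(np.median(obs_q)),
        underpowered=len(obs_q) < 10,
    )


def association_suite(
    classified_breakpoints: dict[str, Sequence[tuple[str, int]]],
    tracks: Sequence[PropertyTrack],
    grid: PixelGrid,
    alpha: float = 0.01,
    n_random: int = 1_000_000,
    seed: int = 0,
) -> list[AssociationResult]:
    """KS test for every (event class, property) pair with BY correction."""
    from statsmodels.stats.multitest import multipletests

    results = []
    for k, (cls, positions) in enumerate(sorted(classified_breakpoints.items())):
        for t, track in enumerate(tracks):
            results.append(
                property_quantile_test(
                    positions, track, grid, n_random=n_random,
                    seed=seed + 1009 * k + t, event_class=cls,
                )
            )
    if results:
        pvals = [r.p for r in results]
        _, qvals, _, _ = multipletests(pvals, method="fdr_by")
        for r, q in zip(results, qvals):
            r.q = float(q)
    for r in results:
        r.significant = (r.q is not None and r.q < alpha) and not r.underpowered
    return results


# ---------------------------------------------------------------------------
# Partner-permutation enrichment


@dataclass
class PartnerPermutationResult:
    pair: tuple[str, str]
    observed: int
    permuted_mean: float
    permuted_sd: float
    fold_change: float
    z: float
    degenerate: bool = False


def _pair_counts(labels_a, labels_b) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for la, lb in zip(labels_a, labels_b):
        key = tuple(sorted((la, lb)))
        counts[key] = counts.get(key, 0) + 1
    return counts


def partner_permutation_enrichment(
    junction_labels: Sequence[tuple[str, str]],
    n_perm: int = 1_000,
    seed: int = 0,
) -> list[PartnerPermutationResult]:
    """Enrichment of junctions joining particular annotation classes.

    *junction_labels* gives the annotation of each junction's two breakends.
    The permutation null preserves every breakend (position, side, label) but
    re-pairs breakends uniformly at random within the sample, so per-genome
    annotation composition is held fixed while partner choice is randomized.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    labels = [l for pair in junction_labels for l in pair]
    if len(labels) % 2 != 0:
        raise ValueError("odd breakend count")
    degenerate = len(junction_labels) < 2
    obs = _pair_counts([a for a, _ in junction_labels], [b for _, b in junction_labels])

    labels_arr = np.array(labels)
    perm_counts: dict[tuple[str, str], list[int]] = {}
    all_pairs = set(obs)
    perm_records = []
    for _ in range(n_perm):
        perm = rng.permutation(len(labels_arr))
        shuffled = labels_arr[perm]
        pc = _pair_counts(shuffled[0::2], shuffled[1::2])
        perm_records.append(pc)
        all_pairs.update(pc)
    results = []
    for pair in sorted(all_pairs):
        vals = np.array([pc.get(pair, 0) for pc in perm_records], dtype=float)
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        o = obs.get(pair, 0)
        fold = o / mean if mean > 0 else np.inf if o else 1.0
        z = (o - mean) / sd if sd > 0 else 0.0
        results.append(
            PartnerPermutationResult(pair, o, mean, sd, fold, z, degenerate)
        )
    return results


def footprint_connectivity(
    clusters, n_perm: int = 1_000, seed: int = 0
) -> list[PartnerPermutationResult]:
    """Connectivity enrichment between footprint structural types.

    Every junction joining two different footprints contributes the unordered
    pair of their local patterns; the same partner-permutation machinery then
    quantifies whether footprints of the same or similar structure connect
    more often than chance.
    """
    pairs = []
    for cluster in clusters:
        fp_of = {}
        for fp in cluster.footprints:
            for bk, j in fp.breakends:
                fp_of[(bk.chrom, bk.pos, bk.side, j.id)] = fp
        for j in cluster.junctions:
            fa = fp_of.get((j.a.chrom, j.a.pos, j.a.side, j.id))
            fb = fp_of.get((j.b.chrom, j.b.pos, j.b.side, j.id))
            if fa is not None and fb is not None and fa is not fb:
                pairs.append((fa.local_pattern, fb.local_pattern))
    results = partner_permutation_enrichment(pairs, n_perm=n_perm, seed=seed)
    types = {t for pair in pairs for t in pair}
    if len(types) <= 1:
        for r in results:
            r.degenerate = True
    return results


# ---------------------------------------------------------------------------
# Microhomology regimes


@dataclass
class MicrohomologyFit:
    """Three log-linear regimes of junction counts by microhomology length.

    Junctions with little or no homology arise by non-homologous end joining
    (NHEJ); a 2-7 bp regime reflects microhomology-mediated end joining
    (MMEJ); homologies of ~10 bp and beyond point to single-strand annealing
    (SSA) or other homologous-recombination-like mechanisms.
    """

    b1: int
    b2: int
    slopes: dict[str, float]
    intercepts: dict[str, float]
    rss: float

    REGIMES = ("NHEJ", "MMEJ", "SSA")

    def regime_of(self, homology_bp: int) -> str:
        if homology_bp < self.b1:
            return "NHEJ"
        if homology_bp < self.b2:
            return "MMEJ"
        return "SSA"


def fit_microhomology_regimes(
    homology_histogram: Sequence[float],
    b1_range: range = range(1, 9),
    b2_range: range = range(8, 16),
) -> MicrohomologyFit:
    """Grid search over integer changepoints (b1 < b2) fitting a least-squares
    line to log10(count + 1) within each regime; returns the global-RSS
    minimizer (first grid point on ties)."""
    counts = np.asarray(homology_histogram, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    if len(counts) <= min(b2_range):
        raise ValueError("histogram shorter than minimum b2")
    x = np.arange(len(counts), dtype=float)
    y = np.log10(counts + 1.0)

    def seg_fit(lo: int, hi: int):
        xs, ys = x[lo:hi], y[lo:hi]
        if len(xs) == 0:
            return 0.0, 0.0, 0.0
        if len(xs) == 1:
            return 0.0, ys[0], 0.0
        slope, intercept = np.polyfit(xs, ys, 1)
        resid = ys - (slope * xs + intercept)
        return slope, intercept, float(resid @ resid)

    best = None
    for b1 in b1_range:
        for b2 in b2_range:
            if not (1 <= b1 < b2 < len(counts)):
                continue
            fits = [seg_fit(0, b1), seg_fit(b1, b2), seg_fit(b2, len(counts))]
            rss = sum(f[2] for f in fits)
            if best is None or rss < best[0] - 1e-12:
                best = (rss, b1, b2, fits)
    if best is None:
        raise ValueError("no valid changepoint pair in the given ranges")
    rss, b1, b2, fits = best
    slopes = dict(zip(MicrohomologyFit.REGIMES, (f[0] for f in fits)))
    intercepts = dict(zip(MicrohomologyFit.REGIMES, (f[1] for f in fits)))
    return MicrohomologyFit(b1, b2, slopes, intercepts, rss)
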