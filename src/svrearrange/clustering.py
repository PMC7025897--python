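"""Pre-filtering of junctions and grouping into clusters and footprints.

A cluster is a set of junctions whose breakpoints are significantly closer
together than expected by chance given the number of breakpoints in the
genome.  The null model is a homogeneous Poisson process of breakpoints at
rate ``lambda = n_breakpoints / callable_size``: the nearest-neighbour
distance D then satisfies ``P(D <= d) = 1 - exp(-lambda * d)``, and two
breakends from *different* junctions merge when that probability falls below
``p_merge``.  The two breakends of one junction are always co-clustered, but
their own separation is excluded from the merge statistic, so a large simple
deletion stays a single cluster regardless of its span.  Maximal
proximity-linked runs of breakends on one chromosome form footprints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .genome_model import (
    CNSegment,
    Junction,
    LEFT,
    RIGHT,
    SVSet,
    chrom_sort_key,
)

DEFAULT_P_MERGE = 1e-3
DEFAULT_BYPASS_TOL_BP = 50
DEFAULT_FOLDBACK_MAX_SPAN_BP = 5_000
DEFAULT_FOLDBACK_CN_WINDOW_BP = 10_000
DEFAULT_BALANCED_OVERLAP_BP = 100

BALANCED_OVERLAP = "balanced_overlap"
CANDIDATE_SHORT_INSERTION = "candidate_short_insertion"
PLAIN = "plain"


@dataclass(frozen=True)
class ClusterModel:
    """Poisson null for breakpoint proximity."""

    n_breakpoints: int
    callable_size: float
    p_merge: float = DEFAULT_P_MERGE

    def __post_init__(self):
        if self.callable_size <= 0:
            raise ValueError("callable_size must be > 0")
        if not 0 < self.p_merge < 1:
            raise ValueError("p_merge must be in (0, 1)")

    @property
    def rate(self) -> float:
        return self.n_breakpoints / self.callable_size

    def merge_p(self, d: float) -> float:
        """P(nearest-neighbour distance <= d) under the uniform null."""
        return 1.0 - math.exp(-self.rate * d)

    @property
    def critical_distance(self) -> float:
        """Distance below which a pair merges: solves merge_p(d) = p_merge."""
        if self.n_breakpoints == 0:
            return 0.0
        return -math.log1p(-self.p_merge) / self.rate


@dataclass
class Footprint:
    """A contiguous run of co-clustered breakends on one chromosome."""

    id: str
    chrom: str
    start: int
    end: int
    breakends: list  # list of (Breakend, Junction)

    @property
    def local_pattern(self) -> str:
        return "".join(bk.code for bk, _ in self.breakends)

    @property
    def n_breakends(self) -> int:
        return len(self.breakends)


@dataclass
class Cluster:
    id: str
    sample: str
    junctions: list[Junction]
    footprints: list[Footprint] = field(default_factory=list)

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    @property
    def chroms(self) -> set[str]:
        return {bk.chrom for j in self.junctions for bk in j.breakends}

    @property
    def span_bp(self) -> Optional[int]:
        """Overall span when all footprints share one chromosome, else None."""
        if len({f.chrom for f in self.footprints}) != 1:
            return None
        return max(f.end for f in self.footprints) - min(f.start for f in self.footprints)


# ---------------------------------------------------------------------------
# Step 2: segment-bypassing removal


def _cn_boundaries(cn: Sequence[CNSegment]) -> set[tuple[str, int]]:
    bounds = set()
    for seg in cn:
        bounds.add((seg.chrom, seg.start))
        bounds.add((seg.chrom, seg.end))
    return bounds


def remove_segment_bypassing(
    junctions: Sequence[Junction],
    cn: Sequence[CNSegment],
    tol_bp: int = DEFAULT_BYPASS_TOL_BP,
) -> tuple[list[Junction], list[dict]]:
    """Remove junctions whose breakends are redundantly explained by a path
    of >= 2 other junctions chained across copy-number segments.

    Two junction ends chain when one ends a segment the other begins: a
    ``left`` breakend at position p connects to a ``right`` breakend within
    *tol_bp* of p on the same chromosome (and vice versa).  A junction J is a
    bypass when such a chain of other junctions runs from a breakend matching
    J's first end (same side, within tol) to one matching its second.
    Returns (kept junctions, removal log with the bypassing paths).
    """
    kept: list[Junction] = []
    removed_log: list[dict] = []

    def matches(x, y) -> bool:
        return x.chrom == y.chrom and x.side == y.side and abs(x.pos - y.pos) <= tol_bp

    def complements(x, y) -> bool:
        return x.chrom == y.chrom and x.side != y.side and abs(x.pos - y.pos) <= tol_bp

    for j in junctions:
        others = [o for o in junctions if o is not j]
        # BFS over chains of other junctions
        starts = [(o, end) for o in others for end in (0, 1)
                  if matches(o.breakends[end], j.a)]
        found = None
        queue = [(o, end, [o]) for o, end in starts]
        seen = set()
        while queue and found is None:
            o, entry_end, path = queue.pop()
            exit_bk = o.breakends[1 - entry_end]
            if len(path) >= 2 and matches(exit_bk, j.b):
                found = path
                break
            if len(path) > len(others):
                continue
            for o2 in others:
                if o2 in path:
                    continue
                for end2 in (0, 1):
                    if complements(exit_bk, o2.breakends[end2]):
                        key = (id(o2), end2, id(o))
                        if key in seen:
                            continue
                        seen.add(key)
                        queue.append((o2, end2, path + [o2]))
        if found is not None:
            removed_log.append({"junction": j.id, "bypassed_by": [o.id for o in found]})
        else:
            kept.append(j)
    return kept, removed_log


# ---------------------------------------------------------------------------
# Step 6: fold-back artefact filtering


def _has_cn_step_near(
    cn: Sequence[CNSegment], chrom: str, pos: int, window_bp: int, min_step: float = 0.5
) -> bool:
    segs = sorted(
        (s for s in cn if s.chrom == chrom), key=lambda s: s.start
    )
    for s1, s2 in zip(segs, segs[1:]):
        boundary = s1.end
        if abs(boundary - pos) <= window_bp and abs(s2.total_cn - s1.total_cn) >= min_step:
            return True
    return False


def filter_foldback_artefacts(
    junctions: Sequence[Junction],
    cn: Sequence[CNSegment],
    max_span_bp: int = DEFAULT_FOLDBACK_MAX_SPAN_BP,
    cn_window_bp: int = DEFAULT_FOLDBACK_CN_WINDOW_BP,
) -> list[Junction]:
    """Drop short inverted (fold-back type) junctions lacking copy-number
    support: an inverted junction spanning < *max_span_bp* is kept only if a
    total-CN step of >= 0.5 lies within *cn_window_bp* of its fold-back point."""
    out = []
    for j in junctions:
        if j.is_inverted and j.span is not None and j.span < max_span_bp:
            fold_point = (j.a.pos + j.b.pos) // 2
            if not _has_cn_step_near(cn, j.a.chrom, fold_point, cn_window_bp):
                continue
        out.append(j)
    return out


# ---------------------------------------------------------------------------
# Step 7: balanced overlapping breakpoints


def resolve_balanced_overlaps(
    junctions: Sequence[Junction],
    max_overlap_bp: int = DEFAULT_BALANCED_OVERLAP_BP,
) -> dict[str, str]:
    """Tag junction pairs as mutually balanced overlaps or as candidates for
    very short templated insertions.

    Two junctions sharing both breakend loci (within *max_overlap_bp*) with
    reciprocal sides are ``balanced_overlap``; two junctions delimiting a
    shared segment shorter than *max_overlap_bp* whose outer ends reach
    elsewhere are ``candidate_short_insertion``; the rest are ``plain``.
    Returns junction id -> tag.
    """
    tags = {j.id: PLAIN for j in junctions}

    def near(x, y) -> bool:
        return x.chrom == y.chrom and abs(x.pos - y.pos) <= max_overlap_bp

    def shared_segment(x, y) -> bool:
        """The two ends delimit a retained segment: right side at the lower
        position, left side at the higher (the hallmark of an inserted
        template, as opposed to a gap between overlapping balanced ends)."""
        lo, hi = (x, y) if x.pos <= y.pos else (y, x)
        return hi.pos > lo.pos and lo.side == RIGHT and hi.side == LEFT

    for i, j1 in enumerate(junctions):
        for j2 in junctions[i + 1:]:
            # both loci shared within tolerance, sides reciprocal at each
            if (
                near(j1.a, j2.a) and near(j1.b, j2.b)
                and j1.a.side != j2.a.side and j1.b.side != j2.b.side
            ):
                if shared_segment(j1.a, j2.a) or shared_segment(j1.b, j2.b):
                    tag = CANDIDATE_SHORT_INSERTION
                else:
                    tag = BALANCED_OVERLAP
                tags[j1.id] = tags[j2.id] = tag
    return tags


# ---------------------------------------------------------------------------
# Step 4: clustering


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def default_callable_size(build) -> float:
    """90% of the build length: a generic stand-in for the callable genome."""
    return 0.9 * build.total_length


def cluster_junctions(
    sv_set: SVSet,
    p_merge: float = DEFAULT_P_MERGE,
    callable_size: Optional[float] = None,
) -> list[Cluster]:
    """Agglomerate junctions into clusters and footprints (see module docs).

    Single-linkage over breakends on each chromosome: adjacent breakends from
    different junctions merge when their distance d gives
    ``1 - exp(-lambda d) < p_merge``.  Ties are resolved deterministically by
    coordinate order.
    """
    junctions = sorted(
        sv_set.junctions, key=lambda j: (j.a.sort_key(), j.b.sort_key(), j.id)
    )
    if not junctions:
        return []
    if callable_size is None:
        callable_size = default_callable_size(sv_set.build)
    model = ClusterModel(2 * len(junctions), callable_size, p_merge)
    d_crit = model.critical_distance

    uf = _UnionFind(len(junctions))
    # breakends annotated with their junction index
    bends: list[tuple] = []
    for ji, j in enumerate(junctions):
        bends.append((j.a, ji))
        bends.append((j.b, ji))
    bends.sort(key=lambda t: (chrom_sort_key(t[0].chrom), t[0].pos, t[0].side, t[1]))

    for (b1, j1), (b2, j2) in zip(bends, bends[1:]):
        if b1.chrom != b2.chrom or j1 == j2:
            continue
        if model.merge_p(b2.pos - b1.pos) < p_merge:
            uf.union(j1, j2)

    groups: dict[int, list[int]] = {}
    for ji in range(len(junctions)):
        groups.setdefault(uf.find(ji), []).append(ji)

    clusters = []
    for gi, (root, members) in enumerate(sorted(groups.items())):
        cluster = Cluster(
            id=f"{sv_set.sample}.c{gi + 1}",
            sample=sv_set.sample,
            junctions=[junctions[ji] for ji in members],
        )
        cluster.footprints = _build_footprints(cluster, d_crit)
        clusters.append(cluster)
    return clusters


def _build_footprints(cluster: Cluster, d_crit: float) -> list[Footprint]:
    """Maximal runs of member breakends with adjacent gaps below d_crit."""
    bends = sorted(
        ((bk, j) for j in cluster.junctions for bk in j.breakends),
        key=lambda t: (chrom_sort_key(t[0].chrom), t[0].pos, t[0].side),
    )
    footprints: list[Footprint] = []
    run: list = []
    for item in bends:
        bk, _ = item
        if run and (bk.chrom != run[-1][0].chrom or bk.pos - run[-1][0].pos >= d_crit):
            footprints.append(_finish_footprint(cluster, footprints, run))
            run = []
        run.append(item)
    if run:
        footprints.append(_finish_footprint(cluster, footprints, run))
    return footprints


def _finish_footprint(cluster: Cluster, existing: list, run: list) -> Footprint:
    return Footprint(
        id=f"{cluster.id}.f{len(existing) + 1}",
        chrom=run[0][0].chrom,
        start=run[0][0].pos,
        end=run[-1][0].pos,
        breakends=list(run),
    )


# ---------------------------------------------------------------------------
# Step 5: heuristic refinement


def _interval_cn(cn: Sequence[CNSegment], chrom: str, lo: int, hi: int) -> Optional[float]:
    total = weight = 0.0
    for s in cn:
        if s.chrom != chrom:
            continue
        ov = min(hi, s.end) - max(lo, s.start)
        if ov > 0:
            total += ov * s.total_cn
            weight += ov
    return total / weight if weight else None


def _is_simple_cn_consistent(
    j: Junction, cn: Sequence[CNSegment], background_cn: float
) -> bool:
    """Deletion- or TD-orientation junction whose interior CN matches."""
    from .genome_model import DEL_LIKE, TD_LIKE

    oc = j.orientation_class
    if oc not in (DEL_LIKE, TD_LIKE) or j.span is None or j.span < 2:
        return False
    interior = _interval_cn(cn, j.a.chrom, min(j.a.pos, j.b.pos) + 1, max(j.a.pos, j.b.pos))
    if interior is None:
        return False
    expected = background_cn - 1 if oc == DEL_LIKE else background_cn + 1
    return abs(interior - expected) < 0.5


def refine_clusters(
    clusters: Sequence[Cluster],
    cn: Sequence[CNSegment],
    background_cn: float,
    d_crit: float,
) -> list[Cluster]:
    """Heuristic refinement: (a) split clusters that decompose into
    independent CN-consistent simple events with no interleaving partner
    breakends; (b) merge clusters whose footprints overlap."""
    # (a) split
    split: list[Cluster] = []
    for cluster in clusters:
        if cluster.n_junctions < 2:
            split.append(cluster)
            continue
        all_bends = [(bk, j) for j in cluster.junctions for bk in j.breakends]
        peel: list[Junction] = []
        for j in cluster.junctions:
            if not _is_simple_cn_consistent(j, cn, background_cn):
                continue
            lo, hi = j.a.pos, j.b.pos
            interior_others = [
                bk for bk, oj in all_bends if oj is not j
                and bk.chrom == j.a.chrom and lo < bk.pos < hi
            ]
            # a breakend of another junction at (almost) the same position
            # indicates a phased structure, not an independent simple event
            shared_locus = any(
                oj is not j and bk.chrom == own.chrom
                and abs(bk.pos - own.pos) <= DEFAULT_BALANCED_OVERLAP_BP
                for bk, oj in all_bends for own in j.breakends
            )
            if not interior_others and not shared_locus:
                peel.append(j)
        rest = [j for j in cluster.junctions if j not in peel]
        if peel and rest or len(peel) > 1:
            parts = [[j] for j in peel]
            if rest:
                parts.append(rest)
            for pi, part in enumerate(parts):
                sub = Cluster(
                    id=f"{cluster.id}.s{pi + 1}", sample=cluster.sample, junctions=part
                )
                sub.footprints = _build_footprints(sub, d_crit)
                split.append(sub)
        else:
            split.append(cluster)

    # (b) merge overlapping footprints
    uf = _UnionFind(len(split))
    for i, c1 in enumerate(split):
        for k in range(i + 1, len(split)):
            c2 = split[k]
            for f1 in c1.footprints:
                if any(
                    f1.chrom == f2.chrom and f1.start <= f2.end and f2.start <= f1.end
                    for f2 in c2.footprints
                ):
                    uf.union(i, k)
                    break
    groups: dict[int, list[int]] = {}
    for i in range(len(split)):
        groups.setdefault(uf.find(i), []).append(i)
    merged = []
    for gi, (root, members) in enumerate(sorted(groups.items())):
        if len(members) == 1:
            merged.append(split[members[0]])
            continue
        junctions = [j for i in members for j in split[i].junctions]
        cluster = Cluster(
            id=f"{split[members[0]].id}+m", sample=split[members[0]].sample,
            junctions=junctions,
        )
        cluster.footprints = _build_footprints(cluster, d_crit)
        merged.append(cluster)
    return merged


def filter_and_cluster(
    sv_set: SVSet,
    p_merge: float = DEFAULT_P_MERGE,
    callable_size: Optional[float] = None,
    bypass_tol_bp: int = DEFAULT_BYPASS_TOL_BP,
) -> tuple[list[Cluster], dict]:
    """Full pre-filtering + clustering + refinement pipeline for one sample.

    Returns (clusters, log dict with removal records and overlap tags).
    """
    if callable_size is None:
        callable_size = default_callable_size(sv_set.build)
    junctions, bypass_log = remove_segment_bypassing(
        sv_set.junctions, sv_set.segments, bypass_tol_bp
    )
    junctions = filter_foldback_artefacts(junctions, sv_set.segments)
    overlap_tags = resolve_balanced_overlaps(junctions)
    filtered = SVSet(
        sample=sv_set.sample, junctions=junctions, segments=sv_set.segments,
        build=sv_set.build, background_cn=sv_set.background_cn,
    )
    clusters = cluster_junctions(filtered, p_merge, callable_size)
    model = ClusterModel(2 * len(junctions) if junctions else 0, callable_size, p_merge)
    d_crit = model.critical_distance if junctions else 0.0
    clusters = refine_clusters(clusters, sv_set.segments, sv_set.background_cn, d_crit)
    return clusters, {"bypass_removed": bypass_log, "overlap_tags": overlap_tags}


def write_clusters_tsv(clusters: Iterable[Cluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tsample\tn_junctions\tfootprints\tjunction_ids\n")
        for c in clusters:
            fps = ";".join(
                f"{f.chrom}:{f.start}-{f.end}({f.local_pattern})" for f in c.footprints
            )
            fh.write(
                f"{c.id}\t{c.sample}\t{c.n_junctions}\t{fps}\t"
                + ",".join(j.id for j in c.junctions) + "\n"
            )
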