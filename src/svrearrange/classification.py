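"""Cluster classification: assigning each cluster an event class.

Junction orientation alone does not determine the event class — a
deletion-type junction inside a complex cluster is not a deletion.  Clusters
are therefore classified from their full context: junction orientations,
copy-number changes at and between breakends, reconstruction of
templated-insertion paths over a segment graph, and canonical-pattern
matching against the configuration library.

The templated-insertion classes describe strings of duplicated templates
inserted into a single derivative (host) chromosome:

* cycle  — the string returns to the host, re-replicating a host segment;
* bridge — the string returns, leaving a deleted gap on the host;
* chain  — the string never returns, ending on two different chromosomes at
  unbalanced copy-number transitions.

Every reported path is replayed as an explicit derivative chromosome and the
junctions and copy-number gains it would emit are compared against the
cluster (the module's internal oracle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

from . import _derivative as dv
from .clustering import Cluster, filter_and_cluster
from .config_library import ConfigLibrary, match_cluster, pattern_key, pattern_key_of
from .genome_model import (
    CNSegment,
    DEL_LIKE,
    HEAD_HEAD,
    INTERCHROM,
    LEFT,
    RIGHT,
    SVSet,
    TAIL_TAIL,
    TD_LIKE,
    chrom_sort_key,
)

log = logging.getLogger(__name__)

EVENT_CLASSES = [
    "deletion",
    "tandem_duplication",
    "reciprocal_inversion",
    "reciprocal_translocation",
    "unbalanced_translocation",
    "foldback_inversion",
    "templated_insertion_cycle",
    "templated_insertion_bridge",
    "templated_insertion_chain",
    "local_2jump_dup_trp_dup",
    "local_2jump_inverted_dups",
    "local_2jump_del_invdup",
    "local_n_jump",
    "local_distant",
    "chromoplexy",
    "chromothripsis_like",
    "complex_unclassified",
]

CN_FLAT_THRESHOLD = 0.5  # |step| below this counts as flat (consensus CN is real-valued)
FOLDBACK_SPAN_BP = 5_000
LOCAL_SPAN_BP = 1_000_000
RECIPROCAL_TOL_BP = 100
CHROMOTHRIPSIS_MIN_JUNCTIONS = 10
CHROMOTHRIPSIS_MIN_OSCILLATIONS = 10


@dataclass
class SegmentGraph:
    """CN intervals between consecutive cluster breakends, plus junction links."""

    cluster: Cluster
    background_cn: float
    # per chromosome: sorted list of (pos, side, junction_index, end_index)
    bends: dict[str, list[tuple[int, str, int, int]]]
    # (chrom, lo, hi) -> integer CN gain relative to background
    gains: dict[tuple[str, int, int], int]

    def gain_between(self, chrom: str, lo: int, hi: int) -> Optional[int]:
        return self.gains.get((chrom, lo, hi))


@dataclass
class TemplatedInsertionPath:
    host_chrom: Optional[str]
    host_breakends: tuple
    templates: list[tuple[str, int, int, str, int]]  # chrom, lo, hi, orientation, cn_gain
    topology: str  # cycle | bridge | chain


@dataclass
class Classification:
    cluster_id: str
    event_class: str
    n_junctions: int
    details: dict = field(default_factory=dict)
    cluster: Optional[Cluster] = None

    @property
    def is_complex_cluster(self) -> bool:
        return self.n_junctions > 1


# ---------------------------------------------------------------------------
# CN helpers (accept either a raw segment list or a prebuilt CNIndex)

from .genome_model import CNIndex


def _ensure_index(cn) -> CNIndex:
    return cn if isinstance(cn, CNIndex) else CNIndex(cn)


def _interval_cn(cn, chrom: str, lo: int, hi: int) -> Optional[float]:
    return _ensure_index(cn).interval_mean(chrom, lo, hi)


def _cn_at(cn, chrom: str, pos: int) -> Optional[float]:
    return _ensure_index(cn).at(chrom, pos)


def _step_at(cn: Sequence[CNSegment], chrom: str, pos: int, w: int = 2) -> Optional[float]:
    """CN difference across a breakend (query just left vs just right)."""
    left = _cn_at(cn, chrom, pos - w)
    right = _cn_at(cn, chrom, pos + w)
    if left is None or right is None:
        return None
    return right - left


def _flat_at(cn, chrom, pos) -> bool:
    step = _step_at(cn, chrom, pos)
    return step is not None and abs(step) < CN_FLAT_THRESHOLD


# ---------------------------------------------------------------------------
# Segment graph


def build_segment_graph(
    cluster: Cluster, cn: Sequence[CNSegment], background_cn: float
) -> SegmentGraph:
    """Intervals between consecutive breakends, annotated with integer CN gain.

    A breakend further than 10 kb from any CN segment boundary triggers a
    warning; the boundary is imputed at the breakend itself (the gain is read
    from the covering segments either way).
    """
    cn = _ensure_index(cn)
    bends: dict[str, list[tuple[int, str, int, int]]] = {}
    for ji, j in enumerate(cluster.junctions):
        for ei, bk in enumerate(j.breakends):
            bends.setdefault(bk.chrom, []).append((bk.pos, bk.side, ji, ei))
            boundaries = cn.boundaries(bk.chrom)
            if boundaries and min(abs(b - bk.pos) for b in boundaries) > 10_000:
                log.warning(
                    "breakend %s:%d is >10 kb from any CN boundary; imputing",
                    bk.chrom, bk.pos,
                )
    gains: dict[tuple[str, int, int], int] = {}
    for chrom, items in bends.items():
        items.sort()
        for (p1, *_), (p2, *_) in zip(items, items[1:]):
            if p2 > p1:
                val = _interval_cn(cn, chrom, p1 + 1, p2 + 1)
                if val is not None:
                    gains[(chrom, p1, p2)] = round(val - background_cn)
    return SegmentGraph(cluster, background_cn, bends, gains)


# ---------------------------------------------------------------------------
# Templated-insertion path search


def find_templated_insertion_path(
    graph: SegmentGraph, cn: Sequence[CNSegment]
) -> Optional[TemplatedInsertionPath]:
    """Search for an alternating walk (junction, gained segment, junction, ...)
    using every cluster junction once, with every interior segment gained.

    Ties between valid walks are broken by maximal junction coverage (always
    all, by construction), then minimal template count, then lexicographic
    order of the walk — deterministic.
    """
    cluster = graph.cluster
    n = cluster.n_junctions
    if n < 2:
        return None

    partner = {}
    bk_of = {}
    for ji, j in enumerate(cluster.junctions):
        partner[(ji, 0)] = (ji, 1)
        partner[(ji, 1)] = (ji, 0)
        bk_of[(ji, 0)] = j.a
        bk_of[(ji, 1)] = j.b

    # template traversal edges between adjacent breakends delimiting a gained segment
    seg_edge: dict[tuple[int, int], tuple[tuple[int, int], tuple[str, int, int, int]]] = {}
    for chrom, items in graph.bends.items():
        for (p1, s1, j1, e1), (p2, s2, j2, e2) in zip(items, items[1:]):
            if s1 == RIGHT and s2 == LEFT and p2 > p1:
                gain = graph.gain_between(chrom, p1, p2)
                if gain is not None and gain >= 1:
                    tpl = (chrom, p1, p2, gain)
                    seg_edge[(j1, e1)] = ((j2, e2), tpl)
                    seg_edge[(j2, e2)] = ((j1, e1), tpl)

    best = None  # (n_templates, walk_key, start, end, templates)

    def dfs(start, current, used: frozenset, templates: tuple, walk: tuple):
        nonlocal best
        ji, _ = current
        if ji in used:
            return
        arrived = partner[current]
        used2 = used | {ji}
        walk2 = walk + (current, arrived)
        if len(used2) == n:
            cand = (len(templates), walk2, start, arrived, templates)
            if best is None or cand[:2] < best[:2]:
                best = cand
            return
        nxt = seg_edge.get(arrived)
        if nxt is not None:
            dest, tpl = nxt
            if dest[0] not in used2:
                # entering at the segment's low end means the template is
                # copied in forward orientation along the walk
                orient = "forward" if bk_of[arrived].pos == tpl[1] else "reverse"
                dfs(start, dest, used2, templates + (tpl + (orient,),), walk2)

    starts = sorted(partner, key=lambda be: (bk_of[be].sort_key(), be))
    for s in starts:
        dfs(s, s, frozenset(), (), ())
    if best is None:
        return None

    _, _, start, end, templates = best
    a, z = bk_of[start], bk_of[end]
    template_list = [
        (chrom, lo, hi, orient, gain) for chrom, lo, hi, gain, orient in templates
    ]

    if a.chrom == z.chrom:
        lo_bk, hi_bk = (a, z) if a.pos <= z.pos else (z, a)
        val = _interval_cn(cn, a.chrom, lo_bk.pos + 1, hi_bk.pos + 1)
        rel = None if val is None else round(val - graph.background_cn)
        if lo_bk.side == RIGHT and hi_bk.side == LEFT and rel is not None and rel >= 1:
            return TemplatedInsertionPath(a.chrom, (a, z), template_list, "cycle")
        if lo_bk.side == LEFT and hi_bk.side == RIGHT and (rel is None or rel <= -1):
            return TemplatedInsertionPath(a.chrom, (a, z), template_list, "bridge")
        return None
    # ends on two different chromosomes: chain, if both transitions unbalanced
    if not template_list:
        return None
    for bk in (a, z):
        step = _step_at(cn, bk.chrom, bk.pos)
        if step is None or abs(step) < CN_FLAT_THRESHOLD:
            return None
    return TemplatedInsertionPath(None, (a, z), template_list, "chain")


# ---------------------------------------------------------------------------
# Path replay oracle


def replay_path(
    path: TemplatedInsertionPath, cluster: Cluster, build
) -> tuple[list, dict]:
    """Rebuild the derivative chromosome a path implies and emit its junctions
    and CN deltas.  Shared consistency oracle with the simulator."""
    a, z = path.host_breakends
    pieces = []
    consumed = []
    if path.topology in ("cycle", "bridge"):
        host = path.host_chrom
        length = build.lengths[host]
        consumed.append((host, 0, length))
        head_bk, tail_bk = (a, z) if a.side == LEFT else (z, a)
        pieces.append(dv.Piece(host, 0, head_bk.pos + 1, True))
        mids, tail = _template_pieces(path, head_bk)
        pieces.extend(mids)
        pieces.append(dv.Piece(host, tail_bk.pos, length, True))
    else:  # chain
        head_bk, tail_bk = (a, z) if a.side == LEFT else (z, a)
        len_a = build.lengths[head_bk.chrom]
        len_z = build.lengths[tail_bk.chrom]
        # losses beyond the unbalanced ends extend an unknowable distance;
        # consume only a window so they are asserted near the junctions and a
        # template sharing a chromosome with an end keeps its gain
        w = 10_000
        consumed.append((head_bk.chrom, 0, min(len_a, head_bk.pos + 1 + w)))
        consumed.append((tail_bk.chrom, max(0, tail_bk.pos - w), len_z))
        pieces.append(dv.Piece(head_bk.chrom, 0, head_bk.pos + 1, True))
        mids, _ = _template_pieces(path, head_bk)
        pieces.extend(mids)
        pieces.append(dv.Piece(tail_bk.chrom, tail_bk.pos, len_z, True))
    derivative = (tuple(pieces),)
    junctions = dv.emit_junctions(derivative)
    deltas = dv.cn_delta_profile(derivative, consumed)
    return junctions, deltas


def _template_pieces(path: TemplatedInsertionPath, head_bk):
    """Order/orient template pieces by chaining junctions from the head end."""
    # The walk recorded templates in traversal order starting from one end;
    # if the head breakend was the walk's end rather than start, reverse the
    # order and flip every orientation.
    templates = list(path.templates)
    a, _ = path.host_breakends
    flip = head_bk is not a
    if flip:
        templates = templates[::-1]
    pieces = [
        dv.Piece(chrom, lo, hi + 1, (orient == "forward") != flip)
        for chrom, lo, hi, orient, _ in templates
    ]
    return pieces, None


def path_replay_consistent(
    path: TemplatedInsertionPath, cluster: Cluster, cn: Sequence[CNSegment],
    background_cn: float, build, edge_window_bp: int = 10_000,
) -> bool:
    """True iff replaying the path regenerates the cluster's junctions exactly
    and every emitted CN delta matches the observed rounded gain.

    Delta intervals bounded by junctions on both sides (templates, the
    re-replicated or deleted host segment) are compared in full.  A loss that
    runs out to a chromosome end (the derivative keeps no material beyond the
    last junction) is compared over a window adjacent to its junction-bounded
    edge only: how far such a loss really extends is not encoded in the
    junctions and need not be reproduced by the path.
    """
    cn = _ensure_index(cn)
    emitted, deltas = replay_path(path, cluster, build)
    want = {frozenset(j.breakends) for j in cluster.junctions}
    got = {frozenset(pair) for pair in emitted}
    if want != got:
        return False
    cutpoints = {
        (bk.chrom, bk.pos + 1 if bk.side == LEFT else bk.pos)
        for pair in emitted for bk in pair
    }
    for chrom, intervals in deltas.items():
        for lo, hi, delta in intervals:
            spans = []
            lo_cut = (chrom, lo) in cutpoints
            hi_cut = (chrom, hi) in cutpoints
            if lo_cut and hi_cut:
                spans.append((lo, hi))
            elif lo_cut:
                spans.append((lo, min(hi, lo + edge_window_bp)))
            elif hi_cut:
                spans.append((max(lo, hi - edge_window_bp), hi))
            else:
                spans.append((lo, hi))
            for s, e in spans:
                val = _interval_cn(cn, chrom, s, e)
                if val is None or round(val - background_cn) != delta:
                    return False
    return True


# ---------------------------------------------------------------------------
# 2-jump reference patterns (canonical keys from explicit derivatives)


@lru_cache(maxsize=None)
def _two_jump_reference_keys() -> dict[str, str]:
    """Keys of the three local 2-jump structures, derived from reference
    derivative chromosomes (single-derivative phasings)."""
    consumed = [("A", 0, 7)]
    builds = {
        # dup - inverted triplication - dup: +1 / +2 / +1 with two inverted junctions
        "local_2jump_dup_trp_dup": (
            dv.Piece("A", 0, 4, True), dv.Piece("A", 3, 5, False), dv.Piece("A", 2, 7, True),
        ),
        # two duplications linked by inverted junctions
        "local_2jump_inverted_dups": (
            dv.Piece("A", 0, 3, True), dv.Piece("A", 4, 5, False), dv.Piece("A", 2, 7, True),
        ),
        # copy-number loss plus nearby duplication linked by inverted junctions
        "local_2jump_del_invdup": (
            dv.Piece("A", 0, 2, True), dv.Piece("A", 3, 5, False), dv.Piece("A", 4, 7, True),
        ),
    }
    return {
        name: pattern_key_of((pieces,), consumed).encoded
        for name, pieces in builds.items()
    }


# ---------------------------------------------------------------------------
# Per-cluster classification


def classify_cluster(
    cluster: Cluster,
    cn: Sequence[CNSegment],
    background_cn: float,
    library: Optional[ConfigLibrary] = None,
    build=None,
    local_span_bp: int = LOCAL_SPAN_BP,
) -> Classification:
    """Assign one event class per cluster (mutually exclusive, exhaustive)."""
    cn = _ensure_index(cn)
    try:
        cls, details = _classify(cluster, cn, background_cn, build, local_span_bp)
    except Exception as exc:  # a bad cluster must never abort the run
        log.warning("cluster %s: classification failed (%s)", cluster.id, exc)
        cls, details = "complex_unclassified", {"error": str(exc)}
    if library is not None:
        try:
            matches = match_cluster(cluster, cn, background_cn, library)
            details["library_matches"] = [
                ([op[0] for op in seq], n_ops) for seq, n_ops in matches
            ]
        except ValueError:
            details["library_matches"] = None
    details["footprints"] = [
        (f.chrom, f.start, f.end, f.local_pattern) for f in cluster.footprints
    ]
    return Classification(
        cluster_id=cluster.id, event_class=cls, n_junctions=cluster.n_junctions,
        details=details, cluster=cluster,
    )


def _classify(cluster, cn, background_cn, build, local_span_bp):
    juncs = cluster.junctions
    n = len(juncs)
    bg = background_cn

    missing_cn = any(
        _cn_at(cn, bk.chrom, bk.pos) is None for j in juncs for bk in j.breakends
    )
    if missing_cn:
        return "complex_unclassified", {"flag": "missing_cn"}

    # (1) single junction
    if n == 1:
        j = juncs[0]
        oc = j.orientation_class
        if oc in (DEL_LIKE, TD_LIKE):
            interior = _interval_cn(cn, j.a.chrom, j.a.pos + 1, j.b.pos + 1)
            if interior is not None:
                expected = bg - 1 if oc == DEL_LIKE else bg + 1
                if abs(interior - expected) < CN_FLAT_THRESHOLD:
                    cls = "deletion" if oc == DEL_LIKE else "tandem_duplication"
                    return cls, {"size_bp": j.span}
        if oc == INTERCHROM:
            steps = [_step_at(cn, bk.chrom, bk.pos) for bk in j.breakends]
            if all(s is not None and abs(s) >= CN_FLAT_THRESHOLD for s in steps):
                return "unbalanced_translocation", {}
        if j.is_inverted and j.span is not None and j.span < FOLDBACK_SPAN_BP:
            fold = (j.a.pos + j.b.pos) // 2
            from .clustering import _has_cn_step_near

            if _has_cn_step_near(cn.segments, j.a.chrom, fold, 10_000):
                return "foldback_inversion", {"size_bp": j.span}

    # (2) two junctions: reciprocal pairs and local 2-jump structures
    if n == 2:
        j1, j2 = juncs
        cls = _classify_pair(j1, j2, cn, bg)
        if cls is not None:
            return cls
        try:
            key = pattern_key(cluster, cn, bg).encoded
            for name, ref in _two_jump_reference_keys().items():
                if key == ref:
                    return name, {"size_bp": cluster.span_bp}
        except ValueError:
            pass

    # (3) templated-insertion path
    if n >= 2:
        graph = build_segment_graph(cluster, cn, bg)
        path = find_templated_insertion_path(graph, cn)
        if path is not None:
            details = {
                "topology": path.topology,
                "templates": path.templates,
                "template_span_bp": sum(hi - lo for _, lo, hi, _, _ in path.templates),
            }
            if build is not None:
                details["replay_consistent"] = path_replay_consistent(
                    path, cluster, cn, bg, build
                )
            details["path"] = path
            return f"templated_insertion_{path.topology}", details

    # (5) chromoplexy checked before the local catch-alls can only trigger for
    # multi-chromosome balanced chains, which are never "local"
    all_flat = all(_flat_at(cn, bk.chrom, bk.pos) for j in juncs for bk in j.breakends)
    n_chroms = len(cluster.chroms)
    if n >= 3 and all_flat and n_chroms >= 2:
        return "chromoplexy", {"n_chromosomes": n_chroms}

    # (6) chromothripsis-like: many junctions, oscillating CN on one chromosome
    if n >= CHROMOTHRIPSIS_MIN_JUNCTIONS:
        graph = build_segment_graph(cluster, cn, bg)
        for chrom, items in graph.bends.items():
            levels = [
                graph.gain_between(chrom, p1, p2)
                for (p1, *_), (p2, *_) in zip(items, items[1:])
            ]
            levels = [l for l in levels if l is not None]
            states = sorted(set(levels))
            if len(states) == 2:
                switches = sum(1 for a, b in zip(levels, levels[1:]) if a != b)
                if switches >= CHROMOTHRIPSIS_MIN_OSCILLATIONS:
                    return "chromothripsis_like", {"oscillations": switches}

    # (4) local catch-alls
    fps = cluster.footprints
    chroms = {f.chrom for f in fps}
    if len(chroms) == 1:
        span = max(f.end for f in fps) - min(f.start for f in fps)
        if span < local_span_bp:
            return "local_n_jump", {"n_jumps": n, "span_bp": span}
    if len(fps) >= 2:
        for i, distant in enumerate(fps):
            rest = [f for k, f in enumerate(fps) if k != i]
            rest_chroms = {f.chrom for f in rest}
            if len(rest_chroms) == 1:
                span = max(f.end for f in rest) - min(f.start for f in rest)
                far = distant.chrom not in rest_chroms or (
                    min(abs(distant.start - f.end) for f in rest) >= local_span_bp
                )
                if span < local_span_bp and far:
                    return "local_distant", {"n_jumps": n}

    # (7)
    return "complex_unclassified", {}


def _classify_pair(j1, j2, cn, bg):
    ocs = {j1.orientation_class, j2.orientation_class}
    flat = all(_flat_at(cn, bk.chrom, bk.pos) for j in (j1, j2) for bk in j.breakends)
    if ocs == {HEAD_HEAD, TAIL_TAIL} and j1.a.chrom == j2.a.chrom and flat:
        if (
            abs(j1.a.pos - j2.a.pos) <= RECIPROCAL_TOL_BP
            and abs(j1.b.pos - j2.b.pos) <= RECIPROCAL_TOL_BP
        ):
            return "reciprocal_inversion", {"size_bp": j1.span}
    if (
        ocs == {INTERCHROM}
        and {j1.a.chrom, j1.b.chrom} == {j2.a.chrom, j2.b.chrom}
        and flat
        and abs(j1.a.pos - j2.a.pos) <= RECIPROCAL_TOL_BP
        and abs(j1.b.pos - j2.b.pos) <= RECIPROCAL_TOL_BP
        and j1.a.side != j2.a.side
        and j1.b.side != j2.b.side
    ):
        return "reciprocal_translocation", {}
    return None


# ---------------------------------------------------------------------------
# Whole-sample classification


def classify_all(
    sv_set: SVSet,
    library: Optional[ConfigLibrary] = None,
    p_merge: float = 1e-3,
    callable_size: Optional[float] = None,
) -> tuple[list[Classification], dict[str, int], list[dict]]:
    """Filters -> clustering -> refinement -> per-cluster classification.

    Returns (classifications, per-sample class counts, per-breakpoint table
    recording simple vs complex-cluster membership).
    """
    clusters, _ = filter_and_cluster(sv_set, p_merge=p_merge, callable_size=callable_size)
    cn_index = _ensure_index(sv_set.segments)
    classifications = []
    counts = {c: 0 for c in EVENT_CLASSES}
    bp_table = []
    for cluster in clusters:
        result = classify_cluster(
            cluster, cn_index, sv_set.background_cn, library, sv_set.build
        )
        classifications.append(result)
        counts[result.event_class] += 1
        for j in cluster.junctions:
            for bk in j.breakends:
                bp_table.append(
                    {
                        "sample": sv_set.sample,
                        "junction": j.id,
                        "chrom": bk.chrom,
                        "pos": bk.pos,
                        "cluster": cluster.id,
                        "event_class": result.event_class,
                        "complex_cluster": result.is_complex_cluster,
                    }
                )
    return classifications, counts, bp_table


def write_classifications_tsv(classifications: Sequence[Classification], sample, path):
    import json

    with open(path, "w") as fh:
        fh.write("cluster_id\tsample\tevent_class\tn_junctions\tfootprints\tdetails\n")
        for c in classifications:
            fps = ";".join(
                f"{ch}:{s}-{e}({pat})" for ch, s, e, pat in c.details.get("footprints", [])
            )
            details = {
                k: v for k, v in c.details.items() if k not in ("footprints", "path")
            }
            fh.write(
                f"{c.cluster_id}\t{sample}\t{c.event_class}\t{c.n_junctions}\t{fps}\t"
                + json.dumps(details, default=str) + "\n"
            )
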