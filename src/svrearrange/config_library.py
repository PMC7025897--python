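"""Enumeration of genomic configurations reachable by simple rearrangements.

The library answers: which observed cluster patterns can be produced by a
short sequence of simple operations (deletion, tandem duplication, inversion,
balanced/unbalanced translocation, chromosome gain/loss), and which cannot
(candidate copy-and-paste / complex events)?

Patterns are compared, not coordinates.  Enumeration therefore runs on an
abstract alphabet: reference chromosomes of a few unit-width segments, with
cuts placed at every distinct position.  Each resulting derivative genome is
reduced to a canonical :class:`PatternKey` — the per-chromosome sequence of
breakend sides and relative copy-number levels plus the junction wiring —
which is invariant under chromosome relabeling, global mirror reflection, and
junction input order.  Observed clusters are reduced to the same key, so a
dictionary lookup matches a cluster to all minimal generating sequences.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from . import _derivative as dv
from .genome_model import LEFT, RIGHT, Breakend, CNSegment

CN_CAP = 3  # relative copy-number levels in keys are capped at +/-3
FLANK_WINDOW_BP = 1_000_000  # window for reading flanking CN levels of observed clusters


@dataclass(frozen=True)
class PatternKey:
    """Canonical text encoding of a rearrangement pattern."""

    encoded: str

    def __str__(self) -> str:
        return self.encoded


def _cutpoint(bk: Breakend) -> int:
    """Half-open cut coordinate of a breakend (left side retains <= pos)."""
    return bk.pos + 1 if bk.side == LEFT else bk.pos


def _canonical_junctions(junctions: Sequence[tuple[Breakend, Breakend]]):
    """Sort junctions by breakend coordinates so keys ignore input order."""
    def jkey(j):
        aa = (j[0].chrom, _cutpoint(j[0]), j[0].side)
        bb = (j[1].chrom, _cutpoint(j[1]), j[1].side)
        return tuple(sorted((aa, bb)))

    return sorted(junctions, key=jkey)


def build_pattern_key(
    junctions: Sequence[tuple[Breakend, Breakend]],
    cn_level_fn: Callable[[str, Optional[int], Optional[int]], int],
    extra_boundaries: Optional[dict[str, list[int]]] = None,
    extra_chromosomes: Iterable[str] = (),
    max_permute: int = 6,
) -> PatternKey:
    """Reduce junctions plus relative CN levels to a canonical key.

    ``cn_level_fn(chrom, lo, hi)`` must return the integer CN level of the
    interval [lo, hi) relative to background; ``lo``/``hi`` of ``None`` denote
    the unbounded flanks.  *extra_boundaries* adds CN-step positions that are
    not breakends (derivative-chromosome termini in the abstract setting).
    """
    junctions = _canonical_junctions(junctions)
    # collapse exact duplicates (re-replicated junctions) into multiplicities
    multiplicity: dict[tuple, int] = {}
    unique: list[tuple[Breakend, Breakend]] = []
    for a, b in junctions:
        sig = (a, b)
        if sig in multiplicity:
            multiplicity[sig] += 1
        else:
            multiplicity[sig] = 1
            unique.append((a, b))
    junctions = unique
    # breakend -> (junction index, end index) at each cutpoint, per chromosome
    by_chrom: dict[str, dict[int, list[tuple[str, int, int]]]] = {}
    for ji, (a, b) in enumerate(junctions):
        for ei, bk in enumerate((a, b)):
            by_chrom.setdefault(bk.chrom, {}).setdefault(_cutpoint(bk), []).append(
                (bk.side, ji, ei)
            )
    for chrom in extra_chromosomes:
        by_chrom.setdefault(chrom, {})
    if extra_boundaries:
        for chrom, cuts in extra_boundaries.items():
            for cut in cuts:
                by_chrom.setdefault(chrom, {}).setdefault(cut, [])

    chroms = sorted(by_chrom)
    chrom_data = []
    for chrom in chroms:
        cuts = sorted(by_chrom[chrom])
        bends = [by_chrom[chrom][c] for c in cuts]
        bounds = [None] + cuts + [None]  # type: ignore[list-item]
        levels = []
        for lo, hi in zip(bounds, bounds[1:]):
            lv = cn_level_fn(chrom, lo, hi)
            levels.append(max(-CN_CAP, min(CN_CAP, int(lv))))
        chrom_data.append((bends, tuple(levels)))

    def serialize(order: Sequence[int], mirror: bool):
        # Fix the traversal; breakends that share a cutpoint and side are
        # interchangeable in the side strings but not in the wiring, so the
        # wiring is minimized over orderings within those tie groups.
        slot_groups: list[list[tuple[int, int]]] = []
        chrom_enc = []
        for ci in order:
            bends, levels = chrom_data[ci]
            if mirror:
                bends = list(reversed(bends))
                levels = tuple(reversed(levels))
            sides_enc = []
            for group in bends:
                grp = sorted(
                    ((RIGHT if s == LEFT else LEFT) if mirror else s, ji, ei)
                    for s, ji, ei in group
                )
                sides_enc.append(tuple(s for s, _, _ in grp))
                for side, members in itertools.groupby(grp, key=lambda t: t[0]):
                    slot_groups.append([(ji, ei) for _, ji, ei in members])
            chrom_enc.append((tuple(sides_enc), levels))

        import math

        n_assign = 1
        for g in slot_groups:
            n_assign *= math.factorial(len(g))

        def wiring_for(assignment: dict[int, tuple[tuple[int, int], ...]]):
            ids: dict[tuple[int, int], int] = {}
            counter = 0
            for gi, group in enumerate(slot_groups):
                ordered = assignment.get(gi, tuple(group))
                for be in ordered:
                    ids[be] = counter
                    counter += 1
            return tuple(
                sorted(
                    (tuple(sorted((ids[(ji, 0)], ids[(ji, 1)]))), multiplicity[junctions[ji]])
                    for ji in range(len(junctions))
                )
            )

        if n_assign == 1 or n_assign > 5_000:
            wiring = wiring_for({})
        else:
            tie_idx = [gi for gi, g in enumerate(slot_groups) if len(g) > 1]
            wiring = min(
                wiring_for(dict(zip(tie_idx, perms)))
                for perms in itertools.product(
                    *(itertools.permutations(slot_groups[gi]) for gi in tie_idx)
                )
            )
        return (tuple(chrom_enc), wiring)

    n = len(chrom_data)
    if n <= max_permute:
        orders = itertools.permutations(range(n))
    else:  # too many chromosomes to canonicalize exactly; fall back to sorted order
        orders = [tuple(sorted(range(n), key=lambda i: chrom_data[i]))]
    best = min(serialize(order, mirror) for order in orders for mirror in (False, True))
    return PatternKey(repr(best))


# ---------------------------------------------------------------------------
# Keys of abstract derivatives


def _ref_lengths(consumed: Iterable[tuple[str, int, int]]) -> dict[str, int]:
    out: dict[str, int] = {}
    for chrom, start, end in consumed:
        out[chrom] = max(out.get(chrom, 0), end)
    return out


def pattern_key_of(
    derivative: dv.Derivative, consumed: Sequence[tuple[str, int, int]]
) -> PatternKey:
    """Canonical pattern key of an abstract derivative genome."""
    junctions = dv.emit_junctions(derivative)
    deltas = dv.cn_delta_profile(derivative, consumed)
    ref_len = _ref_lengths(consumed)

    def level(chrom: str, lo: Optional[int], hi: Optional[int]) -> int:
        if lo is None and hi is None:
            point = ref_len.get(chrom, 1) / 2
        elif lo is None:
            point = hi - 0.5
        elif hi is None:
            point = lo + 0.5
        else:
            point = (lo + hi) / 2
        for s, e, d in deltas.get(chrom, []):
            if s <= point < e:
                return d
        return 0

    extra: dict[str, list[int]] = {}
    cut_set = {
        (bk.chrom, _cutpoint(bk)) for pair in junctions for bk in pair
    }
    for chrom, intervals in deltas.items():
        for s, e, _ in intervals:
            for pos in (s, e):
                if 0 < pos < ref_len.get(chrom, 0) and (chrom, pos) not in cut_set:
                    extra.setdefault(chrom, []).append(pos)
    cn_only = [c for c in deltas if c not in {bk.chrom for p in junctions for bk in p}]
    return build_pattern_key(junctions, level, extra_boundaries=extra, extra_chromosomes=cn_only)


# ---------------------------------------------------------------------------
# Keys of observed clusters


def pattern_key(cluster, cn: Sequence[CNSegment], background_cn: float) -> PatternKey:
    """Canonical pattern key of an observed cluster given its CN context.

    Interval CN levels are length-weighted means over the covering segments,
    taken relative to *background_cn* and rounded to integers; unbounded
    flanks are read over a 1-Mb window adjacent to the outermost breakends.
    A cluster breakend with no CN coverage raises ``ValueError`` naming it.
    """
    junctions = [(j.a, j.b) for j in cluster.junctions]
    if hasattr(cn, "segments"):  # accept a CNIndex
        cn = cn.segments
    segs_by_chrom: dict[str, list[CNSegment]] = {}
    for seg in cn:
        segs_by_chrom.setdefault(seg.chrom, []).append(seg)
    for pair in junctions:
        for bk in pair:
            if not any(s.start <= bk.pos < s.end for s in segs_by_chrom.get(bk.chrom, [])):
                raise ValueError(f"breakend {bk.chrom}:{bk.pos} lacks CN coverage")

    def level(chrom: str, lo: Optional[int], hi: Optional[int]) -> int:
        if lo is None and hi is None:
            return 0
        if lo is None:
            lo = max(0, hi - FLANK_WINDOW_BP)
        if hi is None:
            hi = lo + FLANK_WINDOW_BP
        if hi <= lo:
            return 0
        total = weight = 0.0
        for s in segs_by_chrom.get(chrom, []):
            ov = min(hi, s.end) - max(lo, s.start)
            if ov > 0:
                total += ov * s.total_cn
                weight += ov
        if weight == 0:
            return 0
        return round(total / weight - background_cn)

    return build_pattern_key(junctions, level)


# ---------------------------------------------------------------------------
# Library enumeration


@dataclass
class ConfigLibrary:
    """Map from canonical pattern keys to minimal generating op sequences."""

    depth: int
    n_chroms: int
    units_per_chrom: int
    entries: dict[str, list[tuple[tuple, ...]]] = field(default_factory=dict)

    def min_ops(self, key: PatternKey) -> Optional[int]:
        seqs = self.entries.get(key.encoded)
        return len(seqs[0]) if seqs else None

    def __contains__(self, key: PatternKey) -> bool:
        return key.encoded in self.entries

    def to_json(self, path) -> None:
        payload = {
            "format_version": 1,
            "depth": self.depth,
            "n_chroms": self.n_chroms,
            "units_per_chrom": self.units_per_chrom,
            "entries": {
                k: [[list(op) for op in seq] for seq in seqs]
                for k, seqs in self.entries.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ConfigLibrary":
        with open(path) as fh:
            payload = json.load(fh)
        entries = {
            k: [tuple(tuple(op) for op in seq) for seq in seqs]
            for k, seqs in payload["entries"].items()
        }
        return cls(payload["depth"], payload["n_chroms"], payload["units_per_chrom"], entries)


def initial_genome(n_chroms: int, units_per_chrom: int):
    """Abstract reference: *n_chroms* chromosomes of unit-width segments."""
    deriv = tuple(
        (dv.Piece(f"R{i + 1}", 0, units_per_chrom, True),) for i in range(n_chroms)
    )
    consumed = [(f"R{i + 1}", 0, units_per_chrom) for i in range(n_chroms)]
    return deriv, consumed


def _structural_canonical(deriv: dv.Derivative, chrom_names: list[str]):
    """Canonical form of a derivative under reference relabeling and mirror."""
    def encode(d, relabel):
        return tuple(
            sorted(
                tuple((relabel[p.chrom], p.start, p.end, p.forward) for p in chrom)
                for chrom in d
            )
        )

    mirrored = tuple(dv._reverse(c) for c in deriv)
    best = None
    for perm in itertools.permutations(chrom_names):
        relabel = dict(zip(chrom_names, perm))
        for d in (deriv, mirrored):
            enc = encode(d, relabel)
            if best is None or enc < best:
                best = enc
    return best


def enumerate_library(
    n_chroms: int = 2,
    units_per_chrom: int = 3,
    depth: int = 3,
    max_sequences_per_key: int = 20,
    allow_deep: bool = False,
) -> ConfigLibrary:
    """Breadth-first closure of simple operations over the abstract alphabet.

    States are deduplicated by their full structure (up to chromosome
    relabeling and mirror), which is sound: structurally identical states
    reach identical sets of patterns.  Keys record only minimal-length
    sequences.  Deterministic for fixed alphabet and depth.
    """
    if depth > 5 and not allow_deep:
        raise ValueError("depth > 5 refused (combinatorial guard); pass allow_deep=True")
    start, consumed = initial_genome(n_chroms, units_per_chrom)
    chrom_names = [c for c, _, _ in consumed]
    lib = ConfigLibrary(depth, n_chroms, units_per_chrom)

    def record(key: PatternKey, seq: tuple):
        seqs = lib.entries.setdefault(key.encoded, [])
        if seqs and len(seqs[0]) < len(seq):
            return
        if len(seqs) < max_sequences_per_key:
            seqs.append(seq)

    record(pattern_key_of(start, consumed), ())
    frontier = [(start, ())]
    visited = {_structural_canonical(start, chrom_names)}
    for _ in range(depth):
        nxt = []
        for deriv, seq in frontier:
            for op in dv.enumerate_operations(deriv):
                try:
                    child = dv.apply_operation(deriv, op)
                except IndexError:
                    continue
                if not child:
                    continue  # everything lost; not a pattern
                canon = _structural_canonical(child, chrom_names)
                new_seq = seq + (op,)
                record(pattern_key_of(child, consumed), new_seq)
                if canon not in visited:
                    visited.add(canon)
                    nxt.append((child, new_seq))
        frontier = nxt
    return lib


def brute_force_library(
    n_chroms: int = 2, units_per_chrom: int = 2, depth: int = 2
) -> dict[str, int]:
    """Independent oracle: raw enumeration of every op sequence (no state
    dedup), returning key -> minimal sequence length."""
    start, consumed = initial_genome(n_chroms, units_per_chrom)
    out: dict[str, int] = {pattern_key_of(start, consumed).encoded: 0}
    frontier = [start]
    for d in range(1, depth + 1):
        nxt = []
        for deriv in frontier:
            for op in dv.enumerate_operations(deriv):
                try:
                    child = dv.apply_operation(deriv, op)
                except IndexError:
                    continue
                if not child:
                    continue
                key = pattern_key_of(child, consumed).encoded
                if key not in out:
                    out[key] = d
                nxt.append(child)
        frontier = nxt
    return out


def match_cluster(cluster, cn, background_cn, library: ConfigLibrary):
    """All minimal-length generating sequences for a cluster's pattern.

    Returns ``[(operation_sequence, n_ops), ...]`` sorted by length; an empty
    list marks the pattern as unexplained at this depth (candidate
    copy-and-paste or complex event).
    """
    key = pattern_key(cluster, cn, background_cn)
    seqs = library.entries.get(key.encoded, [])
    return sorted(((seq, len(seq)) for seq in seqs), key=lambda t: t[1])
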