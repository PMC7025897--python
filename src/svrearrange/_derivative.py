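"""Derivative-chromosome construction and junction / copy-number emission.

A derivative genome is modelled as an ordered list of chromosomes, each an
ordered list of oriented reference *pieces* (half-open intervals with an
orientation).  Rearrangement operations edit the piece lists; junctions and
copy-number changes are then *emitted* from the final structure, which
guarantees that every simulated or replayed event is internally consistent:
the same emission code serves as

* the simulator's output path (events are built as derivatives first),
* the classifier's replay oracle for templated-insertion paths, and
* the configuration library's abstract enumeration (unit-width pieces).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_model import LEFT, RIGHT, Breakend


@dataclass(frozen=True)
class Piece:
    """An oriented reference interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    forward: bool = True

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("piece must have end > start")

    @property
    def length(self) -> int:
        return self.end - self.start

    def reverse(self) -> "Piece":
        return Piece(self.chrom, self.start, self.end, not self.forward)


Chrom = tuple[Piece, ...]
Derivative = tuple[Chrom, ...]


def make_chrom(*pieces: Piece) -> Chrom:
    return tuple(pieces)


def piece_end_breakend(p: Piece) -> Breakend:
    """Breakend at the derivative-order *end* of a piece."""
    if p.forward:
        return Breakend(p.chrom, p.end - 1, LEFT)
    return Breakend(p.chrom, p.start, RIGHT)


def piece_start_breakend(p: Piece) -> Breakend:
    """Breakend at the derivative-order *start* of a piece."""
    if p.forward:
        return Breakend(p.chrom, p.start, RIGHT)
    return Breakend(p.chrom, p.end - 1, LEFT)


def reference_adjacent(p: Piece, q: Piece) -> bool:
    """True if q continues p without a novel junction."""
    if p.chrom != q.chrom or p.forward != q.forward:
        return False
    return p.end == q.start if p.forward else p.start == q.end


def emit_junctions(derivative: Derivative) -> list[tuple[Breakend, Breakend]]:
    """Novel adjacencies implied by the derivative structure."""
    out = []
    for chrom in derivative:
        for p, q in zip(chrom, chrom[1:]):
            if not reference_adjacent(p, q):
                out.append((piece_end_breakend(p), piece_start_breakend(q)))
    return out


def cn_delta_profile(
    derivative: Derivative, consumed: Iterable[tuple[str, int, int]]
) -> dict[str, list[tuple[int, int, int]]]:
    """Copy-number change relative to the unrearranged genome.

    *consumed* lists the reference intervals whose single copy the derivative
    replaced (templated insertions copy material without consuming it).
    Returns, per chromosome, merged (start, end, delta) intervals with
    non-zero delta.
    """
    events: dict[str, list[tuple[int, int]]] = {}
    for chrom in derivative:
        for p in chrom:
            events.setdefault(p.chrom, []).append((p.start, +1))
            events.setdefault(p.chrom, []).append((p.end, -1))
    for chrom_name, start, end in consumed:
        events.setdefault(chrom_name, []).append((start, -1))
        events.setdefault(chrom_name, []).append((end, +1))
    out: dict[str, list[tuple[int, int, int]]] = {}
    for chrom_name, evs in events.items():
        evs.sort()
        merged: list[tuple[int, int, int]] = []
        level = 0
        prev = None
        for pos, step in evs:
            if prev is not None and pos > prev and level != 0:
                if merged and merged[-1][1] == prev and merged[-1][2] == level:
                    merged[-1] = (merged[-1][0], pos, level)
                else:
                    merged.append((prev, pos, level))
            level += step
            prev = pos
        if merged:
            out[chrom_name] = merged
    return out


# ---------------------------------------------------------------------------
# Operations on derivatives.  Cut offsets are positions in *derivative*
# coordinates (0..length of the derivative chromosome); pieces are split on
# demand so cuts can fall anywhere.

DEL, TD, INV = "DEL", "TD", "INV"
TRA_BAL, TRA_UNBAL = "TRA_balanced", "TRA_unbalanced"
CHROM_GAIN, CHROM_LOSS = "CHROM_GAIN", "CHROM_LOSS"


def chrom_length(chrom: Chrom) -> int:
    return sum(p.length for p in chrom)


def split_chrom(chrom: Chrom, offset: int) -> tuple[Chrom, Chrom]:
    """Split a derivative chromosome at a derivative-coordinate offset."""
    if not 0 <= offset <= chrom_length(chrom):
        raise IndexError(f"offset {offset} outside chromosome of length {chrom_length(chrom)}")
    left: list[Piece] = []
    right: list[Piece] = []
    acc = 0
    for p in chrom:
        if acc + p.length <= offset:
            left.append(p)
        elif acc >= offset:
            right.append(p)
        else:
            cut = offset - acc
            if p.forward:
                left.append(Piece(p.chrom, p.start, p.start + cut, True))
                right.append(Piece(p.chrom, p.start + cut, p.end, True))
            else:
                left.append(Piece(p.chrom, p.end - cut, p.end, False))
                right.append(Piece(p.chrom, p.start, p.end - cut, False))
        acc += p.length
    return tuple(left), tuple(right)


def _slice3(chrom: Chrom, i: int, j: int) -> tuple[Chrom, Chrom, Chrom]:
    if not 0 <= i < j <= chrom_length(chrom):
        raise IndexError(f"bad cut pair ({i}, {j})")
    head, rest = split_chrom(chrom, i)
    mid, tail = split_chrom(rest, j - i)
    return head, mid, tail


def _reverse(chrom: Chrom) -> Chrom:
    return tuple(p.reverse() for p in reversed(chrom))


def _set(deriv: Derivative, c: int, chrom: Chrom) -> Derivative:
    out = list(deriv)
    if chrom:
        out[c] = chrom
    else:
        del out[c]  # an emptied chromosome is lost
    return tuple(out)


def apply_operation(deriv: Derivative, op: tuple) -> Derivative:
    """Apply one simple rearrangement operation.

    Operations: ``(DEL, c, i, j)``, ``(TD, c, i, j)``, ``(INV, c, i, j)``,
    ``(TRA_balanced, c1, i, c2, j)``, ``(TRA_unbalanced, c1, i, c2, j)``,
    ``(CHROM_GAIN, c)``, ``(CHROM_LOSS, c)``.  Cut offsets are derivative
    coordinates; out-of-range indices raise.
    """
    kind = op[0]
    if kind == DEL:
        _, c, i, j = op
        head, _, tail = _slice3(deriv[c], i, j)
        return _set(deriv, c, head + tail)
    if kind == TD:
        _, c, i, j = op
        head, mid, tail = _slice3(deriv[c], i, j)
        return _set(deriv, c, head + mid + mid + tail)
    if kind == INV:
        _, c, i, j = op
        head, mid, tail = _slice3(deriv[c], i, j)
        return _set(deriv, c, head + _reverse(mid) + tail)
    if kind == TRA_BAL:
        _, c1, i, c2, j = op
        if c1 == c2:
            raise IndexError("balanced translocation needs two chromosomes")
        h1, t1 = split_chrom(deriv[c1], i)
        h2, t2 = split_chrom(deriv[c2], j)
        out = list(deriv)
        out[c1], out[c2] = h1 + t2, h2 + t1
        return tuple(c for c in out if c)
    if kind == TRA_UNBAL:
        _, c1, i, c2, j = op
        if c1 == c2:
            raise IndexError("unbalanced translocation needs two chromosomes")
        h1, _ = split_chrom(deriv[c1], i)
        _, t2 = split_chrom(deriv[c2], j)
        out = [chrom for k, chrom in enumerate(deriv) if k not in (c1, c2)]
        if h1 + t2:
            out.append(h1 + t2)
        return tuple(out)
    if kind == CHROM_GAIN:
        _, c = op
        return deriv + (deriv[c],)
    if kind == CHROM_LOSS:
        _, c = op
        if not 0 <= c < len(deriv):
            raise IndexError(f"no chromosome {c}")
        return tuple(ch for k, ch in enumerate(deriv) if k != c)
    raise ValueError(f"unknown operation {kind!r}")


def enumerate_operations(deriv: Derivative) -> list[tuple]:
    """All distinct operation placements on the current derivative.

    Cuts are placed at every strict-interior offset (derivative coordinates)
    so every operation creates at least one junction; whole-chromosome events
    are covered by CHROM_GAIN / CHROM_LOSS.  Intended for the abstract
    unit-alphabet enumeration where piece lengths are small integers.
    """
    ops: list[tuple] = []
    lengths = [chrom_length(c) for c in deriv]
    for c, L in enumerate(lengths):
        for i in range(1, L):
            for j in range(i + 1, L):
                ops.append((DEL, c, i, j))
                ops.append((TD, c, i, j))
                ops.append((INV, c, i, j))
        ops.append((CHROM_GAIN, c))
        ops.append((CHROM_LOSS, c))
    for c1 in range(len(deriv)):
        for c2 in range(len(deriv)):
            if c1 == c2:
                continue
            for i in range(1, lengths[c1]):
                for j in range(1, lengths[c2]):
                    if c1 < c2:  # balanced swap is symmetric in (c1,i),(c2,j)
                        ops.append((TRA_BAL, c1, i, c2, j))
                    ops.append((TRA_UNBAL, c1, i, c2, j))
    return ops
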