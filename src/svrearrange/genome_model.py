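"""Core genomic data types, coordinate conventions, and file readers/writers.

Coordinate conventions used throughout the package:

* all internal coordinates are 0-based; intervals are half-open ``[start, end)``;
* a breakend is a single base position plus a *side*: ``left`` means the
  retained/joined sequence lies at coordinates ``<= pos``, ``right`` means
  ``>= pos``.  This replaces the ``+``/``-`` strand symbols of BEDPE and the
  bracket notation of VCF breakends with one unambiguous vocabulary;
* BEDPE strand ``+`` maps to ``left`` and ``-`` to ``right``; VCF positions
  (1-based) are converted on input and restored on output.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional

log = logging.getLogger(__name__)

LEFT = "left"
RIGHT = "right"

#: single-letter codes used in footprint patterns
SIDE_CODE = {LEFT: "L", RIGHT: "R"}

_CHROM_RE = re.compile(r"^(chr)?(\d+|[XYM]T?)$", re.IGNORECASE)


def chrom_sort_key(name: str):
    """Natural ordering for chromosome names (chr1 < chr2 < ... < chrX < chrY)."""
    m = _CHROM_RE.match(name)
    if m:
        body = m.group(2).upper()
        if body.isdigit():
            return (0, int(body), "")
        return (0, 100 + "XYM".index(body[0]), body)
    return (1, 0, name)


class ParseError(ValueError):
    """Raised on malformed input rows; carries the offending line number."""


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of chromosomes with lengths in bp."""

    name: str
    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in build")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be > 0")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def rank(self, chrom: str) -> int:
        for i, (c, _) in enumerate(self.chromosomes):
            if c == chrom:
                return i
        raise KeyError(chrom)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


def hg19_build() -> GenomeBuild:
    """hg19 autosomes + chrX, the reference frame for the genome-wide analyses."""
    text = (resources.files("svrearrange") / "data/hg19.chrom.sizes.tsv").read_text()
    chroms = []
    for line in text.strip().splitlines():
        name, length = line.split("\t")
        chroms.append((name, int(length)))
    return GenomeBuild("hg19", tuple(chroms))


def toy_build(n_chroms: int = 3, length: int = 50_000_000) -> GenomeBuild:
    """Small synthetic build on which full pipelines run in seconds."""
    return GenomeBuild(
        f"toy{n_chroms}x{length // 1_000_000}Mb",
        tuple((f"chr{i + 1}", length) for i in range(n_chroms)),
    )


@dataclass(frozen=True, order=True)
class Breakend:
    chrom: str
    pos: int
    side: str

    def __post_init__(self):
        if self.side not in (LEFT, RIGHT):
            raise ValueError(f"invalid side {self.side!r}")
        if self.pos < 0:
            raise ValueError("negative breakend position")

    @property
    def code(self) -> str:
        return SIDE_CODE[self.side]

    def sort_key(self):
        return (chrom_sort_key(self.chrom), self.pos)


# orientation classes of a junction
DEL_LIKE = "DEL-like"
TD_LIKE = "TD-like"
HEAD_HEAD = "head-head"
TAIL_TAIL = "tail-tail"
INTERCHROM = "interchromosomal"


@dataclass(frozen=True)
class Junction:
    """A somatic breakpoint junction: the fusion of two breakends."""

    id: str
    sample: str
    a: Breakend
    b: Breakend
    inserted_seq: str = ""
    homology_len: int = 0
    ccf: Optional[float] = None
    caller_count: Optional[int] = None

    def __post_init__(self):
        if self.a.sort_key() > self.b.sort_key():
            a, b = self.b, self.a
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)
        if self.homology_len < 0:
            raise ValueError("homology_len must be >= 0")

    @property
    def orientation_class(self) -> str:
        if self.a.chrom != self.b.chrom:
            return INTERCHROM
        sides = (self.a.side, self.b.side)
        if sides == (LEFT, RIGHT):
            return DEL_LIKE
        if sides == (RIGHT, LEFT):
            return TD_LIKE
        if sides == (LEFT, LEFT):
            return HEAD_HEAD
        return TAIL_TAIL

    @property
    def is_inverted(self) -> bool:
        return self.orientation_class in (HEAD_HEAD, TAIL_TAIL)

    @property
    def span(self) -> Optional[int]:
        """Distance between breakends, or None for interchromosomal junctions."""
        if self.a.chrom != self.b.chrom:
            return None
        return abs(self.b.pos - self.a.pos)

    @property
    def breakends(self) -> tuple[Breakend, Breakend]:
        return (self.a, self.b)


@dataclass(frozen=True)
class CNSegment:
    """Total copy number on a half-open genomic interval."""

    sample: str
    chrom: str
    start: int
    end: int
    total_cn: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("CN segment must have end > start")
        if self.total_cn < 0:
            raise ValueError("negative total copy number")


@dataclass
class SVSet:
    """One sample's junctions plus its copy-number context."""

    sample: str
    junctions: list[Junction]
    segments: list[CNSegment]
    build: GenomeBuild
    background_cn: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.background_cn is None:
            self.background_cn = estimate_background_cn(self.segments)

    def cn_at(self, chrom: str, pos: int) -> Optional[float]:
        for seg in self.segments:
            if seg.chrom == chrom and seg.start <= pos < seg.end:
                return seg.total_cn
        return None


class CNIndex:
    """Bisect-backed lookup over one sample's CN segments."""

    def __init__(self, segments: Iterable[CNSegment]):
        from bisect import bisect_right

        self._bisect = bisect_right
        self.segments = list(segments)
        self._by_chrom: dict[str, tuple[list[int], list[int], list[float]]] = {}
        per: dict[str, list[CNSegment]] = {}
        for seg in self.segments:
            per.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in per.items():
            segs.sort(key=lambda s: s.start)
            self._by_chrom[chrom] = (
                [s.start for s in segs],
                [s.end for s in segs],
                [s.total_cn for s in segs],
            )

    def at(self, chrom: str, pos: int) -> Optional[float]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, values = entry
        i = self._bisect(starts, pos) - 1
        if i >= 0 and pos < ends[i]:
            return values[i]
        return None

    def interval_mean(self, chrom: str, lo: int, hi: int) -> Optional[float]:
        entry = self._by_chrom.get(chrom)
        if entry is None or hi <= lo:
            return None
        starts, ends, values = entry
        i = max(0, self._bisect(starts, lo) - 1)
        total = weight = 0.0
        while i < len(starts) and starts[i] < hi:
            ov = min(hi, ends[i]) - max(lo, starts[i])
            if ov > 0:
                total += ov * values[i]
                weight += ov
            i += 1
        return total / weight if weight else None

    def boundaries(self, chrom: str) -> list[int]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, _ = entry
        return sorted(set(starts) | set(ends))


def estimate_background_cn(segments: Iterable[CNSegment], default: float = 2.0) -> float:
    """Coverage-weighted modal total copy number, rounded to the nearest 0.5.

    The modal ploidy of the sample is the background against which relative
    copy-number levels of rearrangement clusters are read.
    """
    weights: dict[float, float] = {}
    for seg in segments:
        level = round(seg.total_cn * 2) / 2
        weights[level] = weights.get(level, 0.0) + (seg.end - seg.start)
    if not weights:
        return default
    mode = max(weights.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return mode if mode > 0 else default


# ---------------------------------------------------------------------------
# BEDPE


def read_bedpe(path, sample: str, build: Optional[GenomeBuild] = None) -> list[Junction]:
    """Read SV junctions from a 10+ column BEDPE file.

    Columns: chrom1 start1 end1 chrom2 start2 end2 name score strand1 strand2.
    Coordinates are 0-based half-open; the breakend position is the start of
    its 1-bp interval; strand ``+`` -> side ``left``, ``-`` -> side ``right``.
    Rows whose chromosomes are absent from *build* are dropped (counted).
    """
    junctions: list[Junction] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(f"{path}:{lineno}: expected >=10 BEDPE columns, got {len(fields)}")
            try:
                c1, s1 = fields[0], int(fields[1])
                c2, s2 = fields[3], int(fields[4])
                name = fields[6]
                strand1, strand2 = fields[8], fields[9]
                if strand1 not in "+-" or strand2 not in "+-":
                    raise ValueError(f"bad strands {strand1!r},{strand2!r}")
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if build is not None and (c1 not in build or c2 not in build):
                dropped += 1
                continue
            a = Breakend(c1, s1, LEFT if strand1 == "+" else RIGHT)
            b = Breakend(c2, s2, LEFT if strand2 == "+" else RIGHT)
            extra = {}
            if len(fields) > 10 and fields[10] not in (".", ""):
                extra["homology_len"] = int(fields[10])
            junctions.append(Junction(id=name, sample=sample, a=a, b=b, **extra))
    if dropped:
        log.warning("%s: dropped %d rows on chromosomes absent from build", path, dropped)
    if not junctions:
        log.warning("%s: no junctions read", path)
    return junctions


def write_bedpe(junctions: Iterable[Junction], path) -> None:
    """Write junctions in the same 10(+1)-column BEDPE dialect read_bedpe accepts."""
    with open(path, "w") as fh:
        for j in junctions:
            strand_a = "+" if j.a.side == LEFT else "-"
            strand_b = "+" if j.b.side == LEFT else "-"
            fh.write(
                "\t".join(
                    [
                        j.a.chrom, str(j.a.pos), str(j.a.pos + 1),
                        j.b.chrom, str(j.b.pos), str(j.b.pos + 1),
                        j.id, ".", strand_a, strand_b, str(j.homology_len),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF breakends

_BND_ALT_RE = re.compile(r"^([A-Za-z.*]*)([\[\]])([^:]+):(\d+)([\[\]])([A-Za-z.*]*)$")


def _parse_bnd_alt(alt: str):
    """Split a VCF BND ALT string into (mate chrom, 1-based pos, bracket, t-first).

    ``t[p[`` / ``t]p]`` place the local breakend before the join (side left);
    ``]p]t`` / ``[p[t`` place it after (side right).  The bracket direction
    gives the mate's side: ``[`` joins sequence extending right of p (mate
    side right), ``]`` sequence extending left (mate side left).
    """
    m = _BND_ALT_RE.match(alt)
    if m is None:
        raise ValueError(f"unparseable BND ALT {alt!r}")
    t_before, br1, chrom, pos, br2, t_after = m.groups()
    if br1 != br2:
        raise ValueError(f"mismatched brackets in ALT {alt!r}")
    local_side = LEFT if t_before else RIGHT
    mate_side = RIGHT if br1 == "[" else LEFT
    return chrom, int(pos), local_side, mate_side


def read_vcf_breakends(path, sample: str, build: Optional[GenomeBuild] = None) -> list[Junction]:
    """Collapse VCF 4.2 SVTYPE=BND mate-pair records into one Junction each.

    Mates are paired via MATEID; unpaired mates are dropped with a warning and
    mates whose ALT coordinates disagree with their partner raise an error.
    HOMLEN and INSSEQ/SVINSSEQ are carried through when present.
    """
    import pysam

    records = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.info.get("SVTYPE") != "BND":
                continue
            records[rec.id] = rec

    junctions = []
    seen = set()
    for rid, rec in records.items():
        if rid in seen:
            continue
        mateid = rec.info.get("MATEID")
        if isinstance(mateid, tuple):
            mateid = mateid[0]
        if mateid is None or mateid not in records:
            log.warning("%s: BND record %s has no mate; dropped", path, rid)
            seen.add(rid)
            continue
        mate = records[mateid]
        seen.update((rid, mateid))
        alt = rec.alts[0]
        m_chrom, m_pos, local_side, mate_side = _parse_bnd_alt(alt)
        if m_chrom != mate.chrom or m_pos != mate.pos:
            raise ParseError(
                f"{path}: mate coordinates of {rid} ({m_chrom}:{m_pos}) disagree "
                f"with record {mateid} ({mate.chrom}:{mate.pos})"
            )
        if build is not None and (rec.chrom not in build or m_chrom not in build):
            continue
        a = Breakend(rec.chrom, rec.pos - 1, local_side)  # pysam .pos is 1-based
        b = Breakend(m_chrom, m_pos - 1, mate_side)
        def info(key, default=None):
            try:
                val = rec.info.get(key, default)
            except (KeyError, ValueError):  # key absent from the header
                return default
            return val[0] if isinstance(val, tuple) else val

        hom = info("HOMLEN", 0)
        ins = info("INSSEQ") or info("SVINSSEQ") or ""
        junctions.append(
            Junction(
                id=min(rid, mateid), sample=sample, a=a, b=b,
                homology_len=int(hom or 0), inserted_seq=str(ins),
            )
        )
    return junctions


# ---------------------------------------------------------------------------
# Copy-number segments


def read_cn_segments(path, sample: str, overlap_tol_bp: int = 50) -> list[CNSegment]:
    """Read a chrom/start/end/total_cn TSV of copy-number segments.

    Input is sorted if necessary.  Overlaps of at most *overlap_tol_bp* are
    resolved by trimming the start of the later segment; larger overlaps are
    an error, as is a negative copy number.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "total_cn"], dtype=str)
    if len(df) and not str(df.iloc[0]["start"]).lstrip("-").isdigit():
        df = df.iloc[1:]  # header row present
    segments: list[CNSegment] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, end, cn = int(row.start), int(row.end), float(row.total_cn)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if cn < 0:
            raise ParseError(f"{path}:{lineno}: negative copy number {cn}")
        segments.append(CNSegment(sample, str(row.chrom), start, end, cn))
    segments.sort(key=lambda s: (chrom_sort_key(s.chrom), s.start, s.end))
    out: list[CNSegment] = []
    for seg in segments:
        if out and out[-1].chrom == seg.chrom and seg.start < out[-1].end:
            overlap = out[-1].end - seg.start
            if overlap > overlap_tol_bp:
                raise ParseError(
                    f"{path}: segments overlap by {overlap} bp at "
                    f"{seg.chrom}:{seg.start} (> tolerance {overlap_tol_bp})"
                )
            seg = replace(seg, start=out[-1].end)
            if seg.end <= seg.start:
                continue
        out.append(seg)
    return out


def write_cn_segments(segments: Iterable[CNSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\ttotal_cn\n")
        for seg in segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.total_cn:g}\n")


def read_track(path, grid):
    """Average a bedGraph/4-column BED of numeric values onto a pixel grid.

    Thin forwarding wrapper; see :func:`svrearrange.genome_props.read_track`.
    """
    from . import genome_props

    return genome_props.read_track(path, grid)
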