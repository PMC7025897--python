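"""Synthetic rearranged genomes and cohorts with ground truth.

Every simulated event is constructed as an explicit derivative chromosome
(piece list) first; its junctions and copy-number changes are then *emitted*
from that structure by the shared machinery in :mod:`svrearrange._derivative`.
This guarantees internal consistency: replaying the derivative regenerates
exactly the emitted junctions and CN profile, which is the same oracle the
classifier uses for templated-insertion paths.

The generator emulates the salient features of somatic rearrangement data:
per-class event rates, junction orientations with their copy-number steps,
multimodal size distributions (deletions and tandem duplications have a
~10 kb and a ~250 kb mode; templated-insertion fragments have a dominant
sub-kilobase mode), smooth replication-timing waves with optional placement
bias, Gaussian noise on copy-number segment means, and cohorts with planted
signature exposures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import _derivative as dv
from .genome_model import (
    Breakend,
    CNSegment,
    GenomeBuild,
    Junction,
    SVSet,
    hg19_build,
    toy_build,
)

P = dv.Piece


@dataclass(frozen=True)
class SizeMixture:
    """Log-normal mixture over sizes in bp: (weight, median, sigma_ln)."""

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        if abs(sum(w for w, _, _ in self.components) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    def sample(self, rng: np.random.Generator) -> int:
        weights = [w for w, _, _ in self.components]
        _, median, sigma = self.components[rng.choice(len(weights), p=weights)]
        return max(2, int(median * math.exp(sigma * rng.standard_normal())))


# Per-genome event intensities of the default study mix (~500 events in total)
DEFAULT_INTENSITIES = {
    "deletion": 115,
    "tandem_duplication": 95,
    "reciprocal_inversion": 40,
    "reciprocal_translocation": 25,
    "unbalanced_translocation": 40,
    "foldback_inversion": 30,
    "templated_insertion_cycle": 40,
    "templated_insertion_bridge": 35,
    "templated_insertion_chain": 20,
    "chromoplexy": 10,
    "local_2jump_dup_trp_dup": 12,
    "local_2jump_inverted_dups": 12,
    "local_2jump_del_invdup": 12,
    "local_distant": 10,
    "local_n_jump": 4,
}

SIMPLE_CLASSES = (
    "deletion", "tandem_duplication", "reciprocal_inversion",
    "reciprocal_translocation", "unbalanced_translocation", "foldback_inversion",
)
TEMPLATED_CLASSES = (
    "templated_insertion_cycle", "templated_insertion_bridge",
    "templated_insertion_chain",
)

DEFAULT_SIZES = {
    # bimodal deletion / TD / inversion sizes
    "segment": SizeMixture(((0.55, 10_000, 1.0), (0.45, 250_000, 0.9))),
    # templated-insertion fragments: dominant sub-kb mode
    "template": SizeMixture(((0.7, 500, 0.4), (0.3, 1_000, 0.4))),
    # re-replicated / deleted host segment of cycles and bridges
    "host_segment": SizeMixture(((1.0, 400, 0.4),)),
    # segments of local 2-jump structures
    "jump_segment": SizeMixture(((1.0, 700, 0.4),)),
    "foldback_span": SizeMixture(((1.0, 800, 0.5),)),
    "terminal_loss": SizeMixture(((1.0, 300_000, 0.4),)),
}


@dataclass
class SimConfig:
    seed: int = 0
    build: GenomeBuild = field(default_factory=hg19_build)
    intensities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    sizes: dict[str, SizeMixture] = field(default_factory=lambda: dict(DEFAULT_SIZES))
    rt_bias: dict[str, float] = field(default_factory=dict)  # per-class placement bias
    cn_noise_sd: float = 0.1
    background_cn: float = 2.0
    pad_bp: int = 10_000
    retry_cap: int = 100
    template_count_weights: tuple[float, ...] = (0.5, 0.35, 0.15)  # 1, 2, 3 templates

    def with_total_events(self, total: float) -> "SimConfig":
        scale = total / sum(self.intensities.values())
        return replace(
            self, intensities={k: v * scale for k, v in self.intensities.items()}
        )


@dataclass
class TruthRecord:
    event_id: str
    event_class: str
    junction_ids: list[str]
    params: dict


@dataclass
class SimulatedEvent:
    derivatives: list[tuple]          # piece tuples
    consumed: list[tuple[str, int, int]]
    reserved: list[tuple[str, int, int]]
    params: dict


# ---------------------------------------------------------------------------
# Replication timing model


class RTModel:
    """Smooth deterministic replication-timing wave per chromosome, in [0, 1].

    Higher values represent earlier replication.
    """

    def __init__(self, build: GenomeBuild, wavelength_bp: float = 3_700_000):
        self.build = build
        self.wavelength = wavelength_bp

    def value(self, chrom: str, pos) -> float:
        ci = self.build.rank(chrom)
        phase = 2.4 * ci
        return 0.5 + 0.45 * np.sin(2 * np.pi * np.asarray(pos) / self.wavelength + phase)

    def track(self, grid):
        """The same wave sampled onto a pixel grid (bin midpoints)."""
        from .genome_props import track_from_array

        values = np.empty(grid.total_bins)
        for chrom, _ in self.build.chromosomes:
            n = grid.n_bins[chrom]
            mids = (np.arange(n) + 0.5) * grid.bin_size
            values[grid.offsets[chrom]: grid.offsets[chrom] + n] = self.value(chrom, mids)
        return track_from_array("replication_timing", grid, values)


class _Placer:
    """Samples event anchor positions with optional replication-timing bias."""

    BIN = 100_000

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.build = config.build
        self.rng = rng
        self.rt = RTModel(config.build)
        self.used: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in config.build.chromosomes}
        self._weights_cache: dict[float, tuple[list[str], np.ndarray, dict]] = {}

    def _weights(self, bias: float):
        if bias not in self._weights_cache:
            chrom_names, chrom_w, per_chrom = [], [], {}
            for chrom, length in self.build.chromosomes:
                n = max(1, length // self.BIN)
                mids = (np.arange(n) + 0.5) * self.BIN
                w = np.exp(bias * (self.rt.value(chrom, mids) - 0.5) / 0.29)
                per_chrom[chrom] = w / w.sum()
                chrom_names.append(chrom)
                chrom_w.append(w.sum() * length / (n * self.BIN))
            chrom_w = np.array(chrom_w)
            self._weights_cache[bias] = (chrom_names, chrom_w / chrom_w.sum(), per_chrom)
        return self._weights_cache[bias]

    def overlaps(self, chrom: str, lo: int, hi: int) -> bool:
        return any(lo < e and s < hi for s, e in self.used[chrom])

    def reserve(self, intervals: Sequence[tuple[str, int, int]]) -> None:
        for chrom, lo, hi in intervals:
            self.used[chrom].append((lo, hi))

    def sample_anchor(
        self, span_bp: int, bias: float = 0.0,
        exclude_chrom: Optional[str] = None, margin: int = 20_000,
    ) -> Optional[tuple[str, int]]:
        names, chrom_p, per_chrom = self._weights(bias)
        for _ in range(50):
            ci = self.rng.choice(len(names), p=chrom_p)
            chrom = names[ci]
            if chrom == exclude_chrom:
                continue
            length = self.build.lengths[chrom]
            if length < span_bp + 2 * margin:
                continue
            b = self.rng.choice(len(per_chrom[chrom]), p=per_chrom[chrom])
            pos = int(b * self.BIN + self.rng.integers(0, self.BIN))
            pos = min(max(pos, margin), length - margin - span_bp)
            if not self.overlaps(chrom, pos - margin, pos + span_bp + margin):
                return chrom, pos
        return None


# ---------------------------------------------------------------------------
# Event builders: each returns a SimulatedEvent or None (placement failure)


def _size(config, key, rng) -> int:
    return config.sizes[key].sample(rng)


def _build_deletion_like(config, rng, placer, bias, kind) -> Optional[SimulatedEvent]:
    size = _size(config, "segment", rng)
    pad = config.pad_bp
    anchor = placer.sample_anchor(size + 2 * pad, bias)
    if anchor is None:
        return None
    chrom, w0 = anchor
    s, e = w0 + pad, w0 + pad + size
    w1 = e + pad
    if kind == "deletion":
        pieces = (P(chrom, w0, s), P(chrom, e, w1))
    elif kind == "tandem_duplication":
        pieces = (P(chrom, w0, e), P(chrom, s, w1))
    else:  # reciprocal inversion
        pieces = (P(chrom, w0, s), P(chrom, s, e, False), P(chrom, e, w1))
    return SimulatedEvent(
        [pieces], [(chrom, w0, w1)], [(chrom, w0, w1)], {"size_bp": size, "chrom": chrom}
    )


def _build_foldback(config, rng, placer, bias) -> Optional[SimulatedEvent]:
    span = min(_size(config, "foldback_span", rng), 4_500)
    dup = _size(config, "host_segment", rng)
    loss = _size(config, "terminal_loss", rng)
    pad = config.pad_bp
    total = pad + dup + span + loss
    anchor = placer.sample_anchor(total, bias)
    if anchor is None:
        return None
    chrom, w0 = anchor
    u = w0 + pad
    v = u + dup
    s = v + span
    cap = s + loss
    pieces = (P(chrom, w0, s), P(chrom, u, v, False))
    return SimulatedEvent(
        [pieces], [(chrom, w0, cap)], [(chrom, w0, cap)],
        {"size_bp": span, "chrom": chrom},
    )


def _build_translocation(config, rng, placer, bias, balanced: bool) -> Optional[SimulatedEvent]:
    pad = config.pad_bp
    loss_a = _size(config, "terminal_loss", rng)
    loss_b = _size(config, "terminal_loss", rng)
    a = placer.sample_anchor(pad + (0 if balanced else loss_a), bias)
    if a is None:
        return None
    b = placer.sample_anchor(pad + (0 if balanced else loss_b), bias, exclude_chrom=a[0])
    if b is None:
        return None
    (ca, pa), (cb, pb) = a, b
    if balanced:
        s, t = pa + pad // 2, pb + pad // 2
        pieces = [
            (P(ca, s - pad // 2, s), P(cb, t, t + pad // 2)),
            (P(cb, t - pad // 2, t), P(ca, s, s + pad // 2)),
        ]
        consumed = [(ca, s - pad // 2, s + pad // 2), (cb, t - pad // 2, t + pad // 2)]
        return SimulatedEvent(pieces, consumed, consumed, {"chroms": (ca, cb)})
    s, t = pa + pad // 2, pb + loss_b
    pieces = [(P(ca, s - pad // 2, s), P(cb, t, t + pad // 2))]
    consumed = [(ca, s - pad // 2, s + loss_a), (cb, t - loss_b, t + pad // 2)]
    return SimulatedEvent(pieces, consumed, consumed, {"chroms": (ca, cb)})


def _build_templated_insertion(config, rng, placer, bias, topology) -> Optional[SimulatedEvent]:
    pad = config.pad_bp
    n_templates = 1 + int(
        rng.choice(len(config.template_count_weights), p=config.template_count_weights)
    )
    host_seg = _size(config, "host_segment", rng)
    loss_a = _size(config, "terminal_loss", rng)
    host_span = (
        pad + loss_a if topology == "templated_insertion_chain" else host_seg + 2 * pad
    )
    host = placer.sample_anchor(host_span, bias)
    if host is None:
        return None
    hc, h0 = host
    templates = []
    for _ in range(n_templates):
        tsize = _size(config, "template", rng)
        t = placer.sample_anchor(tsize + 2 * pad, bias, exclude_chrom=hc)
        if t is None:
            return None
        templates.append((t[0], t[1] + pad, t[1] + pad + tsize, bool(rng.random() < 0.3)))

    tpl_pieces = [
        P(c, lo, hi, not rev) for c, lo, hi, rev in templates
    ]
    reserved = [(c, lo - pad, hi + pad) for c, lo, hi, _ in templates]
    params = {
        "n_templates": n_templates,
        "template_span_bp": sum(hi - lo for _, lo, hi, _ in templates),
        "topology": topology.rsplit("_", 1)[-1],
    }
    if topology == "templated_insertion_cycle":
        c1, c2 = h0 + pad, h0 + pad + host_seg
        pieces = (P(hc, h0, c2), *tpl_pieces, P(hc, c1, c2 + pad))
        consumed = [(hc, h0, c2 + pad)]
        reserved.append((hc, h0, c2 + pad))
    elif topology == "templated_insertion_bridge":
        c1, c2 = h0 + pad, h0 + pad + host_seg
        pieces = (P(hc, h0, c1), *tpl_pieces, P(hc, c2, c2 + pad))
        consumed = [(hc, h0, c2 + pad)]
        reserved.append((hc, h0, c2 + pad))
    else:  # chain: never returns to the host chromosome
        loss_c = _size(config, "terminal_loss", rng)
        dest = placer.sample_anchor(loss_c + pad, bias, exclude_chrom=hc)
        if dest is None:
            return None
        cc, d0 = dest
        a = h0 + pad
        c = d0 + loss_c
        pieces = (P(hc, h0, a), *tpl_pieces, P(cc, c, c + pad))
        consumed = [(hc, h0, a + loss_a), (cc, c - loss_c, c + pad)]
        reserved.append((hc, h0, a + loss_a))
        reserved.append((cc, c - loss_c, c + pad))
        params["chroms"] = (hc, cc)
    return SimulatedEvent([pieces], consumed, reserved, params)


def _build_chromoplexy(config, rng, placer, bias, k: int = 3) -> Optional[SimulatedEvent]:
    pad = config.pad_bp
    anchors = []
    for _ in range(k):
        a = placer.sample_anchor(2 * pad, bias)
        if a is None or any(a[0] == c for c, _ in anchors):
            return None
        anchors.append(a)
    cuts = [(c, p + pad) for c, p in anchors]
    pieces = []
    consumed = []
    for i, (ci, si) in enumerate(cuts):
        cj, sj = cuts[(i + 1) % k]
        pieces.append((P(ci, si - pad, si), P(cj, sj, sj + pad)))
        consumed.append((ci, si - pad, si + pad))
    return SimulatedEvent(pieces, consumed, list(consumed), {"n_chromosomes": k})


def _build_two_jump(config, rng, placer, bias, kind) -> Optional[SimulatedEvent]:
    pad = config.pad_bp
    sizes = [_size(config, "jump_segment", rng) for _ in range(3)]
    total = sum(sizes) + 2 * pad
    anchor = placer.sample_anchor(total, bias)
    if anchor is None:
        return None
    chrom, w0 = anchor
    p1 = w0 + pad
    p2 = p1 + sizes[0]
    p3 = p2 + sizes[1]
    p4 = p3 + sizes[2]
    w1 = p4 + pad
    if kind == "local_2jump_dup_trp_dup":
        pieces = (P(chrom, w0, p3), P(chrom, p2, p4, False), P(chrom, p1, w1))
    elif kind == "local_2jump_inverted_dups":
        pieces = (P(chrom, w0, p2), P(chrom, p3, p4, False), P(chrom, p1, w1))
    else:  # local_2jump_del_invdup
        pieces = (P(chrom, w0, p1), P(chrom, p2, p4, False), P(chrom, p3, w1))
    return SimulatedEvent(
        [pieces], [(chrom, w0, w1)], [(chrom, w0, w1)],
        {"sizes": sizes, "span_bp": p4 - p1, "chrom": chrom},
    )


def _build_local_distant(config, rng, placer, bias) -> Optional[SimulatedEvent]:
    """A local deletion phased with a distant unbalanced jump: only a tiny
    (<100 bp) sliver of the host survives between the deletion and the jump,
    so the two junctions form one non-decomposable local footprint."""
    pad = config.pad_bp
    s1 = _size(config, "jump_segment", rng)
    sliver = int(rng.integers(20, 80))
    loss = _size(config, "terminal_loss", rng)
    anchor = placer.sample_anchor(s1 + sliver + pad + loss, bias)
    if anchor is None:
        return None
    chrom, w0 = anchor
    p1 = w0 + pad
    p2 = p1 + s1
    p3 = p2 + sliver
    loss_b = _size(config, "terminal_loss", rng)
    dest = placer.sample_anchor(loss_b + pad, bias, exclude_chrom=chrom)
    if dest is None:
        return None
    cb, d0 = dest
    t = d0 + loss_b
    pieces = (P(chrom, w0, p1), P(chrom, p2, p3), P(cb, t, t + pad))
    consumed = [(chrom, w0, p3 + loss), (cb, t - loss_b, t + pad)]
    return SimulatedEvent(
        [pieces], consumed, list(consumed), {"chroms": (chrom, cb)}
    )


def _build_local_n_jump(config, rng, placer, bias, n_ops: int = 3) -> Optional[SimulatedEvent]:
    pad = config.pad_bp
    window = 30_000
    anchor = placer.sample_anchor(window + 2 * pad, bias)
    if anchor is None:
        return None
    chrom, w0 = anchor
    w1 = w0 + window + 2 * pad
    deriv = ((P(chrom, w0, w1),),)
    for _ in range(n_ops):
        length = dv.chrom_length(deriv[0])
        size = min(_size(config, "jump_segment", rng), length // 4)
        i = int(rng.integers(pad, length - pad - size))
        op = ("DEL", "TD", "INV")[rng.integers(0, 3)]
        deriv = dv.apply_operation(deriv, (op, 0, i, i + size))
    return SimulatedEvent(
        [deriv[0]], [(chrom, w0, w1)], [(chrom, w0, w1)], {"n_ops": n_ops, "chrom": chrom}
    )


_BUILDERS = {
    "deletion": lambda c, r, p, b: _build_deletion_like(c, r, p, b, "deletion"),
    "tandem_duplication": lambda c, r, p, b: _build_deletion_like(c, r, p, b, "tandem_duplication"),
    "reciprocal_inversion": lambda c, r, p, b: _build_deletion_like(c, r, p, b, "reciprocal_inversion"),
    "reciprocal_translocation": lambda c, r, p, b: _build_translocation(c, r, p, b, True),
    "unbalanced_translocation": lambda c, r, p, b: _build_translocation(c, r, p, b, False),
    "foldback_inversion": _build_foldback,
    "templated_insertion_cycle": lambda c, r, p, b: _build_templated_insertion(c, r, p, b, "templated_insertion_cycle"),
    "templated_insertion_bridge": lambda c, r, p, b: _build_templated_insertion(c, r, p, b, "templated_insertion_bridge"),
    "templated_insertion_chain": lambda c, r, p, b: _build_templated_insertion(c, r, p, b, "templated_insertion_chain"),
    "chromoplexy": _build_chromoplexy,
    "local_2jump_dup_trp_dup": lambda c, r, p, b: _build_two_jump(c, r, p, b, "local_2jump_dup_trp_dup"),
    "local_2jump_inverted_dups": lambda c, r, p, b: _build_two_jump(c, r, p, b, "local_2jump_inverted_dups"),
    "local_2jump_del_invdup": lambda c, r, p, b: _build_two_jump(c, r, p, b, "local_2jump_del_invdup"),
    "local_distant": _build_local_distant,
    "local_n_jump": _build_local_n_jump,
}

SUPPORTED_CLASSES = tuple(_BUILDERS)


def simulate_event(
    event_class: str,
    config: SimConfig,
    rng: np.random.Generator,
    placer: Optional[_Placer] = None,
    event_id: str = "e1",
    sample: str = "sim",
) -> tuple[list[Junction], dict, TruthRecord]:
    """Simulate one event; returns (junctions, CN delta profile, truth).

    The event is constructed as a derivative chromosome and its junctions and
    CN deltas are emitted from that structure.  Placement collisions trigger
    resampling up to the configured retry cap.
    """
    if event_class not in _BUILDERS:
        raise ValueError(f"unsupported event class {event_class!r}")
    if placer is None:
        placer = _Placer(config, rng)
    bias = config.rt_bias.get(event_class, 0.0)
    built = None
    for _ in range(config.retry_cap):
        built = _BUILDERS[event_class](config, rng, placer, bias)
        if built is not None:
            break
    if built is None:
        raise RuntimeError(
            f"could not place a {event_class} event after {config.retry_cap} tries; "
            "reduce intensities or enlarge the build"
        )
    placer.reserve(built.reserved)
    derivative = tuple(built.derivatives)
    pairs = dv.emit_junctions(derivative)
    deltas = dv.cn_delta_profile(derivative, built.consumed)
    junctions = [
        Junction(id=f"{event_id}.j{k + 1}", sample=sample, a=a, b=b)
        for k, (a, b) in enumerate(pairs)
    ]
    truth = TruthRecord(event_id, event_class, [j.id for j in junctions], built.params)
    return junctions, deltas, truth


def _segments_from_deltas(
    build: GenomeBuild, all_deltas: list[dict], background: float,
    noise_sd: float, rng: np.random.Generator, sample: str,
) -> list[CNSegment]:
    segments = []
    for chrom, length in build.chromosomes:
        events = []
        for deltas in all_deltas:
            for lo, hi, d in deltas.get(chrom, []):
                events.append((lo, d))
                events.append((hi, -d))
        events.sort()
        cuts = [0] + sorted({p for p, _ in events if 0 < p < length}) + [length]
        level = background
        i = 0
        for lo, hi in zip(cuts, cuts[1:]):
            while i < len(events) and events[i][0] <= lo:
                level += events[i][1]
                i += 1
            value = max(0.0, level + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
            segments.append(CNSegment(sample, chrom, lo, hi, value))
    return segments


def simulate_genome(config: SimConfig, sample: str = "sim") -> tuple[SVSet, list[TruthRecord]]:
    """One rearranged genome: event counts ~ Poisson(intensity), placed with
    optional replication-timing bias, CN deltas merged onto the background
    with optional Gaussian segment noise.  Deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    placer = _Placer(config, rng)
    junctions: list[Junction] = []
    truths: list[TruthRecord] = []
    all_deltas: list[dict] = []
    eid = 0
    for event_class in sorted(config.intensities):
        n = rng.poisson(config.intensities[event_class])
        for _ in range(n):
            eid += 1
            js, deltas, truth = simulate_event(
                event_class, config, rng, placer, event_id=f"{sample}.e{eid}", sample=sample
            )
            junctions.extend(js)
            truths.append(truth)
            all_deltas.append(deltas)
    segments = _segments_from_deltas(
        config.build, all_deltas, config.background_cn, config.cn_noise_sd, rng, sample
    )
    sv_set = SVSet(
        sample=sample, junctions=junctions, segments=segments,
        build=config.build, background_cn=config.background_cn,
    )
    return sv_set, truths


def simulate_uniform_junctions(
    n: int, build: GenomeBuild, seed: int = 0, sample: str = "null"
) -> SVSet:
    """Null genome: n junctions with breakends placed uniformly at random,
    flat copy number.  Used for clustering calibration."""
    rng = np.random.default_rng(seed)
    lengths = np.array([l for _, l in build.chromosomes], dtype=float)
    names = [c for c, _ in build.chromosomes]
    p = lengths / lengths.sum()
    junctions = []
    for k in range(n):
        bends = []
        for _ in range(2):
            ci = rng.choice(len(names), p=p)
            pos = int(rng.integers(0, int(lengths[ci])))
            side = "left" if rng.random() < 0.5 else "right"
            bends.append(Breakend(names[ci], pos, side))
        junctions.append(Junction(id=f"{sample}.j{k + 1}", sample=sample, a=bends[0], b=bends[1]))
    segments = [
        CNSegment(sample, c, 0, l, 2.0) for c, l in build.chromosomes
    ]
    return SVSet(sample=sample, junctions=junctions, segments=segments, build=build,
                 background_cn=2.0)


# ---------------------------------------------------------------------------
# Cohorts with planted signatures


def default_planted_signatures(categories: Sequence[str]) -> "np.ndarray | object":
    """Three well-separated signatures over the default catalogue categories:
    a small-deletion signature (with small reciprocal inversions), a tandem-
    duplication signature, and a templated-insertion signature."""
    import pandas as pd

    spec = {
        "sig_small_del": {
            "del_<50kb_early": 0.25, "del_<50kb_late": 0.25,
            "del_50-500kb_early": 0.15, "del_50-500kb_late": 0.15,
            "recip_inv_small": 0.20,
        },
        "sig_td": {
            "td_<50kb_early": 0.20, "td_<50kb_late": 0.20,
            "td_50-500kb_early": 0.25, "td_50-500kb_late": 0.25, "td_>500kb": 0.10,
        },
        "sig_templated_ins": {
            "cycle_<=100kb": 0.35, "bridge_<=100kb": 0.30,
            "chain_<=100kb": 0.20, "recip_translocation": 0.15,
        },
    }
    S = pd.DataFrame(0.0, index=list(spec), columns=list(categories))
    for sig, weights in spec.items():
        for cat, w in weights.items():
            if cat not in S.columns:
                raise KeyError(f"category {cat} not in catalogue")
            S.loc[sig, cat] = w
    return S.div(S.sum(axis=1), axis=0)


def simulate_cohort(
    n_patients: int,
    signatures,  # K x categories DataFrame, rows sum to 1
    mean_exposure: float = 40.0,
    gamma_shape: float = 1.5,
    seed: int = 0,
):
    """Cohort counts with planted signature exposures.

    Per patient, exposures are Gamma-distributed per signature and category
    counts are Poisson with mean ``exposures @ signatures``.  Returns
    (counts DataFrame, exposures DataFrame).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    K = signatures.shape[0]
    scale = mean_exposure / gamma_shape
    E = rng.gamma(gamma_shape, scale, size=(n_patients, K))
    rates = E @ signatures.to_numpy()
    counts = rng.poisson(rates)
    patients = [f"P{i + 1:04d}" for i in range(n_patients)]
    return (
        pd.DataFrame(counts, index=patients, columns=signatures.columns),
        pd.DataFrame(E, index=patients, columns=signatures.index),
    )


def simulate_driver_cohort(
    n_patients: int = 300,
    effect_size: float = 20.0,
    affected_signature: str = "SV2",
    gene: str = "BRCA1",
    mutated_fraction: float = 0.15,
    n_signatures: int = 3,
    histologies: Sequence[str] = ("breast", "ovary", "pancreas"),
    seed: int = 0,
    histology_confound: float = 0.0,
):
    """Exposure-level cohort for driver-association tests: gene status adds
    *effect_size* to one signature's exposure on top of histology effects."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    patients = [f"P{i + 1:04d}" for i in range(n_patients)]
    sigs = [f"SV{k + 1}" for k in range(n_signatures)]
    histology = pd.Series(rng.choice(histologies, n_patients), index=patients)
    status = pd.DataFrame(
        {gene: (rng.random(n_patients) < mutated_fraction).astype(int)}, index=patients
    )
    # within-histology exposure noise: sd ~7 counts on a mean of ~20, so a
    # 20-count planted effect is estimated to ~1.2 counts (s.e.) at n = 300
    base = rng.gamma(8.0, 2.5, size=(n_patients, n_signatures))
    hist_effect = {h: rng.gamma(2.0, 5.0, n_signatures) for h in histologies}
    E = base + np.array([hist_effect[h] for h in histology])
    col = sigs.index(affected_signature)
    E[:, col] += effect_size * status[gene].to_numpy()
    if histology_confound:
        E[:, col] += histology_confound * (histology == histologies[0]).to_numpy()
    exposures = pd.DataFrame(E, index=patients, columns=sigs)
    return exposures, status, histology


# ---------------------------------------------------------------------------
# Cohort instantiation: planted counts realized as junctions per patient


TOY_FRAGILE_SITES = [
    ("chr1", 10_000_000, 10_500_000),
    ("chr2", 20_000_000, 20_500_000),
    ("chr3", 30_000_000, 30_500_000),
]


def instantiate_patient(
    counts_row, catalogue, config: SimConfig, rt_label, is_fragile,
    seed: int = 0, sample: str = "P1",
) -> tuple[SVSet, dict[str, int]]:
    """Realize one patient's category counts as simulated events.

    Each category is mapped to its event class with sizes drawn inside the
    category's bin; replication-timing categories are placed by rejection
    sampling against the *same* labeler used downstream, and fragile-site
    categories inside the provided sites.  Returns the SVSet and the realized
    truth category counts.
    """
    rng = np.random.default_rng(seed)
    placer = _Placer(config, rng)
    junctions: list[Junction] = []
    all_deltas: list[dict] = []
    realized: dict[str, int] = {}
    eid = 0
    for cat in catalogue.categories:
        n = int(counts_row.get(cat.name, 0))
        if n == 0:
            continue
        ec = cat.event_classes[0]
        if ec not in _BUILDERS:
            continue
        for _ in range(n):
            eid += 1
            cfg = _config_for_category(config, cat, rng)
            if cat.fragile:
                result = _fragile_event(
                    ec, cfg, rng, placer, is_fragile, f"{sample}.e{eid}", sample
                )
                if result is not None:
                    js, deltas, _ = result
                    junctions.extend(js)
                    all_deltas.append(deltas)
                    realized[cat.name] = realized.get(cat.name, 0) + 1
                continue
            for _ in range(config.retry_cap):
                js, deltas, truth = simulate_event(
                    ec, cfg, rng, placer, event_id=f"{sample}.e{eid}", sample=sample
                )
                bk = js[0].a
                ok = True
                if cat.rt is not None and rt_label(bk.chrom, bk.pos) != cat.rt:
                    ok = False
                if any(is_fragile(b.chrom, b.pos) for j in js for b in j.breakends):
                    ok = False
                size = truth.params.get("size_bp", truth.params.get("template_span_bp"))
                if cat.size_lo is not None and (size is None or size < cat.size_lo):
                    ok = False
                if cat.size_hi is not None and (size is None or size >= cat.size_hi):
                    ok = False
                if ok:
                    junctions.extend(js)
                    all_deltas.append(deltas)
                    realized[cat.name] = realized.get(cat.name, 0) + 1
                    break
    segments = _segments_from_deltas(
        config.build, all_deltas, config.background_cn, config.cn_noise_sd, rng, sample
    )
    sv_set = SVSet(sample=sample, junctions=junctions, segments=segments,
                   build=config.build, background_cn=config.background_cn)
    return sv_set, realized


def _fragile_event(ec, config, rng, placer, is_fragile, event_id, sample):
    """Place a small deletion/TD directly inside a fragile site."""
    sites = getattr(is_fragile, "sites", TOY_FRAGILE_SITES)
    for _ in range(config.retry_cap):
        chrom, lo, hi = sites[rng.integers(0, len(sites))]
        size = int(rng.integers(5_000, (hi - lo) // 3))
        pad = config.pad_bp
        start = int(rng.integers(lo + pad, hi - size - pad))
        if placer.overlaps(chrom, start - pad, start + size + pad):
            continue
        w0, s, e = start - pad, start, start + size
        w1 = e + pad
        if ec == "deletion":
            pieces = (P(chrom, w0, s), P(chrom, e, w1))
        else:
            pieces = (P(chrom, w0, e), P(chrom, s, w1))
        placer.reserve([(chrom, w0, w1)])
        derivative = (pieces,)
        pairs = dv.emit_junctions(derivative)
        deltas = dv.cn_delta_profile(derivative, [(chrom, w0, w1)])
        js = [
            Junction(id=f"{event_id}.j{k + 1}", sample=sample, a=a, b=b)
            for k, (a, b) in enumerate(pairs)
        ]
        return js, deltas, TruthRecord(event_id, ec, [j.id for j in js], {"size_bp": size})
    return None


def _config_for_category(config: SimConfig, cat, rng) -> SimConfig:
    """Restrict the size mixture to the category's size bin, if any."""
    lo = cat.size_lo or 2_000
    hi = cat.size_hi or 2_000_000
    if cat.size_lo is None and cat.size_hi is None:
        return config
    median = math.sqrt(lo * hi)
    sizes = dict(config.sizes)
    sizes["segment"] = SizeMixture(((1.0, median, min(0.5, math.log(hi / lo) / 4)),))
    return replace(config, sizes=sizes)


# ---------------------------------------------------------------------------
# Output


def write_truth_tsv(truths: Sequence[TruthRecord], path) -> None:
    import json

    with open(path, "w") as fh:
        fh.write("event_id\tevent_class\tjunction_ids\tparams\n")
        for t in truths:
            fh.write(
                f"{t.event_id}\t{t.event_class}\t{','.join(t.junction_ids)}\t"
                + json.dumps(t.params, default=str) + "\n"
            )
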