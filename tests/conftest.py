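import logging

import pytest

from svrearrange.genome_model import CNSegment, GenomeBuild, toy_build

logging.getLogger("svrearrange").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def build():
    return toy_build()


@pytest.fixture(scope="session")
def small_genome():
    """A seeded 40-event toy genome shared by classification-level tests.

    The toy build is ~20x denser in breakpoints per bp than the genome-scale
    configuration, so inner event segments (templates, re-replicated host
    pieces) are scaled down with it to stay within clustering range.
    """
    from svrearrange.simulator import SimConfig, SizeMixture, simulate_genome

    cfg = SimConfig(seed=11, build=toy_build(), cn_noise_sd=0.0)
    cfg.sizes = dict(cfg.sizes)
    cfg.sizes["template"] = SizeMixture(((1.0, 400, 0.3),))
    cfg.sizes["host_segment"] = SizeMixture(((1.0, 300, 0.3),))
    return simulate_genome(cfg.with_total_events(40))


@pytest.fixture()
def flat_cn(build):
    def make(sample="s", cn=2.0):
        return [CNSegment(sample, c, 0, l, cn) for c, l in build.chromosomes]

    return make


def cn_profile(build, sample, chrom, boundaries, values, background=2.0):
    """CN segments on one chromosome with given interior levels, background elsewhere."""
    segs = []
    length = build.lengths[chrom]
    cuts = [0] + list(boundaries) + [length]
    for (lo, hi), v in zip(zip(cuts, cuts[1:]), values):
        segs.append(CNSegment(sample, chrom, lo, hi, v))
    for c, l in build.chromosomes:
        if c != chrom:
            segs.append(CNSegment(sample, c, 0, l, background))
    return segs
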