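from __future__ import annotations

import numpy as np
import pytest

from scnakit.genome import MB, Chromosome, GenomeModel, Segment, SegmentedProfile


@pytest.fixture
def toy():
    from scnakit.genome import toy_genome

    return toy_genome()


@pytest.fixture
def big():
    from scnakit.genome import default_genome

    return default_genome()


@pytest.fixture
def rng():
    return np.random.default_rng(20220225)


def build_profile(genome: GenomeModel, spec, sample_id="fx"):
    """Build a tiling, status-called profile from sparse (chrom, start_mb,
    end_mb, mean, status) tuples; gaps become 0-mean 'normal' segments."""
    by_chrom: dict[str, list] = {}
    for chrom, s, e, mean, status in spec:
        by_chrom.setdefault(chrom, []).append((int(s * MB), int(e * MB), mean, status))
    segments = []
    for c in genome.chromosomes:
        cursor = 0
        for s, e, mean, status in sorted(by_chrom.get(c.name, [])):
            if s > cursor:
                segments.append(Segment(c.name, cursor, s, 0.0, "normal"))
            segments.append(Segment(c.name, s, e, mean, status))
            cursor = e
        if cursor < c.length:
            segments.append(Segment(c.name, cursor, c.length, 0.0, "normal"))
    return SegmentedProfile(sample_id, tuple(segments))


def profile_rows(profile):
    """(chrom, start, end, status) rows for the oracle functions."""
    return [(s.chrom, s.start, s.end, s.status) for s in profile.segments]


def profile_mean_rows(profile):
    return [(s.chrom, s.start, s.end, s.mean_log2) for s in profile.segments]


def genome_table(genome):
    return {c.name: (c.length, c.centromere) for c in genome.chromosomes}
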