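import numpy as np
import pytest

import viewpoint4c as v4
from viewpoint4c.regions import Region
from viewpoint4c.scoring import ScoreTrack

# 20 bp toy contig: NlaIII sites (CATG) at 2 and 15, DpnII site (GATC) at 9.
TOY_SEQ = "AACATGGTTGATCAACATGA"


def make_track(scores, start=0, width=100, chrom="chr1", stage="raw",
               bait=None, excluded=None):
    """Evenly spaced synthetic fragments carrying the given scores."""
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    starts = start + width * np.arange(n)
    return ScoreTrack(
        chrom=chrom,
        starts=starts,
        ends=starts + width,
        indices=np.arange(n),
        scores=scores,
        stage=stage,
        bait=bait,
        excluded=excluded,
    )


def track_at_distances(distances, scores, chrom="chr1", center=1_000_000,
                       stage="normalized"):
    """Fragments of width 2 whose midpoints sit exactly at bait-center +
    the given distances (ascending)."""
    distances = np.asarray(distances, dtype=float)
    scores = np.asarray(scores, dtype=float)
    mids = center + distances
    starts = (mids - 1).astype(int)
    return ScoreTrack(
        chrom=chrom,
        starts=starts,
        ends=starts + 2,
        indices=np.arange(len(mids)),
        scores=scores,
        stage=stage,
        bait=Region(chrom, center - 2, center + 2, "bait"),
    )


def naive_motif_scan(sequence, motif):
    """Brute-force oracle: motif start positions by checking every window."""
    seq = sequence.upper()
    m = len(motif)
    return [i for i in range(len(seq) - m + 1) if seq[i : i + m] == motif]


@pytest.fixture
def toy_genome():
    return {"toy": TOY_SEQ}


@pytest.fixture
def toy_fmap(toy_genome):
    return v4.digest(toy_genome)


@pytest.fixture(scope="session")
def study_cfg():
    """Study-scale simulation conditions shared across expensive tests."""
    return v4.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def study_fmap(study_cfg):
    """Fragment map of the default 2 Mb toy contig (digested once)."""
    return v4.digest(v4.make_toy_genome(study_cfg))


@pytest.fixture
def small_cfg():
    """A cheaper 600 kb configuration for smoke/IO tests."""
    return v4.SimulationConfig(
        seed=7,
        contig_length=600_000,
        bait_center=300_000,
        excluded=Region("chrS", 297_000, 303_000, "viewpoint_exclusion"),
        peak_region=Region("chrS", 340_000, 349_000, "peak"),
        total_reads=40_000,
    )
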