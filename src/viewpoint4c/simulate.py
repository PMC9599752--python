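"""Synthetic 4C-seq data with the statistical structure the pipeline assumes.

The generator produces (i) a toy contig with CATG/DpnII-style GATC sites
planted at geometrically spaced positions and a background guaranteed free of
accidental sites, and (ii) fragment-level count profiles for two conditions:
expected counts fall off with bait distance d as a power law A * d^exponent
(exponent −1 by default, the model the profile correction fits), one
condition carries a planted contact peak (fold >= 1 over the decay) in a
chosen region — an enhancer–promoter loop present in whisker-pad-like tissue
and absent in the kidney-like control — and realized counts are drawn
negative-binomially (4C fragment counts are overdispersed). Fragments inside
the viewpoint-exclusion zone receive deliberately huge counts so any leak of
the exclusion step is loud. All randomness flows from one integer seed
through per-(condition, replicate) seed sequences, so each track is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import yaml

from .digest import (
    DPNII,
    NLAIII,
    FragmentMap,
    RestrictionEnzymeSpec,
    digest,
    write_fasta,
    write_fragment_map,
)
from .regions import Region
from .scoring import ScoreTrack, write_score_table
from .signal import SignalParams, process_replicate
from .stats import StatsParams, TestResult, compare_conditions

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MOTIF_CODES = {"CATG": np.array([1, 0, 3, 2], dtype=np.uint8),
                "GATC": np.array([2, 0, 3, 1], dtype=np.uint8)}

CONDITIONS = ("enriched", "control")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-like defaults: a 2 Mb cis contig, bait at its center, 100,000
    total reads decaying with exponent −1, a 9 kb peak region ~90 kb from the
    bait (about 30 fragments at the ~300 bp primary-site spacing) with 3-fold
    enrichment in the 'enriched' condition only, negative-binomial dispersion
    0.1, and two replicates per condition. ``peak_fold = 1`` encodes the null
    (kidney-like) case for both conditions."""

    seed: int = 0
    chrom: str = "chrS"
    contig_length: int = 2_000_000
    mean_primary_spacing: int = 300
    mean_secondary_spacing: int = 280
    bait_center: int = 1_000_000
    total_reads: int = 100_000
    decay_exponent: float = -1.0
    peak_region: Region = Region("chrS", 1_090_000, 1_099_000, "peak")
    peak_fold: float = 3.0
    dispersion: float = 0.1
    n_replicates_per_condition: int = 2
    excluded: Region = Region("chrS", 997_000, 1_003_000, "viewpoint_exclusion")

    def __post_init__(self) -> None:
        if min(self.mean_primary_spacing, self.mean_secondary_spacing) < 8:
            raise ValueError("mean restriction-site spacing must be >= 8 bp")
        if self.peak_fold < 1:
            raise ValueError("peak_fold must be >= 1 (1 encodes the null)")
        if not (0 < self.bait_center < self.contig_length):
            raise ValueError("bait_center must lie inside the contig")

    @property
    def bait(self) -> Region:
        return Region(self.chrom, self.bait_center - 2, self.bait_center + 2, "bait")


def _find_motif_positions(codes: np.ndarray, motif: np.ndarray) -> np.ndarray:
    n = len(codes) - len(motif) + 1
    if n <= 0:
        return np.array([], dtype=np.int64)
    mask = np.ones(n, dtype=bool)
    for j, c in enumerate(motif):
        mask &= codes[j : j + n] == c
    return np.flatnonzero(mask)


def _planted_positions(rng: np.random.Generator, mean_spacing: int, length: int) -> np.ndarray:
    n_draw = int(2 * length / mean_spacing) + 20
    gaps = np.maximum(rng.geometric(1.0 / mean_spacing, size=n_draw), 8)
    pos = np.cumsum(gaps)
    return pos[pos < length - 4]


def make_toy_genome(config: SimulationConfig) -> dict[str, str]:
    """Random ACGT contig with primary/secondary motifs planted at
    geometric spacings and no accidental motif occurrences elsewhere."""
    rng = np.random.default_rng([config.seed, 11])
    L = config.contig_length
    primary = _planted_positions(rng, config.mean_primary_spacing, L)
    secondary = _planted_positions(rng, config.mean_secondary_spacing, L)
    # Drop secondary sites colliding with planted primary motifs.
    if len(primary) and len(secondary):
        j = np.searchsorted(primary, secondary)
        left = np.where(j > 0, secondary - primary[np.maximum(j - 1, 0)], 8)
        right = np.where(j < len(primary), primary[np.minimum(j, len(primary) - 1)] - secondary, 8)
        secondary = secondary[(left >= 4) & (right >= 4)]

    codes = rng.integers(0, 4, size=L, dtype=np.uint8)
    for _ in range(200):  # scrub accidental motifs from the background
        hits = np.concatenate(
            [_find_motif_positions(codes, m) for m in _MOTIF_CODES.values()]
        )
        if len(hits) == 0:
            break
        codes[hits + 1] = (codes[hits + 1] + rng.integers(1, 4, size=len(hits))) % 4
    else:
        raise RuntimeError("could not scrub accidental motifs from background")

    covered = np.zeros(L, dtype=bool)
    for pos_arr, motif in ((primary, "CATG"), (secondary, "GATC")):
        for p in pos_arr:
            codes[p : p + 4] = _MOTIF_CODES[motif]
            covered[p : p + 4] = True

    planted = {"CATG": set(primary.tolist()), "GATC": set(secondary.tolist())}
    for _ in range(200):  # scrub junction-created occurrences, keep planted ones
        dirty = False
        for motif, mcodes in _MOTIF_CODES.items():
            for o in _find_motif_positions(codes, mcodes):
                if int(o) in planted[motif]:
                    continue
                mutable = [j for j in range(4) if not covered[o + j]]
                if not mutable:  # fully inside planted bases: impossible by construction
                    raise RuntimeError("accidental motif inside planted sites")
                j = mutable[0]
                codes[o + j] = (codes[o + j] + rng.integers(1, 4)) % 4
                dirty = True
        if not dirty:
            break
    else:
        raise RuntimeError("could not remove junction motif occurrences")

    return {config.chrom: _BASES[codes].tobytes().decode("ascii")}


def planted_primary_cuts(config: SimulationConfig) -> np.ndarray:
    """Cut coordinates implied by the planted primary sites (motif start + 4)."""
    rng = np.random.default_rng([config.seed, 11])
    return _planted_positions(rng, config.mean_primary_spacing, config.contig_length) + 4


def negative_binomial_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draws with var = mean + dispersion * mean^2; Poisson at dispersion 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean).astype(float)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def expected_profile(
    fmap: FragmentMap, config: SimulationConfig
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """(lambda per fragment, amplitude A, excluded mask, peak mask) for the
    fold-free decay; A is chosen so the retained-fragment lambdas sum to
    ``total_reads``."""
    starts, ends, _, _ = fmap.arrays(config.chrom)
    mids = 0.5 * (starts + ends)
    d = np.maximum(np.abs(mids - config.bait_center), 1.0)
    excl = (starts < config.excluded.end) & (ends > config.excluded.start)
    peak = (mids >= config.peak_region.start) & (mids < config.peak_region.end)
    if config.peak_region.end > config.contig_length:
        raise ValueError("peak_region extends beyond the contig")
    base = d ** config.decay_exponent
    A = config.total_reads / base[~excl].sum()
    return A * base, float(A), excl, peak


def decay_intercept_truth(fmap: FragmentMap, config: SimulationConfig) -> float:
    """log10 of the decay amplitude on the normalized scale for the fold-free
    condition: normalization divides scores by the mean expected count of
    retained fragments within ±1 Mb of the bait, so the normalized decay is
    (A / window_mean) / d and its log-log intercept is log10(A / window_mean)."""
    lam, A, excl, _ = expected_profile(fmap, config)
    starts, ends, _, _ = fmap.arrays(config.chrom)
    mids = 0.5 * (starts + ends)
    in_window = np.abs(mids - config.bait_center) <= SignalParams().norm_halfwidth
    window_mean = lam[~excl & in_window].mean()
    return float(np.log10(A / window_mean))


def decay_intercept_estimand(
    fmap: FragmentMap,
    config: SimulationConfig,
    params: SignalParams | None = None,
) -> float:
    """Exact expected value of the decay-fit intercept under the simulator.

    The fit estimator is the mean of log10(score) + log10(distance) over
    positive-score fragments; because the log of a count is a concave
    transform, its expectation differs from log10(lambda) by a small-count
    (Jensen) bias of order -(1/lambda + dispersion)/2 nats plus a
    zero-truncation term. This function computes the estimator's exact
    expectation from the negative-binomial pmf, fragment by fragment — the
    distribution-level truth the fitted intercept converges to. Compare with
    :func:`decay_intercept_truth` (log10 of the amplitude itself) to see the
    size of the log-scale bias at a given depth.
    """
    from scipy import stats as sps

    params = params or SignalParams()
    lam, A, excl, _ = expected_profile(fmap, config)
    starts, ends, _, _ = fmap.arrays(config.chrom)
    mids = 0.5 * (starts + ends)
    d = np.maximum(np.abs(mids - config.bait_center), 1.0)
    in_window = d <= params.norm_halfwidth
    window_mean = lam[~excl & in_window].mean()
    eligible = ~excl & (d >= params.fit_min_distance) & (d <= params.fit_max_distance)
    lam_e, d_e = lam[eligible], d[eligible]
    lam_max = lam_e.max()
    kmax = int(np.ceil(lam_max + 12 * np.sqrt(lam_max + config.dispersion * lam_max**2)))
    ks = np.arange(1, kmax + 1)
    logk = np.log10(ks)
    e_log = np.empty(len(lam_e))
    p_pos = np.empty(len(lam_e))
    chunk = 512
    for lo in range(0, len(lam_e), chunk):
        m = lam_e[lo : lo + chunk, None]
        if config.dispersion <= 1e-12:
            pmf = sps.poisson.pmf(ks[None, :], m)
            p0 = np.exp(-m[:, 0])
        else:
            size = 1.0 / config.dispersion
            pmf = sps.nbinom.pmf(ks[None, :], size, size / (size + m))
            p0 = sps.nbinom.pmf(0, size, size / (size + m[:, 0]))
        p_pos[lo : lo + chunk] = 1.0 - p0
        e_log[lo : lo + chunk] = (pmf * logk).sum(axis=1) / (1.0 - p0)
    terms = e_log - np.log10(window_mean) + np.log10(d_e)
    return float((p_pos * terms).sum() / p_pos.sum())


def simulate_scores(
    fmap: FragmentMap, config: SimulationConfig
) -> dict[str, list[ScoreTrack]]:
    """Raw replicate tracks for the enriched and control conditions.

    The enriched condition multiplies the decay by ``peak_fold`` inside
    ``peak_region``; the control never does. Fragments overlapping the
    exclusion zone get planted counts 50x the largest expected count.
    """
    if config.chrom not in fmap.fragments:
        raise ValueError(f"fragment map has no contig {config.chrom}")
    lam, A, excl, peak = expected_profile(fmap, config)
    starts, ends, idx, _ = fmap.arrays(config.chrom)
    planted_high = float(np.ceil(50 * lam[~excl].max()))
    out: dict[str, list[ScoreTrack]] = {}
    for c, name in enumerate(CONDITIONS):
        fold = config.peak_fold if name == "enriched" else 1.0
        lam_c = np.where(peak, lam * fold, lam)
        reps = []
        for r in range(config.n_replicates_per_condition):
            rng = np.random.default_rng([config.seed, 17, c, r])
            counts = negative_binomial_counts(rng, lam_c, config.dispersion)
            counts[excl] = planted_high
            reps.append(
                ScoreTrack(
                    chrom=config.chrom,
                    starts=starts,
                    ends=ends,
                    indices=idx,
                    scores=counts,
                    stage="raw",
                    bait=config.bait,
                    meta={
                        "condition": name,
                        "replicate": r,
                        "amplitude": A,
                        "peak_fold": fold,
                    },
                )
            )
        out[name] = reps
    return out


class SimulatedComparison(NamedTuple):
    results: dict[str, TestResult]
    processed: dict[str, list[dict[str, ScoreTrack]]]


def simulate_comparison(
    fmap: FragmentMap,
    config: SimulationConfig,
    signal_params: SignalParams | None = None,
    stats_params: StatsParams | None = None,
    region: Region | None = None,
    stages: Sequence[str] = ("normalized", "profile_corrected"),
) -> SimulatedComparison:
    """Simulate both conditions and run the full post-alignment analysis:
    exclusion -> normalization -> profile correction -> region test."""
    signal_params = signal_params or SignalParams()
    tracks = simulate_scores(fmap, config)
    processed = {
        name: [process_replicate(t, config.excluded, signal_params) for t in reps]
        for name, reps in tracks.items()
    }
    results = compare_conditions(
        processed["enriched"],
        processed["control"],
        region or config.peak_region,
        stats_params,
        stages=stages,
    )
    return SimulatedComparison(results, processed)


def write_fixture_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a ready-to-run bundle: FASTA, fragment BED, per-replicate score
    TSVs, and a pipeline YAML config. Byte-stable for a fixed seed."""
    out = Path(out_dir)
    (out / "scores").mkdir(parents=True, exist_ok=True)
    genome = make_toy_genome(config)
    fasta = out / "genome.fa"
    write_fasta(genome, fasta)
    fmap = digest(genome, NLAIII, DPNII, genome_id=f"toy-seed{config.seed}")
    bed = out / "fragments.bed"
    write_fragment_map(fmap, bed)
    tracks = simulate_scores(fmap, config)
    conditions: dict[str, list[str]] = {}
    for name, reps in tracks.items():
        paths = []
        for r, track in enumerate(reps):
            p = out / "scores" / f"{name}_rep{r}.tsv"
            write_score_table(track, p)
            paths.append(str(p.relative_to(out)))
        conditions[name] = paths
    cfg_yaml = {
        "genome": "genome.fa",
        "fragment_map": "fragments.bed",
        "enzymes": {"primary": "NlaIII:CATG:4", "secondary": "DpnII:GATC:0"},
        "input_kind": "table",
        "conditions": conditions,
        "viewpoints": [
            {
                "name": "bait",
                "bait": str(config.bait),
                "excluded": str(config.excluded),
            }
        ],
        "target_regions": [{"name": "peak", "region": str(config.peak_region)}],
        "signal": {
            "norm_halfwidth": SignalParams().norm_halfwidth,
            "smooth_window": SignalParams().smooth_window,
            "fit_min_distance": SignalParams().fit_min_distance,
            "fit_max_distance": SignalParams().fit_max_distance,
        },
        "keep_blind": False,
        "output_dir": "results",
        "seed": config.seed,
    }
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg_yaml, fh, sort_keys=True)
    return {"fasta": fasta, "bed": bed, "config": cfg_path}
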