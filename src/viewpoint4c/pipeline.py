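"""Configured end-to-end runs: digest -> score -> normalize -> correct -> test.

A run is described by a YAML config naming the genome (or a precomputed
fragment map), the per-condition replicate inputs (score tables, SAM/BAM, or
BED reads), the viewpoints with their exclusion zones, and the target regions
to test. Defaults are preloaded with the murine Lef1/Leaf coordinates (mm10)
so a config pointing at mm10-aligned data needs nothing else.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .digest import (
    DPNII,
    NLAIII,
    FragmentMap,
    RestrictionEnzymeSpec,
    digest,
    read_fasta,
    read_fragment_map,
)
from .regions import Region, parse_region
from .scoring import (
    ScoreTrack,
    assign_reads,
    reads_from_bed,
    reads_from_sam,
    track_from_table,
    write_bedgraph,
    write_score_table,
)
from .signal import SignalParams, process_replicate
from .stats import StatsParams, TestResult, compare_conditions

logger = logging.getLogger(__name__)

# mm10 coordinates of the Lef1/Leaf system (half-open, as printed).
LEF1_PROMOTER_EXCLUSION = Region("chr3", 131_104_979, 131_112_546, "Lef1_promoter_viewpoint")
LEAF_EXCLUSION = Region("chr3", 131_016_310, 131_022_769, "Leaf_viewpoint")
LEAF_ANALYSIS_REGION = Region("chr3", 131_008_663, 131_026_430, "Leaf_region")
LEF1_GENE_REGION = Region("chr3", 131_106_987, 131_227_057, "Lef1_promoter_CDS")
LEAF_ELEMENT = Region("chr3", 131_019_746, 131_020_624, "Leaf")
LEAF_PRIMATE_DELETION = Region("chr3", 131_020_103, 131_020_624, "Leaf_primate_deletion")

DEFAULT_VIEWPOINT_REGIONS = {
    "Lef1_promoter": LEF1_PROMOTER_EXCLUSION,
    "Leaf": LEAF_EXCLUSION,
}
DEFAULT_TARGET_REGIONS = (LEAF_ANALYSIS_REGION, LEF1_GENE_REGION)


class ConfigError(ValueError):
    """Aggregated configuration problems, one per line."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid pipeline config:\n  - " + "\n  - ".join(self.problems))


@dataclass(frozen=True)
class Viewpoint:
    """A 4C viewpoint: bait anchor plus the surrounding exclusion zone.

    When the bait is not given separately it defaults to a 4 bp interval at
    the center of the exclusion region (the normalization and decay model
    anchor to the center of the bait coordinates)."""

    name: str
    excluded: Region
    bait: Region | None = None

    def resolved_bait(self) -> Region:
        if self.bait is not None:
            return self.bait
        c = int(self.excluded.midpoint)
        return Region(self.excluded.chrom, c - 2, c + 2, f"{self.name}_bait")


@dataclass
class PipelineConfig:
    conditions: dict[str, list[Path]]
    genome: Path | None = None
    fragment_map: Path | None = None
    primary: RestrictionEnzymeSpec = NLAIII
    secondary: RestrictionEnzymeSpec = DPNII
    input_kind: str = "table"  # table | sam | bed
    viewpoints: tuple[Viewpoint, ...] = tuple(
        Viewpoint(name, region) for name, region in DEFAULT_VIEWPOINT_REGIONS.items()
    )
    target_regions: tuple[Region, ...] = DEFAULT_TARGET_REGIONS
    signal: SignalParams = field(default_factory=SignalParams)
    stats: StatsParams = field(default_factory=StatsParams)
    keep_blind: bool = False
    end_tolerance: int = 5
    min_mapq: int = 0
    output_dir: Path = Path("results")
    seed: int = 0


def _parse_region_entry(entry, problems: list[str], label: str) -> Region | None:
    try:
        if isinstance(entry, dict):
            return parse_region(str(entry["region"]), entry.get("name"))
        return parse_region(str(entry))
    except (ValueError, KeyError) as exc:
        problems.append(f"{label}: {exc}")
        return None


def validate_config(path: str | Path) -> PipelineConfig:
    """Load, default, and validate a YAML pipeline config.

    Relative paths are resolved against the config file's directory; every
    problem found is reported in one aggregated error.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent
    problems: list[str] = []

    def respath(value) -> Path:
        p = Path(value)
        return p if p.is_absolute() else base / p

    conditions: dict[str, list[Path]] = {}
    for name, files in (raw.get("conditions") or {}).items():
        if isinstance(files, (str, Path)):
            files = [files]
        resolved = []
        for f in files:
            rp = respath(f)
            if not rp.exists():
                problems.append(f"conditions.{name}: file not found: {rp}")
            resolved.append(rp)
        if not resolved:
            problems.append(f"conditions.{name}: no input files")
        conditions[name] = resolved
    if not conditions:
        problems.append("conditions: at least one condition with inputs is required")

    genome = raw.get("genome")
    fragmap = raw.get("fragment_map")
    if genome is not None:
        genome = respath(genome)
        if not genome.exists():
            problems.append(f"genome: file not found: {genome}")
    if fragmap is not None:
        fragmap = respath(fragmap)
        if not fragmap.exists():
            problems.append(f"fragment_map: file not found: {fragmap}")
    if genome is None and fragmap is None:
        problems.append("either genome (FASTA) or fragment_map (BED) is required")

    enzymes = raw.get("enzymes") or {}
    primary, secondary = NLAIII, DPNII
    try:
        if "primary" in enzymes:
            primary = RestrictionEnzymeSpec.from_string(enzymes["primary"])
        if "secondary" in enzymes:
            secondary = RestrictionEnzymeSpec.from_string(enzymes["secondary"])
    except ValueError as exc:
        problems.append(f"enzymes: {exc}")

    input_kind = raw.get("input_kind", "table")
    if input_kind not in ("table", "sam", "bed"):
        problems.append(f"input_kind must be table|sam|bed, got {input_kind!r}")

    viewpoints: list[Viewpoint] = []
    for i, vp in enumerate(raw.get("viewpoints") or []):
        name = vp.get("name", f"viewpoint{i}")
        excluded = _parse_region_entry(vp.get("excluded"), problems, f"viewpoints[{i}].excluded")
        bait = None
        if vp.get("bait") is not None:
            bait = _parse_region_entry(vp.get("bait"), problems, f"viewpoints[{i}].bait")
        if excluded is not None:
            if bait is not None and not bait.overlaps(excluded):
                problems.append(
                    f"viewpoints[{i}]: bait {bait} does not overlap exclusion {excluded}"
                )
            viewpoints.append(Viewpoint(name, excluded.with_name(name), bait))
    if not viewpoints:
        viewpoints = [Viewpoint(n, r) for n, r in DEFAULT_VIEWPOINT_REGIONS.items()]

    targets: list[Region] = []
    for i, entry in enumerate(raw.get("target_regions") or []):
        region = _parse_region_entry(entry, problems, f"target_regions[{i}]")
        if region is not None:
            targets.append(region if region.name else region.with_name(f"region{i}"))
    if not targets:
        targets = list(DEFAULT_TARGET_REGIONS)

    signal = SignalParams()
    try:
        signal = SignalParams(**{**dataclasses.asdict(signal), **(raw.get("signal") or {})})
    except (TypeError, ValueError) as exc:
        problems.append(f"signal: {exc}")
    stats = StatsParams()
    stats_raw = raw.get("stats") or {}
    try:
        stats = StatsParams(
            alpha=stats_raw.get("alpha", stats.alpha),
            exact_max_n=stats_raw.get("exact_max_n", stats.exact_max_n),
        )
    except (TypeError, ValueError) as exc:
        problems.append(f"stats: {exc}")

    if problems:
        raise ConfigError(problems)

    return PipelineConfig(
        conditions=conditions,
        genome=genome,
        fragment_map=fragmap,
        primary=primary,
        secondary=secondary,
        input_kind=input_kind,
        viewpoints=tuple(viewpoints),
        target_regions=tuple(targets),
        signal=signal,
        stats=stats,
        keep_blind=bool(raw.get("keep_blind", False)),
        end_tolerance=int(raw.get("end_tolerance", 5)),
        min_mapq=int(raw.get("min_mapq", 0)),
        output_dir=respath(raw.get("output_dir", "results")),
        seed=int(raw.get("seed", 0)),
    )


@dataclass
class PipelineResult:
    fmap: FragmentMap
    tracks: dict  # viewpoint -> condition -> list of {stage: ScoreTrack}
    tests: dict  # viewpoint -> region name -> {stage: TestResult}
    output_dir: Path


def _load_raw_track(
    path: Path, cfg: PipelineConfig, fmap: FragmentMap, vp: Viewpoint
) -> ScoreTrack:
    chrom = vp.excluded.chrom
    if cfg.input_kind == "table":
        track = track_from_table(path, fmap, cfg.keep_blind)
    else:
        reads = (
            reads_from_sam(path, cfg.min_mapq)
            if cfg.input_kind == "sam"
            else reads_from_bed(path)
        )
        result = assign_reads(reads, fmap, cfg.end_tolerance, cfg.keep_blind)
        if chrom not in result.tracks:
            raise ValueError(f"viewpoint chromosome {chrom} absent from fragment map")
        track = result.tracks[chrom]
        track.meta["unassigned"] = result.unassigned
        logger.info("%s: %d reads unassigned", path.name, result.unassigned)
    if track.chrom != chrom:
        raise ValueError(
            f"input {path} is on {track.chrom}, viewpoint {vp.name} on {chrom}"
        )
    if track.bait is None:
        track = dataclasses.replace(track, bait=vp.resolved_bait())
    return track


def _test_result_row(vp: str, region: Region, stage: str, res: TestResult) -> dict:
    return {
        "viewpoint": vp,
        "region": region.name or str(region),
        "region_coords": str(region),
        "stage": stage,
        "n1": res.n1,
        "n2": res.n2,
        "U": res.U,
        "p_two_tailed": res.p_two_tailed,
        "normality_p_a": res.normality_p[0],
        "normality_p_b": res.normality_p[1],
        "stars": res.stars,
        "method": res.method,
    }


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute a full configured run and write the result bundle.

    Per viewpoint and replicate: bedGraphs and score tables for all stages.
    Per viewpoint and target region: TestResult TSV/JSON plus a long-format
    per-fragment score table ready for boxplots. A run log echoes every
    parameter. Outputs are deterministic for fixed inputs.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("viewpoint4c")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("viewpoint4c %s", __version__)
        logger.info("numpy %s", np.__version__)
        logger.info("seed=%d", cfg.seed)
        logger.info(
            "enzymes: primary=%s:%s:%d secondary=%s:%s:%d",
            cfg.primary.name, cfg.primary.motif, cfg.primary.cut_offset,
            cfg.secondary.name, cfg.secondary.motif, cfg.secondary.cut_offset,
        )
        logger.info(
            "signal: norm_halfwidth=%d smooth_window=%d fit_min_distance=%d fit_max_distance=%d",
            cfg.signal.norm_halfwidth, cfg.signal.smooth_window,
            cfg.signal.fit_min_distance, cfg.signal.fit_max_distance,
        )
        logger.info(
            "stats: alpha=%g exact_max_n=%d", cfg.stats.alpha, cfg.stats.exact_max_n
        )
        logger.info(
            "keep_blind=%s end_tolerance=%d min_mapq=%d",
            cfg.keep_blind, cfg.end_tolerance, cfg.min_mapq,
        )

        if cfg.fragment_map is not None:
            fmap = read_fragment_map(cfg.fragment_map)
        else:
            genome = read_fasta(cfg.genome)
            fmap = digest(genome, cfg.primary, cfg.secondary, genome_id=str(cfg.genome))
        logger.info("fragment map: %d fragments on %d contigs",
                    fmap.n_fragments(), len(fmap.chroms))

        all_tracks: dict = {}
        all_tests: dict = {}
        long_rows: list[dict] = []
        for vp in cfg.viewpoints:
            if vp.excluded.chrom not in fmap.fragments:
                logger.warning(
                    "viewpoint %s: chromosome %s not in fragment map; skipped",
                    vp.name, vp.excluded.chrom,
                )
                continue
            vp_dir = out / vp.name
            vp_dir.mkdir(exist_ok=True)
            vp_tracks: dict[str, list[dict[str, ScoreTrack]]] = {}
            for cond, paths in cfg.conditions.items():
                reps = []
                for r, p in enumerate(paths):
                    try:
                        raw = _load_raw_track(Path(p), cfg, fmap, vp)
                        stages = process_replicate(raw, vp.excluded, cfg.signal)
                    except Exception as exc:
                        raise RuntimeError(
                            f"viewpoint {vp.name}, condition {cond}, replicate {r}: {exc}"
                        ) from exc
                    for stage, track in stages.items():
                        stem = f"{cond}_rep{r}.{stage}"
                        write_bedgraph(track, vp_dir / f"{stem}.bedGraph",
                                       name=f"{vp.name}.{stem}")
                        write_score_table(track, vp_dir / f"{stem}.tsv")
                    reps.append(stages)
                vp_tracks[cond] = reps
            all_tracks[vp.name] = vp_tracks

            cond_names = list(cfg.conditions)
            vp_tests: dict[str, dict[str, TestResult]] = {}
            if len(cond_names) == 2:
                a, b = cond_names
                for region in cfg.target_regions:
                    if region.chrom != vp.excluded.chrom:
                        logger.warning(
                            "viewpoint %s: target %s on other chromosome; skipped",
                            vp.name, region,
                        )
                        continue
                    results = compare_conditions(
                        vp_tracks[a], vp_tracks[b], region, cfg.stats
                    )
                    vp_tests[region.name or str(region)] = results
                    for stage, res in results.items():
                        logger.info(
                            "test %s / %s / %s: U=%g p=%.4g %s (n=%d vs %d)",
                            vp.name, region.name or region, stage,
                            res.U, res.p_two_tailed, res.stars, res.n1, res.n2,
                        )
                    for cond in cond_names:
                        for r, rep in enumerate(vp_tracks[cond]):
                            for stage in ("normalized", "profile_corrected"):
                                track = rep[stage]
                                mid = track.midpoints
                                mask = (mid >= region.start) & (mid < region.end)
                                for m, s in zip(mid[mask], track.scores[mask]):
                                    long_rows.append({
                                        "viewpoint": vp.name,
                                        "region": region.name or str(region),
                                        "condition": cond,
                                        "replicate": r,
                                        "stage": stage,
                                        "fragment_midpoint": f"{m:.1f}",
                                        "score": f"{s:.10g}",
                                    })
            else:
                logger.warning(
                    "differential testing needs exactly 2 conditions, got %d; skipped",
                    len(cond_names),
                )
            all_tests[vp.name] = vp_tests

        rows = [
            _test_result_row(vp, region_lookup, stage, res)
            for vp, regions in all_tests.items()
            for rname, per_stage in regions.items()
            for stage, res in per_stage.items()
            for region_lookup in [
                next(t for t in cfg.target_regions if (t.name or str(t)) == rname)
            ]
        ]
        _write_tsv(out / "test_results.tsv", rows)
        with open(out / "test_results.json", "w") as fh:
            json.dump(rows, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")
        _write_tsv(out / "region_scores_long.tsv", long_rows)
        logger.info("outputs written to %s", out)
        return PipelineResult(fmap, all_tracks, all_tests, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _write_tsv(path: Path, rows: list[dict]) -> None:
    with open(path, "w") as fh:
        if not rows:
            fh.write("")
            return
        cols = list(rows[0])
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row[c]) for c in cols) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.10g}"
    return str(v)
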