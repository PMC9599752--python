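"""Per-fragment contact scoring and viewpoint exclusion.

In 4C-seq, valid reads start at a restriction site, so a read is assigned to
a fragment when its 5' end falls within a small tolerance of one of the
fragment's boundaries; the fragment score is the read count summed over both
ends. The fragments directly surrounding the viewpoint are dominated by
self-ligation and undigested products and are removed from all downstream
analysis (viewpoint exclusion).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .digest import FragmentMap
from .regions import Region, parse_region

logger = logging.getLogger(__name__)

STAGES = ("raw", "normalized", "smoothed", "profile_corrected")


@dataclass(frozen=True)
class AlignedRead:
    """Minimal ingestion contract for an aligned read (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read must satisfy start < end: {self}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def anchor(self) -> int:
        """Coordinate used to match restriction-site boundaries.

        For + reads the 5' end is the leftmost base (``start``); for - reads
        it is the rightmost base, compared as the half-open ``end`` so that a
        read abutting a cut site matches it at distance 0.
        """
        return self.start if self.strand == "+" else self.end


@dataclass
class ScoreTrack:
    """Per-fragment scores for one chromosome at one processing stage."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    indices: np.ndarray
    scores: np.ndarray
    stage: str = "raw"
    bait: Region | None = None
    excluded: Region | None = None
    extrapolated: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        n = len(self.starts)
        if not (len(self.ends) == len(self.indices) == len(self.scores) == n):
            raise ValueError("ScoreTrack arrays must have equal length")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if n and np.any(np.diff(self.starts) < 0):
            raise ValueError("ScoreTrack fragments must be sorted by start")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("ScoreTrack scores must be finite")
        if self.stage in ("raw", "normalized", "smoothed") and n and self.scores.min() < 0:
            raise ValueError(f"negative score at stage {self.stage}")

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    def distances(self, center: float | None = None) -> np.ndarray:
        """|fragment midpoint - bait center| for every retained fragment."""
        if center is None:
            if self.bait is None:
                raise ValueError("track has no bait region; pass center explicitly")
            center = self.bait.midpoint
        return np.abs(self.midpoints - center)

    def with_scores(self, scores: np.ndarray, stage: str, **meta) -> "ScoreTrack":
        new = dataclasses.replace(self, scores=np.asarray(scores, dtype=np.float64), stage=stage)
        new.meta = {**self.meta, **meta}
        return new

    def subset(self, mask: np.ndarray) -> "ScoreTrack":
        new = dataclasses.replace(
            self,
            starts=self.starts[mask],
            ends=self.ends[mask],
            indices=self.indices[mask],
            scores=self.scores[mask],
        )
        if self.extrapolated is not None:
            new.extrapolated = self.extrapolated[mask]
        new.meta = dict(self.meta)
        return new


class AssignmentResult(NamedTuple):
    tracks: dict[str, ScoreTrack]
    unassigned: int


def _track_from_map(fmap: FragmentMap, chrom: str, keep_blind: bool) -> ScoreTrack:
    starts, ends, idx, blind = fmap.arrays(chrom)
    keep = np.ones(len(starts), dtype=bool) if keep_blind else ~blind
    return ScoreTrack(
        chrom=chrom,
        starts=starts[keep],
        ends=ends[keep],
        indices=idx[keep],
        scores=np.zeros(int(keep.sum())),
        stage="raw",
        meta={"keep_blind": keep_blind, "n_blind_dropped": int((~keep).sum())},
    )


def _nearest_within(sorted_arr: np.ndarray, point: int, tol: int) -> int:
    """Index of the element of ``sorted_arr`` nearest ``point`` if within
    ``tol``, else -1. Ties go to the left element."""
    if len(sorted_arr) == 0:
        return -1
    j = int(np.searchsorted(sorted_arr, point))
    best, best_d = -1, tol + 1
    for k in (j - 1, j):
        if 0 <= k < len(sorted_arr):
            d = abs(int(sorted_arr[k]) - point)
            if d < best_d:
                best, best_d = k, d
    return best


def assign_reads(
    reads: Iterable[AlignedRead],
    fmap: FragmentMap,
    end_tolerance: int = 5,
    keep_blind: bool = False,
) -> AssignmentResult:
    """Count reads onto fragment ends, returning one raw track per contig.

    A read is assigned to exactly one fragment: a + read to the fragment
    whose *start* boundary is nearest its 5' end (it extends rightward into
    that fragment), a - read to the fragment whose *end* boundary is nearest;
    if the strand-preferred boundary is absent (contig edge), the opposite
    boundary is tried. Reads matching no retained-fragment boundary within
    ``end_tolerance``, or on contigs absent from the map, are tallied as
    unassigned — never an error. Blind-both-ends fragments are dropped
    before assignment unless ``keep_blind``, so the conservation identity
    (sum of scores + unassigned = number of reads) always holds.
    """
    tracks = {c: _track_from_map(fmap, c, keep_blind) for c in fmap.chroms}
    unassigned = 0
    for read in reads:
        track = tracks.get(read.chrom)
        if track is None or len(track) == 0:
            unassigned += 1
            continue
        p = read.anchor
        at_start = _nearest_within(track.starts, p, end_tolerance)
        at_end = _nearest_within(track.ends, p, end_tolerance)
        preferred, fallback = (at_start, at_end) if read.strand == "+" else (at_end, at_start)
        frag = preferred if preferred >= 0 else fallback
        if frag >= 0:
            track.scores[frag] += 1
        else:
            unassigned += 1
    for track in tracks.values():
        track.meta["stage_history"] = ["raw"]
    return AssignmentResult(tracks, unassigned)


def exclude_viewpoint(track: ScoreTrack, excluded: Region) -> ScoreTrack:
    """Drop every fragment overlapping the viewpoint-exclusion region >= 1 bp.

    Idempotent; a region on another chromosome is a warned no-op. Removed
    fragment indices are recorded in ``track.meta['excluded_fragments']``.
    """
    if excluded.chrom != track.chrom:
        warnings.warn(
            f"exclusion region {excluded} is not on track chromosome {track.chrom}; no-op",
            stacklevel=2,
        )
        return track
    overlap = (track.starts < excluded.end) & (track.ends > excluded.start)
    new = track.subset(~overlap)
    new.excluded = excluded
    removed = sorted(
        set(track.meta.get("excluded_fragments", ())) | set(track.indices[overlap].tolist())
    )
    new.meta["excluded_fragments"] = removed
    return new


# ---------------------------------------------------------------------------
# I/O: reads, score tables, bedGraph


def reads_from_sam(path: str | Path, min_mapq: int = 0) -> list[AlignedRead]:
    """Load mapped primary alignments from SAM/BAM as AlignedRead records."""
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            reads.append(
                AlignedRead(
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                )
            )
    return reads


def reads_from_bed(path: str | Path) -> list[AlignedRead]:
    """Load reads from BED (chrom, start, end[, name, score, strand])."""
    reads = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 else "+"
            reads.append(AlignedRead(f[0], int(f[1]), int(f[2]), strand))
    return reads


def write_score_table(track: ScoreTrack, path: str | Path) -> None:
    """Write a TSV score table with track metadata in '#key=value' headers."""
    with open(path, "w") as fh:
        fh.write(f"#stage={track.stage}\n")
        fh.write(f"#chrom={track.chrom}\n")
        if track.bait is not None:
            fh.write(f"#bait={track.bait}\n")
        if track.excluded is not None:
            fh.write(f"#excluded={track.excluded}\n")
        fh.write("chrom\tstart\tend\tindex\tscore\n")
        for s, e, i, v in zip(track.starts, track.ends, track.indices, track.scores):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{i}\t{v:.10g}\n")


def read_score_table(path: str | Path) -> ScoreTrack:
    """Read a TSV written by :func:`write_score_table`."""
    headers: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#") and "=" in line:
                key, _, val = line[1:].rstrip("\n").partition("=")
                headers[key] = val
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    chrom = headers.get("chrom", str(df["chrom"].iloc[0]) if len(df) else "unknown")
    return ScoreTrack(
        chrom=chrom,
        starts=df["start"].to_numpy(),
        ends=df["end"].to_numpy(),
        indices=df["index"].to_numpy() if "index" in df else np.arange(len(df)),
        scores=df["score"].to_numpy(),
        stage=headers.get("stage", "raw"),
        bait=parse_region(headers["bait"]) if "bait" in headers else None,
        excluded=parse_region(headers["excluded"]) if "excluded" in headers else None,
        meta={"source": str(path)},
    )


def track_from_table(
    path: str | Path,
    fmap: FragmentMap | None = None,
    keep_blind: bool = False,
) -> ScoreTrack:
    """Build a raw track from a precomputed fragment-score TSV.

    This bypasses read assignment so users can start from deposited processed
    data (columns chrom, start, end, score at minimum). If a fragment map is
    supplied, rows are matched to map fragments by exact coordinates and
    blind-both-ends fragments are dropped unless ``keep_blind``.
    """
    track = read_score_table(path)
    if fmap is None:
        return track
    starts, ends, idx, blind = fmap.arrays(track.chrom)
    by_coord = {(s, e): k for k, (s, e) in enumerate(zip(starts.tolist(), ends.tolist()))}
    scores = np.zeros(len(starts))
    for s, e, v in zip(track.starts.tolist(), track.ends.tolist(), track.scores):
        k = by_coord.get((s, e))
        if k is None:
            raise ValueError(
                f"score-table row {track.chrom}:{s}-{e} does not match any map fragment"
            )
        scores[k] = v
    keep = np.ones(len(starts), dtype=bool) if keep_blind else ~blind
    return ScoreTrack(
        chrom=track.chrom,
        starts=starts[keep],
        ends=ends[keep],
        indices=idx[keep],
        scores=scores[keep],
        stage="raw",
        bait=track.bait,
        meta={"source": str(path), "keep_blind": keep_blind},
    )


def write_bedgraph(track: ScoreTrack, path: str | Path, name: str | None = None) -> None:
    """Write fragment-resolution bedGraph with 6-significant-digit values."""
    with open(path, "w") as fh:
        label = name or f"{track.chrom}.{track.stage}"
        fh.write(f'track type=bedGraph name="{label}"\n')
        for s, e, v in zip(track.starts, track.ends, track.scores):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v:.6g}\n")
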