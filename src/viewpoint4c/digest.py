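"""In-silico double restriction digestion: genome FASTA -> fragment map.

4C-seq counts contacts at the resolution of primary-cutter fragments. The
primary cutter (NlaIII, CATG^ with the cut after the motif) defines fragment
boundaries; the secondary cutter (DpnII, ^GATC cutting before the motif)
determines whether a fragment end is "blind" — lacking an internal secondary
site, hence with unreliable capture efficiency. Both default motifs are their
own reverse complement, so a single-strand scan finds every site; for
non-palindromic user-supplied enzymes, sites from both strands are merged.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .regions import Region

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzymeSpec:
    """A restriction enzyme: recognition motif and cut position.

    ``cut_offset`` is the number of bases from the motif start at which the
    top-strand cut falls (NlaIII: CATG^, offset 4; DpnII: ^GATC, offset 0).
    """

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError(f"enzyme {self.name}: motif must be non-empty")
        if self.motif != self.motif.upper() or set(self.motif) - set("ACGT"):
            raise ValueError(
                f"enzyme {self.name}: motif must be uppercase over ACGT, got {self.motif!r}"
            )
        if not (0 <= self.cut_offset <= len(self.motif)):
            raise ValueError(
                f"enzyme {self.name}: cut_offset must lie in [0, {len(self.motif)}]"
            )

    @property
    def is_palindromic(self) -> bool:
        return self.motif == reverse_complement(self.motif)

    @classmethod
    def from_string(cls, text: str) -> "RestrictionEnzymeSpec":
        """Parse ``Name:MOTIF:offset`` (e.g. ``NlaIII:CATG:4``)."""
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"expected Name:MOTIF:offset, got {text!r}")
        return cls(parts[0], parts[1].upper(), int(parts[2]))


NLAIII = RestrictionEnzymeSpec("NlaIII", "CATG", 4)
DPNII = RestrictionEnzymeSpec("DpnII", "GATC", 0)


@dataclass(frozen=True)
class Fragment:
    """One primary-digest fragment; ``index`` is its ordinal on the chromosome."""

    region: Region
    index: int
    blind_left: bool
    blind_right: bool

    @property
    def is_blind(self) -> bool:
        """Blind on both ends: no internal secondary-cutter site."""
        return self.blind_left and self.blind_right


@dataclass
class FragmentMap:
    """Ordered restriction fragments tiling each contig exactly."""

    fragments: dict[str, tuple[Fragment, ...]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def chroms(self) -> list[str]:
        return list(self.fragments)

    def n_fragments(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.fragments[chrom])
        return sum(len(v) for v in self.fragments.values())

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, indices, blind_both) numpy views for one contig."""
        frags = self.fragments[chrom]
        starts = np.array([f.region.start for f in frags], dtype=np.int64)
        ends = np.array([f.region.end for f in frags], dtype=np.int64)
        idx = np.array([f.index for f in frags], dtype=np.int64)
        blind = np.array([f.is_blind for f in frags], dtype=bool)
        return starts, ends, idx, blind

    def validate(self) -> None:
        for chrom, frags in self.fragments.items():
            if not frags:
                raise ValueError(f"fragment map for {chrom} is empty")
            if frags[0].region.start != 0:
                raise ValueError(f"{chrom}: first fragment does not start at 0")
            for prev, cur in zip(frags, frags[1:]):
                if cur.region.start != prev.region.end:
                    raise ValueError(
                        f"{chrom}: fragments {prev.index} and {cur.index} do not tile"
                    )
            for ordinal, frag in enumerate(frags):
                if frag.index != ordinal:
                    raise ValueError(f"{chrom}: fragment indices are not 0..n-1 in order")


def find_motif_sites(sequence: str, enzyme: RestrictionEnzymeSpec) -> list[int]:
    """Sorted cut coordinates of every exact motif occurrence in ``sequence``.

    The scan is case-insensitive (sequence is uppercased first); ambiguity
    codes such as N never match. Overlapping occurrences are all reported.
    For non-palindromic motifs the reverse strand is scanned too and cut
    coordinates from both strands are merged.
    """
    seq = sequence.upper()
    oriented = [(enzyme.motif, enzyme.cut_offset)]
    if not enzyme.is_palindromic:
        oriented.append(
            (reverse_complement(enzyme.motif), len(enzyme.motif) - enzyme.cut_offset)
        )
    sites: set[int] = set()
    for motif, offset in oriented:
        start = seq.find(motif)
        while start != -1:
            sites.add(start + offset)
            start = seq.find(motif, start + 1)
    return sorted(sites)


def digest(
    genome: Mapping[str, str],
    primary: RestrictionEnzymeSpec = NLAIII,
    secondary: RestrictionEnzymeSpec = DPNII,
    genome_id: str | None = None,
) -> FragmentMap:
    """Double-digest ``genome`` and return the primary-fragment map.

    Fragments are the intervals between consecutive primary cut sites plus
    the contig ends; a fragment end is blind when no secondary cut falls
    strictly inside the fragment.
    """
    if not genome:
        raise ValueError("genome must contain at least one contig")
    per_chrom: dict[str, tuple[Fragment, ...]] = {}
    for chrom, seq in genome.items():
        length = len(seq)
        if length == 0:
            raise ValueError(f"contig {chrom} is empty")
        primary_cuts = find_motif_sites(seq, primary)
        secondary_cuts = find_motif_sites(seq, secondary)
        boundaries = sorted({0, length, *(c for c in primary_cuts if 0 < c < length)})
        frags = []
        for i, (lo, hi) in enumerate(zip(boundaries, boundaries[1:])):
            j = bisect.bisect_right(secondary_cuts, lo)
            has_internal = j < len(secondary_cuts) and secondary_cuts[j] < hi
            frags.append(
                Fragment(
                    region=Region(chrom, lo, hi),
                    index=i,
                    blind_left=not has_internal,
                    blind_right=not has_internal,
                )
            )
        per_chrom[chrom] = tuple(frags)
    return FragmentMap(
        per_chrom,
        provenance={
            "primary": f"{primary.name}:{primary.motif}:{primary.cut_offset}",
            "secondary": f"{secondary.name}:{secondary.motif}:{secondary.cut_offset}",
            "genome": genome_id or "unnamed",
        },
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA file into {contig: uppercase sequence}."""
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        genome[name] = "".join(chunks).upper()
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fragment_map(fmap: FragmentMap, path: str | Path) -> None:
    """Write the fragment map as BED6; the name column encodes index and
    blind flags as ``<index>;<blind_left><blind_right>`` and round-trips
    losslessly through :func:`read_fragment_map`."""
    with open(path, "w") as fh:
        for chrom in fmap.chroms:
            for frag in fmap.fragments[chrom]:
                name = f"{frag.index};{int(frag.blind_left)}{int(frag.blind_right)}"
                fh.write(
                    f"{chrom}\t{frag.region.start}\t{frag.region.end}\t{name}\t0\t+\n"
                )


def read_fragment_map(path: str | Path, provenance: dict | None = None) -> FragmentMap:
    """Read a fragment-map BED written by :func:`write_fragment_map`.

    An empty file yields an empty map (no contigs)."""
    per_chrom: dict[str, list[Fragment]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            idx_str, _, flags = name.partition(";")
            per_chrom.setdefault(chrom, []).append(
                Fragment(
                    region=Region(chrom, start, end),
                    index=int(idx_str),
                    blind_left=flags[:1] == "1",
                    blind_right=flags[1:2] == "1",
                )
            )
    fmap = FragmentMap.__new__(FragmentMap)
    fmap.fragments = {c: tuple(v) for c, v in per_chrom.items()}
    fmap.provenance = provenance or {"source": str(path)}
    fmap.validate()
    return fmap
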