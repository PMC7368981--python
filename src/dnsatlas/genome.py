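"""Genome assembly, intervals and annotation records.

Coordinates are 0-based half-open (BED convention) everywhere in memory;
GFF3 input is converted on read. An assembly is an ordered set of named
chromosomes with lengths plus a rule mapping chromosome names to subgenome
labels (for allopolyploids such as hexaploid wheat, where "1A".."7D" carry
the subgenome as a trailing letter).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


#: default rule: subgenome = trailing letter of the chromosome name
DEFAULT_SUBGENOME_REGEX = r"([A-Za-z])$"

#: TE superfamily -> class per the three-letter Wicker codes
SUPERFAMILY_CLASS = {
    "RLG": 1, "RLC": 1, "RLX": 1, "RIX": 1,
    "DTC": 2, "DTM": 2, "DTH": 2, "DTT": 2, "DTX": 2, "DXX": 2,
    "XXX": "unclassified",
}


class GenomeError(ValueError):
    """Raised for coordinates or names inconsistent with the assembly."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise GenomeError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise GenomeError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class GenomeAssembly:
    """Ordered chromosomes with lengths and a subgenome-labelling rule.

    Parameters
    ----------
    chromosomes : sequence of (name, length)
        Chromosome names must be unique and lengths positive.
    subgenome_regex : str
        Regex with one capture group applied to the chromosome name; the
        captured text is the subgenome label. The default captures the
        trailing letter ("1A" -> "A").
    """

    def __init__(self, chromosomes, subgenome_regex: str = DEFAULT_SUBGENOME_REGEX):
        self._names: list[str] = []
        self._lengths: dict[str, int] = {}
        for name, length in chromosomes:
            if name in self._lengths:
                raise GenomeError(f"duplicate chromosome name {name!r}")
            if length <= 0:
                raise GenomeError(f"chromosome {name!r} has non-positive length")
            self._names.append(name)
            self._lengths[name] = int(length)
        self._subgenome_re = re.compile(subgenome_regex)

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __iter__(self):
        return iter(self._names)

    def length(self, name: str) -> int:
        try:
            return self._lengths[name]
        except KeyError:
            raise GenomeError(f"unknown chromosome {name!r}") from None

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def genome_of(self, name: str) -> str:
        """Subgenome label of a chromosome (e.g. '3B' -> 'B')."""
        if name not in self._lengths:
            raise GenomeError(f"unknown chromosome {name!r}")
        m = self._subgenome_re.search(name)
        if m is None:
            return ""
        return m.group(1)

    @property
    def subgenomes(self) -> list[str]:
        seen: list[str] = []
        for name in self._names:
            g = self.genome_of(name)
            if g not in seen:
                seen.append(g)
        return seen

    def validate(self, iv: GenomicInterval) -> GenomicInterval:
        if iv.chrom not in self._lengths:
            raise GenomeError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self._lengths[iv.chrom]:
            raise GenomeError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self._lengths[iv.chrom]}"
            )
        return iv

    def __repr__(self) -> str:
        return f"GenomeAssembly({len(self._names)} chromosomes, {self.total_length} bp)"


@dataclass(frozen=True)
class GeneModel:
    """A gene with its CDS span; cds_start/cds_end bound the union of CDS parts."""

    gene_id: str
    interval: GenomicInterval
    cds_start: int
    cds_end: int
    confidence: str = "HC"

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise GenomeError(f"gene {self.gene_id}: strand must be + or -")
        if not (self.interval.start <= self.cds_start < self.cds_end <= self.interval.end):
            raise GenomeError(f"gene {self.gene_id}: CDS span outside gene interval")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class TEAnnotation:
    """A transposable element with Wicker-style SUPERFAMILY_family naming."""

    interval: GenomicInterval
    family: str
    is_cereba: bool = False
    superfamily: str = field(init=False)
    te_class: object = field(init=False)

    def __post_init__(self):
        sf = self.family.split("_", 1)[0].upper()
        if sf not in SUPERFAMILY_CLASS:
            sf = "XXX"
        object.__setattr__(self, "superfamily", sf)
        object.__setattr__(self, "te_class", SUPERFAMILY_CLASS[sf])

    @property
    def chrom(self) -> str:
        return self.interval.chrom


SEGMENT_LABELS = ("R1", "R2a", "C", "R2b", "R3")


class ChromosomeSegments:
    """Per-chromosome R1/R2a/C/R2b/R3 tiling plus the CENH3 interval.

    The five segments must be ordered, non-overlapping and cover the
    chromosome exactly; the CENH3 interval must lie inside C.
    """

    def __init__(self, assembly: GenomeAssembly):
        self.assembly = assembly
        self._segments: dict[str, dict[str, GenomicInterval]] = {}
        self._cenh3: dict[str, GenomicInterval] = {}

    def set_chromosome(self, chrom, segments: dict, cenh3: GenomicInterval):
        if set(segments) != set(SEGMENT_LABELS):
            raise GenomeError(f"{chrom}: need exactly segments {SEGMENT_LABELS}")
        pos = 0
        for label in SEGMENT_LABELS:
            iv = segments[label]
            if iv.chrom != chrom or iv.start != pos:
                raise GenomeError(f"{chrom}: segment {label} does not tile (gap/overlap at {pos})")
            pos = iv.end
        if pos != self.assembly.length(chrom):
            raise GenomeError(f"{chrom}: segments do not cover the chromosome")
        c = segments["C"]
        if not (c.start <= cenh3.start and cenh3.end <= c.end):
            raise GenomeError(f"{chrom}: CENH3 interval not inside segment C")
        self._segments[chrom] = dict(segments)
        self._cenh3[chrom] = cenh3

    @property
    def chromosomes(self) -> list[str]:
        return [c for c in self.assembly.names if c in self._segments]

    def segment(self, chrom: str, label: str) -> GenomicInterval:
        return self._segments[chrom][label]

    def cenh3(self, chrom: str) -> GenomicInterval:
        return self._cenh3[chrom]

    def label_at(self, chrom: str, pos: int) -> str:
        """Segment label containing a position."""
        for label in SEGMENT_LABELS:
            iv = self._segments[chrom][label]
            if iv.start <= pos < iv.end:
                return label
        raise GenomeError(f"position {chrom}:{pos} outside chromosome")

    def intervals(self, label: str) -> list[GenomicInterval]:
        """All chromosomes' intervals for one segment label."""
        return [self._segments[c][label] for c in self.chromosomes]
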