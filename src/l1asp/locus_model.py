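"""Genomic locus representation for a bidirectional LINE-1 promoter.

A full-length LINE-1 (L1) retrotransposon carries a CpG-island promoter that
is bidirectional: a sense promoter drives the element's own transcript and an
antisense promoter (ASP) can drive chimeric transcripts into the surrounding
host gene.  This module models such a locus as a top-strand reference sequence
with 1-based inclusive coordinates, classifies every cytosine into the
dinucleotide contexts that matter for combined endogenous-methylation /
GpC-methyltransferase footprinting assays, and scans gene/repeat annotation
sets for candidate antisense-L1 promoters (full-length, intronic, antisense to
the host gene).

Coordinate convention: all user-facing positions are 1-based inclusive, the
style used in genome-browser spans such as ``ch7:116364010-116364564``.  A
site's position is the position of the C of its dinucleotide on the top
strand; only the top strand is analysed (bisulfite PCR reads one converted
strand per clone).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")
_DNA_ALPHABET = frozenset("ACGTN")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise DataError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise DataError(
                f"malformed interval: end {self.end} < start {self.start}"
            )
        if self.strand not in VALID_STRANDS:
            raise DataError(f"strand must be one of {VALID_STRANDS!r}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __len__(self) -> int:
        return self.length

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if not self.overlaps(other):
            return 0
        return min(self.end, other.end) - max(self.start, other.start) + 1

    def shifted(self, k: int) -> "GenomicInterval":
        return replace(self, start=self.start + k, end=self.end + k)

    @classmethod
    def from_string(cls, text: str, strand: str = ".") -> "GenomicInterval":
        """Parse a browser-style span like ``ch7:116364010-116364564``.

        Accepts ``-``, en-dash and em-dash separators and embedded commas.
        """
        m = re.fullmatch(
            r"\s*([\w.]+):([\d,]+)\s*[-–—]\s*([\d,]+)\s*", text
        )
        if m is None:
            raise DataError(f"cannot parse interval {text!r}")
        start = int(m.group(2).replace(",", ""))
        end = int(m.group(3).replace(",", ""))
        return cls(m.group(1), start, end, strand)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def interval_length(iv: GenomicInterval) -> int:
    """Inclusive length in bp of a 1-based closed interval (end - start + 1)."""
    return iv.length


def _check_ascending_disjoint(name: str, values: Sequence[int]) -> None:
    for i in range(1, len(values)):
        if values[i] <= values[i - 1]:
            raise DataError(f"{name} positions must be strictly ascending")


@dataclass(frozen=True)
class SiteMap:
    """Informative cytosine positions of a locus, split by dinucleotide context.

    ``cpg_sites`` are Cs followed by G (endogenous methylation readout),
    ``gpc_sites`` are Cs preceded by G (GpC-methyltransferase accessibility
    readout), and ``excluded_sites`` are Cs in GpCpG context, where the two
    readouts are indistinguishable and both are discarded.
    """

    cpg_sites: tuple[int, ...]
    gpc_sites: tuple[int, ...]
    excluded_sites: tuple[int, ...]

    def __post_init__(self) -> None:
        _check_ascending_disjoint("cpg", self.cpg_sites)
        _check_ascending_disjoint("gpc", self.gpc_sites)
        _check_ascending_disjoint("excluded", self.excluded_sites)
        groups = (set(self.cpg_sites), set(self.gpc_sites), set(self.excluded_sites))
        total = sum(len(g) for g in groups)
        if len(groups[0] | groups[1] | groups[2]) != total:
            raise DataError("site classes must be pairwise disjoint")

    @property
    def informative_sites(self) -> tuple[int, ...]:
        """CpG and GpC positions merged, ascending (excluded sites omitted)."""
        return tuple(sorted(self.cpg_sites + self.gpc_sites))

    def site_class(self, pos: int) -> str:
        if pos in self.cpg_sites:
            return "cpg"
        if pos in self.gpc_sites:
            return "gpc"
        if pos in self.excluded_sites:
            return "excluded"
        return "none"


def classify_sites(sequence: str, offset: int = 1) -> SiteMap:
    """Classify every cytosine of a top-strand sequence by dinucleotide context.

    A C preceded and followed by G (GpCpG) is *excluded*: enzyme-applied GpC
    methylation and endogenous CpG methylation overlap there and cannot be
    told apart, so both readouts are dropped.  A C followed by G only is a
    CpG site; preceded by G only, a GpC site.  N voids any context it touches.

    Parameters
    ----------
    sequence:
        Top-strand DNA over ``{A, C, G, T, N}`` (case-insensitive).
    offset:
        Position reported for the first base (default 1, i.e. positions are
        1-based along the given sequence).
    """
    if not sequence:
        raise DataError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise DataError(f"sequence contains invalid characters: {sorted(bad)}")
    cpg: list[int] = []
    gpc: list[int] = []
    excluded: list[int] = []
    for i, base in enumerate(seq):
        if base != "C":
            continue
        prev_g = i > 0 and seq[i - 1] == "G"
        next_g = i + 1 < len(seq) and seq[i + 1] == "G"
        pos = offset + i
        if prev_g and next_g:
            excluded.append(pos)
        elif next_g:
            cpg.append(pos)
        elif prev_g:
            gpc.append(pos)
    return SiteMap(tuple(cpg), tuple(gpc), tuple(excluded))


@dataclass(frozen=True)
class LocusModel:
    """A promoter locus: reference sequence, coordinates, site map and TSSs.

    ``tss_sense`` is the L1 sense transcription start site and
    ``tss_antisense`` the antisense-promoter start site; the two point in
    opposite directions with room for one +1 nucleosome downstream of each
    between them.
    """

    reference: str
    interval: GenomicInterval
    site_map: SiteMap
    tss_sense: int
    tss_antisense: int
    l1_interval: GenomicInterval

    def __post_init__(self) -> None:
        if len(self.reference) != self.interval.length:
            raise DataError(
                f"reference length {len(self.reference)} does not match "
                f"interval length {self.interval.length}"
            )
        for name, pos in (("tss_sense", self.tss_sense), ("tss_antisense", self.tss_antisense)):
            if not self.interval.contains(pos):
                raise DataError(f"{name} position {pos} outside locus {self.interval}")
        all_sites = (
            self.site_map.cpg_sites + self.site_map.gpc_sites + self.site_map.excluded_sites
        )
        for pos in all_sites:
            if not self.interval.contains(pos):
                raise DataError(f"site position {pos} outside locus {self.interval}")
        if not self.interval.contains_interval(self.l1_interval):
            raise DataError(f"L1 interval {self.l1_interval} outside locus {self.interval}")

    def to_index(self, pos: int) -> int:
        """Convert a genomic position to a 0-based index into ``reference``."""
        return pos - self.interval.start

    def base_at(self, pos: int) -> str:
        return self.reference[self.to_index(pos)]


def build_locus_model(
    reference: str,
    annotations: Mapping[str, GenomicInterval],
) -> LocusModel:
    """Assemble a :class:`LocusModel` from a reference and named annotations.

    Required annotation keys: ``tss_sense``, ``tss_antisense`` (single-base
    intervals) and ``l1``.  An optional ``locus`` interval places the
    reference at genomic coordinates; otherwise positions start at 1.
    """
    for key in ("tss_sense", "tss_antisense", "l1"):
        if key not in annotations:
            raise DataError(f"missing required annotation {key!r}")
    l1 = annotations["l1"]
    if "locus" in annotations:
        interval = annotations["locus"]
        if interval.length != len(reference):
            raise DataError(
                f"locus annotation length {interval.length} does not match "
                f"reference length {len(reference)}"
            )
    else:
        interval = GenomicInterval(l1.chrom, 1, len(reference))
    for key, ann in annotations.items():
        if key == "locus":
            continue
        if not interval.contains_interval(ann):
            raise DataError(f"annotation {key!r} {ann} outside reference extent {interval}")
    tss_sense = annotations["tss_sense"].start
    tss_antisense = annotations["tss_antisense"].start
    if tss_sense == tss_antisense:
        logger.warning("degenerate annotation: tss_sense == tss_antisense == %d", tss_sense)
    site_map = classify_sites(reference, offset=interval.start)
    return LocusModel(
        reference=reference.upper(),
        interval=interval,
        site_map=site_map,
        tss_sense=tss_sense,
        tss_antisense=tss_antisense,
        l1_interval=l1,
    )


@dataclass(frozen=True)
class TranscriptModel:
    """An (observed or predicted) transcript: ordered exons plus a TSS."""

    exons: tuple[GenomicInterval, ...]
    tss: int
    host_gene: str
    source: str  # "host" or "L1-ASP"

    def __post_init__(self) -> None:
        if self.source not in ("host", "L1-ASP"):
            raise DataError(f"transcript source must be 'host' or 'L1-ASP', got {self.source!r}")
        strand = self.strand
        ordered = list(self.exons)
        if strand == "-":
            ordered = ordered[::-1]
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise DataError("exons must be non-overlapping and ordered by transcription direction")

    @property
    def strand(self) -> str:
        return self.exons[0].strand if self.exons else "."


@dataclass(frozen=True)
class GeneModel:
    """A host gene with exon structure, for antisense-L1 promoter scanning."""

    name: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    @property
    def strand(self) -> str:
        return self.interval.strand

    def introns(self) -> tuple[GenomicInterval, ...]:
        exons = sorted(self.exons, key=lambda e: e.start)
        out = []
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end + 1:
                out.append(
                    GenomicInterval(self.interval.chrom, a.end + 1, b.start - 1, self.strand)
                )
        return tuple(out)


@dataclass(frozen=True)
class AspCandidate:
    """A candidate antisense-L1 promoter: the repeat, its host, a predicted transcript."""

    l1: GenomicInterval
    host_gene: str
    transcript: TranscriptModel


def _predicted_transcript(l1: GenomicInterval, gene: GeneModel) -> TranscriptModel:
    """Predict the chimeric transcript driven by the L1 antisense promoter.

    The ASP sits at the L1 5' end and fires opposite to the L1, i.e. in the
    host gene's sense direction; the predicted transcript starts inside the
    L1 and splices onto the host exons downstream in transcription direction.
    """
    # 5' end of an antisense (minus-strand) L1 in a plus-strand gene is its
    # right coordinate, and vice versa.
    tss = l1.end if l1.strand == "-" else l1.start
    if gene.strand == "+":
        first = GenomicInterval(l1.chrom, tss, l1.end, "+")
        downstream = [replace(e, strand="+") for e in sorted(gene.exons, key=lambda e: e.start) if e.start > l1.end]
        exons = (first, *downstream)
    else:
        first = GenomicInterval(l1.chrom, l1.start, tss, "-")
        # transcription runs right-to-left: downstream host exons descend
        downstream = [
            replace(e, strand="-")
            for e in sorted(gene.exons, key=lambda e: e.start, reverse=True)
            if e.end < l1.start
        ]
        exons = (first, *downstream)
    return TranscriptModel(exons=exons, tss=tss, host_gene=gene.name, source="L1-ASP")


def scan_candidate_asps(
    genes: Sequence[GeneModel],
    repeats: Sequence[GenomicInterval],
    min_full_length: int = 6000,
) -> list[AspCandidate]:
    """Find L1 repeats able to act as antisense promoters for host genes.

    A repeat qualifies when it (a) is full length (``length >=
    min_full_length``, default 6000 bp — only full-length elements retain the
    bidirectional promoter), (b) lies entirely within an intron of a gene
    (no overlap with any exon), and (c) is on the strand opposite the host
    gene, so that its antisense promoter fires in the host's sense direction
    and can yield a chimeric transcript sense with the host coding sequence.

    Returns one :class:`AspCandidate` per qualifying (repeat, host) pair.
    Empty inputs yield an empty list.
    """
    out: list[AspCandidate] = []
    for l1 in repeats:
        if l1.length < min_full_length:
            continue
        if l1.strand not in ("+", "-"):
            continue
        for gene in genes:
            if gene.strand not in ("+", "-") or l1.strand == gene.strand:
                continue
            if not any(intron.contains_interval(l1) for intron in gene.introns()):
                continue
            out.append(AspCandidate(l1=l1, host_gene=gene.name, transcript=_predicted_transcript(l1, gene)))
    return out
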