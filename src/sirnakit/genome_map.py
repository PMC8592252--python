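"""Exact-match genome mapping and structural-RNA subtraction.

Tags are located on both strands by full-length exact match (no mismatches,
no clipping).  Tags with any hit overlapping an annotated structural/known
RNA interval by >= 1 bp are removed entirely; the removal tally uses the
class precedence rRNA > tRNA > snRNA > snoRNA > miRNA.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from sirnakit.preprocess import ReadTag
from sirnakit.utils import intervals_overlap, revcomp

logger = logging.getLogger(__name__)

STRUCTURAL_PRECEDENCE: tuple[str, ...] = ("rRNA", "tRNA", "snRNA", "snoRNA", "miRNA")


@dataclass(frozen=True)
class GenomeHit:
    """Exact full-length alignment of a tag (0-based half-open, stranded)."""

    tag_sequence: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'


class GenomeIndex:
    """Seed-and-verify exact-match index over a FASTA genome.

    A fixed-length k-mer table over the forward strand seeds candidate
    positions; candidates are verified by full string comparison.  Minus
    strand hits are found by searching the reverse complement of the query
    against the forward strand.
    """

    def __init__(self, genome: dict[str, str], seed_length: int = 16):
        if not genome:
            raise ValueError("empty genome")
        if len(set(genome)) != len(genome):
            raise ValueError("duplicate chromosome names")
        self.seed_length = seed_length
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        k = seed_length
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[i:i + k], []).append((chrom, i))

    @classmethod
    def from_fasta(cls, path: Path, seed_length: int = 16) -> "GenomeIndex":
        genome: dict[str, str] = {}
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in genome:
                raise ValueError(f"duplicate chromosome name: {record.id}")
            genome[record.id] = str(record.seq).upper()
        return cls(genome, seed_length)

    def _forward_positions(self, query: str) -> list[tuple[str, int]]:
        k = self.seed_length
        if len(query) < k:
            raise ValueError(f"query shorter than seed length {k}")
        hits = []
        for chrom, pos in self._seeds.get(query[:k], ()):
            seq = self.genome[chrom]
            if seq[pos:pos + len(query)] == query:
                hits.append((chrom, pos))
        return hits

    def find(self, query: str) -> list[GenomeHit]:
        """All exact full-length occurrences of ``query`` on both strands."""
        query = query.upper()
        out = []
        for chrom, pos in self._forward_positions(query):
            out.append(GenomeHit(query, chrom, pos, pos + len(query), "+"))
        for chrom, pos in self._forward_positions(revcomp(query)):
            out.append(GenomeHit(query, chrom, pos, pos + len(query), "-"))
        out.sort(key=lambda h: (h.chrom, h.start, h.strand))
        return out


def map_exact(tag: ReadTag, index: GenomeIndex) -> list[GenomeHit]:
    """Exact hits of a tag, sorted by (chrom, start, strand); [] if unmapped."""
    return index.find(tag.sequence)


@dataclass
class AnnotationIndex:
    """Labeled interval sets per chromosome (0-based half-open)."""

    intervals: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ivs in self.intervals.values():
            ivs.sort()
        # precomputed arrays for binary search
        self._starts = {c: [iv[0] for iv in ivs] for c, ivs in self.intervals.items()}

    @classmethod
    def from_gff3(cls, path: Path, valid_chroms: set[str] | None = None) -> "AnnotationIndex":
        """Load structural classes from GFF3 (1-based inclusive -> half-open).

        Feature types are matched case-insensitively against the five class
        names; other feature types are ignored.
        """
        classes = {c.lower(): c for c in STRUCTURAL_PRECEDENCE}
        intervals: dict[str, list[tuple[int, int, str]]] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 8:
                    continue
                chrom, _, ftype, start, end = parts[:5]
                cls_name = classes.get(ftype.lower())
                if cls_name is None:
                    continue
                if valid_chroms is not None and chrom not in valid_chroms:
                    logger.warning("annotation chromosome %s not in genome; ignored", chrom)
                    continue
                intervals.setdefault(chrom, []).append((int(start) - 1, int(end), cls_name))
        return cls(intervals)

    def overlapping_classes(self, chrom: str, start: int, end: int) -> list[str]:
        """Classes of all annotated intervals overlapping [start, end) by >= 1 bp."""
        ivs = self.intervals.get(chrom)
        if not ivs:
            return []
        # scan intervals with iv_start < end; starts are sorted
        hi = bisect_right(self._starts[chrom], end - 1)
        return [
            cls
            for s, e, cls in ivs[:hi]
            if intervals_overlap(start, end, s, e)
        ]


def subtract_annotated(
    hits_by_tag: dict[str, list[GenomeHit]],
    annotation: AnnotationIndex,
) -> tuple[dict[str, list[GenomeHit]], dict[str, int]]:
    """Remove tags with any hit overlapping any annotated interval.

    Returns (kept hits keyed by tag sequence, removed-tag tally per class).
    """
    kept: dict[str, list[GenomeHit]] = {}
    tally = {cls: 0 for cls in STRUCTURAL_PRECEDENCE}
    for tag_seq, hits in hits_by_tag.items():
        classes: set[str] = set()
        for hit in hits:
            classes.update(annotation.overlapping_classes(hit.chrom, hit.start, hit.end))
        if classes:
            for cls in STRUCTURAL_PRECEDENCE:
                if cls in classes:
                    tally[cls] += 1
                    break
        else:
            kept[tag_seq] = hits
    return kept, tally


def map_tags(
    tags: list[ReadTag],
    index: GenomeIndex,
    max_hits: int = 20,
) -> tuple[dict[str, list[GenomeHit]], list[str], list[str]]:
    """Map tags; returns (hits by tag sequence, unmapped tags, capped tags).

    Tags exceeding ``max_hits`` genomic locations are dropped and logged, to
    bound pathological repeats.
    """
    mapped: dict[str, list[GenomeHit]] = {}
    unmapped: list[str] = []
    capped: list[str] = []
    for tag in tags:
        hits = map_exact(tag, index)
        if not hits:
            unmapped.append(tag.sequence)
        elif len(hits) > max_hits:
            capped.append(tag.sequence)
            logger.info("tag %s dropped: %d hits > cap %d", tag.sequence, len(hits), max_hits)
        else:
            mapped[tag.sequence] = hits
    return mapped, unmapped, capped


def write_hits_bed6(
    hits_by_tag: dict[str, list[GenomeHit]],
    tag_totals: dict[str, int],
    path: Path,
) -> None:
    """BED6: name = tag sequence, score = total raw count across libraries."""
    rows = []
    for tag_seq, hits in hits_by_tag.items():
        for h in hits:
            rows.append((h.chrom, h.start, h.end, tag_seq, tag_totals.get(tag_seq, 0), h.strand))
    rows.sort()
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def write_tally_tsv(tally: dict[str, int], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tremoved_tags\n")
        for cls in STRUCTURAL_PRECEDENCE:
            fh.write(f"{cls}\t{tally.get(cls, 0)}\n")
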