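"""siRNA duplex calling from exact-match genome hits.

A duplex is a plus-strand hit paired with a minus-strand hit on the same
chromosome such that each strand's 3' end overhangs the partner's 5' end by
exactly 2 nt: plus.start - minus.start == 2 and plus.end - minus.end == 2
(the canonical Dicer signature; the minus interval is the plus interval
shifted left by 2 for equal lengths).  A relaxed geometry (overhangs 1-3 nt,
unequal lengths allowed) is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from sirnakit.genome_map import GenomeHit
from sirnakit.preprocess import ReadTag
from sirnakit.utils import LIBRARIES

LENGTH_RANGE = (20, 24)


@dataclass
class SirnaDuplex:
    """A called siRNA locus (plus/minus hit pair with the duplex geometry)."""

    sirna_id: str
    chrom: str
    plus_hit: GenomeHit
    minus_hit: GenomeHit
    guide_sequence: str
    guide_strand: str
    counts: tuple[int, int, int, int]  # guide + passenger, per library

    @property
    def guide_length(self) -> int:
        return len(self.guide_sequence)

    @property
    def first_base(self) -> str:
        return self.guide_sequence[0]


def is_duplex_pair(plus: GenomeHit, minus: GenomeHit, relaxed: bool = False) -> bool:
    """Check the 2-nt 3' overhang geometry for a (+, -) hit pair."""
    if plus.chrom != minus.chrom or plus.strand != "+" or minus.strand != "-":
        return False
    d_start = plus.start - minus.start
    d_end = plus.end - minus.end
    if relaxed:
        return 1 <= d_start <= 3 and 1 <= d_end <= 3
    return d_start == 2 and d_end == 2


def find_duplexes(
    hits_by_tag: dict[str, list[GenomeHit]],
    tag_counts: dict[str, tuple[int, int, int, int]],
    relaxed: bool = False,
    len_min: int = LENGTH_RANGE[0],
    len_max: int = LENGTH_RANGE[1],
) -> list[SirnaDuplex]:
    """Emit every hit pair satisfying the overhang geometry.

    The guide strand is the tag with the larger total count (ties go to the
    plus strand); the duplex count vector sums guide and passenger tags.
    Guides outside [len_min, len_max] are not called.  Output is
    deduplicated and ordered by (chrom, plus.start, plus.end), with serial
    ids assigned after sorting so identifiers are reproducible.
    """
    plus_hits: list[GenomeHit] = []
    minus_by_key: dict[tuple[str, int, int], list[GenomeHit]] = {}
    for hits in hits_by_tag.values():
        for h in hits:
            if h.strand == "+":
                plus_hits.append(h)
            else:
                minus_by_key.setdefault((h.chrom, h.start, h.end), []).append(h)

    pairs: dict[tuple, tuple[GenomeHit, GenomeHit]] = {}
    for ph in plus_hits:
        if relaxed:
            candidates = [
                m
                for ds in (1, 2, 3)
                for de in (1, 2, 3)
                for m in minus_by_key.get((ph.chrom, ph.start - ds, ph.end - de), ())
            ]
        else:
            candidates = minus_by_key.get((ph.chrom, ph.start - 2, ph.end - 2), [])
        for mh in candidates:
            key = (ph.chrom, ph.start, ph.end, mh.start, mh.end,
                   ph.tag_sequence, mh.tag_sequence)
            pairs.setdefault(key, (ph, mh))

    duplexes = []
    for ph, mh in sorted(
        pairs.values(), key=lambda p: (p[0].chrom, p[0].start, p[0].end, p[1].start)
    ):
        plus_counts = tag_counts[ph.tag_sequence]
        minus_counts = tag_counts[mh.tag_sequence]
        if sum(minus_counts) > sum(plus_counts):
            guide_seq, guide_strand = mh.tag_sequence, "-"
        else:
            guide_seq, guide_strand = ph.tag_sequence, "+"
        if not len_min <= len(guide_seq) <= len_max:
            continue
        counts = tuple(a + b for a, b in zip(plus_counts, minus_counts))
        duplexes.append(
            SirnaDuplex(
                sirna_id="",
                chrom=ph.chrom,
                plus_hit=ph,
                minus_hit=mh,
                guide_sequence=guide_seq,
                guide_strand=guide_strand,
                counts=counts,  # type: ignore[arg-type]
            )
        )
    for i, d in enumerate(duplexes):
        d.sirna_id = f"sir{i + 1:05d}"
    return duplexes


def abundance_filter(duplex: SirnaDuplex, min_reads: int = 5, mode: str = "all") -> bool:
    """Criterion: more than ``min_reads`` raw reads per sample.

    mode='all': strictly > min_reads in every library (default);
    mode='any': in at least one library.
    """
    if mode == "all":
        return all(c > min_reads for c in duplex.counts)
    if mode == "any":
        return any(c > min_reads for c in duplex.counts)
    raise ValueError(f"unknown mode: {mode}")


def call_sirnas(
    hits_by_tag: dict[str, list[GenomeHit]],
    tags: list[ReadTag],
    min_reads: int = 5,
    mode: str = "all",
    relaxed: bool = False,
    len_min: int = LENGTH_RANGE[0],
    len_max: int = LENGTH_RANGE[1],
) -> list[SirnaDuplex]:
    """find_duplexes + abundance filter; ids re-serialized after filtering."""
    tag_counts = {t.sequence: t.counts for t in tags}
    duplexes = find_duplexes(hits_by_tag, tag_counts, relaxed, len_min, len_max)
    kept = [d for d in duplexes if abundance_filter(d, min_reads, mode)]
    for i, d in enumerate(kept):
        d.sirna_id = f"sir{i + 1:05d}"
    return kept


def length_first_base_stats(sirnas: list[SirnaDuplex],
                            len_min: int = LENGTH_RANGE[0],
                            len_max: int = LENGTH_RANGE[1]) -> pd.DataFrame:
    """Guide length x 5' first base contingency table (rows: lengths)."""
    lengths = list(range(len_min, len_max + 1))
    bases = ["A", "C", "G", "T"]
    table = pd.DataFrame(
        np.zeros((len(lengths), len(bases)), dtype=int), index=lengths, columns=bases
    )
    table.index.name = "length"
    for s in sirnas:
        if s.guide_length in table.index:
            table.loc[s.guide_length, s.first_base] += 1
    return table


def write_catalogue_tsv(sirnas: list[SirnaDuplex], path: Path) -> None:
    cols = [
        "sirna_id", "chrom", "plus_start", "plus_end", "minus_start", "minus_end",
        "guide_sequence", "guide_strand", "guide_length", "first_base",
    ] + [f"count_{lib}" for lib in LIBRARIES]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in sirnas:
            row = [
                s.sirna_id, s.chrom,
                str(s.plus_hit.start), str(s.plus_hit.end),
                str(s.minus_hit.start), str(s.minus_hit.end),
                s.guide_sequence, s.guide_strand,
                str(s.guide_length), s.first_base,
            ] + [str(c) for c in s.counts]
            fh.write("\t".join(row) + "\n")


def read_catalogue_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
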