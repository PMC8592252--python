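"""Read cleanup: adapter trimming, quality/length filtering, tag collapsing.

Raw libraries are reduced to unique sequence tags with per-library counts.
Reads lacking any 3' adapter evidence are rejected as invalid-adapter reads
(an insert shorter than the read must expose the adapter); reads containing
N after trimming are dropped because downstream mapping is exact-match only.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from sirnakit.utils import DNA_ALPHABET, LIBRARIES, phred_mean

_VALID_CHARS = frozenset("ACGTN")


@dataclass
class ReadTag:
    """A collapsed unique small-RNA sequence with per-library raw counts."""

    sequence: str
    counts: tuple[int, int, int, int]

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass
class CleanupStats:
    """Per-library read accounting through the cleanup stages."""

    raw: dict[str, int] = field(default_factory=dict)
    low_quality: dict[str, int] = field(default_factory=dict)
    invalid_adapter: dict[str, int] = field(default_factory=dict)
    empty_insert: dict[str, int] = field(default_factory=dict)
    contains_n: dict[str, int] = field(default_factory=dict)
    bad_length: dict[str, int] = field(default_factory=dict)
    surviving: dict[str, int] = field(default_factory=dict)

    def to_rows(self) -> list[dict[str, int | str]]:
        rows = []
        for lib in LIBRARIES:
            rows.append(
                {
                    "library": lib,
                    "raw": self.raw.get(lib, 0),
                    "low_quality": self.low_quality.get(lib, 0),
                    "invalid_adapter": self.invalid_adapter.get(lib, 0),
                    "empty_insert": self.empty_insert.get(lib, 0),
                    "contains_n": self.contains_n.get(lib, 0),
                    "bad_length": self.bad_length.get(lib, 0),
                    "surviving": self.surviving.get(lib, 0),
                }
            )
        return rows


class AdapterRejection(Exception):
    """Internal signal: read rejected at the adapter-trimming stage."""

    def __init__(self, reason: str):
        self.reason = reason


def trim_adapter(read_sequence: str, adapter: str, min_overlap: int = 6) -> str:
    """Return the insert preceding the leftmost 3' adapter match.

    A match is either the full adapter anywhere in the read, or a 3'-terminal
    prefix of the adapter of length >= ``min_overlap``.  Raises
    :class:`AdapterRejection` for no-adapter or empty-insert reads and
    ``ValueError`` for non-ACGTN input.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 6:
        raise ValueError("min_overlap must be >= 6")
    seq = read_sequence.upper()
    if not set(seq) <= _VALID_CHARS:
        bad = sorted(set(seq) - _VALID_CHARS)
        raise ValueError(f"non-ACGTN characters in read: {bad}")

    cut = seq.find(adapter)
    if cut == -1:
        # 3'-terminal partial adapter: suffix of the read == prefix of adapter
        n = len(seq)
        for i in range(max(0, n - len(adapter) + 1), n - min_overlap + 1):
            if adapter.startswith(seq[i:]):
                cut = i
                break
    if cut == -1:
        raise AdapterRejection("invalid_adapter")
    if cut == 0:
        raise AdapterRejection("empty_insert")
    return seq[:cut]


def quality_filter(quality_string: str, sequence: str, min_mean_phred: float = 20.0) -> bool:
    """Keep iff mean Phred >= threshold (inclusive boundary)."""
    if len(quality_string) != len(sequence):
        raise ValueError("quality/sequence length mismatch")
    return phred_mean(quality_string) >= min_mean_phred


def length_filter(sequence: str, min_len: int = 18, max_len: int = 30) -> bool:
    """Keep iff min_len <= len <= max_len (both inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return min_len <= len(sequence) <= max_len


def collapse_tags(reads_per_library: dict[str, list[str]]) -> list[ReadTag]:
    """Collapse cleaned reads into unique tags with per-library counts.

    Output is sorted by total count descending, ties lexicographic.
    """
    counters = {lib: Counter(reads_per_library.get(lib, [])) for lib in LIBRARIES}
    sequences = set()
    for c in counters.values():
        sequences.update(c)
    tags = [
        ReadTag(seq, tuple(counters[lib][seq] for lib in LIBRARIES))
        for seq in sequences
    ]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def _iter_fastq(path: Path):
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield seq, qual


def preprocess_libraries(
    fastq_paths: dict[str, Path],
    adapter: str,
    min_overlap: int = 6,
    min_mean_phred: float = 20.0,
    min_len: int = 18,
    max_len: int = 30,
) -> tuple[list[ReadTag], CleanupStats]:
    """Run the full cleanup on one FASTQ per library and collapse to tags.

    Filter order: quality -> adapter -> N-drop -> length.
    """
    stats = CleanupStats()
    cleaned: dict[str, list[str]] = {}
    for lib in LIBRARIES:
        path = fastq_paths[lib]
        raw = lowq = bad_adapter = empty = with_n = badlen = 0
        kept: list[str] = []
        for seq, qual in _iter_fastq(path):
            raw += 1
            if not quality_filter(qual, seq, min_mean_phred):
                lowq += 1
                continue
            try:
                insert = trim_adapter(seq, adapter, min_overlap)
            except AdapterRejection as exc:
                if exc.reason == "invalid_adapter":
                    bad_adapter += 1
                else:
                    empty += 1
                continue
            if "N" in insert:
                with_n += 1
                continue
            if not length_filter(insert, min_len, max_len):
                badlen += 1
                continue
            kept.append(insert)
        cleaned[lib] = kept
        stats.raw[lib] = raw
        stats.low_quality[lib] = lowq
        stats.invalid_adapter[lib] = bad_adapter
        stats.empty_insert[lib] = empty
        stats.contains_n[lib] = with_n
        stats.bad_length[lib] = badlen
        stats.surviving[lib] = len(kept)
    return collapse_tags(cleaned), stats


def write_tag_tsv(tags: list[ReadTag], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\t" + "\t".join(f"count_{lib}" for lib in LIBRARIES) + "\n")
        for t in tags:
            fh.write(t.sequence + "\t" + "\t".join(map(str, t.counts)) + "\n")


def read_tag_tsv(path: Path) -> list[ReadTag]:
    tags = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence"):
            raise ValueError("tag TSV missing header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            tags.append(ReadTag(parts[0], tuple(int(x) for x in parts[1:5])))
    return tags


def write_stats_tsv(stats: CleanupStats, path: Path) -> None:
    rows = stats.to_rows()
    cols = list(rows[0].keys())
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
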