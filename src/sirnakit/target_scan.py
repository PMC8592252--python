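"""Dual-scheme siRNA target-site scoring with consensus calling.

Two independent position-weighted complementarity scorers are evaluated at
every transcript offset; only sites passing both cutoffs ("consensus") mimic
the predicted-by-both-tools selection rule.  Guide positions are 1-based
from the guide 5' end; the guide binds the transcript antiparallel, so guide
position i pairs with site position L - i (0-based).

Scheme A: mismatch 1.0, G:U wobble 0.5, single-nucleotide target bulge 1.0,
all doubled at guide positions 2-13; default cutoff 4.0.
Scheme B: mismatch 1.0, G:U wobble 0.5, no bulges, and a hard seed
constraint of at most 1.0 penalty point within guide positions 2-8;
default cutoff 2.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

CUTOFF_A = 4.0
CUTOFF_B = 2.5
CORE_RANGE = (2, 13)  # scheme A doubling window, 1-based guide positions
SEED_RANGE = (2, 8)  # scheme B hard-constraint window
SEED_MAX_PENALTY = 1.0

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _pair_penalty(guide_base: str, target_base: str) -> float:
    """0 for Watson-Crick, 0.5 for G:U wobble, 1.0 for mismatch."""
    if _COMPLEMENT.get(guide_base) == target_base:
        return 0.0
    if (guide_base == "G" and target_base == "T") or (
        guide_base == "T" and target_base == "G"
    ):
        return 0.5
    return 1.0


def _position_pairs(guide: str, site: str) -> list[tuple[int, float]]:
    """(1-based guide position, raw penalty) for an equal-length alignment."""
    L = len(guide)
    if len(site) != L:
        raise ValueError("guide/site length mismatch")
    return [
        (i + 1, _pair_penalty(guide[i], site[L - 1 - i]))
        for i in range(L)
    ]


def score_site_scheme_a(guide: str, site: str) -> float:
    """Position-weighted penalty; ``site`` may carry one extra target base
    (a single bulge, penalty 1.0, doubled when it falls in the core)."""
    L = len(guide)
    if len(site) == L:
        total = 0.0
        for pos, pen in _position_pairs(guide, site):
            total += pen * (2.0 if CORE_RANGE[0] <= pos <= CORE_RANGE[1] else 1.0)
        return total
    if len(site) == L + 1:
        best = math.inf
        for d in range(len(site)):
            reduced = site[:d] + site[d + 1:]
            # bulged target base sits opposite the junction after this guide position
            bulge_pos = min(max(L - d, 1), L)
            pen = 1.0 * (2.0 if CORE_RANGE[0] <= bulge_pos <= CORE_RANGE[1] else 1.0)
            best = min(best, score_site_scheme_a(guide, reduced) + pen)
        return best
    raise ValueError("site length must equal guide length (+1 for one bulge)")


def score_site_scheme_b(guide: str, site: str) -> float:
    """Penalty with hard seed rule: > 1.0 penalty points within guide
    positions 2-8 rejects the site (returns inf).  No bulges."""
    total = 0.0
    seed_total = 0.0
    for pos, pen in _position_pairs(guide, site):
        total += pen
        if SEED_RANGE[0] <= pos <= SEED_RANGE[1]:
            seed_total += pen
    if seed_total > SEED_MAX_PENALTY:
        return math.inf
    return total


@dataclass
class TargetHit:
    """An siRNA binding site on a transcript, scored under both schemes."""

    sirna_id: str
    transcript_id: str
    site_start: int  # 0-based half-open on the transcript
    site_end: int
    score_a: float
    score_b: float
    consensus: bool


def scan_transcript(
    sirna_id: str,
    guide: str,
    transcript_id: str,
    transcript: str,
    cutoff_a: float = CUTOFF_A,
    cutoff_b: float = CUTOFF_B,
    allow_bulge: bool = True,
) -> list[TargetHit]:
    """Score every offset of one guide against one transcript.

    At each offset the exact-length window is scored under both schemes;
    scheme A additionally considers the (L+1)-length bulged window starting
    at the same offset, keeping the better score.  A hit is emitted when
    either scheme passes its cutoff; consensus requires both.
    """
    L = len(guide)
    n = len(transcript)
    hits = []
    for i in range(n - L + 1):
        window = transcript[i:i + L]
        sa = score_site_scheme_a(guide, window)
        end = i + L
        if allow_bulge and i + L + 1 <= n:
            sa_bulge = score_site_scheme_a(guide, transcript[i:i + L + 1])
            if sa_bulge < sa:
                sa, end = sa_bulge, i + L + 1
        sb = score_site_scheme_b(guide, window)
        pass_a = sa <= cutoff_a
        pass_b = sb <= cutoff_b
        if pass_a or pass_b:
            hits.append(
                TargetHit(sirna_id, transcript_id, i, end, sa, sb, pass_a and pass_b)
            )
    return hits


def scan_transcripts(
    guides: dict[str, str],
    transcripts: dict[str, str],
    cutoff_a: float = CUTOFF_A,
    cutoff_b: float = CUTOFF_B,
    allow_bulge: bool = True,
) -> list[TargetHit]:
    """All guide x transcript hits, ordered (sirna_id, transcript_id, start)."""
    hits: list[TargetHit] = []
    for sirna_id in sorted(guides):
        for tx_id in sorted(transcripts):
            hits.extend(
                scan_transcript(
                    sirna_id, guides[sirna_id], tx_id, transcripts[tx_id],
                    cutoff_a, cutoff_b, allow_bulge,
                )
            )
    return hits


def read_transcripts_fasta(path: Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_hits_tsv(hits: list[TargetHit], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sirna_id\ttranscript_id\tsite_start\tsite_end\t"
                 "score_a\tscore_b\tconsensus\n")
        for h in hits:
            sb = "inf" if math.isinf(h.score_b) else f"{h.score_b:.2f}"
            fh.write(
                f"{h.sirna_id}\t{h.transcript_id}\t{h.site_start}\t{h.site_end}\t"
                f"{h.score_a:.2f}\t{sb}\t{int(h.consensus)}\n"
            )


def consensus_target_genes(hits: list[TargetHit]) -> set[str]:
    return {h.transcript_id for h in hits if h.consensus}
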