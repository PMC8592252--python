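"""End-to-end orchestration: preprocess -> map -> call -> differential expression.

Library sizes for TPM default to the total mapped cleaned reads per library
(all tags with at least one exact genome hit, before structural-RNA
subtraction); ``library_size_mode='called'`` switches the denominator to the
summed counts of called siRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from sirnakit import diffexpr, genome_map, preprocess, sirna_call
from sirnakit.utils import LIBRARIES


@dataclass
class PipelineResult:
    tags: list[preprocess.ReadTag]
    cleanup_stats: preprocess.CleanupStats
    kept_hits: dict[str, list[genome_map.GenomeHit]]
    subtraction_tally: dict[str, int]
    sirnas: list[sirna_call.SirnaDuplex]
    library_sizes: np.ndarray
    de_table: pd.DataFrame


def run_pipeline(
    genome_fasta: Path,
    annotation_gff3: Path,
    fastq_paths: dict[str, Path],
    adapter: str,
    outdir: Path | None = None,
    min_len: int = 18,
    max_len: int = 30,
    min_mean_phred: float = 20.0,
    max_hits: int = 20,
    min_reads: int = 5,
    abundance_mode: str = "all",
    relaxed_geometry: bool = False,
    test: str = "binomial",
    alpha: float = 0.05,
    lfc: float = 1.0,
    pseudocount: float = 0.01,
    floor: float = 30.0,
    library_size_mode: str = "mapped",
    seed_length: int = 16,
) -> PipelineResult:
    tags, stats = preprocess.preprocess_libraries(
        fastq_paths, adapter, min_mean_phred=min_mean_phred,
        min_len=min_len, max_len=max_len,
    )

    index = genome_map.GenomeIndex.from_fasta(genome_fasta, seed_length=seed_length)
    mapped, _unmapped, _capped = genome_map.map_tags(tags, index, max_hits=max_hits)
    annotation = genome_map.AnnotationIndex.from_gff3(
        annotation_gff3, valid_chroms=set(index.genome)
    )
    kept, tally = genome_map.subtract_annotated(mapped, annotation)

    kept_tags = [t for t in tags if t.sequence in kept]
    sirnas = sirna_call.call_sirnas(
        kept, kept_tags, min_reads=min_reads, mode=abundance_mode,
        relaxed=relaxed_geometry,
    )

    counts_by_tag = {t.sequence: t.counts for t in tags}
    if library_size_mode == "mapped":
        sizes = np.zeros(len(LIBRARIES))
        for seq in mapped:
            sizes += np.asarray(counts_by_tag[seq], dtype=float)
    elif library_size_mode == "called":
        sizes = np.zeros(len(LIBRARIES))
        for s in sirnas:
            sizes += np.asarray(s.counts, dtype=float)
    else:
        raise ValueError(f"unknown library_size_mode: {library_size_mode}")

    raw = np.array([s.counts for s in sirnas], dtype=int)
    ids = [s.sirna_id for s in sirnas]
    de_table = diffexpr.differential_expression(
        ids, raw, sizes, test=test, alpha=alpha, lfc=lfc,
        pseudocount=pseudocount, floor=floor,
    )

    result = PipelineResult(tags, stats, kept, tally, sirnas, sizes, de_table)
    if outdir is not None:
        write_outputs(result, Path(outdir))
    return result


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    preprocess.write_tag_tsv(result.tags, outdir / "tags.tsv")
    preprocess.write_stats_tsv(result.cleanup_stats, outdir / "cleanup_stats.tsv")
    totals = {t.sequence: t.total for t in result.tags}
    genome_map.write_hits_bed6(result.kept_hits, totals, outdir / "hits.bed")
    genome_map.write_tally_tsv(result.subtraction_tally, outdir / "subtraction_tally.tsv")
    sirna_call.write_catalogue_tsv(result.sirnas, outdir / "sirna_catalogue.tsv")
    stats_table = sirna_call.length_first_base_stats(result.sirnas)
    stats_table.to_csv(outdir / "length_first_base.tsv", sep="\t")
    result.de_table.to_csv(outdir / "de_table.tsv", sep="\t", index=False,
                           float_format="%.6g")
    reports = diffexpr.intersection_reports(result.de_table)
    diffexpr.write_intersections_json(reports, outdir / "intersections.json")
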