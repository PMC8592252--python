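"""Synthetic small-RNA experiment generator with planted ground truth.

Produces a toy genome with annotated structural-RNA loci, planted siRNA
duplex loci (20-24 nt guides, minus-strand partner shifted left by 2 so
every locus carries the canonical 2-nt 3' overhang), four adapter-ligated
FASTQ libraries with planted temporal fold changes, a transcriptome with
planted complementary target sites, a gene->GO map with one designated
enriched term, and a qPCR Ct table consistent with the planted dynamics.
Everything is keyed off a single RNG seed and is byte-reproducible.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from sirnakit.utils import COMPARISONS, LIBRARIES, intervals_overlap, revcomp

STRUCTURAL_CLASSES: tuple[str, ...] = ("rRNA", "tRNA", "snRNA", "snoRNA", "miRNA")

#: Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

TRUTH_COLUMNS = [
    "locus_id",
    "chrom",
    "plus_start",
    "plus_end",
    "minus_start",
    "minus_end",
    "guide_length",
    "guide_sequence",
    "status_1h",
    "status_6h",
    "status_12h",
    "tpm_0h",
    "tpm_1h",
    "tpm_6h",
    "tpm_12h",
    "target_ids",
]


class PlacementError(RuntimeError):
    """Raised when loci cannot be placed without overlap."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Fractions are proportions of each library's depth; ``seed`` fixes every
    random choice, so identical configs produce byte-identical files.
    """

    genome_length: int = 100_000
    chrom_name: str = "chr1"
    n_up: int = 20
    n_down: int = 20
    n_flat: int = 20
    fold_up: float = 4.0
    fold_down: float = 0.25
    guide_len_min: int = 20
    guide_len_max: int = 24
    n_structural: dict[str, int] = field(
        default_factory=lambda: {c: 4 for c in STRUCTURAL_CLASSES}
    )
    structural_len_min: int = 70
    structural_len_max: int = 160
    library_depth: int | tuple[int, int, int, int] = 100_000
    adapter: str = DEFAULT_ADAPTER
    junk_fraction: float = 0.05
    lowq_fraction: float = 0.02
    guide_strand_fraction: float = 0.7
    n_transcripts: int = 60
    transcript_length: int = 500
    n_target_loci: int = 20
    go_designated_term: str = "GO:9990001"
    go_background_fraction: float = 0.05
    n_go_terms: int = 12
    qpcr_panel_size: int = 18
    qpcr_replicates: int = 3
    qpcr_ct_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("junk_fraction", "lowq_fraction", "guide_strand_fraction",
                     "go_background_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.junk_fraction + self.lowq_fraction >= 1.0:
            raise ValueError("junk_fraction + lowq_fraction must be < 1")
        if min(self.depths) < 0:
            raise ValueError("library depth must be >= 0")
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10000")
        if not 1 <= self.guide_len_min <= self.guide_len_max:
            raise ValueError("invalid guide length bounds")

    @property
    def depths(self) -> tuple[int, int, int, int]:
        d = self.library_depth
        if isinstance(d, int):
            return (d, d, d, d)
        d = tuple(int(x) for x in d)
        if len(d) != len(LIBRARIES):
            raise ValueError("library_depth must be scalar or one per library")
        return d  # type: ignore[return-value]

    @property
    def n_sirna_loci(self) -> int:
        return self.n_up + self.n_down + self.n_flat


@dataclass
class StructuralLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    feature_class: str


@dataclass
class TruthRecord:
    """One planted siRNA duplex locus with its expected dynamics."""

    locus_id: str
    chrom: str
    plus_interval: tuple[int, int]
    minus_interval: tuple[int, int]
    guide_length: int
    guide_sequence: str
    planted_status: dict[str, str]  # comparison -> up/down/flat
    planted_tpm: dict[str, float]  # library -> expected TPM
    planted_target_ids: list[str] = field(default_factory=list)

    @property
    def status(self) -> str:
        # statuses are uniform across heat timepoints by construction
        return self.planted_status[COMPARISONS[0]]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _place_nonoverlapping(
    rng: np.random.Generator,
    lengths: list[int],
    genome_length: int,
    occupied: list[tuple[int, int]],
    margin: int = 2,
    max_tries: int = 2000,
) -> list[tuple[int, int]]:
    """Sample non-overlapping intervals by rejection; margin pads the left
    edge so a 2-nt shifted partner interval also stays clear."""
    placed: list[tuple[int, int]] = []
    taken = list(occupied)
    for length in lengths:
        for _ in range(max_tries):
            start = int(rng.integers(margin, genome_length - length))
            iv = (start - margin, start + length)
            if all(not intervals_overlap(iv[0], iv[1], s, e) for s, e in taken):
                placed.append((start, start + length))
                taken.append(iv)
                break
        else:
            raise PlacementError(
                f"could not place a {length}-bp locus after {max_tries} tries"
            )
    return placed


def make_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[StructuralLocus]]:
    """Random genome plus non-overlapping structural-RNA annotations."""
    rng = np.random.default_rng(config.seed)
    genome = {config.chrom_name: _random_dna(rng, config.genome_length)}

    lengths: list[int] = []
    classes: list[str] = []
    for cls in STRUCTURAL_CLASSES:
        n = config.n_structural.get(cls, 0)
        for _ in range(n):
            lengths.append(
                int(rng.integers(config.structural_len_min,
                                 config.structural_len_max + 1))
            )
            classes.append(cls)
    intervals = _place_nonoverlapping(rng, lengths, config.genome_length, [])
    loci = [
        StructuralLocus(f"{cls.lower()}_{i + 1:03d}", config.chrom_name, s, e, cls)
        for i, ((s, e), cls) in enumerate(zip(intervals, classes))
    ]
    return genome, loci


def _status_fold(status: str, config: SimulationConfig) -> float:
    return {"up": config.fold_up, "down": config.fold_down, "flat": 1.0}[status]


def plant_sirna_loci(
    genome: dict[str, str],
    structural: list[StructuralLocus],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[TruthRecord], np.ndarray, np.ndarray]:
    """Plant duplex loci and lay out per-library expected counts.

    Returns (truth records, expected planted count matrix n_loci x 4,
    expected structural count matrix n_struct x 4).  Weights of the "down"
    group are scaled so each library carries the same total expected signal;
    expected TPM ratios then equal the planted folds exactly.
    """
    chrom = config.chrom_name
    seq = genome[chrom]
    occupied = [(s.start, s.end) for s in structural]

    lengths = [
        int(rng.integers(config.guide_len_min, config.guide_len_max + 1))
        for _ in range(config.n_sirna_loci)
    ]
    intervals = _place_nonoverlapping(
        rng, lengths, config.genome_length, occupied, margin=2
    )
    intervals.sort()

    statuses = (
        ["up"] * config.n_up + ["down"] * config.n_down + ["flat"] * config.n_flat
    )
    statuses = [statuses[i] for i in rng.permutation(len(statuses))]

    weights = rng.uniform(100.0, 300.0, size=len(intervals))
    up = np.array([s == "up" for s in statuses])
    down = np.array([s == "down" for s in statuses])
    # balance library composition: up-surplus == down-deficit
    surplus = float(weights[up].sum()) * (config.fold_up - 1.0)
    deficit_unit = float(weights[down].sum()) * (1.0 - config.fold_down)
    if surplus > 0 and deficit_unit > 0:
        weights[down] *= surplus / deficit_unit

    folds = np.array([_status_fold(s, config) for s in statuses])
    expected = np.empty((len(intervals), len(LIBRARIES)))
    expected[:, 0] = weights
    for j in range(1, len(LIBRARIES)):
        expected[:, j] = weights * folds

    n_struct = len(structural)
    struct_weights = rng.uniform(300.0, 2000.0, size=n_struct)
    struct_expected = np.tile(struct_weights[:, None], (1, len(LIBRARIES)))

    # scale expected weights into read counts within each library's signal budget
    signal_frac = 1.0 - config.junk_fraction - config.lowq_fraction
    total_weight = expected[:, 0].sum() + struct_weights.sum()
    for j, depth in enumerate(config.depths):
        scale = depth * signal_frac / total_weight
        expected[:, j] *= scale
        struct_expected[:, j] *= scale

    # expected TPM relative to the mapped-read total of each library
    mapped_totals = expected.sum(axis=0) + struct_expected.sum(axis=0)
    mapped_totals[mapped_totals == 0] = 1.0  # zero-depth libraries: TPM 0
    records = []
    for i, ((start, end), status) in enumerate(zip(intervals, statuses)):
        tpm = {
            lib: float(expected[i, j] / mapped_totals[j] * 1e6)
            for j, lib in enumerate(LIBRARIES)
        }
        records.append(
            TruthRecord(
                locus_id=f"locus{i + 1:05d}",
                chrom=chrom,
                plus_interval=(start, end),
                minus_interval=(start - 2, end - 2),
                guide_length=end - start,
                guide_sequence=seq[start:end],
                planted_status={c: status for c in COMPARISONS},
                planted_tpm=tpm,
            )
        )
    return records, expected, struct_expected


def _quality(length: int, high: bool) -> str:
    # 'I' = Phred 40, '#' = Phred 2 (mean < 20 -> dropped by the QC filter)
    return ("I" if high else "#") * length


def simulate_reads(
    genome: dict[str, str],
    truth: list[TruthRecord],
    structural: list[StructuralLocus],
    expected: np.ndarray,
    struct_expected: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    outdir: Path,
) -> dict[str, Path]:
    """Write one adapter-ligated FASTQ per library; counts ~ Poisson(expected)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    adapter = config.adapter
    for j, lib in enumerate(LIBRARIES):
        depth = config.depths[j]
        entries: list[tuple[str, str]] = []  # (sequence, quality)

        for i, rec in enumerate(truth):
            n = int(rng.poisson(expected[i, j]))
            n_guide = int(rng.binomial(n, config.guide_strand_fraction))
            guide = rec.guide_sequence
            passenger = revcomp(
                genome[rec.chrom][rec.minus_interval[0]:rec.minus_interval[1]]
            )
            for seq, count in ((guide, n_guide), (passenger, n - n_guide)):
                read = seq + adapter
                q = _quality(len(read), high=True)
                entries.extend([(read, q)] * count)

        for i, loc in enumerate(structural):
            n = int(rng.poisson(struct_expected[i, j]))
            locus_seq = genome[loc.chrom][loc.start:loc.end]
            for _ in range(n):
                ln = int(rng.integers(config.guide_len_min, config.guide_len_max + 1))
                off = int(rng.integers(0, len(locus_seq) - ln + 1))
                read = locus_seq[off:off + ln] + adapter
                entries.append((read, _quality(len(read), high=True)))

        n_junk = int(rng.poisson(depth * config.junk_fraction))
        for _ in range(n_junk):
            ln = int(rng.integers(config.guide_len_min, config.guide_len_max + 1))
            read = _random_dna(rng, ln) + adapter
            entries.append((read, _quality(len(read), high=True)))

        n_lowq = int(rng.poisson(depth * config.lowq_fraction))
        for _ in range(n_lowq):
            src = truth[int(rng.integers(0, len(truth)))]
            read = src.guide_sequence + adapter
            entries.append((read, _quality(len(read), high=False)))

        path = outdir / f"lib_{lib}.fastq"
        with open(path, "w") as fh:
            for k, (seq, qual) in enumerate(entries):
                fh.write(f"@{lib}_read{k + 1:07d}\n{seq}\n+\n{qual}\n")
        paths[lib] = path
    return paths


def write_genome_fasta(genome: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_annotation_gff3(structural: list[StructuralLocus], path: Path) -> None:
    """GFF3 with 1-based inclusive coordinates, per the format spec."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in structural:
            fh.write(
                "\t".join(
                    [
                        loc.chrom,
                        "sirnakit_sim",
                        loc.feature_class,
                        str(loc.start + 1),
                        str(loc.end),
                        ".",
                        "+",
                        ".",
                        f"ID={loc.locus_id}",
                    ]
                )
                + "\n"
            )


def write_truth_tsv(truth: list[TruthRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in truth:
            row = [
                r.locus_id,
                r.chrom,
                str(r.plus_interval[0]),
                str(r.plus_interval[1]),
                str(r.minus_interval[0]),
                str(r.minus_interval[1]),
                str(r.guide_length),
                r.guide_sequence,
                r.planted_status["1h"],
                r.planted_status["6h"],
                r.planted_status["12h"],
                *(f"{r.planted_tpm[lib]:.6f}" for lib in LIBRARIES),
                ",".join(r.planted_target_ids),
            ]
            fh.write("\t".join(row) + "\n")


def read_truth_tsv(path: Path) -> list[TruthRecord]:
    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            records.append(
                TruthRecord(
                    locus_id=row["locus_id"],
                    chrom=row["chrom"],
                    plus_interval=(int(row["plus_start"]), int(row["plus_end"])),
                    minus_interval=(int(row["minus_start"]), int(row["minus_end"])),
                    guide_length=int(row["guide_length"]),
                    guide_sequence=row["guide_sequence"],
                    planted_status={c: row[f"status_{c}"] for c in COMPARISONS},
                    planted_tpm={lib: float(row[f"tpm_{lib}"]) for lib in LIBRARIES},
                    planted_target_ids=(
                        row["target_ids"].split(",") if row["target_ids"] else []
                    ),
                )
            )
    return records


def make_transcriptome_and_go(
    truth: list[TruthRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
    outdir: Path,
) -> dict[str, Path]:
    """Transcript FASTA with planted perfect-complement sites, GO map with one
    designated enriched term, and a Ct table encoding the planted folds.

    Mutates ``truth``: planted_target_ids is filled for the chosen loci.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    de_loci = [r for r in truth if r.status in ("up", "down")]
    target_loci = de_loci[: config.n_target_loci]
    n_tx = max(config.n_transcripts, len(target_loci))

    transcripts: dict[str, str] = {}
    target_tx_ids: list[str] = []
    for i in range(n_tx):
        tx_id = f"tx{i + 1:05d}"
        seq = _random_dna(rng, config.transcript_length)
        if i < len(target_loci):
            rec = target_loci[i]
            site = revcomp(rec.guide_sequence)
            pos = int(rng.integers(0, config.transcript_length - len(site) + 1))
            seq = seq[:pos] + site + seq[pos + len(site):]
            rec.planted_target_ids.append(tx_id)
            target_tx_ids.append(tx_id)
        transcripts[tx_id] = seq

    tx_path = outdir / "transcripts.fa"
    with open(tx_path, "w") as fh:
        for tx_id, seq in transcripts.items():
            fh.write(f">{tx_id}\n")
            for k in range(0, len(seq), 70):
                fh.write(seq[k:k + 70] + "\n")

    # GO map: designated term covers every target gene plus a small slice of
    # background; filler terms are assigned at random across namespaces.
    namespaces = ("biological_process", "molecular_function", "cellular_component")
    go_rows: list[tuple[str, str, str]] = []
    background = [t for t in transcripts if t not in target_tx_ids]
    n_bg_hit = max(1, int(round(config.go_background_fraction * len(background))))
    bg_hit = [background[i] for i in rng.choice(len(background), n_bg_hit, replace=False)]
    for gene in target_tx_ids + bg_hit:
        go_rows.append((gene, config.go_designated_term, "biological_process"))
    filler_terms = [f"GO:{1000000 + t}" for t in range(config.n_go_terms)]
    for gene in transcripts:
        k = int(rng.integers(1, 3))
        for t in rng.choice(len(filler_terms), k, replace=False):
            go_rows.append((gene, filler_terms[t], namespaces[t % 3]))
    go_path = outdir / "go_map.tsv"
    with open(go_path, "w") as fh:
        fh.write("gene_id\tgo_id\tnamespace\n")
        for row in sorted(go_rows):
            fh.write("\t".join(row) + "\n")

    # qPCR Ct table: reference at 20 cycles, target shifted by -log2(fold),
    # so 2^-ddCT recovers the planted fold change exactly at zero noise.
    by_status: dict[str, list[TruthRecord]] = {"up": [], "down": [], "flat": []}
    for r in truth:
        by_status[r.status].append(r)
    panel: list[TruthRecord] = []
    want = config.qpcr_panel_size
    per = max(1, want // 3)
    for status in ("up", "down", "flat"):
        panel.extend(by_status[status][:per])
    for status in ("up", "down", "flat"):
        for r in by_status[status][per:]:
            if len(panel) >= want:
                break
            panel.append(r)
    panel = panel[:want]

    ct_path = outdir / "qpcr_ct.csv"
    with open(ct_path, "w") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sirna_id", "timepoint", "replicate", "ct_target", "ct_reference"])
        for r in panel:
            for lib in LIBRARIES:
                fold = 1.0 if lib == "0h" else _status_fold(r.status, config)
                base_ct = 24.0 - math.log2(fold)
                for rep in range(1, config.qpcr_replicates + 1):
                    noise_t = float(rng.normal(0, config.qpcr_ct_noise_sd))
                    noise_r = float(rng.normal(0, config.qpcr_ct_noise_sd))
                    writer.writerow(
                        [
                            r.locus_id,
                            lib,
                            rep,
                            f"{base_ct + noise_t:.4f}",
                            f"{20.0 + noise_r:.4f}",
                        ]
                    )

    return {"transcripts": tx_path, "go_map": go_path, "qpcr_ct": ct_path}


def simulate_experiment(config: SimulationConfig, outdir: Path) -> dict[str, Path]:
    """Generate the full synthetic experiment into ``outdir``.

    Returns a dict of file paths: genome, annotation, truth, per-library
    FASTQs, transcripts, go_map, qpcr_ct.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, structural = make_genome(config)
    # separate stream so genome bytes only depend on (seed, genome params)
    rng = np.random.default_rng((config.seed, 1))
    truth, expected, struct_expected = plant_sirna_loci(genome, structural, config, rng)
    aux = make_transcriptome_and_go(truth, config, rng, outdir)
    fastqs = simulate_reads(
        genome, truth, structural, expected, struct_expected, config, rng, outdir
    )

    genome_path = outdir / "genome.fa"
    write_genome_fasta(genome, genome_path)
    gff_path = outdir / "annotation.gff3"
    write_annotation_gff3(structural, gff_path)
    truth_path = outdir / "truth.tsv"
    write_truth_tsv(truth, truth_path)

    paths = {"genome": genome_path, "annotation": gff_path, "truth": truth_path}
    paths.update({f"fastq_{lib}": p for lib, p in fastqs.items()})
    paths.update(aux)
    return paths
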