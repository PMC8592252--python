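import numpy as np
import pytest

from sirnakit.genome_map import (
    AnnotationIndex,
    GenomeIndex,
    map_exact,
    map_tags,
    subtract_annotated,
)
from sirnakit.preprocess import ReadTag
from sirnakit.utils import revcomp


def _random_genome(rng, length=5000):
    return "".join(rng.choice(list("ACGT"), size=length))


def naive_scan(genome: dict[str, str], query: str):
    """O(n*m) full-scan oracle over both strands."""
    hits = []
    for chrom, seq in genome.items():
        for strand, q in (("+", query), ("-", revcomp(query))):
            start = seq.find(q)
            while start != -1:
                hits.append((chrom, start, start + len(query), strand))
                start = seq.find(q, start + 1)
    return sorted(hits)


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(77)
    return {"chr1": _random_genome(rng, 5000), "chr2": _random_genome(rng, 3000)}


@pytest.fixture(scope="module")
def index(genome):
    return GenomeIndex(genome, seed_length=16)


class TestGenomeIndex:
    def test_planted_plus_strand_query(self, genome, index):
        query = genome["chr1"][100:121]
        hits = index.find(query)
        assert any(
            (h.chrom, h.start, h.end, h.strand) == ("chr1", 100, 121, "+")
            for h in hits
        )

    def test_reverse_complement_query_hits_minus(self, genome, index):
        query = revcomp(genome["chr1"][100:121])
        hits = index.find(query)
        assert any(
            (h.chrom, h.start, h.end, h.strand) == ("chr1", 100, 121, "-")
            for h in hits
        )

    def test_strand_symmetry(self, genome, index):
        query = genome["chr2"][500:522]
        fwd = {(h.chrom, h.start, h.end, h.strand) for h in index.find(query)}
        rev = {(h.chrom, h.start, h.end, h.strand) for h in index.find(revcomp(query))}
        swap = {"+": "-", "-": "+"}
        assert rev == {(c, s, e, swap[st]) for c, s, e, st in fwd}

    def test_equivalence_with_naive_scan_on_random_tags(self, genome, index):
        rng = np.random.default_rng(5)
        seq = genome["chr1"]
        for _ in range(200):
            ln = int(rng.integers(18, 25))
            if rng.random() < 0.7:
                start = int(rng.integers(0, len(seq) - ln))
                query = seq[start:start + ln]
                if rng.random() < 0.5:
                    query = revcomp(query)
            else:
                query = "".join(rng.choice(list("ACGT"), size=ln))
            got = {(h.chrom, h.start, h.end, h.strand) for h in index.find(query)}
            assert got == set(naive_scan(genome, query))

    def test_planted_duplicate_found_twice(self):
        rng = np.random.default_rng(9)
        core = _random_genome(rng, 1000)
        motif = _random_genome(rng, 21)
        genome = {"c": core[:300] + motif + core[300:600] + motif + core[600:]}
        index = GenomeIndex(genome)
        hits = [h for h in index.find(motif) if h.strand == "+"]
        assert len(hits) == len([h for h in naive_scan(genome, motif) if h[3] == "+"])

    def test_duplicate_chromosomes_rejected(self, tmp_path):
        fa = tmp_path / "dup.fa"
        fa.write_text(">c1\nACGTACGTACGTACGTACGT\n>c1\nACGTACGTACGTACGTACGT\n")
        with pytest.raises(ValueError):
            GenomeIndex.from_fasta(fa)

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            GenomeIndex({})


class TestMapExact:
    def test_unmapped_junk_tag(self):
        rng = np.random.default_rng(1)
        genome = {"c": _random_genome(rng, 2000)}
        index = GenomeIndex(genome)
        tag = ReadTag("TTTTTTTTTTTTTTTTTTTTT", (1, 1, 1, 1))
        if "T" * 21 not in genome["c"]:
            assert map_exact(tag, index) == []

    def test_hit_ordering(self):
        rng = np.random.default_rng(2)
        genome = {"a": _random_genome(rng, 3000), "b": _random_genome(rng, 3000)}
        motif = genome["a"][50:71]
        genome["b"] = motif + genome["b"][21:]
        index = GenomeIndex(genome)
        hits = map_exact(ReadTag(motif, (1, 0, 0, 0)), index)
        keys = [(h.chrom, h.start, h.strand) for h in hits]
        assert keys == sorted(keys)

    def test_max_hits_cap_drops_tag(self):
        motif = "ACGTACGTACGTACGTACGT"
        genome = {"c": ("TTTT" + motif) * 5 + "TTTTTTTTTTTTTTTTTTTT"}
        index = GenomeIndex(genome, seed_length=16)
        tags = [ReadTag(motif, (9, 9, 9, 9))]
        mapped, unmapped, capped = map_tags(tags, index, max_hits=3)
        assert capped == [motif] and not mapped and not unmapped


class TestSubtractAnnotated:
    def _hits(self, *intervals):
        out = {}
        for i, (start, end) in enumerate(intervals):
            from sirnakit.genome_map import GenomeHit

            seq = f"TAG{i}"
            out[seq] = [GenomeHit(seq, "chr1", start, end, "+")]
        return out

    def test_hit_inside_rrna_removed_and_tallied(self):
        ann = AnnotationIndex({"chr1": [(100, 200, "rRNA")]})
        kept, tally = subtract_annotated(self._hits((120, 141)), ann)
        assert not kept
        assert tally["rRNA"] == 1

    def test_halfopen_adjacency_kept(self):
        ann = AnnotationIndex({"chr1": [(100, 200, "tRNA")]})
        kept, tally = subtract_annotated(self._hits((200, 221), (79, 100)), ann)
        assert len(kept) == 2
        assert sum(tally.values()) == 0

    def test_single_bp_overlap_removed(self):
        ann = AnnotationIndex({"chr1": [(100, 200, "tRNA")]})
        kept, tally = subtract_annotated(self._hits((80, 101)), ann)
        assert not kept
        assert tally["tRNA"] == 1

    def test_class_precedence(self):
        ann = AnnotationIndex(
            {"chr1": [(100, 200, "miRNA"), (150, 250, "rRNA")]}
        )
        kept, tally = subtract_annotated(self._hits((160, 181)), ann)
        assert tally["rRNA"] == 1 and tally["miRNA"] == 0

    def test_multimapper_removed_entirely_if_any_hit_annotated(self):
        from sirnakit.genome_map import GenomeHit

        ann = AnnotationIndex({"chr1": [(100, 200, "snoRNA")]})
        hits = {
            "TAGX": [
                GenomeHit("TAGX", "chr1", 150, 171, "+"),
                GenomeHit("TAGX", "chr1", 3000, 3021, "+"),
            ]
        }
        kept, tally = subtract_annotated(hits, ann)
        assert not kept and tally["snoRNA"] == 1

    def test_random_instances_match_interval_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            n_ann = int(rng.integers(1, 8))
            ann_ivs = []
            for _ in range(n_ann):
                s = int(rng.integers(0, 4000))
                ann_ivs.append((s, s + int(rng.integers(20, 300)), "miRNA"))
            ann = AnnotationIndex({"chr1": sorted(ann_ivs)})
            hits = self._hits(
                *[
                    (s, s + 21)
                    for s in rng.integers(0, 4300, size=20)
                ]
            )
            kept, _ = subtract_annotated(hits, ann)
            for seq, hs in hits.items():
                h = hs[0]
                overlaps = any(
                    h.start < e and s < h.end for s, e, _ in ann_ivs
                )
                assert (seq in kept) == (not overlaps)

    def test_gff3_round_trip_with_unknown_chrom_warning(self, tmp_path, caplog):
        gff = tmp_path / "ann.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tx\trRNA\t101\t200\t.\t+\t.\tID=r1\n"
            "chrX\tx\ttRNA\t1\t50\t.\t+\t.\tID=t1\n"
            "chr1\tx\tgene\t500\t900\t.\t+\t.\tID=g1\n"
        )
        ann = AnnotationIndex.from_gff3(gff, valid_chroms={"chr1"})
        assert ann.intervals == {"chr1": [(100, 200, "rRNA")]}


def test_partition_property(small_pipeline):
    # kept + removed + unmapped partitions the tag universe
    result = small_pipeline
    kept = set(result.kept_hits)
    all_tags = {t.sequence for t in result.tags}
    assert kept <= all_tags
    removed = sum(result.subtraction_tally.values())
    assert len(kept) + removed <= len(all_tags)
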