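"""Mapper contracts: index correctness, identity arithmetic, competitive
specificity, strand symmetry and the brute-force oracle equivalence."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bathypan import dnautil, recruit, simulate
from bathypan.experiments import bruteforce_best_identity
from bathypan.recruit import MappingParams, MappingRecord
from bathypan.simulate import AnnotatedGenome


def _genome(genome_id, seqs):
    return AnnotatedGenome(genome_id=genome_id, chromosomes=seqs, genes=[])


class TestKmerIndex:
    def test_position_count_is_length_minus_k_plus_one(self):
        rng = np.random.default_rng(0)
        seq = dnautil.decode(rng.integers(0, 4, 100).astype(np.uint8))
        idx = recruit.build_index(_genome("A", [("chr01", seq)]), k=15)
        assert idx.n_positions == 86

    def test_absent_kmer_returns_empty(self):
        idx = recruit.build_index(_genome("A", [("chr01", "AC" * 60)]), k=15)
        assert idx.lookup("G" * 15) == []

    def test_lookup_returns_true_positions(self, tiny_pair):
        """Every indexed position yields exactly its k-mer (substring oracle)."""
        _, ga, _, _ = tiny_pair
        seq = ga.chromosomes[0][1]
        idx = recruit.build_index(ga, k=15)
        rng = np.random.default_rng(3)
        for pos in rng.integers(0, len(seq) - 15, size=10):
            kmer = seq[pos : pos + 15]
            hits = idx.lookup(kmer)
            assert ("chr01", int(pos), "+") in hits
            for cid, p, strand in hits:
                sub = ga.sequence(cid)[p : p + 15]
                assert sub == (kmer if strand == "+" else dnautil.revcomp(kmer))

    def test_k_larger_than_chromosome_rejected(self):
        with pytest.raises(ValueError):
            recruit.build_index(_genome("A", [("chr01", "ACGT" * 3)]), k=15)

    def test_k_range_enforced(self, tiny_pair):
        _, ga, _, _ = tiny_pair
        with pytest.raises(ValueError):
            recruit.build_index(ga, k=9)


@pytest.fixture(scope="module")
def indexes(tiny_pair):
    _, ga, gb, _ = tiny_pair
    return recruit.build_index(ga), recruit.build_index(gb)


class TestMapRead:
    def test_exact_substring_maps_at_100(self, tiny_pair, indexes):
        _, ga, _, _ = tiny_pair
        ia, ib = indexes
        read = ga.sequence("chr01")[1000:1100]
        rec = recruit.map_read(read, ia, ib)
        assert (rec.genome_id, rec.chrom_id, rec.start) == ("A", "chr01", 1000)
        assert rec.identity == 100.0 and rec.strand == "+"

    def test_five_substitutions_give_95(self, tiny_pair, indexes):
        _, ga, _, _ = tiny_pair
        ia, ib = indexes
        codes = dnautil.encode(ga.sequence("chr01")[1000:1100])
        for p in (5, 25, 45, 65, 85):
            codes[p] = (codes[p] + 1) % 4
        rec = recruit.map_read(dnautil.decode(codes), ia, ib)
        assert rec.identity == 95.0 and rec.start == 1000

    def test_strand_symmetry(self, tiny_pair, indexes):
        _, ga, _, _ = tiny_pair
        ia, ib = indexes
        read = ga.sequence("chr01")[2000:2100]
        fwd = recruit.map_read(read, ia, ib)
        rev = recruit.map_read(dnautil.revcomp(read), ia, ib)
        assert (fwd.chrom_id, fwd.start, fwd.identity) == (
            rev.chrom_id, rev.start, rev.identity,
        )
        assert {fwd.strand, rev.strand} == {"+", "-"}

    def test_garbage_read_unmapped(self, indexes):
        ia, ib = indexes
        rng = np.random.default_rng(1)
        read = dnautil.decode(rng.integers(0, 4, 100).astype(np.uint8))
        assert recruit.map_read(read, ia, ib) is None

    def test_reads_from_one_genome_recruit_to_it(self, tiny_pair, indexes):
        """Error-free reads from genome A at ~78% inter-genome identity map
        best to A in >=99% of cases."""
        _, ga, _, _ = tiny_pair
        ia, ib = indexes
        seq = ga.sequence("chr01")
        rng = np.random.default_rng(5)
        correct = 0
        n = 300
        for pos in rng.integers(0, len(seq) - 100, size=n):
            rec = recruit.map_read(seq[pos : pos + 100], ia, ib)
            correct += rec is not None and rec.genome_id == "A"
        assert correct / n >= 0.99


class TestCompetitiveFilter:
    @pytest.mark.parametrize(
        "ident,other,expected",
        [
            (100.0, 78.0, True),   # clear margin: specific
            (99.0, 98.0, False),   # 1 point < margin 3: ambiguous
            (100.0, None, True),   # no placement on the other genome
            (94.0, 78.0, False),   # below identity floor
            (98.0, 95.0, True),    # margin exactly 3: specific (>=)
        ],
    )
    def test_rule(self, ident, other, expected):
        rec = MappingRecord(
            read_id="r", genome_id="A", chrom_id="chr01", start=0,
            strand="+", aligned_length=100, identity=ident,
            best_other_identity=other,
        )
        assert recruit.competitive_filter(rec).specific is expected


class TestBatchMapping:
    def test_batch_agrees_with_single_read_path(self, tiny_pair, indexes):
        _, ga, gb, _ = tiny_pair
        ia, ib = indexes
        sample = dataclasses.replace(
            simulate.simulate_station_series(2, seed=2)[0],
            true_fraction_a=0.5, true_fraction_b=0.4, background_fraction=0.1,
            total_reads=300,
        )
        reads, _ = simulate.simulate_reads(sample, {"A": ga, "B": gb}, seed=7)
        batch = recruit.map_reads(reads, ia, ib, MappingParams(seed_stride=1))
        by_id = batch.set_index("read_id")
        for name, codes in zip(reads.names, reads.codes):
            rec = recruit.map_read(dnautil.decode(codes), ia, ib)
            if rec is None:
                assert name not in by_id.index
            else:
                row = by_id.loc[name]
                assert row["genome_id"] == rec.genome_id
                assert row["start"] == rec.start
                assert row["identity"] == pytest.approx(rec.identity)
                assert bool(row["specific"]) == rec.specific

    def test_partition_specific_ambiguous_unmapped(self, tiny_pair, indexes):
        """Specific-to-A / specific-to-B / ambiguous / unmapped partition the
        read set: mutually exclusive and exhaustive."""
        _, ga, gb, _ = tiny_pair
        ia, ib = indexes
        sample = dataclasses.replace(
            simulate.simulate_station_series(2, seed=2)[0],
            true_fraction_a=0.4, true_fraction_b=0.4, background_fraction=0.2,
            total_reads=2_000,
        )
        reads, _ = simulate.simulate_reads(sample, {"A": ga, "B": gb}, seed=9)
        maps = recruit.map_reads(reads, ia, ib, MappingParams(seed_stride=4))
        assert maps["read_id"].is_unique
        spec_a = ((maps.genome_id == "A") & maps.specific).sum()
        spec_b = ((maps.genome_id == "B") & maps.specific).sum()
        ambiguous = (~maps.specific).sum()
        unmapped = len(reads) - len(maps)
        assert spec_a + spec_b + ambiguous + unmapped == len(reads)

    def test_mapper_matches_bruteforce_on_tiny_genomes(self, tiny_pair, indexes):
        """Chosen-locus identity equals exhaustive all-position alignment."""
        _, ga, gb, _ = tiny_pair
        ia, ib = indexes
        chroms = [dnautil.encode(ga.sequence("chr01")), dnautil.encode(gb.sequence("chr01"))]
        rng = np.random.default_rng(13)
        params = MappingParams(seed_stride=1)
        for i in range(60):
            src = chroms[i % 2]
            pos = int(rng.integers(0, len(src) - 60))
            codes = dnautil.mutate_codes(rng, src[pos : pos + 60], 0.02)
            rec = recruit.map_read(dnautil.decode(codes), ia, ib, params)
            best = bruteforce_best_identity(codes, chroms)
            if rec is None:
                assert best < params.min_identity
            else:
                assert rec.identity == pytest.approx(best, abs=1e-9)


class TestRecruitmentProfile:
    def _records(self, rows):
        cols = [
            "read_id", "genome_id", "chrom_id", "start", "strand",
            "aligned_length", "identity", "best_other_identity", "specific",
        ]
        return pd.DataFrame(rows, columns=cols)

    def test_empty_records_give_zero_track(self, tiny_pair):
        _, ga, _, _ = tiny_pair
        tracks = recruit.recruitment_profile(self._records([]), ga, 1000)
        assert all(not t.depth.any() for t in tracks.values())

    def test_single_read_depth(self, tiny_pair):
        _, ga, _, _ = tiny_pair
        rec = self._records(
            [["r1", "A", "chr01", 100, "+", 100, 100.0, np.nan, True]]
        )
        track = recruit.recruitment_profile(rec, ga, 1000)["chr01"]
        assert track.depth[0] == pytest.approx(0.1)
        assert track.identity_hist[0, 100] == 1

    def test_nonpositive_window_rejected(self, tiny_pair):
        _, ga, _, _ = tiny_pair
        with pytest.raises(ValueError):
            recruit.recruitment_profile(self._records([]), ga, 0)

    def test_uniform_coverage_depth_within_poisson_bounds(self, tiny_pair):
        """~10x uniform simulation: windowed depth within 3 sigma nearly
        everywhere."""
        _, ga, gb, _ = tiny_pair
        ia, ib = recruit.build_index(ga), recruit.build_index(gb)
        depth_target = 10.0
        total = int(depth_target * ga.total_length / 100 / 0.95)
        sample = dataclasses.replace(
            simulate.simulate_station_series(2, seed=2)[0],
            true_fraction_a=0.95, true_fraction_b=0.0, background_fraction=0.05,
            total_reads=total,
        )
        reads, _ = simulate.simulate_reads(sample, {"A": ga, "B": gb}, seed=21)
        maps = recruit.map_reads(reads, ia, ib, MappingParams(seed_stride=4))
        maps = maps[maps.genome_id == "A"]
        track = recruit.recruitment_profile(maps, ga, 500)["chr01"]
        inner = track.depth[1:-1]  # edge windows lose overhanging reads
        sigma = np.sqrt(depth_target * 100 / 500)
        ok = np.abs(inner - depth_target) <= 3 * sigma
        assert ok.mean() >= 0.9


def test_sam_export_minimal_fields(tiny_pair, tmp_path):
    _, ga, _, _ = tiny_pair
    rec = pd.DataFrame(
        [["r1", "A", "chr01", 99, "-", 100, 97.0, np.nan, True]],
        columns=[
            "read_id", "genome_id", "chrom_id", "start", "strand",
            "aligned_length", "identity", "best_other_identity", "specific",
        ],
    )
    path = tmp_path / "out.sam"
    recruit.write_sam(rec, ga, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0].startswith("@HD") and lines[1].startswith("@SQ")
    fields = lines[-1].split("\t")
    assert fields[:6] == ["r1", "16", "chr01", "100", "60", "100M"]
    assert fields[-1] == "NM:i:3"
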