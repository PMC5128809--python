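"""Generator contracts: determinism, planted identities, population structure,
station series, read sets and expression signal."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bathypan import dnautil, simulate
from bathypan.simulate import GenomePairSpec, NicheParams


def hamming_identity(genome_a, genome_b, gene_a, gene_b):
    a, b = genome_a.gene(gene_a), genome_b.gene(gene_b)
    sa = dnautil.encode(genome_a.sequence(a.chrom_id)[a.start : a.end])
    sb = dnautil.encode(genome_b.sequence(b.chrom_id)[b.start : b.end])
    return 100.0 * float(np.mean(sa == sb))


@settings(max_examples=25, deadline=None)
@given(st.text(alphabet="ACGT", min_size=1, max_size=200))
def test_revcomp_is_involution(seq):
    assert dnautil.revcomp(dnautil.revcomp(seq)) == seq
    assert dnautil.decode(dnautil.encode(seq)) == seq


class TestGenomePair:
    def test_fixed_seed_reproduces_identical_files(self, tmp_path):
        files = []
        for run in range(2):
            ga, gb, _ = simulate.simulate_genome_pair(GenomePairSpec(seed=7))
            fa, gf = tmp_path / f"a{run}.fna", tmp_path / f"a{run}.gff3"
            simulate.write_fasta(ga, fa)
            simulate.write_gff3(ga, gf)
            files.append((fa.read_bytes(), gf.read_bytes()))
        assert files[0] == files[1]

    def test_zero_divergence_gives_identical_orthologs(self):
        spec = GenomePairSpec(
            target_nt_identity=1.0, conserved_gene_count=0, seed=3,
            n_chromosomes=2, genes_per_chromosome=10, outlier_chromosome_index=1,
        )
        ga, gb, truth = simulate.simulate_genome_pair(spec)
        idents = [hamming_identity(ga, gb, r.gene_a, r.gene_b) for r in truth.itertuples()]
        assert idents == [100.0] * len(idents)

    def test_planted_identity_matches_target(self, desk_pair):
        """Mean ortholog identity lands within 2 points of the 78% target.

        Oracle: direct pairwise comparison of every planted ortholog pair
        (equivalent to global alignment since the divergence model is
        indel-free), spot-validated against Biopython's global aligner.
        """
        _, ga, gb, truth = desk_pair
        reg = truth[~truth.conserved]
        idents = [hamming_identity(ga, gb, r.gene_a, r.gene_b) for r in reg.itertuples()]
        assert abs(float(np.mean(idents)) - 78.0) <= 2.0
        from Bio import Align

        al = Align.PairwiseAligner()
        al.mode = "global"
        for r in list(reg.itertuples())[:3]:
            a, b = ga.gene(r.gene_a), gb.gene(r.gene_b)
            sa = ga.sequence(a.chrom_id)[a.start : a.end]
            sb = gb.sequence(b.chrom_id)[b.start : b.end]
            aln = al.align(sa, sb)[0]
            c = aln.counts()
            bio_ident = 100.0 * c.identities / (c.gaps + c.identities + c.mismatches)
            assert bio_ident >= hamming_identity(ga, gb, r.gene_a, r.gene_b) - 1e-9

    def test_conserved_genes_forced_above_99(self, desk_pair):
        _, ga, gb, truth = desk_pair
        cons = truth[truth.conserved]
        assert len(cons) == 6
        for r in cons.itertuples():
            assert hamming_identity(ga, gb, r.gene_a, r.gene_b) > 99.0

    def test_outlier_chromosome_lower_gc_and_shorter_genes(self, desk_pair):
        spec, ga, _, _ = desk_pair
        outlier = f"chr{spec.outlier_chromosome_index + 1:02d}"
        gc = {cid: dnautil.gc_content(seq) for cid, seq in ga.chromosomes}
        regular = [v for cid, v in gc.items() if cid != outlier]
        assert gc[outlier] < min(regular)
        mean_len = lambda cid: np.mean([g.length for g in ga.genes_on(cid)])
        assert mean_len(outlier) < 0.7 * np.mean(
            [mean_len(cid) for cid in gc if cid != outlier]
        )

    def test_gene_layout_is_valid(self, desk_pair):
        _, ga, gb, _ = desk_pair
        for g in (ga, gb):
            g.validate()
            lens = g.chromosome_lengths()
            prev_end = {}
            for gene in g.genes:
                assert 0 <= gene.start < gene.end <= lens[gene.chrom_id]
                assert gene.start >= prev_end.get(gene.chrom_id, 0)
                prev_end[gene.chrom_id] = gene.end

    def test_chromosome_too_short_raises(self):
        spec = GenomePairSpec(chromosome_length=5_000, genes_per_chromosome=30, seed=1)
        with pytest.raises(ValueError, match="too short"):
            simulate.simulate_genome_pair(spec)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GenomePairSpec(target_nt_identity=0.0)
        with pytest.raises(ValueError):
            GenomePairSpec(gc_outlier=0.5, gc_regular=0.48)
        with pytest.raises(ValueError):
            GenomePairSpec(conserved_gene_count=10_000)

    def test_gff3_roundtrip(self, tmp_path, desk_pair):
        _, ga, _, _ = desk_pair
        simulate.write_fasta(ga, tmp_path / "a.fna")
        simulate.write_gff3(ga, tmp_path / "a.gff3")
        loaded = simulate.load_genome("A", tmp_path / "a.fna", tmp_path / "a.gff3")
        assert loaded.chromosomes == ga.chromosomes
        assert loaded.genes == ga.genes


class TestPopulationVariants:
    @pytest.fixture()
    def planted(self, tiny_pair):
        _, ga, _, _ = tiny_pair
        return simulate.plant_cassettes(ga, [("chr01", 1, 2, 0.5)])

    @pytest.mark.parametrize("freq,expect", [(1.0, 1.0), (0.0, 0.0)])
    def test_degenerate_frequencies(self, planted, freq, expect):
        genome, model = planted
        model = simulate.PopulationModel(
            genome_id="A",
            cassettes=[dataclasses.replace(model.cassettes[0], carrier_frequency=freq)],
        )
        cells = simulate.apply_population_variants(genome, model, 500, seed=0)
        assert cells.mean() == expect

    def test_carrier_frequency_converges(self, planted):
        genome, model = planted
        cells = simulate.apply_population_variants(genome, model, 10_000, seed=1)
        assert abs(cells.mean() - 0.5) <= 0.02

    def test_non_contiguous_cassette_rejected(self, tiny_pair):
        _, ga, _, _ = tiny_pair
        ids = [g.gene_id for g in ga.genes_on("chr01")]
        bad = simulate.PopulationModel(
            genome_id="A",
            cassettes=[simulate.Cassette("chr01", (ids[0], ids[2]), 0.5)],
        )
        with pytest.raises(ValueError, match="contiguous"):
            simulate.apply_population_variants(ga, bad, 10, seed=0)

    def test_dispensable_truth_flags_set(self, planted):
        genome, model = planted
        flagged = {g.gene_id for g in genome.genes if g.dispensable_truth}
        assert flagged == set(model.cassettes[0].gene_ids)


class TestStationSeries:
    def test_fractions_sum_to_one(self):
        for s in simulate.simulate_station_series(12, seed=3):
            total = s.true_fraction_a + s.true_fraction_b + s.background_fraction
            assert abs(total - 1.0) < 1e-9

    def test_zero_coefficients_give_constant_share(self):
        p = NicheParams(beta0=0.3, beta_temp=0.0, beta_depth=0.0)
        samples = simulate.simulate_station_series(10, p, seed=2)
        shares = {
            round(s.true_fraction_b / (s.true_fraction_a + s.true_fraction_b), 12)
            for s in samples
        }
        assert len(shares) == 1

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_station_series(1, seed=0)

    def test_grouped_mode_plants_temperature_offset(self):
        """+3 degC planted between groups: recovered within +-1.5 degC."""
        samples = simulate.simulate_station_series(
            30, NicheParams(mode="grouped"), seed=5
        )
        df = simulate.samples_to_frame(samples)
        b_dom = df["true_fraction_b"] > df["true_fraction_a"]
        diff = df.loc[b_dom, "temperature"].mean() - df.loc[~b_dom, "temperature"].mean()
        assert abs(diff - 3.1) <= 1.5  # planted means 21.5 vs 18.4


class TestReads:
    @pytest.fixture()
    def genomes(self, tiny_pair):
        _, ga, gb, _ = tiny_pair
        return {"A": ga, "B": gb}

    def sample(self, fa, fb, total=5_000):
        base = simulate.simulate_station_series(2, seed=9)[0]
        return dataclasses.replace(
            base,
            true_fraction_a=fa,
            true_fraction_b=fb,
            background_fraction=1.0 - fa - fb,
            total_reads=total,
        )

    def test_error_free_reads_match_reference(self, genomes):
        reads, truth = simulate.simulate_reads(
            self.sample(0.6, 0.3), genomes, error_rate=0.0, seed=4
        )
        seqs = dict(zip(reads.names, reads.codes))
        for r in truth[truth.origin != "background"].head(50).itertuples():
            ref = dnautil.encode(
                genomes[r.origin].sequence(r.chrom_id)[r.pos : r.pos + 100]
            )
            got = seqs[r.read_id]
            expected = ref if r.strand == "+" else dnautil.revcomp_codes(ref)
            assert np.array_equal(got, expected)

    def test_zero_fraction_origin_yields_no_reads(self, genomes):
        _, truth = simulate.simulate_reads(self.sample(0.0, 0.5), genomes, seed=4)
        assert (truth.origin == "A").sum() == 0

    def test_origin_counts_conserve_total_and_follow_binomial(self, genomes):
        n = 100_000
        _, truth = simulate.simulate_reads(
            self.sample(0.02, 0.01, total=n), genomes, seed=8
        )
        assert len(truth) == n
        n_a = (truth.origin == "A").sum()
        sigma = np.sqrt(n * 0.02 * 0.98)
        assert abs(n_a - n * 0.02) <= 3 * sigma

    def test_non_carrier_cells_never_yield_cassette_reads(self, tiny_pair):
        _, ga, gb, _ = tiny_pair
        genome, model = simulate.plant_cassettes(ga, [("chr01", 1, 2, 0.0)])
        cells = simulate.apply_population_variants(genome, model, 50, seed=0)
        reads, truth = simulate.simulate_reads(
            self.sample(0.9, 0.0, total=20_000),
            {"A": genome, "B": gb},
            genotypes={"A": (model, cells)},
            seed=3,
        )
        chrom_genes = {g.gene_id: g for g in genome.genes_on("chr01")}
        span = (
            chrom_genes[model.cassettes[0].gene_ids[0]].start,
            chrom_genes[model.cassettes[0].gene_ids[-1]].end,
        )
        sub = truth[(truth.origin == "A") & (truth.chrom_id == "chr01")]
        overlap = (sub.pos < span[1]) & (sub.pos + 100 > span[0])
        assert overlap.sum() == 0

    def test_bad_error_rate_rejected(self, genomes):
        with pytest.raises(ValueError):
            simulate.simulate_reads(self.sample(0.5, 0.2), genomes, error_rate=0.5)

    def test_fastq_deterministic(self, genomes, tmp_path):
        out = []
        for run in range(2):
            reads, _ = simulate.simulate_reads(self.sample(0.3, 0.3), genomes, seed=6)
            p = tmp_path / f"r{run}.fastq"
            reads.write_fastq(p)
            out.append(p.read_bytes())
        assert out[0] == out[1]


class TestExpression:
    def test_degenerate_fractions(self, tiny_pair):
        _, ga, _, _ = tiny_pair
        sids = [f"S{i}" for i in range(5)]
        full, _ = simulate.simulate_expression(ga.genes, sids, active_fraction=1.0, seed=0)
        none, _ = simulate.simulate_expression(ga.genes, sids, active_fraction=0.0, seed=0)
        assert full.all().all() and not none.any().any()

    def test_expressed_counts_binomial(self, desk_pair):
        _, ga, _, _ = desk_pair
        sids = [f"S{i}" for i in range(10)]
        table, _ = simulate.simulate_expression(ga.genes, sids, active_fraction=0.6, seed=2)
        counts = table.sum(axis=1)
        sigma = np.sqrt(10 * 0.6 * 0.4)
        assert (np.abs(counts - 6.0) <= 3 * sigma).mean() >= 0.95

    def test_dispensable_activity_elevated(self, tiny_pair):
        _, ga, _, _ = tiny_pair
        genome, _ = simulate.plant_cassettes(ga, [("chr01", 0, 2, 0.5)])
        # average over many draws: planted means 0.73 vs 0.56
        acts = [
            simulate.simulate_expression(genome.genes, ["S1"], seed=s)[1]
            for s in range(40)
        ]
        act = pd.concat(acts, axis=1).mean(axis=1)
        disp = [g.gene_id for g in genome.genes if g.dispensable_truth]
        core = [g.gene_id for g in genome.genes if not g.dispensable_truth]
        assert act[disp].mean() > act[core].mean()


def test_barcode_counts_scale_with_summed_fraction():
    samples = simulate.simulate_station_series(30, seed=4)
    counts = simulate.simulate_barcode_counts(samples, seed=1, scale=0.05)
    totals = np.array([s.true_fraction_a + s.true_fraction_b for s in samples])
    assert np.corrcoef(counts.to_numpy(), totals)[0, 1] > 0.9
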