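"""Dispensable filter chain, cassette clustering, depletion and borders."""

import numpy as np
import pandas as pd
import pytest

from bathypan import pangenome
from bathypan.abundance import GeneSampleMatrix, ThresholdConfig
from bathypan.pangenome import CassetteCall
from bathypan.recruit import RecruitmentTrack
from bathypan.simulate import AnnotatedGenome, GeneModel


def _detection(gene_rows, samples):
    return pd.DataFrame(gene_rows, columns=samples).astype(bool)


SAMPLES = [f"S{i}" for i in range(1, 10)]  # 9 eligible samples


def _row(n_detected, n=9):
    return [True] * n_detected + [False] * (n - n_detected)


class TestCallDispensable:
    def _expr(self, index, n_expressed, n_samples=9):
        rows = [[True] * n_expressed + [False] * (n_samples - n_expressed)] * len(index)
        return pd.DataFrame(rows, index=index, columns=SAMPLES[:n_samples])

    def test_filter_chain_boundaries(self):
        det = _detection([_row(4), _row(9), _row(4)], SAMPLES)
        det.index = ["pass", "core", "low_expr"]
        expr = pd.concat(
            [
                self._expr(["pass"], 6),
                self._expr(["core"], 9),
                self._expr(["low_expr"], 5),
            ]
        )
        calls = pangenome.call_dispensable(det, expr, SAMPLES)
        # detected 4 / absent 5 / expressed 6: dispensable
        assert bool(calls.at["pass", "dispensable"])
        # detected everywhere: core
        assert not calls.at["core", "dispensable"]
        # expression signal in only 5 samples: filtered out
        assert not calls.at["low_expr", "dispensable"]
        assert calls.at["pass", "n_samples_detected"] == 4
        assert calls.at["pass", "n_samples_absent"] == 5

    def test_too_few_eligible_samples_raises(self):
        det = _detection([_row(4)], SAMPLES)
        expr = self._expr(det.index, 9)
        with pytest.raises(ValueError, match="eligible samples"):
            pangenome.call_dispensable(det, expr, SAMPLES[:8])

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(1)
        samples = [f"S{i}" for i in range(12)]
        det = pd.DataFrame(
            rng.random((60, 12)) < 0.5, index=[f"g{i}" for i in range(60)], columns=samples
        )
        expr = pd.DataFrame(True, index=det.index, columns=samples)
        base = pangenome.call_dispensable(det, expr, samples)["dispensable"]
        for kw in ({"min_detect_samples": 5}, {"min_absent_samples": 6}):
            cfg = ThresholdConfig(**kw)
            stricter = pangenome.call_dispensable(det, expr, samples, cfg)["dispensable"]
            assert not (stricter & ~base).any()

    def test_excluded_genes_dropped(self):
        det = _detection([_row(4), _row(4)], SAMPLES)
        det.index = ["keep", "conserved"]
        expr = self._expr(det.index, 9)
        calls = pangenome.call_dispensable(det, expr, SAMPLES, exclude={"conserved"})
        assert list(calls.index) == ["keep"]


def _chrom_genome(n_genes=12, gene_len=100, spacer=50):
    genes, pos = [], spacer
    for i in range(n_genes):
        genes.append(GeneModel(f"g{i}", "chr01", pos, pos + gene_len, "+"))
        pos += gene_len + spacer
    seq = "A" * pos
    return AnnotatedGenome("A", [("chr01", seq)], genes)


def _calls(disp_ids, genome):
    idx = [g.gene_id for g in genome.genes]
    return pd.DataFrame({"dispensable": [g in disp_ids for g in idx]}, index=idx)


class TestClusterCassettes:
    def test_contiguous_run_forms_one_cassette(self):
        genome = _chrom_genome()
        cassettes, singles = pangenome.cluster_cassettes(
            _calls({"g5", "g6", "g7"}, genome), genome
        )
        assert len(cassettes) == 1 and not singles
        assert cassettes[0].gene_ids == ["g5", "g6", "g7"]
        assert cassettes[0].start == genome.gene("g5").start
        assert cassettes[0].end == genome.gene("g7").end

    def test_isolated_genes_are_singletons(self):
        genome = _chrom_genome()
        cassettes, singles = pangenome.cluster_cassettes(
            _calls({"g5", "g9"}, genome), genome
        )
        assert not cassettes and set(singles) == {"g5", "g9"}

    def test_partition_of_dispensable_set(self):
        genome = _chrom_genome()
        disp = {"g0", "g1", "g4", "g6", "g7", "g8", "g11"}
        cassettes, singles = pangenome.cluster_cassettes(_calls(disp, genome), genome)
        members = [g for c in cassettes for g in c.gene_ids] + singles
        assert sorted(members) == sorted(disp)

    def test_absence_pattern(self):
        genome = _chrom_genome()
        det = pd.DataFrame(
            {
                "S1": {g.gene_id: True for g in genome.genes},
                "S2": {g.gene_id: g.gene_id not in {"g5", "g6"} for g in genome.genes},
                "S3": {g.gene_id: g.gene_id != "g5" for g in genome.genes},
            }
        )
        cassettes, _ = pangenome.cluster_cassettes(
            _calls({"g5", "g6"}, genome), genome, det, ["S1", "S2", "S3"]
        )
        # only S2 lacks every member gene
        assert cassettes[0].absent_samples == ["S2"]


def _depth_matrix(genome, depths_by_gene, sample="S1"):
    idx = [g.gene_id for g in genome.genes]
    depth = pd.DataFrame({sample: [depths_by_gene.get(g, 10.0) for g in idx]}, index=idx)
    return GeneSampleMatrix(
        genome_id="A",
        counts=(depth * 5).astype(int),
        covered_fraction=(depth > 0).astype(float),
        mean_depth=depth,
        specific_totals=pd.Series({sample: 1000}),
        gene_lengths=pd.Series(100, index=idx),
        genome_length=genome.total_length,
    )


class TestDepletionProfile:
    def test_states(self):
        genome = _chrom_genome()
        m = _depth_matrix(genome, {"g5": 0.0, "g6": 5.0, "g7": 10.0})
        disp = {"g5", "g6", "g7"}
        states = {
            g: pangenome.depletion_profile(m, genome, disp, g, "S1") for g in disp
        }
        assert states["g5"].state == "absent" and states["g5"].depletion_ratio == 0.0
        assert states["g6"].state == "partial"
        assert states["g6"].depletion_ratio == pytest.approx(0.5)
        assert states["g7"].state == "present"
        assert states["g7"].depletion_ratio == pytest.approx(1.0)

    def test_zero_baseline_undefined(self):
        genome = _chrom_genome()
        m = _depth_matrix(genome, {g.gene_id: 0.0 for g in genome.genes})
        prof = pangenome.depletion_profile(m, genome, {"g5"}, "g5", "S1")
        assert prof.state == "undefined" and np.isnan(prof.depletion_ratio)

    def test_scale_invariance(self):
        genome = _chrom_genome()
        m1 = _depth_matrix(genome, {"g5": 4.0})
        m10 = _depth_matrix(genome, {"g5": 40.0})
        m10.mean_depth = m1.mean_depth * 10
        r1 = pangenome.depletion_profile(m1, genome, {"g5"}, "g5", "S1")
        r10 = pangenome.depletion_profile(m10, genome, {"g5"}, "g5", "S1")
        assert r1.depletion_ratio == pytest.approx(r10.depletion_ratio)


def _track(depth, window=200):
    n = len(depth)
    return RecruitmentTrack(
        chrom_id="chr01",
        window=window,
        starts=np.arange(n) * window,
        depth=np.asarray(depth, dtype=float),
        identity_hist=np.zeros((n, 101), dtype=int),
    )


class TestBorderConsistency:
    def _cassette(self):
        return CassetteCall(
            chrom_id="chr01", gene_ids=["g5", "g6"], start=2000, end=3000,
            absent_samples=["S1", "S2"],
        )

    def test_identical_tracks_zero_deviation(self):
        depth = [20.0] * 10 + [0.0] * 5 + [20.0] * 10
        tracks = {s: {"chr01": _track(depth)} for s in ("S1", "S2")}
        est, dev = pangenome.border_consistency(tracks, self._cassette(), 200)
        assert dev == 0.0
        assert est.loc["S1", "left"] == 2000.0
        assert est.loc["S1", "right"] == 3000.0

    def test_single_absent_sample_rejected(self):
        tracks = {"S1": {"chr01": _track([1.0] * 25)}}
        cass = self._cassette()
        cass.absent_samples = ["S1"]
        with pytest.raises(ValueError, match=">= 2"):
            pangenome.border_consistency(tracks, cass, 200)

    def test_no_flanking_coverage_undefined(self):
        flat = [0.0] * 25
        good = [20.0] * 10 + [0.0] * 5 + [20.0] * 10
        tracks = {"S1": {"chr01": _track(flat)}, "S2": {"chr01": _track(good)}}
        est, _ = pangenome.border_consistency(tracks, self._cassette(), 200)
        assert np.isnan(est.loc["S1", "left"])
        assert est.loc["S2", "left"] == 2000.0


class TestExpressionContrast:
    def _calls(self, disp, core):
        idx = disp + core
        return pd.DataFrame(
            {"dispensable": [g in set(disp) for g in idx]}, index=idx
        )

    def test_identical_groups_p_one(self):
        calls = self._calls(["d1", "d2"], ["c1", "c2"])
        act = pd.Series({"d1": 0.5, "d2": 0.7, "c1": 0.5, "c2": 0.7})
        m_d, m_c, p = pangenome.dispensable_expression_contrast(act, calls)
        assert m_d == m_c and p == 1.0

    def test_complete_separation_exact_p(self):
        """4 vs 4, dispensable strictly greater: exact p = 2/70."""
        disp = [f"d{i}" for i in range(4)]
        core = [f"c{i}" for i in range(4)]
        act = pd.Series(
            {**{g: 0.8 + i * 0.01 for i, g in enumerate(disp)},
             **{g: 0.3 + i * 0.01 for i, g in enumerate(core)}}
        )
        _, _, p = pangenome.dispensable_expression_contrast(act, self._calls(disp, core))
        assert p == pytest.approx(2 / 70)

    def test_empty_group_rejected(self):
        calls = self._calls([], ["c1", "c2"])
        act = pd.Series({"c1": 0.5, "c2": 0.7})
        with pytest.raises(ValueError):
            pangenome.dispensable_expression_contrast(act, calls)
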