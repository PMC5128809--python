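"""End-to-end study drivers with known ground truth.

Each function runs one self-contained experiment of the survey pipeline —
simulate, recruit, quantify, score against the planted truth — and returns
both the intermediate tables and a flat ``metrics`` dict.  The numbered
scripts under ``analysis/``, the test suite and ``scripts/acceptance.py``
all call these drivers, so every reported number is recomputed from scratch.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from . import abundance, niche, orthology, pangenome, recruit, simulate
from .abundance import ThresholdConfig
from .simulate import GenomePairSpec, NicheParams


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent sub-seeds (< 2**31) from one master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31, size=n)]


@dataclass
class StudyResult:
    """Tables plus a flat name -> number metrics dict for one experiment."""

    metrics: dict[str, float]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# mixture recovery / specificity / barcode concordance
# ---------------------------------------------------------------------------


def run_mixture_study(
    seed: int,
    n_samples: int = 30,
    reads_per_sample: int = 100_000,
    read_length: int = 100,
    error_rate: float = 0.01,
    seed_stride: int = 4,
) -> StudyResult:
    """Recover per-sample genome mixtures from competitive recruitment.

    Simulates the desk-scale genome pair, a station series whose mixture
    fractions follow the logistic temperature/depth link, and one shotgun
    read set per sample; maps every read competitively, masks conserved
    genes found by the orthology stage, and compares estimated relative
    abundances with the realized per-read origin composition of each read
    set.  Also scores conserved-read ambiguity and the metabarcode
    concordance.
    """
    s_pair, s_station, s_barcode, *s_reads = _child_seeds(seed, 3 + n_samples)
    spec = GenomePairSpec(seed=s_pair)
    genome_a, genome_b, truth = simulate.simulate_genome_pair(spec)

    pairs = orthology.find_orthologs(genome_a, genome_b)
    conserved = orthology.conserved_genes(pairs)
    planted_conserved = set(truth.loc[truth["conserved"], "gene_a"]) | set(
        truth.loc[truth["conserved"], "gene_b"]
    )
    merged = truth.merge(pairs, on="gene_a", how="inner", suffixes=("", "_called"))
    pairing_accuracy = float((merged["gene_b"] == merged["gene_b_called"]).mean())
    mean_identity = float(pairs["identity"].mean())

    samples = simulate.simulate_station_series(
        n_samples, NicheParams(total_reads=reads_per_sample), seed=s_station
    )
    index_a = recruit.build_index(genome_a)
    index_b = recruit.build_index(genome_b)
    params = recruit.MappingParams(seed_stride=seed_stride)
    genomes = {"A": genome_a, "B": genome_b}

    cons_intervals = {
        gid: [
            (g.chrom_id, g.start, g.end)
            for g in genomes[gid].genes
            if g.gene_id in planted_conserved
        ]
        for gid in genomes
    }

    all_maps = []
    realized_rows = []
    cons_total = 0
    cons_ambiguous = 0
    for sp, rs in zip(samples, s_reads):
        reads, rtruth = simulate.simulate_reads(
            sp, genomes, read_length=read_length, error_rate=error_rate, seed=rs
        )
        maps = recruit.map_reads(reads, index_a, index_b, params)
        maps["sample_id"] = sp.sample_id
        all_maps.append(maps)
        for gid in ("A", "B"):
            realized_rows.append(
                {
                    "sample_id": sp.sample_id,
                    "genome_id": gid,
                    "realized_fraction": (rtruth["origin"] == gid).mean(),
                    "latent_fraction": sp.true_fraction_a
                    if gid == "A"
                    else sp.true_fraction_b,
                }
            )
        # reads whose origin lies fully inside a planted conserved gene
        spec_ids = set(maps.loc[maps["specific"], "read_id"])
        for gid in ("A", "B"):
            sub = rtruth[rtruth["origin"] == gid]
            for chrom, gs, ge in cons_intervals[gid]:
                inside = sub[
                    (sub["chrom_id"] == chrom)
                    & (sub["pos"] >= gs)
                    & (sub["pos"] + read_length <= ge)
                ]
                cons_total += len(inside)
                cons_ambiguous += (~inside["read_id"].isin(spec_ids)).sum()

    mappings = pd.concat(all_maps, ignore_index=True)
    sample_ids = [sp.sample_id for sp in samples]
    matrices = {
        gid: abundance.gene_read_counts(mappings, genomes[gid], sample_ids)
        for gid in genomes
    }
    totals = pd.Series(reads_per_sample, index=sample_ids, dtype=float)
    cfg = ThresholdConfig()
    abund = abundance.relative_abundance(matrices, totals, conserved, cfg)

    table = pd.DataFrame(realized_rows)
    table["estimated_fraction"] = [
        abund.at[r.sample_id, f"abund_{r.genome_id}"] / 100.0
        for r in table.itertuples()
    ]
    table["rel_error"] = (
        table["estimated_fraction"] - table["realized_fraction"]
    ).abs() / table["realized_fraction"].where(table["realized_fraction"] > 0)

    big = table[table["realized_fraction"] >= 0.001]
    r = float(
        np.corrcoef(table["realized_fraction"], table["estimated_fraction"])[0, 1]
    )
    r_latent = float(
        np.corrcoef(table["latent_fraction"], table["estimated_fraction"])[0, 1]
    )

    barcode = simulate.simulate_barcode_counts(samples, seed=s_barcode, scale=0.05)
    abund_sum = abund["abund_A"] + abund["abund_B"]
    rho, pearson_bc, n_bc = niche.barcode_correlation(barcode, abund_sum)

    metrics = {
        "mixture_pearson_r": r,
        "mixture_pearson_r_latent": r_latent,
        "mixture_max_rel_error": float(big["rel_error"].max()),
        "mixture_n_scored": int(len(big)),
        "conserved_read_ambiguous_fraction": cons_ambiguous / max(cons_total, 1),
        "conserved_reads_total": cons_total,
        "conserved_set_exact": float(conserved == planted_conserved),
        "ortholog_mean_identity": mean_identity,
        "ortholog_pairing_accuracy": pairing_accuracy,
        "barcode_spearman_rho": float(rho),
        "barcode_pearson_r": float(pearson_bc),
        "barcode_n": n_bc,
    }
    return StudyResult(
        metrics=metrics,
        tables={"recovery": table, "abundance": abund.reset_index(names="sample_id")},
    )


# ---------------------------------------------------------------------------
# dominance rule table
# ---------------------------------------------------------------------------


def dominance_reference_cases() -> pd.DataFrame:
    """Hand-built boundary cases for the dominance rules (expected by hand).

    Covers the 0.01% combined floor (strictly-above required), the strict
    >70% dominance share, the inclusive 40-60% co-occurrence window, and the
    'mixed' gap between them.
    """
    cases = [
        (0.50, 0.10, "A_dominant"),  # share 0.833
        (0.10, 0.50, "B_dominant"),
        (0.020, 0.018, "co_occurring"),  # shares 0.526/0.474
        (0.004, 0.002, "below_floor"),  # sum 0.006 <= 0.01
        (0.006, 0.004, "below_floor"),  # sum exactly at the floor
        (0.0075, 0.0035, "mixed"),  # above floor, share 0.682
        (7.0, 3.0, "mixed"),  # share exactly 0.70: not dominant (strict >)
        (0.355, 0.145, "A_dominant"),  # share 0.71
        (0.060, 0.040, "co_occurring"),  # shares exactly 0.60/0.40
        (0.061, 0.039, "mixed"),  # just outside the window
        (0.20, 0.0, "A_dominant"),  # single-genome sample, share 1
        (0.0, 0.0, "below_floor"),  # empty sample
    ]
    return pd.DataFrame(cases, columns=["abund_a", "abund_b", "expected"])


def run_dominance_check() -> StudyResult:
    cases = dominance_reference_cases()
    cfg = ThresholdConfig()
    cases["called"] = [
        abundance.classify_dominance(r.abund_a, r.abund_b, cfg) for r in cases.itertuples()
    ]
    agree = float((cases["called"] == cases["expected"]).mean())
    return StudyResult(
        metrics={"dominance_rule_agreement": agree, "dominance_n_cases": len(cases)},
        tables={"cases": cases},
    )


# ---------------------------------------------------------------------------
# pan-genome: dispensable genes and cassettes
# ---------------------------------------------------------------------------


def pangenome_pair_spec(seed: int) -> GenomePairSpec:
    """Genome configuration for the pan-genome study.

    Dispensable genes must be a small fraction of the genome for the 98%
    completeness gate to behave as in the real survey (~100 of ~7900 genes),
    so this study uses 4 x 160 genes of ~380 bp: a sample missing all 12
    planted dispensable genes still detects 622/634 = 98.1% of the
    non-conserved genes and stays eligible.
    """
    return GenomePairSpec(
        chromosome_length=80_000,
        genes_per_chromosome=160,
        gene_length=380,
        gene_length_jitter=0.15,
        seed=seed,
    )


def _place_cassettes(
    genome: simulate.AnnotatedGenome,
    conserved: set[str],
    sizes_and_chroms: list[tuple[str, int, int]],
) -> list[tuple[str, int, int, float]]:
    """Pick cassette start ranks avoiding conserved genes (deterministic)."""
    plan = []
    for chrom_id, start_rank, n_genes in sizes_and_chroms:
        chrom_genes = genome.genes_on(chrom_id)
        rank = start_rank
        while any(
            g.gene_id in conserved for g in chrom_genes[rank : rank + n_genes]
        ):
            rank += 1
            if rank + n_genes > len(chrom_genes):
                raise ValueError(f"no conserved-free slot on {chrom_id}")
        plan.append((chrom_id, rank, n_genes, 1.0))
    return plan


def run_pangenome_study(
    seed: int,
    n_samples: int = 14,
    coverage: float = 12.0,
    read_length: int = 100,
    error_rate: float = 0.01,
    min_present: int = 5,
    max_present: int = 8,
) -> StudyResult:
    """Plant three cassettes (7+3+2 genes), recover them through the full
    detection -> completeness -> dispensable -> cassette chain.

    Each cassette is present (carried by the whole population) in a random
    5-8 of the 14 samples and absent from the rest, so every planted gene
    satisfies the >=4 detected / >=5 absent filters by construction; the
    expression signal fires at 0.95 per gene-sample, putting every gene far
    above the >=6 expressed filter.
    """
    s_pair, s_station, s_expr, s_pattern, *s_reads = _child_seeds(seed, 4 + n_samples)
    spec = pangenome_pair_spec(s_pair)
    genome_a, genome_b, _truth = simulate.simulate_genome_pair(spec)

    pairs = orthology.find_orthologs(genome_a, genome_b)
    conserved = orthology.conserved_genes(pairs)

    plan_sites = [("chr01", 30, 7), ("chr02", 80, 3), ("chr03", 120, 2)]
    plan = _place_cassettes(genome_a, conserved, plan_sites)
    genome_a, model = simulate.plant_cassettes(genome_a, plan)
    planted = {gid for c in model.cassettes for gid in c.gene_ids}

    rng = np.random.default_rng(s_pattern)
    presence = np.zeros((n_samples, len(model.cassettes)), dtype=bool)
    for j in range(len(model.cassettes)):
        k = int(rng.integers(min_present, max_present + 1))
        presence[rng.choice(n_samples, size=k, replace=False), j] = True

    frac_a = 0.85
    total_reads = int(round(coverage * genome_a.total_length / read_length / frac_a))
    base_samples = simulate.simulate_station_series(
        n_samples, NicheParams(total_reads=total_reads), seed=s_station
    )
    samples = [
        dataclasses.replace(
            sp,
            true_fraction_a=frac_a,
            true_fraction_b=0.0,
            background_fraction=1.0 - frac_a,
        )
        for sp in base_samples
    ]
    sample_ids = [sp.sample_id for sp in samples]

    index_a = recruit.build_index(genome_a)
    index_b = recruit.build_index(genome_b)
    params = recruit.MappingParams(seed_stride=4)
    genomes = {"A": genome_a, "B": genome_b}

    all_maps = []
    for i, (sp, rs) in enumerate(zip(samples, s_reads)):
        sample_model = simulate.PopulationModel(
            genome_id="A",
            cassettes=[
                dataclasses.replace(c, carrier_frequency=1.0 if presence[i, j] else 0.0)
                for j, c in enumerate(model.cassettes)
            ],
        )
        cells = simulate.apply_population_variants(genome_a, sample_model, 1, seed=rs)
        reads, _ = simulate.simulate_reads(
            sp,
            genomes,
            genotypes={"A": (sample_model, cells)},
            read_length=read_length,
            error_rate=error_rate,
            seed=rs,
        )
        maps = recruit.map_reads(reads, index_a, index_b, params)
        maps["sample_id"] = sp.sample_id
        all_maps.append(maps)
    mappings = pd.concat(all_maps, ignore_index=True)

    matrix = abundance.gene_read_counts(mappings, genome_a, sample_ids)
    cfg = ThresholdConfig()
    detection = abundance.detect_genes(matrix, cfg)
    completeness = abundance.sample_completeness(detection, conserved, cfg)
    eligible = list(completeness.index[completeness["eligible"]])

    expressed, activity = simulate.simulate_expression(
        genome_a.genes, sample_ids, active_fraction=0.95, seed=s_expr
    )
    calls = pangenome.call_dispensable(detection, expressed, eligible, cfg, exclude=conserved)
    called = set(calls.index[calls["dispensable"]])
    tp = len(called & planted)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(planted)

    cassettes, singletons = pangenome.cluster_cassettes(calls, genome_a, detection, eligible)
    called_sets = {frozenset(c.gene_ids) for c in cassettes}
    planted_sets = {frozenset(c.gene_ids) for c in model.cassettes}
    mean_disp, mean_core, p_expr = pangenome.dispensable_expression_contrast(activity, calls)

    metrics = {
        "eligible_samples": len(eligible),
        "dispensable_precision": precision,
        "dispensable_recall": recall,
        "dispensable_called": len(called),
        "cassette_count": len(cassettes),
        "cassette_membership_exact": float(called_sets == planted_sets),
        "cassette_singletons": len(singletons),
        "expression_mean_dispensable": mean_disp,
        "expression_mean_core": mean_core,
        "expression_contrast_p": p_expr,
    }
    tables = {
        "calls": calls.reset_index(names="gene_id"),
        "completeness": completeness.reset_index(names="sample_id"),
    }
    return StudyResult(metrics=metrics, tables=tables)


# ---------------------------------------------------------------------------
# sub-population depletion
# ---------------------------------------------------------------------------


def run_depletion_study(
    seed: int,
    n_reps: int = 50,
    coverage: float = 20.0,
    carrier_frequency: float = 0.5,
    n_cells: int = 400,
    read_length: int = 100,
) -> StudyResult:
    """Cassette carried by half the population: depletion ratio and state.

    Each replicate simulates one sample at ~20x baseline coverage of a small
    genome with one 3-gene cassette at carrier frequency 0.5, runs the full
    mapping and per-gene depth chain, and records the cassette's mean
    depletion ratio and per-gene states.  A replicate 'passes' when the mean
    ratio lies in carrier_frequency +/- 0.15 and all member genes are called
    'partial'.
    """
    s_pair, s_station, *s_reps = _child_seeds(seed, 2 + n_reps)
    spec = GenomePairSpec(
        n_chromosomes=2,
        outlier_chromosome_index=1,
        conserved_gene_count=0,
        seed=s_pair,
    )
    genome_a, genome_b, _ = simulate.simulate_genome_pair(spec)
    genome_a, model = simulate.plant_cassettes(
        genome_a, [("chr01", 10, 3, carrier_frequency)]
    )
    planted = {gid for c in model.cassettes for gid in c.gene_ids}

    frac_a = 0.9
    total_reads = int(round(coverage * genome_a.total_length / read_length / frac_a))
    (base_sample,) = simulate.simulate_station_series(
        2, NicheParams(total_reads=total_reads), seed=s_station
    )[:1]
    sample = dataclasses.replace(
        base_sample,
        true_fraction_a=frac_a,
        true_fraction_b=0.0,
        background_fraction=1.0 - frac_a,
    )

    index_a = recruit.build_index(genome_a)
    index_b = recruit.build_index(genome_b)
    params = recruit.MappingParams(seed_stride=4)
    genomes = {"A": genome_a, "B": genome_b}
    cfg = ThresholdConfig()

    rows = []
    for rep, rs in enumerate(s_reps):
        cells = simulate.apply_population_variants(genome_a, model, n_cells, seed=rs)
        reads, _ = simulate.simulate_reads(
            sample,
            genomes,
            genotypes={"A": (model, cells)},
            read_length=read_length,
            error_rate=0.01,
            seed=rs,
        )
        maps = recruit.map_reads(reads, index_a, index_b, params)
        maps["sample_id"] = sample.sample_id
        matrix = abundance.gene_read_counts(maps, genome_a, [sample.sample_id])
        profs = [
            pangenome.depletion_profile(matrix, genome_a, planted, g, sample.sample_id, cfg)
            for g in sorted(planted)
        ]
        mean_ratio = float(np.mean([p.depletion_ratio for p in profs]))
        all_partial = all(p.state == "partial" for p in profs)
        rows.append(
            {
                "rep": rep,
                "mean_ratio": mean_ratio,
                "all_partial": all_partial,
                "pass": abs(mean_ratio - carrier_frequency) <= 0.15 and all_partial,
            }
        )
    table = pd.DataFrame(rows)
    metrics = {
        "depletion_ratio_mean": float(table["mean_ratio"].mean()),
        "depletion_pass_rate": float(table["pass"].mean()),
        "depletion_partial_rate": float(table["all_partial"].mean()),
        "depletion_n_reps": n_reps,
    }
    return StudyResult(metrics=metrics, tables={"replicates": table})


# ---------------------------------------------------------------------------
# cassette border consistency
# ---------------------------------------------------------------------------


def run_border_study(
    seed: int,
    n_absent: int = 6,
    n_present: int = 2,
    coverage: float = 20.0,
    window: int = 200,
    read_length: int = 100,
) -> StudyResult:
    """Recover planted cassette borders from windowed depth tracks.

    Simulates samples where the cassette is completely absent (plus a few
    carrier samples as contrast), builds per-sample recruitment profiles and
    estimates both borders per absent sample; reports the worst offset from
    the annotated edges and the maximum pairwise deviation between samples.
    """
    n_samples = n_absent + n_present
    s_pair, s_station, *s_reads = _child_seeds(seed, 2 + n_samples)
    spec = GenomePairSpec(
        n_chromosomes=2,
        outlier_chromosome_index=1,
        conserved_gene_count=0,
        seed=s_pair,
    )
    genome_a, genome_b, _ = simulate.simulate_genome_pair(spec)
    genome_a, model = simulate.plant_cassettes(genome_a, [("chr01", 12, 3, 0.0)])
    cass = model.cassettes[0]
    chrom_genes = {g.gene_id: g for g in genome_a.genes_on(cass.chrom_id)}
    true_left = chrom_genes[cass.gene_ids[0]].start
    true_right = chrom_genes[cass.gene_ids[-1]].end

    frac_a = 0.9
    total_reads = int(round(coverage * genome_a.total_length / read_length / frac_a))
    base = simulate.simulate_station_series(
        n_samples, NicheParams(total_reads=total_reads), seed=s_station
    )
    samples = [
        dataclasses.replace(
            sp, true_fraction_a=frac_a, true_fraction_b=0.0, background_fraction=1.0 - frac_a
        )
        for sp in base
    ]
    absent_ids = [sp.sample_id for sp in samples[:n_absent]]

    index_a = recruit.build_index(genome_a)
    index_b = recruit.build_index(genome_b)
    params = recruit.MappingParams(seed_stride=4)
    genomes = {"A": genome_a, "B": genome_b}

    tracks = {}
    for i, (sp, rs) in enumerate(zip(samples, s_reads)):
        freq = 0.0 if i < n_absent else 1.0
        sample_model = simulate.PopulationModel(
            genome_id="A",
            cassettes=[dataclasses.replace(cass, carrier_frequency=freq)],
        )
        cells = simulate.apply_population_variants(genome_a, sample_model, 1, seed=rs)
        reads, _ = simulate.simulate_reads(
            sp,
            genomes,
            genotypes={"A": (sample_model, cells)},
            read_length=read_length,
            error_rate=0.01,
            seed=rs,
        )
        maps = recruit.map_reads(reads, index_a, index_b, params)
        maps_a = maps[maps["genome_id"] == "A"]
        tracks[sp.sample_id] = recruit.recruitment_profile(maps_a, genome_a, window)

    call = pangenome.CassetteCall(
        chrom_id=cass.chrom_id,
        gene_ids=list(cass.gene_ids),
        start=true_left,
        end=true_right,
        absent_samples=absent_ids,
    )
    est, deviation = pangenome.border_consistency(tracks, call, window)
    max_offset = float(
        np.nanmax(
            np.abs(
                est[["left", "right"]].to_numpy()
                - np.array([true_left, true_right])[None, :]
            )
        )
    )
    metrics = {
        "border_max_offset_bp": max_offset,
        "border_max_pairwise_deviation_bp": float(deviation),
        "border_window_bp": window,
        "border_n_absent_samples": n_absent,
        "border_true_left": true_left,
        "border_true_right": true_right,
    }
    return StudyResult(metrics=metrics, tables={"breakpoints": est.reset_index(names="sample_id")})


# ---------------------------------------------------------------------------
# MWW calibration
# ---------------------------------------------------------------------------


def mww_bruteforce_p(a, b) -> float:
    """Two-sided MWW p by exhaustive enumeration of all labelings.

    Independent check route for the DP implementation: walks every
    C(n+m, n) assignment of the pooled values to group A (tie-free inputs
    only).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if len(np.unique(pooled)) < len(pooled):
        raise ValueError("brute-force oracle requires tie-free input")
    n = len(a)

    def u_of(idx: tuple[int, ...]) -> int:
        va = pooled[list(idx)]
        vb = np.delete(pooled, list(idx))
        return int((va[:, None] > vb[None, :]).sum())

    u_obs = u_of(tuple(range(n)))
    us = np.array([u_of(c) for c in combinations(range(len(pooled)), n)])
    total = comb(len(pooled), n)
    lower = (us <= u_obs).sum() / total
    upper = (us >= u_obs).sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def run_mww_calibration(
    seed: int, n_oracle: int = 200, n_null: int = 1000, null_n: int = 8
) -> StudyResult:
    """Exactness against enumeration + type-I error of the exact MWW test."""
    rng = np.random.default_rng(seed)
    agree = 0
    max_dp = 0.0
    for _ in range(n_oracle):
        na = int(rng.integers(2, 6))
        nb = int(rng.integers(2, min(6, 10 - na) + 1))
        vals = rng.normal(size=na + nb)
        while len(np.unique(vals)) < na + nb:  # pragma: no cover
            vals = rng.normal(size=na + nb)
        a, b = vals[:na], vals[na:]
        _, p = niche.mww_test(a, b)
        p_ref = mww_bruteforce_p(a, b)
        max_dp = max(max_dp, abs(p - p_ref))
        agree += int(np.isclose(p, p_ref, rtol=0, atol=1e-12))

    rejections = 0
    for _ in range(n_null):
        a = rng.normal(size=null_n)
        b = rng.normal(size=null_n)
        _, p = niche.mww_test(a, b)
        rejections += int(p < 0.05)

    metrics = {
        "mww_oracle_agreement": agree / n_oracle,
        "mww_oracle_max_abs_dp": max_dp,
        "mww_type1_rate": rejections / n_null,
        "mww_n_oracle": n_oracle,
        "mww_n_null": n_null,
    }
    return StudyResult(metrics=metrics)


# ---------------------------------------------------------------------------
# niche recovery
# ---------------------------------------------------------------------------


def run_niche_study(
    seed: int,
    n_reps: int = 100,
    n_samples: int = 30,
    alpha: float = 0.05,
) -> StudyResult:
    """Planted 3 degC offset between genome-dominant groups: power and recovery.

    Each replicate simulates a grouped station series (15 samples dominated
    by each genome, temperature means 18.4 vs 21.5 degC, sd 2), classifies
    dominance from the true relative abundances and runs the temperature MWW
    test between the dominant groups.
    """
    seeds = _child_seeds(seed, n_reps)
    params = NicheParams(mode="grouped")
    cfg = ThresholdConfig()
    rows = []
    for rs in seeds:
        samples = simulate.simulate_station_series(n_samples, params, seed=rs)
        prof = simulate.samples_to_frame(samples)
        abund = pd.DataFrame(
            {
                "abund_A": 100 * prof["true_fraction_a"],
                "abund_B": 100 * prof["true_fraction_b"],
            }
        )
        abund["class"] = [
            abundance.classify_dominance(r.abund_A, r.abund_B, cfg)
            for r in abund.itertuples()
        ]
        summary = niche.niche_summary(abund, prof, parameters=["temperature"])
        t = summary.loc["temperature"]
        rows.append(
            {
                "p": t["p"],
                "diff": t["mean_b"] - t["mean_a"],
                "n_a": t["n_a"],
                "n_b": t["n_b"],
            }
        )
    table = pd.DataFrame(rows)
    metrics = {
        "niche_power": float((table["p"] < alpha).mean()),
        "niche_mean_temp_diff": float(table["diff"].mean()),
        "niche_n_reps": n_reps,
    }
    return StudyResult(metrics=metrics, tables={"replicates": table})


# ---------------------------------------------------------------------------
# synteny summary recovery
# ---------------------------------------------------------------------------


def run_synteny_study(seed: int) -> StudyResult:
    """5% translocated + 5% genome-specific genes: summary fraction recovery."""
    spec = GenomePairSpec(
        translocation_fraction=0.05, specific_gene_fraction=0.05, seed=seed
    )
    genome_a, genome_b, truth = simulate.simulate_genome_pair(spec)
    pairs = orthology.find_orthologs(genome_a, genome_b)
    blocks, summary = orthology.synteny_blocks(pairs, genome_a, genome_b)
    metrics = {
        "synteny_collinear_a": float(summary.loc["A", "collinear"]),
        "synteny_specific_a": float(summary.loc["A", "genome_specific"]),
        "synteny_outside_a": float(summary.loc["A", "shared_outside_blocks"]),
        "synteny_n_blocks": len(blocks),
        "synteny_planted_translocated": float(truth["translocated"].mean()),
    }
    return StudyResult(metrics=metrics, tables={"summary": summary.reset_index(names="genome")})


# ---------------------------------------------------------------------------
# mapper oracle equivalence
# ---------------------------------------------------------------------------


def bruteforce_best_identity(
    read_codes: np.ndarray, genome_codes: list[np.ndarray]
) -> float:
    """Best gapless identity of a read over every end-to-end placement on
    every chromosome of both genomes, both strands.  Returns -1 when no
    placement exists (read longer than every chromosome)."""
    from . import dnautil

    L = len(read_codes)
    best = -1.0
    for arr in (read_codes, dnautil.revcomp_codes(read_codes)):
        for chrom in genome_codes:
            if len(chrom) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(chrom, L)
            matches = (windows == arr).sum(axis=1)
            best = max(best, 100.0 * matches.max() / L)
    return best


def run_mapper_oracle_study(
    seed: int, n_reads: int = 500, read_length: int = 60, error_rate: float = 0.02
) -> StudyResult:
    """map_read vs exhaustive all-position alignment on tiny genomes.

    Draws reads (with substitution errors) from a 5 kb genome pair, maps each
    with the exact stride-1 single-read path, and compares the mapped
    identity with the brute-force maximum over every placement on both
    genomes; unmapped agrees when the brute-force maximum is below the
    mapper's identity floor.
    """
    s_pair, s_draw = _child_seeds(seed, 2)
    spec = GenomePairSpec(
        n_chromosomes=1,
        chromosome_length=5_000,
        genes_per_chromosome=4,
        gene_length=600,
        outlier_chromosome_index=0,
        gc_outlier=0.44,
        gc_regular=0.48,
        conserved_gene_count=0,
        seed=s_pair,
    )
    genome_a, genome_b, _ = simulate.simulate_genome_pair(spec)
    index_a = recruit.build_index(genome_a)
    index_b = recruit.build_index(genome_b)
    params = recruit.MappingParams(seed_stride=1)
    from . import dnautil

    chroms = [dnautil.encode(seq) for g in (genome_a, genome_b) for _, seq in g.chromosomes]
    per_genome = [dnautil.encode(genome_a.chromosomes[0][1]), dnautil.encode(genome_b.chromosomes[0][1])]

    rng = np.random.default_rng(s_draw)
    agree = 0
    for i in range(n_reads):
        src = per_genome[i % 2]
        pos = int(rng.integers(0, len(src) - read_length + 1))
        codes = src[pos : pos + read_length].copy()
        if rng.random() < 0.5:
            codes = dnautil.revcomp_codes(codes)
        codes = dnautil.mutate_codes(rng, codes, error_rate)
        read = dnautil.decode(codes)
        rec = recruit.map_read(read, index_a, index_b, params)
        best = bruteforce_best_identity(codes, chroms)
        if rec is None:
            agree += int(best < params.min_identity)
        else:
            agree += int(np.isclose(rec.identity, best, rtol=0, atol=1e-9))
    metrics = {
        "mapper_oracle_agreement": agree / n_reads,
        "mapper_oracle_n_reads": n_reads,
    }
    return StudyResult(metrics=metrics)
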