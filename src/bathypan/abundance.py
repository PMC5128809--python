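"""Gene x sample matrices, relative genomic abundance and dominance classes.

The relative genomic abundance of a genome in a sample is the percentage of
the sample's total reads that map *specifically* to that genome, after
discarding reads in genes conserved between the two genomes (those reads
cannot be attributed).  Because masking removes a known fraction of the
genome, the numerator is rescaled by genome_length / (genome_length -
conserved span) by default so the estimator stays unbiased.

Dominance classes per sample follow the survey's printed rules: below the
0.01% combined-abundance floor the sample is uninformative; a genome taking
more than 70% of the two genomes' summed specific reads is dominant; shares
between 40% and 60% are co-occurrence; everything else is 'mixed' (a class
added because the printed rules are not exhaustive).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import AnnotatedGenome


@dataclass(frozen=True)
class ThresholdConfig:
    """Every tunable threshold of the abundance / pan-genome chain.

    Percent-scale: ``abundance_floor`` (combined relative abundance, percent
    of total reads).  Fractions: dominance and co-occurrence are shares of
    the two genomes' summed specific reads; ``completeness_min`` is the
    fraction of (non-conserved) genes detected that makes a sample eligible
    for pan-genome analysis.  Detection: a gene is detected in a sample at
    >= ``detect_min_reads`` specific reads covering >=
    ``detect_min_covered_fraction`` of its length — at 5x coverage a present
    gene is detected with probability ~1 while an absent gene needs two
    independent false mappings.
    """

    abundance_floor: float = 0.01
    dominance_share: float = 0.70
    co_low: float = 0.40
    co_high: float = 0.60
    completeness_min: float = 0.98
    min_detect_samples: int = 4
    min_absent_samples: int = 5
    min_expressed_samples: int = 6
    detect_min_reads: int = 2
    detect_min_covered_fraction: float = 0.2
    include_intergenic: bool = True
    mask_correction: bool = True
    depletion_absent_max: float = 0.1
    depletion_present_min: float = 0.8
    min_baseline_genes: int = 3

    def __post_init__(self):
        for name in (
            "dominance_share", "co_low", "co_high", "completeness_min",
            "detect_min_covered_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GeneSampleMatrix:
    """Per-gene, per-sample recruitment summaries for one genome.

    Row order equals genome gene order (required downstream by cassette
    clustering).  ``specific_totals`` counts all specific reads of the genome
    per sample, genic and intergenic.
    """

    genome_id: str
    counts: pd.DataFrame
    covered_fraction: pd.DataFrame
    mean_depth: pd.DataFrame
    specific_totals: pd.Series
    gene_lengths: pd.Series
    genome_length: int


def _union_and_overlap(starts: np.ndarray, ends: np.ndarray) -> tuple[int, int]:
    """(union length, summed overlap) of intervals sorted by start."""
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    cme = np.maximum.accumulate(e)
    prev = np.concatenate([[s[0]], cme[:-1]])
    union = int(np.maximum(0, e - np.maximum(s, prev)).sum())
    return union, int((e - s).sum())


def gene_read_counts(
    mappings: pd.DataFrame,
    genome: AnnotatedGenome,
    sample_ids: list[str],
) -> GeneSampleMatrix:
    """Aggregate specific mappings into the gene x sample matrix.

    ``mappings`` needs a ``sample_id`` column on top of the mapper output.
    A read belongs to the gene containing its start (half-open test);
    intergenic reads count toward the genome total but no gene.  Covered
    fraction is the union of assigned read intervals clipped to the gene;
    mean depth is assigned read bases over gene length.
    """
    genes = genome.genes
    gene_ids = [g.gene_id for g in genes]
    lens = pd.Series({g.gene_id: g.length for g in genes})
    shape = (len(gene_ids), len(sample_ids))
    counts = pd.DataFrame(np.zeros(shape, dtype=int), index=gene_ids, columns=sample_ids)
    covered = pd.DataFrame(np.zeros(shape), index=gene_ids, columns=sample_ids)
    depth = pd.DataFrame(np.zeros(shape), index=gene_ids, columns=sample_ids)
    totals = pd.Series(0, index=sample_ids, dtype=int)

    df = mappings[
        (mappings["genome_id"] == genome.genome_id) & mappings["specific"]
    ]
    known = set(genome.chromosome_lengths())
    bad = set(df["chrom_id"].unique()) - known
    if bad:
        raise ValueError(f"mappings reference unknown chromosomes: {sorted(bad)}")
    totals = totals.add(df.groupby("sample_id").size(), fill_value=0).astype(int)

    for cid in sorted(known):
        chrom_genes = genome.genes_on(cid)
        if not chrom_genes:
            continue
        gs = np.array([g.start for g in chrom_genes])
        ge = np.array([g.end for g in chrom_genes])
        sub = df[df["chrom_id"] == cid]
        if not len(sub):
            continue
        rs = sub["start"].to_numpy(dtype=np.int64)
        re_ = rs + sub["aligned_length"].to_numpy(dtype=np.int64)
        gi = np.searchsorted(gs, rs, side="right") - 1
        inside = (gi >= 0) & (rs < ge[np.maximum(gi, 0)])
        sub = sub.assign(_gene=gi, _start=rs, _end=re_)[inside]
        for (g_idx, sid), grp in sub.groupby(["_gene", "sample_id"]):
            g = chrom_genes[int(g_idx)]
            s = grp["_start"].to_numpy()
            e = np.minimum(grp["_end"].to_numpy(), g.end)
            union, overlap = _union_and_overlap(s, e)
            counts.at[g.gene_id, sid] = len(grp)
            covered.at[g.gene_id, sid] = union / g.length
            depth.at[g.gene_id, sid] = overlap / g.length
    return GeneSampleMatrix(
        genome_id=genome.genome_id,
        counts=counts,
        covered_fraction=covered,
        mean_depth=depth,
        specific_totals=totals.reindex(sample_ids, fill_value=0),
        gene_lengths=lens,
        genome_length=genome.total_length,
    )


def detect_genes(matrix: GeneSampleMatrix, cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Boolean detection matrix: enough reads AND enough horizontal coverage."""
    cfg = cfg or ThresholdConfig()
    return (matrix.counts >= cfg.detect_min_reads) & (
        matrix.covered_fraction >= cfg.detect_min_covered_fraction
    )


def relative_abundance(
    matrices: dict[str, GeneSampleMatrix],
    totals: pd.Series,
    conserved: set[str],
    cfg: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Relative genomic abundance and share per (sample, genome).

    Returns a frame indexed by sample with, per genome g: ``abund_<g>``
    (percent of total sample reads mapping specifically to g, conserved-gene
    reads excluded, mask-corrected by default) and ``share_<g>``; plus the
    dominance ``class``.
    """
    cfg = cfg or ThresholdConfig()
    if len(matrices) != 2:
        raise ValueError("expected matrices for exactly two genomes")
    gids = sorted(matrices)
    samples = matrices[gids[0]].counts.columns
    missing = [s for s in samples if s not in totals.index or not np.isfinite(totals[s])]
    if missing:
        raise ValueError(f"totals missing for samples: {missing}")

    numerators = {}
    for gid in gids:
        m = matrices[gid]
        cons = [g for g in m.counts.index if g in conserved]
        cons_reads = m.counts.loc[cons].sum(axis=0) if cons else 0
        if cfg.include_intergenic:
            num = m.specific_totals - cons_reads
        else:
            num = m.counts.sum(axis=0) - cons_reads
        if cfg.mask_correction:
            masked = float(m.gene_lengths.loc[cons].sum()) if cons else 0.0
            num = num * (m.genome_length / max(m.genome_length - masked, 1.0))
        numerators[gid] = num.astype(float)

    out = pd.DataFrame(index=samples)
    for gid in gids:
        out[f"abund_{gid}"] = 100.0 * numerators[gid] / totals.loc[samples]
    both = numerators[gids[0]] + numerators[gids[1]]
    for gid in gids:
        out[f"share_{gid}"] = np.where(both > 0, numerators[gid] / both.where(both > 0), np.nan)
    out["class"] = [
        classify_dominance(out[f"abund_{gids[0]}"][s], out[f"abund_{gids[1]}"][s], cfg)
        for s in samples
    ]
    return out


def classify_dominance(
    abund_a: float, abund_b: float, cfg: ThresholdConfig | None = None
) -> str:
    """Dominance class of one sample from the two relative abundances (percent).

    below_floor if the combined abundance is at or below the floor; dominant
    if one genome takes strictly more than ``dominance_share`` of the summed
    signal; co_occurring if both shares lie within [co_low, co_high]; mixed
    otherwise.
    """
    cfg = cfg or ThresholdConfig()
    if abund_a < 0 or abund_b < 0:
        raise ValueError("abundances must be non-negative")
    total = abund_a + abund_b
    if total <= cfg.abundance_floor:
        return "below_floor"
    share_a = abund_a / total
    share_b = 1.0 - share_a
    if share_a > cfg.dominance_share:
        return "A_dominant"
    if share_b > cfg.dominance_share:
        return "B_dominant"
    if cfg.co_low <= share_a <= cfg.co_high and cfg.co_low <= share_b <= cfg.co_high:
        return "co_occurring"
    return "mixed"


def sample_completeness(
    detection: pd.DataFrame,
    conserved: set[str],
    cfg: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Per-sample fraction of (non-conserved) genes detected + eligibility.

    Samples are eligible for pan-genome analysis when at least
    ``completeness_min`` of the genome's genes are detected — conserved genes
    are excluded from numerator and denominator since they can never recruit
    specific reads.
    """
    cfg = cfg or ThresholdConfig()
    keep = [g for g in detection.index if g not in conserved]
    sub = detection.loc[keep]
    frac = sub.sum(axis=0) / len(keep)
    return pd.DataFrame(
        {"fraction_detected": frac, "eligible": frac >= cfg.completeness_min}
    )


def write_matrix_tsv(matrix: GeneSampleMatrix, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gid = matrix.genome_id
    matrix.counts.to_csv(out / f"counts_{gid}.tsv", sep="\t")
    matrix.covered_fraction.to_csv(out / f"covered_{gid}.tsv", sep="\t")
    matrix.mean_depth.to_csv(out / f"depth_{gid}.tsv", sep="\t")
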