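"""Synthetic study generator with known ground truth.

Emulates the sampling design of a two-ecotype picoeukaryote survey: a pair of
cryptic sister genomes of equal layout and ~78% mean nucleotide identity in
orthologous genes, a handful of near-identical (>99%) conserved genes, one
"outlier" chromosome with lower GC and shorter genes, dispensable gene
cassettes carried by only part of the population, a series of station/depth
samples whose environmental covariates drive the mixture of the two genomes,
shotgun read sets with substitution errors, and a per-gene metatranscriptomic
signal.  Every stochastic choice is recorded as ground truth so each
downstream stage can be scored exactly.

Coordinates are 0-based half-open internally; GFF3 export converts to
1-based inclusive.  Genes are single-exon; the divergence model is i.i.d.
per-site substitution without indels, which keeps identity arithmetic exact.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dnautil

BACKGROUND = "background"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A single-exon gene on one chromosome (0-based half-open interval)."""

    gene_id: str
    chrom_id: str
    start: int
    end: int
    strand: str
    outlier_flag: bool = False
    ortholog_id: str | None = None
    dispensable_truth: bool = False

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """Nucleotide sequences plus ordered gene models per chromosome."""

    genome_id: str
    chromosomes: list[tuple[str, str]]
    genes: list[GeneModel]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        lens = self.chromosome_lengths()
        seen: dict[str, int] = {}
        for g in self.genes:
            if g.chrom_id not in lens:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom_id}")
            if g.end > lens[g.chrom_id]:
                raise ValueError(f"gene {g.gene_id} extends past chromosome end")
            prev = seen.get(g.chrom_id, -1)
            if g.start < prev:
                raise ValueError(
                    f"genes on {g.chrom_id} overlap or are unsorted at {g.gene_id}"
                )
            seen[g.chrom_id] = g.end

    def chromosome_lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.chromosomes)

    def sequence(self, chrom_id: str) -> str:
        for cid, seq in self.chromosomes:
            if cid == chrom_id:
                return seq
        raise KeyError(chrom_id)

    def genes_on(self, chrom_id: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom_id == chrom_id]

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_rank(self) -> dict[str, tuple[str, int]]:
        """Map gene_id -> (chrom_id, rank within chromosome gene order)."""
        out: dict[str, tuple[str, int]] = {}
        counter: dict[str, int] = {}
        for g in self.genes:
            r = counter.get(g.chrom_id, 0)
            out[g.gene_id] = (g.chrom_id, r)
            counter[g.chrom_id] = r + 1
        return out


@dataclass(frozen=True)
class GenomePairSpec:
    """Parameters of the two-genome simulation.

    ``target_nt_identity`` is the expected nucleotide identity of ortholog
    pairs (the survey's sister genomes sit near 0.78); conserved genes are
    substituted at ``conserved_divergence`` (<=0.01) instead, mimicking the
    small set of >99%-identity genes.  The outlier chromosome is drawn at
    ``gc_outlier`` with genes shortened by ``outlier_gene_length_factor``.
    ``translocation_fraction`` moves that share of genome-B genes to a random
    other location (breaking collinearity); ``specific_gene_fraction`` makes
    that share of gene slots genome-specific (no ortholog on the other side).
    """

    n_chromosomes: int = 4
    chromosome_length: int = 50_000
    genes_per_chromosome: int = 30
    target_nt_identity: float = 0.78
    conserved_gene_count: int = 6
    gc_regular: float = 0.48
    gc_outlier: float = 0.44
    outlier_chromosome_index: int = 3
    outlier_gene_length_factor: float = 0.5
    gene_length: int = 900
    gene_length_jitter: float = 0.2
    conserved_divergence: float = 0.004
    translocation_fraction: float = 0.0
    specific_gene_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.target_nt_identity <= 1.0:
            raise ValueError("target_nt_identity must be in (0, 1]")
        if not self.gc_outlier < self.gc_regular:
            raise ValueError("gc_outlier must be below gc_regular")
        total = self.n_chromosomes * self.genes_per_chromosome
        if self.conserved_gene_count > total:
            raise ValueError("conserved_gene_count exceeds total gene count")
        if not 0.0 < self.outlier_gene_length_factor <= 1.0:
            raise ValueError("outlier_gene_length_factor must be in (0, 1]")
        if not 0 <= self.outlier_chromosome_index < self.n_chromosomes:
            raise ValueError("outlier_chromosome_index out of range")
        if not 0.0 <= self.conserved_divergence <= 0.01:
            raise ValueError("conserved_divergence must be in [0, 0.01]")


@dataclass(frozen=True)
class Cassette:
    """A run of contiguous genes gained/lost as a unit by sub-populations."""

    chrom_id: str
    gene_ids: tuple[str, ...]
    carrier_frequency: float

    def __post_init__(self):
        if not 0.0 <= self.carrier_frequency <= 1.0:
            raise ValueError("carrier_frequency must be in [0, 1]")


@dataclass
class PopulationModel:
    genome_id: str
    cassettes: list[Cassette]


@dataclass
class SampleProfile:
    """One station/depth sample: environmental covariates plus the true
    mixture of reads drawn from each genome and from background taxa."""

    sample_id: str
    depth_layer: str
    temperature: float
    oxygen: float
    depth: float
    par: float
    nitrate: float
    phosphate: float
    chlorophyll: float
    salinity: float
    total_reads: int
    true_fraction_a: float
    true_fraction_b: float
    background_fraction: float

    def __post_init__(self):
        s = self.true_fraction_a + self.true_fraction_b + self.background_fraction
        if abs(s - 1.0) > 1e-9:
            raise ValueError("mixture fractions must sum to 1")
        for name in (
            "temperature", "oxygen", "depth", "par",
            "nitrate", "phosphate", "chlorophyll", "salinity",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


ENV_PARAMETERS = [
    "temperature", "oxygen", "depth", "par",
    "nitrate", "phosphate", "chlorophyll", "salinity",
]


@dataclass(frozen=True)
class NicheParams:
    """Environmental model of the station series.

    ``mode='logistic'``: the genome-B share of the two-genome mixture follows
    a logistic link of standardized temperature and depth.  ``mode='grouped'``
    plants a balanced design instead: each sample is assigned a dominant
    genome and its temperature drawn at that group's mean, giving an exact
    configured offset between genome-dominant groups.
    """

    mode: str = "logistic"
    beta0: float = 0.0
    beta_temp: float = 1.8
    beta_depth: float = -0.5
    temp_mean_a: float = 18.4
    temp_mean_b: float = 21.5
    temp_sd: float = 2.0
    total_fraction_low: float = 0.005
    total_fraction_high: float = 0.04
    dominant_share_low: float = 0.75
    dominant_share_high: float = 0.95
    total_reads: int = 100_000


# ---------------------------------------------------------------------------
# genome pair
# ---------------------------------------------------------------------------


def _chrom_id(i: int) -> str:
    return f"chr{i + 1:02d}"


def simulate_genome_pair(
    spec: GenomePairSpec,
) -> tuple[AnnotatedGenome, AnnotatedGenome, pd.DataFrame]:
    """Generate the sister-genome pair and its ortholog truth table.

    Genome A is drawn fresh; genome B is derived from A by i.i.d. per-site
    substitution at rate ``1 - target_nt_identity`` (conserved genes at
    ``conserved_divergence``), with optional translocations and
    genome-specific gene slots.  Returns ``(genome_a, genome_b, truth)``
    where ``truth`` has one row per planted ortholog pair with columns
    ``ortholog_id, gene_a, gene_b, conserved``.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_chromosomes * spec.genes_per_chromosome

    # --- plan gene roles on the flat gene index -------------------------
    conserved_idx = set(
        rng.choice(n_total, size=spec.conserved_gene_count, replace=False).tolist()
    )
    remaining = np.array(sorted(set(range(n_total)) - conserved_idx))
    n_specific = int(round(spec.specific_gene_fraction * n_total))
    specific_idx: set[int] = set()
    if n_specific:
        specific_idx = set(rng.choice(remaining, size=n_specific, replace=False).tolist())
    remaining = np.array(sorted(set(remaining.tolist()) - specific_idx))
    n_trans = int(round(spec.translocation_fraction * n_total))
    trans_idx: set[int] = set()
    if n_trans:
        trans_idx = set(rng.choice(remaining, size=n_trans, replace=False).tolist())

    # --- per-chromosome layout ------------------------------------------
    # entries: per chromosome, ordered list of dicts describing gene slots
    layout: list[list[dict]] = []
    spacers_a: list[list[np.ndarray]] = []
    flat = 0
    for ci in range(spec.n_chromosomes):
        outlier = ci == spec.outlier_chromosome_index
        gc = spec.gc_outlier if outlier else spec.gc_regular
        n = spec.genes_per_chromosome
        mean_len = spec.gene_length * (spec.outlier_gene_length_factor if outlier else 1.0)
        j = spec.gene_length_jitter
        lens = np.round(mean_len * rng.uniform(1 - j, 1 + j, size=n)).astype(int)
        lens = np.maximum(lens, 60)
        spacer_budget = spec.chromosome_length - int(lens.sum())
        if spacer_budget < 20 * (n + 1):
            raise ValueError(
                f"chromosome {_chrom_id(ci)} too short for {n} genes of ~{mean_len:.0f} bp"
            )
        w = rng.uniform(0.5, 1.5, size=n + 1)
        sp = np.floor(w / w.sum() * spacer_budget).astype(int)
        sp[-1] += spacer_budget - int(sp.sum())
        entries = []
        for gi in range(n):
            idx = flat + gi
            entries.append(
                {
                    "flat": idx,
                    "seq_a": dnautil.random_codes(rng, int(lens[gi]), gc),
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "conserved": idx in conserved_idx,
                    "specific": idx in specific_idx,
                    "translocated": idx in trans_idx,
                    "outlier": outlier,
                    "gc": gc,
                }
            )
        layout.append(entries)
        spacers_a.append([dnautil.random_codes(rng, int(s), gc) for s in sp])
        flat += n

    sub_rate = 1.0 - spec.target_nt_identity

    # --- derive genome B entries ----------------------------------------
    layout_b: list[list[dict]] = [[] for _ in range(spec.n_chromosomes)]
    for ci, entries in enumerate(layout):
        for e in entries:
            b = dict(e)
            if e["specific"]:
                # unrelated sequence of the same length: no ortholog
                b["seq_b"] = dnautil.random_codes(rng, len(e["seq_a"]), e["gc"])
            elif e["conserved"]:
                # exact substitution count: conserved genes are *forced*
                # above the >99%-identity regime, never left to sampling noise
                n_subs = int(round(spec.conserved_divergence * len(e["seq_a"])))
                b["seq_b"] = dnautil.mutate_codes_exact(rng, e["seq_a"], n_subs)
            else:
                b["seq_b"] = dnautil.mutate_codes(rng, e["seq_a"], sub_rate)
            layout_b[ci].append(b)
    # translocations: move selected genome-B entries to a random slot
    moved: list[dict] = []
    for ci in range(spec.n_chromosomes):
        keep = []
        for b in layout_b[ci]:
            (moved if b["translocated"] else keep).append(b)
        layout_b[ci] = keep
    for b in moved:
        ci = int(rng.integers(spec.n_chromosomes))
        pos = int(rng.integers(len(layout_b[ci]) + 1))
        layout_b[ci].insert(pos, b)

    def assemble(
        genome_id: str, lay: list[list[dict]], seq_key: str, mutate_spacers: bool
    ) -> AnnotatedGenome:
        chroms: list[tuple[str, str]] = []
        genes: list[GeneModel] = []
        for ci in range(spec.n_chromosomes):
            parts: list[np.ndarray] = []
            pos = 0
            spl = spacers_a[ci]
            n_slots = len(lay[ci])
            # spacer pool: reuse genome-A spacers (mutated for B), padding with
            # fresh spacers if translocations added slots on this chromosome
            gc = spec.gc_outlier if ci == spec.outlier_chromosome_index else spec.gc_regular
            mean_sp = max(20, int(np.mean([len(s) for s in spl])))
            for si in range(n_slots + 1):
                if si < len(spl):
                    sp = spl[si]
                    if mutate_spacers:
                        sp = dnautil.mutate_codes(rng_b_spacers, sp, sub_rate)
                else:
                    sp = dnautil.random_codes(rng_b_spacers, mean_sp, gc)
                parts.append(sp)
                pos += len(sp)
                if si < n_slots:
                    e = lay[ci][si]
                    seq = e[seq_key]
                    gid = f"{genome_id}_g{e['flat']:04d}"
                    genes.append(
                        GeneModel(
                            gene_id=gid,
                            chrom_id=_chrom_id(ci),
                            start=pos,
                            end=pos + len(seq),
                            strand=e["strand"],
                            outlier_flag=e["outlier"],
                            ortholog_id=None if e["specific"] else f"og{e['flat']:04d}",
                        )
                    )
                    parts.append(seq)
                    pos += len(seq)
            chroms.append((_chrom_id(ci), dnautil.decode(np.concatenate(parts))))
        return AnnotatedGenome(genome_id=genome_id, chromosomes=chroms, genes=genes)

    rng_b_spacers = np.random.default_rng(rng.integers(2**31))
    genome_a = assemble("A", layout, "seq_a", mutate_spacers=False)
    genome_b = assemble("B", layout_b, "seq_b", mutate_spacers=True)

    rows = []
    for ci, entries in enumerate(layout):
        for e in entries:
            if e["specific"]:
                continue
            rows.append(
                {
                    "ortholog_id": f"og{e['flat']:04d}",
                    "gene_a": f"A_g{e['flat']:04d}",
                    "gene_b": f"B_g{e['flat']:04d}",
                    "conserved": e["conserved"],
                    "translocated": e["translocated"],
                }
            )
    truth = pd.DataFrame(rows, columns=["ortholog_id", "gene_a", "gene_b", "conserved", "translocated"])
    return genome_a, genome_b, truth


# ---------------------------------------------------------------------------
# population structure
# ---------------------------------------------------------------------------


def plant_cassettes(
    genome: AnnotatedGenome,
    plan: list[tuple[str, int, int, float]],
) -> tuple[AnnotatedGenome, PopulationModel]:
    """Mark cassettes of contiguous genes as dispensable ground truth.

    ``plan`` rows are ``(chrom_id, start_rank, n_genes, carrier_frequency)``
    with ranks in chromosome gene order.  Returns a new genome whose member
    genes carry ``dispensable_truth=True`` plus the population model.
    """
    cassettes = []
    flagged: set[str] = set()
    for chrom_id, start_rank, n_genes, freq in plan:
        chrom_genes = genome.genes_on(chrom_id)
        if start_rank < 0 or start_rank + n_genes > len(chrom_genes):
            raise ValueError(f"cassette exceeds gene count on {chrom_id}")
        ids = tuple(g.gene_id for g in chrom_genes[start_rank : start_rank + n_genes])
        cassettes.append(Cassette(chrom_id=chrom_id, gene_ids=ids, carrier_frequency=freq))
        flagged.update(ids)
    genes = [
        dataclasses.replace(g, dispensable_truth=True) if g.gene_id in flagged else g
        for g in genome.genes
    ]
    new = AnnotatedGenome(genome.genome_id, genome.chromosomes, genes)
    return new, PopulationModel(genome_id=genome.genome_id, cassettes=cassettes)


def _check_contiguous(genome: AnnotatedGenome, cassette: Cassette) -> tuple[int, int]:
    """Validate contiguity in gene order; return the cassette's base span."""
    chrom_genes = genome.genes_on(cassette.chrom_id)
    ids = [g.gene_id for g in chrom_genes]
    try:
        ranks = [ids.index(g) for g in cassette.gene_ids]
    except ValueError as exc:
        raise ValueError(f"cassette gene not on {cassette.chrom_id}: {exc}") from exc
    if ranks != list(range(ranks[0], ranks[0] + len(ranks))):
        raise ValueError("cassette genes are not contiguous in gene order")
    return chrom_genes[ranks[0]].start, chrom_genes[ranks[-1]].end


def apply_population_variants(
    genome: AnnotatedGenome,
    model: PopulationModel,
    n_cells: int,
    seed: int,
) -> np.ndarray:
    """Draw per-cell cassette presence: boolean (n_cells, n_cassettes).

    Each cell carries each cassette independently with its carrier frequency.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    for c in model.cassettes:
        _check_contiguous(genome, c)
    rng = np.random.default_rng(seed)
    freqs = np.array([c.carrier_frequency for c in model.cassettes])
    return rng.random((n_cells, len(model.cassettes))) < freqs


# ---------------------------------------------------------------------------
# station series
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_station_series(
    n_samples: int,
    params: NicheParams | None = None,
    seed: int = 0,
) -> list[SampleProfile]:
    """Simulate station/depth samples with covariates and mixture fractions.

    Surface and deep-chlorophyll-maximum (DCM) layers alternate.  Covariates
    follow simple oceanographic couplings (oxygen decreasing with
    temperature, nutrients increasing and PAR decreasing with depth,
    chlorophyll peaking at the DCM).  The genome-B share of the two-genome
    mixture comes from the configured link (see :class:`NicheParams`).
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    p = params or NicheParams()
    rng = np.random.default_rng(seed)

    layer = np.array(["surface", "DCM"])[np.arange(n_samples) % 2]
    group_b = np.arange(n_samples) % 4 >= 2  # balanced across layers

    if p.mode == "grouped":
        means = np.where(group_b, p.temp_mean_b, p.temp_mean_a)
        temp = rng.normal(means, p.temp_sd)
    elif p.mode == "logistic":
        temp = rng.normal((p.temp_mean_a + p.temp_mean_b) / 2.0, 4.0, size=n_samples)
    else:
        raise ValueError(f"unknown niche mode {p.mode!r}")
    temp = temp - np.where(layer == "DCM", 1.5, 0.0)

    depth = np.where(
        layer == "surface", rng.uniform(5, 15, n_samples), rng.uniform(40, 120, n_samples)
    )
    par = np.where(
        layer == "surface",
        rng.normal(35, 6, n_samples),
        rng.normal(4, 1.5, n_samples),
    ).clip(0.1)
    oxygen = (260.0 - 3.2 * temp + rng.normal(0, 12, n_samples)).clip(20.0)
    nitrate = (0.05 + 0.035 * depth + rng.normal(0, 0.4, n_samples)).clip(0.01)
    phosphate = (nitrate / 16.0 + rng.normal(0, 0.02, n_samples)).clip(0.005)
    chlorophyll = np.where(
        layer == "DCM", rng.normal(0.55, 0.12, n_samples), rng.normal(0.22, 0.08, n_samples)
    ).clip(0.01)
    salinity = rng.normal(35.5, 1.0, n_samples)

    if p.mode == "grouped":
        share = rng.uniform(p.dominant_share_low, p.dominant_share_high, n_samples)
        frac_b_share = np.where(group_b, share, 1.0 - share)
    else:
        zt = (temp - temp.mean()) / max(temp.std(), 1e-12)
        zd = (depth - depth.mean()) / max(depth.std(), 1e-12)
        frac_b_share = _sigmoid(p.beta0 + p.beta_temp * zt + p.beta_depth * zd)

    total = rng.uniform(p.total_fraction_low, p.total_fraction_high, n_samples)
    fa = total * (1.0 - frac_b_share)
    fb = total * frac_b_share
    if np.all(fa + fb <= 0):
        warnings.warn("degenerate link: all mixture fractions are zero", stacklevel=2)

    samples = []
    for i in range(n_samples):
        samples.append(
            SampleProfile(
                sample_id=f"S{i + 1:03d}",
                depth_layer=str(layer[i]),
                temperature=float(temp[i]),
                oxygen=float(oxygen[i]),
                depth=float(depth[i]),
                par=float(par[i]),
                nitrate=float(nitrate[i]),
                phosphate=float(phosphate[i]),
                chlorophyll=float(chlorophyll[i]),
                salinity=float(salinity[i]),
                total_reads=p.total_reads,
                true_fraction_a=float(fa[i]),
                true_fraction_b=float(fb[i]),
                background_fraction=float(1.0 - fa[i] - fb[i]),
            )
        )
    return samples


def samples_to_frame(samples: list[SampleProfile]) -> pd.DataFrame:
    """Tabulate SampleProfiles (one row per sample)."""
    return pd.DataFrame([dataclasses.asdict(s) for s in samples]).set_index("sample_id")


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Simulated reads: names plus an (n_reads, read_length) code matrix."""

    names: list[str]
    codes: np.ndarray

    def __len__(self) -> int:
        return len(self.names)

    @property
    def read_length(self) -> int:
        return self.codes.shape[1]

    def sequences(self) -> list[str]:
        return [dnautil.decode(row) for row in self.codes]

    def write_fastq(self, path: str | Path) -> None:
        qual = "I" * self.read_length
        with open(path, "w") as fh:
            for name, row in zip(self.names, self.codes):
                fh.write(f"@{name}\n{dnautil.decode(row)}\n+\n{qual}\n")


def _genotype_classes(
    genome: AnnotatedGenome,
    model: PopulationModel | None,
    genotypes: np.ndarray | None,
) -> list[tuple[float, list[tuple[int, int]]]]:
    """Collapse per-cell cassette genotypes into (frequency, excluded spans).

    Spans are in concatenated-genome coordinates.
    """
    offsets = {}
    pos = 0
    for cid, seq in genome.chromosomes:
        offsets[cid] = pos
        pos += len(seq)
    if model is None or genotypes is None or genotypes.size == 0:
        return [(1.0, [])]
    spans = []
    for c in model.cassettes:
        s, e = _check_contiguous(genome, c)
        spans.append((offsets[c.chrom_id] + s, offsets[c.chrom_id] + e))
    patterns, counts = np.unique(genotypes, axis=0, return_counts=True)
    classes = []
    for pat, cnt in zip(patterns, counts):
        excl = [spans[i] for i in range(len(spans)) if not pat[i]]
        classes.append((cnt / genotypes.shape[0], excl))
    return classes


def _allowed_start_intervals(
    genome: AnnotatedGenome, read_length: int, excluded: list[tuple[int, int]]
) -> np.ndarray:
    """Valid read-start intervals (global coords), as an (n, 2) array.

    A read must lie fully within one chromosome and, for cells lacking a
    cassette, must not overlap the deleted span (no junction reads are
    simulated), so starts in ``[span_start - read_length + 1, span_end)``
    are excluded.
    """
    ivals = []
    pos = 0
    for _, seq in genome.chromosomes:
        ivals.append([pos, pos + len(seq) - read_length + 1])
        pos += len(seq)
    for s, e in sorted(excluded):
        nxt = []
        for a, b in ivals:
            lo, hi = max(a, s - read_length + 1), min(b, e)
            if lo >= hi:
                nxt.append([a, b])
            else:
                if a < lo:
                    nxt.append([a, lo])
                if hi < b:
                    nxt.append([hi, b])
        ivals = nxt
    return np.array([iv for iv in ivals if iv[1] > iv[0]], dtype=np.int64)


def _sample_starts(rng, intervals: np.ndarray, n: int) -> np.ndarray:
    lens = intervals[:, 1] - intervals[:, 0]
    cum = np.concatenate([[0], np.cumsum(lens)])
    u = rng.integers(0, cum[-1], size=n)
    which = np.searchsorted(cum, u, side="right") - 1
    return intervals[which, 0] + (u - cum[which])


def simulate_reads(
    sample: SampleProfile,
    genomes: dict[str, AnnotatedGenome],
    genotypes: dict[str, tuple[PopulationModel, np.ndarray]] | None = None,
    read_length: int = 100,
    error_rate: float = 0.01,
    seed: int = 0,
) -> tuple[ReadSet, pd.DataFrame]:
    """Draw a shotgun read set for one sample with per-read origin truth.

    Read counts per origin (genome A, genome B, background taxa) follow a
    multinomial over the sample's true fractions.  Genome reads are uniform
    over start positions valid for a random cell of the population (cells
    lacking a cassette never yield reads from the deleted span); background
    reads are GC-matched random sequence.  Substitution errors are i.i.d. at
    ``error_rate``.  Returns the reads and a truth table with columns
    ``read_id, origin, chrom_id, pos, strand``.
    """
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    ids = sorted(genomes)
    if len(ids) != 2:
        raise ValueError("expected exactly two reference genomes")
    for g in genomes.values():
        if g.total_length == 0 or not g.chromosomes:
            raise ValueError(f"genome {g.genome_id} is empty")
        if read_length > min(len(s) for _, s in g.chromosomes):
            raise ValueError("read_length exceeds shortest chromosome")

    rng = np.random.default_rng(seed)
    fracs = [sample.true_fraction_a, sample.true_fraction_b, sample.background_fraction]
    counts = rng.multinomial(sample.total_reads, fracs)

    all_codes: list[np.ndarray] = []
    names: list[str] = []
    truth_rows: list[pd.DataFrame] = []
    mean_gc = float(
        np.mean([dnautil.gc_content(seq) for g in genomes.values() for _, seq in g.chromosomes])
    )

    ridx = 0
    for oi, gid in enumerate(ids):
        n = int(counts[oi])
        if n == 0:
            continue
        genome = genomes[gid]
        concat = np.concatenate([dnautil.encode(seq) for _, seq in genome.chromosomes])
        bounds = np.cumsum([0] + [len(seq) for _, seq in genome.chromosomes])
        chrom_ids = [cid for cid, _ in genome.chromosomes]

        model, cells = (None, None)
        if genotypes and gid in genotypes:
            model, cells = genotypes[gid]
        classes = _genotype_classes(genome, model, cells)
        class_n = rng.multinomial(n, [f for f, _ in classes])
        starts = np.concatenate(
            [
                _sample_starts(rng, _allowed_start_intervals(genome, read_length, excl), k)
                if k
                else np.empty(0, dtype=np.int64)
                for (f, excl), k in zip(classes, class_n)
            ]
        )
        windows = concat[starts[:, None] + np.arange(read_length)]
        minus = rng.random(n) < 0.5
        windows[minus] = dnautil.revcomp_codes(windows[minus])
        ci = np.searchsorted(bounds, starts, side="right") - 1
        local = starts - bounds[ci]
        strands = np.where(minus, "-", "+")
        batch_names = [
            f"{sample.sample_id}|{gid}|{chrom_ids[c]}|{p}|r{ridx + k}"
            for k, (c, p) in enumerate(zip(ci, local))
        ]
        truth_rows.append(
            pd.DataFrame(
                {
                    "read_id": batch_names,
                    "origin": gid,
                    "chrom_id": [chrom_ids[c] for c in ci],
                    "pos": local,
                    "strand": strands,
                }
            )
        )
        all_codes.append(windows)
        names.extend(batch_names)
        ridx += n

    n_bg = int(counts[2])
    if n_bg:
        at = (1.0 - mean_gc) / 2.0
        bg = rng.choice(
            4, size=(n_bg, read_length), p=[at, mean_gc / 2, mean_gc / 2, at]
        ).astype(np.uint8)
        batch_names = [
            f"{sample.sample_id}|{BACKGROUND}|.|-1|r{ridx + k}" for k in range(n_bg)
        ]
        truth_rows.append(
            pd.DataFrame(
                {
                    "read_id": batch_names,
                    "origin": BACKGROUND,
                    "chrom_id": ".",
                    "pos": -1,
                    "strand": ".",
                }
            )
        )
        all_codes.append(bg)
        names.extend(batch_names)

    codes = (
        np.vstack(all_codes) if all_codes else np.empty((0, read_length), dtype=np.uint8)
    )
    if error_rate > 0 and codes.size:
        codes = dnautil.mutate_codes(rng, codes, error_rate)
    truth = (
        pd.concat(truth_rows, ignore_index=True)
        if truth_rows
        else pd.DataFrame(columns=["read_id", "origin", "chrom_id", "pos", "strand"])
    )
    return ReadSet(names=names, codes=codes), truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    genes: list[GeneModel],
    sample_ids: list[str],
    active_fraction: float = 0.9,
    seed: int = 0,
    activity_core: float = 0.56,
    activity_dispensable: float = 0.73,
    activity_sd: float = 0.15,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene metatranscriptomic signal.

    Each gene is "expressed" in each sample independently with probability
    ``active_fraction`` (boolean table, genes x samples).  Each gene also
    gets a continuous relative activity, drawn around a higher mean for
    dispensable genes than core genes (0.73 vs 0.56 by default), clipped to
    [0, 1]; the boolean table feeds the dispensable-gene filter, the activity
    feeds the descriptive contrast statistic.
    """
    if not 0.0 <= active_fraction <= 1.0:
        raise ValueError("active_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genes]
    expressed = pd.DataFrame(
        rng.random((len(genes), len(sample_ids))) < active_fraction,
        index=gene_ids,
        columns=sample_ids,
    )
    means = np.array(
        [activity_dispensable if g.dispensable_truth else activity_core for g in genes]
    )
    activity = pd.Series(
        np.clip(rng.normal(means, activity_sd), 0.0, 1.0), index=gene_ids, name="activity"
    )
    return expressed, activity


def simulate_barcode_counts(
    samples: list[SampleProfile], seed: int = 0, scale: float = 1.0
) -> pd.Series:
    """Amplicon (V9-style) counts: Poisson, proportional to the summed
    two-genome fraction of each sample.  The marker cannot separate the two
    genomes, so only the sum is observable."""
    rng = np.random.default_rng(seed)
    lam = np.array(
        [scale * (s.true_fraction_a + s.true_fraction_b) * s.total_reads for s in samples]
    )
    return pd.Series(
        rng.poisson(lam), index=[s.sample_id for s in samples], name="barcode_count"
    )


# ---------------------------------------------------------------------------
# file export / import
# ---------------------------------------------------------------------------


def write_fasta(genome: AnnotatedGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, seq in genome.chromosomes:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_gff3(genome: AnnotatedGenome, path: str | Path) -> None:
    """GFF3 export: 1-based inclusive coordinates, truth in attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id}"
            if g.ortholog_id:
                attrs += f";ortholog_id={g.ortholog_id}"
            attrs += f";dispensable_truth={str(g.dispensable_truth).lower()}"
            attrs += f";outlier={str(g.outlier_flag).lower()}"
            fh.write(
                f"{g.chrom_id}\tbathypan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def load_genome(genome_id: str, fasta: str | Path, gff3: str | Path) -> AnnotatedGenome:
    """Load a genome from FASTA + GFF3 written by this package."""
    from Bio import SeqIO

    chroms = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(fasta), "fasta")]
    genes = []
    with open(gff3) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            if ftype != "gene":
                continue
            kv = dict(item.split("=", 1) for item in attrs.split(";"))
            genes.append(
                GeneModel(
                    gene_id=kv["ID"],
                    chrom_id=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    outlier_flag=kv.get("outlier") == "true",
                    ortholog_id=kv.get("ortholog_id"),
                    dispensable_truth=kv.get("dispensable_truth") == "true",
                )
            )
    return AnnotatedGenome(genome_id=genome_id, chromosomes=chroms, genes=genes)


def write_provenance(spec: GenomePairSpec, path: str | Path, **extra) -> None:
    payload = {"spec": dataclasses.asdict(spec), **extra}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
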