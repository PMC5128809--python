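# Methods

`bathypan` implements, at desk scale, the comparative-metagenomics analysis
used to study a pair of cryptic sister *Bathycoccus* genomes in ocean
shotgun data: the two ecotypes share identical rRNA marker genes, so the
only way to separate them is competitive, genome-specific read recruitment
against both reference genomes. Everything downstream — relative genomic
abundance, dominance classes, the dispensable-gene/cassette pan-genome,
sub-population coverage depletion, and environmental niche statistics — is
built on that separation. Because the real survey's read sets and reference
assemblies are not required to build or test the package, a synthetic-data
generator plants every signal with known ground truth and each stage is
scored against it.

## The synthetic study

`simulate.simulate_genome_pair` draws genome A fresh and derives genome B by
i.i.d. per-site substitution at rate `1 − target_nt_identity` (default 0.78,
the ecotypes' ortholog identity regime). There are no indels by default,
which keeps identity arithmetic exact: the planted identity of a gene pair
is a binomial realisation around the target, and global alignment of the
pair recovers it without ambiguity. Conserved genes (default 6) are the
exception: they are substituted with an *exact* count of
`round(0.004 × length)` sites so that every planted conserved gene is
guaranteed to sit above the 99% identity threshold that defines the
conserved-gene mask — these genes model the small set of near-identical
genes that defeat read-level separation. One chromosome is an "outlier":
lower GC (0.44 vs 0.48) and genes shortened by a factor 0.5, mirroring the
atypical chromosome of these algae. Genes are single-exon and placement is
collinear between the genomes; `translocation_fraction` and
`specific_gene_fraction` optionally break collinearity and plant unpaired
genes for the synteny analysis.

Default desk scale is 2 genomes × 4 chromosomes × 50 kb with 30 genes of
~900 bp per chromosome. The pan-genome study instead uses 4 × 160 genes of
~380 bp (same 80 kb chromosomes): the survey's 98%-completeness gate only
behaves as it does on real data when dispensable genes are a small fraction
of the genome (there, ~100 of ~7900 genes), and with 12 planted dispensable
genes a genome needs ≥ ~620 non-conserved genes for a sample missing every
cassette to remain eligible (622/634 = 98.1%).

Population structure is planted as cassettes — runs of contiguous genes
carried by a cell with probability `carrier_frequency`. Reads from a cell
lacking a cassette are never drawn from the deleted span (start positions
within `read_length − 1` upstream through the span are excluded); junction
reads across the deletion breakpoint are not simulated, so absent-sample
coverage tapers linearly over one read length at the borders instead of
carrying chimeric reads. Station series
(`simulate.simulate_station_series`) draw environmental covariates with
simple oceanographic couplings (oxygen decreasing with temperature,
nutrients rising and PAR falling with depth, chlorophyll peaking at the
DCM) and compute the genome-B share of the two-genome mixture either by a
logistic link of standardized temperature and depth (default) or in
"grouped" mode, which assigns each sample a dominant genome and draws its
temperature at that group's mean (18.4 vs 21.5 °C, sd 2). The grouped mode
exists because a pure logistic link cannot plant an exact between-group
offset: selecting samples by realised dominance class biases the recovered
offset upward of the planted one.

Read sets are multinomial over (genome A, genome B, background) fractions;
genome reads are uniform over valid start positions for a random cell,
strand-symmetric, with i.i.d. substitution errors (default 1%); background
reads — the rest of the community — are GC-matched random sequence, which
exercises false-mapping behaviour without real third-party genomes. The
expression signal is Bernoulli per gene × sample (`active_fraction`), plus
a continuous per-gene activity drawn around 0.73 for dispensable and 0.56
for core genes (sd 0.15, clipped to [0, 1]); the boolean table feeds the
dispensable filter, the activity only the descriptive contrast.

## Recruitment and the competitive filter

The mapper is seed-and-extend with exact k-mer seeds (k = 15) and gapless
extension; identity = matching columns / alignment columns × 100. A read is
mapped when some locus reaches `min_identity` (95%) over at least 80% of
its length, and the record keeps the best locus per genome. The competitive
filter marks a read *specific* when its identity beats the best identity on
the other genome by ≥ 3 points (or the other genome has no placement);
otherwise it is ambiguous. These defaults are self-consistent: at ~78%
inter-genome identity the wrong genome essentially never seeds (an exact
15-mer survives with probability 0.78^15 ≈ 0.02 per position), while reads
from >99%-identity conserved genes seed both genomes and differ by roughly
the number of divergent sites in the read (~0.4 expected per 100 bp),
far below the margin — they are flagged ambiguous, as intended.

Exactness: a 100 bp read with ≤ 3 mismatches (≥ 97% identity) always
contains an exact 15-mer by pigeonhole, so the stride-1 single-read path
(`map_read`) provably finds every locus at or above the identity floor and
its chosen identity equals brute-force alignment at every position. The
vectorised batch path (`map_reads`) samples seed offsets at stride 4 by
default, which still guarantees an offset-aligned clean 15-mer for ≤ 3
mismatches (longest clean run ≥ ⌈97/4⌉ = 25 ≥ k + stride − 1); reads with
more errors fall below the floor anyway. Batch alignments are end-to-end;
the single-read path also handles clipped alignments at chromosome ends.
Ties break toward the lowest chromosome/start and '+' strand. Multi-mapping
within one genome keeps the single best locus; within-genome repeats are
out of scope.

## Orthology, conserved mask, synteny

Orthologs are reciprocal best hits: an 11-mer prefilter proposes candidate
partners from both sides (keeping RBH symmetric), candidates are aligned
globally (match +1, mismatch −1, gap −2; Biopython's `PairwiseAligner`),
and identity is identical columns over alignment columns. Identity is
computed on nucleotide gene sequences — one source of truth with the
simulator — with a protein mode (translate, then align) available but off
by default. Pairs above `min_ortholog_identity` (60%; unrelated genes align
near 50%) are kept. The conserved-gene mask is all genes of pairs strictly
above 99%. Synteny blocks chain pairs whose gene ranks advance by ≤ 2 on
both genomes with a consistent orientation, minimum 3 genes per block; the
per-genome summary (collinear / shared-outside-blocks / genome-specific)
partitions genes and sums to 1.

## Abundance and dominance

A specific read belongs to the gene containing its start (each read counted
exactly once); intergenic reads count toward the genome total but no gene.
Relative genomic abundance of genome g in sample s is

    A_g(s) = 100 × (specific reads of g, conserved-gene reads removed) / (total reads of s)

with the numerator rescaled by `L / (L − L_conserved)` (genome length over
unmasked length, default on): discarding conserved-gene reads removes a
known fraction of the genome's signal, and the rescaling keeps the
estimator unbiased. Detection requires ≥ 2 specific reads covering ≥ 20% of
the gene — at ≥ 5× coverage a present gene is detected with probability ~1
while an absent gene needs two independent false mappings. Dominance
classes per sample follow the survey's printed rules: `below_floor` when
combined abundance ≤ 0.01% of reads; a genome with > 70% of the two-genome
signal is dominant; both shares within [40%, 60%] is `co_occurring`; the
remaining share patterns (e.g. 65/35), which the printed rules do not
cover, are `mixed`. Mixture recovery is scored against the realised
per-read origin composition of each simulated read set rather than the
latent multinomial fraction — the two differ by sampling noise no estimator
can remove.

## Pan-genome

Samples enter the pan-genome analysis only when ≥ 98% of the genome's
non-conserved genes are detected (conserved genes are excluded from both
sides of that ratio — they can never recruit specific reads). A gene is
dispensable when, over eligible samples, it is detected in ≥ 4 and
undetected in ≥ 5, and shows an expression signal in ≥ 6 samples (counted
over all samples with transcriptome data; all three counts configurable).
Maximal runs of rank-adjacent dispensable genes are cassettes (≥ 2 genes);
isolated calls are singletons; together they partition the dispensable set.

Depletion: a gene's mean depth over the median mean-depth of
non-dispensable genes on its chromosome in the same sample. Ratios ≤ 0.1
are `absent`, ≥ 0.8 `present`, in between `partial` — the sub-population
signature; with fewer than 3 informative baseline genes the state is
undefined. Border estimates use the windowed depth track (200 bp windows):
each border is the window boundary with the maximum depth change within
± 3 windows of the annotated edge (ties resolve toward the edge), a simple
change-point estimator chosen over an HMM because, at desk scale, absent
samples show a near-step coverage profile; the survey's contig-alignment
evidence is replaced by this coverage-based proxy. The depth change at a
boundary is the difference of mean depth over the two windows on each side:
with gapless mapping, fragments spanning the deletion junction are
unmappable, so coverage tapers over one read length at the edge and the
two-window support keeps the estimator from drifting to a neighbouring
boundary under Poisson noise. Estimates are undefined for samples without
flanking coverage, and ≥ 2 absent samples are required.

## Niche statistics

`niche.mww_test` is exact for combined samples ≤ 16 without ties: the U
null distribution comes from the subset-sum recurrence (counts of rank
subsets by rank sum), and the two-sided p is twice the smaller tail
(capped at 1). Otherwise the normal approximation with tie and continuity
corrections applies; fully tied input returns p = 1. The test is validated
against an independent exhaustive-enumeration oracle and against SciPy's
exact method. Group comparisons run between A-dominant and B-dominant
samples only (mixed, co-occurring and below-floor samples are excluded);
raw p-values are reported with Benjamini–Hochberg flags at 0.05 alongside.
The PCA standardizes each parameter, decomposes the correlation matrix, and
fixes signs so each component's largest-magnitude loading is positive; rows
with missing values and zero-variance parameters are dropped with a
warning. Barcode concordance correlates amplicon counts (Poisson,
proportional to the summed two-genome fraction — the marker cannot separate
the ecotypes) with the summed estimated abundances (Spearman and Pearson).

## Problem sizes and numerical choices

The studies run by `analysis/` and `scripts/acceptance.py` use: 30 samples
× 100k reads (100 bp, 1% error) for mixture recovery; 14 samples at ~12×
coverage of the 640-gene genome for the pan-genome chain; 50 replicates at
20× for depletion; 6 absent samples at 20× with 200 bp windows for borders;
200 random instances + 1000 null replicates for MWW calibration; 100
replicates of 15 + 15 samples for the niche offset; 500 reads of 60 bp on a
5 kb genome pair for the brute-force mapper check. Seeds derive from one
master seed via `numpy.random.default_rng`; identical seeds reproduce
byte-identical FASTA/FASTQ/GFF3/TSV outputs. Coordinates are 0-based
half-open internally; GFF3 export is 1-based inclusive.

## What passing tests do and do not show

The generator plants clean signals: substitution-only divergence, uniform
read sampling, crisp per-sample cassette presence, GC-matched random
background. Passing the recovery checks therefore shows the *method chain*
is correct and calibrated under its own assumptions — it does not show
robustness to indels and rearrangements, amplification or GC bias, uneven
community composition, within-genome repeats, or real mapper artefacts.
Observed survey quantities that depend on real coverage (counts of
dispensable genes, the 91% single-genome dominance rate, the real 3 °C
niche offset) are treated as observations to emulate, not targets to
reproduce. Other known limitations: no paired-end inserts, no junction
reads across deletions, single-exon gene models, and no organellar or rRNA
operon structure.
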