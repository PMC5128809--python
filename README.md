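# bathypan

Competitive read recruitment, pan-genome and niche analysis for a pair of
cryptic sister picoeukaryote genomes in ocean metagenomes.

## The problem

*Bathycoccus* is one of the dominant green picoalgae of the global ocean.
Two of its lineages are cryptic sister species: their rRNA marker genes
(including the V9 metabarcode) are identical, yet their orthologous genes
are only ~78% identical at the nucleotide level. Amplicon surveys therefore
cannot separate them — but shotgun metagenomes can, if reads are recruited
*competitively* against both reference genomes and only genome-specific
signal is kept. This package implements that analysis chain for
ecologists and comparative genomicists, at desk scale, with a synthetic-data
generator that plants every signal with known ground truth so each stage is
scored exactly:

1. **simulate** — genome pair (collinear gene order, target ortholog
   identity, >99%-identity conserved genes, a low-GC outlier chromosome,
   dispensable gene cassettes carried by sub-populations), station series
   with environmental covariates driving the mixture of the two genomes,
   shotgun reads with errors, and a per-gene expression signal.
2. **recruit** — seed-and-extend mapping against both genomes; a read is
   *specific* when its identity beats the other genome by ≥ 3 points.
3. **orthology** — reciprocal-best-hit pairs, the >99%-identity
   conserved-gene mask, synteny blocks and collinearity fractions.
4. **abundance** — gene × sample matrices; relative genomic abundance
   `A_g(s) = 100 · n_specific(g, s) / n_total(s)` with conserved genes
   masked; dominance classes (floor 0.01%, dominant > 70% share,
   co-occurring at 40–60%).
5. **pangenome** — dispensable genes (detected in ≥ 4 samples, absent in
   ≥ 5, expressed in ≥ 6, over samples with ≥ 98% of genes detected),
   cassette clustering, sub-population coverage depletion
   (gene depth / chromosome baseline), cassette-border change points.
6. **niche** — exact Mann–Whitney–Wilcoxon tests between genome-dominant
   sample groups, environmental PCA, metabarcode concordance.

See `docs/methods.md` for the model, defaults and limitations.

## Worked example

The numbered drivers under `analysis/` run the full study (each accepts
`--seed`, default 1, and writes tables under `results/`):

```bash
python analysis/01_simulate_study.py     # export genomes, stations, reads
python analysis/02_genome_structure.py   # orthologs, conserved mask, synteny
python analysis/03_abundance_mixture.py  # recruitment and abundance recovery
python analysis/04_pangenome.py          # dispensable genes and cassettes
python analysis/05_niche.py              # niche statistics
```

`analysis/03_abundance_mixture.py` simulates 30 stations × 100,000 reads
(100 bp, 1% error), recruits every read against both genomes and prints:

```
Pearson r (realized vs estimated fractions): 1.0000
worst relative error at truth >= 0.1%: 2.6%
conserved-gene reads flagged ambiguous: 99.9% of 1720
dominance classes: {'B_dominant': 10, 'A_dominant': 9, 'co_occurring': 6, 'mixed': 5}
barcode concordance: Spearman rho = 0.971 over 30 samples
```

Reading this: per-genome mixture fractions between 0.1% and ~3% of the
community are recovered to within a few percent relative error; reads from
the planted near-identical conserved genes are almost all flagged ambiguous
(they carry no genome-specific information, which is why those genes are
masked from the abundance numerator); and a simulated V9-style amplicon
tracks the summed abundance of the pair but cannot split it.

`analysis/04_pangenome.py` recovers the planted pan-genome:

```
eligible samples (98% completeness gate): 14/14
dispensable genes called: 12 (precision 1.00, recall 1.00)
cassettes: 3 — memberships match planted: True
transcriptomic activity: dispensable 0.76 vs core 0.56 (MWW p = 7.46e-05)
depletion at carrier frequency 0.5: mean ratio 0.495, 'partial' in 100% of 50 reps
border estimates within 170 bp of planted edges (200 bp windows, 6 absent samples)
```

The three cassettes (7 + 3 + 2 genes) pass the detected/absent/expressed
filter chain exactly; a cassette carried by half the population shows the
diagnostic *partial* depletion (ratio ≈ 0.5); and the loss breakpoints land
at the same window boundaries in every sample lacking the cassette.

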