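"""Ortholog pairing, conserved-gene masking and synteny between the genomes.

Orthologs are reciprocal best hits (RBH) from all-vs-all gene comparison:
an 11-mer prefilter proposes candidate partners, candidates are aligned
globally (match +1 / mismatch -1 / gap -2) and identity is computed as
identical columns over alignment columns.  Identity is computed on gene
nucleotide sequences by default — one source of truth for the identity
arithmetic — with an optional protein mode (translate, then align).

Pairs above 99% identity form the conserved-gene mask that the abundance
stage must exclude: reads from those genes cannot be assigned to either
genome.  Synteny blocks chain rank-adjacent pairs and yield the per-genome
collinear / shared-outside-blocks / genome-specific fractions.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from . import dnautil
from .simulate import AnnotatedGenome


@dataclass(frozen=True)
class OrthologyParams:
    prefilter_k: int = 11
    max_candidates: int = 5
    min_ortholog_identity: float = 60.0
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    protein_mode: bool = False


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    identity: float
    alignment_length: int


@dataclass
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    pairs: list[tuple[str, str]]
    orientation: str  # 'same' | 'inverted'


def _gene_sequences(genome: AnnotatedGenome, protein: bool) -> dict[str, str]:
    seqs = {}
    for cid, seq in genome.chromosomes:
        for g in genome.genes_on(cid):
            s = seq[g.start : g.end]
            if g.strand == "-":
                s = dnautil.revcomp(s)
            if protein:
                s = str(Seq(s[: len(s) - len(s) % 3]).translate())
            seqs[g.gene_id] = s
    return seqs


def _aligner(params: OrthologyParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = params.match
    al.mismatch_score = params.mismatch
    al.open_gap_score = params.gap
    al.extend_gap_score = params.gap
    return al


def _alignment_identity(aligner, sa: str, sb: str) -> tuple[float, int]:
    aln = aligner.align(sa, sb)[0]
    c = aln.counts()
    cols = c.gaps + c.identities + c.mismatches
    return 100.0 * c.identities / cols, cols


def find_orthologs(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    params: OrthologyParams | None = None,
) -> pd.DataFrame:
    """Reciprocal-best-hit ortholog pairs between two annotated genomes.

    Returns a DataFrame with columns ``gene_a, gene_b, identity,
    alignment_length`` sorted by ``gene_a``; each gene appears in at most one
    pair.  Symmetric: swapping the genomes yields the same pairing.
    """
    params = params or OrthologyParams()
    if not genome_a.genes or not genome_b.genes:
        raise ValueError("both genomes must carry gene annotations")
    seqs_a = _gene_sequences(genome_a, params.protein_mode)
    seqs_b = _gene_sequences(genome_b, params.protein_mode)
    k = params.prefilter_k

    def _kmer_map(seqs: dict[str, str]) -> dict[str, set[str]]:
        m: dict[str, set[str]] = defaultdict(set)
        for gid, s in seqs.items():
            for i in range(len(s) - k + 1):
                m[s[i : i + k]].add(gid)
        return m

    def _candidates(
        query: dict[str, str], target_map: dict[str, set[str]]
    ) -> set[tuple[str, str]]:
        out = set()
        for gq, s in query.items():
            shared: Counter[str] = Counter()
            for i in range(len(s) - k + 1):
                for gt in target_map.get(s[i : i + k], ()):
                    shared[gt] += 1
            # deterministic order: most shared k-mers, then gene id
            for gt in sorted(shared, key=lambda g: (-shared[g], g))[: params.max_candidates]:
                out.add((gq, gt))
        return out

    # propose candidate pairs from both sides so the RBH result is symmetric
    pairs_ab = _candidates(seqs_a, _kmer_map(seqs_b))
    pairs_ba = {(ga, gb) for gb, ga in _candidates(seqs_b, _kmer_map(seqs_a))}

    aligner = _aligner(params)
    scored: dict[tuple[str, str], tuple[float, int]] = {}
    for ga, gb in sorted(pairs_ab | pairs_ba):
        scored[(ga, gb)] = _alignment_identity(aligner, seqs_a[ga], seqs_b[gb])

    best_b: dict[str, tuple[str, float, int]] = {}
    best_a: dict[str, tuple[str, float, int]] = {}
    for (ga, gb), (ident, cols) in scored.items():
        if ident < params.min_ortholog_identity:
            continue
        if ga not in best_b or (ident, gb) > (best_b[ga][1], best_b[ga][0]):
            # ties break toward the lexicographically larger id for
            # determinism; any fixed rule keeps RBH symmetric
            best_b[ga] = (gb, ident, cols)
        if gb not in best_a or (ident, ga) > (best_a[gb][1], best_a[gb][0]):
            best_a[gb] = (ga, ident, cols)

    rows = []
    for ga, (gb, ident, cols) in best_b.items():
        if best_a.get(gb, (None,))[0] == ga:
            rows.append(
                {"gene_a": ga, "gene_b": gb, "identity": ident, "alignment_length": cols}
            )
    return (
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "identity", "alignment_length"])
        .sort_values("gene_a")
        .reset_index(drop=True)
    )


def conserved_genes(pairs: pd.DataFrame, threshold: float = 99.0) -> set[str]:
    """Gene ids (both genomes) of pairs strictly above the identity threshold.

    This set is the mask the abundance stage excludes: reads from these genes
    cannot be attributed to one genome.
    """
    sel = pairs[pairs["identity"] > threshold]
    return set(sel["gene_a"]) | set(sel["gene_b"])


def _ranks(genome: AnnotatedGenome) -> dict[str, tuple[str, int]]:
    return genome.gene_rank()


def synteny_blocks(
    pairs: pd.DataFrame,
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    min_block_genes: int = 3,
    max_rank_gap: int = 1,
) -> tuple[list[SyntenyBlock], pd.DataFrame]:
    """Chain rank-adjacent ortholog pairs into collinear blocks.

    Pairs on the same chromosome pair chain greedily while the gene-rank gap
    on both genomes is <= ``max_rank_gap`` (a gap of g skips g intervening
    genes) and the orientation stays consistent.  Returns the blocks plus a
    per-genome summary with ``collinear``, ``shared_outside_blocks`` and
    ``genome_specific`` fractions (summing to 1).
    """
    ra, rb = _ranks(genome_a), _ranks(genome_b)
    items = []
    for row in pairs.itertuples():
        ca, qa = ra[row.gene_a]
        cb, qb = rb[row.gene_b]
        items.append((ca, cb, qa, qb, row.gene_a, row.gene_b))
    items.sort()

    blocks: list[SyntenyBlock] = []
    grouped: dict[tuple[str, str], list] = defaultdict(list)
    for it in items:
        grouped[(it[0], it[1])].append(it)

    in_block: set[str] = set()
    for (ca, cb), group in sorted(grouped.items()):
        chain: list = []
        direction = 0  # 0 undecided, +1 same, -1 inverted
        max_step = max_rank_gap + 1

        def flush():
            nonlocal chain, direction
            if len(chain) >= min_block_genes:
                blocks.append(
                    SyntenyBlock(
                        chrom_a=ca,
                        chrom_b=cb,
                        pairs=[(it[4], it[5]) for it in chain],
                        orientation="inverted" if direction < 0 else "same",
                    )
                )
                in_block.update(it[4] for it in chain)
                in_block.update(it[5] for it in chain)
            chain, direction = [], 0

        for it in group:
            if not chain:
                chain = [it]
                continue
            da = it[2] - chain[-1][2]
            db = it[3] - chain[-1][3]
            ok = 1 <= da <= max_step and 1 <= abs(db) <= max_step
            step_dir = int(np.sign(db))
            if ok and (direction == 0 or step_dir == direction):
                if direction == 0:
                    direction = step_dir
                chain.append(it)
            else:
                flush()
                chain = [it]
        flush()

    paired_a = set(pairs["gene_a"])
    paired_b = set(pairs["gene_b"])
    rows = {}
    for genome, paired in ((genome_a, paired_a), (genome_b, paired_b)):
        total = len(genome.genes)
        coll = sum(1 for g in genome.genes if g.gene_id in in_block)
        outside = sum(
            1 for g in genome.genes if g.gene_id in paired and g.gene_id not in in_block
        )
        rows[genome.genome_id] = {
            "collinear": coll / total,
            "shared_outside_blocks": outside / total,
            "genome_specific": (total - coll - outside) / total,
        }
    summary = pd.DataFrame(rows).T
    return blocks, summary


def write_orthologs_tsv(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def write_conserved_list(gene_ids: set[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(gene_ids)))


def write_synteny_tsv(blocks: list[SyntenyBlock], path: str | Path) -> None:
    rows = []
    for i, b in enumerate(blocks):
        for ga, gb in b.pairs:
            rows.append(
                {
                    "block": i,
                    "chrom_a": b.chrom_a,
                    "chrom_b": b.chrom_b,
                    "orientation": b.orientation,
                    "gene_a": ga,
                    "gene_b": gb,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
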