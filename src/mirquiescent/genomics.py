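"""Genomic organisation of dysregulated miRNA genes.

Three questions: (i) which cytogenetic bands carry two (duplex) or three or
more (cluster) dysregulated miRNA genes; (ii) which genes fall within a
window of known susceptibility loci; (iii) how many genes would land near
those loci by chance if placed uniformly over the genome (binomial model,
with an optional Monte-Carlo check).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .containers import LocusSet, MirGeneAnnotation
from .errors import ConfigError

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 250_000


@dataclass
class BandGroup:
    chromosome: str
    band: str
    gene_ids: list[str]

    @property
    def category(self) -> str:
        n = len(self.gene_ids)
        if n >= 3:
            return "cluster"
        return "duplex" if n == 2 else "singleton"


def group_by_band(
    annotation: list[MirGeneAnnotation],
    restrict_to: set[str] | None = None,
) -> list[BandGroup]:
    """Group miRNA genes by (chromosome, cytogenetic band).

    ``restrict_to`` filters on the miRNA id produced (the usual use: the
    dysregulated set).  Band grouping is strand-agnostic.  Groups come back
    sorted by chromosome then band.
    """
    groups: dict[tuple[str, str], list[str]] = {}
    for rec in annotation:
        if restrict_to is not None and rec.mirna_id not in restrict_to:
            continue
        groups.setdefault((rec.chromosome, rec.band), []).append(rec.gene_id)
    return [
        BandGroup(chromosome=c, band=b, gene_ids=sorted(g))
        for (c, b), g in sorted(groups.items())
    ]


def colocalize_with_loci(
    annotation: list[MirGeneAnnotation],
    loci: LocusSet,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """(gene, locus) pairs where the window-expanded gene hits a locus.

    A gene co-localizes with a locus iff [start − window, end + window]
    intersects the locus interval on the same chromosome.  Chromosome names
    present on one side only are warned about, since silent mismatches (chr1
    vs 1) would otherwise produce an empty table.
    """
    if window_bp < 0:
        raise ConfigError("window_bp must be non-negative")
    trees: dict[str, IntervalTree] = {}
    for lid, row in loci.frame.iterrows():
        # +1 on end: IntervalTree is half-open, internal coords are closed
        trees.setdefault(row["chromosome"], IntervalTree()).addi(
            int(row["start"]), int(row["end"]) + 1, lid
        )
    gene_chroms = {rec.chromosome for rec in annotation}
    locus_chroms = set(trees)
    unmatched = sorted(gene_chroms ^ locus_chroms)
    if annotation and len(loci) and not (gene_chroms & locus_chroms):
        logger.warning(
            "no shared chromosome names between annotation and loci: %s", unmatched
        )
    rows = []
    for rec in annotation:
        tree = trees.get(rec.chromosome)
        if tree is None:
            continue
        lo = max(1, rec.start - window_bp)
        hi = rec.end + window_bp + 1
        for hit in sorted(tree.overlap(lo, hi)):
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "mirna_id": rec.mirna_id,
                    "chromosome": rec.chromosome,
                    "locus_id": hit.data,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "mirna_id", "chromosome", "locus_id"])


@dataclass
class EnrichmentResult:
    observed: int
    expected: float
    fold_enrichment: float
    p_value: float
    covered_fraction: float
    mc_expected: float | None = None
    mc_draws: int = 0


def _union_length(intervals: list[tuple[int, int]], chrom_size: int) -> int:
    """Total bp covered by the union of closed intervals, clipped to the chromosome."""
    clipped = [
        (max(1, s), min(chrom_size, e)) for s, e in intervals if s <= chrom_size and e >= 1
    ]
    if not clipped:
        return 0
    clipped.sort()
    total = 0
    cur_s, cur_e = clipped[0]
    for s, e in clipped[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total


def chance_expectation(
    n_genes: int,
    loci: LocusSet,
    window_bp: int,
    genome_sizes: dict[str, int],
    observed: int,
    mc_draws: int = 0,
    seed: int = 0,
) -> EnrichmentResult:
    """How many of ``n_genes`` uniformly placed genes would hit the loci by chance.

    The window-expanded loci are unioned per chromosome before measuring, so
    overlapping or duplicated loci are never double counted.  Expected count
    = n_genes × covered fraction of the genome; the tail p-value is
    P(X ≥ observed) for X ~ Binomial(n_genes, fraction).  ``mc_draws`` > 0
    adds a Monte-Carlo estimate from random single-bp gene placements.
    """
    missing = set(loci.frame["chromosome"]) - set(genome_sizes)
    if missing:
        raise ConfigError(f"genome_sizes lacks chromosome(s): {sorted(missing)}")
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, row in loci.frame.iterrows():
        per_chrom.setdefault(row["chromosome"], []).append(
            (int(row["start"]) - window_bp, int(row["end"]) + window_bp)
        )
    genome_bp = sum(genome_sizes.values())
    covered_bp = sum(
        _union_length(iv, genome_sizes[c]) for c, iv in per_chrom.items()
    )
    fraction = covered_bp / genome_bp if genome_bp else 0.0
    expected = n_genes * fraction
    fold = observed / expected if expected > 0 else float("nan")
    p = float(stats.binom.sf(observed - 1, n_genes, fraction)) if n_genes else 1.0
    mc_expected = None
    if mc_draws > 0:
        rng = np.random.default_rng(seed)
        chroms = sorted(genome_sizes)
        sizes = np.array([genome_sizes[c] for c in chroms], dtype=float)
        trees = {
            c: sorted((max(1, s), min(genome_sizes[c], e)) for s, e in per_chrom.get(c, []))
            for c in chroms
        }
        hits = 0
        chrom_idx = rng.choice(len(chroms), size=(mc_draws, n_genes), p=sizes / sizes.sum())
        pos = rng.random((mc_draws, n_genes))
        for d in range(mc_draws):
            for g in range(n_genes):
                c = chroms[chrom_idx[d, g]]
                bp = int(pos[d, g] * genome_sizes[c]) + 1
                for s, e in trees[c]:
                    if s <= bp <= e:
                        hits += 1
                        break
        mc_expected = hits / mc_draws
    return EnrichmentResult(
        observed=observed,
        expected=float(expected),
        fold_enrichment=float(fold),
        p_value=p,
        covered_fraction=float(fraction),
        mc_expected=mc_expected,
        mc_draws=mc_draws,
    )
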