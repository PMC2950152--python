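"""Target-set logic for dysregulated miRNAs.

Given a pre-computed miRNA → gene catalog, derives (i) the union of putative
targets of a miRNA set, (ii) the *strictly down-regulated* genes — those
whose catalogued 3'-UTR interactions, within a chosen miRNA universe, involve
only over-expressed miRNAs — and (iii) raw per-biological-process counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .containers import TargetCatalog
from .errors import ConfigError

logger = logging.getLogger(__name__)

UNANNOTATED = "unannotated"


def target_genes(catalog: TargetCatalog, mirna_set: Iterable[str]) -> set[str]:
    """Union of genes with at least one catalogued interaction with the set."""
    mirna_set = set(mirna_set)
    absent = mirna_set - catalog.mirna_ids
    if absent:
        logger.warning(
            "%d miRNA(s) absent from the catalog (zero targets): %s",
            len(absent), sorted(absent),
        )
    return catalog.genes_for(mirna_set)


def strictly_downregulated(
    catalog: TargetCatalog,
    up_set: Iterable[str],
    universe: Iterable[str] | None = None,
) -> set[str]:
    """Genes targeted *only* by over-expressed miRNAs (within the universe).

    ``universe`` restricts which catalog interactions count — typically the
    measured panel, so interactions with unmeasured miRNAs cannot veto
    strictness; ``None`` uses every miRNA in the catalog.  A strict gene must
    retain at least one interaction with ``up_set``.
    """
    up_set = set(up_set)
    pairs = catalog.pairs
    if universe is not None:
        universe = set(universe)
        if not up_set <= universe:
            raise ConfigError("up_set must be a subset of the universe")
        pairs = pairs[pairs["mirna_id"].isin(universe)]
    targeted_by_up = set(pairs.loc[pairs["mirna_id"].isin(up_set), "gene_id"])
    targeted_by_other = set(pairs.loc[~pairs["mirna_id"].isin(up_set), "gene_id"])
    return targeted_by_up - targeted_by_other


@dataclass
class TargetSummary:
    """Per-process tallies of putative-target and strictly-down genes."""

    counts: pd.DataFrame  # index process; columns total_targets, strict_down
    genes_by_process: dict[str, set[str]] = field(default_factory=dict)
    strict_by_process: dict[str, set[str]] = field(default_factory=dict)


def function_summary(
    gene_set: Iterable[str],
    strict_set: Iterable[str],
    process_table: pd.DataFrame,
) -> TargetSummary:
    """Count gene-set and strict-set members per biological process.

    ``process_table`` holds one (gene_id, process) row per membership; genes
    with several processes count once in each, and genes with no row are
    tallied under ``unannotated``.
    """
    gene_set, strict_set = set(gene_set), set(strict_set)
    not_strict_targets = strict_set - gene_set
    if not_strict_targets:
        raise ConfigError(
            f"strict genes outside the target set: {sorted(not_strict_targets)}"
        )
    mapping: dict[str, set[str]] = {}
    for _, row in process_table.iterrows():
        mapping.setdefault(str(row["gene_id"]), set()).add(str(row["process"]))
    genes_by_process: dict[str, set[str]] = {}
    strict_by_process: dict[str, set[str]] = {}
    for g in gene_set:
        for proc in mapping.get(g, {UNANNOTATED}):
            genes_by_process.setdefault(proc, set()).add(g)
            if g in strict_set:
                strict_by_process.setdefault(proc, set()).add(g)
    processes = sorted(genes_by_process)
    counts = pd.DataFrame(
        {
            "total_targets": [len(genes_by_process[p]) for p in processes],
            "strict_down": [len(strict_by_process.get(p, set())) for p in processes],
        },
        index=pd.Index(processes, name="process"),
    )
    return TargetSummary(
        counts=counts,
        genes_by_process=genes_by_process,
        strict_by_process=strict_by_process,
    )
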