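"""K-means co-regulation analysis.

miRNAs whose patient-level alteration profiles move together are grouped by
k-means (k = 20 by default) independently within each disease × state
condition; a set of miRNAs repeatedly landing in one cluster across
conditions is evidence of coordinated regulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import RelExprMatrix, SampleTable
from .errors import ConfigError, FormatError

logger = logging.getLogger(__name__)

DEFAULT_K = 20


@dataclass
class ClusterAssignment:
    """Cluster labels for one condition's miRNA profiles."""

    condition: str
    labels: pd.Series  # miRNA id → label in 0..k_eff-1
    centroids: np.ndarray
    wcss: float
    k_requested: int

    @property
    def k_effective(self) -> int:
        return self.centroids.shape[0]

    def members(self, label: int) -> set[str]:
        return set(self.labels.index[self.labels == label])


def kmeans_cluster(
    rel: RelExprMatrix,
    samples: SampleTable,
    condition: str,
    k: int = DEFAULT_K,
    seed: int = 0,
    restarts: int = 10,
    standardize: bool = False,
    mirna_subset: list[str] | None = None,
) -> ClusterAssignment:
    """Cluster per-miRNA patient log-fold vectors within one condition.

    Euclidean distance on raw log-fold vectors (optionally row-standardised);
    k-means++ initialisation, best of ``restarts`` runs by within-cluster sum
    of squares, deterministic given ``seed``.  With fewer points than k the
    effective k drops to the point count, so exactly min(k, n) clusters are
    non-empty.  miRNAs with missing patient values are dropped with a warning.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    members = samples.samples_in_condition(condition)
    if not members:
        raise FormatError(f"condition {condition!r} has no samples")
    block = rel.log_fold[members]
    if mirna_subset is not None:
        block = block.loc[[m for m in mirna_subset if m in block.index]]
    complete = block.dropna(axis=0)
    n_dropped = len(block) - len(complete)
    if n_dropped:
        logger.warning(
            "%s: dropped %d miRNA(s) with missing patient values", condition, n_dropped
        )
    if complete.empty:
        raise FormatError(f"no complete miRNA profiles in condition {condition!r}")
    X = complete.to_numpy(dtype=float)
    if standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    k_eff = min(k, len(complete))
    km = KMeans(
        n_clusters=k_eff,
        init="k-means++",
        n_init=restarts,
        random_state=seed,
    ).fit(X)
    labels = pd.Series(km.labels_, index=complete.index, name="cluster")
    return ClusterAssignment(
        condition=condition,
        labels=labels,
        centroids=km.cluster_centers_,
        wcss=float(km.inertia_),
        k_requested=k,
    )


@dataclass
class CoMembershipReport:
    """How a query miRNA set distributes over clusters, per condition and jointly."""

    query: set[str]
    per_condition: dict[str, dict[int, set[str]]]  # condition → label → members
    largest_shared: dict[str, set[str]]  # condition → biggest single-cluster subset
    intersection: set[str]  # subset sharing one cluster in EVERY condition
    unassessable: set[str]  # query miRNAs absent from some assignment


def comembership(
    assignments: list[ClusterAssignment], query: set[str] | list[str]
) -> CoMembershipReport:
    """Find the query miRNAs that co-cluster within and across conditions.

    Per condition, reports the partition of the query by cluster label and the
    largest subset sharing one label.  The cross-condition subset is the
    largest group of query miRNAs whose label tuple over *all* conditions is
    identical (miRNAs missing from any assignment are unassessable).
    """
    if not assignments:
        raise FormatError("no cluster assignments supplied")
    query = set(query)
    assessable = {
        m for m in query if all(m in a.labels.index for a in assignments)
    }
    unassessable = query - assessable
    if unassessable:
        logger.warning("query miRNA(s) absent from an assignment: %s",
                       sorted(unassessable))
    per_condition: dict[str, dict[int, set[str]]] = {}
    largest_shared: dict[str, set[str]] = {}
    for a in assignments:
        groups: dict[int, set[str]] = {}
        for m in query & set(a.labels.index):
            groups.setdefault(int(a.labels[m]), set()).add(m)
        per_condition[a.condition] = groups
        largest_shared[a.condition] = (
            max(groups.values(), key=lambda s: (len(s), sorted(s))) if groups else set()
        )
    tuples: dict[tuple[int, ...], set[str]] = {}
    for m in assessable:
        key = tuple(int(a.labels[m]) for a in assignments)
        tuples.setdefault(key, set()).add(m)
    intersection = (
        max(tuples.values(), key=lambda s: (len(s), sorted(s))) if tuples else set()
    )
    return CoMembershipReport(
        query=query,
        per_condition=per_condition,
        largest_shared=largest_shared,
        intersection=intersection,
        unassessable=unassessable,
    )
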