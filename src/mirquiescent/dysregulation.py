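"""Dispersion-derived dysregulation calling.

The core statistic: per-miRNA patient-to-patient standard deviations of the
10×log10 relative expression are pooled over the four disease × state
conditions into (mean_Disp, SD_Disp); the magnitude cut-off is
|mean_Disp + 0.5·SD_Disp| — with the published dispersion of 6.3 ± 1.4 this
yields ±7, i.e. >5-fold up or <0.2-fold down.  A miRNA is *dysregulated* in a
condition when its mean log-fold exceeds the cut-off in magnitude AND a
two-sided Mann-Whitney test against healthy controls gives p ≤ alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    DISEASE_CONDITIONS,
    DysregulationCall,
    RelExprMatrix,
    SampleTable,
    split_condition,
)
from .errors import ConfigError, FormatError
from .quantify import DetectionReport

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_MULTIPLIER = 0.5
#: Largest n+m for which the exact Mann-Whitney null distribution is used.
EXACT_LIMIT = 16


# ---------------------------------------------------------------------------
# Dispersion and cut-off
# ---------------------------------------------------------------------------

@dataclass
class DispersionSummary:
    """Per-(miRNA, condition) SDs of log-fold and their pooled moments."""

    sd_mirna: pd.DataFrame  # miRNAs × conditions, NaN where skipped
    mean_disp: float
    sd_disp: float
    n_cells: int


@dataclass
class Cutoff:
    """The dysregulation threshold on the 10×log10 scale and its fold bounds."""

    cutoff: float
    mean_disp: float
    sd_disp: float
    multiplier: float

    @property
    def fold_upper(self) -> float:
        """Linear fold change implied for up-regulation (≈5 at cutoff 7)."""
        return 10.0 ** (self.cutoff / 10.0)

    @property
    def fold_lower(self) -> float:
        """Linear fold change implied for down-regulation (≈0.2 at cutoff 7)."""
        return 10.0 ** (-self.cutoff / 10.0)


def dispersion_summary(
    rel: RelExprMatrix,
    samples: SampleTable,
    conditions: tuple[str, ...] | list[str] = DISEASE_CONDITIONS,
    detection: DetectionReport | None = None,
) -> DispersionSummary:
    """Pool per-miRNA patient SDs of log-fold over the disease conditions.

    SDs use the n−1 denominator; cells with fewer than two values are skipped
    (logged at debug level).  When a detection report is supplied, only
    (miRNA, condition) pairs detected jointly with controls contribute —
    undetected miRNAs carry no interpretable relative expression.
    """
    cols = {}
    for cond in conditions:
        members = samples.samples_in_condition(cond)
        if len(members) < 2:
            raise FormatError(f"condition {cond!r} has fewer than 2 samples")
        block = rel.log_fold[members]
        sd = block.std(axis=1, ddof=1)
        sd[block.notna().sum(axis=1) < 2] = np.nan
        if detection is not None:
            mask = detection.detected(cond).reindex(sd.index, fill_value=False)
            sd = sd.where(mask)
        cols[cond] = sd
    sd_mirna = pd.DataFrame(cols)
    pooled = sd_mirna.to_numpy().ravel()
    pooled = pooled[np.isfinite(pooled)]
    n_skipped = sd_mirna.size - pooled.size
    if n_skipped:
        logger.debug("skipped %d (miRNA, condition) SD cells", n_skipped)
    if pooled.size < 1:
        raise FormatError("no usable SD values; cannot pool dispersion")
    if pooled.size == 1:
        logger.warning("single SD value pooled; SD of dispersions set to 0")
    return DispersionSummary(
        sd_mirna=sd_mirna,
        mean_disp=float(pooled.mean()),
        sd_disp=float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        n_cells=int(pooled.size),
    )


def derive_cutoff(
    mean_disp: float, sd_disp: float, multiplier: float = DEFAULT_MULTIPLIER
) -> Cutoff:
    """cutoff = |mean_Disp + multiplier·SD_Disp| on the 10×log10 scale."""
    if multiplier < 0:
        raise ConfigError("cut-off multiplier must be non-negative")
    if mean_disp < 0 or sd_disp < 0:
        raise ConfigError("dispersion moments must be non-negative")
    cutoff = abs(mean_disp + multiplier * sd_disp)
    return Cutoff(
        cutoff=cutoff, mean_disp=mean_disp, sd_disp=sd_disp, multiplier=multiplier
    )


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def mann_whitney(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of `a`, p).

    ``auto`` uses the exact null distribution when n+m ≤ 16 and the data are
    tie-free, otherwise the tie-corrected normal approximation with
    continuity correction.  Degenerate input (all values identical in both
    groups) returns p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise FormatError("mann_whitney needs at least 2 values per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        method = "exact" if (len(a) + len(b) <= EXACT_LIMIT and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        if mode == "exact" and has_ties:
            raise ConfigError("exact mode is unavailable with tied values")
        method = mode
    else:
        raise ConfigError(f"unknown mann_whitney mode {mode!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# Calling and set partitioning
# ---------------------------------------------------------------------------

def call_dysregulation(
    rel: RelExprMatrix,
    samples: SampleTable,
    cutoff: Cutoff | float,
    alpha: float = DEFAULT_ALPHA,
    detection: DetectionReport | None = None,
    conditions: tuple[str, ...] | list[str] | None = None,
    bh_correct: bool = False,
) -> list[DysregulationCall]:
    """Apply the dual magnitude + significance rule per (miRNA, condition).

    ``passes_cutoff`` requires the per-miRNA mean of patient log-folds to
    exceed the cut-off strictly in magnitude; ``significant`` additionally
    requires the Mann-Whitney p (condition vs controls, on log-fold) ≤ alpha.
    Undetected miRNAs are reported as unchanged.  No multiple-testing
    correction is applied by default (matching the raw p ≤ 0.05 procedure);
    ``bh_correct=True`` switches to Benjamini-Hochberg adjusted p-values
    within each condition.
    """
    thr = cutoff.cutoff if isinstance(cutoff, Cutoff) else float(cutoff)
    if conditions is None:
        conditions = samples.conditions_present()
    controls = samples.samples_in_group("control")
    ctl_block = rel.log_fold[controls]
    calls: list[DysregulationCall] = []
    for cond in conditions:
        members = samples.samples_in_condition(cond)
        block = rel.log_fold[members]
        detected = (
            detection.detected(cond).reindex(rel.log_fold.index, fill_value=False)
            if detection is not None
            else pd.Series(True, index=rel.log_fold.index)
        )
        cond_calls: list[DysregulationCall] = []
        for mid in rel.log_fold.index:
            vals = block.loc[mid].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            ctl = ctl_block.loc[mid].to_numpy(dtype=float)
            ctl = ctl[np.isfinite(ctl)]
            n = len(vals)
            if not detected[mid] or n < 2 or len(ctl) < 2:
                cond_calls.append(
                    DysregulationCall(
                        mirna_id=mid,
                        condition=cond,
                        mean_log_fold=float(vals.mean()) if n else float("nan"),
                        sd_log_fold=float(vals.std(ddof=1)) if n >= 2 else float("nan"),
                        direction="unchanged",
                        p_value=float("nan"),
                        passes_cutoff=False,
                        significant=False,
                        n=n,
                    )
                )
                continue
            mean_lf = float(vals.mean())
            sd_lf = float(vals.std(ddof=1))
            passes = abs(mean_lf) > thr
            _, p = mann_whitney(vals, ctl)
            direction = "unchanged"
            if passes:
                direction = "up" if mean_lf > 0 else "down"
            cond_calls.append(
                DysregulationCall(
                    mirna_id=mid,
                    condition=cond,
                    mean_log_fold=mean_lf,
                    sd_log_fold=sd_lf,
                    direction=direction,
                    p_value=p,
                    passes_cutoff=passes,
                    significant=False,  # set below, after optional BH
                    n=n,
                )
            )
        pvals = np.array([c.p_value for c in cond_calls])
        if bh_correct:
            ok = np.isfinite(pvals)
            adj = np.full_like(pvals, np.nan)
            if ok.any():
                adj[ok] = stats.false_discovery_control(pvals[ok], method="bh")
            pvals = adj
        for c, p in zip(cond_calls, pvals):
            c.significant = bool(c.passes_cutoff and np.isfinite(p) and p <= alpha)
        calls.extend(cond_calls)
    return calls


@dataclass
class VennPartition:
    """Direction-aware set algebra over the significant calls.

    Per disease: significant miRNAs specific to the quiescent state, specific
    to the inflamed state, and altered (same direction) in both states.
    Across diseases: miRNAs significantly altered in the same direction in
    quiescent UC *and* quiescent CD.
    """

    per_disease: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    common_quiescent: set[str] = field(default_factory=set)

    def summary_sizes(self) -> dict[str, int]:
        out = {}
        for disease, sets in self.per_disease.items():
            for key, members in sets.items():
                out[f"{disease}_{key}"] = len(members)
        out["common_quiescent"] = len(self.common_quiescent)
        return out


def _signed_significant(calls, condition) -> dict[str, str]:
    return {
        c.mirna_id: c.direction
        for c in calls
        if c.condition == condition and c.significant
    }


def venn_partition(calls: list[DysregulationCall]) -> VennPartition:
    """Partition significant calls by disease state and across diseases.

    Direction-aware throughout: a miRNA up in one condition and down in
    another is never "common" between them.
    """
    conditions = sorted({c.condition for c in calls})
    if len(conditions) < 2:
        raise FormatError("venn_partition needs calls for at least 2 conditions")
    diseases = sorted({split_condition(c)[0] for c in conditions})
    part = VennPartition()
    for disease in diseases:
        q = _signed_significant(calls, f"{disease}_quiescent")
        i = _signed_significant(calls, f"{disease}_inflamed")
        both = {m for m in q.keys() & i.keys() if q[m] == i[m]}
        part.per_disease[disease] = {
            "quiescent_only": set(q) - both,
            "inflamed_only": set(i) - both,
            "both": both,
        }
    if {"UC", "CD"} <= set(diseases):
        uq = _signed_significant(calls, "UC_quiescent")
        cq = _signed_significant(calls, "CD_quiescent")
        part.common_quiescent = {m for m in uq.keys() & cq.keys() if uq[m] == cq[m]}
    return part
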