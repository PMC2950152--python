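"""Comparative threshold-cycle (2^-ΔΔCT) quantification.

The chain is CT → ΔCT (normalised to the U6 small RNA within each sample) →
ΔΔCT (relative to the pooled healthy-control baseline) → fold = 2^-ΔΔCT →
log_fold = 10·log10(fold).  Equal PCR efficiency of target and reference is
assumed throughout, so no efficiency correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CtMatrix, RelExprMatrix, SampleTable
from .errors import ConfigError, FormatError

logger = logging.getLogger(__name__)

#: CT above which a reaction is treated as a false positive.
DEFAULT_CT_CUTOFF = 35.0


@dataclass
class DetectionReport:
    """Which miRNAs rise above the detection limit, per condition and overall.

    ``per_condition`` is a boolean miRNAs × conditions frame;
    ``in_controls`` a boolean Series.  A miRNA counts as detected *overall*
    for a condition only if it is detected both there and in controls, since
    relative quantification needs a measurable baseline.
    """

    per_condition: pd.DataFrame
    in_controls: pd.Series
    ct_cutoff: float
    policy: str

    def detected(self, condition: str) -> pd.Series:
        return self.per_condition[condition] & self.in_controls

    def detected_set(self, condition: str) -> set[str]:
        mask = self.detected(condition)
        return set(mask.index[mask])

    def detected_any(self) -> set[str]:
        """miRNAs detected (jointly with controls) in at least one condition."""
        out: set[str] = set()
        for cond in self.per_condition.columns:
            out |= self.detected_set(cond)
        return out


def _detected_by_policy(block: pd.DataFrame, cutoff: float, policy: str) -> pd.Series:
    # NaN wells never amplified: treat as CT at/above the cut-off.
    filled = block.fillna(np.inf)
    if policy == "median":
        return filled.median(axis=1) < cutoff
    if policy == "any":
        return (filled < cutoff).any(axis=1)
    if policy == "all":
        return (filled < cutoff).all(axis=1)
    raise ConfigError(f"unknown detection policy {policy!r}")


def detection_filter(
    ct: CtMatrix,
    samples: SampleTable,
    ct_cutoff: float = DEFAULT_CT_CUTOFF,
    conditions: list[str] | None = None,
    policy: str = "median",
) -> DetectionReport:
    """Flag miRNAs expressed above the detection limit (CT < cut-off).

    Under the default ``median`` policy a miRNA is detected in a condition iff
    its median CT across that condition's samples is below the cut-off
    (undetermined wells count as CT ≥ cut-off).  ``any``/``all`` policies are
    available for sensitivity analyses.  The reference row is excluded.
    """
    samples.validate_against(ct)
    if conditions is None:
        conditions = samples.conditions_present()
    body = ct.without_reference()
    controls = samples.samples_in_group("control")
    if not controls:
        raise FormatError("no control samples for detection baseline")
    cols = {}
    for cond in conditions:
        members = samples.samples_in_condition(cond)
        if not members:
            raise FormatError(f"condition {cond!r} has no samples")
        cols[cond] = _detected_by_policy(body[members], ct_cutoff, policy)
    per_condition = pd.DataFrame(cols, index=body.index)
    in_controls = _detected_by_policy(body[controls], ct_cutoff, policy)
    return DetectionReport(
        per_condition=per_condition,
        in_controls=in_controls,
        ct_cutoff=ct_cutoff,
        policy=policy,
    )


def delta_ct(ct: CtMatrix, reference_id: str | None = None) -> pd.DataFrame:
    """ΔCT = CT(miRNA, sample) − CT(reference, sample); NaN wells propagate."""
    ref_id = reference_id or ct.reference_id
    if ref_id not in ct.values.index:
        raise FormatError(f"reference row {ref_id!r} absent")
    ref = ct.values.loc[ref_id]
    missing = ref.index[ref.isna()]
    if len(missing):
        raise FormatError(
            f"reference {ref_id!r} has no CT in sample(s): {list(missing)}"
        )
    return ct.values.drop(index=ref_id).sub(ref, axis=1)


def relative_expression(
    dct: pd.DataFrame,
    samples: SampleTable,
    control_group: str = "control",
    baseline: str = "mean",
) -> RelExprMatrix:
    """ΔΔCT against the pooled control baseline, plus fold and log-fold.

    The baseline is the arithmetic mean (Livak convention; ``median``
    available) of control-sample ΔCTs per miRNA.  miRNAs with fewer than two
    control ΔCT values are excluded and logged rather than aborting the run.
    """
    controls = samples.samples_in_group(control_group)
    if len(controls) < 2:
        raise FormatError(
            f"need >=2 samples in control group {control_group!r}, got {len(controls)}"
        )
    ctl = dct[controls]
    n_ok = ctl.notna().sum(axis=1)
    keep = n_ok >= 2
    dropped = list(dct.index[~keep])
    if dropped:
        logger.warning(
            "%d miRNA(s) lack a control baseline (fewer than 2 control "
            "values) and were excluded: %s%s",
            len(dropped),
            ", ".join(dropped[:5]),
            "..." if len(dropped) > 5 else "",
        )
    dct = dct.loc[keep]
    if baseline == "mean":
        base = dct[controls].mean(axis=1)
    elif baseline == "median":
        base = dct[controls].median(axis=1)
    else:
        raise ConfigError(f"unknown baseline {baseline!r}")
    ddct = dct.sub(base, axis=0)
    fold = np.power(2.0, -ddct)
    log_fold = 10.0 * np.log10(fold)
    return RelExprMatrix(
        delta_ct=dct,
        delta_delta_ct=ddct,
        fold=fold,
        log_fold=log_fold,
        control_sample_ids=controls,
    )
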