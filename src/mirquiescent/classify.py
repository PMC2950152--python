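"""Marker scoring, panel assembly and KNN leave-one-out class prediction.

Discriminating miRNAs are ranked by a signal-to-noise score on log-fold
values; a panel (forced markers plus the top-ranked remainder) feeds a
k-nearest-neighbour classifier evaluated in leave-one-out cross-validation,
the per-sample confidence being the winning share of the neighbour weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import RelExprMatrix, SampleTable, condition_label
from .errors import ConfigError, FormatError

#: The six miRNAs with significantly distinct alteration in quiescent UC vs CD,
#: used as the default forced marker set.
DEFAULT_FORCED_MARKERS = (
    "mir-150",
    "mir-196b",
    "mir-199a-3p",
    "mir-199b-5p",
    "mir-223",
    "mir-320a",
)

_EPS = 1e-9  # distance-weighting regulariser


@dataclass
class MarkerScore:
    mirna_id: str
    score: float
    rank: int


@dataclass
class Prediction:
    sample_id: str
    true_class: str
    predicted_class: str
    confidence: float
    correct: bool


@dataclass
class ClassificationResult:
    predictions: list[Prediction]
    accuracy: float
    panel: list[str]
    k: int
    weighting: str


def _class_blocks(
    rel: RelExprMatrix,
    samples: SampleTable,
    class_a: str,
    class_b: str,
    state: str = "quiescent",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    sa = samples.samples_in_condition(condition_label(class_a, state))
    sb = samples.samples_in_condition(condition_label(class_b, state))
    if len(sa) < 2 or len(sb) < 2:
        raise FormatError(
            f"need >=2 samples per class; got {len(sa)} {class_a}, {len(sb)} {class_b}"
        )
    return rel.log_fold[sa], rel.log_fold[sb]


def score_markers(
    rel: RelExprMatrix,
    samples: SampleTable,
    class_a: str = "UC",
    class_b: str = "CD",
    state: str = "quiescent",
) -> list[MarkerScore]:
    """Signal-to-noise marker scores: (μ_a − μ_b) / (σ_a + σ_b) on log-fold.

    Each class SD (n−1 denominator) is floored at max(0.2·|μ|, 0.2), the
    usual guard against vanishing within-class variance.  Markers are ranked
    by |score| descending, ties broken by miRNA id; miRNAs with missing
    values in either class are skipped.
    """
    a, b = _class_blocks(rel, samples, class_a, class_b, state)
    scores = []
    for mid in rel.log_fold.index:
        xa = a.loc[mid].to_numpy(dtype=float)
        xb = b.loc[mid].to_numpy(dtype=float)
        if np.isnan(xa).any() or np.isnan(xb).any():
            continue
        mu_a, mu_b = xa.mean(), xb.mean()
        sd_a = max(xa.std(ddof=1), 0.2 * abs(mu_a), 0.2)
        sd_b = max(xb.std(ddof=1), 0.2 * abs(mu_b), 0.2)
        scores.append((mid, (mu_a - mu_b) / (sd_a + sd_b)))
    scores.sort(key=lambda t: (-abs(t[1]), t[0]))
    return [
        MarkerScore(mirna_id=mid, score=float(s), rank=r)
        for r, (mid, s) in enumerate(scores, start=1)
    ]


def select_markers(
    scores: list[MarkerScore],
    forced: set[str] | list[str] | tuple[str, ...] = (),
    n_additional: int = 9,
) -> list[str]:
    """Panel = forced markers ∪ top ``n_additional`` scored markers not already forced."""
    forced = list(dict.fromkeys(forced))
    scored_ids = [s.mirna_id for s in scores]
    missing = set(forced) - set(scored_ids)
    if missing:
        raise FormatError(f"forced marker(s) not scoreable: {sorted(missing)}")
    extra = [m for m in scored_ids if m not in set(forced)]
    if n_additional > len(extra):
        raise ConfigError(
            f"requested {n_additional} additional markers, only {len(extra)} available"
        )
    return forced + extra[:n_additional]


def knn_loocv(
    rel: RelExprMatrix,
    samples: SampleTable,
    panel: list[str],
    classes: tuple[str, str] = ("UC", "CD"),
    state: str = "quiescent",
    k: int = 3,
    weighting: str = "distance",
) -> ClassificationResult:
    """Leave-one-out KNN prediction of disease class from a marker panel.

    Features are the panel's log-folds, z-scored with training-fold statistics
    only.  Neighbour weights are 1/(d+ε) (``distance``) or 1 (``uniform``);
    the predicted class takes the larger summed weight, an exact tie falling
    back to the single nearest neighbour.  Confidence is the winning weight
    share, in (0, 1].
    """
    if weighting not in ("distance", "uniform"):
        raise ConfigError(f"unknown weighting {weighting!r}")
    sample_ids: list[str] = []
    labels: list[str] = []
    for cls in classes:
        for sid in samples.samples_in_condition(condition_label(cls, state)):
            sample_ids.append(sid)
            labels.append(cls)
    # canonical sample order, so predictions are invariant to input ordering
    pairs = sorted(zip(sample_ids, labels))
    sample_ids = [p[0] for p in pairs]
    labels = [p[1] for p in pairs]
    n = len(sample_ids)
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k >= n:
        raise ConfigError(f"k={k} must be smaller than the sample count {n}")
    missing_panel = [m for m in panel if m not in rel.log_fold.index]
    if missing_panel:
        raise FormatError(f"panel miRNA(s) absent from expression: {missing_panel}")
    X = rel.log_fold.loc[list(panel), sample_ids].to_numpy(dtype=float).T
    if np.isnan(X).any():
        raise FormatError("panel features contain missing values")
    y = np.array(labels)
    preds: dict[str, Prediction] = {}
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        d = np.linalg.norm(Z[train] - Z[i], axis=1)
        nn = np.argsort(d, kind="stable")[:k]
        w = 1.0 / (d[nn] + _EPS) if weighting == "distance" else np.ones(k)
        y_train = y[train]
        weight_by_class = {c: float(w[y_train[nn] == c].sum()) for c in classes}
        total = sum(weight_by_class.values())
        best = max(classes, key=lambda c: weight_by_class[c])
        tie = len({round(v, 12) for v in weight_by_class.values()}) == 1
        if tie:
            best = y_train[nn[0]]  # nearest single neighbour breaks the tie
            confidence = 0.5
        else:
            confidence = weight_by_class[best] / total
        preds[sample_ids[i]] = Prediction(
            sample_id=sample_ids[i],
            true_class=y[i],
            predicted_class=best,
            confidence=confidence,
            correct=bool(best == y[i]),
        )
    ordered = [preds[s] for s in sample_ids]
    accuracy = float(np.mean([p.correct for p in ordered]))
    return ClassificationResult(
        predictions=ordered,
        accuracy=accuracy,
        panel=list(panel),
        k=k,
        weighting=weighting,
    )
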