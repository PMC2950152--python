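"""Independent brute-force oracles, kept free of the package's code paths."""

import itertools
import math


def mw_enumeration(a, b):
    """Two-sided exact Mann-Whitney by exhaustive enumeration of all
    C(n+m, n) group assignments of the pooled (tie-free) values."""
    pooled = sorted(a) + sorted(b)
    n = len(a)

    def u_stat(group_a):
        group_b = [v for v in pooled if v not in group_a]
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = sum(1 for x in a for y in b if x > y)
    us = [u_stat(c) for c in itertools.combinations(pooled, n)]
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


def loocv_oracle(features, labels, k, weighting="distance"):
    """Brute-force fold-by-fold KNN with train-fold z-scoring, no numpy.

    features: sample_id -> feature list; labels: sample_id -> class.
    Returns sample_id -> (predicted class, confidence).
    """
    sids = sorted(features)
    preds = {}
    for left_out in sids:
        train = [s for s in sids if s != left_out]
        dim = len(features[left_out])
        mus, sds = [], []
        for j in range(dim):
            col = [features[s][j] for s in train]
            mu = sum(col) / len(col)
            var = sum((v - mu) ** 2 for v in col) / (len(col) - 1)
            sd = math.sqrt(var) or 1.0
            mus.append(mu)
            sds.append(sd)
        z = {
            s: [(features[s][j] - mus[j]) / sds[j] for j in range(dim)]
            for s in sids
        }
        dists = sorted((math.dist(z[left_out], z[s]), s) for s in train)
        nn = dists[:k]
        wsum = {}
        for d, s in nn:
            w = 1.0 / (d + 1e-9) if weighting == "distance" else 1.0
            wsum[labels[s]] = wsum.get(labels[s], 0.0) + w
        best = max(sorted(wsum), key=lambda c: wsum[c])
        total = sum(wsum.values())
        preds[left_out] = (best, wsum[best] / total)
    return preds
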