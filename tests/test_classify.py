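import math

import numpy as np
import pandas as pd
import pytest

from mirquiescent import knn_loocv, score_markers, select_markers
from mirquiescent.classify import MarkerScore
from mirquiescent.errors import ConfigError

from conftest import make_samples, rel_from_log_fold


def _rel_two_classes(profiles: dict[str, tuple[list[float], list[float]]]):
    """miRNA → (UC patient values, CD patient values) on quiescent biopsies."""
    n_uc = len(next(iter(profiles.values()))[0])
    n_cd = len(next(iter(profiles.values()))[1])
    samples = make_samples(n_controls=2, n_uc=n_uc, n_cd=n_cd)
    cols = ["C0", "C1"] + [f"UC{i}_Q" for i in range(n_uc)] + [
        f"CD{i}_Q" for i in range(n_cd)
    ]
    rows = {
        m: [0.0, 0.0] + list(uc) + list(cd) for m, (uc, cd) in profiles.items()
    }
    lf = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return rel_from_log_fold(lf, ["C0", "C1"]), samples


from oracles import loocv_oracle


class TestScoreMarkers:
    def test_identical_distributions_score_zero(self):
        rel, samples = _rel_two_classes({"m1": ([1.0, 3.0], [1.0, 3.0])})
        (s,) = score_markers(rel, samples)
        assert s.score == pytest.approx(0.0)

    def test_signal_to_noise_formula(self):
        rel, samples = _rel_two_classes({"m1": ([1.0, 3.0], [-1.0, -3.0])})
        (s,) = score_markers(rel, samples)
        assert s.score == pytest.approx(4 / (2 * math.sqrt(2)))

    def test_sign_flips_when_classes_swap(self):
        rel, samples = _rel_two_classes({"m1": ([1.0, 3.0], [-1.0, -3.0])})
        (fwd,) = score_markers(rel, samples, "UC", "CD")
        (rev,) = score_markers(rel, samples, "CD", "UC")
        assert fwd.score == pytest.approx(-rev.score)

    def test_sd_floor_guards_tight_classes(self):
        # within-class SD ~0 → denominator floored at 0.2·|mean|
        rel, samples = _rel_two_classes({"m1": ([10.0, 10.0], [-10.0, -10.0])})
        (s,) = score_markers(rel, samples)
        assert s.score == pytest.approx(20 / (2 + 2))

    def test_ranking_by_absolute_score(self):
        rel, samples = _rel_two_classes(
            {
                "weak": ([0.5, 1.0], [0.0, 0.3]),
                "strong_dn": ([-9.0, -11.0], [9.0, 11.0]),
            }
        )
        scores = score_markers(rel, samples)
        assert scores[0].mirna_id == "strong_dn" and scores[0].rank == 1


class TestSelectMarkers:
    def _scores(self, n=20):
        return [MarkerScore(f"m{i:02d}", float(n - i), i + 1) for i in range(n)]

    def test_forced_plus_additional(self):
        panel = select_markers(self._scores(), forced=["m10", "m11"], n_additional=9)
        assert len(panel) == 11
        assert panel[:2] == ["m10", "m11"]
        assert panel[2:] == [f"m{i:02d}" for i in range(9)]

    def test_forced_member_in_top_not_double_counted(self):
        panel = select_markers(self._scores(), forced=["m00"], n_additional=3)
        assert panel == ["m00", "m01", "m02", "m03"]

    def test_zero_additional_returns_forced(self):
        assert select_markers(self._scores(), forced=["m05"], n_additional=0) == ["m05"]

    def test_too_many_additional_rejected(self):
        with pytest.raises(ConfigError):
            select_markers(self._scores(5), forced=[], n_additional=6)


class TestKnnLoocv:
    def test_separable_clouds_all_correct_full_confidence(self):
        profiles = {
            "m1": ([10.0, 10.1, 10.2, 9.9], [-10.0, -10.1, -9.9, -10.2]),
            "m2": ([5.0, 5.1, 4.9, 5.2], [-5.0, -5.1, -4.9, -5.2]),
        }
        rel, samples = _rel_two_classes(profiles)
        res = knn_loocv(rel, samples, ["m1", "m2"], k=1)
        assert res.accuracy == 1.0
        assert all(p.confidence == 1.0 for p in res.predictions)

    def test_odd_k_uniform_confidence_above_half(self):
        rng = np.random.default_rng(4)
        profiles = {
            f"m{j}": (list(rng.normal(3, 2, 6)), list(rng.normal(-3, 2, 6)))
            for j in range(4)
        }
        rel, samples = _rel_two_classes(profiles)
        res = knn_loocv(rel, samples, list(profiles), k=3, weighting="uniform")
        for p in res.predictions:
            assert 0.5 < p.confidence <= 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        profiles = {
            f"m{j}": (list(rng.normal(1.5, 2, 8)), list(rng.normal(-1.5, 2, 8)))
            for j in range(5)
        }
        rel, samples = _rel_two_classes(profiles)
        panel = sorted(profiles)
        for weighting in ("distance", "uniform"):
            res = knn_loocv(rel, samples, panel, k=3, weighting=weighting)
            feats = {
                s: [rel.log_fold.loc[m, s] for m in panel]
                for p in res.predictions
                for s in [p.sample_id]
            }
            labels = {
                p.sample_id: p.true_class for p in res.predictions
            }
            oracle = loocv_oracle(feats, labels, k=3, weighting=weighting)
            for p in res.predictions:
                o_cls, o_conf = oracle[p.sample_id]
                assert p.predicted_class == o_cls
                assert p.confidence == pytest.approx(o_conf, abs=1e-6)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        profiles = {
            f"m{j}": (list(rng.normal(2, 2, 5)), list(rng.normal(-2, 2, 5)))
            for j in range(3)
        }
        rel, samples = _rel_two_classes(profiles)
        res1 = knn_loocv(rel, samples, sorted(profiles), k=3)
        # permute the column order of the expression matrix
        perm = list(rng.permutation(rel.log_fold.columns))
        rel2 = rel
        rel2.log_fold = rel.log_fold[perm]
        res2 = knn_loocv(rel2, samples, sorted(profiles), k=3)
        assert [
            (p.sample_id, p.predicted_class, round(p.confidence, 9))
            for p in res1.predictions
        ] == [
            (p.sample_id, p.predicted_class, round(p.confidence, 9))
            for p in res2.predictions
        ]

    def test_k_not_smaller_than_n_rejected(self):
        rel, samples = _rel_two_classes({"m1": ([1.0, 2.0], [3.0, 4.0])})
        with pytest.raises(ConfigError):
            knn_loocv(rel, samples, ["m1"], k=4)
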