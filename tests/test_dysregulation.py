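import math

import numpy as np
import pandas as pd
import pytest

from mirquiescent import (
    DysregulationCall,
    call_dysregulation,
    derive_cutoff,
    dispersion_summary,
    mann_whitney,
    venn_partition,
)
from mirquiescent.errors import ConfigError, FormatError

from conftest import make_samples, rel_from_log_fold


from oracles import mw_enumeration


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        u, p = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_same_multiset_symmetric(self):
        _, p = mann_whitney([1, 5, 9], [1, 5, 9])
        assert p == 1.0

    @pytest.mark.parametrize("n,m", [(2, 2), (2, 3), (3, 3), (3, 4), (4, 4), (5, 5), (4, 6)])
    def test_exact_matches_enumeration_oracle(self, n, m):
        rng = np.random.default_rng(100 * n + m)
        for _ in range(20):
            vals = rng.permutation(rng.normal(size=n + m))
            a, b = list(vals[:n]), list(vals[n:])
            u, p = mann_whitney(a, b, mode="exact")
            u_or, p_or = mw_enumeration(a, b)
            assert u == u_or
            assert p == pytest.approx(p_or, abs=1e-12)

    def test_exact_and_normal_approx_agree(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            a = rng.normal(size=8)
            b = rng.normal(0.5, 1, size=8)
            _, p_ex = mann_whitney(a, b, mode="exact")
            _, p_as = mann_whitney(a, b, mode="asymptotic")
            assert abs(p_ex - p_as) < 0.02

    def test_ties_fall_back_to_asymptotic(self):
        a = [1, 1, 2, 3]
        b = [2, 2, 3, 4]
        _, p = mann_whitney(a, b)  # auto mode must not crash on ties
        assert 0 < p <= 1
        with pytest.raises(ConfigError):
            mann_whitney(a, b, mode="exact")

    def test_tiny_groups_rejected(self):
        with pytest.raises(FormatError):
            mann_whitney([1], [2, 3])


class TestDispersion:
    def _rel(self, uc_values):
        samples = make_samples(n_controls=2, n_uc=len(uc_values))
        uc_cols = [f"UC{i}_Q" for i in range(len(uc_values))]
        lf = pd.DataFrame(
            {"C0": [0.0], "C1": [0.0], **{c: [v] for c, v in zip(uc_cols, uc_values)}},
            index=["mir-x"],
        )
        return rel_from_log_fold(lf, ["C0", "C1"]), samples

    def test_identical_values_have_zero_sd(self):
        rel, samples = self._rel([5.0, 5.0, 5.0])
        d = dispersion_summary(rel, samples, conditions=["UC_quiescent"])
        assert d.sd_mirna.loc["mir-x", "UC_quiescent"] == 0.0

    def test_sample_sd_uses_n_minus_one(self):
        rel, samples = self._rel([4.0, 8.0])
        d = dispersion_summary(rel, samples, conditions=["UC_quiescent"])
        assert d.sd_mirna.loc["mir-x", "UC_quiescent"] == pytest.approx(math.sqrt(8))

    def test_pooled_moments(self):
        samples = make_samples(n_controls=2, n_uc=2, n_cd=2)
        # two miRNAs: per-condition SDs are 5 (UC) and 9 (CD) for mir-a,
        # NaN elsewhere via missing values
        lf = pd.DataFrame(
            {
                "C0": [0.0, 0.0],
                "C1": [0.0, 0.0],
                "UC0_Q": [0.0, np.nan],
                "UC1_Q": [5 * math.sqrt(2), np.nan],
                "CD0_Q": [np.nan, 0.0],
                "CD1_Q": [np.nan, 9 * math.sqrt(2)],
            },
            index=["mir-a", "mir-b"],
        )
        rel = rel_from_log_fold(lf, ["C0", "C1"])
        d = dispersion_summary(
            rel, samples, conditions=["UC_quiescent", "CD_quiescent"]
        )
        assert d.n_cells == 2
        assert d.mean_disp == pytest.approx(7.0)
        assert d.sd_disp == pytest.approx(math.sqrt(8))


class TestCutoff:
    def test_published_dispersion_gives_seven(self):
        cut = derive_cutoff(6.3, 1.4, 0.5)
        assert cut.cutoff == pytest.approx(7.0, abs=1e-12)
        assert cut.fold_upper == pytest.approx(10 ** 0.7, rel=1e-12)
        assert cut.fold_upper > 5.0
        assert cut.fold_lower == pytest.approx(10 ** -0.7, rel=1e-12)
        assert cut.fold_lower < 0.2

    @pytest.mark.parametrize(
        "mean,sd,mult,expected", [(0.0, 0.0, 0.5, 0.0), (5.0, 2.0, 0.5, 6.0)]
    )
    def test_arithmetic(self, mean, sd, mult, expected):
        assert derive_cutoff(mean, sd, mult).cutoff == pytest.approx(expected)

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ConfigError):
            derive_cutoff(6.3, 1.4, -1.0)


class TestCalling:
    def _rel_and_samples(self, uc_mean, spread=0.5, n_uc=5, n_ctl=5):
        samples = make_samples(n_controls=n_ctl, n_uc=n_uc)
        rng = np.random.default_rng(0)
        ctl_cols = [f"C{i}" for i in range(n_ctl)]
        uc_cols = [f"UC{i}_Q" for i in range(n_uc)]
        ctl_vals = rng.normal(0, spread, n_ctl)
        uc_vals = uc_mean + rng.normal(0, spread, n_uc)
        lf = pd.DataFrame(
            [list(ctl_vals) + list(uc_vals)], index=["mir-x"], columns=ctl_cols + uc_cols
        )
        return rel_from_log_fold(lf, ctl_cols), samples

    def test_large_shift_called_up_significant(self):
        rel, samples = self._rel_and_samples(uc_mean=9.0)
        (call,) = call_dysregulation(rel, samples, cutoff=7.0)
        assert call.direction == "up" and call.passes_cutoff and call.significant

    def test_magnitude_without_significance(self):
        # one extreme patient drives the mean over the cut-off, p stays high
        samples = make_samples(n_controls=4, n_uc=4)
        lf = pd.DataFrame(
            [[0.0, 0.5, -0.5, 0.0, 40.0, 0.2, -0.1, 0.3]],
            index=["mir-x"],
            columns=samples.sample_ids,
        )
        rel = rel_from_log_fold(lf, [f"C{i}" for i in range(4)])
        (call,) = call_dysregulation(rel, samples, cutoff=7.0)
        assert call.passes_cutoff and not call.significant
        assert call.direction == "up"

    def test_strictly_below_cutoff_is_unchanged(self):
        rel, samples = self._rel_and_samples(uc_mean=3.0, spread=0.01)
        (call,) = call_dysregulation(rel, samples, cutoff=7.0)
        assert not call.passes_cutoff and call.direction == "unchanged"

    def test_raising_cutoff_never_adds_calls(self, default_rel):
        rel, samples, det = default_rel
        lo = call_dysregulation(rel, samples, cutoff=5.0, detection=det)
        hi = call_dysregulation(rel, samples, cutoff=9.0, detection=det)
        sig_lo = {(c.mirna_id, c.condition) for c in lo if c.significant}
        sig_hi = {(c.mirna_id, c.condition) for c in hi if c.significant}
        assert sig_hi <= sig_lo

    def test_invalid_direction_combination_rejected(self):
        with pytest.raises(FormatError):
            DysregulationCall("m", "UC_quiescent", 9.0, 1.0, "up", 0.01, False, True, 8)


class TestVenn:
    def _call(self, mirna, condition, direction, significant=True):
        mean = 9.0 if direction == "up" else -9.0
        return DysregulationCall(
            mirna, condition, mean, 1.0, direction, 0.01, True, significant, 8
        )

    def test_common_requires_same_direction(self):
        calls = [
            self._call("mir-1", "UC_quiescent", "up"),
            self._call("mir-1", "CD_quiescent", "up"),
            self._call("mir-2", "UC_quiescent", "up"),
            self._call("mir-2", "CD_quiescent", "down"),
            self._call("mir-3", "UC_quiescent", "up"),
        ]
        part = venn_partition(calls)
        assert part.common_quiescent == {"mir-1"}
        assert "mir-3" in part.per_disease["UC"]["quiescent_only"]

    def test_within_disease_state_partition(self):
        calls = [
            self._call("mir-1", "UC_quiescent", "up"),
            self._call("mir-1", "UC_inflamed", "up"),
            self._call("mir-2", "UC_quiescent", "down"),
            self._call("mir-3", "UC_inflamed", "up"),
            self._call("mir-4", "UC_quiescent", "up"),
            self._call("mir-4", "UC_inflamed", "down"),  # direction flip: not "both"
        ]
        part = venn_partition(calls)
        uc = part.per_disease["UC"]
        assert uc["both"] == {"mir-1"}
        assert uc["quiescent_only"] == {"mir-2", "mir-4"}
        assert uc["inflamed_only"] == {"mir-3", "mir-4"}

    def test_only_significant_calls_enter_sets(self):
        calls = [
            self._call("mir-1", "UC_quiescent", "up", significant=False),
            self._call("mir-2", "CD_quiescent", "up"),
        ]
        part = venn_partition(calls)
        assert part.common_quiescent == set()
        assert part.per_disease["UC"]["quiescent_only"] == set()
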