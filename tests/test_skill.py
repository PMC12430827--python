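"""GOALS labelling, Mann-Whitney U vs the permutation oracle, group comparison."""

import itertools

import numpy as np
import pytest

from surgikit import (
    GoalsSheet,
    StitchKinematics,
    ValidationError,
    compare_groups,
    label_proficiency,
    mann_whitney_u,
    summarize_metric,
)
from surgikit.skill import NON_PROFICIENT, PROFICIENT

from oracles import permutation_p_two_sided


class TestGoals:
    def test_mean_over_raters_and_cutoff(self):
        # three raters totalling 15, 16, 17 -> mean 16 -> proficient
        sheet = GoalsSheet("v", ((4, 4, 4, 3), (4, 4, 4, 4), (5, 4, 4, 4)))
        assert sheet.rater_totals == (15, 16, 17)
        lab = label_proficiency(sheet)
        assert lab.mean_score == 16 and lab.group == PROFICIENT

    def test_floor_of_range(self):
        lab = label_proficiency(GoalsSheet("v", ((1, 1, 1, 1),)))
        assert lab.mean_score == 4 and lab.group == NON_PROFICIENT

    def test_boundary_score_is_proficient(self):
        # rater totals 11, 12, 13 -> mean exactly 12 -> proficient under >=
        sheet = GoalsSheet("v", ((3, 3, 3, 2), (3, 3, 3, 3), (4, 3, 3, 3)))
        assert sheet.mean_score == 12
        assert label_proficiency(sheet).group == PROFICIENT

    def test_out_of_range_facet_rejected(self):
        with pytest.raises(ValidationError):
            GoalsSheet("v", ((0, 3, 3, 3),))
        with pytest.raises(ValidationError):
            GoalsSheet("v", ((6, 3, 3, 3),))

    def test_monotone_in_every_facet(self):
        base = ((2, 3, 3, 3),)
        base_score = label_proficiency(GoalsSheet("v", base)).mean_score
        for facet in range(4):
            bumped = list(base[0])
            bumped[facet] += 1
            score = label_proficiency(GoalsSheet("v", (tuple(bumped),))).mean_score
            assert score > base_score


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0

    def test_identical_samples_u_half(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.u_statistic == 4.5  # n^2 / 2

    def test_u_sum_identity_with_ties(self, rng):
        for _ in range(20):
            a = rng.integers(0, 5, size=8).tolist()
            b = rng.integers(0, 5, size=6).tolist()
            u_a = mann_whitney_u(a, b).u_statistic
            u_b = mann_whitney_u(b, a).u_statistic
            assert u_a + u_b == pytest.approx(len(a) * len(b))

    def test_degenerate_input(self):
        res = mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.degenerate and res.p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])

    def test_exact_p_matches_permutation_oracle(self, rng):
        """Exact p equals full enumeration for tie-free samples, n <= 10."""
        for n_a, n_b in [(3, 2), (4, 4), (5, 5), (2, 7), (5, 3)]:
            for _ in range(10):
                pooled = rng.permutation(100)[: n_a + n_b].astype(float)
                a, b = pooled[:n_a].tolist(), pooled[n_a:].tolist()
                res = mann_whitney_u(a, b)
                assert res.method == "exact"
                assert res.p_value == pytest.approx(permutation_p_two_sided(a, b))

    def test_u_invariant_under_monotone_transform(self, rng):
        for _ in range(10):
            a = rng.uniform(0, 10, 7).tolist()
            b = rng.uniform(0, 10, 9).tolist()
            base = mann_whitney_u(a, b)
            for f in (np.exp, lambda x: x**3, lambda x: 5 * x - 2):
                res = mann_whitney_u(f(np.array(a)).tolist(), f(np.array(b)).tolist())
                assert res.u_statistic == pytest.approx(base.u_statistic)

    def test_null_calibration(self, rng):
        """Type-I error at alpha=0.05 within 3 SE of 0.05 under the null."""
        n_sim, alpha = 2000, 0.05
        rejections = 0
        for _ in range(n_sim):
            a = rng.normal(size=20)
            b = rng.normal(size=12)
            if mann_whitney_u(a, b).p_value < alpha:
                rejections += 1
        rate = rejections / n_sim
        se = (alpha * (1 - alpha) / n_sim) ** 0.5
        assert abs(rate - alpha) <= 3 * se


class TestSummarize:
    def test_linear_interpolation_quartiles(self):
        s = summarize_metric([1, 2, 3, 4, 5])
        assert (s.median, s.q1, s.q3, s.iqr) == (3, 2, 4, 2)

    def test_single_and_constant(self):
        s = summarize_metric([7.0])
        assert (s.median, s.q1, s.q3, s.iqr) == (7, 7, 7, 0)
        assert summarize_metric([3, 3, 3, 3]).iqr == 0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize_metric([])


def _kin(video, stitch, path, time, cls=4):
    return StitchKinematics(video, stitch, cls, path, time, path / time)


def _labels(groups):
    from surgikit import ProficiencyLabel

    return [
        ProficiencyLabel(v, 16.0 if g == PROFICIENT else 6.0, g, 12.0)
        for v, g in groups.items()
    ]


class TestCompareGroups:
    def test_known_effect_detected(self, rng):
        # proficient stochastically shorter paths / times, higher velocity
        kin = []
        for i in range(40):
            kin.append(_kin("p", i, float(rng.normal(500, 50)), int(rng.normal(100, 8))))
            kin.append(_kin("n", i, float(rng.normal(900, 80)), int(rng.normal(180, 15))))
        labels = _labels({"p": PROFICIENT, "n": NON_PROFICIENT})
        out = compare_groups(kin, labels)
        assert len(out) == 3
        by_metric = {c.metric: c for c in out}
        assert by_metric["path_length"].direction == "proficient_lower"
        assert by_metric["moving_time"].direction == "proficient_lower"
        assert by_metric["velocity"].direction == "proficient_higher"
        assert all(c.significant for c in out)
        assert by_metric["path_length"].proficient.n == 40

    def test_identical_groups_not_significant(self):
        values = [(float(100 + 7 * i % 40), 10 + i % 5) for i in range(20)]
        kin = [_kin("p", i, p, t) for i, (p, t) in enumerate(values)]
        kin += [_kin("n", i, p, t) for i, (p, t) in enumerate(values)]
        out = compare_groups(kin, _labels({"p": PROFICIENT, "n": NON_PROFICIENT}))
        assert not any(c.significant for c in out)

    def test_group_sizes_reported(self, rng):
        kin = [_kin("p", i, 100.0 + i, 10) for i in range(62)]
        kin += [_kin("n", i, 200.0 + i, 20) for i in range(28)]
        out = compare_groups(kin, _labels({"p": PROFICIENT, "n": NON_PROFICIENT}))
        assert out[0].proficient.n == 62 and out[0].non_proficient.n == 28

    def test_missing_label_rejected(self):
        kin = [_kin("p", 1, 100.0, 10), _kin("x", 1, 100.0, 10)]
        with pytest.raises(ValidationError, match="x"):
            compare_groups(kin, _labels({"p": PROFICIENT}))

    def test_empty_group_rejected(self):
        kin = [_kin("p", i, 100.0, 10) for i in range(5)]
        with pytest.raises(ValidationError, match="non_proficient"):
            compare_groups(kin, _labels({"p": PROFICIENT, "n": NON_PROFICIENT}))
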