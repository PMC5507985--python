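"""Statistical kernels and screens, checked against hand-written oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mirdegrade.model import ValidationError
from mirdegrade.preprocess import detection_filter, glog_normalize
from mirdegrade.simulate import SimConfig, simulate_timecourse
from mirdegrade.stats import (
    bh_adjust,
    correlation_screen,
    detected_counts_by_era,
    differential_expression,
    pearson,
    wmw_test,
)
from mirdegrade.model import MiRBaseAnnotation
from conftest import make_matrix


# ---------------------------------------------------------------------------
# oracles


def wmw_enumeration_p(a, b):
    """Exact two-sided p by enumerating every group assignment of the pooled
    values (symmetric-tail count), assuming no ties."""
    pooled = list(a) + list(b)
    m, n = len(a), len(b)
    center = m * n / 2.0

    obs = 0
    for x in a:
        for y in b:
            if x > y:
                obs += 1
    dev = abs(obs - center)
    count = 0
    total = 0
    for comb in itertools.combinations(range(m + n), m):
        grp = [pooled[i] for i in comb]
        rest = [pooled[i] for i in range(m + n) if i not in comb]
        u = sum(1 for x in grp for y in rest if x > y)
        total += 1
        if abs(u - center) >= dev - 1e-12:
            count += 1
    return count / total


def bh_stepup_oracle(p):
    """Direct step-up formula: p_(i) * m / i with cumulative min from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# kernels


class TestPearson:
    def test_perfect_positive_and_negative(self):
        assert pearson([1, 2, 3], [2, 4, 6])[0] == pytest.approx(1.0)
        assert pearson([1, 2, 3], [6, 4, 2])[0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, p = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_matches_closed_form_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            r, _ = pearson(x, y)
            # oracle: covariance / product of SDs
            expected = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            pearson([1, 2], [3, 4])


class TestWMW:
    def test_separated_groups_exact_p(self):
        u, p = wmw_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_full_ties_give_p_1(self):
        _, p = wmw_test([5.0] * 10, [5.0] * 10)
        assert p == pytest.approx(1.0)

    def test_exact_p_equals_enumeration_5_plus_5(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            pooled = rng.permutation(np.arange(10, dtype=float) + 1)
            a, b = pooled[:5], pooled[5:]
            _, p = wmw_test(a, b)
            assert p == pytest.approx(wmw_enumeration_p(a, b), abs=1e-12)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=9)
        b = rng.normal(size=14)
        assert wmw_test(a, b)[1] == pytest.approx(wmw_test(b, a)[1], rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wmw_test([], [1.0])


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_ordered_triple(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_pair(self):
        assert bh_adjust([0.001, 0.04]) == pytest.approx([0.002, 0.04])

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(bh_stepup_oracle(p), abs=1e-12)

    @given(st.permutations(list(range(8))))
    def test_permutation_equivariance(self, perm):
        base = np.array([0.001, 0.01, 0.02, 0.2, 0.5, 0.04, 0.9, 0.06])
        perm = np.array(perm)
        adj = bh_adjust(base)
        adj_perm = bh_adjust(base[perm])
        assert adj_perm == pytest.approx(adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# screens


class TestCorrelationScreen:
    def test_noise_free_calls_match_class_signs(self, noise_free_study):
        tc = glog_normalize(noise_free_study.timecourse, c=0.0, calibrate=False)
        res = correlation_screen(tc, noise_free_study.timecourse_meta, "rin")
        truth = noise_free_study.truth_by_id()
        for r in res:
            klass = truth[r.mirna_id].klass
            if klass == "artifact":
                assert r.call == "negative"
            elif klass == "resilient":
                assert r.call == "ns"

    def test_default_simulation_artifact_recovery(
        self, default_study, normalized_timecourse
    ):
        """≥ 90% of truth-artifact miRNAs are called negatively correlated
        with RIN (oracle: compare calls to the generator's labels)."""
        res = correlation_screen(
            normalized_timecourse, default_study.timecourse_meta, "rin"
        )
        truth = default_study.truth_by_id()
        art = [r for r in res if truth[r.mirna_id].klass == "artifact"]
        frac = sum(r.call == "negative" for r in art) / len(art)
        assert frac >= 0.9

    def test_time_screen_restricts_to_temperature_arm(
        self, default_study, normalized_timecourse
    ):
        res = correlation_screen(
            normalized_timecourse, default_study.timecourse_meta, "time_4C"
        )
        assert len(res) == normalized_timecourse.n_mirnas

    def test_too_few_samples_rejected(self, default_study, normalized_timecourse):
        meta = default_study.timecourse_meta[:2]
        m = normalized_timecourse.select_samples([x.sample_id for x in meta])
        with pytest.raises(ValidationError, match="fewer than 3"):
            correlation_screen(m, meta, "rin")

    def test_null_simulation_type_i_control(self):
        """All-resilient noise-only simulation: BH-adjusted discovery fraction
        stays within 0.05 + 2 binomial SEs."""
        sim = SimConfig(n_resilient=500, n_sensitive=0, n_artifact=0,
                        n_dna_background=0, seed=21)
        tc, meta, _, _ = simulate_timecourse(sim)
        norm = glog_normalize(detection_filter(tc, 5))
        res = correlation_screen(norm, meta, "rin")
        frac = np.mean([r.p_adj < 0.05 for r in res])
        se = math.sqrt(0.05 * 0.95 / len(res))
        assert frac <= 0.05 + 2 * se


class TestDifferentialExpression:
    def _meta(self, rins):
        from conftest import timecourse_meta_row

        return [
            timecourse_meta_row(sample_id=f"S{i + 1}", rin=r, time_h=0)
            for i, r in enumerate(rins)
        ]

    def test_identical_groups_not_significant(self):
        vals = np.tile([[5.0, 5.0, 5.0, 5.0]], (3, 1))
        m = make_matrix(vals, state="normalized")
        res = differential_expression(m, self._meta([3, 3, 9, 9]))
        for r in res:
            assert r.log2fc == 0.0
            assert not r.significant

    def test_constructed_two_fold_shift(self):
        # 4 + 4 fully separated: exact WMW two-sided p = 2/70 < 0.05
        low = [[8.0, 8.1, 7.9, 8.2], [5.0, 5.1, 4.9, 5.2]]
        high = [[6.0, 6.1, 5.9, 6.2], [5.05, 5.15, 4.95, 5.25]]
        vals = np.hstack([low, high])
        m = make_matrix(vals, state="normalized")
        res = differential_expression(m, self._meta([2, 2, 2, 2, 9, 9, 9, 9]))
        assert res[0].log2fc == pytest.approx(2.0)
        assert res[0].significant
        assert not res[1].significant

    def test_log2fc_sign_flips_with_group_swap(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(5, 1, size=(4, 10))
        m = make_matrix(vals, state="normalized")
        meta_a = self._meta([2] * 5 + [9] * 5)
        meta_b = self._meta([9] * 5 + [2] * 5)
        ra = differential_expression(m, meta_a)
        rb = differential_expression(m, meta_b)
        for x, y in zip(ra, rb):
            assert x.log2fc == pytest.approx(-y.log2fc)
            assert x.p == pytest.approx(y.p, rel=1e-9)

    def test_small_group_rejected(self):
        m = make_matrix(np.ones((2, 3)) * [[1, 2, 3], [1, 2, 3]],
                        state="normalized")
        with pytest.raises(ValidationError, match="low-integrity"):
            differential_expression(m, self._meta([3, 9, 9]))

    def test_recovers_strong_sensitive_mirnas(self, default_study,
                                              normalized_timecourse):
        """Liver high- vs low-RIN contrast: every sensitive miRNA with a
        ≥ 2 log2 effect and full detection is called down (negative shift,
        WMW p < 0.05).  The low-integrity group contains moderately degraded
        samples, so the group-median shift is attenuated below the latent
        effect; the two-fold magnitude filter is therefore checked for the
        overwhelming majority rather than for every single miRNA."""
        meta = default_study.timecourse_meta
        liver = [m.sample_id for m in meta if m.tissue == "liver"]
        sub = normalized_timecourse.select_samples(liver)
        res = differential_expression(sub, meta)
        truth = default_study.truth_by_id()
        detected_all = sub.detected.all(axis=1)
        strong = [
            r
            for r in res
            if truth[r.mirna_id].klass == "sensitive"
            and truth[r.mirna_id].effect_log2 <= -2
            and detected_all[r.mirna_id]
        ]
        assert len(strong) > 50
        for r in strong:
            assert r.log2fc < 0 and r.p < 0.05
        assert np.mean([r.significant for r in strong]) >= 0.9


class TestDetectedCountsByEra:
    def _ann(self, versions):
        return [
            MiRBaseAnnotation(f"miR-{i + 1}", "ACGTACGTACGTACGTACGT", v)
            for i, v in enumerate(versions)
        ]

    def test_zero_detected_gives_zero_column(self):
        m = make_matrix(np.ones((3, 2)), detected=np.zeros((3, 2), dtype=bool))
        tab = detected_counts_by_era(m, self._ann([2, 17, 21]),
                                     era_bins=((1, 3), (16, 21)))
        assert (tab["S1"] == 0).all()

    def test_simple_two_bin_counts(self):
        m = make_matrix(np.ones((3, 1)))
        tab = detected_counts_by_era(m, self._ann([2, 17, 21]),
                                     era_bins=((1, 3), (16, 21)))
        assert tab["S1"].tolist() == [1, 2]

    def test_era_totals_sum_to_detected_count(self, default_study):
        tc = default_study.timecourse
        tab = detected_counts_by_era(tc, default_study.annotation)
        assert (tab.sum(axis=0).to_numpy()
                == tc.detected.sum(axis=0).to_numpy()).all()

    def test_recent_era_grows_with_degradation(self, default_study):
        """Along the liver RT time course, the detected count from the
        recent annotation era (16–21) rises far more than the earliest era."""
        meta = default_study.timecourse_meta
        liver_rt = [m.sample_id for m in meta
                    if m.tissue == "liver" and m.temperature == "RT"]
        first, last = liver_rt[0], liver_rt[-1]
        tab = detected_counts_by_era(default_study.timecourse,
                                     default_study.annotation,
                                     sample_ids=[first, last])
        growth_recent = tab.loc["16-21", last] - tab.loc["16-21", first]
        growth_early = tab.loc["1-3", last] - tab.loc["1-3", first]
        assert growth_recent > growth_early

    def test_unannotated_mirna_rejected(self):
        m = make_matrix(np.ones((2, 1)))
        with pytest.raises(ValidationError, match="miR-2"):
            detected_counts_by_era(m, self._ann([5]))
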