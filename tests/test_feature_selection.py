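"""Window DE features, plug-in MI and the DMIM greedy ranking."""

import itertools
import math

import numpy as np
import pytest

from emoselect.feature_selection import (
    DMIMWindowSelector,
    conditional_mi,
    de_features,
    discrete_mi,
    dmim_rank,
    dmim_score,
    equal_frequency_bins,
    map_to_raw,
    mutual_information,
    segment_windows,
    select_top_windows,
    window_de,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_mi_from_joint(joint):
    """Exhaustive term-by-term MI sum (natural log)."""
    joint = np.asarray(joint, dtype=float)
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    total = 0.0
    for i, j in itertools.product(range(joint.shape[0]),
                                  range(joint.shape[1])):
        p = joint[i, j]
        if p > 0:
            total += p * math.log(p / (pa[i] * pb[j]))
    return total


def oracle_mi_from_codes(a, b):
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    vals_a, vals_b = sorted(set(a.tolist())), sorted(set(b.tolist()))
    joint = np.zeros((len(vals_a), len(vals_b)))
    for x, y in zip(a, b):
        joint[vals_a.index(x), vals_b.index(y)] += 1.0 / n
    return oracle_mi_from_joint(joint)


def oracle_cmi(a, b, c):
    c = np.asarray(c)
    total = 0.0
    for v in sorted(set(c.tolist())):
        m = c == v
        total += m.mean() * oracle_mi_from_codes(np.asarray(a)[m],
                                                 np.asarray(b)[m])
    return total


def oracle_dmim(candidate, selected, labels):
    rel = oracle_mi_from_codes(candidate, labels)
    if not selected:
        return rel
    red = max(oracle_mi_from_codes(candidate, s) for s in selected)
    cred = max(oracle_cmi(candidate, s, labels) for s in selected)
    return rel - red + cred


# ---------------------------------------------------------------------------
# windowing + DE
# ---------------------------------------------------------------------------

class TestSegmentWindows:
    @pytest.mark.parametrize("duration,sfreq,expected", [
        (60, 128, 30), (240, 128, 120), (60, 256, 30), (2, 128, 1),
        (5, 128, 2),   # trailing partial second window discarded
    ])
    def test_window_counts(self, duration, sfreq, expected):
        spans = segment_windows(duration * sfreq, sfreq, 2.0)
        assert len(spans) == expected
        n = 2 * sfreq
        assert all(b - a == n for a, b in spans)
        assert spans[0] == (0, n)

    def test_half_open_non_overlapping(self):
        spans = segment_windows(1024, 128.0, 2.0)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert b1 == a2

    def test_window_longer_than_trial_raises(self):
        with pytest.raises(ValueError):
            segment_windows(100, 128.0, 2.0)


class TestWindowDe:
    def test_unit_power(self):
        w = np.ones(256)
        assert window_de(w) == pytest.approx(
            0.5 * math.log(2 * math.pi * math.e * 256), rel=1e-12)

    def test_closed_form_p_e_squared(self):
        n = 256
        w = np.full(n, math.e)  # P = e^2
        assert window_de(w) == pytest.approx(
            1.0 + 0.5 * math.log(2 * math.pi * math.e * n), rel=1e-12)

    def test_scaling_adds_log_c(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(128)
        c = 3.7
        assert window_de(c * w) == pytest.approx(
            window_de(w) + math.log(c), rel=1e-10)

    def test_zero_window_minus_inf(self):
        assert window_de(np.zeros(64)) == -np.inf


# ---------------------------------------------------------------------------
# MI
# ---------------------------------------------------------------------------

class TestMutualInformation:
    def test_independent_variables_zero(self):
        joint = np.outer([0.3, 0.7], [0.4, 0.6])
        assert mutual_information(joint) == pytest.approx(0.0, abs=1e-15)

    def test_identical_fair_binary_ln2(self):
        joint = np.array([[0.5, 0.0], [0.0, 0.5]])
        assert mutual_information(joint) == pytest.approx(math.log(2),
                                                          rel=1e-12)

    def test_given_table_matches_enumeration(self):
        joint = np.array([[0.4, 0.1], [0.1, 0.4]])
        assert mutual_information(joint) == pytest.approx(
            oracle_mi_from_joint(joint), abs=1e-15)

    def test_random_joints_match_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            shape = (rng.integers(2, 5), rng.integers(2, 5))
            joint = rng.random(shape)
            joint[rng.random(shape) < 0.2] = 0.0  # zero cells allowed
            if joint.sum() == 0:
                continue
            joint /= joint.sum()
            assert mutual_information(joint) == pytest.approx(
                oracle_mi_from_joint(joint), abs=1e-12)

    def test_unnormalized_joint_raises(self):
        with pytest.raises(ValueError):
            mutual_information(np.array([[0.5, 0.5], [0.5, 0.5]]))

    def test_conditional_mi_nonnegative(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = rng.integers(0, 3, 60)
            b = rng.integers(0, 3, 60)
            c = rng.integers(0, 2, 60)
            got = conditional_mi(a, b, c)
            assert got >= -1e-12
            assert got == pytest.approx(oracle_cmi(a, b, c), abs=1e-12)


# ---------------------------------------------------------------------------
# DMIM
# ---------------------------------------------------------------------------

class TestDmimScore:
    def test_empty_selection_is_relevance(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 4, 80)
        y = rng.integers(0, 2, 80)
        assert dmim_score(x, [], y) == pytest.approx(
            oracle_mi_from_codes(x, y), abs=1e-12)

    def test_duplicate_feature_independent_of_class_nonpositive(self):
        # X_i == X_s and X_i independent of C: score = 0 - H(X) + H(X|C) <= 0
        rng = np.random.default_rng(8)
        x = rng.integers(0, 2, 400)
        y = rng.integers(0, 2, 400)
        assert dmim_score(x, [x], y) <= 1e-9

    def test_three_feature_toy_matches_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            feats = [rng.integers(0, 3, 50) for _ in range(3)]
            y = rng.integers(0, 2, 50)
            got = dmim_score(feats[0], feats[1:], y)
            want = oracle_dmim(feats[0], feats[1:], y)
            assert got == pytest.approx(want, abs=1e-12)


class TestDmimRank:
    @staticmethod
    def features_with_planted(seed=0, n_trials=60, n_channels=3,
                              n_windows=6, informative=(1, 4)):
        # per-window noise keeps the two planted windows correlated with the
        # class but not duplicates of each other (duplicates are legitimately
        # suppressed by the redundancy term)
        rng = np.random.default_rng(seed)
        y = np.array(["a", "b"] * (n_trials // 2))
        h = rng.standard_normal((n_trials, n_channels, n_windows)) * 0.8
        for w in informative:
            h[:, :, w] += (y == "b")[:, None] * 2.0
        return h, y

    def test_full_ranking_is_permutation(self):
        h, y = self.features_with_planted()
        r = dmim_rank(h, y, n_select=None)
        assert sorted(r.order) == list(range(h.shape[2]))

    def test_first_selected_maximizes_relevance(self):
        h, y = self.features_with_planted()
        r = dmim_rank(h, y)
        rel = r.relevance
        assert rel[r.order[0]] == max(rel.values())

    def test_planted_windows_rank_first(self):
        h, y = self.features_with_planted(informative=(1, 4))
        r = dmim_rank(h, y, n_select=2)
        assert set(r.order) == {1, 4}

    def test_tie_breaks_to_lower_ordinal(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 4, 30).astype(float)
        h = np.stack([col, col, col], axis=1)[:, None, :]  # 3 identical windows
        y = (col > 1).astype(int)
        r = dmim_rank(h, y, n_select=1)
        assert r.order[0] == 0

    def test_single_class_raises(self):
        h = np.random.default_rng(0).standard_normal((10, 2, 4))
        with pytest.raises(ValueError):
            dmim_rank(h, np.zeros(10))

    def test_accuracy_stopping_produces_trace(self):
        h, y = self.features_with_planted(n_trials=48)
        r = dmim_rank(h, y, stop="accuracy")
        assert len(r.accuracy_trace) == h.shape[2]
        assert 1 <= len(r.order) <= h.shape[2]

    def test_monotone_rescaling_invariance(self):
        h, y = self.features_with_planted(seed=2)
        r1 = dmim_rank(h, y, n_select=4)
        r2 = dmim_rank(np.exp(h / 2.0), y, n_select=4)  # strictly increasing
        assert r1.order == r2.order


class TestSelectAndMap:
    def test_top_k_spans(self):
        spans = segment_windows(1024, 128.0, 2.0)
        h = np.random.default_rng(0).standard_normal((20, 2, len(spans)))
        y = np.array([0, 1] * 10)
        r = dmim_rank(h, y, n_select=2, spans=spans)
        got = select_top_windows(r, 2)
        assert len(got) == 2
        assert all(s in spans for s in got)

    def test_k_zero_empty(self):
        r = dmim_rank(np.random.default_rng(1).standard_normal((10, 1, 4)),
                      np.array([0, 1] * 5), spans=segment_windows(1024, 128, 2))
        assert select_top_windows(r, 0) == []

    def test_map_identity_when_all_spans(self):
        x = np.arange(2 * 1 * 8, dtype=float).reshape(2, 1, 8)
        spans = [(0, 4), (4, 8)]
        assert np.array_equal(map_to_raw(spans, x), x)

    def test_single_span_length(self):
        x = np.random.default_rng(2).standard_normal((3, 2, 512))
        out = map_to_raw([(256, 512)], x)
        assert out.shape == (3, 2, 256)
        assert np.array_equal(out, x[:, :, 256:512])

    def test_selection_order_preserved(self):
        x = np.arange(8, dtype=float).reshape(1, 1, 8)
        out = map_to_raw([(4, 8), (0, 4)], x)
        assert np.array_equal(out[0, 0], [4, 5, 6, 7, 0, 1, 2, 3])

    def test_overlapping_spans_raise(self):
        x = np.zeros((1, 1, 8))
        with pytest.raises(ValueError, match="overlap"):
            map_to_raw([(0, 4), (2, 6)], x)

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError):
            map_to_raw([(0, 9)], np.zeros((1, 1, 8)))


class TestWindowSelectorEstimator:
    def test_reduced_length_is_k_times_n(self, tiny_epochs):
        from emoselect.containers import class_vector

        y = class_vector(tiny_epochs, "binary_valence")
        sel = DMIMWindowSelector(n_select=1).fit(tiny_epochs, y)
        out = sel.transform(tiny_epochs)
        n = int(2.0 * tiny_epochs.sfreq)
        assert out.n_samples == 1 * n

    def test_planted_window_found(self, tiny_epochs):
        from emoselect.containers import class_vector

        y = class_vector(tiny_epochs, "binary_valence")
        sel = DMIMWindowSelector(n_select=1).fit(tiny_epochs, y)
        assert sel.selected_windows_ == tiny_epochs.meta["informative_windows"]

    def test_bare_array_needs_sfreq(self):
        with pytest.raises(ValueError, match="sfreq"):
            DMIMWindowSelector().fit(np.zeros((4, 2, 512)), [0, 1, 0, 1])

    def test_equal_frequency_bins_balanced(self):
        rng = np.random.default_rng(0)
        codes = equal_frequency_bins(rng.standard_normal(400), n_bins=4)
        counts = np.bincount(codes, minlength=4)
        assert counts.max() - counts.min() <= 2
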