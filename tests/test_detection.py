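"""Detection module tests against independent textbook/enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from doppelscan.data_model import AbundanceTable, SampleLabels, SamplePair
from doppelscan.detection import (
    DoppelgangerDetector,
    derive_cutoff,
    detect,
    identify_doppelgangers,
    pairwise_correlation,
    remove_doppelgangers,
    validate_cutoff,
)

from conftest import random_labels, random_table


# ---------------------------------------------------------------- oracles

def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def rank_mid(v):
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def kendall_oracle(x, y):
    """Tau-b via direct concordant/discordant pair counting."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))


def _tie_term(v):
    _, counts = np.unique(v, return_counts=True)
    return sum(c * (c - 1) / 2 for c in counts)


def brute_force_flagged(corr: pd.DataFrame, labels: SampleLabels):
    """Exhaustive enumeration: within-class pairs above the between-class max."""
    ids = list(corr.index)
    between = [
        corr.loc[a, b]
        for a, b in itertools.combinations(ids, 2)
        if labels[a] != labels[b]
    ]
    cutoff = max(between)
    return cutoff, {
        tuple(sorted((a, b)))
        for a, b in itertools.combinations(ids, 2)
        if labels[a] == labels[b] and corr.loc[a, b] > cutoff
    }


# ------------------------------------------------------- pairwise correlation

class TestPairwiseCorrelation:
    def test_identical_samples_correlate_perfectly(self, toy_table):
        t = AbundanceTable(("a", "b"), ("f", "g", "h"),
                           np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]]))
        corr = pairwise_correlation(t, transform="relative")
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        t = AbundanceTable(("a", "b"), ("f", "g", "h"),
                           np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]))
        corr = pairwise_correlation(t, method="pearson", transform="raw")
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("method,oracle", [
        ("pearson", pearson_oracle),
        ("spearman", lambda x, y: pearson_oracle(rank_mid(x), rank_mid(y))),
        ("kendall", kendall_oracle),
    ])
    def test_matches_textbook_formula_oracle(self, method, oracle):
        values = np.array([[3.0, 1.0, 4.0, 1.0],
                           [5.0, 9.0, 2.0, 6.0],
                           [5.0, 3.0, 5.0, 8.0]])
        t = AbundanceTable(("a", "b", "c"), ("f1", "f2", "f3", "f4"), values)
        corr = pairwise_correlation(t, method=method, transform="raw")
        for i, j in itertools.combinations(range(3), 2):
            expected = oracle(values[i], values[j])
            assert corr.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, 8, 12)
        corr = pairwise_correlation(t)
        C = corr.to_numpy()
        np.testing.assert_allclose(C, C.T, atol=1e-15)
        np.testing.assert_allclose(np.diag(C), 1.0)
        assert np.all(C >= -1) and np.all(C <= 1)

    def test_constant_sample_is_an_error(self):
        t = AbundanceTable(("a", "b"), ("f", "g"),
                           np.array([[2.0, 2.0], [1.0, 3.0]]))
        with pytest.raises(ValueError, match="a"):
            pairwise_correlation(t, transform="raw")

    def test_too_small_inputs_rejected(self, toy_table):
        one = toy_table.select_samples(["s1"])
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_correlation(one)


# ------------------------------------------------------------ cutoff + pairs

class TestCutoffAndIdentification:
    def test_cutoff_is_listed_maximum(self):
        ids = ["a", "b", "c", "d"]
        C = np.eye(4)
        # cases a,b; controls c,d; between entries: ac .30 ad .55 bc .10 bd .42
        C[0, 2] = C[2, 0] = 0.30
        C[0, 3] = C[3, 0] = 0.55
        C[1, 2] = C[2, 1] = 0.10
        C[1, 3] = C[3, 1] = 0.42
        C[0, 1] = C[1, 0] = 0.90
        C[2, 3] = C[3, 2] = 0.20
        corr = pd.DataFrame(C, index=ids, columns=ids)
        labels = SampleLabels({"a": "case", "b": "case", "c": "control", "d": "control"})
        assert derive_cutoff(corr, labels) == pytest.approx(0.55)

    def test_degenerate_two_sample_cutoff(self):
        corr = pd.DataFrame([[1.0, 0.37], [0.37, 1.0]], index=["a", "b"], columns=["a", "b"])
        labels = SampleLabels({"a": "case", "b": "control"})
        assert derive_cutoff(corr, labels) == pytest.approx(0.37)

    def test_single_class_has_no_cutoff(self):
        corr = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            labels = SampleLabels({"a": "case", "b": "case"})

    def test_cutoff_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(11)
        t = random_table(rng, 20, 30)
        labels = SampleLabels(
            {s: ("case" if i < 10 else "control") for i, s in enumerate(t.sample_ids)}
        )
        corr = pairwise_correlation(t)
        expected, _ = brute_force_flagged(corr, labels)
        assert derive_cutoff(corr, labels) == pytest.approx(expected)

    def test_tie_at_cutoff_not_flagged_strict_inequality(self):
        ids = ["a", "b", "c", "d"]
        C = np.eye(4)
        C[0, 1] = C[1, 0] = 0.5   # within-case, equals cutoff
        C[0, 2] = C[2, 0] = 0.5   # between: defines cutoff
        corr = pd.DataFrame(C, index=ids, columns=ids)
        labels = SampleLabels({"a": "case", "b": "case", "c": "control", "d": "control"})
        assert identify_doppelgangers(corr, labels, 0.5) == []

    def test_flagged_sorted_by_descending_correlation(self, injected_dataset):
        table, labels, _, _ = injected_dataset
        res = detect(table, labels, validate=False)
        rs = [p.correlation for p in res.pairs]
        assert rs == sorted(rs, reverse=True)

    def test_flagged_set_equals_enumeration_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            t = random_table(rng, n, 15)
            labels = random_labels(rng, t)
            if len(labels.members("case")) == 0 or len(labels.members("control")) == 0:
                continue
            corr = pairwise_correlation(t)
            cutoff, expected = brute_force_flagged(corr, labels)
            got = {p.ids for p in identify_doppelgangers(corr, labels, cutoff)}
            assert got == expected
            # specificity by construction: between-class pairs never flagged
            for p in identify_doppelgangers(corr, labels, cutoff):
                assert labels[p.id_a] == labels[p.id_b]

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(3)
        t = random_table(rng, 10, 20)
        labels = random_labels(rng, t)
        corr = pairwise_correlation(t)
        prev = None
        for cutoff in np.linspace(-1, 1, 21):
            flagged = {p.ids for p in identify_doppelgangers(corr, labels, cutoff)}
            if prev is not None:
                assert flagged <= prev
            prev = flagged

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(19)
        t = random_table(rng, 9, 14)
        labels = random_labels(rng, t)
        res = detect(t, labels, validate=False)
        perm = list(rng.permutation(t.sample_ids))
        res_p = detect(t.select_samples(perm), labels, validate=False)
        assert {p.ids for p in res.pairs} == {p.ids for p in res_p.pairs}
        assert res_p.cutoff == pytest.approx(res.cutoff)


# ------------------------------------------------------------- validation

class TestValidateCutoff:
    def test_exact_statistic_matches_enumeration(self):
        # groups {0.1, 0.2} (between) vs {0.8, 0.9} (within): U of the first
        # group against the second is 0 (all between < all within)
        from doppelscan._stats import rank_sum_test

        stat, p = rank_sum_test(np.array([0.1, 0.2]), np.array([0.8, 0.9]))
        assert stat == 0.0
        # exact two-sided p for complete separation with n=m=2: 2 * 1/C(4,2)
        assert p == pytest.approx(2 / 6)

    def test_shifted_within_group_detected(self):
        rng = np.random.default_rng(21)
        rejections = 0
        n_rep = 20
        for _ in range(n_rep):
            between = rng.normal(0.3, 0.1, size=50)
            within = rng.normal(0.6, 0.1, size=50)  # +0.3 shift
            from doppelscan._stats import rank_sum_test

            _, p = rank_sum_test(between, within)
            rejections += p < 0.05
        assert rejections == n_rep  # shift is large relative to sd at n=50

    def test_histogram_spans_both_groups(self, injected_dataset):
        table, labels, _, _ = injected_dataset
        res = detect(table, labels, validate=True)
        v = res.validation
        assert v is not None
        assert 0 <= v.pvalue <= 1
        assert v.bin_edges.size == 31
        n = table.n_samples
        assert v.n_between + v.n_within == n * (n - 1) // 2
        assert v.between_counts.sum() == v.n_between
        assert v.within_counts.sum() == v.n_within

    def test_too_few_pairs_is_an_error(self):
        corr = pd.DataFrame(np.eye(3) + 0.1 - np.diag([0.1] * 3),
                            index=list("abc"), columns=list("abc"))
        labels = SampleLabels({"a": "case", "b": "case", "c": "control"})
        with pytest.raises(ValueError, match="at least 2"):
            validate_cutoff(corr, labels)


# --------------------------------------------------------------- removal

class TestRemoval:
    def _table(self, ids):
        rng = np.random.default_rng(1)
        vals = rng.integers(1, 20, size=(len(ids), 6)).astype(float)
        return AbundanceTable(tuple(ids), tuple(f"f{j}" for j in range(6)), vals)

    def test_disjoint_pairs_remove_one_each(self):
        t = self._table(["a", "b", "c", "d", "e"])
        pairs = [SamplePair("a", "b", 0.99, "within_case"),
                 SamplePair("c", "d", 0.98, "within_case")]
        cleaned, removed = remove_doppelgangers(t, pairs, policy="greedy_degree")
        assert len(removed) == 2
        survivors = set(cleaned.sample_ids)
        for p in pairs:
            assert not set(p.ids) <= survivors

    def test_chain_removes_only_shared_member(self):
        # brute-force minimum vertex cover of path a-b-c is {b}
        t = self._table(["a", "b", "c"])
        pairs = [SamplePair("a", "b", 0.99, "within_case"),
                 SamplePair("b", "c", 0.98, "within_case")]
        cleaned, removed = remove_doppelgangers(t, pairs)
        assert removed == ["b"]
        assert cleaned.sample_ids == ("a", "c")

    def test_second_member_policy(self):
        t = self._table(["a", "b", "c", "d"])
        pairs = [SamplePair("a", "b", 0.99, "within_case"),
                 SamplePair("a", "c", 0.97, "within_case")]
        cleaned, removed = remove_doppelgangers(t, pairs, policy="second_member")
        assert removed == ["b", "c"]

    def test_empty_pairs_identity(self, toy_table):
        cleaned, removed = remove_doppelgangers(toy_table, [])
        assert cleaned == toy_table and removed == []

    def test_unknown_sample_rejected(self, toy_table):
        with pytest.raises(KeyError):
            remove_doppelgangers(toy_table, [SamplePair("s1", "zz", 0.9, "within_case")])


# -------------------------------------------------------- sklearn estimator

class TestDoppelgangerDetector:
    def test_fit_transform_removes_flagged_samples(self, injected_dataset):
        table, labels, _, injected = injected_dataset
        det = DoppelgangerDetector()
        cleaned = det.fit_transform(table, labels)
        assert det.cutoff_ == pytest.approx(derive_cutoff(det.correlation_, labels))
        survivors = set(cleaned.sample_ids)
        for a, b in injected:
            assert not {a, b} <= survivors

    def test_accepts_plain_arrays(self):
        rng = np.random.default_rng(2)
        X = rng.integers(1, 40, size=(12, 20)).astype(float)
        y = ["case"] * 6 + ["control"] * 6
        det = DoppelgangerDetector().fit(X, y)
        assert det.correlation_.shape == (12, 12)

    def test_get_params_round_trip(self):
        det = DoppelgangerDetector(method="spearman", policy="second_member")
        params = det.get_params()
        assert params["method"] == "spearman"
        det2 = DoppelgangerDetector().set_params(**params)
        assert det2.policy == "second_member"
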