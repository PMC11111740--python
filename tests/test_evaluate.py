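"""Identity, grouping, LOGOCV, ranking metrics and the baseline ranker."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phagematch.evaluate import (
    FoldResult,
    confusion_summary,
    group_by_identity,
    hit_ratio_at_k,
    identity_matrix,
    informed_microbiologist_rank,
    mean_hit_ratio_curve,
    pairwise_identity,
    roc_auc,
    run_logocv,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_identity(a, b, match=1, mismatch=-1, gap=-2):
    """Enumerate every global alignment recursively; take the one maximizing
    (score, matches, diagonal columns) and return 100*matches/columns."""

    def rec(i, j):
        # returns set of (score, matches, diag, columns) over alignments of
        # a[i:], b[j:]
        if i == len(a) and j == len(b):
            return {(0, 0, 0, 0)}
        out = set()
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            eq = 1 if a[i] == b[j] else 0
            out |= {
                (s + sc, eq + m, 1 + d, 1 + c) for sc, m, d, c in rec(i + 1, j + 1)
            }
        if i < len(a):
            out |= {(gap + sc, m, d, 1 + c) for sc, m, d, c in rec(i + 1, j)}
        if j < len(b):
            out |= {(gap + sc, m, d, 1 + c) for sc, m, d, c in rec(i, j + 1)}
        return out

    best = max(rec(0, 0), key=lambda t: (t[0], t[1], t[2]))
    return 100.0 * best[1] / best[3]


def brute_force_auc(scores, labels):
    """Exhaustive pair counting with ties worth 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------

class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGTACGT", "ACGTACGT", 100.0),
            ("ACGT", "ACGA", 75.0),
            ("AAAA", "TTTT", 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert pairwise_identity(a, b) == expected

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            n, m = rng.integers(1, 13, size=2)
            a = "".join(rng.choice(list("ACGT"), size=n))
            b = "".join(rng.choice(list("ACGT"), size=m))
            got = pairwise_identity(a, b)
            want = brute_force_identity(a, b)
            assert got == pytest.approx(want), (a, b)
            # symmetry
            assert pairwise_identity(b, a) == pytest.approx(got)

    def test_hundred_iff_identical(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=12))
            b = "".join(rng.choice(list("ACGT"), size=12))
            ident = pairwise_identity(a, b)
            assert (ident == 100.0) == (a == b)


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def _matrix(values):
    return np.array(values, dtype=float)


class TestGrouping:
    def test_threshold_100_merges_identical_only(self):
        M = _matrix([[100, 100, 50], [100, 100, 50], [50, 50, 100]])
        groups = group_by_identity(M, 100, ids=["A", "B", "C"])
        assert groups.mapping["A"] == groups.mapping["B"]
        assert groups.mapping["C"] != groups.mapping["A"]

    def test_single_linkage_chain(self):
        # AB=80, BC=80, AC=60 at t=75: transitive chain pulls all together
        M = _matrix([[100, 80, 60], [80, 100, 80], [60, 80, 100]])
        groups = group_by_identity(M, 75, ids=list("ABC"))
        assert len(set(groups.mapping.values())) == 1

    def test_all_singletons_below_threshold(self):
        M = _matrix([[100, 60, 60], [60, 100, 60], [60, 60, 100]])
        groups = group_by_identity(M, 75)
        assert len(set(groups.mapping.values())) == 3

    def test_asymmetric_matrix_errors(self):
        M = _matrix([[100, 80], [70, 100]])
        with pytest.raises(ValueError, match="symmetric"):
            group_by_identity(M, 75)

    def test_higher_threshold_refines_lower(self):
        rng = np.random.default_rng(8)
        n = 12
        M = rng.uniform(50, 100, size=(n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 100.0)
        low = group_by_identity(M, 75).mapping
        high = group_by_identity(M, 90).mapping
        # two bacteria grouped at the high threshold share a group at the low
        for i, j in itertools.combinations(range(n), 2):
            if high[str(i)] == high[str(j)]:
                assert low[str(i)] == low[str(j)]


# ---------------------------------------------------------------------------
# metric helpers on hand-built fold results
# ---------------------------------------------------------------------------

def fold_from_rows(rows, group_id="g0"):
    return FoldResult(
        group_id,
        pd.DataFrame(rows, columns=["phage_id", "bacterium_id", "score", "label"]),
    )


def single_positive_fold(rank, n_phages=10, bacterium="b1"):
    """One bacterium whose only positive sits at the given rank."""
    rows = []
    for i in range(n_phages):
        rows.append((f"p{i:02d}", bacterium, 1.0 - i / n_phages,
                     1 if i == rank - 1 else 0))
    return fold_from_rows(rows)


class TestHitRatio:
    def test_single_positive_ranked_third(self):
        folds = [single_positive_fold(rank=3)]
        assert hit_ratio_at_k(folds, 1) == 0.0
        assert hit_ratio_at_k(folds, 2) == 0.0
        assert hit_ratio_at_k(folds, 3) == 1.0

    def test_in_vitro_style_mean(self):
        # 28 bacteria tested, 16 with >= 1 positive, 15 with a hit in the
        # top five: mean top-five hit ratio 15/16 = 0.9375
        folds = []
        for i in range(15):
            folds.append(single_positive_fold(3, 17, bacterium=f"hit{i:02d}"))
        folds.append(single_positive_fold(7, 17, bacterium="miss"))
        for i in range(12):
            rows = [(f"p{j:02d}", f"neg{i:02d}", 0.5, 0) for j in range(17)]
            folds.append(fold_from_rows(rows))
        assert hit_ratio_at_k(folds, 5) == pytest.approx(15 / 16)
        assert round(100 * hit_ratio_at_k(folds, 5), 1) == 93.8

    def test_k_out_of_range_errors(self):
        folds = [single_positive_fold(1, n_phages=5)]
        with pytest.raises(ValueError):
            hit_ratio_at_k(folds, 0)
        with pytest.raises(ValueError):
            hit_ratio_at_k(folds, 6)

    def test_all_rank_one_gives_one_everywhere(self):
        folds = [single_positive_fold(1, 6, bacterium=f"b{i}") for i in range(4)]
        for k in range(1, 7):
            assert hit_ratio_at_k(folds, k) == 1.0


class TestHitRatioCurve:
    def test_monotone_with_terminal_one(self):
        rng = np.random.default_rng(3)
        folds = []
        for b in range(8):
            labels = np.zeros(12, dtype=int)
            labels[rng.integers(0, 12)] = 1
            rows = [
                (f"p{j:02d}", f"b{b}", rng.random(), labels[j]) for j in range(12)
            ]
            folds.append(fold_from_rows(rows))
        curve = mean_hit_ratio_curve(folds)
        assert (np.diff(curve.mean_hit_ratio) >= 0).all()
        assert curve.mean_hit_ratio[-1] == 1.0

    def test_perfect_model_constant_one(self):
        folds = [single_positive_fold(1, 8, bacterium=f"b{i}") for i in range(5)]
        curve = mean_hit_ratio_curve(folds)
        assert (curve.mean_hit_ratio == 1.0).all()

    def test_random_scores_expectation_linear_in_k(self):
        # 1 positive among 30 phages with random scores: E[hit@k] = k/30
        rng = np.random.default_rng(12)
        n_phages, n_rep = 30, 1200
        hits = np.zeros(n_phages)
        for _ in range(n_rep):
            scores = rng.random(n_phages)
            pos = rng.integers(0, n_phages)
            rank = 1 + (scores > scores[pos]).sum()
            hits += np.arange(1, n_phages + 1) >= rank
        empirical = hits / n_rep
        expected = np.arange(1, n_phages + 1) / n_phages
        assert np.abs(empirical - expected).max() < 0.05


class TestRocAuc:
    def test_perfectly_separated(self):
        folds = [fold_from_rows([("p1", "b1", 0.9, 1), ("p2", "b1", 0.1, 0)])]
        assert roc_auc(folds) == 1.0

    def test_all_ties_half(self):
        folds = [fold_from_rows(
            [("p1", "b1", 0.5, 1), ("p2", "b1", 0.5, 0), ("p3", "b1", 0.5, 0)]
        )]
        assert roc_auc(folds) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n_pos, n_neg = rng.integers(1, 11, size=2)
            scores = np.round(rng.random(n_pos + n_neg), 1)  # force some ties
            labels = np.array([1] * n_pos + [0] * n_neg)
            rows = [
                (f"p{i}", "b1", scores[i], labels[i]) for i in range(len(labels))
            ]
            assert roc_auc([fold_from_rows(rows)]) == pytest.approx(
                brute_force_auc(scores, labels)
            )

    def test_single_class_errors(self):
        folds = [fold_from_rows([("p1", "b1", 0.9, 1)])]
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(folds)


class TestInformedMicrobiologist:
    def test_same_kl_narrow_before_broad(self):
        ranking = informed_microbiologist_rank(
            "KL1", {"A": {"KL1"}, "B": {"KL1", "KL2"}}
        )
        assert ranking == ["A", "B"]

    def test_no_match_broadest_first(self):
        ranking = informed_microbiologist_rank(
            "KL9", {"C": {"KL1", "KL2", "KL3"}, "D": {"KL4"}}
        )
        assert ranking == ["C", "D"]

    def test_tie_broken_lexicographically(self):
        ranking = informed_microbiologist_rank(
            "KL1", {"Z": {"KL1"}, "A": {"KL1"}}
        )
        assert ranking == ["A", "Z"]

    def test_unknown_kl_warns_and_uses_breadth(self):
        with pytest.warns(UserWarning):
            ranking = informed_microbiologist_rank(
                "unknown", {"A": {"KL1"}, "B": {"KL1", "KL2"}}
            )
        assert ranking == ["B", "A"]


class TestConfusionSummary:
    def _case(self, tp, fp, fn):
        topk = [(f"tp{i}", "b") for i in range(tp)] + [
            (f"fp{i}", "b") for i in range(fp)
        ]
        lab = {pair: 1 for pair in topk[:tp]}
        lab.update({pair: 0 for pair in topk[tp:]})
        lab.update({(f"fn{i}", "b"): 1 for i in range(fn)})
        return topk, lab

    def test_wet_lab_counts(self):
        # 26 confirmed in the top five, 7 confirmed outside: recall 78.8%
        topk, lab = self._case(tp=26, fp=114, fn=7)
        summary = confusion_summary(topk, lab)
        assert summary["TP"] == 26 and summary["FP"] == 114 and summary["FN"] == 7
        assert summary["recall_pct"] == 78.8
        assert summary["precision_pct"] == 18.6
        assert summary["TN"] == "not considered"

    def test_zero_recall(self):
        topk, lab = self._case(tp=0, fp=3, fn=3)
        assert confusion_summary(topk, lab)["recall_pct"] == 0.0

    def test_duplicate_pair_errors(self):
        with pytest.raises(ValueError, match="twice"):
            confusion_summary([("p", "b"), ("p", "b")], {("p", "b"): 1})


# ---------------------------------------------------------------------------
# LOGOCV on the synthetic dataset
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def logocv_run(tiny_dataset, tiny_features):
    phages, bacteria, table, truth = tiny_dataset
    X, y, table, *_ = tiny_features
    M = identity_matrix([b.klocus_nt for b in bacteria])
    groups = group_by_identity(M, 100, [b.bacterium_id for b in bacteria])
    folds = run_logocv(X, table.frame, groups, seed=0)
    return groups, folds, table


class TestLogocv:
    def test_one_fold_per_group_with_tested_pairs(self, logocv_run):
        groups, folds, table = logocv_run
        groups_with_rows = set(
            table.frame["bacterium_id"].map(groups.mapping)
        )
        assert {f.group_id for f in folds} == groups_with_rows

    def test_fold_disjointness(self, logocv_run, tiny_dataset):
        groups, folds, table = logocv_run
        for fold in folds:
            held = set(fold.pairs["bacterium_id"])
            train_bact = set(table.frame["bacterium_id"]) - {
                b for b, g in groups.mapping.items() if g == fold.group_id
            }
            assert not held & train_bact

    def test_every_tested_pair_predicted_exactly_once(self, logocv_run):
        _, folds, table = logocv_run
        pooled = pd.concat([f.pairs for f in folds])
        seen = set(zip(pooled["phage_id"], pooled["bacterium_id"]))
        expected = set(zip(table.frame["phage_id"], table.frame["bacterium_id"]))
        assert seen == expected and len(pooled) == len(table)

    def test_planted_rule_recovered(self, logocv_run):
        _, folds, _ = logocv_run
        assert roc_auc(folds) >= 0.9

    def test_single_group_errors(self, tiny_features):
        X, y, table, *_ = tiny_features
        mapping = {b: "g0" for b in table.frame["bacterium_id"]}
        with pytest.raises(ValueError):
            run_logocv(X, table.frame, mapping, seed=0)
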