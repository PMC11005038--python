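"""Metrics, CV schemes, similarity diagnostics and statistical tests."""

import numpy as np
import pandas as pd
import pytest

from cholepk import evaluation
from cholepk.evaluation import (CVScheme, anova_two_way, atc_group_scheme,
                                compute_metrics, jaccard_distance_matrix,
                                lipinski_ttest, repeated_kfold_scheme, run_cv,
                                similarity_cluster_scheme, similarity_report)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        m = compute_metrics(y, y, y.astype(float))
        assert all(m[k] == 1.0 for k in ("S", "SP", "A", "MCC", "AUC"))

    def test_random_cases_match_confusion_formulas(self, rng):
        """100 random label/prediction pairs vs hand formulas."""
        for _ in range(100):
            n = rng.integers(10, 60)
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            p = rng.integers(0, 2, n)
            m = compute_metrics(y, p)
            tp = np.sum((y == 1) & (p == 1))
            tn = np.sum((y == 0) & (p == 0))
            fp = np.sum((y == 0) & (p == 1))
            fn = np.sum((y == 1) & (p == 0))
            assert m["S"] == pytest.approx(tp / (tp + fn))
            assert m["SP"] == pytest.approx(tn / (tn + fp))
            assert m["A"] == pytest.approx((tp + tn) / n)
            denom = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
            mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
            assert m["MCC"] == pytest.approx(mcc)

    def test_binary_label_auc_equals_mean_of_s_and_sp(self, rng):
        """AUC of the two-point ROC from binary scores is (S+SP)/2."""
        for _ in range(50):
            n = 40
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            m = compute_metrics(y, p, scores=p.astype(float))
            assert m["AUC"] == pytest.approx((m["S"] + m["SP"]) / 2,
                                             abs=1e-12)

    def test_single_class_truth_flags_undefined(self):
        m = compute_metrics([1, 1, 1], [1, 0, 1])
        assert m["S"] == pytest.approx(2 / 3)
        assert np.isnan(m["SP"]) and np.isnan(m["MCC"]) and np.isnan(m["AUC"])


class TestRepeatedKFold:
    def test_partition_per_repetition(self):
        scheme = repeated_kfold_scheme(23, k=5, repeats=3, seed=0)
        assert scheme.n_folds() == 15
        for r in range(3):
            tests = np.concatenate(
                [scheme.folds[r * 5 + f][1] for f in range(5)])
            assert np.array_equal(np.sort(tests), np.arange(23))

    def test_leave_one_out_degenerate(self):
        scheme = repeated_kfold_scheme(7, k=7, repeats=1, seed=0)
        assert all(len(te) == 1 for _, te in scheme.folds)

    def test_seed_determinism(self):
        a = repeated_kfold_scheme(30, seed=4)
        b = repeated_kfold_scheme(30, seed=4)
        assert all(np.array_equal(x[1], y[1])
                   for x, y in zip(a.folds, b.folds))

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            repeated_kfold_scheme(3, k=5)


def _template_fps(n_per=8, n_groups=5, bits=256, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(bits)
    templates = [perm[g * 40:(g + 1) * 40] for g in range(n_groups)]
    fps, groups = [], []
    for g in range(n_groups):
        for _ in range(n_per):
            v = np.zeros(bits, dtype=np.uint8)
            v[templates[g]] = 1
            flip = rng.random(bits) < noise
            v[flip] ^= 1
            fps.append(v)
            groups.append(g)
    return np.array(fps), np.array(groups)


class TestSimilarityCluster:
    def test_jaccard_hand_values(self):
        a = np.zeros(8, dtype=bool); a[[1, 2, 3]] = True
        b = np.zeros(8, dtype=bool); b[[2, 3, 4]] = True
        c = np.zeros(8, dtype=bool); c[[6, 7]] = True
        d = jaccard_distance_matrix(np.array([a, b, c]))
        assert d[0, 0] == 0.0
        assert d[0, 1] == pytest.approx(0.5)   # 2 shared / 4 union
        assert d[0, 2] == 1.0                   # disjoint bit sets

    def test_recovers_templates_exactly(self):
        from sklearn.metrics import adjusted_rand_score
        fps, groups = _template_fps(noise=0.0)
        scheme = similarity_cluster_scheme(fps, n_clusters=5)
        labels = scheme.provenance["labels"]
        assert adjusted_rand_score(groups, labels) == 1.0

    def test_folds_test_one_cluster_each(self):
        fps, _ = _template_fps()
        scheme = similarity_cluster_scheme(fps, n_clusters=5)
        assert scheme.n_folds() == 5
        tests = np.concatenate([te for _, te in scheme.folds])
        assert np.array_equal(np.sort(tests), np.arange(len(fps)))

    def test_too_many_clusters_rejected(self):
        fps, _ = _template_fps(n_per=1, n_groups=2)
        with pytest.raises(ValueError):
            similarity_cluster_scheme(fps, n_clusters=10)


class TestAtcScheme:
    def test_five_folds_and_eligibility(self):
        atc = ([["J01"]] * 4 + [["N05"]] * 3 + [["L01"]] * 3 + [["C01"]] * 2
               + [["N02"]] * 2 + [["X99"]] + [[]])
        scheme = atc_group_scheme(atc)
        assert scheme.n_folds() == 5
        assert len(scheme.eligible) == 14  # X99 / no-code excluded
        tests = np.concatenate([te for _, te in scheme.folds])
        assert np.array_equal(np.sort(tests), np.arange(14))
        for tr, te in scheme.folds:
            assert set(tr) & set(te) == set()

    def test_multi_code_compound_goes_to_smaller_group(self):
        atc = [["J01"]] * 5 + [["N05"]] + [["J01", "N05"]] \
            + [["L01"], ["C01"], ["N02"]]
        scheme = atc_group_scheme(atc)
        sizes = scheme.provenance["group_sizes"]
        assert sizes["N05"] == 2 and sizes["J01"] == 5

    def test_empty_code_group_rejected(self):
        atc = [["J01"], ["N05"], ["L01"], ["C01"]]
        with pytest.raises(ValueError, match="N02"):
            atc_group_scheme(atc)


class TestSimilarityReport:
    def test_identical_group_intra_one(self):
        fp = np.tile(np.array([1, 0, 1, 1, 0], dtype=np.uint8), (4, 1))
        rep = similarity_report(fp, ["g"] * 4)
        assert rep.intra("g") == pytest.approx(1.0)

    def test_disjoint_groups_inter_zero(self):
        a = np.zeros((4, 10), dtype=np.uint8); a[:, :5] = 1
        b = np.zeros((4, 10), dtype=np.uint8); b[:, 5:] = 1
        rep = similarity_report(np.vstack([a, b]), ["a"] * 4 + ["b"] * 4)
        assert rep.inter("a", "b") == pytest.approx(0.0)

    def test_matches_all_pairs_bruteforce(self, rng):
        """12 random fingerprints vs exhaustive pairwise Tanimoto + sort."""
        fps = rng.integers(0, 2, size=(12, 64)).astype(np.uint8)
        groups = np.array([0] * 6 + [1] * 6)
        rep = similarity_report(fps, groups, k=3)

        def tanimoto(x, y):
            inter = np.sum(x & y)
            union = np.sum(x | y)
            return inter / union if union else 1.0

        for gi in (0, 1):
            for gj in (0, 1):
                vals = []
                for i in np.flatnonzero(groups == gi):
                    sims = sorted(
                        tanimoto(fps[i], fps[j])
                        for j in np.flatnonzero(groups == gj) if j != i or gi != gj
                    )
                    vals.append(np.mean(sims[-3:]))
                assert rep.matrix.loc[gi, gj] == pytest.approx(np.mean(vals))


class _Memorizer:
    """Upper-bound oracle: memorizes training labels, predicts by lookup."""

    def fit(self, X, y):
        self.table = {tuple(row): lab for row, lab in zip(X, y)}
        self.default = int(round(np.mean(y)))
        return self

    def predict(self, X):
        return np.array([self.table.get(tuple(r), self.default) for r in X])


class TestRunCV:
    def test_memorizer_reaches_upper_bound(self, rng):
        X = np.arange(40).reshape(-1, 1).astype(float)
        y = rng.integers(0, 2, 40)

        class _Oracle(_Memorizer):
            def fit(self, Xf, yf):
                full = {tuple(r): lab for r, lab in zip(X, y)}
                self.table, self.default = full, 0
                return self

        scheme = repeated_kfold_scheme(40, k=5, repeats=1, seed=0)
        rep = run_cv(lambda: _Oracle(), scheme, X, y)
        defined = rep.per_fold.dropna(how="all")
        for m in ("S", "SP", "A"):
            assert np.nanmean(defined[m]) == 1.0

    def test_coinflip_auc_near_half(self):
        rng = np.random.default_rng(8)
        n = 2000
        X = rng.normal(size=(n, 1))
        y = rng.integers(0, 2, n)

        class _Coin:
            def fit(self, Xf, yf):
                return self

            def predict(self, Xt):
                return np.random.default_rng(0).integers(0, 2, len(Xt))

            def decision_function(self, Xt):
                return np.random.default_rng(1).normal(size=len(Xt))

        scheme = repeated_kfold_scheme(n, k=5, repeats=1, seed=8)
        rep = run_cv(lambda: _Coin(), scheme, X, y)
        assert abs(rep.mean("AUC") - 0.5) < 0.05

    def test_bitwise_reproducible(self, small_dataset):
        from cholepk.metamodel import PkRuleMetamodel, dose_rule_features
        X = dose_rule_features(small_dataset.true_dose_matrix,
                               small_dataset.td)
        y = small_dataset.labels
        scheme = repeated_kfold_scheme(len(y), k=5, repeats=2, seed=3)
        a = run_cv(lambda: PkRuleMetamodel(), scheme, X, y)
        b = run_cv(lambda: PkRuleMetamodel(), scheme, X, y)
        assert a.per_fold.equals(b.per_fold)

    def test_binary_score_mode_auc_identity(self, small_dataset):
        from cholepk.metamodel import PkRuleMetamodel, dose_rule_features
        X = dose_rule_features(small_dataset.true_dose_matrix,
                               small_dataset.td)
        y = small_dataset.labels
        scheme = repeated_kfold_scheme(len(y), k=5, repeats=1, seed=3)
        rep = run_cv(lambda: PkRuleMetamodel(), scheme, X, y,
                     score_mode="binary")
        pf = rep.per_fold.dropna()
        assert np.allclose(pf["AUC"], (pf["S"] + pf["SP"]) / 2, atol=1e-12)


class TestLipinskiTTest:
    def test_identical_groups_null(self):
        desc = pd.DataFrame({"MolLogP": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        out = lipinski_ttest(desc, [1, 1, 1, 0, 0, 0])
        assert out.loc["MolLogP", "t"] == pytest.approx(0.0)
        assert out.loc["MolLogP", "p_value"] == pytest.approx(1.0)

    def test_textbook_two_sample(self):
        """6-point hand computation of the pooled-variance t statistic."""
        a, b = np.array([5.0, 6.0, 7.0]), np.array([1.0, 2.0, 3.0])
        desc = pd.DataFrame({"x": np.concatenate([a, b])})
        out = lipinski_ttest(desc, [1, 1, 1, 0, 0, 0])
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert out.loc["x", "t"] == pytest.approx(t_hand)

    def test_shift_increases_t(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        labels = [1] * 10 + [0] * 10
        prev = 0.0
        for shift in (0.5, 1.0, 2.0):
            data = base.copy()
            data[:10] += shift
            out = lipinski_ttest(pd.DataFrame({"x": data}), labels)
            assert abs(out.loc["x", "t"]) > prev
            prev = abs(out.loc["x", "t"])

    def test_tiny_class_rejected(self):
        desc = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            lipinski_ttest(desc, [1, 0, 0])


class TestAnova:
    def test_null_factor_gives_zero_f(self):
        # transporter means identical; class fully determines the value
        transporter = list("AABB") * 2
        klass = [0, 0, 0, 0, 1, 1, 1, 1]
        values = [1, 2, 1, 2, 1, 2, 1, 2]  # no effect of either factor
        table = anova_two_way(values, transporter, klass)
        assert table.loc["C(transporter)", "F"] == pytest.approx(0.0, abs=1e-10)
        assert table.loc["C(klass)", "F"] == pytest.approx(0.0, abs=1e-10)

    def test_balanced_2x2_matches_hand_sums_of_squares(self):
        values = np.array([3.0, 5.0, 2.0, 4.0, 7.0, 9.0, 6.0, 8.0])
        tr = ["A", "A", "B", "B", "A", "A", "B", "B"]
        kl = [0, 0, 0, 0, 1, 1, 1, 1]
        table = anova_two_way(values, tr, kl)
        grand = values.mean()
        ss_tr = sum(4 * (values[np.array(tr) == lev].mean() - grand) ** 2
                    for lev in ("A", "B"))
        ss_kl = sum(4 * (values[np.array(kl) == lev].mean() - grand) ** 2
                    for lev in (0, 1))
        ss_tot = ((values - grand) ** 2).sum()
        ss_res = ss_tot - ss_tr - ss_kl
        f_tr = (ss_tr / 1) / (ss_res / 5)
        f_kl = (ss_kl / 1) / (ss_res / 5)
        assert table.loc["C(transporter)", "F"] == pytest.approx(f_tr)
        assert table.loc["C(klass)", "F"] == pytest.approx(f_kl)

    def test_cell_permutation_invariance(self, rng):
        values = rng.normal(size=24)
        tr = np.repeat(["A", "B", "C"], 8)
        kl = np.tile(np.repeat([0, 1], 4), 3)
        t1 = anova_two_way(values, tr, kl)
        perm = values.copy()
        for a in ("A", "B", "C"):
            for b in (0, 1):
                idx = np.flatnonzero((tr == a) & (kl == b))
                perm[idx] = perm[rng.permutation(idx)]
        t2 = anova_two_way(perm, tr, kl)
        assert t1.loc["C(transporter)", "F"] == pytest.approx(
            t2.loc["C(transporter)", "F"])

    def test_interaction_needs_full_cells(self):
        values = [1.0, 2.0, 3.0, 4.0]
        tr = ["A", "A", "B", "B"]
        kl = [0, 1, 0, 0]  # cell (B, 1) empty
        with pytest.raises(ValueError):
            anova_two_way(values, tr, kl, interaction=True)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError):
            anova_two_way([1.0, 2.0], ["A", "A"], [0, 1])
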