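import numpy as np
import pytest

import wavefeat as wf
from wavefeat.datasets import InvalidInputError
from wavefeat.selection import _encode_labels, stratified_folds

from conftest import make_score_table


class TestParallelAnalysis:
    def test_boundary_equal_to_reference_retains_nothing(self):
        ref = wf.parallel_reference(40, np.full(40, 1 / 40), n_reps=10, seed=0)
        assert wf.parallel_analysis(ref.copy(), 40, np.full(40, 1 / 40),
                                    reference=ref) == []

    def test_dominant_signal_retained(self):
        ref = wf.parallel_reference(40, np.full(40, 1 / 40), n_reps=10, seed=1)
        eig = np.zeros(101)
        eig[0] = 101.0
        assert wf.parallel_analysis(eig, 40, np.full(40, 1 / 40),
                                    reference=ref) == [1]

    def test_matches_independent_reimplementation(self):
        n, reps, seed = 35, 20, 123
        rng = np.random.default_rng(7)
        w = rng.uniform(0.5, 1.5, n)
        w /= w.sum()
        X_obs = np.random.default_rng(8).normal(size=(n, 101))
        model = wf.fit_variable_pca(X_obs, w)
        got = wf.parallel_analysis(model.eigenvalues, n, w, n_reps=reps, seed=seed)

        # independent re-run with the same replicate stream
        rng2 = np.random.default_rng(seed)
        acc = np.zeros(101)
        for _ in range(reps):
            X = rng2.normal(size=(n, 101))
            mu = w @ X
            sd = np.sqrt(w @ (X - mu) ** 2)
            Z = (X - mu) / sd
            R = (Z * w[:, None]).T @ Z
            acc += np.clip(np.linalg.eigvalsh(0.5 * (R + R.T))[::-1], 0, None)
        ref = acc / reps
        expected = [k + 1 for k in range(101) if model.eigenvalues[k] > ref[k]]
        assert got == expected

    def test_too_few_trials_rejected(self):
        with pytest.raises(InvalidInputError):
            wf.parallel_reference(1, np.array([1.0]), n_reps=10, seed=0)


class TestScreening:
    def test_identical_distributions_dropped(self):
        x = np.tile([0.0, 1.0, 2.0, 3.0], 2)
        table = make_score_table(x, ["symptomatic"] * 4 + ["control"] * 4)
        out = wf.screen_features(table)
        assert out["t"].iloc[0] == pytest.approx(0.0)
        assert not out["retained"].iloc[0]

    def test_hand_computed_welch_t(self):
        # {0,0,1,1} vs {2,2,3,3}: diff -2, se = sqrt(1/3/4 + 1/3/4) -> t = -4.899?
        # Welch: va=vb=1/3, se=sqrt(1/12+1/12)=0.40825 -> t = -4.899
        x = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        table = make_score_table(x, ["symptomatic"] * 4 + ["control"] * 4)
        out = wf.screen_features(table)
        assert out["t"].iloc[0] == pytest.approx(-4.8989794855, abs=1e-6)
        assert out["retained"].iloc[0]

    def test_threshold_is_inclusive_at_two(self):
        # two-per-group samples with exactly solvable t = -m / sqrt(0.5)
        def t_for(m):
            x = np.array([0.0, 1.0, m, m + 1.0])
            table = make_score_table(x, ["symptomatic"] * 2 + ["control"] * 2)
            return wf.screen_features(table)

        just_below = t_for(1.999 * np.sqrt(0.5))
        assert not just_below["retained"].iloc[0]
        above = t_for(2.001 * np.sqrt(0.5))
        assert above["retained"].iloc[0]

    def test_group_swap_flips_sign(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        groups = ["symptomatic"] * 18 + ["control"] * 12
        flipped = ["control" if g == "symptomatic" else "symptomatic"
                   for g in groups]
        t1 = wf.screen_features(make_score_table(x, groups))["t"].iloc[0]
        t2 = wf.screen_features(make_score_table(x, flipped))["t"].iloc[0]
        assert t1 == pytest.approx(-t2)

    def test_sorted_by_descending_magnitude(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 6))
        X[:20, 2] += 4.0
        out = wf.screen_features(make_score_table(
            X, ["symptomatic"] * 20 + ["control"] * 20))
        assert out["abs_t"].is_monotonic_decreasing


class TestNaiveBayesCV:
    def test_perfectly_separated_classes(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-10, 0.5, 30), rng.normal(10, 0.5, 30)])
        groups = np.array(["symptomatic"] * 30 + ["control"] * 30)
        assert wf.naive_bayes_cv_error(x, groups, n_folds=10, seed=0) == 0.0

    def test_empty_feature_set_majority_rule(self):
        groups = np.array(["symptomatic"] * 193 + ["control"] * 107)
        X = np.empty((300, 0))
        err = wf.naive_bayes_cv_error(X, groups, n_folds=10, seed=1)
        assert err == pytest.approx(107 / 300)

    def test_four_trial_toy_hand_computed(self):
        # classes {0,1} vs {10,11}; fold [0,1,0,1] trains on {1,11} and {0,10}.
        # Zero class variances floor to 1e-9 * pooled; each held-out point is
        # orders of magnitude nearer its own class mean -> error 0.
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        groups = np.array(["symptomatic"] * 2 + ["control"] * 2)
        err = wf.naive_bayes_cv_error(X, groups, n_folds=2,
                                      fold=np.array([0, 1, 0, 1]))
        assert err == 0.0

    def test_matches_sklearn_gaussian_nb_per_fold(self):
        from sklearn.naive_bayes import GaussianNB

        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 2, 60)
        y[:12] = 0
        y[12:24] = 1  # ensure both classes well represented
        groups = np.where(y == 0, "symptomatic", "control")
        fold = stratified_folds(_encode_labels(groups), 5,
                                np.random.default_rng(6))
        ours = wf.naive_bayes_cv_error(X, groups, n_folds=5, fold=fold)
        errors = 0
        y01 = _encode_labels(groups)
        for k in range(5):
            clf = GaussianNB(var_smoothing=0.0)
            clf.fit(X[fold != k], y01[fold != k])
            errors += int((clf.predict(X[fold == k]) != y01[fold == k]).sum())
        assert ours == pytest.approx(errors / 60)

    def test_label_independent_feature_errs_at_majority_rate(self):
        rng = np.random.default_rng(7)
        groups = np.array(["symptomatic"] * 24 + ["control"] * 16)
        errs = [wf.naive_bayes_cv_error(rng.normal(size=40), groups,
                                        n_folds=4, seed=rng)
                for _ in range(100)]
        # permutation-null CV error concentrates near the minority rate 0.4
        assert np.mean(errs) == pytest.approx(0.45, abs=0.1)

    def test_too_few_per_class_for_folds(self):
        groups = np.array(["symptomatic"] * 3 + ["control"] * 12)
        with pytest.raises(InvalidInputError):
            wf.naive_bayes_cv_error(np.zeros((15, 1)), groups, n_folds=5, seed=0)


class TestSequentialSelection:
    def _table_and_screened(self, X, groups):
        table = make_score_table(X, groups)
        screened = wf.screen_features(table, threshold=0.0)
        screened["retained"] = True
        return table, screened

    def test_single_informative_feature_always_selected(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(-3, 1, 30), rng.normal(3, 1, 20)])
        groups = ["symptomatic"] * 30 + ["control"] * 20
        table, screened = self._table_and_screened(x, groups)
        res = wf.sequential_selection(table, screened, n_iterations=50,
                                      n_folds=5, seed=9)
        (fid,) = res.main_features
        assert res.selection_frequency[fid] == 50

    def test_greedy_path_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        n = 60
        groups = np.array(["symptomatic"] * 36 + ["control"] * 24)
        signal = np.where(groups == "symptomatic", -1.0, 1.0)
        X = np.column_stack([
            signal + rng.normal(0, 1.2, n),
            signal + rng.normal(0, 2.0, n),
            rng.normal(size=n),
        ])
        table, screened = self._table_and_screened(X, groups)
        seed = 11
        res = wf.sequential_selection(table, screened, n_iterations=1,
                                      n_folds=5, seed=seed)

        # oracle: replay the same fold stream, then exhaustively evaluate
        # every candidate addition at every greedy step
        rng2 = np.random.default_rng(seed)
        y01 = _encode_labels(np.asarray(groups))
        fold = stratified_folds(y01, 5, rng2)
        feats = [wf.FeatureId(v, int(p))
                 for v, p in zip(screened["variable"], screened["pc"])]
        cols = {f: table.feature(f) for f in feats}
        selected = []
        current = wf.naive_bayes_cv_error(np.empty((n, 0)), groups,
                                          n_folds=5, fold=fold)
        while len(selected) < 10:
            best = None
            for f in feats:
                if f in selected:
                    continue
                Xs = np.column_stack([cols[g] for g in selected + [f]])
                e = wf.naive_bayes_cv_error(Xs, groups, n_folds=5, fold=fold)
                if best is None or e < best[0]:
                    best = (e, f)
            if best is None or best[0] >= current:
                break
            current = best[0]
            selected.append(best[1])
        assert set(f for f, c in res.selection_frequency.items() if c > 0) \
            == set(selected)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(50, 4))
        X[:30, 0] -= 1.5
        groups = ["symptomatic"] * 30 + ["control"] * 20
        table, screened = self._table_and_screened(X, groups)
        r1 = wf.sequential_selection(table, screened, n_iterations=30,
                                     n_folds=5, seed=13)
        r2 = wf.sequential_selection(table, screened, n_iterations=30,
                                     n_folds=5, seed=13)
        assert r1.main_features == r2.main_features
        assert r1.selection_frequency == r2.selection_frequency

    def test_containment_invariant(self, acceptance_run):
        sel = acceptance_run.selection
        sel.validate_containment()
        assert set(sel.main_features) <= set(sel.screened_features())
        assert set(sel.screened_features()) <= set(sel.retained_after_parallel)

    def test_no_screened_features_rejected(self):
        table = make_score_table(np.zeros((10, 0)),
                                 ["symptomatic"] * 5 + ["control"] * 5)
        screened = wf.screen_features(table)
        with pytest.raises(InvalidInputError):
            wf.sequential_selection(table, screened, seed=0)
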