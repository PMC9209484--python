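"""Filtering criteria: classifier vote, feature importance, marker ranges."""

import numpy as np
import pandas as pd
import pytest

import netfate as nf
from netfate.filters import CLASSIFIER_NAMES
from netfate.screen import ScreenResult


def _blobs(n_per=60, n_features=6, sep=8.0, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 0.5, (n_per, n_features))
    X1 = rng.normal(sep, 0.5, (n_per, n_features))
    X = pd.DataFrame(
        np.vstack([X0, X1]),
        index=[f"a{i}" for i in range(2 * n_per)],
        columns=[f"g{j}" for j in range(n_features)],
    )
    y = pd.Series([0] * n_per + [1] * n_per, index=X.index)
    return X, y


def _screen_from(values: np.ndarray, scheme_ids, replicates, columns) -> ScreenResult:
    index = pd.MultiIndex.from_tuples(
        [(r, sid) for sid in scheme_ids for r in replicates],
        names=["replicate", "scheme_id"],
    )
    attr = pd.DataFrame(values, index=index, columns=columns)
    conv = pd.Series(True, index=index)
    iters = pd.Series(1, index=index)
    return ScreenResult(attr, conv, iters, list(scheme_ids), list(replicates))


class TestTrainClassifiers:
    def test_separable_blobs_high_accuracy(self):
        X, y = _blobs()
        clfs = nf.train_classifiers(X, y, seed=0)
        assert all(acc >= 0.99 for acc in clfs.training_accuracy.values())

    def test_shuffled_labels_near_chance_on_held_out(self):
        X, y = _blobs(n_per=100)
        rng = np.random.default_rng(1)
        y_shuf = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        train = X.index[:150]
        test = X.index[150:]
        clfs = nf.train_classifiers(X.loc[train], y_shuf.loc[train], seed=0)
        preds = clfs.predict(X.loc[test])
        accs = [float((p == y_shuf.loc[test].to_numpy()).mean()) for p in preds.values()]
        assert all(acc < 0.7 for acc in accs)  # no signal to learn

    def test_single_cluster_rejected(self):
        X, _ = _blobs(n_per=10)
        y = pd.Series(0, index=X.index)
        with pytest.raises(ValueError, match="at least 2 clusters"):
            nf.train_classifiers(X, y, seed=0)

    def test_refit_same_seed_identical_predictions(self):
        X, y = _blobs(n_per=40, sep=2.0)
        p1 = nf.train_classifiers(X, y, seed=3).predict(X)
        p2 = nf.train_classifiers(X, y, seed=3).predict(X)
        for name in CLASSIFIER_NAMES:
            np.testing.assert_array_equal(p1[name], p2[name])


class TestCriterion1:
    @pytest.fixture
    def fitted(self):
        X, y = _blobs()
        return nf.train_classifiers(X, y, seed=0), X.columns

    def test_two_of_three_vote_rule(self, fitted):
        clfs, cols = fitted
        # one attractor deep in cluster-1 territory, one in cluster-0
        screen = _screen_from(
            np.array([[8.0] * 6, [0.0] * 6]), ["s_pass", "s_fail"], ["r0"], cols
        )
        votes = nf.criterion1(clfs, screen, desired_clusters={1})
        assert votes.loc[("r0", "s_pass"), "passes"]
        assert not votes.loc[("r0", "s_fail"), "passes"]

    def test_all_replicates_required(self, fitted):
        clfs, cols = fitted
        # same scheme lands in the desired cluster for r0 but not r1
        values = np.array([[8.0] * 6, [0.0] * 6])
        screen = _screen_from(values, ["s"], ["r0", "r1"], cols)
        votes = nf.criterion1(clfs, screen, desired_clusters={1})
        assert votes.loc[("r0", "s"), "passes"]
        assert not votes.loc[("r1", "s"), "passes"]
        assert not votes["pass_all_replicates"].any()

    def test_empty_desired_clusters_rejected(self, fitted):
        clfs, cols = fitted
        screen = _screen_from(np.zeros((1, 6)), ["s"], ["r0"], cols)
        with pytest.raises(ValueError):
            nf.criterion1(clfs, screen, desired_clusters=set())


class TestFeatureImportance:
    def test_top_list_length_is_ceil_ten_percent(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            rng.normal(0, 1, (80, 36)), columns=[f"g{j}" for j in range(36)]
        )
        y = pd.Series((X["g0"] > 0).astype(int).to_numpy(), index=X.index)
        X.loc[:, "g0"] += y.to_numpy() * 5  # make it learnable
        clfs = nf.train_classifiers(X, y, seed=0)
        imp = nf.feature_importance(clfs, X, y)
        for name in CLASSIFIER_NAMES:
            assert imp[name]["top"].sum() == 4  # ceil(0.1 * 36)

    def test_planted_informative_node_ranks_first(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            rng.normal(0, 0.2, (120, 10)), columns=[f"g{j}" for j in range(10)]
        )
        y = pd.Series(np.repeat([0, 1], 60), index=X.index)
        X.loc[:, "g7"] += y.to_numpy() * 6.0  # the only informative feature
        clfs = nf.train_classifiers(X, y, seed=0)
        imp = nf.feature_importance(clfs, X, y)
        for name in CLASSIFIER_NAMES:
            assert imp[name].iloc[0]["feature"] == "g7"

    def test_constant_feature_zero_permutation_importance(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(
            {
                "informative": np.repeat([0.0, 5.0], 40) + rng.normal(0, 0.1, 80),
                "constant": np.full(80, 1.0),
            }
        )
        y = pd.Series(np.repeat([0, 1], 40), index=X.index)
        clfs = nf.train_classifiers(X, y, seed=0)
        imp = nf.feature_importance(clfs, X, y)
        nb = imp["naive_bayes"].set_index("feature")
        assert nb.loc["constant", "importance"] == pytest.approx(0.0)

    def test_summary_tabulates_recurrence(self):
        X, y = _blobs(n_per=40)
        clfs = nf.train_classifiers(X, y, seed=0)
        imp = nf.feature_importance(clfs, X, y)
        assert set(imp["summary"]["n_classifiers"]) <= {1, 2, 3}


def _marker_setup(attr_value, desired=2.0, undesired=1.0):
    screen = _screen_from(
        np.array([[attr_value]]), ["s"], ["r0"], ["m"]
    )
    desired_df = pd.DataFrame({"m": [desired]})
    undesired_df = pd.DataFrame({"m": [undesired]})
    return screen, desired_df, undesired_df


class TestCriterion2:
    def test_strict_pass_beyond_desired_value(self):
        screen, d, u = _marker_setup(2.3)
        rep = nf.criterion2(screen, [nf.MarkerSpec("m")], d, u, mode="strict")
        assert rep.loc[("r0", "s"), "passes"]

    def test_between_values_fails_strict_passes_relaxed(self):
        screen, d, u = _marker_setup(1.5)
        strict = nf.criterion2(screen, [nf.MarkerSpec("m")], d, u, mode="strict")
        relaxed = nf.criterion2(screen, [nf.MarkerSpec("m")], d, u, mode="relaxed")
        assert not strict.loc[("r0", "s"), "passes"]
        assert relaxed.loc[("r0", "s"), "passes"]

    def test_down_direction(self):
        screen, d, u = _marker_setup(0.4, desired=0.5, undesired=1.0)
        rep = nf.criterion2(screen, [nf.MarkerSpec("m")], d, u, mode="strict")
        assert rep.loc[("r0", "s"), "passes"]

    @pytest.mark.parametrize("n_pass,verdict", [(9, True), (8, False)])
    def test_ninety_percent_threshold(self, n_pass, verdict):
        cols = [f"m{i}" for i in range(10)]
        values = np.array([[2.5] * n_pass + [1.5] * (10 - n_pass)])
        screen = _screen_from(values, ["s"], ["r0"], cols)
        d = pd.DataFrame({c: [2.0] for c in cols})
        u = pd.DataFrame({c: [1.0] for c in cols})
        rep = nf.criterion2(screen, [nf.MarkerSpec(c) for c in cols], d, u)
        assert rep.loc[("r0", "s"), "passes"] == verdict

    def test_groups_checked_independently(self):
        cols = ["a0", "a1", "p0"]
        # both apoptosis markers pass, the proliferation one fails
        screen = _screen_from(np.array([[2.5, 2.5, 1.5]]), ["s"], ["r0"], cols)
        d = pd.DataFrame({c: [2.0] for c in cols})
        u = pd.DataFrame({c: [1.0] for c in cols})
        markers = [
            nf.MarkerSpec("a0", group="apoptosis"),
            nf.MarkerSpec("a1", group="apoptosis"),
            nf.MarkerSpec("p0", group="proliferation"),
        ]
        rep = nf.criterion2(screen, markers, d, u, threshold=0.9)
        assert not rep.loc[("r0", "s"), "passes"]
        assert rep.loc[("r0", "s"), "fraction_apoptosis"] == 1.0
        assert rep.loc[("r0", "s"), "fraction_proliferation"] == 0.0

    def test_unresolvable_marker_excluded_with_warning(self):
        cols = ["good", "flat"]
        screen = _screen_from(np.array([[2.5, 1.0]]), ["s"], ["r0"], cols)
        d = pd.DataFrame({"good": [2.0], "flat": [1.0]})
        u = pd.DataFrame({"good": [1.0], "flat": [1.0]})
        with pytest.warns(RuntimeWarning, match="unresolvable"):
            rep = nf.criterion2(
                screen, [nf.MarkerSpec("good"), nf.MarkerSpec("flat")], d, u
            )
        assert rep.loc[("r0", "s"), "passes"]  # denominator is the single good marker

    def test_marker_and_group_order_invariance(self):
        cols = ["a", "b", "c"]
        screen = _screen_from(np.array([[2.5, 2.5, 0.5]]), ["s"], ["r0"], cols)
        d = pd.DataFrame({c: [2.0] for c in cols})
        u = pd.DataFrame({c: [1.0] for c in cols})
        markers = [nf.MarkerSpec("a"), nf.MarkerSpec("b"), nf.MarkerSpec("c")]
        r1 = nf.criterion2(screen, markers, d, u, threshold=0.5)
        r2 = nf.criterion2(screen, markers[::-1], d, u, threshold=0.5)
        assert (
            r1.loc[("r0", "s"), "passes"] == r2.loc[("r0", "s"), "passes"]
            and r1.loc[("r0", "s"), "fraction"] == r2.loc[("r0", "s"), "fraction"]
        )

    def test_threshold_monotonicity(self):
        cols = [f"m{i}" for i in range(4)]
        screen = _screen_from(np.array([[2.5, 2.5, 2.5, 1.5]]), ["s"], ["r0"], cols)
        d = pd.DataFrame({c: [2.0] for c in cols})
        u = pd.DataFrame({c: [1.0] for c in cols})
        markers = [nf.MarkerSpec(c) for c in cols]
        passed = [
            nf.criterion2(screen, markers, d, u, threshold=t).loc[("r0", "s"), "passes"]
            for t in (0.5, 0.75, 0.9, 1.0)
        ]
        # once failing, never passes again at a higher threshold
        assert passed == sorted(passed, reverse=True)


class TestSummarize:
    def _report(self, survivor_ids, replicates=("r0",)):
        all_ids = list(survivor_ids)
        tuples = [(r, s) for s in all_ids for r in replicates]
        votes_index = pd.MultiIndex.from_arrays(
            [[t[0] for t in tuples], [t[1] for t in tuples]],
            names=["replicate", "scheme_id"],
        )
        votes = pd.DataFrame(
            {"passes": True, "pass_all_replicates": True}, index=votes_index
        )
        c2 = pd.DataFrame({"passes": True, "fraction": 1.0}, index=votes_index)
        return nf.FilterReport(votes, c2)

    def test_smallest_scheme_ranks_first(self):
        report = self._report(["A:up|B:up|C:up", "A:up|B:unchanged|C:unchanged"])
        ranked, _ = nf.summarize(report)
        assert ranked.iloc[0]["n_perturbed"] == 1

    def test_universal_assignment_frequency_one(self):
        report = self._report(["A:up|B:up", "A:up|B:unchanged"])
        _, rec = nf.summarize(report)
        assert rec.set_index("assignment").loc["A:up", "frequency"] == 1.0

    def test_empty_survivor_set_notes_explanation(self):
        report = self._report([])
        ranked, rec = nf.summarize(report)
        assert ranked.empty and rec.empty
        assert "no scheme passed" in ranked.attrs["note"]
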