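"""Landscape estimation: sampling, clustering, k selection, marker checks."""

import numpy as np
import pandas as pd
import pytest

import netfate as nf
from netfate.landscape import LandscapeResult, SeparationError, _elbow_k


def _expr(values: dict, phenotype: dict) -> nf.ExpressionTable:
    return nf.ExpressionTable(pd.DataFrame(values), phenotype)


@pytest.fixture
def small_expr():
    return _expr(
        {
            "u1": [1.0, 0.7, 2.0],
            "u2": [2.0, 0.7, 2.2],
            "d1": [3.0, 0.7, 4.0],
        },
        {"u1": "undesired", "u2": "undesired", "d1": "desired"},
    )


class TestExpressionTable:
    def test_unlabelled_sample_rejected(self):
        with pytest.raises(ValueError, match="without phenotype"):
            _expr({"s1": [1.0]}, {})

    def test_unknown_phenotype_rejected(self):
        with pytest.raises(ValueError, match="unknown phenotype"):
            _expr({"s1": [1.0]}, {"s1": "blue"})

    def test_restrict_drops_extra_and_errors_on_missing(self, three_cycle):
        expr = nf.ExpressionTable(
            pd.DataFrame({"s": [1.0, 2.0, 3.0, 4.0]}, index=["A", "B", "C", "X"]),
            {"s": "undesired"},
        )
        aligned = expr.restrict_to(three_cycle)
        assert list(aligned.values.index) == ["A", "B", "C"]
        expr2 = nf.ExpressionTable(
            pd.DataFrame({"s": [1.0]}, index=["A"]), {"s": "undesired"}
        )
        with pytest.raises(ValueError, match="missing"):
            expr2.restrict_to(three_cycle)


class TestSampleInitialStates:
    def test_values_within_node_ranges(self, small_expr):
        batch = nf.sample_initial_states(small_expr, 500, seed=0)
        arr = batch.values.to_numpy()
        assert arr[0].min() >= 1.0 and arr[0].max() <= 3.0
        assert arr[2].min() >= 2.0 and arr[2].max() <= 4.0

    def test_constant_node_stays_constant(self, small_expr):
        batch = nf.sample_initial_states(small_expr, 100, seed=0)
        assert (batch.values.iloc[1] == 0.7).all()

    def test_count_contract_and_tagging(self, small_expr):
        batch = nf.sample_initial_states(small_expr, 1234, seed=3)
        assert len(batch) == 1234
        first = next(iter(batch))
        assert first.provenance == "random"

    def test_seed_reproducibility(self, small_expr):
        a = nf.sample_initial_states(small_expr, 50, seed=9).values
        b = nf.sample_initial_states(small_expr, 50, seed=9).values
        pd.testing.assert_frame_equal(a, b)

    def test_stratified_mode_respects_per_phenotype_ranges(self, small_expr):
        batch = nf.sample_initial_states(
            small_expr, 10, seed=0, phenotypes=["undesired", "desired"], stratify=True
        )
        # odd columns emulate the desired phenotype whose node-0 range is {3.0}
        assert (batch.values.iloc[0, 1::2] == 3.0).all()


class TestBuildLandscape:
    def test_attractor_count_is_samples_plus_random(self, standard_fixture):
        fx = standard_fixture
        land = nf.build_landscape(fx.network, fx.expression, n_random=50, seed=0)
        assert len(land.attractors) == len(fx.expression.samples) + 50

    def test_zero_random_states(self, standard_fixture):
        fx = standard_fixture
        land = nf.build_landscape(fx.network, fx.expression, n_random=0, seed=0)
        assert len(land.attractors) == len(fx.expression.samples)

    def test_deterministic_under_seed(self, standard_fixture):
        fx = standard_fixture
        a = nf.build_landscape(fx.network, fx.expression, n_random=30, seed=5)
        b = nf.build_landscape(fx.network, fx.expression, n_random=30, seed=5)
        pd.testing.assert_frame_equal(a.attractors, b.attractors)

    def test_non_converged_excluded_from_clustering(self, standard_fixture):
        fx = standard_fixture
        cfg = nf.SfaConfig(max_iterations=2)
        land = nf.build_landscape(fx.network, fx.expression, cfg, n_random=10, seed=0)
        assert len(land.non_converged) > 0
        assert len(land.clusterable) == len(land.attractors) - len(land.non_converged)


def _blob_landscape(centers, n_per, sigma, seed=0, labelled=(0, 1)):
    """Synthetic landscape of Gaussian blobs with one experimental
    attractor planted in each labelled blob."""
    rng = np.random.default_rng(seed)
    rows, ids, sources, phenos = [], [], [], []
    for bi, c in enumerate(centers):
        for i in range(n_per):
            rows.append(rng.normal(c, sigma, size=len(c)))
            ids.append(f"b{bi}_{i}")
            sources.append("random")
            phenos.append("random")
    for pheno, bi in zip(("undesired", "desired"), labelled):
        rows.append(np.asarray(centers[bi], dtype=float))
        ids.append(pheno)
        sources.append("experimental")
        phenos.append(pheno)
    attr = pd.DataFrame(rows, index=ids, columns=[f"g{j}" for j in range(len(centers[0]))])
    prov = pd.DataFrame(
        {"source": sources, "phenotype": phenos,
         "converged": True, "iterations": 1},
        index=ids,
    )
    return LandscapeResult(attr, prov)


class TestChooseK:
    def test_two_separated_blobs_give_k2(self):
        land = _blob_landscape([(0.0, 0.0), (10.0, 10.0)], 50, sigma=0.1)
        model = nf.choose_k(land, k_range=range(2, 7), seed=0)
        assert model.k == 2
        assert model.desired_clusters.isdisjoint(model.undesired_clusters)

    def test_identical_centers_fail_separation(self):
        land = _blob_landscape([(0.0, 0.0), (0.0, 0.0)], 50, sigma=0.1)
        with pytest.raises(SeparationError):
            nf.choose_k(land, k_range=range(2, 5), seed=0)

    def test_three_blobs_with_phenotypes_in_two(self):
        land = _blob_landscape(
            [(0.0, 0.0), (10.0, 0.0), (0.0, 10.0)], 40, sigma=0.1, labelled=(0, 2)
        )
        model = nf.choose_k(land, k_range=range(2, 7), seed=0)
        assert model.desired_clusters.isdisjoint(model.undesired_clusters)

    def test_determinism_under_seed(self):
        land = _blob_landscape([(0.0, 0.0), (5.0, 5.0)], 40, sigma=0.3)
        m1 = nf.choose_k(land, seed=7)
        m2 = nf.choose_k(land, seed=7)
        assert m1.k == m2.k
        pd.testing.assert_series_equal(m1.assignments, m2.assignments)

    def test_elbow_detects_knee(self):
        # sharp knee at k=3 on a convex-then-flat curve
        wcss = {2: 100.0, 3: 10.0, 4: 9.0, 5: 8.5}
        assert _elbow_k(wcss) == 3


class TestMarkerConsistency:
    def _landscape(self, undesired, desired):
        attr = pd.DataFrame(
            {"m": undesired + desired},
            index=[f"u{i}" for i in range(len(undesired))]
            + [f"d{i}" for i in range(len(desired))],
        )
        prov = pd.DataFrame(
            {
                "source": "experimental",
                "phenotype": ["undesired"] * len(undesired) + ["desired"] * len(desired),
                "converged": True,
                "iterations": 1,
            },
            index=attr.index,
        )
        return LandscapeResult(attr, prov)

    def test_expected_up_passes(self):
        land = self._landscape([1.0], [2.0])
        report = nf.check_marker_consistency(land, [("m", "up")])
        assert report.loc[0, "passes"]

    def test_sign_mismatch_flagged(self):
        land = self._landscape([1.0], [0.5])
        with pytest.warns(RuntimeWarning, match="flagged"):
            report = nf.check_marker_consistency(land, [("m", "up")])
        assert not report.loc[0, "passes"]

    def test_overlapping_replicate_ranges_flagged(self):
        land = self._landscape([1.0, 2.0], [1.5, 2.5])
        with pytest.warns(RuntimeWarning, match="flagged"):
            report = nf.check_marker_consistency(land, [("m", "up")])
        assert report.loc[0, "range_overlap"]
        assert not report.loc[0, "passes"]

    def test_unknown_marker_rejected(self, three_cycle):
        land = self._landscape([1.0], [2.0])
        with pytest.raises(KeyError):
            nf.check_marker_consistency(land, [("zzz", "up")], three_cycle)

    def test_order_invariance(self):
        attr = pd.DataFrame(
            {"a": [1.0, 2.0], "b": [2.0, 1.0]}, index=["u0", "d0"]
        )
        prov = pd.DataFrame(
            {"source": "experimental", "phenotype": ["undesired", "desired"],
             "converged": True, "iterations": 1},
            index=attr.index,
        )
        land = LandscapeResult(attr, prov)
        markers = [("a", "up"), ("b", "down")]
        r1 = nf.check_marker_consistency(land, markers)
        r2 = nf.check_marker_consistency(land, markers[::-1])
        pd.testing.assert_frame_equal(r1, r2)
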