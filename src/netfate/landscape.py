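"""Attractor landscape estimation and phenotype association.

The landscape is estimated by propagating (1) every experimental sample
and (2) a large batch of random initial states drawn uniformly within
each node's observed expression range, then partitioning the resulting
fixed points with k-means.  The number of clusters k is chosen by the
elbow (maximum-curvature of the within-cluster-sum-of-squares curve) and
mean-silhouette optima; when they disagree, the smallest candidate k
that keeps the undesired- and desired-phenotype experimental attractors
in different clusters wins.  A marker-consistency check then confirms
that user-supplied internal-marker nodes behave as expected between the
phenotype-associated clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .network import SignedDigraph
from .sfa import InitialState, OverrideSet, SfaConfig, propagate_many, weight_matrix

__all__ = [
    "ExpressionTable",
    "InitialStateBatch",
    "ClusterModel",
    "LandscapeResult",
    "SeparationError",
    "read_expression",
    "sample_initial_states",
    "build_landscape",
    "choose_k",
    "check_marker_consistency",
]

logger = logging.getLogger(__name__)

PHENOTYPE_LABELS = ("undesired", "desired", "other")


class SeparationError(RuntimeError):
    """No candidate k separates the undesired and desired attractors.

    Mirrors the guidance that an inseparable landscape calls for network
    or marker revision rather than silently accepting a clustering.
    """


@dataclass
class ExpressionTable:
    """Normalized (log-scale) expression: nodes x samples, plus labels.

    ``phenotype`` maps each sample column to undesired / desired / other.
    Samples sharing a phenotype are treated as replicates of it.
    """

    values: pd.DataFrame
    phenotype: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.phenotype]
        if missing:
            raise ValueError(f"samples without phenotype label: {missing}")
        bad = {s: p for s, p in self.phenotype.items() if p not in PHENOTYPE_LABELS}
        if bad:
            raise ValueError(f"unknown phenotype labels: {bad}")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression table contains non-finite values")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, phenotype: str) -> list[str]:
        return [s for s in self.values.columns if self.phenotype[s] == phenotype]

    def node_values(self, node: str, phenotype: str | None = None) -> np.ndarray:
        cols = self.samples if phenotype is None else self.samples_for(phenotype)
        return self.values.loc[node, cols].to_numpy(dtype=float)

    def restrict_to(self, g: SignedDigraph, fill: float | None = None) -> "ExpressionTable":
        """Align rows to the network's node order.

        Extra rows are dropped with a log message; missing network nodes
        are an error unless a ``fill`` value is given.
        """
        extra = [n for n in self.values.index if n not in g]
        if extra:
            logger.info("ignoring %d expression rows absent from the network", len(extra))
        missing = [n for n in g.nodes if n not in self.values.index]
        if missing and fill is None:
            raise ValueError(
                f"network nodes missing from expression table: {missing[:10]}"
            )
        mat = self.values.reindex(g.nodes)
        if missing:
            logger.warning("filling %d missing nodes with %g", len(missing), fill)
            mat = mat.fillna(fill)
        return ExpressionTable(mat, dict(self.phenotype))


def read_expression(
    expr_path: str | Path,
    phenotype_path: str | Path,
) -> ExpressionTable:
    """Load a node x sample TSV and a sample<TAB>phenotype map."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    pheno_df = pd.read_csv(
        phenotype_path, sep="\t", header=None, names=["sample", "phenotype"],
        comment="#",
    )
    phenotype = dict(zip(pheno_df["sample"].astype(str), pheno_df["phenotype"]))
    return ExpressionTable(values, phenotype)


@dataclass
class InitialStateBatch:
    """A matrix-backed collection of initial states (nodes x states).

    Iterating yields :class:`InitialState` views; the matrix form is
    what the propagation engine consumes.
    """

    values: pd.DataFrame
    labels: list[str]
    provenance: str = "random"

    def __len__(self) -> int:
        return self.values.shape[1]

    def __iter__(self) -> Iterator[InitialState]:
        for i, label in enumerate(self.labels):
            yield InitialState(
                values=self.values.iloc[:, i].to_dict(),
                label=label,
                provenance=self.provenance,
            )


def sample_initial_states(
    expr: ExpressionTable,
    n: int,
    seed: int,
    phenotypes: Sequence[str] | None = None,
    stratify: bool = False,
) -> InitialStateBatch:
    """Draw ``n`` random initial states within per-node expression ranges.

    For each node the value is uniform on [min, max] across the samples
    of the phenotypes being emulated (all supplied phenotypes pooled by
    default; ``stratify=True`` draws each state from one phenotype's
    range instead, cycling through them).  Constant nodes stay constant.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = list(expr.values.index)

    def ranges(cols: list[str]) -> tuple[np.ndarray, np.ndarray]:
        sub = expr.values[cols].to_numpy(dtype=float)
        return sub.min(axis=1), sub.max(axis=1)

    if phenotypes is None:
        phenotypes = sorted({p for p in expr.phenotype.values() if p != "other"})
    if not stratify:
        cols = [s for p in phenotypes for s in expr.samples_for(p)]
        if not cols:
            raise ValueError(f"no samples for phenotypes {phenotypes}")
        lo, hi = ranges(cols)
        mat = rng.uniform(lo[:, None], hi[:, None], size=(len(nodes), n))
    else:
        mat = np.empty((len(nodes), n))
        for i in range(n):
            p = phenotypes[i % len(phenotypes)]
            lo, hi = ranges(expr.samples_for(p))
            mat[:, i] = rng.uniform(lo, hi)
    labels = [f"random_{i}" for i in range(n)]
    return InitialStateBatch(
        values=pd.DataFrame(mat, index=nodes, columns=labels),
        labels=labels,
        provenance="random",
    )


@dataclass
class LandscapeResult:
    """Estimated landscape: one attractor row per initial state."""

    attractors: pd.DataFrame  # rows = attractor ids, columns = nodes
    provenance: pd.DataFrame  # columns: source, phenotype, converged, iterations
    non_converged: list[str] = field(default_factory=list)

    @property
    def clusterable(self) -> pd.DataFrame:
        """Attractors eligible for clustering (non-converged excluded)."""
        if not self.non_converged:
            return self.attractors
        return self.attractors.drop(index=self.non_converged)

    def experimental_ids(self, phenotype: str) -> list[str]:
        mask = (self.provenance["phenotype"] == phenotype) & (
            self.provenance["source"] == "experimental"
        )
        return list(self.provenance.index[mask])

    def to_tsv(self, path: str | Path) -> None:
        out = self.attractors.join(self.provenance[["converged", "iterations"]])
        out.to_csv(path, sep="\t")


def build_landscape(
    g: SignedDigraph,
    expr: ExpressionTable,
    cfg: SfaConfig | None = None,
    n_random: int = 100_000,
    seed: int = 0,
    baseline_overrides: OverrideSet | None = None,
    phenotypes: Sequence[str] | None = None,
    chunk: int = 20_000,
) -> LandscapeResult:
    """Estimate the attractor landscape.

    One attractor per experimental sample plus one per random state
    (total = samples + n_random); baseline overrides (e.g. mutations)
    apply to every run.  Deterministic under a fixed seed.  Any
    non-converged attractor is reported and excluded from clustering.
    """
    cfg = cfg or SfaConfig()
    expr = expr.restrict_to(g)
    W = weight_matrix(g)

    blocks: list[np.ndarray] = []
    ids: list[str] = []
    sources: list[str] = []
    phenos: list[str] = []
    conv_all: list[np.ndarray] = []
    iters_all: list[int] = []

    B_exp = expr.values.to_numpy(dtype=float)
    X, conv, iters = propagate_many(g, B_exp, baseline_overrides, cfg, W=W)
    blocks.append(X)
    ids.extend(expr.samples)
    sources.extend(["experimental"] * len(expr.samples))
    phenos.extend(expr.phenotype[s] for s in expr.samples)
    conv_all.append(conv)
    iters_all.extend([iters] * len(expr.samples))

    if n_random > 0:
        batch = sample_initial_states(expr, n_random, seed, phenotypes=phenotypes)
        B = batch.values.to_numpy(dtype=float)
        for start in range(0, n_random, chunk):
            sl = slice(start, min(start + chunk, n_random))
            X, conv, iters = propagate_many(g, B[:, sl], baseline_overrides, cfg, W=W)
            blocks.append(X)
            conv_all.append(conv)
            count = sl.stop - sl.start
            iters_all.extend([iters] * count)
        ids.extend(batch.labels)
        sources.extend(["random"] * n_random)
        phenos.extend(["random"] * n_random)

    matrix = np.concatenate(blocks, axis=1).T
    converged = np.concatenate(conv_all)
    attractors = pd.DataFrame(matrix, index=ids, columns=g.nodes)
    provenance = pd.DataFrame(
        {
            "source": sources,
            "phenotype": phenos,
            "converged": converged,
            "iterations": iters_all,
        },
        index=ids,
    )
    non_conv = list(provenance.index[~provenance["converged"]])
    if non_conv:
        logger.warning(
            "%d attractor(s) did not converge within %d iterations; "
            "excluded from clustering", len(non_conv), cfg.max_iterations,
        )
    return LandscapeResult(attractors, provenance, non_conv)


@dataclass
class ClusterModel:
    """Fitted k-means partition with its phenotype association."""

    k: int
    kmeans: KMeans
    assignments: pd.Series  # attractor id -> cluster label
    elbow_curve: dict[int, float]
    silhouette_curve: dict[int, float]
    rationale: str
    phenotype_clusters: dict[str, set[int]]

    @property
    def desired_clusters(self) -> set[int]:
        return self.phenotype_clusters.get("desired", set())

    @property
    def undesired_clusters(self) -> set[int]:
        return self.phenotype_clusters.get("undesired", set())

    def predictors(self) -> KMeans:
        return self.kmeans


def _elbow_k(wcss: dict[int, float]) -> int | None:
    """Maximum-curvature point of the WCSS curve via second differences."""
    ks = sorted(wcss)
    if len(ks) < 3:
        return None
    curv = {
        ks[i]: wcss[ks[i - 1]] - 2.0 * wcss[ks[i]] + wcss[ks[i + 1]]
        for i in range(1, len(ks) - 1)
    }
    return max(curv, key=lambda k: (curv[k], -k))


def _fit_kmeans(X: np.ndarray, k: int, seed: int, n_init: int = 10) -> KMeans:
    return KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)


def choose_k(
    landscape: LandscapeResult,
    k_range: Sequence[int] = range(2, 11),
    seed: int = 0,
    silhouette_sample: int = 5000,
) -> ClusterModel:
    """Fit k-means across ``k_range`` and pick the cluster count.

    Elbow and silhouette optima are computed; if they agree *and* that k
    separates the undesired and desired experimental attractors it is
    used.  Otherwise the smallest candidate optimum that separates them
    wins.  If none does, :class:`SeparationError` is raised.
    """
    X_df = landscape.clusterable
    X = X_df.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 attractors to cluster")
    ks = [k for k in k_range if 2 <= k <= X.shape[0] - 1]
    if not ks:
        raise ValueError("k_range contains no feasible k")

    undes = [i for i in landscape.experimental_ids("undesired") if i in X_df.index]
    des = [i for i in landscape.experimental_ids("desired") if i in X_df.index]

    models: dict[int, KMeans] = {}
    wcss: dict[int, float] = {}
    sil: dict[int, float] = {}
    rng = np.random.default_rng(seed)
    sample_idx = (
        rng.choice(X.shape[0], size=silhouette_sample, replace=False)
        if X.shape[0] > silhouette_sample
        else None
    )
    for k in ks:
        km = _fit_kmeans(X, k, seed)
        models[k] = km
        wcss[k] = float(km.inertia_)
        labels = km.labels_
        if sample_idx is not None:
            sub_labels = labels[sample_idx]
            if len(np.unique(sub_labels)) < 2:
                sil[k] = -1.0
            else:
                sil[k] = float(silhouette_score(X[sample_idx], sub_labels))
        else:
            sil[k] = float(silhouette_score(X, labels))

    k_elbow = _elbow_k(wcss)
    k_sil = max(sil, key=lambda k: (sil[k], -k))

    def separates(k: int) -> bool:
        labels = pd.Series(models[k].labels_, index=X_df.index)
        cu = set(labels.loc[undes]) if undes else set()
        cd = set(labels.loc[des]) if des else set()
        return not (cu & cd)

    candidates = sorted({k for k in (k_elbow, k_sil) if k is not None})
    chosen: int | None = None
    if k_elbow is not None and k_elbow == k_sil and separates(k_elbow):
        chosen = k_elbow
        rationale = f"elbow and silhouette agree at k={chosen}"
    else:
        for k in candidates:
            if separates(k):
                chosen = k
                rationale = (
                    f"metrics disagree (elbow={k_elbow}, silhouette={k_sil}); "
                    f"smallest candidate separating the phenotypes is k={chosen}"
                )
                break
    if chosen is None:
        raise SeparationError(
            f"no candidate k in {candidates} separates undesired and desired "
            "experimental attractors; consider revising the network, the "
            "marker set, or the simulation settings"
        )

    labels = pd.Series(models[chosen].labels_, index=X_df.index, name="cluster")
    phenotype_clusters = {
        "undesired": set(int(c) for c in labels.loc[undes]) if undes else set(),
        "desired": set(int(c) for c in labels.loc[des]) if des else set(),
    }
    return ClusterModel(
        k=chosen,
        kmeans=models[chosen],
        assignments=labels,
        elbow_curve=wcss,
        silhouette_curve=sil,
        rationale=rationale,
        phenotype_clusters=phenotype_clusters,
    )


def check_marker_consistency(
    landscape: LandscapeResult,
    markers: Sequence[tuple[str, str]],
    g: SignedDigraph | None = None,
) -> pd.DataFrame:
    """Verify internal-marker behaviour between phenotype attractors.

    ``markers`` is a list of ``(node, expected_direction)`` where the
    direction is the expected change desired-vs-undesired (``up`` or
    ``down``).  Per marker the report gives the observed sign and, when
    replicates exist, whether the undesired and desired value ranges
    overlap (an overlapping marker is unreliable for separating the
    phenotypes).  The report is invariant to marker order.
    """
    if g is not None:
        unknown = [m for m, _ in markers if m not in g]
        if unknown:
            raise KeyError(f"markers not in network: {unknown}")
    undes = landscape.experimental_ids("undesired")
    des = landscape.experimental_ids("desired")
    rows = []
    for node, expected in markers:
        if node not in landscape.attractors.columns:
            raise KeyError(f"marker {node!r} absent from attractor table")
        u = landscape.attractors.loc[undes, node].to_numpy(dtype=float)
        d = landscape.attractors.loc[des, node].to_numpy(dtype=float)
        diff = float(d.mean() - u.mean()) if len(d) and len(u) else np.nan
        observed = "up" if diff > 0 else ("down" if diff < 0 else "unchanged")
        overlap = (
            len(u) > 1 and len(d) > 1 and (u.min() <= d.max()) and (d.min() <= u.max())
        )
        ok = observed == expected and not overlap
        rows.append(
            {
                "marker": node,
                "expected": expected,
                "observed": observed,
                "difference": diff,
                "range_overlap": bool(overlap),
                "passes": bool(ok),
            }
        )
    report = pd.DataFrame(rows).sort_values("marker").reset_index(drop=True)
    flagged = report.loc[~report["passes"], "marker"].tolist()
    if flagged:
        warnings.warn(
            f"markers flagged as inconsistent or unreliable: {flagged}",
            RuntimeWarning,
            stacklevel=2,
        )
    return report
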