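"""Filtering of perturbation schemes: classifier vote plus marker ranges.

Criterion 1: three classifiers (Gaussian Naive Bayes, linear-kernel
SVM, Random Forest) are trained on the full landscape attractors with
their k-means cluster labels; a screened attractor passes when at least
2 of 3 predict a desired-phenotype cluster, and a scheme passes overall
only if it passes on *every* replicate.

Criterion 2: among criterion-1 survivors, at least a threshold fraction
(default 90%) of the internal-marker nodes must land in the expected
range.  ``strict`` mode demands the value move beyond the desired-
phenotype attractor range boundary in the expected direction; ``relaxed``
only beyond the undesired value.  When marker groups are defined the
threshold applies to each group independently.  Replicates are evaluated
separately, mirroring per-replicate survivor lists.

These criteria are deterministic filters, not hypothesis tests; no
multiple-testing correction applies.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .screen import ScreenResult, parse_scheme_id

__all__ = [
    "MarkerSpec",
    "TrainedClassifiers",
    "FilterReport",
    "train_classifiers",
    "criterion1",
    "feature_importance",
    "criterion2",
    "summarize",
]

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("naive_bayes", "svm", "random_forest")


@dataclass(frozen=True)
class MarkerSpec:
    """An internal-marker node and how its expected range is defined."""

    node: str
    direction: str | None = None  # literature direction (up/down); inferred when None
    group: str = "markers"


@dataclass
class TrainedClassifiers:
    """The three fitted classifiers plus training bookkeeping."""

    models: dict[str, object]
    feature_names: list[str]
    classes: np.ndarray
    training_accuracy: dict[str, float]
    seed: int

    def predict(self, X: pd.DataFrame) -> dict[str, np.ndarray]:
        Xv = X[self.feature_names].to_numpy(dtype=float)
        return {name: m.predict(Xv) for name, m in self.models.items()}


def train_classifiers(
    attractors: pd.DataFrame,
    cluster_labels: pd.Series,
    seed: int = 0,
) -> TrainedClassifiers:
    """Fit NB, linear SVM and RF on attractor vectors vs cluster labels.

    Features are the entire per-node attractor vectors.  Hyperparameters
    are library defaults with fixed seeds; the SVM uses a linear kernel
    so coefficient-based feature importance is well defined.  Training
    accuracy is recorded (the landscape is the full training set).
    """
    y = cluster_labels.loc[attractors.index].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 clusters to train classifiers")
    X = attractors.to_numpy(dtype=float)
    models = {
        "naive_bayes": GaussianNB(),
        "svm": SVC(kernel="linear", random_state=seed),
        "random_forest": RandomForestClassifier(random_state=seed),
    }
    acc = {}
    for name, model in models.items():
        model.fit(X, y)
        acc[name] = float((model.predict(X) == y).mean())
    return TrainedClassifiers(
        models=models,
        feature_names=list(attractors.columns),
        classes=np.unique(y),
        training_accuracy=acc,
        seed=seed,
    )


def criterion1(
    classifiers: TrainedClassifiers,
    screen: ScreenResult,
    desired_clusters: set[int],
) -> pd.DataFrame:
    """2-of-3 classifier vote per (replicate, scheme), plus overall verdict.

    Returns a frame indexed like the screen with one vote column per
    classifier, the per-cell pass, and ``pass_all_replicates`` — the
    scheme-level verdict requiring a pass on every replicate.
    """
    if not desired_clusters:
        raise ValueError("no desired cluster ids supplied")
    preds = classifiers.predict(screen.attractors)
    votes = pd.DataFrame(
        {name: np.isin(p, list(desired_clusters)) for name, p in preds.items()},
        index=screen.attractors.index,
    )
    votes["n_votes"] = votes[list(CLASSIFIER_NAMES)].sum(axis=1)
    votes["passes"] = votes["n_votes"] >= 2
    per_scheme = votes.groupby(level="scheme_id", sort=False)["passes"].all()
    votes["pass_all_replicates"] = per_scheme.loc[
        votes.index.get_level_values("scheme_id")
    ].to_numpy()
    return votes


def feature_importance(
    classifiers: TrainedClassifiers,
    attractors: pd.DataFrame,
    cluster_labels: pd.Series,
    top_fraction: float = 0.1,
    n_repeats: int = 10,
) -> dict[str, pd.DataFrame]:
    """Ranked features per classifier with a top-10% cut.

    Random Forest: impurity importances.  Linear SVM: mean |coefficient|
    across class boundaries.  Naive Bayes: seeded permutation importance
    (NB has no native ranking).  The extra key ``summary`` tabulates how
    often each top feature recurs across classifiers (top sets that do
    not overlap at all are mutually exclusive).
    """
    names = classifiers.feature_names
    n_top = math.ceil(top_fraction * len(names))
    X = attractors[names].to_numpy(dtype=float)
    y = cluster_labels.loc[attractors.index].to_numpy()

    scores: dict[str, np.ndarray] = {}
    rf = classifiers.models["random_forest"]
    scores["random_forest"] = np.asarray(rf.feature_importances_)
    svm = classifiers.models["svm"]
    scores["svm"] = np.abs(np.atleast_2d(svm.coef_)).mean(axis=0)
    perm = permutation_importance(
        classifiers.models["naive_bayes"], X, y,
        n_repeats=n_repeats, random_state=classifiers.seed,
    )
    scores["naive_bayes"] = perm.importances_mean

    out: dict[str, pd.DataFrame] = {}
    top_sets: dict[str, list[str]] = {}
    for name, sc in scores.items():
        ranked = (
            pd.DataFrame({"feature": names, "importance": sc})
            .sort_values(["importance", "feature"], ascending=[False, True])
            .reset_index(drop=True)
        )
        ranked["top"] = ranked.index < n_top
        out[name] = ranked
        top_sets[name] = ranked.loc[ranked["top"], "feature"].tolist()
    all_top = sorted({f for s in top_sets.values() for f in s})
    out["summary"] = pd.DataFrame(
        {
            "feature": all_top,
            "n_classifiers": [
                sum(f in s for s in top_sets.values()) for f in all_top
            ],
        }
    )
    return out


def _resolve_direction(
    spec: MarkerSpec,
    desired: np.ndarray,
    undesired: np.ndarray,
) -> str | None:
    if spec.direction in ("up", "down"):
        return spec.direction
    diff = desired.mean() - undesired.mean()
    if diff > 0:
        return "up"
    if diff < 0:
        return "down"
    return None  # unresolvable: identical values


def _marker_passes(
    value: float,
    direction: str,
    desired: np.ndarray,
    undesired: np.ndarray,
    mode: str,
) -> bool:
    if mode == "strict":
        # beyond the desired-range boundary nearer the undesired side
        return value > desired.min() if direction == "up" else value < desired.max()
    # relaxed: beyond the undesired extremum in the expected direction
    return value > undesired.max() if direction == "up" else value < undesired.min()


def criterion2(
    screen: ScreenResult,
    markers: Sequence[MarkerSpec],
    desired_attractors: pd.DataFrame,
    undesired_attractors: pd.DataFrame,
    threshold: float = 0.9,
    mode: str = "strict",
    scheme_ids: Sequence[str] | None = None,
    overridden: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Internal-marker range check per (replicate, scheme).

    Parameters
    ----------
    desired_attractors, undesired_attractors
        Node-column frames of the phenotype-associated experimental
        attractors (rows = replicates); their per-marker [min, max]
        define the expected ranges.
    threshold
        Minimum passing-marker fraction, applied independently within
        each marker group.
    scheme_ids
        Restrict evaluation to these schemes (criterion-1 survivors).
    overridden
        Optional map scheme_id -> nodes pinned by that scheme; a marker
        that is itself overridden is evaluated on its pinned value and
        flagged in the output.

    Markers whose direction cannot be resolved (identical desired and
    undesired values) are excluded from the denominator with a warning.
    Verdicts are invariant to marker and group order.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"mode must be strict or relaxed, got {mode!r}")

    resolved: list[tuple[MarkerSpec, str]] = []
    dropped: list[str] = []
    ranges: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for spec in markers:
        d = desired_attractors[spec.node].to_numpy(dtype=float)
        u = undesired_attractors[spec.node].to_numpy(dtype=float)
        direction = _resolve_direction(spec, d, u)
        if direction is None:
            dropped.append(spec.node)
            continue
        resolved.append((spec, direction))
        ranges[spec.node] = (d, u)
    if dropped:
        warnings.warn(
            f"markers with unresolvable direction excluded from the "
            f"denominator: {sorted(dropped)}",
            RuntimeWarning,
            stacklevel=2,
        )
    if not resolved:
        raise ValueError("no usable markers remain")

    groups = sorted({spec.group for spec, _ in resolved})
    if scheme_ids is None:
        scheme_ids = screen.scheme_ids
    wanted = set(scheme_ids)

    rows = []
    for (rep, sid), values in screen.attractors.iterrows():
        if sid not in wanted:
            continue
        marker_pass: dict[str, bool] = {}
        flags: list[str] = []
        for spec, direction in resolved:
            d, u = ranges[spec.node]
            ok = _marker_passes(float(values[spec.node]), direction, d, u, mode)
            marker_pass[spec.node] = ok
            if overridden and spec.node in overridden.get(sid, set()):
                flags.append(spec.node)
        group_frac = {}
        verdict = True
        for grp in groups:
            members = [spec.node for spec, _ in resolved if spec.group == grp]
            frac = sum(marker_pass[m] for m in members) / len(members)
            group_frac[grp] = frac
            verdict = verdict and frac >= threshold
        row = {
            "replicate": rep,
            "scheme_id": sid,
            "fraction": min(group_frac.values()),
            "passes": verdict,
            "overridden_markers": ",".join(sorted(flags)),
        }
        for grp, frac in group_frac.items():
            row[f"fraction_{grp}"] = frac
        for node, ok in marker_pass.items():
            row[f"marker_{node}"] = ok
        rows.append(row)
    report = pd.DataFrame(rows).set_index(["replicate", "scheme_id"])
    return report


@dataclass
class FilterReport:
    """Aggregate result of both criteria across a screen."""

    criterion1_votes: pd.DataFrame
    criterion2_report: pd.DataFrame
    importance: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def criterion1_survivors(self) -> list[str]:
        passed = self.criterion1_votes.loc[
            self.criterion1_votes["pass_all_replicates"]
        ]
        seen: list[str] = []
        for sid in passed.index.get_level_values("scheme_id"):
            if sid not in seen:
                seen.append(sid)
        return seen

    def criterion2_survivors(self, replicate: str) -> list[str]:
        rep = self.criterion2_report.xs(replicate, level="replicate")
        return list(rep.index[rep["passes"]])

    @property
    def survivors(self) -> list[str]:
        """Schemes passing criterion 1 and criterion 2 on every replicate."""
        c1 = set(self.criterion1_survivors)
        per_scheme = self.criterion2_report.groupby(level="scheme_id", sort=False)[
            "passes"
        ].all()
        c2 = set(per_scheme.index[per_scheme])
        ordered = [
            sid
            for sid in self.criterion1_survivors
            if sid in c1 and sid in c2
        ]
        return ordered


def summarize(report: FilterReport) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank survivors and tabulate recurring single-node assignments.

    Survivors are sorted by (number of perturbed nodes ascending, scheme
    id) — smallest intervention first.  The recurrence table gives, for
    every node:symbol assignment, the fraction of survivors containing
    it (1.0 = present in all passing schemes).
    """
    survivors = report.survivors
    if not survivors:
        ranked = pd.DataFrame(
            columns=["scheme_id", "n_perturbed"],
        )
        ranked.attrs["note"] = (
            "no scheme passed both criteria; consider relaxed mode, fewer "
            "markers, or network revision"
        )
        return ranked, pd.DataFrame(columns=["assignment", "frequency"])
    schemes = [parse_scheme_id(s) for s in survivors]
    ranked = (
        pd.DataFrame(
            {
                "scheme_id": survivors,
                "n_perturbed": [s.n_perturbed for s in schemes],
            }
        )
        .sort_values(["n_perturbed", "scheme_id"])
        .reset_index(drop=True)
    )
    counts: dict[str, int] = {}
    for s in schemes:
        for node, symbol in s.assignment:
            if symbol != "unchanged":
                key = f"{node}:{symbol}"
                counts[key] = counts.get(key, 0) + 1
    recurrence = (
        pd.DataFrame(
            {
                "assignment": list(counts),
                "frequency": [c / len(schemes) for c in counts.values()],
            }
        )
        .sort_values(["frequency", "assignment"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return ranked, recurrence
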