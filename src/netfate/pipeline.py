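"""End-to-end orchestration of the three-step reprogramming study.

Step 1 estimates the attractor landscape and associates its k-means
clusters with the phenotypes; step 2 finds the feedback vertex set,
derives the control nodes and runs the 3^n perturbation screen from the
undesired-phenotype initial states; step 3 applies the two filtering
criteria and ranks the surviving schemes.

:func:`run_study` is the in-memory core used programmatically and by
the tests; :func:`run` wraps it with file IO, per-step checkpoint
manifests (content hashes, so a resumed run re-executes exactly the
stale steps) and a JSON report of every stage count.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import filters as flt
from . import fvs as fvs_mod
from . import landscape as ls
from . import screen as scr
from .network import SignedDigraph, read_network
from .sfa import OverrideSet, SfaConfig

__all__ = ["RunConfig", "StudyResult", "run_study", "run", "validate_inputs"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a file-based run needs; round-trips through YAML."""

    network: str
    expression: str
    phenotypes: str
    markers: str
    mutations: str | None = None
    treatments: dict[str, str] = field(default_factory=dict)
    out_dir: str = "netfate_out"
    alpha: float = 0.9
    tolerance: float = 1e-6
    max_iterations: int = 1000
    n_random: int = 100_000
    k_min: int = 2
    k_max: int = 10
    threshold: float = 0.9
    mode: str = "strict"
    scheme_cap: int = 16
    allow_large: bool = False
    fvs_index: int = 0
    seed: int = 0
    steps: tuple[str, ...] = ("landscape", "screen", "filter")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        if "steps" in data:
            data["steps"] = tuple(data["steps"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["steps"] = list(data["steps"])
        with Path(path).open("w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @property
    def sfa(self) -> SfaConfig:
        return SfaConfig(self.alpha, self.tolerance, self.max_iterations)

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)


@dataclass
class StudyResult:
    """All intermediate and final artifacts of one in-memory study."""

    landscape: ls.LandscapeResult
    cluster_model: ls.ClusterModel
    marker_report: pd.DataFrame
    fvs_family: list[frozenset[str]]
    control_nodes: list[str]
    screen: scr.ScreenResult
    filter_report: flt.FilterReport
    ranked: pd.DataFrame
    recurrence: pd.DataFrame

    @property
    def counts(self) -> dict:
        return {
            "attractors": len(self.landscape.attractors),
            "non_converged": len(self.landscape.non_converged),
            "k": self.cluster_model.k,
            "n_fvs": len(self.fvs_family),
            "n_control_nodes": len(self.control_nodes),
            "schemes": len(self.screen.scheme_ids),
            "criterion1_survivors": len(self.filter_report.criterion1_survivors),
            "criterion2_survivors_per_replicate": {
                r: len(self.filter_report.criterion2_survivors(r))
                for r in self.screen.replicates
            },
            "survivors": len(self.filter_report.survivors),
        }


def _overridden_map(
    schemes: Sequence[scr.PerturbationScheme],
) -> dict[str, set[str]]:
    return {
        s.id: {n for n, sym in s.assignment if sym != "unchanged"} for s in schemes
    }


def run_study(
    g: SignedDigraph,
    expr: ls.ExpressionTable,
    markers: Sequence[tuple[str, str]] | Sequence[flt.MarkerSpec],
    cfg: SfaConfig | None = None,
    n_random: int = 1000,
    k_range: Sequence[int] = range(2, 7),
    seed: int = 0,
    mutations: scr.MutationProfile | None = None,
    treatments: Mapping[str, str] | None = None,
    threshold: float = 0.9,
    mode: str = "strict",
    control_nodes: Sequence[str] | None = None,
    scheme_cap: int = scr.DEFAULT_SCHEME_CAP,
    allow_large: bool = False,
    fvs_index: int = 0,
) -> StudyResult:
    """Run the full three-step study in memory.

    ``control_nodes`` may be passed to reuse a previously determined
    FVS (the network, hence its FVS, is unchanged across e.g. noise
    replicates); otherwise the minimum-FVS family is enumerated and the
    ``fvs_index``-th set (deterministic lexicographic order) is used,
    minus any mutation/treatment-fixed nodes.
    """
    cfg = cfg or SfaConfig()
    expr = expr.restrict_to(g)
    marker_specs = [
        m if isinstance(m, flt.MarkerSpec) else flt.MarkerSpec(m[0], m[1])
        for m in markers
    ]

    baseline = scr.resolve_overrides(None, expr, mutations, treatments)

    # -- step 1: landscape --------------------------------------------------
    land = ls.build_landscape(
        g, expr, cfg, n_random=n_random, seed=seed, baseline_overrides=baseline
    )
    model = ls.choose_k(land, k_range=k_range, seed=seed)
    marker_report = ls.check_marker_consistency(
        land, [(m.node, m.direction or "up") for m in marker_specs], g
    )

    # -- step 2: FVS + screen ----------------------------------------------
    if control_nodes is None:
        family = fvs_mod.enumerate_fvs(g, fvs_mod.SaSchedule(seed=seed))
        if not family:
            family = [frozenset()]
        chosen = family[fvs_index % len(family)]
        fixed = set(baseline.entries)
        control_nodes = fvs_mod.exclude_fixed_nodes(chosen, fixed)
    else:
        family = [frozenset(control_nodes)]
        control_nodes = list(control_nodes)
    if not control_nodes:
        raise ValueError("control node set is empty; nothing to screen")

    schemes = scr.generate_schemes(control_nodes, cap=scheme_cap, allow_large=allow_large)
    undesired_cols = expr.samples_for("undesired")
    replicate_states = expr.values[undesired_cols]
    screen_res = scr.run_screen(
        g, schemes, replicate_states, expr, cfg,
        mutations=mutations, treatments=treatments,
    )

    # -- step 3: filters -----------------------------------------------------
    clusterable = land.clusterable
    clfs = flt.train_classifiers(clusterable, model.assignments, seed=seed)
    votes = flt.criterion1(clfs, screen_res, model.desired_clusters)
    importance = flt.feature_importance(clfs, clusterable, model.assignments)
    c1_ids = [
        sid
        for sid in screen_res.scheme_ids
        if votes.loc[pd.IndexSlice[:, sid], "pass_all_replicates"].all()
    ]
    desired_ids = land.experimental_ids("desired")
    undesired_ids = land.experimental_ids("undesired")
    c2 = flt.criterion2(
        screen_res,
        marker_specs,
        land.attractors.loc[desired_ids],
        land.attractors.loc[undesired_ids],
        threshold=threshold,
        mode=mode,
        scheme_ids=c1_ids,
        overridden=_overridden_map(schemes),
    )
    report = flt.FilterReport(votes, c2, importance)
    ranked, recurrence = flt.summarize(report)
    return StudyResult(
        landscape=land,
        cluster_model=model,
        marker_report=marker_report,
        fvs_family=family,
        control_nodes=list(control_nodes),
        screen=screen_res,
        filter_report=report,
        ranked=ranked,
        recurrence=recurrence,
    )


# ---------------------------------------------------------------------------
# file-based orchestration with checkpoints
# ---------------------------------------------------------------------------

def _read_markers(path: str | Path) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            node, _, direction = line.partition("\t")
            out.append((node, direction or "up"))
    return out


def _read_mutations(path: str | Path) -> scr.MutationProfile:
    entries: dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, _, cls = line.partition("\t")
            entries[gene] = cls
    return scr.MutationProfile(entries)


def _hash_files(paths: Sequence[Path], extra: str = "") -> str:
    h = hashlib.sha256()
    for p in paths:
        h.update(p.name.encode())
        h.update(p.read_bytes())
    h.update(extra.encode())
    return h.hexdigest()


def validate_inputs(config: RunConfig) -> dict:
    """Cross-check node names across all input files.

    Fails (raises) on markers or mutated genes naming unknown nodes;
    expression rows absent from the network are a warning only.
    """
    g = read_network(config.network)
    expr = ls.read_expression(config.expression, config.phenotypes)
    markers = _read_markers(config.markers)
    report: dict = {"errors": [], "warnings": [], "n_nodes": g.n_nodes, "n_edges": g.n_edges}

    extra_rows = [n for n in expr.values.index if n not in g]
    if extra_rows:
        report["warnings"].append(
            f"{len(extra_rows)} expression rows absent from the network are ignored"
        )
    missing_rows = [n for n in g.nodes if n not in expr.values.index]
    if missing_rows:
        report["errors"].append(
            f"network nodes missing from the expression table: {missing_rows[:10]}"
        )
    bad_markers = [m for m, _ in markers if m not in g]
    if bad_markers:
        report["errors"].append(f"markers not in network: {bad_markers}")
    if config.mutations:
        muts = _read_mutations(config.mutations)
        bad_genes = [m for m in muts.entries if m not in g]
        if bad_genes:
            report["errors"].append(f"mutated genes not in network: {bad_genes}")
    bad_treat = [n for n in config.treatments if n not in g]
    if bad_treat:
        report["errors"].append(f"treatment targets not in network: {bad_treat}")
    if report["errors"]:
        raise ValueError("input validation failed: " + "; ".join(report["errors"]))
    return report


def _checkpoint_fresh(manifest_path: Path, content_hash: str, outputs: list[Path]) -> bool:
    if not manifest_path.exists():
        return False
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError:
        return False
    if manifest.get("hash") != content_hash:
        logger.info("stale checkpoint %s (input hash changed); re-running", manifest_path.name)
        return False
    return all(Path(p).exists() for p in manifest.get("outputs", []))


def _write_checkpoint(manifest_path: Path, content_hash: str, outputs: list[Path]) -> None:
    manifest_path.write_text(
        json.dumps({"hash": content_hash, "outputs": [str(p) for p in outputs]}, indent=2)
    )


def run(config: RunConfig) -> dict:
    """Execute the pipeline from files, with checkpoint/resume.

    Each step writes its outputs plus a manifest of input hashes; on a
    re-run a step is skipped when its manifest hash matches and its
    outputs exist.  Returns the aggregated stage-count report (also
    written as ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    validate_inputs(config)

    inputs = [Path(config.network), Path(config.expression), Path(config.phenotypes),
              Path(config.markers)]
    if config.mutations:
        inputs.append(Path(config.mutations))
    cfg_repr = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    content_hash = _hash_files(inputs, extra=cfg_repr)

    step_outputs = {
        "landscape": [out / "attractors.tsv", out / "clusters.tsv", out / "k_report.json"],
        "screen": [out / "fvs.tsv", out / "scheme_manifest.tsv", out / "screen_attractors.tsv"],
        "filter": [out / "criterion1_pass.tsv", out / "feature_importance.tsv",
                   out / "survivors_ranked.tsv", out / "summary.json"],
    }
    manifests = {s: out / f".checkpoint_{s}.json" for s in step_outputs}
    stale = [
        s for s in config.steps
        if not _checkpoint_fresh(manifests[s], content_hash, step_outputs[s])
    ]
    if not stale:
        logger.info("all checkpoints fresh; nothing to do")
        return json.loads((out / "report.json").read_text())

    g = read_network(config.network)
    expr = ls.read_expression(config.expression, config.phenotypes)
    markers = _read_markers(config.markers)
    mutations = _read_mutations(config.mutations) if config.mutations else None

    result = run_study(
        g, expr, markers,
        cfg=config.sfa,
        n_random=config.n_random,
        k_range=config.k_range,
        seed=config.seed,
        mutations=mutations,
        treatments=config.treatments,
        threshold=config.threshold,
        mode=config.mode,
        scheme_cap=config.scheme_cap,
        allow_large=config.allow_large,
        fvs_index=config.fvs_index,
    )

    # -- write step outputs -------------------------------------------------
    if "landscape" in stale:
        result.landscape.to_tsv(out / "attractors.tsv")
        result.cluster_model.assignments.to_frame().join(
            result.landscape.provenance["source"]
        ).to_csv(out / "clusters.tsv", sep="\t")
        (out / "k_report.json").write_text(json.dumps({
            "k": result.cluster_model.k,
            "rationale": result.cluster_model.rationale,
            "elbow_curve": result.cluster_model.elbow_curve,
            "silhouette_curve": result.cluster_model.silhouette_curve,
            "sampling_distribution": "uniform within pooled phenotype ranges",
        }, indent=2))
        _write_checkpoint(manifests["landscape"], content_hash, step_outputs["landscape"])
    if "screen" in stale:
        pd.DataFrame(
            {
                "members": [",".join(sorted(f)) for f in result.fvs_family],
                "size": [len(f) for f in result.fvs_family],
                "seed": config.seed,
            }
        ).to_csv(out / "fvs.tsv", sep="\t", index=False)
        result.screen.manifest().to_csv(out / "scheme_manifest.tsv", sep="\t", index=False)
        result.screen.attractors.join(result.screen.converged).to_csv(
            out / "screen_attractors.tsv", sep="\t"
        )
        _write_checkpoint(manifests["screen"], content_hash, step_outputs["screen"])
    if "filter" in stale:
        result.filter_report.criterion1_votes.to_csv(out / "criterion1_pass.tsv", sep="\t")
        for rep in result.screen.replicates:
            result.filter_report.criterion2_report.xs(
                rep, level="replicate"
            ).to_csv(out / f"criterion2_pass_{rep}.tsv", sep="\t")
        pd.concat(
            {k: v for k, v in result.filter_report.importance.items() if k != "summary"},
            names=["classifier"],
        ).to_csv(out / "feature_importance.tsv", sep="\t")
        result.ranked.to_csv(out / "survivors_ranked.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(result.counts, indent=2))
        _write_checkpoint(manifests["filter"], content_hash, step_outputs["filter"])

    report = {"seed": config.seed, **result.counts}
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
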