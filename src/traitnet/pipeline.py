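"""End-to-end orchestration: simulate/load → decompose → transform → learn → SEM → assess.

The run directory collects every stage's artifacts as CSV/DOT/GraphML plus
a provenance file (config echo, seed, package version).  Learned
structures are deduplicated at the Markov-equivalence-class level before
SEM fitting: when two settings infer equivalent networks for the same
component, the SEM is fitted once (equivalent structures share their fit
metrics).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from traitnet.assess import (
    MTMModel,
    SEMModel,
    SingleTraitModel,
    compute_dic,
    cross_validate,
    marginal_loglik,
    rank_models,
)
from traitnet.dag import DAGStructure, cpdag_of, representative_extension, to_structure_matrix
from traitnet.learn import ArcStrengths, bootstrap_average, make_learner
from traitnet.mtm import MCMCSettings, MTMHyperParams, fit_mtm, posterior_correlations
from traitnet.sem import SEMSpec, count_parameters, fit_sem
from traitnet.simulate import (
    SyntheticTruth,
    TraitPanel,
    kinship_from_csv,
    kinship_from_markers,
    kinship_to_csv,
    simulate_markers,
    simulate_panel,
    standardize_panel,
)
from traitnet.transform import cholesky_factor, decorrelate

__all__ = ["RunConfig", "run_pipeline", "export_network"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full pipeline configuration; loadable from YAML."""

    # input: either synthetic generation ...
    n_lines: int = 800
    n_markers: int = 2000
    n_families: int = 10
    d: int = 5
    truth_yaml: str | None = None  # optional SyntheticTruth file
    # ... or CSV paths for measured data
    panel_csv: str | None = None
    kinship_csv: str | None = None

    # stage settings
    mcmc_burn_in: int = 1000
    mcmc_n_iter: int = 5000
    mcmc_thin: int = 2
    alpha: float = 0.01
    n_permutations: int = 450
    bootstrap_B: int = 500
    settings: tuple[str, ...] = ("gs1", "gs2", "gs3", "gs4", "tabu1", "tabu2")
    sem_variants: tuple[str, ...] = ("genomic", "residual", "both")
    cv_replicates: int = 0  # 0 disables cross-validation
    cv_folds: int = 5
    outdir: str = "run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        cfg = cls(**payload)
        for p in (cfg.truth_yaml, cfg.panel_csv, cfg.kinship_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _default_truth(d: int, seed: int) -> SyntheticTruth:
    """Sparse ground-truth structures: 3 genomic and 3 residual arcs."""
    lam_u = np.zeros((d, d))
    lam_e = np.zeros((d, d))
    arcs_u = [(1, 0), (2, 0), (3, 2)]
    arcs_e = [(2, 1), (3, 1), (4, 3)]
    for child, parent in arcs_u:
        if child < d and parent < d:
            lam_u[child, parent] = 0.7
    for child, parent in arcs_e:
        if child < d and parent < d:
            lam_e[child, parent] = 0.6
    return SyntheticTruth(
        lambda_u=lam_u,
        lambda_e=lam_e,
        psi_u=np.full(d, 0.5),
        psi_e=np.full(d, 0.5),
        mu=np.zeros(d),
        seed=seed,
    )


def export_network(
    dag: DAGStructure, strengths: ArcStrengths | None, path_prefix
) -> tuple[Path, Path]:
    """Write a learned network as DOT and GraphML.

    Edge labels carry bootstrap strength and direction fraction formatted to
    two decimals, e.g. ``"1.00 (0.80)"``.
    """
    if strengths is not None and set(dag.nodes) != set(strengths.nodes):
        raise ValueError("DAG nodes inconsistent with arc-strength table")
    path_prefix = Path(path_prefix)
    path_prefix.parent.mkdir(parents=True, exist_ok=True)

    def label(a, b):
        if strengths is None:
            return ""
        s = strengths.pair_strength(a, b)
        f = strengths.direction_fraction.get((a, b), 0.0)
        return f"{s:.2f} ({f:.2f})"

    lines = ["digraph trait_network {"]
    for node in dag.nodes:
        lines.append(f'  "{node}";')
    for a, b in sorted(dag.directed_arcs):
        lines.append(f'  "{a}" -> "{b}" [label="{label(a, b)}"];')
    for e in sorted(map(sorted, dag.undirected_edges)):
        a, b = e
        lines.append(f'  "{a}" -> "{b}" [dir=none, label="{label(a, b)}"];')
    lines.append("}")
    dot_path = path_prefix.with_suffix(".dot")
    dot_path.write_text("\n".join(lines) + "\n")

    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    for a, b in dag.directed_arcs:
        attrs = {}
        if strengths is not None:
            attrs = {
                "strength": strengths.pair_strength(a, b),
                "direction": strengths.direction_fraction.get((a, b), 0.0),
            }
        g.add_edge(a, b, **attrs)
    for e in dag.undirected_edges:
        a, b = sorted(e)
        g.add_edge(a, b, undirected=True)
    gml_path = path_prefix.with_suffix(".graphml")
    nx.write_graphml(g, gml_path)
    return dot_path, gml_path


def read_network_graphml(path) -> DAGStructure:
    g = nx.read_graphml(path)
    arcs = set()
    und = set()
    for a, b, attrs in g.edges(data=True):
        if attrs.get("undirected"):
            und.add(frozenset((a, b)))
        else:
            arcs.add((a, b))
    return DAGStructure(list(g.nodes), arcs, und)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure propagates with the stage name; artifacts written by
    completed stages remain in place.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(ss.generate_state(1)[0] % (2**31))
        for name, ss in zip(
            ("simulate", "mtm", "learn", "sem", "cv"), master.spawn(5)
        )
    }
    (out / "provenance.json").write_text(
        json.dumps(
            {
                "config": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(config).items()
                },
                "config_hash": config.config_hash(),
                "stage_seeds": seeds,
            },
            indent=2,
        )
    )

    stage = "simulate"
    try:
        if config.panel_csv is not None:
            panel = TraitPanel.from_csv(config.panel_csv)
            if config.kinship_csv is None:
                raise ValueError("kinship_csv required when panel_csv is given")
            K, _ = kinship_from_csv(config.kinship_csv)
            panel = standardize_panel(panel)
            truth = None
        else:
            if config.truth_yaml is not None:
                truth = SyntheticTruth.from_yaml(config.truth_yaml)
            else:
                truth = _default_truth(config.d, seeds["simulate"])
            markers = simulate_markers(
                config.n_lines, config.n_markers, config.n_families, seeds["simulate"]
            )
            K = kinship_from_markers(markers)
            panel = simulate_panel(
                truth,
                K,
                seed=seeds["simulate"],
                genotype_ids=markers.line_ids,
                family_ids=markers.family_ids,
            )
            panel = standardize_panel(panel)
            truth.to_yaml(out / "truth.yaml")
        panel.to_csv(out / "panel.csv")
        kinship_to_csv(K, panel.genotype_ids, out / "kinship.csv")

        stage = "decompose"
        mcmc = MCMCSettings(
            burn_in=config.mcmc_burn_in,
            n_iter=config.mcmc_n_iter,
            thin=config.mcmc_thin,
            seed=seeds["mtm"],
        )
        mtm_post = fit_mtm(panel, K, mcmc=mcmc)
        mtm_post.export(out / "mtm")

        stage = "transform"
        transform = cholesky_factor(K)
        if transform.ridge_used:
            logger.warning("kinship PD repair applied: ridge %.2e", transform.ridge_used)
        U_star = decorrelate(mtm_post.U_hat, transform)
        pd.DataFrame(U_star, columns=panel.trait_names).to_csv(
            out / "U_star.csv", index=False
        )

        stage = "learn"
        learned: dict[tuple[str, str], DAGStructure] = {}
        for comp_name, comp_data in (("genomic", U_star), ("residual", mtm_post.E_hat)):
            for setting in config.settings:
                learner = make_learner(
                    setting,
                    alpha=config.alpha,
                    n_permutations=config.n_permutations,
                    nodes=panel.trait_names,
                )
                strengths, avg = bootstrap_average(
                    comp_data,
                    learner,
                    B=config.bootstrap_B,
                    seed=seeds["learn"],
                    nodes=panel.trait_names,
                )
                export_network(avg, strengths, out / "networks" / f"{comp_name}_{setting}")
                learned[(comp_name, setting)] = avg

        stage = "sem"
        # deduplicate structures per component at the equivalence-class level
        def distinct(component: str):
            classes: dict[tuple, tuple[str, DAGStructure]] = {}
            for (comp, setting), g in learned.items():
                if comp != component:
                    continue
                rep = representative_extension(g)
                key = _class_key(rep)
                if key in classes:
                    classes[key] = (classes[key][0] + "+" + setting, classes[key][1])
                else:
                    classes[key] = (setting, rep)
            return list(classes.values())

        sem_metrics = []
        counts = {}
        mtm_metrics = compute_dic(
            mtm_post.deviance_draws, mtm_post.deviance_at_mean, "MTM"
        )
        mtm_metrics.log_marginal = marginal_loglik(mtm_post, panel, K)
        all_metrics = [mtm_metrics]
        counts["MTM"] = (
            panel.d * (panel.d - 1) // 2,
            panel.d * (panel.d - 1) // 2,
            panel.d * (panel.d + 1) // 2,
            panel.d * (panel.d + 1) // 2,
        )
        sem_mcmc = MCMCSettings(
            burn_in=config.mcmc_burn_in,
            n_iter=config.mcmc_n_iter,
            thin=config.mcmc_thin,
            seed=seeds["sem"],
        )
        genomic_structs = distinct("genomic")
        residual_structs = distinct("residual")
        specs: list[SEMSpec] = []
        if "genomic" in config.sem_variants:
            for tag, g in genomic_structs:
                specs.append(
                    SEMSpec(
                        structure_genomic=to_structure_matrix(g),
                        label=f"SEM G*({tag}) R",
                    )
                )
        if "residual" in config.sem_variants:
            for tag, g in residual_structs:
                specs.append(
                    SEMSpec(
                        structure_residual=to_structure_matrix(g),
                        label=f"SEM G R*({tag})",
                    )
                )
        if "both" in config.sem_variants:
            for tag_g, gg in genomic_structs:
                for tag_r, gr in residual_structs:
                    specs.append(
                        SEMSpec(
                            structure_genomic=to_structure_matrix(gg),
                            structure_residual=to_structure_matrix(gr),
                            label=f"SEM G*({tag_g}) R*({tag_r})",
                        )
                    )
        for spec in specs:
            post = fit_sem(panel, K, spec, sem_mcmc)
            fm = compute_dic(post.deviance_draws, post.deviance_at_mean, spec.label)
            fm.log_marginal = marginal_loglik(post, panel, K)
            all_metrics.append(fm)
            counts[spec.label] = count_parameters(spec, panel.d)
            sem_metrics.append(fm)

        stage = "assess"
        cv = None
        if config.cv_replicates > 0:
            models = [MTMModel(mcmc=sem_mcmc), SingleTraitModel(mcmc=sem_mcmc)]
            models += [SEMModel(spec, mcmc=sem_mcmc) for spec in specs]
            cv = cross_validate(
                panel, K, models, config.cv_replicates, config.cv_folds, seeds["cv"]
            )
            cv.ability_mean.to_csv(out / "cv_ability_mean.csv")
            cv.ability_sd.to_csv(out / "cv_ability_sd.csv")
        if len(all_metrics) >= 2:
            table = rank_models(all_metrics, cv=cv, counts=counts)
            table.to_csv(out / "model_comparison.csv")
            (out / "model_comparison.txt").write_text(table.to_string() + "\n")
        else:
            pd.DataFrame(
                [{"model": m.model_label, "dic": m.dic, "p_d": m.p_d,
                  "logL": m.log_marginal} for m in all_metrics]
            ).to_csv(out / "model_comparison.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out


def _class_key(dag: DAGStructure) -> tuple:
    cp = cpdag_of(dag) if dag.is_fully_directed else dag
    return (
        tuple(sorted(cp.directed_arcs)),
        tuple(sorted(tuple(sorted(e)) for e in cp.undirected_edges)),
    )
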