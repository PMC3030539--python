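"""End-to-end orchestration of the correlation-network workflow.

One run takes a profile matrix (from files or the synthetic generator) and,
per analysis group: Spearman correlations with local-fdr edge calls, a
topology threshold sweep with randomized-data nulls, threshold selection,
network construction, DPClus clustering, pathway enrichment and the
S-value permutation assessment.  Across groups it runs rank-product
differential abundance against the control group, PCA over all samples,
and Fisher-Z differential correlation between group pairs.  All artifacts
are written deterministically, so identical config + seed reproduce a
byte-identical bundle.

The single top-level seed fans out to per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn``, in a fixed documented order, so
every stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .abundance import log2_transform, pca, rank_product_test
from .containers import ProfileMatrix
from .correlation import (correlation_table, differential_correlation_table)
from .dpclus import DPClusParams, cluster_adjacency, run_dpclus, unclustered_nodes
from .enrichment import assess_clusters
from .synthetic import SyntheticConfig, generate_pathway_annotation, generate_profiles
from .topology import (build_network, randomize_profiles, select_threshold,
                       sweep_thresholds)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "compare_conditions"]

#: fixed fan-out order of per-stage child seeds
STAGE_NAMES = ("synthetic", "annotation", "rankprod", "randomize", "assessment")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (fully serializable)."""

    # input: either file paths or a synthetic config
    matrix_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    synthetic: SyntheticConfig | None = None
    n_decoy_pathways: int = 5

    # analysis design
    analysis_groups: tuple | None = None   # default: every group
    control_group: str | None = None       # default: first group
    log2: bool | None = None               # default: True for files, False synthetic

    # stage defaults
    fdr_cutoff: float = 0.05
    grid_step: float = 0.01
    n_random: int = 100
    n_perm: int = 1000
    cp_in: float = 0.5
    d_in: float = 0.5
    overlapping: bool = True
    min_cluster_size: int = 2
    threshold_override: float | None = None
    only_positive: bool = True

    seed: int = 0
    output_dir: str | None = None

    def stage_seeds(self) -> dict:
        children = np.random.SeedSequence(self.seed).spawn(len(STAGE_NAMES))
        return {
            name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(STAGE_NAMES, children)
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d


def _load_inputs(config: PipelineConfig):
    seeds = config.stage_seeds()
    truth = None
    if config.synthetic is not None:
        syn = config.synthetic
        matrix, truth = generate_profiles(syn)
        annotation = generate_pathway_annotation(
            truth, n_decoy_pathways=config.n_decoy_pathways,
            seed=seeds["annotation"], universe=matrix.metabolite_ids,
        )
        already_log = True
    elif config.matrix_path is not None:
        matrix = mio.read_profile_matrix(config.matrix_path, config.metadata_path)
        annotation = (
            mio.read_annotation(config.annotation_path,
                                universe=matrix.metabolite_ids)
            if config.annotation_path else None
        )
        already_log = False
    else:
        raise ValueError("config needs matrix_path or a synthetic section")
    do_log2 = config.log2 if config.log2 is not None else not already_log
    if do_log2:
        matrix = log2_transform(matrix)
    return matrix, annotation, truth, seeds


def _condition_analysis(matrix, group, annotation, config, seeds, outdir):
    """Correlation -> sweep -> network -> DPClus -> enrichment for one group."""
    sub = matrix.subset_group(group)
    corr = correlation_table(sub, fdr_cutoff=config.fdr_cutoff)
    nulls = randomize_profiles(sub, n_random=config.n_random,
                               seed=seeds["randomize"])
    sweep = sweep_thresholds(corr, nulls, grid_step=config.grid_step,
                             only_positive=config.only_positive)
    threshold = select_threshold(sweep, override=config.threshold_override)
    graph = build_network(corr, threshold, only_positive=config.only_positive)
    params = DPClusParams(cp_in=config.cp_in, d_in=config.d_in,
                          overlapping=config.overlapping,
                          min_cluster_size=config.min_cluster_size)
    clusters = run_dpclus(graph, params)
    result = {
        "group": group,
        "correlations": corr,
        "sweep": sweep,
        "threshold": threshold,
        "graph": graph,
        "clusters": clusters,
        "unclustered": sorted(unclustered_nodes(graph, clusters)),
        "cluster_graph": cluster_adjacency(clusters, graph),
        "assessment": None,
    }
    if annotation is not None and clusters:
        result["assessment"] = assess_clusters(
            clusters, annotation, n_random=config.n_random,
            seed=seeds["assessment"],
        )
    if outdir is not None:
        d = outdir / f"condition_{group}"
        d.mkdir(parents=True, exist_ok=True)
        corr.to_csv(d / "correlations.tsv", sep="\t", index=False,
                    lineterminator="\n", float_format="%.10g")
        sweep.to_frame().to_csv(d / "sweep.tsv", sep="\t", index=False,
                                lineterminator="\n", float_format="%.10g")
        mio.write_network(graph, d / "network.tsv", fmt="edgelist")
        mio.write_network(graph, d / "network.graphml", fmt="graphml")
        mio.write_json({
            "threshold": threshold,
            "clusters": [
                {
                    "id": i,
                    "members": sorted(c.members),
                    "extended_members": sorted(c.extended_members),
                    "density": c.density,
                    "seed_node": str(c.seed_node),
                }
                for i, c in enumerate(clusters)
            ],
            "unclustered": result["unclustered"],
        }, d / "clusters.json")
        if result["assessment"] is not None:
            mio.write_json(result["assessment"].to_dict(), d / "assessment.json")
            enr = pd.concat(
                [r.table.assign(cluster=r.cluster_id)
                 for r in result["assessment"].per_cluster if len(r.table)],
                ignore_index=True,
            ) if result["assessment"].per_cluster else pd.DataFrame()
            enr.to_csv(d / "enrichment.tsv", sep="\t", index=False,
                       lineterminator="\n", float_format="%.10g")
    return result


def run_all(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the in-memory result bundle."""
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    matrix, annotation, truth, seeds = _load_inputs(config)
    groups = list(config.analysis_groups or matrix.groups)
    control = config.control_group or groups[0]

    bundle: dict = {"matrix": matrix, "annotation": annotation, "truth": truth,
                    "config": config, "conditions": {}, "rankprod": {},
                    "differential": {}}

    # PCA over all samples
    bundle["pca"] = pca(matrix, scaling="uv", missing="mean")

    # rank product: each non-control group vs control
    for g in groups:
        if g == control:
            continue
        bundle["rankprod"][(g, control)] = rank_product_test(
            matrix, g, control, n_perm=config.n_perm, seed=seeds["rankprod"],
        )

    # per-condition network analysis
    for g in groups:
        bundle["conditions"][g] = _condition_analysis(
            matrix, g, annotation, config, seeds, outdir,
        )

    # differential correlation between group pairs
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            diff = differential_correlation_table(
                bundle["conditions"][ga]["correlations"],
                bundle["conditions"][gb]["correlations"],
                fdr_cutoff=config.fdr_cutoff,
            )
            bundle["differential"][(ga, gb)] = diff

    # edge-count / differential-count summary table
    rows = []
    for g in groups:
        c = bundle["conditions"][g]
        rows.append({
            "kind": "condition", "label": g,
            "n_pairs": len(c["correlations"]),
            "n_significant_edges": int(c["correlations"]["significant"].sum()),
            "threshold": c["threshold"],
            "n_network_edges": c["graph"].number_of_edges(),
            "n_clusters": len(c["clusters"]),
            "S": (np.nan if c["assessment"] is None else c["assessment"].S),
            "empirical_p": (np.nan if c["assessment"] is None
                            else c["assessment"].empirical_p),
        })
    for (ga, gb), diff in bundle["differential"].items():
        rows.append({
            "kind": "differential", "label": f"{ga}_vs_{gb}",
            "n_pairs": len(diff),
            "n_significant_edges": int(diff["significant"].sum()),
            "threshold": np.nan, "n_network_edges": np.nan,
            "n_clusters": np.nan, "S": np.nan, "empirical_p": np.nan,
        })
    summary = pd.DataFrame(rows)
    bundle["summary"] = summary

    if outdir is not None:
        mio.write_profile_matrix(matrix, outdir / "profiles.tsv",
                                 outdir / "samples.tsv")
        if annotation is not None:
            mio.write_annotation(annotation, outdir / "annotation.tsv")
        bundle["pca"].scores.to_csv(outdir / "pca_scores.tsv", sep="\t",
                                    lineterminator="\n", float_format="%.10g")
        bundle["pca"].loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t",
                                      lineterminator="\n", float_format="%.10g")
        for (g, ctrl), rp in bundle["rankprod"].items():
            rp.table.to_csv(outdir / f"rankprod_{g}_vs_{ctrl}.tsv", sep="\t",
                            index=False, lineterminator="\n",
                            float_format="%.10g")
        for (ga, gb), diff in bundle["differential"].items():
            diff.to_csv(outdir / f"diffcorr_{ga}_vs_{gb}.tsv", sep="\t",
                        index=False, lineterminator="\n", float_format="%.10g")
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False,
                       lineterminator="\n", float_format="%.10g")
        (outdir / "config_resolved.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=True)
        )
        _write_run_log(outdir / "run_log.txt", config, seeds)
    return bundle


def _write_run_log(path: Path, config: PipelineConfig, seeds: dict) -> None:
    import networkx
    import scipy
    import sklearn
    lines = [
        "metcornet run log",
        f"seed: {config.seed}",
        *(f"stage_seed {k}: {v}" for k, v in sorted(seeds.items())),
        f"numpy: {np.__version__}",
        f"scipy: {scipy.__version__}",
        f"pandas: {pd.__version__}",
        f"networkx: {networkx.__version__}",
        f"scikit-learn: {sklearn.__version__}",
    ]
    path.write_text("\n".join(lines) + "\n")


def compare_conditions(
    matrix_a: ProfileMatrix,
    matrix_b: ProfileMatrix,
    fdr_cutoff: float = 0.05,
) -> dict:
    """Differential correlation between two independent datasets.

    Restricts both to their exact-string common metabolites (must be >= 4,
    logged), computes each condition's Spearman table, and applies the
    Fisher-Z difference with local fdr.  Returns the differential table and
    summary counts.
    """
    common = [m for m in matrix_a.metabolite_ids
              if m in set(matrix_b.metabolite_ids)]
    if len(common) < 4:
        raise ValueError(
            f"common metabolite intersection too small: {len(common)}"
        )
    logger.info("restricting to %d common metabolites", len(common))
    a = matrix_a.restrict_metabolites(common)
    b = matrix_b.restrict_metabolites(common)
    corr_a = correlation_table(a, fdr_cutoff=fdr_cutoff)
    corr_b = correlation_table(b, fdr_cutoff=fdr_cutoff)
    diff = differential_correlation_table(corr_a, corr_b, fdr_cutoff=fdr_cutoff)
    return {
        "n_common_metabolites": len(common),
        "correlations_a": corr_a,
        "correlations_b": corr_b,
        "differential": diff,
        "n_significant_a": int(corr_a["significant"].sum()),
        "n_significant_b": int(corr_b["significant"].sum()),
        "n_differential": int(diff["significant"].sum()),
    }
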