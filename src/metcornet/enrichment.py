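"""Pathway over-representation of clusters and the S-value assessment.

Each cluster is tested against every pathway with a one-sided Fisher exact
test on the 2x2 table (in cluster / not in cluster) x (in pathway / not in
pathway) over a fixed metabolite universe; the over-representation p-value
is the upper hypergeometric tail P(X >= a).  A cluster's score is its best
(minimum) p-value over pathways, p_min, and the cluster set's S-value is
the mean of p_min over clusters.  Significance of the whole clustering is
judged against size-preserving randomized cluster sets: each randomized
cluster replaces its members by a uniform draw from the universe of the
same size, and the empirical p is the fraction of randomized S-values at
least as good (small) as the real one, with a +1 correction so it is never
zero.

Raw per-pathway p-values are reported without multiple-testing correction
across pathways; the S-value permutation null is the global control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import PathwayAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "ClusterAssessment",
    "fisher_exact_enrichment",
    "s_value",
    "randomized_cluster_sets",
    "assess_clusters",
]

P_CUTOFF = 0.05


@dataclass
class ContingencyTable:
    """2x2 counts: cluster x pathway over the universe."""

    a: int  # in cluster and pathway
    b: int  # in pathway, outside cluster
    c: int  # in cluster, outside pathway
    d: int  # in neither

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    cluster_id: int
    #: per-pathway table: pathway, a, b, c, d, p
    table: pd.DataFrame
    p_min: float          # NaN when the cluster has no annotated member
    best_pathway: str | None
    significant: bool

    @property
    def is_ns(self) -> bool:
        return np.isnan(self.p_min)


def _members_of(cluster) -> frozenset:
    return frozenset(getattr(cluster, "members", cluster))


def fisher_exact_enrichment(
    cluster,
    annotation: PathwayAnnotation,
    cluster_id: int = 0,
    p_cutoff: float = P_CUTOFF,
) -> EnrichmentResult:
    """One-sided over-representation test of a cluster against each pathway.

    The universe is the annotation's universe (already restricted to the
    analyzed metabolites by the caller); the cluster is restricted to it.
    An empty restricted cluster yields an "n.s." result with p_min = NaN.
    """
    universe = annotation.universe
    n = len(universe)
    cl = _members_of(cluster) & universe
    if not cl:
        logger.warning("cluster %s has no member in the universe: n.s.",
                       cluster_id)
        return EnrichmentResult(
            cluster_id=cluster_id,
            table=pd.DataFrame(columns=["pathway", "a", "b", "c", "d", "p"]),
            p_min=float("nan"), best_pathway=None, significant=False,
        )
    rows = []
    for pw in sorted(annotation.members):
        mem = annotation.members[pw]
        a = len(cl & mem)
        b = len(mem) - a
        c = len(cl) - a
        d = n - a - b - c
        # upper tail P(X >= a), hypergeometric with pathway size a+b,
        # cluster size a+c, universe n
        p = float(hypergeom.sf(a - 1, n, a + b, a + c))
        rows.append((pw, a, b, c, d, min(1.0, p)))
    table = pd.DataFrame(rows, columns=["pathway", "a", "b", "c", "d", "p"])
    best = table.loc[table["p"].idxmin()]
    return EnrichmentResult(
        cluster_id=cluster_id,
        table=table,
        p_min=float(best["p"]),
        best_pathway=str(best["pathway"]),
        significant=bool(best["p"] <= p_cutoff),
    )


def s_value(results) -> float:
    """Mean of p_min over clusters with a defined p_min."""
    results = list(results)
    p_mins = [r.p_min for r in results if not np.isnan(r.p_min)]
    n_missing = len(results) - len(p_mins)
    if n_missing:
        logger.warning("%d clusters with undefined p_min excluded from S",
                       n_missing)
    if not p_mins:
        raise ValueError("no cluster has a defined p_min")
    return float(np.mean(p_mins))


def randomized_cluster_sets(
    clusters,
    universe,
    n_random: int = 100,
    seed: int = 0,
    global_permutation: bool = False,
):
    """Yield size-preserving randomized cluster sets.

    Default: each cluster's members are replaced by an independent uniform
    draw without replacement from the universe, preserving its size.  With
    ``global_permutation`` a single random relabelling (bijection) of the
    universe is applied to all clusters of a set — the strict reading of
    permuting the metabolite names — which also preserves overlaps.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    pool = sorted(universe)
    sizes = [len(_members_of(c)) for c in clusters]
    if any(s > len(pool) for s in sizes):
        raise ValueError("cluster larger than the universe")
    rng = np.random.default_rng(seed)
    member_sets = [_members_of(c) for c in clusters]
    for _ in range(n_random):
        if global_permutation:
            relabel = dict(zip(pool, rng.permutation(pool)))
            yield [
                frozenset(relabel.get(m, m) for m in mem) for mem in member_sets
            ]
        else:
            yield [
                frozenset(
                    pool[i] for i in rng.choice(len(pool), size=s, replace=False)
                )
                for s in sizes
            ]


@dataclass
class ClusterAssessment:
    """Real S-value against its size-preserving permutation null."""

    S: float
    null_S: np.ndarray
    n_random: int
    empirical_p: float
    per_cluster: list = field(default_factory=list)  # EnrichmentResults

    def to_dict(self) -> dict:
        return {
            "S": self.S,
            "null_S": [float(x) for x in self.null_S],
            "n_random": self.n_random,
            "empirical_p": self.empirical_p,
            "per_cluster": [
                {
                    "cluster_id": r.cluster_id,
                    "p_min": None if np.isnan(r.p_min) else r.p_min,
                    "best_pathway": r.best_pathway,
                    "significant": r.significant,
                }
                for r in self.per_cluster
            ],
        }


def assess_clusters(
    clusters,
    annotation: PathwayAnnotation,
    n_random: int = 100,
    seed: int = 0,
    global_permutation: bool = False,
) -> ClusterAssessment:
    """Compute the real S-value and its randomized-cluster null.

    ``empirical_p = (1 + #{null S <= real S}) / (n_random + 1)`` — never
    exactly zero.
    """
    results = [
        fisher_exact_enrichment(c, annotation, cluster_id=i)
        for i, c in enumerate(clusters)
    ]
    S = s_value(results)
    null_S = np.empty(n_random)
    for k, rand_set in enumerate(randomized_cluster_sets(
        clusters, annotation.universe, n_random=n_random, seed=seed,
        global_permutation=global_permutation,
    )):
        rand_results = [
            fisher_exact_enrichment(mem, annotation, cluster_id=i)
            for i, mem in enumerate(rand_set)
        ]
        null_S[k] = s_value(rand_results)
    empirical_p = (1 + int(np.sum(null_S <= S))) / (n_random + 1)
    return ClusterAssessment(
        S=S, null_S=null_S, n_random=n_random,
        empirical_p=float(empirical_p), per_cluster=results,
    )
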