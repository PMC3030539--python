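"""Differential-abundance statistics: log2 transform, rank product, PCA.

The rank product is the two-group "all cross-pairs" variant: for each of the
``n_a * n_b`` cross-group sample pairs the per-metabolite log-ratios are
ranked (rank 1 = most up-regulated for the "up" analysis, most
down-regulated for "down"; ties get average ranks) and the rank product of
a metabolite is the geometric mean of its ranks over all pairs.  The null
distribution is simulated by independent draws of uniformly random rank
assignments, and the per-metabolite pfp (percentage of false positives,
an FDR estimate) is the expected number of null rank products at least as
extreme divided by the metabolite's rank among observed rank products.
pfp values may exceed 1 and are reported uncapped alongside a capped column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA as _SkPCA

from .containers import ProfileMatrix

logger = logging.getLogger(__name__)

__all__ = ["log2_transform", "rank_product_test", "pca",
           "RankProductResult", "PCAResult"]


def log2_transform(matrix: ProfileMatrix) -> ProfileMatrix:
    """Elementwise log2; missing values preserved, nonpositive cells error."""
    vals = matrix.values
    bad = (vals <= 0) & vals.notna()
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"nonpositive value at metabolite {vals.index[i]!r}, "
            f"sample {vals.columns[j]!r}: {vals.iat[i, j]}"
        )
    out = matrix.copy()
    out.values.iloc[:, :] = np.log2(vals.to_numpy(dtype=float))
    return out


@dataclass
class RankProductResult:
    """Per-metabolite rank products for both directions.

    ``table`` columns: metabolite, direction ("up"/"down"), RP, p, pfp,
    pfp_capped.  ``n_perm`` is the number of null permutations used.
    """

    table: pd.DataFrame
    n_perm: int

    def significant(self, direction=None, pfp_cutoff: float = 0.05) -> pd.DataFrame:
        t = self.table
        if direction is not None:
            t = t[t["direction"] == direction]
        return t[t["pfp"] < pfp_cutoff]


def _rank_products(diffs: np.ndarray, sign: float) -> np.ndarray:
    # rank 1 = most extreme in the requested direction, average ranks on ties
    ranks = rankdata(-sign * diffs, axis=0, method="average")
    return np.exp(np.mean(np.log(ranks), axis=1))


def rank_product_test(
    matrix: ProfileMatrix,
    group_a: str,
    group_b: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> RankProductResult:
    """Rank-product differential abundance of group_a relative to group_b.

    Expects log-scale values, so the per-pair log-ratio is the difference
    ``x_a - x_b``.  Rows with missing values are not permitted.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ids_a = matrix.samples_in_group(group_a)
    ids_b = matrix.samples_in_group(group_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    A = matrix.values[ids_a].to_numpy(dtype=float)
    B = matrix.values[ids_b].to_numpy(dtype=float)
    if np.isnan(A).any() or np.isnan(B).any():
        bad = matrix.values.index[
            np.isnan(A).any(axis=1) | np.isnan(B).any(axis=1)
        ]
        raise ValueError(
            f"rank product requires complete rows; missing in {list(bad)}"
        )
    m = A.shape[0]
    diffs = (A[:, :, None] - B[:, None, :]).reshape(m, -1)
    K = diffs.shape[1]

    rp = {"up": _rank_products(diffs, +1.0), "down": _rank_products(diffs, -1.0)}

    # null: permute the sample group labels and recompute the rank product.
    # Label permutation preserves the strong dependence among the K
    # cross-group pairs of one metabolite (pairs share samples), which an
    # independent-uniform-ranks null ignores; the same null serves both
    # directions because swapping the groups is itself a label permutation.
    rng = np.random.default_rng(seed)
    pooled = np.hstack([A, B])
    na = A.shape[1]
    n_tot = pooled.shape[1]
    null_vals = np.empty(n_perm * m)
    for k in range(n_perm):
        idx = rng.permutation(n_tot)
        Ap, Bp = pooled[:, idx[:na]], pooled[:, idx[na:]]
        dp = (Ap[:, :, None] - Bp[:, None, :]).reshape(m, -1)
        null_vals[k * m:(k + 1) * m] = _rank_products(dp, +1.0)
    null_vals.sort()

    rows = []
    for direction, rp_dir in rp.items():
        order_rank = rankdata(rp_dir, method="average")
        cnt = np.searchsorted(null_vals, rp_dir, side="right")
        p = cnt / (n_perm * m)
        pfp = (cnt / n_perm) / order_rank
        for g in range(m):
            rows.append((
                matrix.metabolite_ids[g], direction, rp_dir[g],
                p[g], pfp[g], min(1.0, pfp[g]),
            ))
    table = pd.DataFrame(
        rows, columns=["metabolite", "direction", "RP", "p", "pfp", "pfp_capped"]
    )
    return RankProductResult(table=table, n_perm=n_perm)


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # metabolites x components
    explained_variance_ratio: np.ndarray


def pca(
    matrix: ProfileMatrix,
    n_components: int | None = None,
    scaling: str = "uv",
    missing: str = "error",
) -> PCAResult:
    """PCA of the column-centered sample x metabolite matrix.

    scaling: "uv" (unit variance, the default for metabolomic data with
    heterogeneous ranges) or "none" (centering only).  missing: "error",
    "drop" (drop incomplete metabolites, logged) or "mean" (impute the
    metabolite mean, logged).
    """
    X = matrix.values.T  # samples x metabolites
    if X.isna().any().any():
        if missing == "error":
            raise ValueError("missing values present; set missing='drop' or 'mean'")
        if missing == "drop":
            bad = X.columns[X.isna().any()]
            logger.warning("PCA dropping %d incomplete metabolites", len(bad))
            X = X.drop(columns=bad)
        elif missing == "mean":
            logger.warning("PCA mean-imputing %d missing cells",
                           int(X.isna().sum().sum()))
            X = X.fillna(X.mean())
        else:
            raise ValueError(f"unknown missing policy: {missing!r}")
    arr = X.to_numpy(dtype=float)
    max_comp = min(arr.shape[0] - 1, arr.shape[1])
    if n_components is None:
        n_components = min(max_comp, 10)
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(dim)-1={max_comp}"
        )
    if scaling == "uv":
        sd = arr.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.warning("PCA dropping %d constant metabolites",
                           int((~keep).sum()))
            arr = arr[:, keep]
            X = X.loc[:, keep]
            sd = sd[keep]
        arr = (arr - arr.mean(axis=0)) / sd
    elif scaling == "none":
        arr = arr - arr.mean(axis=0)
    else:
        raise ValueError(f"unknown scaling: {scaling!r}")
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(arr)
    comp_ids = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_ids),
        loadings=pd.DataFrame(model.components_.T, index=X.columns,
                              columns=comp_ids),
        explained_variance_ratio=model.explained_variance_ratio_,
    )
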