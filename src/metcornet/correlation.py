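"""Spearman correlation, significance tests, local fdr, and Fisher-Z
differential correlation.

Spearman's rank correlation is used throughout because it is robust to the
heavy-tailed outliers typical of relative-abundance metabolite data and
depends only on monotonicity.  Pairs are computed over pairwise-complete
samples, with the per-pair sample count recorded and used in every test
denominator.

The local false discovery rate follows the two-component mixture
``f(p) = eta0 * 1 + (1 - eta0) * h(p)``: eta0 is Storey's estimator at
lambda = 0.5 and the marginal density f is the Grenander nonincreasing
density estimator (left derivative of the least concave majorant of the
p-value ECDF); ``fdr(p) = min(1, eta0 / f(p))``.  Significance calls use
fdr < 0.05.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import isotonic_regression

from .containers import ProfileMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "spearman_matrix",
    "correlation_pvalue",
    "local_fdr",
    "fisher_z_difference",
    "correlation_table",
    "differential_correlation_table",
    "rho_matrix",
]

FDR_CUTOFF = 0.05
MIN_PAIR_N = 4


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return stats.rankdata(X, axis=1, method="average")


def spearman_matrix(
    matrix: ProfileMatrix, sample_subset=None
) -> pd.DataFrame:
    """All-pairs Spearman correlation as a long table.

    Returns one row per unordered metabolite pair with columns
    ``u, v, r, n``.  ``r`` is the Pearson correlation of average ranks over
    pairwise-complete samples.  Pairs with fewer than 4 complete samples or
    zero rank variance get ``r = NaN`` and are excluded from testing
    downstream (logged).
    """
    pm = matrix if sample_subset is None else matrix.subset_samples(sample_subset)
    X = pm.values.to_numpy(dtype=float)
    ids = pm.metabolite_ids
    m, n = X.shape
    pairs = list(itertools.combinations(range(m), 2))

    if not np.isnan(X).any():
        if n < MIN_PAIR_N:
            raise ValueError(f"need >= {MIN_PAIR_N} samples, got {n}")
        ranks = _rank_rows(X)
        sd = ranks.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(ranks)
        const = sd == 0
        if const.any():
            logger.warning("%d constant metabolites excluded from correlation",
                           int(const.sum()))
        rows = []
        for i, j in pairs:
            r = np.nan if (const[i] or const[j]) else R[i, j]
            rows.append((ids[i], ids[j], r, n))
        return pd.DataFrame(rows, columns=["u", "v", "r", "n"])

    rows = []
    n_skipped = 0
    for i, j in pairs:
        mask = ~(np.isnan(X[i]) | np.isnan(X[j]))
        nn = int(mask.sum())
        if nn < MIN_PAIR_N:
            rows.append((ids[i], ids[j], np.nan, nn))
            n_skipped += 1
            continue
        xi = stats.rankdata(X[i, mask])
        xj = stats.rankdata(X[j, mask])
        if xi.std() == 0 or xj.std() == 0:
            rows.append((ids[i], ids[j], np.nan, nn))
            n_skipped += 1
            continue
        rows.append((ids[i], ids[j], float(np.corrcoef(xi, xj)[0, 1]), nn))
    if n_skipped:
        logger.warning("%d pairs excluded (n < %d or constant)",
                       n_skipped, MIN_PAIR_N)
    return pd.DataFrame(rows, columns=["u", "v", "r", "n"])


def rho_matrix(corr_table: pd.DataFrame, metabolite_ids=None) -> pd.DataFrame:
    """Square symmetric Spearman matrix from a long pair table (diag 1)."""
    if metabolite_ids is None:
        metabolite_ids = sorted(set(corr_table["u"]) | set(corr_table["v"]))
    pos = {m: k for k, m in enumerate(metabolite_ids)}
    R = np.eye(len(metabolite_ids))
    iu = corr_table["u"].map(pos).to_numpy()
    iv = corr_table["v"].map(pos).to_numpy()
    r = corr_table["r"].to_numpy(dtype=float)
    R[iu, iv] = r
    R[iv, iu] = r
    return pd.DataFrame(R, index=metabolite_ids, columns=metabolite_ids)


def spearman_square(matrix: ProfileMatrix) -> np.ndarray:
    """Square Spearman matrix for a complete (no-missing) profile matrix.

    Fast path used by the topology sweep's randomized nulls; NaN where a
    metabolite is constant.
    """
    X = matrix.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        tab = spearman_matrix(matrix)
        return rho_matrix(tab, matrix.metabolite_ids).to_numpy()
    ranks = _rank_rows(X)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(ranks)
    return R


def correlation_pvalue(r, n):
    """t statistic and two-sided p for H0: no correlation.

    ``t = r * sqrt((n - 2) / (1 - r^2))``, referred to Student t with n - 2
    degrees of freedom.  |r| = 1 gives p = 0 by convention (logged).
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    scalar = r.ndim == 0
    r, n = np.atleast_1d(r), np.atleast_1d(np.broadcast_to(n, r.shape))
    t = np.full(r.shape, np.nan)
    p = np.full(r.shape, np.nan)
    ok = ~np.isnan(r) & (n >= MIN_PAIR_N)
    perfect = ok & (np.abs(r) >= 1.0)
    if perfect.any():
        logger.warning("%d perfect correlations: p set to 0", int(perfect.sum()))
        t[perfect] = np.sign(r[perfect]) * np.inf
        p[perfect] = 0.0
    reg = ok & ~perfect
    t[reg] = r[reg] * np.sqrt((n[reg] - 2) / (1 - r[reg] ** 2))
    p[reg] = 2 * stats.t.sf(np.abs(t[reg]), df=n[reg] - 2)
    if scalar:
        return float(t[0]), float(p[0])
    return t, p


def local_fdr(p_values) -> np.ndarray:
    """Local false discovery rate of each p-value.

    Two-component mixture with Storey's eta0 at lambda = 0.5 (capped at 1)
    and the Grenander nonincreasing density estimator for the marginal;
    fdr = min(1, eta0 / f_hat).  NaN inputs give NaN outputs.
    """
    p_in = np.asarray(p_values, dtype=float)
    if p_in.size == 0:
        raise ValueError("local_fdr needs at least one p-value")
    valid = ~np.isnan(p_in)
    p = np.clip(p_in[valid], 1e-15, 1.0)
    if p.size == 0:
        raise ValueError("local_fdr: all p-values missing")
    if p.size < 50:
        logger.warning("local_fdr on only %d p-values; estimate is unstable",
                       p.size)
    eta0 = min(1.0, float(np.mean(p > 0.5)) / 0.5)

    xs, counts = np.unique(p, return_counts=True)
    F = np.cumsum(counts) / p.size
    x_knots = np.concatenate([[0.0], xs])
    widths = np.diff(x_knots)
    slopes = np.diff(np.concatenate([[0.0], F])) / widths
    fit = isotonic_regression(slopes, weights=widths, increasing=False)
    f_hat_seg = np.asarray(fit.x)

    idx = np.searchsorted(xs, p)
    f_hat = np.maximum(f_hat_seg[idx], 1e-300)
    fdr_valid = np.minimum(1.0, eta0 / f_hat)

    out = np.full(p_in.shape, np.nan)
    out[valid] = fdr_valid
    return out


def correlation_table(
    matrix: ProfileMatrix, sample_subset=None, fdr_cutoff: float = FDR_CUTOFF
) -> pd.DataFrame:
    """Long table of Spearman records: u, v, r, n, t, p, fdr, significant.

    Local fdr is computed across all testable pairs of this analysis set.
    """
    tab = spearman_matrix(matrix, sample_subset=sample_subset)
    t, p = correlation_pvalue(tab["r"].to_numpy(), tab["n"].to_numpy())
    tab["t"], tab["p"] = t, p
    tab["fdr"] = local_fdr(tab["p"].to_numpy())
    tab["significant"] = tab["fdr"] < fdr_cutoff
    return tab


def fisher_z_difference(r1, n1, r2, n2):
    """Fisher-Z test for equality of two correlations.

    ``z_i = atanh(r_i)``; ``Z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3))``;
    two-sided standard-normal p.  Returns ``(z1, z2, Z, p_diff)`` (arrays
    or scalars following the input).  |r| = 1 raises (transform diverges).
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    scalar = r1.ndim == 0 and r2.ndim == 0
    r1, r2 = np.atleast_1d(r1), np.atleast_1d(r2)
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), r1.shape)
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), r2.shape)
    finite = ~(np.isnan(r1) | np.isnan(r2))
    if np.any(np.abs(r1[finite]) >= 1) or np.any(np.abs(r2[finite]) >= 1):
        raise ValueError("|r| = 1: Fisher transform diverges; flag the pair")
    if np.any(n1[finite] < MIN_PAIR_N) or np.any(n2[finite] < MIN_PAIR_N):
        raise ValueError(f"both conditions need n >= {MIN_PAIR_N}")
    with np.errstate(invalid="ignore"):
        z1, z2 = np.arctanh(r1), np.arctanh(r2)
        Z = (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
        p = 2 * stats.norm.sf(np.abs(Z))
    if scalar:
        return float(z1[0]), float(z2[0]), float(Z[0]), float(p[0])
    return z1, z2, Z, p


def differential_correlation_table(
    corr1: pd.DataFrame,
    corr2: pd.DataFrame,
    fdr_cutoff: float = FDR_CUTOFF,
) -> pd.DataFrame:
    """Cross-condition comparison of two correlation tables.

    Joins on the unordered pair, computes the Fisher-Z difference with each
    pair's own sample counts, the local fdr over all tested pairs, and
    ``delta = r1 - r2``.  Pairs missing or perfect in either condition are
    reported with NaN statistics.
    """
    k1 = corr1.set_index(["u", "v"])
    k2 = corr2.set_index(["u", "v"])
    common = k1.index.intersection(k2.index)
    if len(common) == 0:
        raise ValueError("no shared metabolite pairs between conditions")
    a, b = k1.loc[common], k2.loc[common]
    out = pd.DataFrame({
        "u": [u for u, _ in common],
        "v": [v for _, v in common],
        "r1": a["r"].to_numpy(), "n1": a["n"].to_numpy(),
        "r2": b["r"].to_numpy(), "n2": b["n"].to_numpy(),
        "p1": a["p"].to_numpy() if "p" in a else np.nan,
        "p2": b["p"].to_numpy() if "p" in b else np.nan,
    })
    testable = (
        out[["r1", "r2"]].notna().all(axis=1)
        & (np.abs(out["r1"]) < 1) & (np.abs(out["r2"]) < 1)
        & (out["n1"] >= MIN_PAIR_N) & (out["n2"] >= MIN_PAIR_N)
    ).to_numpy()
    z1 = np.full(len(out), np.nan)
    z2 = np.full(len(out), np.nan)
    Z = np.full(len(out), np.nan)
    p = np.full(len(out), np.nan)
    if testable.any():
        z1[testable], z2[testable], Z[testable], p[testable] = fisher_z_difference(
            out.loc[testable, "r1"].to_numpy(), out.loc[testable, "n1"].to_numpy(),
            out.loc[testable, "r2"].to_numpy(), out.loc[testable, "n2"].to_numpy(),
        )
    n_dropped = int((~testable).sum())
    if n_dropped:
        logger.warning("%d pairs not testable for differential correlation",
                       n_dropped)
    out["z1"], out["z2"], out["Z"], out["p_diff"] = z1, z2, Z, p
    out["fdr"] = local_fdr(p) if np.any(~np.isnan(p)) else np.nan
    out["delta"] = out["r1"] - out["r2"]
    out["significant"] = out["fdr"] < fdr_cutoff
    return out
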