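"""Synthetic metabolite profiles with planted correlation modules.

The generator emulates the structure of a GC-TOF/MS metabolite profiling
experiment on log2 scale: blocks of co-regulated metabolites driven by a
shared latent factor (one factor per module, all-positive loadings, since
metabolomic correlation studies find predominantly positive correlations),
genotype-specific mean shifts for designated metabolites (a
"Met over-accumulation"-like effect), and heavy-tailed outlier contamination
produced by multiplying a residual by a large scale factor with small
probability — the kind of contamination that motivates rank (Spearman)
correlation over Pearson.

Randomness comes from numpy's PCG64 generator (``numpy.random.default_rng``);
the seed is a required config field and identical configs reproduce identical
matrices bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import PathwayAnnotation, ProfileMatrix

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_profiles",
    "generate_pathway_annotation",
]

#: default design: 59 metabolites over three genotype groups of 17/16/20
#: samples, four planted modules.
DEFAULT_GROUPS = (("WT", 17), ("mto1", 16), ("tt4", 20))
DEFAULT_MODULE_SIZES = (12, 10, 8, 6)


@dataclass
class SyntheticConfig:
    """Configuration of one synthetic dataset.

    Attributes
    ----------
    n_metabolites
        Total number of metabolites (module members plus independent noise).
    module_sizes
        Sizes of the planted co-regulation modules; each must be >= 2 and
        their sum must not exceed ``n_metabolites``.  Module m occupies the
        next ``module_sizes[m]`` metabolite indices after module m-1.
    groups
        ``(label, n_samples)`` pairs defining the sample groups.
    factor_loading
        Nominal coefficient of a module metabolite on its module's latent
        factor (log2 scale).  Signal-to-noise is ``factor_loading /
        noise_sd``.
    loading_jitter
        Relative half-width of the per-metabolite loading distribution:
        each module metabolite's loading is drawn as
        ``factor_loading * Uniform(1 - jitter, 1 + jitter)``, so module
        members couple to their pathway factor with heterogeneous strength,
        as real co-regulated metabolites do.  Must be in [0, 1).
    noise_sd
        Standard deviation of the independent log2-scale residual.
    shift_spec
        ``(group_label, metabolite_index, log2_shift)`` triples: additive
        mean offsets applied to one metabolite in one group.
    outlier_fraction, outlier_scale
        With probability ``outlier_fraction`` an entry's residual is
        multiplied by ``outlier_scale`` (>= 1), producing heavy tails.
    baseline_mean, baseline_sd
        Distribution of per-metabolite baseline log2 abundances.
    seed
        Required PRNG seed.
    """

    n_metabolites: int = 59
    module_sizes: tuple = DEFAULT_MODULE_SIZES
    groups: tuple = DEFAULT_GROUPS
    factor_loading: float = 1.0
    loading_jitter: float = 0.4
    noise_sd: float = 0.5
    shift_spec: tuple = (("mto1", 0, 2.0),)
    outlier_fraction: float = 0.02
    outlier_scale: float = 5.0
    baseline_mean: float = 10.0
    baseline_sd: float = 2.0
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.groups)

    def validate(self) -> None:
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be >= 1")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("module_sizes entries must be >= 2")
        if sum(self.module_sizes) > self.n_metabolites:
            raise ValueError(
                f"sum(module_sizes)={sum(self.module_sizes)} exceeds "
                f"n_metabolites={self.n_metabolites}"
            )
        if not self.groups:
            raise ValueError("at least one sample group is required")
        labels = [g for g, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")
        for g, i, _ in self.shift_spec:
            if g not in labels:
                raise ValueError(f"shift_spec references unknown group {g!r}")
            if not (0 <= i < self.n_metabolites):
                raise ValueError(f"shift_spec index {i} out of range")
        if not (0.0 <= self.outlier_fraction <= 1.0):
            raise ValueError("outlier_fraction must be in [0, 1]")
        if self.outlier_scale < 1.0:
            raise ValueError("outlier_scale must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.factor_loading <= 0:
            raise ValueError("factor_loading must be > 0")
        if not (0.0 <= self.loading_jitter < 1.0):
            raise ValueError("loading_jitter must be in [0, 1)")
        if self.seed is None:
            raise ValueError("seed is required")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset."""

    #: metabolite id -> module index, or absent if the metabolite is noise
    module_membership: dict = field(default_factory=dict)
    #: group label -> set of metabolite ids with a nonzero planted mean shift
    shifted_metabolites: dict = field(default_factory=dict)
    #: module index -> pathway label used for that module in the annotation
    pathway_truth: dict = field(default_factory=dict)

    def module_members(self, module: int) -> frozenset:
        return frozenset(
            m for m, k in self.module_membership.items() if k == module
        )

    @property
    def modules(self) -> list[int]:
        return sorted(set(self.module_membership.values()))


def _metabolite_ids(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"met{str(i).zfill(width)}" for i in range(n)]


def generate_profiles(config: SyntheticConfig) -> tuple[ProfileMatrix, GroundTruth]:
    """Draw one synthetic log2 profile matrix with its ground truth.

    Metabolite i of module m in sample s has value

        mu_i + shift(group(s), i) + loading_i * f[m, s] + eps[i, s]

    with per-metabolite loading ``loading_i`` (see ``loading_jitter``),
    ``f`` standard normal per sample and module, and
    ``eps ~ Normal(0, noise_sd)``; with probability ``outlier_fraction``
    the residual of an entry is multiplied by ``outlier_scale``.
    Metabolites outside all modules are baseline plus independent noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_met = config.n_metabolites
    met_ids = _metabolite_ids(n_met)
    sample_ids: list[str] = []
    group_of: list[str] = []
    for label, n in config.groups:
        sample_ids.extend(f"{label}_{j + 1}" for j in range(n))
        group_of.extend([label] * n)
    n_samp = len(sample_ids)

    # module membership: consecutive index blocks
    membership = np.full(n_met, -1, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes):
        membership[pos:pos + size] = m
        pos += size

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n_met)
    loadings = config.factor_loading * rng.uniform(
        1.0 - config.loading_jitter, 1.0 + config.loading_jitter, size=n_met
    )
    factors = rng.standard_normal((config.n_modules, n_samp))
    eps = rng.normal(0.0, config.noise_sd, size=(n_met, n_samp))
    if config.outlier_fraction > 0 and config.outlier_scale > 1:
        hits = rng.random((n_met, n_samp)) < config.outlier_fraction
        eps = np.where(hits, eps * config.outlier_scale, eps)

    X = mu[:, None] + eps
    in_module = membership >= 0
    if in_module.any():
        X[in_module] += (loadings[in_module, None]
                         * factors[membership[in_module]])

    shifted: dict[str, set] = {}
    group_arr = np.asarray(group_of)
    for g, i, delta in config.shift_spec:
        if delta == 0:
            continue
        X[i, group_arr == g] += delta
        shifted.setdefault(g, set()).add(met_ids[i])

    values = pd.DataFrame(X, index=met_ids, columns=sample_ids)
    matrix = ProfileMatrix(
        values=values,
        sample_groups=pd.Series(group_of, index=sample_ids, name="group"),
        sample_tissue=pd.Series("root", index=sample_ids, name="tissue"),
    )
    truth = GroundTruth(
        module_membership={
            met_ids[i]: int(membership[i])
            for i in range(n_met) if membership[i] >= 0
        },
        shifted_metabolites=shifted,
        pathway_truth={m: f"pathway_module{m}" for m in range(config.n_modules)},
    )
    return matrix, truth


def generate_pathway_annotation(
    truth: GroundTruth,
    n_decoy_pathways: int = 0,
    seed: int = 0,
    universe=None,
    decoy_size_range: tuple[int, int] = (4, 12),
) -> PathwayAnnotation:
    """Emit a pathway annotation matching the planted modules.

    Each planted module's metabolites share one pathway label.  Decoy
    pathways are uniform random metabolite sets of comparable size drawn
    from the universe; like real KEGG pathways, pathways may overlap and a
    metabolite may carry several labels.
    """
    if n_decoy_pathways < 0:
        raise ValueError("n_decoy_pathways must be >= 0")
    rng = np.random.default_rng(seed)
    members: dict[str, frozenset] = {}
    for m in truth.modules:
        members[truth.pathway_truth[m]] = truth.module_members(m)
    if universe is None:
        universe = frozenset().union(*members.values()) if members else frozenset()
    universe = frozenset(universe)
    pool = sorted(universe)
    lo, hi = decoy_size_range
    hi = min(hi, len(pool))
    for d in range(n_decoy_pathways):
        size = int(rng.integers(min(lo, hi), hi + 1))
        picked = rng.choice(len(pool), size=size, replace=False)
        members[f"decoy_pathway{d}"] = frozenset(pool[i] for i in sorted(picked))
    return PathwayAnnotation(members=members, universe=universe)
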