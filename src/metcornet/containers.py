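"""Core in-memory containers shared by every pipeline stage.

A :class:`ProfileMatrix` is a metabolites x samples abundance table with
per-sample group (genotype) and tissue labels.  A :class:`PathwayAnnotation`
maps pathway ids to metabolite sets over a fixed test universe.  Correlation
networks are plain :class:`networkx.Graph` objects whose edges carry the
correlation coefficient as attribute ``r``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ProfileMatrix", "PathwayAnnotation"]


@dataclass
class ProfileMatrix:
    """Metabolite abundance matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by metabolite id with one column per sample.
        Values are relative abundances (raw) or log2 abundances after the
        transform stage.  Missing values are ``NaN``.
    sample_groups
        Series mapping sample id -> group (genotype) label.  Every sample
        in ``values`` must be present.
    sample_tissue
        Optional Series mapping sample id -> tissue label.
    """

    values: pd.DataFrame
    sample_groups: pd.Series
    sample_tissue: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate metabolite ids: {dupes}")
        if cols.has_duplicates:
            dupes = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dupes}")
        missing = [s for s in cols if s not in self.sample_groups.index]
        if missing:
            raise ValueError(
                f"samples absent from metadata: {missing}"
            )
        # keep metadata aligned to the matrix column order
        self.sample_groups = self.sample_groups.reindex(cols)
        if self.sample_tissue is not None:
            self.sample_tissue = self.sample_tissue.reindex(cols)

    # -- basic accessors -------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.sample_groups:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        sel = self.sample_groups[self.sample_groups == group]
        if sel.empty:
            raise KeyError(f"unknown group label: {group!r}")
        return list(sel.index)

    def subset_samples(self, sample_ids) -> "ProfileMatrix":
        sample_ids = list(sample_ids)
        unknown = [s for s in sample_ids if s not in self.values.columns]
        if unknown:
            raise KeyError(f"unknown sample ids: {unknown}")
        return ProfileMatrix(
            values=self.values[sample_ids].copy(),
            sample_groups=self.sample_groups.loc[sample_ids].copy(),
            sample_tissue=(
                None if self.sample_tissue is None
                else self.sample_tissue.loc[sample_ids].copy()
            ),
        )

    def subset_group(self, group: str) -> "ProfileMatrix":
        return self.subset_samples(self.samples_in_group(group))

    def restrict_metabolites(self, metabolite_ids) -> "ProfileMatrix":
        """Exact-string restriction to a common metabolite list (order kept)."""
        metabolite_ids = [m for m in metabolite_ids if m in self.values.index]
        return ProfileMatrix(
            values=self.values.loc[metabolite_ids].copy(),
            sample_groups=self.sample_groups.copy(),
            sample_tissue=(
                None if self.sample_tissue is None else self.sample_tissue.copy()
            ),
        )

    def copy(self) -> "ProfileMatrix":
        return ProfileMatrix(
            values=self.values.copy(),
            sample_groups=self.sample_groups.copy(),
            sample_tissue=(
                None if self.sample_tissue is None else self.sample_tissue.copy()
            ),
        )


@dataclass
class PathwayAnnotation:
    """Pathway membership sets over a metabolite universe.

    ``members`` maps pathway id -> frozenset of metabolite ids.  The
    ``universe`` is the set of metabolites eligible for enrichment testing;
    member sets are intersected with it and empty pathways dropped (with a
    logged warning) on construction.
    """

    members: dict[str, frozenset] = field(default_factory=dict)
    universe: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = frozenset().union(*self.members.values()) \
                if self.members else frozenset()
        self.universe = frozenset(self.universe)
        cleaned: dict[str, frozenset] = {}
        for pw, mem in self.members.items():
            mem = frozenset(mem) & self.universe
            if not mem:
                logger.warning("dropping pathway %r: no members in universe", pw)
                continue
            cleaned[pw] = mem
        self.members = cleaned

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.members)

    def restrict(self, universe) -> "PathwayAnnotation":
        """Restrict the test universe (e.g. to the analyzed metabolites)."""
        return PathwayAnnotation(
            members=dict(self.members),
            universe=frozenset(universe) & self.universe
            if self.universe else frozenset(universe),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, PathwayAnnotation):
            return NotImplemented
        return self.members == other.members and self.universe == other.universe


def as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)
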