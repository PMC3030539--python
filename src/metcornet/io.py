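"""Readers and writers for every artifact the pipeline touches.

All writers are deterministic: rows are sorted by a documented stable key so
repeated runs produce byte-identical files.  Metabolite identifiers are
opaque strings; cross-dataset joins are exact-string intersections.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import PathwayAnnotation, ProfileMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_profile_matrix",
    "write_profile_matrix",
    "read_annotation",
    "write_annotation",
    "write_network",
    "read_network",
    "write_json",
]


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_profile_matrix(path, metadata_path) -> ProfileMatrix:
    """Read an abundance matrix plus sample metadata.

    The matrix file is TSV/CSV with metabolite ids in the first column and a
    header row of sample ids.  Metadata is TSV/CSV with columns
    ``sample``, ``group`` and optionally ``tissue``; every sample in the
    matrix must appear.  Unparseable numeric cells become missing values,
    with the count logged.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dupes = sorted(raw.index[raw.index.duplicated()].unique())
        raise ValueError(f"duplicate metabolite row ids in {path}: {dupes}")
    if raw.columns.has_duplicates:
        dupes = sorted(raw.columns[raw.columns.duplicated()].unique())
        raise ValueError(f"duplicate sample column ids in {path}: {dupes}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    values.index.name = None
    values.columns.name = None
    n_bad = int(values.isna().sum().sum() - raw.isna().sum().sum())
    if n_bad:
        logger.warning("%d unparseable cells set to missing in %s", n_bad, path)
    n_missing = int(values.isna().sum().sum())
    if n_missing:
        logger.info("%d missing values in %s", n_missing, path)

    meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path), dtype=str)
    if "sample" not in meta.columns or "group" not in meta.columns:
        raise ValueError(
            f"metadata {metadata_path} must have 'sample' and 'group' columns"
        )
    meta = meta.set_index("sample")
    absent = [s for s in values.columns if s not in meta.index]
    if absent:
        raise ValueError(f"samples in matrix absent from metadata: {absent}")
    tissue = meta["tissue"] if "tissue" in meta.columns else None
    return ProfileMatrix(
        values=values,
        sample_groups=meta["group"],
        sample_tissue=tissue,
    )


def write_profile_matrix(matrix: ProfileMatrix, path, metadata_path=None) -> None:
    """Write matrix (and optionally metadata) as TSV/CSV."""
    path = Path(path)
    out = matrix.values.copy()
    out.index.name = "metabolite"
    out.to_csv(path, sep=_sep_for(path), lineterminator="\n")
    if metadata_path is not None:
        metadata_path = Path(metadata_path)
        meta = pd.DataFrame({"sample": matrix.sample_ids})
        meta["group"] = matrix.sample_groups.values
        if matrix.sample_tissue is not None:
            meta["tissue"] = matrix.sample_tissue.values
        meta.to_csv(metadata_path, sep=_sep_for(metadata_path), index=False,
                    lineterminator="\n")


# -- pathway annotation ------------------------------------------------------

def read_annotation(path, universe=None) -> PathwayAnnotation:
    """Read a pathway annotation from two-column TSV or GMT.

    GMT lines are ``pathway<TAB>description<TAB>member...``; two-column
    lines are ``metabolite<TAB>pathway``.  The format is chosen by file
    extension (``.gmt``) or by field count.  The universe defaults to the
    union of members; pass ``universe`` to restrict to the analyzed set.
    """
    path = Path(path)
    lines = [
        ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()
    ]
    if not lines:
        raise ValueError(f"empty annotation file: {path}")
    members: dict[str, set] = {}
    is_gmt = path.suffix.lower() == ".gmt" or any(
        len(ln.split("\t")) > 2 for ln in lines
    )
    if is_gmt:
        for ln in lines:
            fields = ln.split("\t")
            pw, mets = fields[0], [m for m in fields[2:] if m]
            members.setdefault(pw, set()).update(mets)
    else:
        header_skipped = False
        for ln in lines:
            fields = ln.split("\t") if "\t" in ln else ln.split(",")
            if len(fields) != 2:
                raise ValueError(f"malformed annotation line: {ln!r}")
            met, pw = fields
            if not header_skipped and met.lower() in {"metabolite", "id"}:
                header_skipped = True
                continue
            members.setdefault(pw, set()).add(met)
    members = {pw: frozenset(m) for pw, m in members.items() if m}
    if not members:
        raise ValueError(f"no pathways parsed from {path}")
    ann = PathwayAnnotation(members=members)
    if universe is not None:
        ann = ann.restrict(universe)
    return ann


def write_annotation(annotation: PathwayAnnotation, path, fmt="tsv") -> None:
    """Write annotation as two-column TSV or GMT (sorted, deterministic)."""
    path = Path(path)
    if fmt == "tsv":
        rows = sorted(
            (met, pw)
            for pw, mems in annotation.members.items() for met in mems
        )
        text = "metabolite\tpathway\n" + "".join(
            f"{met}\t{pw}\n" for met, pw in rows
        )
    elif fmt == "gmt":
        text = "".join(
            f"{pw}\t{pw}\t" + "\t".join(sorted(mems)) + "\n"
            for pw, mems in sorted(annotation.members.items())
        )
    else:
        raise ValueError(f"unknown annotation format: {fmt!r}")
    path.write_text(text)


# -- networks ----------------------------------------------------------------

def write_network(graph: nx.Graph, path, fmt="edgelist") -> None:
    """Write a correlation network.

    ``edgelist``: TSV with columns source, target, r, sorted
    lexicographically by (source, target) with source < target, so output
    is byte-stable.  ``graphml``: GraphML with ``r`` as an edge attribute.
    """
    path = Path(path)
    if fmt == "edgelist":
        rows = []
        for u, v, data in graph.edges(data=True):
            a, b = sorted((str(u), str(v)))
            rows.append((a, b, data.get("r", float("nan"))))
        rows.sort(key=lambda t: (t[0], t[1]))
        with open(path, "w") as fh:
            fh.write("source\ttarget\tr\n")
            for a, b, r in rows:
                fh.write(f"{a}\t{b}\t{r:.10g}\n")
    elif fmt == "graphml":
        # networkx GraphML writer preserves insertion order; rebuild sorted
        g = nx.Graph()
        g.add_nodes_from(sorted(graph.nodes, key=str))
        for u, v, data in sorted(
            graph.edges(data=True), key=lambda e: tuple(sorted((str(e[0]), str(e[1]))))
        ):
            g.add_edge(u, v, **data)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format: {fmt!r}")


def read_network(path, fmt="edgelist") -> nx.Graph:
    path = Path(path)
    if fmt == "edgelist":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for _, row in df.iterrows():
            g.add_edge(row["source"], row["target"], r=float(row["r"]))
        return g
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown network format: {fmt!r}")


# -- results documents -------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path) -> None:
    """Write a results document as deterministic, sorted-key JSON."""
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n"
    )
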