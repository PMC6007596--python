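"""Timetree and presence/absence matrix containers and I/O.

A :class:`TimeTree` is a rooted phylogeny whose branch lengths are absolute
time (Myr).  Node ages (Ma) are reconstructed from branch lengths by
root-to-tip accumulation, anchoring the deepest tip at 0 Ma, so trees need
not be ultrametric.  An optional *root stem* extends above the root (e.g. to
a 720 Ma analysis horizon) so that events can be placed on the branch
subtending the root clade.

A :class:`PresenceMatrix` is a families x taxa binary matrix (pandas
DataFrame, families as rows).  Validation drops all-absent families and
rejects non-binary cells; binding a matrix to a tree requires the taxon set
to equal the tree's tip set exactly.
"""

from __future__ import annotations

import io
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TimeTree",
    "Branch",
    "PresenceMatrix",
    "TreeValidationError",
    "MatrixValidationError",
    "BindingError",
    "read_timetree",
    "read_matrix",
    "write_events",
    "read_events",
    "reroot_at_outgroup",
]

_AGE_TOL = 1e-9


class TreeValidationError(ValueError):
    """Raised when a tree violates the timetree invariants."""


class MatrixValidationError(ValueError):
    """Raised when a presence/absence matrix is malformed."""


class BindingError(ValueError):
    """Raised when a matrix's taxa do not match a tree's tips."""


@dataclass(frozen=True)
class Branch:
    """A single branch, identified by its child node id.

    ``start`` is the older end (parent age, Ma), ``end`` the younger end
    (child age); ``duration = start - end`` (Myr).  The root stem, when
    present, is the branch whose child is the root and whose parent is None.
    """

    child: int
    parent: int | None
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.start - self.end


class TimeTree:
    """Rooted time-calibrated phylogeny with integer node ids.

    Nodes are numbered 0..n-1; tips carry labels, internal nodes may be
    anonymous.  Exactly one root; every non-root node has one parent; parent
    age >= child age on every branch.
    """

    def __init__(
        self,
        parent: Sequence[int],
        children: Sequence[Sequence[int]],
        age: Sequence[float],
        labels: Sequence[str | None],
        stem_age: float | None = None,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = tuple(tuple(c) for c in children)
        self.age = np.asarray(age, dtype=float)
        self.labels = list(labels)
        self.stem_age = stem_age
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeValidationError(f"expected exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self._validate()
        self._postorder = self._compute_postorder()
        self._tipdesc: np.ndarray | None = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, stem_age: float | None = None) -> "TimeTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n)]
        depth = np.zeros(n)
        labels: list[str | None] = [None] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise TreeValidationError("branch lengths are required on every edge")
                if nd.edge.length < 0:
                    raise TreeValidationError(f"negative branch length {nd.edge.length}")
                parent[i] = p
                children[p].append(i)
                depth[i] = depth[p] + nd.edge.length
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeValidationError("every tip must be labelled")
                labels[i] = nd.taxon.label.strip()
        age = depth.max() - depth
        root_i = int(np.flatnonzero(parent < 0)[0])
        if stem_age is None:
            root_edge = nodes[root_i].edge.length
            if root_edge:
                stem_age = float(age[root_i] + root_edge)
        return cls(parent, children, age, labels, stem_age=stem_age)

    @classmethod
    def from_newick(cls, newick: str, stem_age: float | None = None) -> "TimeTree":
        dtree = _parse_tree_string(newick, "newick")
        return cls.from_dendropy(dtree, stem_age=stem_age)

    def _validate(self) -> None:
        seen_tips: set[str] = set()
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                if self.age[p] - self.age[i] < -_AGE_TOL:
                    raise TreeValidationError(
                        f"parent age {self.age[p]} < child age {self.age[i]} at node {i}"
                    )
            if not self.children[i]:
                lab = self.labels[i]
                if lab is None:
                    raise TreeValidationError(f"unlabelled tip at node {i}")
                if lab in seen_tips:
                    raise TreeValidationError(f"duplicate tip label {lab!r}")
                seen_tips.add(lab)
        if self.stem_age is not None and self.stem_age < self.age[self.root] - _AGE_TOL:
            raise TreeValidationError("stem age must be older than the root age")

    # -- topology helpers ---------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_ids(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if not self.children[i]])

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids]

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def root_age(self) -> float:
        return float(self.age[self.root])

    @property
    def has_stem(self) -> bool:
        return self.stem_age is not None

    def _compute_postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            order.append(nd)
            stack.extend(self.children[nd])
        return np.array(order[::-1], dtype=np.int64)

    @property
    def postorder(self) -> np.ndarray:
        """Node ids in postorder (children before parents)."""
        return self._postorder

    def tip_index(self, label: str) -> int:
        for i in self.tip_ids:
            if self.labels[i] == label.strip():
                return int(i)
        raise KeyError(f"unknown tip {label!r}")

    def tip_descendants(self) -> np.ndarray:
        """Boolean matrix (n_nodes x n_tips): tip j descends from node i."""
        if self._tipdesc is None:
            tips = self.tip_ids
            col = {int(t): k for k, t in enumerate(tips)}
            mat = np.zeros((self.n_nodes, len(tips)), dtype=bool)
            for nd in self._postorder:
                if not self.children[nd]:
                    mat[nd, col[int(nd)]] = True
                else:
                    for c in self.children[nd]:
                        mat[nd] |= mat[c]
            self._tipdesc = mat
        return self._tipdesc

    def mrca(self, node_ids: Iterable[int]) -> int:
        ids = list(node_ids)
        if not ids:
            raise ValueError("mrca of an empty set")
        tipdesc = self.tip_descendants()
        col = {int(t): k for k, t in enumerate(self.tip_ids)}
        want = np.zeros(len(self.tip_ids), dtype=bool)
        stackable = list(ids)
        for nd in stackable:
            want |= tipdesc[nd]
        # lowest node covering all wanted tips
        cover = (tipdesc | ~want).all(axis=1)
        cand = np.flatnonzero(cover)
        return int(cand[np.argmin(tipdesc[cand].sum(axis=1))])

    def branch(self, child: int) -> Branch:
        """Branch above ``child``; the stem branch when child is the root."""
        p = int(self.parent[child])
        if p < 0:
            if self.stem_age is None:
                raise TreeValidationError(
                    "the root has no subtending branch; construct the tree with a "
                    "stem_age (e.g. the analysis horizon) to place events above the root"
                )
            return Branch(child=child, parent=None, start=self.stem_age, end=float(self.age[child]))
        return Branch(child=child, parent=p, start=float(self.age[p]), end=float(self.age[child]))

    def branches(self, include_stem: bool = True) -> list[Branch]:
        out = []
        for i in range(self.n_nodes):
            if self.parent[i] >= 0:
                out.append(self.branch(i))
        if include_stem and self.stem_age is not None:
            out.append(self.branch(self.root))
        return out

    def total_branch_time(self, include_stem: bool = True) -> float:
        return float(sum(b.duration for b in self.branches(include_stem=include_stem)))

    def subtree_nodes(self, node: int) -> np.ndarray:
        out, stack = [], [node]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(self.children[nd])
        return np.array(out, dtype=np.int64)

    def path_to_root(self, node: int) -> list[int]:
        """Node ids from ``node`` up to and including the root."""
        path = [node]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def is_descendant(self, node: int, ancestor: int) -> bool:
        return ancestor in self.path_to_root(node)

    def branch_label(self, child: int) -> str:
        """Stable human-readable branch name: the child tip label, or the
        smallest tip label below the child prefixed with 'mrca:'."""
        if not self.children[child]:
            return self.labels[child]  # type: ignore[return-value]
        below = sorted(
            self.labels[int(t)] for t in self.tip_ids[self.tip_descendants()[child]]
        )
        return f"mrca:{below[0]}+{len(below) - 1}"

    # -- serialization ------------------------------------------------

    def to_newick(self) -> str:
        def rec(nd: int) -> str:
            if not self.children[nd]:
                name = self.labels[nd]
            else:
                name = "(" + ",".join(rec(c) for c in self.children[nd]) + ")"
            p = self.parent[nd]
            if p >= 0:
                return f"{name}:{self.age[p] - self.age[nd]:.10g}"
            if self.stem_age is not None:
                return f"{name}:{self.stem_age - self.age[nd]:.10g}"
            return name

        return rec(self.root) + ";"

    def __repr__(self) -> str:
        stem = f", stem={self.stem_age:g} Ma" if self.stem_age is not None else ""
        return f"<TimeTree: {self.n_tips} tips, root {self.root_age:g} Ma{stem}>"


def _parse_tree_string(data: str, fmt: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=data, schema=fmt, suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises a zoo of error types
        raise TreeValidationError(f"could not parse {fmt} tree: {exc}") from exc


def read_timetree(path: str | Path, format: str = "newick", stem_age: float | None = None) -> TimeTree:
    """Read a rooted timetree from a Newick or NEXUS file.

    Node ages are reconstructed by root-to-tip accumulation of branch
    lengths with the deepest tip anchored at 0 Ma.  A root edge length in
    the file, or an explicit ``stem_age``, defines a root stem.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format {format!r}")
    text = Path(path).read_text()
    dtree = _parse_tree_string(text, format)
    return TimeTree.from_dendropy(dtree, stem_age=stem_age)


def reroot_at_outgroup(tree: TimeTree, outgroup: str) -> TimeTree:
    """Reroot on the branch subtending ``outgroup`` (simple utility).

    Ages are recomputed from the rerooted branch lengths, so the result is
    generally non-ultrametric; topology-only analyses (parsimony steps) are
    unaffected by this.
    """
    dtree = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    og = dtree.find_node_with_taxon_label(outgroup)
    if og is None:
        raise KeyError(f"unknown tip {outgroup!r}")
    half = (og.edge.length or 0.0) / 2.0
    dtree.reroot_at_edge(og.edge, length1=half, length2=half, update_bipartitions=False)
    return TimeTree.from_dendropy(dtree)


# ---------------------------------------------------------------------------
# presence/absence matrices
# ---------------------------------------------------------------------------


@dataclass
class MatrixReport:
    """Counts reported by matrix validation (never silently reconciled)."""

    n_families: int
    n_taxa: int
    n_singletons: int
    n_dropped_all_absent: int
    dropped_families: list[str] = field(default_factory=list)


class PresenceMatrix:
    """Binary families x taxa matrix.

    ``data`` has family ids as the index and taxon ids as columns, values in
    {0, 1}.  All-absent families are dropped (with a warning) at validation;
    every retained family has at least one presence.
    """

    def __init__(self, data: pd.DataFrame, unknown_policy: str = "reject"):
        self.data, self.report = _validate_matrix(data, unknown_policy=unknown_policy)

    @property
    def families(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def family(self, fam: str) -> pd.Series:
        return self.data.loc[fam]

    def singletons(self) -> list[str]:
        counts = self.data.sum(axis=1)
        return list(self.data.index[counts == 1])

    def bind(self, tree: TimeTree) -> "PresenceMatrix":
        """Check taxa == tree tips; return self with columns in tip order."""
        tips = set(tree.tip_labels)
        taxa = set(self.taxa)
        if tips != taxa:
            missing = sorted(tips - taxa)
            extra = sorted(taxa - tips)
            raise BindingError(
                f"matrix taxa do not match tree tips; missing from matrix: {missing}; "
                f"not in tree: {extra}"
            )
        out = PresenceMatrix.__new__(PresenceMatrix)
        out.data = self.data[tree.tip_labels]
        out.report = self.report
        return out

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep)

    def __repr__(self) -> str:
        return f"<PresenceMatrix: {self.shape[0]} families x {self.shape[1]} taxa>"


def _validate_matrix(df: pd.DataFrame, unknown_policy: str = "reject") -> tuple[pd.DataFrame, MatrixReport]:
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise MatrixValidationError(f"duplicate family ids: {dups}")
    if df.columns.duplicated().any():
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise MatrixValidationError(f"duplicate taxon ids: {dups}")
    df = df.copy()
    df.index = [str(i).strip() for i in df.index]
    df.columns = [str(c).strip() for c in df.columns]

    vals = df.to_numpy(dtype=object)
    unknown_mask = np.zeros(vals.shape, dtype=bool)
    for code in ("?", "-", "NA", ""):
        unknown_mask |= vals == code
    if unknown_mask.any():
        if unknown_policy == "reject":
            i, j = np.argwhere(unknown_mask)[0]
            raise MatrixValidationError(
                f"unknown cell at family {df.index[i]!r}, taxon {df.columns[j]!r} "
                "(unknown_policy='reject'; use 'absent' to treat '?' as absence)"
            )
        elif unknown_policy == "absent":
            vals[unknown_mask] = 0
        else:
            raise ValueError(f"unknown_policy must be 'reject' or 'absent', got {unknown_policy!r}")
    try:
        arr = vals.astype(float)
    except (TypeError, ValueError) as exc:
        raise MatrixValidationError(f"non-numeric cell in matrix: {exc}") from exc
    if not np.isin(arr, (0.0, 1.0)).all():
        bad = np.argwhere(~np.isin(arr, (0.0, 1.0)))[0]
        raise MatrixValidationError(
            f"non-binary cell {arr[bad[0], bad[1]]!r} at family {df.index[bad[0]]!r}, "
            f"taxon {df.columns[bad[1]]!r}"
        )
    out = pd.DataFrame(arr.astype(np.int8), index=df.index, columns=df.columns)

    absent = out.sum(axis=1) == 0
    dropped = list(out.index[absent])
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} all-absent families: {dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=3,
        )
        out = out.loc[~absent]
    if out.shape[0] == 0 and df.shape[0] > 0:
        raise MatrixValidationError("matrix has no family with at least one presence")
    report = MatrixReport(
        n_families=out.shape[0],
        n_taxa=out.shape[1],
        n_singletons=int((out.sum(axis=1) == 1).sum()),
        n_dropped_all_absent=len(dropped),
        dropped_families=dropped,
    )
    return out, report


def read_matrix(
    path: str | Path,
    format: str = "csv",
    orientation: str = "families-as-rows",
    unknown_policy: str = "reject",
) -> PresenceMatrix:
    """Read a presence/absence matrix from CSV, TSV or a NEXUS characters block.

    ``orientation`` declares whether families are rows or columns; it is
    never guessed.
    """
    if orientation not in ("families-as-rows", "families-as-columns"):
        raise ValueError(f"bad orientation {orientation!r}")
    path = Path(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=object)
    elif format == "nexus":
        df = _read_nexus_characters(path.read_text())
        # NEXUS matrices are taxa x characters
        if orientation == "families-as-rows":
            df = df.T
        return PresenceMatrix(df, unknown_policy=unknown_policy)
    else:
        raise ValueError(f"unsupported matrix format {format!r}")
    if orientation == "families-as-columns":
        df = df.T
    return PresenceMatrix(df, unknown_policy=unknown_policy)


def _read_nexus_characters(text: str) -> pd.DataFrame:
    """Minimal NEXUS characters/data block reader for binary 01 matrices."""
    m = re.search(r"matrix(.*?);", text, flags=re.IGNORECASE | re.DOTALL)
    if not m:
        raise MatrixValidationError("no MATRIX statement found in NEXUS file")
    rows: dict[str, list[str]] = {}
    for line in m.group(1).strip().splitlines():
        line = line.strip()
        if not line or line.startswith("[") :
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise MatrixValidationError(f"cannot parse NEXUS matrix row: {line!r}")
        name = parts[0].strip("'\"")
        states = parts[1].replace(" ", "")
        rows.setdefault(name, []).extend(list(states))
    n_chars = {len(v) for v in rows.values()}
    if len(n_chars) != 1:
        raise MatrixValidationError("NEXUS matrix rows have unequal lengths")
    k = n_chars.pop()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[f"char{i + 1}" for i in range(k)])
    return df


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["replicate", "family", "type", "branch", "time"]


def write_events(events: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write an event table (one row per event) as TSV or JSON.

    Expected columns: replicate (int), family (str), type ('gain'|'loss'),
    branch (int child-node id; the root id denotes the stem), time (Ma).
    Round-trips exactly through :func:`read_events`.
    """
    df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    elif format == "json":
        payload = {"columns": EVENT_COLUMNS, "rows": df.values.tolist()}
        path.write_text(json.dumps(payload))
    else:
        raise ValueError(f"unsupported event format {format!r}")


def read_events(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"replicate": np.int64, "family": str,
                                                "type": str, "branch": np.int64, "time": float})
        if df.shape[0] == 0:
            df = pd.DataFrame(columns=EVENT_COLUMNS)
        return df[EVENT_COLUMNS] if df.shape[1] else df
    elif format == "json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload["rows"], columns=payload["columns"])
        if len(df):
            df = df.astype({"replicate": np.int64, "branch": np.int64, "time": float})
        return df
    raise ValueError(f"unsupported event format {format!r}")
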