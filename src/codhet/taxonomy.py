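"""Hierarchical cause-of-death classifications and tree-path dissimilarities.

A cause list such as the GBD classification is organised as an L-level tree:
level 1 holds a few broad groups (communicable, non-communicable, injuries),
deeper levels refine them, and the *analysis causes* — the mutually exclusive
categories a mortality profile is defined over — sit at the deepest level L.

The dissimilarity between two analysis causes i and j is the normalised
shortest-path length between them in that tree,

    d_ij = (L - l) / L,

where ``l`` is the deepest level at which i and j still belong to the same
group (``l = L`` iff i == j, so d_ii = 0).  For a 3-level tree the possible
values are {0, 1/3, 2/3, 1}.  Because all analysis causes sit at the same
depth, d is an ultrametric: d_ij <= max(d_ih, d_hj) for every triple.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import AlignmentError, HierarchyError

__all__ = [
    "CauseNode",
    "CauseTree",
    "DissimilarityMatrix",
    "parse_hierarchy",
    "pairwise_dissimilarity",
    "dissimilarity_matrix",
    "uniform_dissimilarity",
    "gbd_fixture_tree",
]

HIERARCHY_COLUMNS = ("cause_id", "cause_name", "level", "parent_id")


@dataclass(frozen=True)
class CauseNode:
    """One node of the classification tree.

    Parameters
    ----------
    id : str
        Opaque unique identifier; all lookups are by id, never display name.
    name : str
        Human-readable label (may contain commas/apostrophes; never a key).
    level : int
        Depth, 1 = coarsest.
    parent_id : str or None
        Id of the containing node at ``level - 1``; None iff ``level == 1``.
    """

    id: str
    name: str
    level: int
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise HierarchyError("node id must be a non-empty string")
        if self.level < 1:
            raise HierarchyError(f"node {self.id!r}: level must be >= 1, got {self.level}")
        if self.level == 1 and self.parent_id is not None:
            raise HierarchyError(f"level-1 node {self.id!r} must not have a parent")
        if self.level > 1 and not self.parent_id:
            raise HierarchyError(f"node {self.id!r} at level {self.level} has no parent")


class CauseTree:
    """A validated L-level cause classification.

    Analysis causes are the nodes at the deepest level ``depth``; their order
    follows node insertion order and is the canonical cause order for
    matrices and profiles built from the tree.
    """

    def __init__(self, nodes: Iterable[CauseNode]):
        self._nodes: dict[str, CauseNode] = {}
        for node in nodes:
            if node.id in self._nodes:
                raise HierarchyError(f"duplicate cause id {node.id!r}")
            self._nodes[node.id] = node
        if not self._nodes:
            raise HierarchyError("empty hierarchy")
        self._depth = max(n.level for n in self._nodes.values())
        for node in self._nodes.values():
            if node.level > 1:
                parent = self._nodes.get(node.parent_id)
                if parent is None:
                    raise HierarchyError(
                        f"orphan node {node.id!r}: parent {node.parent_id!r} not found"
                    )
                if parent.level != node.level - 1:
                    raise HierarchyError(
                        f"node {node.id!r} at level {node.level} has parent "
                        f"{parent.id!r} at level {parent.level}; expected level "
                        f"{node.level - 1}"
                    )
        self._analysis_causes = tuple(
            n.id for n in self._nodes.values() if n.level == self._depth
        )
        # lineage cache: cause id -> tuple of ancestor ids (level 1 .. L)
        self._lineages: dict[str, tuple[str, ...]] = {}
        for cid in self._analysis_causes:
            chain = []
            node = self._nodes[cid]
            while node is not None:
                chain.append(node.id)
                node = self._nodes[node.parent_id] if node.parent_id else None
            self._lineages[cid] = tuple(reversed(chain))

    @property
    def depth(self) -> int:
        """Number of levels L; analysis causes live at this level."""
        return self._depth

    @property
    def analysis_causes(self) -> tuple[str, ...]:
        return self._analysis_causes

    @property
    def nodes(self) -> tuple[CauseNode, ...]:
        return tuple(self._nodes.values())

    def node(self, cause_id: str) -> CauseNode:
        try:
            return self._nodes[cause_id]
        except KeyError:
            raise HierarchyError(f"unknown cause id {cause_id!r}") from None

    def name(self, cause_id: str) -> str:
        return self.node(cause_id).name

    def lineage(self, cause_id: str) -> tuple[str, ...]:
        """Ancestor chain of an analysis cause, level 1 first, itself last."""
        try:
            return self._lineages[cause_id]
        except KeyError:
            raise HierarchyError(
                f"{cause_id!r} is not an analysis cause of this tree"
            ) from None

    def ancestor_at(self, cause_id: str, level: int) -> str:
        """Id of the level-``level`` group containing an analysis cause."""
        if not 1 <= level <= self._depth:
            raise HierarchyError(f"level must be in [1, {self._depth}], got {level}")
        return self.lineage(cause_id)[level - 1]

    def to_frame(self) -> pd.DataFrame:
        """Tabular (cause_id, cause_name, level, parent_id) view."""
        return pd.DataFrame(
            [(n.id, n.name, n.level, n.parent_id or "") for n in self._nodes.values()],
            columns=list(HIERARCHY_COLUMNS),
        )

    def __contains__(self, cause_id: str) -> bool:
        return cause_id in self._nodes

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CauseTree(depth={self._depth}, nodes={len(self._nodes)}, "
            f"analysis_causes={len(self._analysis_causes)})"
        )


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric matrix of pairwise cause dissimilarities in [0, 1]."""

    causes: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "causes", tuple(self.causes))
        object.__setattr__(self, "values", values)
        k = len(self.causes)
        if k == 0:
            raise AlignmentError("empty cause list")
        if len(set(self.causes)) != k:
            raise AlignmentError("duplicate cause ids in dissimilarity matrix")
        if values.shape != (k, k):
            raise AlignmentError(
                f"matrix shape {values.shape} does not match {k} causes"
            )
        if not np.allclose(values, values.T, atol=1e-12):
            raise AlignmentError("dissimilarity matrix must be symmetric")
        if np.any(np.abs(np.diag(values)) > 1e-12):
            raise AlignmentError("dissimilarity matrix must have zero diagonal")
        if values.min() < -1e-12 or values.max() > 1 + 1e-12:
            raise AlignmentError("dissimilarities must lie in [0, 1]")

    @property
    def k(self) -> int:
        return len(self.causes)

    def reorder(self, causes: Sequence[str]) -> "DissimilarityMatrix":
        """Return a copy with rows/columns permuted to the given id order."""
        index = {c: i for i, c in enumerate(self.causes)}
        missing = [c for c in causes if c not in index]
        extra = [c for c in self.causes if c not in set(causes)]
        if missing or extra or len(causes) != self.k:
            raise AlignmentError(
                f"cause sets differ: missing from matrix {missing!r}, "
                f"absent from request {extra!r}"
            )
        perm = np.array([index[c] for c in causes])
        return DissimilarityMatrix(tuple(causes), self.values[np.ix_(perm, perm)])


def parse_hierarchy(source) -> CauseTree:
    """Read a cause hierarchy from delimited text or a nested mapping.

    Accepts a filesystem path, a string of CSV content with header
    ``cause_id,cause_name,level,parent_id``, a file-like object, or a nested
    YAML/dict structure ``{id, name, children: [...]}``.
    """
    if isinstance(source, CauseTree):
        return source
    if isinstance(source, Mapping) or (
        isinstance(source, list) and source and isinstance(source[0], Mapping)
    ):
        return _tree_from_nested(source)
    text = None
    if isinstance(source, (str, os.PathLike)):
        if isinstance(source, os.PathLike) or (
            "\n" not in str(source) and os.path.exists(source)
        ):
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        else:
            text = str(source)
    elif hasattr(source, "read"):
        text = source.read()
    else:
        raise HierarchyError(f"unsupported hierarchy source type {type(source)!r}")
    stripped = text.lstrip()
    if stripped.startswith("cause_id"):
        return _tree_from_csv(text)
    # fall back to nested YAML
    try:
        data = yaml.safe_load(stripped)
    except yaml.YAMLError as exc:
        raise HierarchyError(f"could not parse hierarchy source: {exc}") from exc
    if not isinstance(data, (Mapping, list)):
        raise HierarchyError(
            "hierarchy text must be CSV with a 'cause_id' header or a nested "
            "YAML document"
        )
    return _tree_from_nested(data)


def _tree_from_csv(text: str) -> CauseTree:
    try:
        frame = pd.read_csv(io.StringIO(text), dtype=str, keep_default_na=False)
    except Exception as exc:
        raise HierarchyError(f"could not parse hierarchy CSV: {exc}") from exc
    missing = [c for c in HIERARCHY_COLUMNS if c not in frame.columns]
    if missing:
        raise HierarchyError(f"hierarchy file is missing columns {missing!r}")
    nodes = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            level = int(row.level)
        except (TypeError, ValueError):
            raise HierarchyError(
                f"row {row_no}: level {row.level!r} is not an integer"
            ) from None
        parent = row.parent_id or None
        try:
            nodes.append(CauseNode(row.cause_id, row.cause_name, level, parent))
        except HierarchyError as exc:
            raise HierarchyError(f"row {row_no}: {exc}") from None
    return CauseTree(nodes)


def _tree_from_nested(data) -> CauseTree:
    roots = data if isinstance(data, list) else [data]
    nodes: list[CauseNode] = []

    def walk(entry, level, parent_id):
        if not isinstance(entry, Mapping) or "id" not in entry:
            raise HierarchyError(f"nested hierarchy entry {entry!r} lacks an 'id'")
        nodes.append(
            CauseNode(str(entry["id"]), str(entry.get("name", entry["id"])), level, parent_id)
        )
        for child in entry.get("children", []) or []:
            walk(child, level + 1, str(entry["id"]))

    for root in roots:
        walk(root, 1, None)
    return CauseTree(nodes)


def pairwise_dissimilarity(tree: CauseTree, i: str, j: str) -> float:
    """Normalised tree-path dissimilarity (L - l)/L between analysis causes."""
    lin_i, lin_j = tree.lineage(i), tree.lineage(j)
    L = tree.depth
    shared = 0
    for a, b in zip(lin_i, lin_j):
        if a != b:
            break
        shared += 1
    return (L - shared) / L


def dissimilarity_matrix(
    tree: CauseTree, causes: Sequence[str] | None = None
) -> DissimilarityMatrix:
    """Pairwise tree dissimilarities over the given analysis causes.

    Defaults to all analysis causes of the tree in canonical order.
    """
    if causes is None:
        causes = tree.analysis_causes
    causes = tuple(causes)
    if not causes:
        raise AlignmentError("empty cause list")
    L = tree.depth
    lineages = [tree.lineage(c) for c in causes]
    k = len(causes)
    # integer codes per level so equality tests vectorise
    codes = np.empty((k, L), dtype=np.intp)
    for lvl in range(L):
        ids = [lin[lvl] for lin in lineages]
        codes[:, lvl] = pd.factorize(np.asarray(ids, dtype=object))[0]
    same = np.ones((k, k), dtype=bool)
    shared = np.zeros((k, k), dtype=np.intp)
    for lvl in range(L):
        same &= codes[:, lvl][:, None] == codes[None, :, lvl]
        shared += same
    values = (L - shared) / L
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(causes, values)


def uniform_dissimilarity(
    k: int, d: float = 1.0, causes: Sequence[str] | None = None
) -> DissimilarityMatrix:
    """Constant off-diagonal dissimilarity; with d = 1 the inequality index
    coincides with Simpson diversity.  Default cause ids are ``c0..c{k-1}``."""
    if k < 1:
        raise AlignmentError(f"need at least one cause, got k={k}")
    if not 0 < d <= 1:
        raise AlignmentError(f"constant dissimilarity must be in (0, 1], got {d}")
    values = np.full((k, k), float(d))
    np.fill_diagonal(values, 0.0)
    if causes is None:
        causes = tuple(f"c{i}" for i in range(k))
    return DissimilarityMatrix(tuple(causes), values)


def gbd_fixture_tree() -> CauseTree:
    """The packaged GBD-style 3-level fixture hierarchy.

    A representative (not official) encoding of the GBD cause list: 3 level-1
    groups, 22 level-2 groups and 133 level-3 analysis causes, including the
    commonly cited causes (ischaemic heart disease, leukaemia, Alzheimer's
    disease, interpersonal violence, ...).
    """
    from importlib import resources

    ref = resources.files("codhet.data").joinpath("gbd3_hierarchy.csv")
    return parse_hierarchy(ref.read_text(encoding="utf-8"))
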