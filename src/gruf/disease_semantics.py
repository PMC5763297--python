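"""Disease-disease similarity from hierarchical descriptor DAGs.

Each disease is assigned one or more descriptor codes in a hierarchical
disease classification (MeSH tree numbers such as ``C04.588.180``); the
disease's DAG is the set of its descriptors plus all of their ancestors.
A node contributes ``decay ** depth`` (depth = minimum hop count from any of
the disease's own descriptors), and two diseases are compared by how much
semantic contribution their DAGs share:

    sim(A, B) = sum_{t in A∩B} (D_A(t) + D_B(t)) / (DV(A) + DV(B))

with DV(X) = sum of contributions over X.  Identical DAGs score 1, disjoint
DAGs score 0.  An ICD same-category indicator similarity is provided for
datasets annotated with ICD categories instead of descriptor codes.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .containers import SimilarityMatrix

__all__ = [
    "MeshHierarchy",
    "DiseaseDag",
    "build_disease_dag",
    "mesh_semantic_similarity",
    "mesh_similarity_matrix",
    "icd_category_similarity",
]

DEFAULT_DECAY = 0.5


class MeshHierarchy:
    """Child -> parent descriptor relation forming a DAG.

    Either built from an explicit edge list or derived from the dot-structure
    of tree numbers themselves (``C04.588.180`` -> ``C04.588`` -> ``C04``).
    """

    def __init__(self, edges: Iterable[tuple[str, str]]):
        self._parents: dict[str, set[str]] = {}
        graph = nx.DiGraph()
        for child, parent in edges:
            child, parent = str(child), str(parent)
            if child == parent:
                raise ValueError(f"self-loop on descriptor {child!r}")
            self._parents.setdefault(child, set()).add(parent)
            self._parents.setdefault(parent, set())
            graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"descriptor hierarchy contains a cycle: {cycle}")

    @classmethod
    def from_tree_numbers(cls, codes: Iterable[str]) -> "MeshHierarchy":
        """Derive ancestry by truncating dot-separated tree numbers."""
        edges = []
        seen = set()
        stack = [str(c) for c in codes]
        while stack:
            code = stack.pop()
            if code in seen:
                continue
            seen.add(code)
            if "." in code:
                parent = code.rsplit(".", 1)[0]
                edges.append((code, parent))
                stack.append(parent)
        hierarchy = cls(edges)
        # register isolated roots that never appear in an edge
        for code in seen:
            hierarchy._parents.setdefault(code, set())
        return hierarchy

    def __contains__(self, code: str) -> bool:
        return code in self._parents

    def parents(self, code: str) -> frozenset[str]:
        try:
            return frozenset(self._parents[code])
        except KeyError:
            raise KeyError(f"unknown descriptor code {code!r}") from None

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(self._parents)


@dataclass(frozen=True)
class DiseaseDag:
    """A disease's descriptor DAG with per-node minimum depths.

    The disease's own descriptors sit at depth 0; every ancestor appears once
    at its minimum hop distance from any descriptor.
    """

    disease_id: str
    depths: Mapping[str, int]

    def __post_init__(self):
        if not self.depths:
            raise ValueError(f"disease {self.disease_id!r} has an empty DAG")
        object.__setattr__(self, "depths", dict(self.depths))

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.depths)

    def contributions(self, decay: float = DEFAULT_DECAY) -> dict[str, float]:
        if not (0.0 < decay < 1.0):
            raise ValueError(f"decay must lie in (0, 1), got {decay}")
        return {t: decay**d for t, d in self.depths.items()}


def build_disease_dag(
    disease_id: str,
    descriptors: Sequence[str],
    hierarchy: MeshHierarchy | None = None,
) -> DiseaseDag:
    """BFS upward from the disease's descriptors through the parent relation.

    With ``hierarchy=None`` ancestry is derived from the descriptors' own
    dot-separated tree numbers.
    """
    descriptors = [str(d) for d in descriptors]
    if not descriptors:
        raise ValueError(f"disease {disease_id!r} has no descriptors")
    if hierarchy is None:
        hierarchy = MeshHierarchy.from_tree_numbers(descriptors)
    for code in descriptors:
        if code not in hierarchy:
            raise KeyError(
                f"descriptor {code!r} of disease {disease_id!r} not in hierarchy"
            )
    depths: dict[str, int] = {}
    queue = deque((code, 0) for code in descriptors)
    while queue:
        code, depth = queue.popleft()
        if code in depths and depths[code] <= depth:
            continue
        depths[code] = depth
        for parent in hierarchy.parents(code):
            queue.append((parent, depth + 1))
    return DiseaseDag(disease_id, depths)


def mesh_semantic_similarity(
    a: DiseaseDag, b: DiseaseDag, decay: float = DEFAULT_DECAY
) -> float:
    """Shared semantic contribution of two descriptor DAGs, in [0, 1]."""
    da = a.contributions(decay)
    db = b.contributions(decay)
    dv = sum(da.values()) + sum(db.values())
    shared = sum(da[t] + db[t] for t in da.keys() & db.keys())
    return shared / dv


def mesh_similarity_matrix(
    dags: Sequence[DiseaseDag], decay: float = DEFAULT_DECAY
) -> SimilarityMatrix:
    """Pairwise semantic similarity matrix over a list of disease DAGs."""
    ids = tuple(d.disease_id for d in dags)
    n = len(dags)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = mesh_semantic_similarity(
                dags[i], dags[j], decay
            )
    return SimilarityMatrix(ids, values)


def icd_category_similarity(labels: Mapping[str, str]) -> SimilarityMatrix:
    """Same-category indicator similarity: 1 iff two diseases share a category."""
    ids = tuple(str(d) for d in labels)
    if not ids:
        raise ValueError("no diseases given")
    cats = []
    for d in ids:
        cat = labels[d]
        if cat is None or str(cat) == "":
            raise ValueError(f"disease {d!r} has no category label")
        cats.append(str(cat))
    arr = np.array(cats)
    values = (arr[:, None] == arr[None, :]).astype(float)
    return SimilarityMatrix(ids, values)
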