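"""Disease semantic similarity over ontology DAGs.

Each disease A is described by a rooted DAG ``(A, T(A), E(A))`` extracted from
a disease ontology (MeSH-style descriptor hierarchy): ``T(A)`` contains A and
all of its ancestor terms, ``E(A)`` the child->parent links among them. Every
term t in the DAG contributes

    D_A(t) = 1                                      if t = A
    D_A(t) = max{ decay * D_A(t') : t' child of t } otherwise

with decay 0.5 by default. Because the decay factor is a single constant,
the max-over-children recursion reduces to ``decay ** h`` where h is the
minimum number of child->parent hops from A up to t. The semantic value of a
disease is ``DV(A) = sum_t D_A(t)`` and the similarity of two diseases is

    S(A, B) = sum_{t in T(A) ∩ T(B)} (D_A(t) + D_B(t)) / (DV(A) + DV(B))

which lies in [0, 1], equals 1 for identical DAGs and 0 for disjoint ones.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .exceptions import ParseError, ValidationError
from .matrices import SimilarityMatrix

DEFAULT_DECAY = 0.5


@dataclass
class DiseaseDAG:
    """Rooted ancestor DAG of one disease term.

    ``nodes`` holds the disease's own term plus all ancestors; ``edges`` are
    (child, parent) pairs. Every node except the disease term itself must be
    reachable from it by following child->parent edges.
    """

    disease_id: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    root: str | None = None  # ontology term of the disease; defaults to disease_id

    def __post_init__(self) -> None:
        if self.root is None:
            self.root = self.disease_id
        self.nodes = frozenset(self.nodes)
        self.edges = frozenset((str(c), str(p)) for c, p in self.edges)
        self.validate()

    def validate(self) -> None:
        if self.root not in self.nodes:
            raise ValidationError(
                f"root term {self.root!r} missing from the DAG of {self.disease_id!r}"
            )
        for child, parent in self.edges:
            if child not in self.nodes or parent not in self.nodes:
                raise ValidationError(
                    f"edge ({child!r}, {parent!r}) references a node outside the DAG"
                )
        graph = self.to_networkx()
        if not nx.is_directed_acyclic_graph(graph):
            raise ValidationError(f"cycle detected in DAG of {self.disease_id!r}")
        reachable = nx.descendants(graph, self.root) | {self.root}
        unreachable = self.nodes - reachable
        if unreachable:
            raise ValidationError(
                f"nodes unreachable from {self.disease_id!r}: {sorted(unreachable)[:5]}"
            )

    def to_networkx(self) -> nx.DiGraph:
        """Child->parent digraph (edges point from a term to its parent)."""
        graph = nx.DiGraph()
        graph.add_nodes_from(self.nodes)
        graph.add_edges_from(self.edges)
        return graph


@dataclass
class ContributionMap:
    """Per-term contributions D_A(t) of one disease's DAG."""

    disease_id: str
    contributions: dict[str, float]
    root: str | None = None

    def __post_init__(self) -> None:
        if self.root is None:
            self.root = self.disease_id
        if self.contributions.get(self.root) != 1.0:
            raise ValidationError("root term must contribute exactly 1")
        for term, value in self.contributions.items():
            if not (0.0 < value <= 1.0):
                raise ValidationError(
                    f"contribution of {term!r} is {value}, outside (0, 1]"
                )


def contributions(dag: DiseaseDAG, decay: float = DEFAULT_DECAY) -> ContributionMap:
    """Compute D_A(t) for every term of the DAG.

    With a constant decay the recursive max-over-children rule equals
    ``decay ** h`` for h the shortest hop count from the root up to t, so a
    breadth-first traversal along child->parent edges suffices.
    """
    if not (0.0 < decay <= 1.0):
        raise ValidationError(f"decay must be in (0, 1], got {decay}")
    dag.validate()
    hops = {dag.root: 0}
    queue = deque([dag.root])
    parents: dict[str, list[str]] = {}
    for child, parent in dag.edges:
        parents.setdefault(child, []).append(parent)
    while queue:
        term = queue.popleft()
        for parent in parents.get(term, ()):
            if parent not in hops:
                hops[parent] = hops[term] + 1
                queue.append(parent)
    return ContributionMap(
        dag.disease_id, {term: decay**h for term, h in hops.items()}, root=dag.root
    )


def semantic_value(cm: ContributionMap) -> float:
    """DV(A): the sum of all term contributions (always >= 1)."""
    return float(sum(cm.contributions.values()))


def _pair_similarity(cma: ContributionMap, cmb: ContributionMap) -> float:
    shared = cma.contributions.keys() & cmb.contributions.keys()
    if not shared:
        return 0.0
    numerator = sum(cma.contributions[t] + cmb.contributions[t] for t in shared)
    return float(numerator / (semantic_value(cma) + semantic_value(cmb)))


def semantic_similarity(
    dag_a: DiseaseDAG, dag_b: DiseaseDAG, decay: float = DEFAULT_DECAY
) -> float:
    """Similarity of two diseases from their shared ancestor contributions."""
    return _pair_similarity(contributions(dag_a, decay), contributions(dag_b, decay))


def semantic_similarity_matrix(
    dags: Sequence[DiseaseDAG], decay: float = DEFAULT_DECAY
) -> SimilarityMatrix:
    """Pairwise semantic similarity matrix (symmetric, unit diagonal)."""
    ids = [dag.disease_id for dag in dags]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate disease ids among the DAGs")
    maps = [contributions(dag, decay) for dag in dags]
    n = len(dags)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = _pair_similarity(maps[i], maps[j])
    return SimilarityMatrix(values, ids, kind="semantic")


# ---------------------------------------------------------------------------
# ontology I/O
# ---------------------------------------------------------------------------


def read_dags(
    edges_path: str | Path, roster_path: str | Path
) -> list[DiseaseDAG]:
    """Build per-disease DAGs from a global ontology edge list and a roster.

    ``edges_path``: TSV with columns ``child_term<TAB>parent_term`` (no
    header) covering the whole ontology. ``roster_path``: TSV mapping
    ``disease_id<TAB>root_term`` (no header). Each disease's DAG is the
    ancestor closure of its root term. A roster entry whose term does not
    appear in the ontology raises rather than silently yielding a singleton.
    """
    parents: dict[str, set[str]] = {}
    known_terms: set[str] = set()
    with open(edges_path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            tokens = line.split("\t")
            if len(tokens) != 2:
                raise ParseError(
                    f"expected child<TAB>parent, got {len(tokens)} fields", line=lineno
                )
            child, parent = tokens[0].strip(), tokens[1].strip()
            parents.setdefault(child, set()).add(parent)
            known_terms.update((child, parent))

    roster: list[tuple[str, str]] = []
    with open(roster_path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            tokens = line.split("\t")
            if len(tokens) != 2:
                raise ParseError(
                    f"expected disease_id<TAB>root_term, got {len(tokens)} fields",
                    line=lineno,
                )
            roster.append((tokens[0].strip(), tokens[1].strip()))
    if not roster:
        raise ValidationError(f"empty disease roster {roster_path}")

    dags = []
    for disease_id, root in roster:
        if root not in known_terms:
            raise ValidationError(
                f"disease {disease_id!r}: term {root!r} not found in the ontology"
            )
        nodes = {root}
        edges: set[tuple[str, str]] = set()
        queue = deque([root])
        while queue:
            term = queue.popleft()
            for parent in parents.get(term, ()):
                edges.add((term, parent))
                if parent not in nodes:
                    nodes.add(parent)
                    queue.append(parent)
        dags.append(
            DiseaseDAG(disease_id=disease_id, nodes=nodes, edges=edges, root=root)
        )
    return dags
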