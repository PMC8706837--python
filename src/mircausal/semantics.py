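"""Wang-style disease semantic similarity over the MeSH hierarchy.

Every MeSH tree number (e.g. ``C11.768.257``) places a disease in a rooted
hierarchy: each dot-prefix of the code is an ancestor.  A disease with
several tree numbers sits at several positions at once, so the union of its
prefix chains forms a small DAG.  The contribution of an ancestor d to a
target disease D decays with distance,

    DD_D(D) = 1,    DD_D(d) = max over children d' of d on a path to D
                              of delta * DD_D(d'),

the semantic value DC(D) sums the contributions over D's ancestor set T(D),
and the similarity of two diseases is the contribution mass of their shared
ancestors relative to their total semantic values:

    DSS(Di, Dj) = sum_{d in T(Di) ^ T(Dj)} (DD_i(d) + DD_j(d))
                  / (DC(Di) + DC(Dj)).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .types import SimilarityMatrix

log = logging.getLogger(__name__)

_CODE_RE = re.compile(r"^[A-Za-z]\d+(\.\d+)*$")


class MalformedCodeError(ValueError):
    """A MeSH tree number does not match letter+digits(.digits)*."""


@dataclass
class DiseaseDag:
    """Directed acyclic ancestry graph over MeSH codes.

    ``graph`` holds child -> parent edges between code nodes; ``aliases``
    maps each disease name to the code nodes that represent it.  Arbitrary
    DAGs (not only prefix forests) are accepted, which the property tests
    exploit.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    aliases: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("disease ancestry graph contains a cycle")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.out_degree(n) == 0}

    def parents(self, node: str) -> set[str]:
        return set(self.graph.successors(node))

    def children(self, node: str) -> set[str]:
        return set(self.graph.predecessors(node))

    def resolve(self, target: str) -> tuple[str, ...]:
        """Disease name or raw code -> the code nodes representing it."""
        if target in self.aliases:
            return self.aliases[target]
        if target in self.graph:
            return (target,)
        raise KeyError(f"{target!r} is neither a known disease nor a DAG node")

    def ancestor_set(self, target: str) -> set[str]:
        """T(D): the disease's own code nodes plus all their ancestors."""
        own = set(self.resolve(target))
        closure = set(own)
        for node in own:
            closure |= nx.descendants(self.graph, node)  # edges point child->parent
        return closure


def build_dag(tree_numbers: Mapping[str, Sequence[str]]) -> DiseaseDag:
    """Build the ancestry DAG from a disease -> tree-number mapping.

    Every dot-prefix of every code becomes a node; each code points to its
    immediate prefix.  A disease with several codes keeps one alias entry
    listing them all.
    """
    graph = nx.DiGraph()
    aliases: dict[str, tuple[str, ...]] = {}
    for disease, codes in tree_numbers.items():
        own: list[str] = []
        for code in codes:
            code = code.strip()
            if not _CODE_RE.match(code):
                raise MalformedCodeError(f"malformed MeSH tree number {code!r} for {disease!r}")
            parts = code.split(".")
            chain = [".".join(parts[: i + 1]) for i in range(len(parts))]
            for node in chain:
                graph.add_node(node)
            for child, parent in zip(chain[1:], chain[:-1]):
                graph.add_edge(child, parent)
            own.append(code)
        aliases[disease] = tuple(dict.fromkeys(own))
    return DiseaseDag(graph, aliases)


def semantic_contributions(dag: DiseaseDag, d_target: str, delta: float = 0.5) -> dict[str, float]:
    """Decayed contribution DD of every node in T(d_target) to the target."""
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must lie in (0, 1)")
    own = set(dag.resolve(d_target))
    t_set = dag.ancestor_set(d_target)
    sub = dag.graph.subgraph(t_set)
    dd: dict[str, float] = {}
    # child->parent edges: topological order yields children before parents
    for node in nx.topological_sort(sub):
        if node in own:
            dd[node] = 1.0
        else:
            dd[node] = max(delta * dd[c] for c in sub.predecessors(node))
    return dd


def semantic_value(contributions: Mapping[str, float]) -> float:
    """DC(D): total contribution mass over the ancestor set."""
    if not contributions:
        raise ValueError("contributions must be non-empty")
    return float(sum(contributions.values()))


def semantic_similarity_matrix(
    dag: DiseaseDag, diseases: Sequence[str], delta: float = 0.5
) -> SimilarityMatrix:
    """Pairwise DSS over an ordered disease list.

    Diseases absent from the DAG get similarity 0 to all others and 1 to
    themselves (with a logged warning), so the matrix stays total.
    """
    ids = tuple(diseases)
    contribs: dict[str, dict[str, float]] = {}
    values_dc: dict[str, float] = {}
    for d in ids:
        try:
            dd = semantic_contributions(dag, d, delta)
        except KeyError:
            log.warning("disease %r missing from MeSH mapping; similarity set to 0", d)
            continue
        contribs[d] = dd
        values_dc[d] = semantic_value(dd)
    n = len(ids)
    values = np.eye(n)
    for a in range(n):
        da = ids[a]
        if da not in contribs:
            continue
        for b in range(a + 1, n):
            db = ids[b]
            if db not in contribs:
                continue
            shared = contribs[da].keys() & contribs[db].keys()
            if not shared:
                continue
            num = sum(contribs[da][d] + contribs[db][d] for d in shared)
            values[a, b] = values[b, a] = num / (values_dc[da] + values_dc[db])
    return SimilarityMatrix(values, ids)
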