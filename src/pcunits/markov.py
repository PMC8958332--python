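"""Conditional independencies implied by a protein-coding-unit DAG.

Every missing edge of a Bayesian network corresponds to a (conditional)
independence x _|_ y | C for a suitable d-separating set C.  For three-layer
DAGs with edges only a->s and s->p the nodes can be well-ordered so that
local (parent-conditioning) and global (d-separation) Markov conditions
coincide; the canonical conditioning sets used here reproduce that local
form:

    a - a   : C = {}            (roots; every connecting path has a collider)
    a -> s  : C = pa(s)         (a not a parent of s)
    s - s   : C = pa(s1) U pa(s2)  (same unit; the s-s pair is a moral edge)
    a -> p  : C = ch(a), augmented with co-parents of ch(a) when peaks share
              splices (conditioning on a shared child opens the collider, so
              the co-parent must be blocked too)
    s - s'  : C = pa(s) ^ pa(s') across units of a shared-peak joint graph
              (the common peaks)
    p - p   : C = pa(p_first), the full splice set of the first protein

The class s->p never occurs: every splice is connected to its protein by
construction.  Each emitted set is asserted to d-separate its pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .graphs import ProteinCodingUnitDAG

__all__ = [
    "MarkovCondition",
    "KLASSES",
    "d_separated",
    "moral_graph",
    "canonical_conditioning_set",
    "minimal_conditioning_set",
    "condition_klass",
    "enumerate_markov_conditions",
]

KLASSES = ("a-a", "s-s", "a->s", "a->p", "s-between", "p-p")


@dataclass(frozen=True)
class MarkovCondition:
    """A conditional independence x _|_ y | C implied by a DAG."""

    x: str
    y: str
    C: tuple[str, ...]
    klass: str
    dag_id: str

    def __post_init__(self) -> None:
        if self.x == self.y:
            raise ValueError("x and y must differ")
        if self.x in self.C or self.y in self.C:
            raise ValueError("x, y must not belong to the conditioning set")
        if self.klass not in KLASSES:
            raise ValueError(f"unknown klass {self.klass!r}")

    @property
    def variables(self) -> tuple[str, ...]:
        return (self.x, self.y, *self.C)


def d_separated(dag: ProteinCodingUnitDAG, x: str, y: str, C) -> bool:
    """True iff C d-separates x from y in the DAG (moralized-ancestral check).

    Undirected complex edges are not part of the directed graph and are
    ignored here; pairs joined by one are treated as adjacent upstream and
    never reach this predicate through enumeration.
    """
    for n in (x, y, *C):
        if n not in dag.g:
            raise KeyError(f"unknown node {n!r} in DAG {dag.dag_id}")
    if x == y or x in C or y in C:
        raise ValueError("require x != y and x, y not in C")
    return nx.is_d_separator(dag.g, {x}, {y}, set(C))


def moral_graph(dag: ProteinCodingUnitDAG) -> nx.Graph:
    """Undirected moral graph: skeleton plus edges between co-parents."""
    if not nx.is_directed_acyclic_graph(dag.g):
        raise ValueError(f"DAG {dag.dag_id} is cyclic")
    return nx.moral_graph(dag.g)


def condition_klass(dag: ProteinCodingUnitDAG, x: str, y: str) -> str | None:
    """Layer-pair class of a non-adjacent pair; None if the pair is untested.

    Cross-unit s/p pairs have no class (s and p are never considered
    conditionally independent) and are not enumerated.
    """
    lx, ly = dag.layer(x), dag.layer(y)
    pair = frozenset((lx, ly))
    if pair == frozenset(("a",)):
        return "a-a"
    if pair == frozenset(("s",)):
        return "s-s" if dag.unit(x) == dag.unit(y) else "s-between"
    if pair == {"a", "s"}:
        return "a->s"
    if pair == {"a", "p"}:
        return "a->p"
    if pair == frozenset(("p",)):
        return "p-p"
    return None  # s/p cross-unit pair


def canonical_conditioning_set(
    dag: ProteinCodingUnitDAG, x: str, y: str
) -> tuple[str, ...]:
    """Canonical d-separating set for a non-adjacent pair (rules above)."""
    if dag.is_adjacent(x, y):
        raise ValueError(f"({x},{y}) adjacent in DAG {dag.dag_id}")
    klass = condition_klass(dag, x, y)
    if klass is None:
        raise ValueError(f"({x},{y}): cross-unit s/p pairs carry no condition")
    lx = dag.layer(x)
    if klass == "a-a":
        C: set[str] = set()
    elif klass == "a->s":
        s = y if lx == "a" else x
        C = dag.parents(s)
    elif klass == "s-s":
        C = dag.parents(x) | dag.parents(y)
    elif klass == "a->p":
        a = x if lx == "a" else y
        ch = dag.children(a)
        coparents = set().union(*(dag.parents(s) for s in ch)) - {a}
        C = ch | coparents
    elif klass == "s-between":
        C = dag.parents(x) & dag.parents(y)
    else:  # p-p
        first = min(x, y)
        C = dag.parents(first)
    C -= {x, y}
    assert d_separated(dag, x, y, C), (
        f"canonical set for ({x},{y}) fails to d-separate in {dag.dag_id}"
    )
    return tuple(sorted(C))


def minimal_conditioning_set(
    dag: ProteinCodingUnitDAG, x: str, y: str
) -> tuple[str, ...]:
    """Greedy pruning of the canonical set to a minimal d-separator."""
    C = list(canonical_conditioning_set(dag, x, y))
    for c in sorted(C):
        trial = [v for v in C if v != c]
        if d_separated(dag, x, y, trial):
            C = trial
    return tuple(sorted(C))


def enumerate_markov_conditions(
    dag: ProteinCodingUnitDAG, minimal: bool = False
) -> list[MarkovCondition]:
    """All Markov conditions of a DAG, one per eligible non-adjacent pair.

    Pairs joined by a directed or undirected-complex edge are skipped, as
    are cross-unit s/p pairs of joint graphs.  ``minimal=True`` prunes each
    conditioning set to a minimal d-separator (this changes the Fisher
    degrees of freedom downstream).
    """
    if not nx.is_directed_acyclic_graph(dag.g):
        raise ValueError(f"DAG {dag.dag_id} is cyclic")
    nodes = sorted(dag.g.nodes)
    out = []
    chooser = minimal_conditioning_set if minimal else canonical_conditioning_set
    for i, x in enumerate(nodes):
        for y in nodes[i + 1:]:
            if dag.is_adjacent(x, y):
                continue
            klass = condition_klass(dag, x, y)
            if klass is None:
                continue
            x_, y_ = _orient(dag, x, y, klass)
            out.append(MarkovCondition(x_, y_, chooser(dag, x, y), klass, dag.dag_id))
    return out


def _orient(dag: ProteinCodingUnitDAG, x: str, y: str, klass: str) -> tuple[str, str]:
    """Put the node the conditioning set is 'about' first.

    For local-style conditions C relates to one endpoint (pa(s) for a->s,
    ch(a) for a->p, the first protein's splices for p-p); null-model
    benchmarks keep x with C and randomize y, so x must be that endpoint.
    """
    if klass == "a->s":
        return (x, y) if dag.layer(x) == "s" else (y, x)
    if klass == "a->p":
        return (x, y) if dag.layer(x) == "a" else (y, x)
    return (x, y) if x < y else (y, x)
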