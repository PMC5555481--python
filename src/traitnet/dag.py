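"""Directed acyclic graph containers, equivalence classes, structure matrices.

A learned Bayesian network is held as a :class:`DAGStructure`: an ordered
node list, a set of directed arcs, and possibly undirected edges (the
output of constraint-based learning is in general a CPDAG, the partially
directed representative of a Markov equivalence class).  Helpers compute
the CPDAG of a DAG (v-structures plus Meek-rule closure), enumerate the
consistent extensions of a partially directed graph, and translate a DAG
into the strictly-lower-triangular structure matrix Λ used by the SEM: one
freely varying coefficient at (child row, parent column) per arc, zeros
elsewhere, with a trait reordering that makes the pattern triangular.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "DAGStructure",
    "StructureMatrix",
    "to_structure_matrix",
    "cpdag_of",
    "consistent_extensions",
    "representative_extension",
]

Edge = tuple[str, str]


@dataclass(frozen=True)
class DAGStructure:
    """Network structure over trait nodes; may contain undirected edges."""

    nodes: tuple[str, ...]
    directed_arcs: frozenset[Edge]
    undirected_edges: frozenset[frozenset]

    def __init__(self, nodes, directed_arcs=(), undirected_edges=()):
        object.__setattr__(self, "nodes", tuple(nodes))
        arcs = frozenset((str(a), str(b)) for a, b in directed_arcs)
        und = frozenset(frozenset(e) for e in undirected_edges)
        object.__setattr__(self, "directed_arcs", arcs)
        object.__setattr__(self, "undirected_edges", und)
        node_set = set(self.nodes)
        for a, b in arcs:
            if a == b:
                raise ValueError(f"self-loop on {a}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"arc ({a},{b}) references unknown node")
            if frozenset((a, b)) in und:
                raise ValueError(f"edge {a}-{b} both directed and undirected")
        for e in und:
            if len(e) != 2 or not e <= node_set:
                raise ValueError(f"bad undirected edge {set(e)}")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(arcs)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"directed part contains a cycle: {cycle}")

    @property
    def d(self) -> int:
        return len(self.nodes)

    @property
    def is_fully_directed(self) -> bool:
        return not self.undirected_edges

    def skeleton(self) -> frozenset[frozenset]:
        return frozenset(
            {frozenset((a, b)) for a, b in self.directed_arcs} | self.undirected_edges
        )

    def parents(self, node: str) -> set[str]:
        return {a for a, b in self.directed_arcs if b == node}

    def neighbors(self, node: str) -> set[str]:
        out = {b for a, b in self.directed_arcs if a == node}
        inn = self.parents(node)
        und = {next(iter(e - {node})) for e in self.undirected_edges if node in e}
        return out | inn | und

    def to_digraph(self) -> nx.DiGraph:
        if not self.is_fully_directed:
            raise ValueError("graph has undirected edges; extend it first")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed_arcs)
        return g

    def v_structures(self) -> set[tuple[str, str, str]]:
        """Colliders x→z←y with x, y non-adjacent, as sorted (x, y, z) triples."""
        skel = self.skeleton()
        out = set()
        for z in self.nodes:
            pa = sorted(self.parents(z))
            for x, y in itertools.combinations(pa, 2):
                if frozenset((x, y)) not in skel:
                    out.add((x, y, z))
        return out

    def __repr__(self) -> str:
        arcs = ", ".join(f"{a}->{b}" for a, b in sorted(self.directed_arcs))
        und = ", ".join("-".join(sorted(e)) for e in sorted(map(sorted, self.undirected_edges)))
        return f"DAGStructure([{arcs}]" + (f" + [{und}]" if und else "") + ")"


def _meek_closure(
    nodes: tuple[str, ...],
    directed: set[Edge],
    undirected: set[frozenset],
) -> tuple[set[Edge], set[frozenset]]:
    """Orient undirected edges by Meek's rules until a fixed point.

    R1: a→b, b−c, a,c non-adjacent            => b→c
    R2: a→b→c, a−c                            => a→c
    R3: a−b, a−c, a−d, c→b, d→b, c,d non-adj  => a→b
    R4: a−d, a−c, d→c (a,?) ... (standard R4 with c→b, a−b)
    Only orientations that neither create a cycle nor a new v-structure are
    admissible; Meek's rules guarantee this by construction.
    """
    directed = set(directed)
    undirected = set(undirected)

    def adjacent(x, y):
        return (
            (x, y) in directed
            or (y, x) in directed
            or frozenset((x, y)) in undirected
        )

    changed = True
    while changed:
        changed = False
        for e in list(undirected):
            if e not in undirected:
                continue
            x, y = tuple(e)
            for a, b in ((x, y), (y, x)):
                # R1
                if any(
                    (c, a) in directed and not adjacent(c, b)
                    for c in _other_nodes(nodes, a, b)
                ):
                    if _orient(a, b, directed, undirected):
                        changed = True
                    break
                # R2
                if any(
                    (a, c) in directed and (c, b) in directed
                    for c in _other_nodes(nodes, a, b)
                ):
                    if _orient(a, b, directed, undirected):
                        changed = True
                    break
                # R3
                cands = [
                    c
                    for c in _other_nodes(nodes, a, b)
                    if frozenset((a, c)) in undirected and (c, b) in directed
                ]
                if any(
                    not adjacent(c1, c2)
                    for c1, c2 in itertools.combinations(cands, 2)
                ):
                    if _orient(a, b, directed, undirected):
                        changed = True
                    break
                # R4
                if any(
                    frozenset((a, d)) in undirected
                    and any(
                        (d, c) in directed and (c, b) in directed
                        and not adjacent(d, b) and adjacent(a, c)
                        for c in _other_nodes(nodes, a, b, d)
                    )
                    for d in _other_nodes(nodes, a, b)
                ):
                    if _orient(a, b, directed, undirected):
                        changed = True
                    break
    return directed, undirected


def _other_nodes(nodes, *exclude):
    ex = set(exclude)
    return [n for n in nodes if n not in ex]


def _creates_cycle(a: str, b: str, directed: set[Edge]) -> bool:
    """Would adding a→b close a directed cycle (i.e. is there a path b→a)?"""
    children: dict[str, list[str]] = {}
    for p, c in directed:
        children.setdefault(p, []).append(c)
    stack, seen = [b], set()
    while stack:
        v = stack.pop()
        if v == a:
            return True
        if v in seen:
            continue
        seen.add(v)
        stack.extend(children.get(v, ()))
    return False


def _orient(a: str, b: str, directed: set[Edge], undirected: set[frozenset]) -> bool:
    """Orient a−b as a→b unless that would close a directed cycle.

    On a consistent CPDAG Meek's rules never create cycles, but orientations
    derived from noisy independence tests can conflict; the guard leaves the
    edge undirected in that case.
    """
    if _creates_cycle(a, b, directed):
        return False
    undirected.discard(frozenset((a, b)))
    directed.add((a, b))
    return True


def cpdag_of(dag: DAGStructure) -> DAGStructure:
    """Markov-equivalence-class representative (CPDAG) of a fully directed DAG.

    Keeps the skeleton, orients exactly the v-structures, and closes under
    Meek's rules; the remaining edges are reversible and stay undirected.
    Two DAGs are Markov equivalent iff their CPDAGs are identical.
    """
    if not dag.is_fully_directed:
        raise ValueError("cpdag_of expects a fully directed DAG")
    directed: set[Edge] = set()
    undirected = {frozenset((a, b)) for a, b in dag.directed_arcs}
    for x, y, z in dag.v_structures():
        for p in (x, y):
            undirected.discard(frozenset((p, z)))
            directed.add((p, z))
    directed, undirected = _meek_closure(dag.nodes, directed, undirected)
    return DAGStructure(dag.nodes, directed, undirected)


def consistent_extensions(pdag: DAGStructure) -> list[DAGStructure]:
    """All DAGs extending a partially directed graph without changing its class.

    Enumerates orientations of the undirected edges and keeps those that are
    acyclic and introduce no v-structure absent from the input (nor lose
    one).  Intended for the small trait networks this package targets.
    """
    base_v = pdag.v_structures() if pdag.is_fully_directed else None
    und = [tuple(sorted(e)) for e in pdag.undirected_edges]
    und.sort()
    out = []
    for bits in itertools.product((0, 1), repeat=len(und)):
        arcs = set(pdag.directed_arcs)
        for (a, b), bit in zip(und, bits):
            arcs.add((a, b) if bit == 0 else (b, a))
        try:
            cand = DAGStructure(pdag.nodes, arcs)
        except ValueError:
            continue
        # keep the equivalence class fixed: same v-structures as the input's
        # directed core extended with no new colliders among former undirected
        if base_v is None:
            ref = pdag.v_structures()
            if cand.v_structures() != ref:
                continue
        out.append(cand)
    return out


def representative_extension(pdag: DAGStructure) -> DAGStructure:
    """Deterministic class representative: the consistent extension whose
    sorted arc list is lexicographically first under canonical node order."""
    if pdag.is_fully_directed:
        return pdag
    exts = consistent_extensions(pdag)
    if not exts:
        raise ValueError("partially directed graph admits no consistent extension")
    return min(exts, key=lambda g: tuple(sorted(g.directed_arcs)))


@dataclass
class StructureMatrix:
    """Pattern of the SEM structure matrix Λ: free vs structurally-zero entries.

    ``pattern[i, j]`` is True when trait j (parent) has a freely varying
    coefficient into trait i (child), indices in the original trait order.
    ``node_order`` is a permutation of the traits under which the pattern
    is strictly lower triangular (a topological order of the DAG).
    """

    pattern: np.ndarray
    trait_names: list[str]
    node_order: list[str] = field(default_factory=list)

    @property
    def d(self) -> int:
        return self.pattern.shape[0]

    @property
    def n_connections(self) -> int:
        return int(self.pattern.sum())

    def permuted_pattern(self) -> np.ndarray:
        idx = [self.trait_names.index(t) for t in self.node_order]
        return self.pattern[np.ix_(idx, idx)]

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            np.where(self.pattern, "free", ""),
            index=self.trait_names,
            columns=self.trait_names,
        )
        df.to_csv(path)


def to_structure_matrix(dag: DAGStructure) -> StructureMatrix:
    """Translate a learned network into the SEM structure-matrix pattern.

    Each arc parent→child becomes a free coefficient at (child row, parent
    column); a topological sort supplies the trait order under which the
    pattern is strictly lower triangular.  A partially directed input is
    first replaced by its deterministic class representative (any member of
    the class yields the same fit metrics).
    """
    dag = representative_extension(dag)
    g = dag.to_digraph()
    order = list(nx.lexicographical_topological_sort(g))
    names = list(dag.nodes)
    d = len(names)
    pattern = np.zeros((d, d), dtype=bool)
    for parent, child in dag.directed_arcs:
        pattern[names.index(child), names.index(parent)] = True
    sm = StructureMatrix(pattern=pattern, trait_names=names, node_order=order)
    perm = sm.permuted_pattern()
    assert not np.any(np.triu(perm)), "topological order failed to triangularize"
    return sm
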