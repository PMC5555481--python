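"""Structure learning: Grow-Shrink, tabu search, and bootstrap averaging.

The constraint-based learner (Grow-Shrink) estimates each node's Markov
blanket by a grow phase (add variables dependent on the target given the
current blanket) and a shrink phase (remove variables independent given
the rest), applies an AND-symmetry correction, resolves blankets to direct
neighbors by testing against all subsets of the smaller blanket, orients
v-structures from the recorded separating sets, and closes under Meek's
orientation rules; the result may retain undirected (reversible) edges.

The score-based learner (tabu search) walks the DAG space by single-arc
additions, deletions and reversals, always taking the best admissible move
(moves undoing a recent change are tabu, unless they beat the best score
seen — aspiration), and returns the highest-scoring DAG visited.

Bootstrap averaging resamples genotypes with replacement, relearns the
structure per replicate, and summarizes each unordered pair by its
*strength* (fraction of replicate networks containing the edge in either
direction) and each orientation by its *direction fraction*.  The
significance threshold on strengths is estimated from their empirical
distribution: noise edges have strength near 0 and real edges near 1, so
the ideal strength CDF is flat at some level c on [0, 1); the L1-closest
such level to the empirical CDF gives c*, and edges stronger than the
c*-quantile are kept.  The averaged network orients kept edges by majority
direction (ties toward the earlier node in canonical trait order) and
breaks any resulting cycle by dropping its weakest arc.
"""

from __future__ import annotations

import itertools
import logging
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from traitnet.citest import CITestConfig, ci_test
from traitnet.dag import DAGStructure, _creates_cycle, _meek_closure
from traitnet.scores import BGeHyperParams, ScoreCache

__all__ = [
    "grow_shrink",
    "tabu_search",
    "bootstrap_average",
    "ArcStrengths",
    "make_learner",
    "LEARNER_SETTINGS",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Grow-Shrink
# --------------------------------------------------------------------------

def _dependent(data, x, y, Z, config) -> bool:
    return ci_test(data, x, y, Z, config).p_value <= config.alpha


def _markov_blanket(data, target, nodes, config) -> list[int]:
    mb: list[int] = []
    changed = True
    while changed:  # grow
        changed = False
        for x in nodes:
            if x == target or x in mb:
                continue
            if _dependent(data, x, target, mb, config):
                mb.append(x)
                changed = True
    for x in list(mb):  # shrink
        rest = [z for z in mb if z != x]
        if not _dependent(data, x, target, rest, config):
            mb.remove(x)
    return mb


def grow_shrink(
    data: np.ndarray,
    config: CITestConfig | None = None,
    nodes: list[str] | None = None,
) -> DAGStructure:
    """Constraint-based structure learning; may return undirected edges."""
    config = config or CITestConfig()
    data = np.asarray(data, dtype=float)
    n, d = data.shape
    if n <= d + 2:
        raise ValueError(f"need n > d + 2; got n={n}, d={d}")
    names = list(nodes) if nodes is not None else [f"V{k+1}" for k in range(d)]
    idx = list(range(d))

    mb = {t: _markov_blanket(data, t, idx, config) for t in idx}
    # AND-symmetry correction on blankets
    for t in idx:
        mb[t] = [x for x in mb[t] if t in mb[x]]

    # blanket -> direct neighbors, recording separating sets
    sepset: dict[frozenset, tuple[int, ...]] = {}
    adjacent: set[frozenset] = set()
    for x, y in itertools.combinations(idx, 2):
        if y not in mb[x]:
            sepset[frozenset((x, y))] = tuple(z for z in mb[x] if z != y)
            continue
        base_x = [z for z in mb[x] if z != y]
        base_y = [z for z in mb[y] if z != x]
        base = base_x if len(base_x) <= len(base_y) else base_y
        separated = False
        for r in range(len(base) + 1):
            for S in itertools.combinations(base, r):
                if len(S) > n - 3:
                    continue
                if not _dependent(data, x, y, list(S), config):
                    sepset[frozenset((x, y))] = S
                    separated = True
                    break
            if separated:
                break
        if not separated:
            adjacent.add(frozenset((x, y)))

    # v-structures: x -> z <- y when z is outside the separating set of (x, y)
    directed: set[tuple[int, int]] = set()
    undirected = set(adjacent)
    for x, y in sorted(
        (tuple(sorted(p)) for p in sepset), key=lambda p: (p[0], p[1])
    ):
        common = [
            z
            for z in idx
            if frozenset((x, z)) in adjacent and frozenset((y, z)) in adjacent
        ]
        for z in common:
            if z in sepset[frozenset((x, y))]:
                continue
            if (z, x) in directed or (z, y) in directed:
                continue  # conflicting collider claim; keep earlier orientation
            for p in (x, y):
                if (p, z) not in directed and _creates_cycle(p, z, directed):
                    continue  # noisy tests produced contradictory colliders
                undirected.discard(frozenset((p, z)))
                directed.add((p, z))

    name_directed = {(names[a], names[b]) for a, b in directed}
    name_und = {frozenset((names[a], names[b])) for e in undirected for a, b in [tuple(e)]}
    name_directed, name_und = _meek_closure(tuple(names), name_directed, name_und)
    return DAGStructure(names, name_directed, name_und)


# --------------------------------------------------------------------------
# Tabu search
# --------------------------------------------------------------------------

def tabu_search(
    data: np.ndarray,
    score: str = "bic",
    tabu_length: int = 10,
    max_iter: int = 200,
    seed: int = 0,
    nodes: list[str] | None = None,
    bge: BGeHyperParams | None = None,
    cache: ScoreCache | None = None,
) -> DAGStructure:
    """Score-based search over DAGs; deterministic given data and settings.

    Starts from the empty graph; at every step applies the best
    non-tabu single-arc move (add/delete/reverse), allowing score-decreasing
    moves to escape local optima, and stops after ``tabu_length`` consecutive
    non-improving steps or ``max_iter`` steps.  Returns the best DAG visited.
    """
    data = np.asarray(data, dtype=float)
    n, d = data.shape
    names = list(nodes) if nodes is not None else [f"V{k+1}" for k in range(d)]
    cache = cache or ScoreCache(data, score=score, bge=bge)

    parents: list[frozenset] = [frozenset() for _ in range(d)]

    def creates_cycle(a: int, b: int, parent_sets) -> bool:
        # does adding a -> b close a directed path b ~> a ?
        stack, seen = [a], set()
        while stack:
            v = stack.pop()
            if v == b:
                return True
            if v in seen:
                continue
            seen.add(v)
            stack.extend(parent_sets[v])
        return False

    current = cache.total(parents)
    best = current
    best_parents = list(parents)
    tabu: deque[tuple] = deque(maxlen=max(1, tabu_length))
    stall = 0

    for _ in range(max_iter):
        moves = []  # (delta, order-key, move)
        for a, b in itertools.permutations(range(d), 2):
            if a in parents[b]:
                # delete a -> b
                delta = cache.local(b, parents[b] - {a}) - cache.local(b, parents[b])
                moves.append((delta, ("del", a, b)))
                # reverse a -> b
                if not creates_cycle(b, a, _without(parents, a, b)):
                    delta_r = (
                        cache.local(b, parents[b] - {a})
                        - cache.local(b, parents[b])
                        + cache.local(a, parents[a] | {b})
                        - cache.local(a, parents[a])
                    )
                    moves.append((delta_r, ("rev", a, b)))
            elif b not in parents[a] and not creates_cycle(a, b, parents):
                delta = cache.local(b, parents[b] | {a}) - cache.local(b, parents[b])
                moves.append((delta, ("add", a, b)))
        if not moves:
            break
        moves.sort(key=lambda m: (-m[0], m[1]))
        applied = False
        for delta, move in moves:
            if move in tabu and current + delta <= best + 1e-12:
                continue  # tabu, and aspiration does not apply
            kind, a, b = move
            if kind == "add":
                parents[b] = parents[b] | {a}
                tabu.append(("del", a, b))
            elif kind == "del":
                parents[b] = parents[b] - {a}
                tabu.append(("add", a, b))
            else:
                parents[b] = parents[b] - {a}
                parents[a] = parents[a] | {b}
                tabu.append(("rev", b, a))
            current += delta
            applied = True
            break
        if not applied:
            break
        if current > best + 1e-12:
            best = current
            best_parents = list(parents)
            stall = 0
        else:
            stall += 1
            if stall >= max(1, tabu_length):
                break

    arcs = {
        (names[p], names[child])
        for child, pset in enumerate(best_parents)
        for p in pset
    }
    return DAGStructure(names, arcs)


def _without(parents: list[frozenset], a: int, b: int) -> list[frozenset]:
    out = list(parents)
    out[b] = out[b] - {a}
    return out


# --------------------------------------------------------------------------
# Bootstrap averaging
# --------------------------------------------------------------------------

@dataclass
class ArcStrengths:
    """Bootstrap support for every candidate edge.

    ``strength[{a, b}]`` is the fraction of replicate networks containing
    the edge in either direction; ``direction_fraction[(a, b)]`` the share
    of those supporting the orientation a→b (0.5 each way for an
    undirected occurrence).
    """

    nodes: tuple[str, ...]
    strength: dict = field(default_factory=dict)
    direction_fraction: dict = field(default_factory=dict)
    threshold: float = 0.0
    B: int = 0

    def pair_strength(self, a: str, b: str) -> float:
        return self.strength.get(frozenset((a, b)), 0.0)


def estimate_strength_threshold(strengths: np.ndarray) -> float:
    """L1-optimal significance cutoff on bootstrap arc strengths.

    Fits the flat ideal CDF level c on [0, 1) minimizing the L1 distance to
    the empirical strength CDF (the minimizer is the length-weighted median
    of the empirical CDF levels) and returns the c-quantile of the
    strengths; edges *strictly above* it are significant.
    """
    s = np.sort(np.asarray(strengths, dtype=float))
    if s.size == 0:
        return 1.0
    # empirical CDF of strengths is a step function on [0, 1]
    xs = np.concatenate(([0.0], np.unique(s), [1.0]))
    levels, weights = [], []
    for lo, hi in zip(xs[:-1], xs[1:]):
        if hi <= lo:
            continue
        levels.append(np.searchsorted(s, lo, side="right") / s.size)
        weights.append(hi - lo)
    levels = np.asarray(levels)
    weights = np.asarray(weights)
    order = np.argsort(levels)
    cum = np.cumsum(weights[order])
    c_star = levels[order][np.searchsorted(cum, cum[-1] / 2.0)]
    return float(np.quantile(s, c_star))


def bootstrap_average(
    data: np.ndarray,
    learner,
    B: int = 500,
    seed: int = 0,
    nodes: list[str] | None = None,
) -> tuple[ArcStrengths, DAGStructure]:
    """Bootstrap model averaging of a structure learner.

    ``learner`` is a callable ``learner(data, seed) -> DAGStructure``; rows
    (genotypes) are resampled jointly across all columns.  Replicates where
    the learner fails are skipped and counted; more than 10% failures abort.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    data = np.asarray(data, dtype=float)
    n, d = data.shape
    names = list(nodes) if nodes is not None else [f"V{k+1}" for k in range(d)]
    master = np.random.SeedSequence(seed)
    boot_ss, learn_ss = master.spawn(2)
    rng = np.random.default_rng(boot_ss)
    learner_seeds = learn_ss.generate_state(B)

    edge_counts: dict[frozenset, float] = {}
    dir_counts: dict[tuple[str, str], float] = {}
    failures = 0
    for b in range(B):
        rows = rng.integers(0, n, size=n)
        try:
            g = learner(data[rows], int(learner_seeds[b] % (2**31)))
        except Exception as exc:  # pragma: no cover - defensive
            failures += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            if failures > 0.1 * B:
                raise RuntimeError(
                    f"{failures} of {b + 1} bootstrap replicates failed (>10%)"
                ) from exc
            continue
        for a, c in g.directed_arcs:
            edge_counts[frozenset((a, c))] = edge_counts.get(frozenset((a, c)), 0) + 1
            dir_counts[(a, c)] = dir_counts.get((a, c), 0) + 1.0
        for e in g.undirected_edges:
            a, c = tuple(e)
            edge_counts[e] = edge_counts.get(e, 0) + 1
            dir_counts[(a, c)] = dir_counts.get((a, c), 0) + 0.5
            dir_counts[(c, a)] = dir_counts.get((c, a), 0) + 0.5
    used = B - failures
    if used == 0:
        raise RuntimeError("all bootstrap replicates failed")

    strength = {}
    direction = {}
    for a, c in itertools.combinations(names, 2):
        e = frozenset((a, c))
        cnt = edge_counts.get(e, 0)
        strength[e] = cnt / used
        if cnt:
            direction[(a, c)] = dir_counts.get((a, c), 0.0) / cnt
            direction[(c, a)] = dir_counts.get((c, a), 0.0) / cnt
        else:
            direction[(a, c)] = direction[(c, a)] = 0.0

    svals = np.array([strength[frozenset(p)] for p in itertools.combinations(names, 2)])
    q = estimate_strength_threshold(svals)
    kept = [
        tuple(sorted(frozenset(p)))
        for p in itertools.combinations(names, 2)
        if strength[frozenset(p)] > q or strength[frozenset(p)] >= 1.0
    ]
    threshold = min((strength[frozenset(p)] for p in kept), default=1.0)

    # orient kept edges by majority direction; canonical-order tie-break
    order = {nm: i for i, nm in enumerate(names)}
    arcs: set[tuple[str, str]] = set()
    for a, c in kept:
        fa = direction[(a, c)]
        fc = direction[(c, a)]
        if fa > fc or (fa == fc and order[a] < order[c]):
            arcs.add((a, c))
        else:
            arcs.add((c, a))

    # cycles from combining majority directions: drop the weakest arc per cycle
    g = nx.DiGraph()
    g.add_nodes_from(names)
    g.add_edges_from(arcs)
    while not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        weakest = min(cycle, key=lambda e: strength[frozenset(e[:2])])
        logger.warning("breaking averaging cycle at arc %s", weakest[:2])
        g.remove_edge(*weakest[:2])
        arcs.discard(tuple(weakest[:2]))

    avg = DAGStructure(names, arcs)
    stats = ArcStrengths(
        nodes=tuple(names),
        strength=strength,
        direction_fraction=direction,
        threshold=threshold,
        B=used,
    )
    return stats, avg


# --------------------------------------------------------------------------
# The six learning settings
# --------------------------------------------------------------------------

LEARNER_SETTINGS = {
    "gs1": ("gs", "pearson_exact_t"),
    "gs2": ("gs", "pearson_permutation"),
    "gs3": ("gs", "mutual_information_chi2"),
    "gs4": ("gs", "mutual_information_permutation"),
    "tabu1": ("tabu", "bic"),
    "tabu2": ("tabu", "bge"),
}


def make_learner(
    setting: str,
    alpha: float = 0.01,
    n_permutations: int = 450,
    tabu_length: int = 10,
    max_iter: int = 200,
    nodes: list[str] | None = None,
):
    """Build a ``learner(data, seed) -> DAGStructure`` for one of the six
    settings: gs1–gs4 (Grow-Shrink with the four independence tests) or
    tabu1/tabu2 (tabu search with BIC/BGe)."""
    if setting not in LEARNER_SETTINGS:
        raise ValueError(f"unknown setting {setting!r}; choose from {sorted(LEARNER_SETTINGS)}")
    kind, variant = LEARNER_SETTINGS[setting]
    if kind == "gs":

        def learner(data, seed=0):
            cfg = CITestConfig(
                statistic=variant,
                alpha=alpha,
                n_permutations=n_permutations,
                seed=seed,
            )
            return grow_shrink(data, cfg, nodes=nodes)

    else:

        def learner(data, seed=0):
            return tabu_search(
                data,
                score=variant,
                tabu_length=tabu_length,
                max_iter=max_iter,
                seed=seed,
                nodes=nodes,
            )

    return learner
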