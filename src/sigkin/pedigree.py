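"""Kinship directed acyclic graphs (kDAGs) and relatedness coefficients.

A genealogy is represented as a directed acyclic graph with one node per
individual and a directed edge from each parent to each of its children.
Two relatedness computations are provided:

* :func:`path_relatedness` — the path-additive rule used throughout the
  pipeline: every kinship-informative path (a chain that ascends zero or more
  parent edges and then descends zero or more child edges, never revisiting a
  node) of length ``phi`` contributes ``k**phi``, with ``k = 0.5`` the
  parent–child coefficient, and contributions of distinct paths add.
* :func:`wright_relatedness` — the classical numerator-relationship value from
  the recursive kinship-matrix construction, kept as an independent oracle.
  The two agree exactly whenever common ancestors are non-inbred; the
  path-additive rule deliberately omits the (1 + F) inbred-ancestor
  correction and is the pipeline default.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Optional

import networkx as nx

from .studbook_io import FEMALE, MALE, UNKNOWN, StudbookTable

#: default parent-child coefficient of relatedness
K_PARENT_CHILD = 0.5
#: default cap on kinship path length (ascent + descent edges)
DEFAULT_MAX_LEN = 8


@dataclass(frozen=True)
class KinPath:
    """A single kinship-informative path between two individuals.

    ``nodes`` runs from the first individual up to the apex (most ancestral
    node on the path) and back down to the second; ``up``/``down`` count the
    ascending parent edges and descending child edges.  Edges are
    role-labelled: the dam edge and the sire edge are distinct paths even
    when one individual fills both roles (selfing), so ``ascent`` is the sex
    string of the ascending steps read focal -> apex.
    """

    nodes: tuple[str, ...]
    up: int
    down: int
    ascent: str = ""

    @property
    def length(self) -> int:
        return self.up + self.down


def build_kdag(table: StudbookTable) -> nx.DiGraph:
    """Build and validate the kinship DAG from a cleaned studbook table.

    Nodes carry ``sex``, ``dam`` and ``sire`` attributes; edges run
    parent -> child.  Parents referenced but excluded from analysis are added
    as ghost nodes.  A cycle or a sex-inconsistent parent assignment is fatal.
    """
    graph = nx.DiGraph()
    for rid, rec in table.records.items():
        graph.add_node(rid, sex=rec.sex, dam=rec.dam_id, sire=rec.sire_id,
                       birth=rec.birth_month, death=rec.death_month)
    for rid, rec in table.records.items():
        selfed = rec.dam_id is not None and rec.dam_id == rec.sire_id
        for parent, role, sex in ((rec.dam_id, "dam", FEMALE),
                                  (rec.sire_id, "sire", MALE)):
            if parent is None:
                continue
            if selfed:
                # a selfing hermaphrodite fills both roles; no sex constraint
                if parent not in graph:
                    ghost = table.ghosts.get(parent)
                    graph.add_node(parent, sex=ghost.sex if ghost else UNKNOWN,
                                   dam=None, sire=None,
                                   birth=ghost.birth_month if ghost else None,
                                   death=ghost.death_month if ghost else None)
                graph.add_edge(parent, rid)
                continue
            if parent not in graph:
                ghost = table.ghosts.get(parent)
                graph.add_node(parent, sex=ghost.sex if ghost else sex,
                               dam=None, sire=None,
                               birth=ghost.birth_month if ghost else None,
                               death=ghost.death_month if ghost else None)
            psex = graph.nodes[parent]["sex"]
            if psex == UNKNOWN:
                graph.nodes[parent]["sex"] = sex
            elif psex != sex:
                raise ValueError(
                    f"{role} {parent!r} of {rid!r} is recorded as sex {psex!r}")
            graph.add_edge(parent, rid)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"pedigree contains a cycle: {cycle}")
    return graph


def parents_of(graph: nx.DiGraph, node: str) -> tuple[Optional[str], Optional[str]]:
    """(dam, sire) of a node; either may be None."""
    attrs = graph.nodes[node]
    return attrs.get("dam"), attrs.get("sire")


def founders(graph: nx.DiGraph) -> set[str]:
    return {n for n in graph if graph.in_degree(n) == 0}


def _descend(graph: nx.DiGraph, start: str, target: Optional[str], budget: int,
             blocked: frozenset[str], path: list[str],
             out: list[tuple[tuple[str, ...], int]]) -> None:
    """Enumerate role-labelled descending chains from ``start``.

    Each step to a child counts once per parental role ``start`` fills for it
    (dam and sire edges are parallel when selfed).  ``target=None`` collects
    every descendant chain within budget instead of chains ending at a target.
    """
    if target is None:
        if len(path) > 1:
            out.append((tuple(path), len(path) - 1))
    elif start == target:
        out.append((tuple(path), len(path) - 1))
        return
    if budget == 0:
        return
    for child in graph.successors(start):
        if child in blocked or child in path:
            continue
        dam, sire = parents_of(graph, child)
        n_roles = (dam == start) + (sire == start)
        for _ in range(n_roles):
            path.append(child)
            _descend(graph, child, target, budget - 1, blocked, path, out)
            path.pop()


def kinship_paths(graph: nx.DiGraph, a: str, b: str,
                  max_len: int = DEFAULT_MAX_LEN) -> list[KinPath]:
    """All kinship-informative simple paths from ``a`` to ``b``.

    A path ascends zero or more parent edges from ``a`` and then descends zero
    or more child edges to ``b``; it never revisits a node and never descends
    then ascends.  ``a == b`` yields the empty set (self-relatedness is out of
    scope).
    """
    if a not in graph or b not in graph:
        raise KeyError(f"{a!r} or {b!r} not in pedigree")
    if a == b:
        return []
    paths: list[KinPath] = []

    # ascent steps are role-labelled: the dam branch ('F') and the sire
    # branch ('M') are distinct even when one individual fills both roles
    def _ascend(chain: list[str], ascent: str) -> None:
        apex = chain[-1]
        up = len(chain) - 1
        down_paths: list[tuple[tuple[str, ...], int]] = []
        _descend(graph, apex, b, max_len - up,
                 frozenset(chain[:-1]), [apex], down_paths)
        for nodes, down in down_paths:
            if down == 0 and up == 0:
                continue
            paths.append(KinPath(tuple(chain[:-1]) + nodes, up, down, ascent))
        if up < max_len:
            dam, sire = parents_of(graph, apex)
            for parent, label in ((dam, "F"), (sire, "M")):
                if parent is not None and parent not in chain:
                    _ascend(chain + [parent], ascent + label)

    _ascend([a], "")
    return paths


def path_relatedness(graph: nx.DiGraph, a: str, b: str,
                     max_len: int = DEFAULT_MAX_LEN,
                     k: float = K_PARENT_CHILD) -> float:
    """Path-additive coefficient of relatedness: sum of k**length over paths."""
    if not 0.0 < k <= 1.0:
        raise ValueError(f"k must lie in (0, 1], got {k}")
    return sum(k ** p.length for p in kinship_paths(graph, a, b, max_len))


def ancestor_chains(graph: nx.DiGraph, a: str,
                    max_up: int) -> list[tuple[str, int, frozenset[str]]]:
    """Role-labelled simple ascent chains from ``a``.

    Each entry is ``(terminal, length, interior)`` where ``interior`` holds
    every chain node except the terminal (so the trivial chain is
    ``(a, 0, {})``).  The dam and sire branches are enumerated separately, so
    a selfed step yields two chains with identical node sets.
    """
    out: list[tuple[str, int, frozenset[str]]] = []

    def walk(node: str, length: int, interior: frozenset[str]) -> None:
        out.append((node, length, interior))
        if length < max_up:
            dam, sire = parents_of(graph, node)
            for p in (dam, sire):
                if p is not None and p not in interior and p != node:
                    walk(p, length + 1, interior | {node})

    walk(a, 0, frozenset())
    return out


def _chain_pair_relatedness(chains_a, chains_b, max_len: int, k: float) -> float:
    """Sum of k**length over simple ascend-then-descend paths.

    A kinship path a -> X -> b corresponds to one ascent chain of ``a`` and
    one of ``b`` sharing the terminal X with disjoint interiors; this is the
    classical path-counting evaluation of the additive rule and agrees
    exactly with enumerating paths directly.
    """
    by_term: dict[str, list[tuple[int, frozenset[str]]]] = {}
    for term, length, interior in chains_b:
        by_term.setdefault(term, []).append((length, interior))
    r = 0.0
    for term, la, ia in chains_a:
        for lb, ib in by_term.get(term, ()):
            total = la + lb
            if total == 0 or total > max_len:
                continue
            if ia & ib:
                continue
            r += k ** total
    return r


class RelatednessCache:
    """Memoized path-additive relatedness over one graph (symmetric in the pair).

    Uses the ancestor-chain join, which is equivalent to summing over
    enumerated kinship paths but does not traverse descendant subtrees.
    """

    def __init__(self, graph: nx.DiGraph, max_len: int = DEFAULT_MAX_LEN,
                 k: float = K_PARENT_CHILD):
        self.graph = graph
        self.max_len = max_len
        self.k = k
        self._cache: dict[tuple[str, str], float] = {}
        self._chains: dict[str, list[tuple[str, int, frozenset[str]]]] = {}

    def _chains_of(self, a: str) -> list[tuple[str, int, frozenset[str]]]:
        chains = self._chains.get(a)
        if chains is None:
            chains = ancestor_chains(self.graph, a, self.max_len)
            self._chains[a] = chains
        return chains

    def __call__(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        r = self._cache.get(key)
        if r is None:
            r = _chain_pair_relatedness(self._chains_of(key[0]),
                                        self._chains_of(key[1]),
                                        self.max_len, self.k)
            self._cache[key] = r
        return r


def _kinship_matrix_fn(graph: nx.DiGraph):
    """Recursive kinship coefficient phi(i, j) over the whole pedigree."""
    order = {n: i for i, n in enumerate(nx.topological_sort(graph))}

    @lru_cache(maxsize=None)
    def phi(i: str, j: str) -> float:
        if order[i] < order[j]:
            i, j = j, i
        dam, sire = parents_of(graph, i)
        pd = phi(dam, j) if dam is not None else 0.0
        ps = phi(sire, j) if sire is not None else 0.0
        if i == j:
            both = phi(dam, sire) if dam is not None and sire is not None else 0.0
            return 0.5 + 0.5 * both
        return 0.5 * (pd + ps)

    return phi


def wright_relatedness_fn(graph: nx.DiGraph):
    """Memoized pairwise numerator-relationship function over one pedigree."""
    phi = _kinship_matrix_fn(graph)
    return lambda a, b: 2.0 * phi(a, b)


def wright_relatedness(graph: nx.DiGraph, a: str, b: str) -> float:
    """Numerator relationship A(a, b) = 2 * phi(a, b) from the kinship matrix.

    The classical recursive construction; serves as the independent oracle for
    :func:`path_relatedness` on outbred pedigrees.
    """
    if a == b:
        raise ValueError("self-relatedness is out of scope")
    phi = _kinship_matrix_fn(graph)
    return 2.0 * phi(a, b)


def mean_relatedness(graph: nx.DiGraph, a: str) -> float:
    """Mean numerator relationship of ``a`` to every other individual (r_mean).

    The quantity whose dependence on entry order and documented-ancestor count
    motivates the standard-inheritance-graph reduction.
    """
    others = [n for n in graph if n != a]
    if not others:
        raise ValueError("r_mean undefined on a singleton pedigree")
    phi = _kinship_matrix_fn(graph)
    return sum(2.0 * phi(a, x) for x in others) / len(others)


def write_ped(graph: nx.DiGraph, path: str | Path) -> None:
    """Export as 4-column ped-like text: id, sire, dam, sex."""
    with open(path, "w", encoding="utf-8") as fh:
        for node in nx.topological_sort(graph):
            dam, sire = parents_of(graph, node)
            fh.write(f"{node}\t{sire or '0'}\t{dam or '0'}\t"
                     f"{graph.nodes[node]['sex']}\n")


def read_ped(path: str | Path) -> nx.DiGraph:
    graph = nx.DiGraph()
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rid, sire, dam, sex = line.split()
            rows.append((rid, None if sire == "0" else sire,
                         None if dam == "0" else dam, sex))
    for rid, sire, dam, sex in rows:
        graph.add_node(rid, sex=sex, dam=dam, sire=sire, birth=None, death=None)
    for rid, sire, dam, _ in rows:
        for parent in (dam, sire):
            if parent is not None:
                graph.add_edge(parent, rid)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("ped file encodes a cyclic pedigree")
    return graph
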