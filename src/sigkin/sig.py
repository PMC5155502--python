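"""Standard inheritance graphs (SIGs).

A SIG reduces the kinship sub-graph around a focal individual to a fixed set
of path classes.  Every kinship-informative path either only ascends
(ascendant, class I), ascends then descends (lateral, class II), or only
descends (descendant, class III).  A path class is keyed by the sex string of
its ascent (read focal -> ancestor, e.g. ``"FM"`` is the mother's father) and
its descent depth.  Regardless of inbreeding, a focal individual with fully
documented ancestors has exactly ``2**phi`` ascendant paths at degree
``phi`` — four grandparental paths even when the grandparents number two —
and each ascendant path terminates at exactly one individual of a
determinate sex, so ascendant classes hold exactly one member while lateral
and descendant classes hold any number of individuals of any sex.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .pedigree import _descend, parents_of


@dataclass(frozen=True, order=True)
class SIGClassKey:
    """A path class: ascent sex-string plus descent depth.

    class I  <=> ascent non-empty, depth 0 (an ancestor);
    class II <=> ascent non-empty, depth >= 1 (lateral kin);
    class III <=> empty ascent, depth >= 1 (a descendant).
    """

    ascent: str
    descent_depth: int

    def __post_init__(self):
        if self.ascent == "" and self.descent_depth == 0:
            raise ValueError("(ascent='', depth=0) is the focal itself")
        if any(c not in "MF" for c in self.ascent):
            raise ValueError(f"ascent must be over {{M,F}}: {self.ascent!r}")

    @property
    def sig_class(self) -> str:
        if self.descent_depth == 0:
            return "I"
        return "III" if self.ascent == "" else "II"

    @property
    def path_length(self) -> int:
        return len(self.ascent) + self.descent_depth

    def label(self) -> str:
        """Stable column label, e.g. 'F', 'MF', 'M1', 'D2' (pure descent)."""
        if self.ascent == "":
            return f"D{self.descent_depth}"
        if self.descent_depth == 0:
            return self.ascent
        return f"{self.ascent}{self.descent_depth}"


def all_class_keys(diameter: int, descent_cap: Optional[int] = None) -> list[SIGClassKey]:
    """Every class key of a SIG of the given diameter, in a stable order."""
    cap = diameter if descent_cap is None else descent_cap
    ascents = [""]
    frontier = [""]
    for _ in range(diameter):
        frontier = [a + s for a in frontier for s in "FM"]
        ascents.extend(frontier)
    keys = []
    for a in ascents:
        for b in range(0, cap + 1):
            if a == "" and b == 0:
                continue
            keys.append(SIGClassKey(a, b))
    return sorted(keys, key=lambda k: (len(k.ascent), k.ascent, k.descent_depth))


@dataclass
class SIG:
    """Per-focal reduced kinship structure: class key -> member individuals."""

    focal_id: str
    diameter: int
    descent_cap: int
    members: dict[SIGClassKey, set[str]] = field(default_factory=dict)

    def class_members(self, sig_class: str) -> dict[SIGClassKey, set[str]]:
        return {k: v for k, v in self.members.items() if k.sig_class == sig_class}

    def to_json_obj(self) -> dict:
        return {
            "focal": self.focal_id,
            "diameter": self.diameter,
            "descent_cap": self.descent_cap,
            "classes": [
                {"ascent": k.ascent, "descent_depth": k.descent_depth,
                 "members": sorted(v)}
                for k, v in sorted(self.members.items(),
                                   key=lambda kv: (len(kv[0].ascent),
                                                   kv[0].ascent,
                                                   kv[0].descent_depth))
            ],
        }


def ascendant_paths(graph: nx.DiGraph, focal: str,
                    degree: int) -> list[tuple[str, str]]:
    """All documented ascendant paths of exactly ``degree`` steps.

    Returns one ``(sex_string, terminal_id)`` entry per documented sex string
    in {M,F}^degree.  Distinct sex strings may share a terminal in inbred
    pedigrees; missing parents simply yield absent entries.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    out: list[tuple[str, str]] = []

    def walk(node: str, ascent: str) -> None:
        if len(ascent) == degree:
            out.append((ascent, node))
            return
        dam, sire = parents_of(graph, node)
        if dam is not None:
            walk(dam, ascent + "F")
        if sire is not None:
            walk(sire, ascent + "M")

    walk(focal, "")
    return out


def has_complete_sig(graph: nx.DiGraph, focal: str, d: int) -> bool:
    """True iff every ascendant path up to degree ``d`` is documented.

    Equivalent to ``ascendant_paths`` returning all ``2**phi`` entries for
    every ``phi <= d`` (completeness at depth d implies all prefixes).
    """
    if d not in (1, 2, 3):
        raise ValueError("SIG diameter must be 1, 2 or 3")
    return len(ascendant_paths(graph, focal, d)) == 2 ** d


def _ascent_chain(graph: nx.DiGraph, focal: str, ascent: str) -> Optional[list[str]]:
    """Node chain focal -> ... -> terminus for one sex string, if documented."""
    chain = [focal]
    for step in ascent:
        dam, sire = parents_of(graph, chain[-1])
        nxt = dam if step == "F" else sire
        if nxt is None:
            return None
        chain.append(nxt)
    return chain


def _descendant_chains(graph: nx.DiGraph, start: str, cap: int,
                       blocked: frozenset[str]) -> list[tuple[tuple[str, ...], int]]:
    out: list[tuple[tuple[str, ...], int]] = []
    _descend(graph, start, None, cap, blocked, [start], out)
    return out


def relative_path_keys(graph: nx.DiGraph, focal: str, other: str,
                       d: int, descent_cap: Optional[int] = None) -> Counter:
    """Multiset of class keys over all focal->other paths within the SIG bounds.

    The multiplicity of a key is the number of distinct kinship paths mapped
    to it, so ``sum(k**key.path_length * count)`` recovers the path-additive
    relatedness restricted to ascent <= d and descent <= descent_cap.
    """
    cap = d if descent_cap is None else descent_cap
    keys: Counter = Counter()
    if focal == other:
        return keys

    def walk(chain: list[str], ascent: str) -> None:
        apex = chain[-1]
        if ascent and apex == other:
            keys[SIGClassKey(ascent, 0)] += 1
        down: list[tuple[tuple[str, ...], int]] = []
        _descend(graph, apex, other, cap, frozenset(chain[:-1]), [apex], down)
        for _, depth in down:
            if depth >= 1:
                keys[SIGClassKey(ascent, depth)] += 1
        if len(ascent) < d:
            dam, sire = parents_of(graph, apex)
            for parent, label in ((dam, "F"), (sire, "M")):
                if parent is not None and parent not in chain:
                    walk(chain + [parent], ascent + label)

    walk([focal], "")
    return keys


def classify_relative(graph: nx.DiGraph, focal: str, other: str,
                      d: int, descent_cap: Optional[int] = None) -> set[SIGClassKey]:
    """Class keys under which ``other`` appears in the focal's SIG.

    Empty set <=> structurally unrelated within the SIG diameter.
    """
    return set(relative_path_keys(graph, focal, other, d, descent_cap))


def build_sig(graph: nx.DiGraph, focal: str, d: int,
              descent_cap: Optional[int] = None) -> SIG:
    """Construct the focal's SIG of diameter ``d``.

    Class I holds each ascendant-path terminus; class II the descendants (to
    ``descent_cap``) of each class-I ancestor reached without re-entering the
    ascent chain or the focal; class III the focal's own descendants.  The
    focal never appears as a member; one individual may occupy several keys.
    """
    cap = d if descent_cap is None else descent_cap
    if not has_complete_sig(graph, focal, d):
        raise ValueError(
            f"{focal!r} lacks a complete degree-{d} ascendant set; "
            "screen candidates with has_complete_sig first")
    members: dict[SIGClassKey, set[str]] = {}

    def add(key: SIGClassKey, member: str) -> None:
        if member != focal:
            members.setdefault(key, set()).add(member)

    for phi in range(1, d + 1):
        for ascent, terminal in ascendant_paths(graph, focal, phi):
            add(SIGClassKey(ascent, 0), terminal)
            chain = _ascent_chain(graph, focal, ascent)
            assert chain is not None
            for nodes, depth in _descendant_chains(
                    graph, terminal, cap, frozenset(chain[:-1])):
                add(SIGClassKey(ascent, depth), nodes[-1])
    for nodes, depth in _descendant_chains(graph, focal, cap, frozenset()):
        add(SIGClassKey("", depth), nodes[-1])
    return SIG(focal_id=focal, diameter=d, descent_cap=cap, members=members)
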