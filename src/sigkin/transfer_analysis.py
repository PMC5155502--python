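"""Co-transfer analysis: littermates versus pseudo-siblings.

Same-sex siblings born into a single-paternity litter ('littermates') share
identical kinship structures and ages, so comparing individuals co-moved to
a new institution with littermates against individuals co-moved with
unrelated age- and sex-matched animals ('pseudo-siblings') isolates the kin
component of the cohabitation effect on subsequent reproductive success.
Individuals that reproduced before their first transfer are excluded to
avoid bias against transferring proven breeders; stratified reproductive
success is compared with Kruskal-Wallis rank-sum tests, and two confound
checks (sibling number vs reproductive success, parent-offspring lifetime
reproductive success) probe heritable fecundity as an alternative
explanation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .covariates import DEFAULT_AGE_TOLERANCE, ReproductiveSuccess
from .pedigree import RelatednessCache, parents_of
from .studbook_io import WILD, StudbookTable


@dataclass
class CoTransferMember:
    individual_id: str
    n_littermates: int            # same-sex littermates co-transferred
    n_matched_nonsib: int         # unrelated same-sex age-matched co-transfers
    litter_size: int              # initial size of the member's own litter
    subsequent_rs: float


@dataclass
class CoTransferGroup:
    event_month: int
    origin: str
    destination: str
    member_ids: list[str]
    members: list[CoTransferMember] = field(default_factory=list)


def find_cotransfers(table: StudbookTable, graph: nx.DiGraph,
                     rs: Optional[ReproductiveSuccess] = None,
                     age_tolerance: int = DEFAULT_AGE_TOLERANCE,
                     rel: Optional[RelatednessCache] = None) -> list[CoTransferGroup]:
    """Groups of >= 2 individuals first-moved together between zoos.

    Only each individual's first transfer counts; arrivals from the wild are
    entries, not co-transfers.  Members with any offspring born before the
    event are excluded from the per-member statistics (the group is retained
    with its remaining analyzable members).  Littermates share dam, sire,
    birth month and sex; matched non-siblings are co-transferred same-sex
    individuals within the age tolerance and path-unrelated to the member.
    """
    rs = rs or ReproductiveSuccess(graph, table)
    rel = rel or rs.rel

    first: dict[str, tuple[int, str, str]] = {}
    for t in sorted(table.transfers, key=lambda t: t.event_month):
        if t.from_institution == WILD or t.to_institution == WILD:
            continue
        if t.individual_id not in first and t.individual_id in table.records:
            first[t.individual_id] = (t.event_month, t.from_institution,
                                      t.to_institution)

    grouped: dict[tuple[int, str, str], list[str]] = {}
    for rid, key in first.items():
        grouped.setdefault(key, []).append(rid)

    groups: list[CoTransferGroup] = []
    for (month, origin, dest), ids in sorted(grouped.items()):
        if len(ids) < 2:
            continue
        group = CoTransferGroup(month, origin, dest, sorted(ids))
        for rid in group.member_ids:
            rec = table.records[rid]
            if rid in graph and any(
                    (b := table.record_or_ghost(c)) and b.birth_month is not None
                    and b.birth_month < month
                    for c in graph.successors(rid)):
                continue   # reproduced before first transfer
            if rec.birth_month is None:
                continue
            n_lit = n_pseudo = 0
            for other in group.member_ids:
                if other == rid:
                    continue
                orec = table.records[other]
                if orec.birth_month is None:
                    continue
                same_litter = (rec.dam_id is not None and rec.sire_id is not None
                               and orec.dam_id == rec.dam_id
                               and orec.sire_id == rec.sire_id
                               and orec.birth_month == rec.birth_month)
                if same_litter and orec.sex == rec.sex:
                    n_lit += 1
                elif (orec.sex == rec.sex
                      and abs(orec.birth_month - rec.birth_month) <= age_tolerance
                      and (rid not in graph or other not in graph
                           or rel(rid, other) == 0.0)):
                    n_pseudo += 1
            litter_size = 1
            if rec.dam_id is not None and rec.dam_id in graph:
                litter_size = sum(
                    1 for c in graph.successors(rec.dam_id)
                    if (crec := table.record_or_ghost(c)) is not None
                    and crec.birth_month == rec.birth_month
                    and crec.sire_id == rec.sire_id)
            end = rec.death_month if rec.death_month is not None else table.data_end
            subsequent = rs(rid, month, end) if rid in graph and month <= end else 0.0
            group.members.append(CoTransferMember(
                rid, n_lit, n_pseudo, litter_size, subsequent))
        groups.append(group)
    return groups


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis rank-sum H with tie correction; p from chi-squared.

    Identical values across all groups give (0, 1).
    """
    groups = [np.asarray(s, dtype=float) for s in samples if len(s) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    h = 12.0 / (n * (n + 1)) * sum(
        r.sum() ** 2 / len(r)
        for r in np.split(ranks, np.cumsum([len(g) for g in groups]))[:-1]
    ) - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    if tie_corr == 0.0:          # every observation identical
        return 0.0, 1.0
    h /= tie_corr
    df = len(groups) - 1
    return float(h), float(stats.chi2.sf(h, df))


def _strata(values: Sequence[int], rs_values: Sequence[float],
            bins: Optional[Sequence[int]]) -> dict[int, list[float]]:
    out: dict[int, list[float]] = {}
    for v, r in zip(values, rs_values):
        stratum = min(v, bins[-1]) if bins else v
        out.setdefault(stratum, []).append(r)
    return out


def littermate_vs_pseudo(groups: Sequence[CoTransferGroup],
                         bins: Optional[Sequence[int]] = (0, 1, 2, 3)) -> dict:
    """Kruskal-Wallis tests of subsequent r_III by co-transfer composition.

    Test (i) stratifies by the number of co-transferred same-sex littermates,
    test (ii) by the number of co-transferred matched non-siblings; a
    litter-size-stratified variant of (i) controls for initial litter size.
    Counts above ``bins[-1]`` pool into the top stratum; ``bins=None`` keeps
    raw counts.  A stratification with fewer than two strata is skipped with
    a notice.
    """
    members = [m for g in groups for m in g.members]
    report: dict = {"n_members": len(members), "n_groups": len(groups)}

    def run(tag: str, counts: list[int], rs_values: list[float]) -> None:
        strata = _strata(counts, rs_values, bins)
        if len(strata) < 2:
            report[tag] = {"skipped": "fewer than two strata",
                           "strata": {k: len(v) for k, v in strata.items()}}
            return
        h, p = kruskal_wallis([strata[k] for k in sorted(strata)])
        report[tag] = {"H": h, "p": p,
                       "strata_n": {k: len(strata[k]) for k in sorted(strata)},
                       "strata_median_rs": {k: float(np.median(strata[k]))
                                            for k in sorted(strata)}}

    run("littermate", [m.n_littermates for m in members],
        [m.subsequent_rs for m in members])
    run("pseudo_sibling", [m.n_matched_nonsib for m in members],
        [m.subsequent_rs for m in members])

    by_litter: dict = {}
    for size in sorted({m.litter_size for m in members}):
        sub = [m for m in members if m.litter_size == size]
        strata = _strata([m.n_littermates for m in sub],
                         [m.subsequent_rs for m in sub], bins)
        if len(strata) < 2 or sum(len(v) for v in strata.values()) < 4:
            continue
        h, p = kruskal_wallis([strata[k] for k in sorted(strata)])
        by_litter[size] = {"H": h, "p": p,
                           "strata_n": {k: len(strata[k]) for k in sorted(strata)}}
    report["littermate_by_litter_size"] = by_litter
    return report


def confound_checks(table: StudbookTable, graph: nx.DiGraph,
                    rs: Optional[ReproductiveSuccess] = None) -> dict:
    """Heritable-fecundity confound checks.

    Spearman rank correlations of (number of siblings, lifetime r_III) and of
    (parent lifetime r_III, offspring lifetime r_III).  Fewer than three
    usable pairs is an error; a constant outcome is reported as undefined.
    """
    rs = rs or ReproductiveSuccess(graph, table)
    lifetime = {rid: rs.lifetime(rid) for rid in table.records if rid in graph}

    sib_pairs = []
    for rid, rec in table.records.items():
        if rid not in graph or (rec.dam_id is None and rec.sire_id is None):
            continue
        sibs = set()
        for parent in parents_of(graph, rid):
            if parent is not None and parent in graph:
                sibs.update(c for c in graph.successors(parent) if c != rid)
        sib_pairs.append((len(sibs), lifetime[rid]))

    po_pairs = []
    for rid in table.records:
        if rid not in graph:
            continue
        for parent in parents_of(graph, rid):
            if parent is not None and parent in lifetime:
                po_pairs.append((lifetime[parent], lifetime[rid]))

    def spearman(pairs: list[tuple[float, float]], tag: str) -> dict:
        if len(pairs) < 3:
            raise ValueError(f"{tag}: fewer than 3 usable pairs")
        x, y = zip(*pairs)
        if len(set(x)) < 2 or len(set(y)) < 2:
            return {"n": len(pairs), "rho": None, "p": None,
                    "note": "correlation undefined (constant values)"}
        rho, p = stats.spearmanr(x, y)
        return {"n": len(pairs), "rho": float(rho), "p": float(p)}

    return {"sibling_number_vs_rs": spearman(sib_pairs, "sibling_number_vs_rs"),
            "parent_vs_offspring_rs": spearman(po_pairs, "parent_vs_offspring_rs")}


def cotransfer_table(groups: Sequence[CoTransferGroup]) -> pd.DataFrame:
    """Per-member co-transfer covariates as a flat table."""
    rows = [{"individual": m.individual_id, "event_month": g.event_month,
             "origin": g.origin, "destination": g.destination,
             "group_size": len(g.member_ids),
             "n_littermates": m.n_littermates,
             "n_matched_nonsib": m.n_matched_nonsib,
             "litter_size": m.litter_size,
             "subsequent_rs": m.subsequent_rs}
            for g in groups for m in g.members]
    return pd.DataFrame(rows)
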