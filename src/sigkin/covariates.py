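"""Monthly predictor/outcome rows for reproductive-success models.

For every focal individual with a complete standard inheritance graph (SIG)
and every month of its zoo residency, a design row holds:

* base variables — age (months), sex, and female / male / total / age-binned
  group sizes in the focal's zoo;
* kin counts per SIG class key: local kin alpha (living relatives in the same
  zoo), non-local kin beta (living relatives in other zoos), global kin
  (alpha + beta), and pseudo-kin gamma (unrelated cohabitants matching the
  age and sex of a living relative in the class);
* the outcome ``r_III`` — the focal's reproductive success over the target
  window, the sum of path-additive relatedness coefficients to all
  descendants born within the window (one child contributes 0.5, one
  grandchild 0.25, so a window gaining both scores 0.75).

The competing model specifications keep these counts separate (``split``:
alpha and gamma as independent variables) or merge them (``sigma``:
alpha + gamma per class), alongside the single-set local / non-local /
global / pseudo variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import networkx as nx
import pandas as pd

from .pedigree import (DEFAULT_MAX_LEN, K_PARENT_CHILD, RelatednessCache)
from .sig import SIG, SIGClassKey, all_class_keys, build_sig, has_complete_sig
from .studbook_io import (FEMALE, MALE, UNKNOWN, ResidencyTable, StudbookTable)

VariableSet = Literal["local", "nonlocal", "global", "pseudo", "sigma", "split"]

#: default age tolerance (months) for pseudo-kin age matching
DEFAULT_AGE_TOLERANCE = 3
#: default age-bin edges (months) for age-specific group sizes
DEFAULT_AGE_BINS = (6, 24)

SEX_CODE = {FEMALE: 0.0, MALE: 1.0, UNKNOWN: float("nan")}


@dataclass
class ModelSpec:
    """Which kin variables enter the design matrix, at which SIG diameter.

    ``include_descendant_classes=False`` drops the class III (descendant)
    counts from the predictors: a focal's living-descendant count is a thin
    proxy for its own reproductive history and therefore leaks the outcome
    into models meant to measure social-structure effects; reproductive
    history belongs in the explicit ``prev_rs`` predictor of forecast mode.
    """

    variable_set: VariableSet = "split"
    d: int = 1
    descent_cap: Optional[int] = None
    horizon: int = 12
    age_tolerance: int = DEFAULT_AGE_TOLERANCE
    age_bins: tuple[int, ...] = DEFAULT_AGE_BINS
    include_descendant_classes: bool = True

    @property
    def cap(self) -> int:
        return self.d if self.descent_cap is None else self.descent_cap

    def class_keys(self) -> list[SIGClassKey]:
        keys = all_class_keys(self.d, self.cap)
        if not self.include_descendant_classes:
            keys = [k for k in keys if k.sig_class != "III"]
        return keys

    def kin_columns(self) -> list[str]:
        labels = [k.label() for k in self.class_keys()]
        prefix = {"local": ["a_"], "nonlocal": ["b_"], "global": ["t_"],
                  "pseudo": ["g_"], "sigma": ["s_"], "split": ["a_", "g_"]}
        return [p + lab for lab in labels for p in prefix[self.variable_set]]


@dataclass
class KinCounts:
    """Per-class-key kin counts at one (focal, month)."""

    alpha: dict[SIGClassKey, int] = field(default_factory=dict)
    beta: dict[SIGClassKey, int] = field(default_factory=dict)

    def global_count(self, key: SIGClassKey) -> int:
        return self.alpha.get(key, 0) + self.beta.get(key, 0)


class ReproductiveSuccess:
    """Cached r_III computation: per-focal descendant birth/contribution lists.

    The contribution of each descendant is its full path-additive relatedness
    to the focal, so differential grand-offspring production is weighted in.
    """

    def __init__(self, graph: nx.DiGraph, table: StudbookTable,
                 k: float = K_PARENT_CHILD, max_len: int = DEFAULT_MAX_LEN):
        self.graph = graph
        self.table = table
        self.rel = RelatednessCache(graph, max_len=max_len, k=k)
        self._events: dict[str, list[tuple[int, float]]] = {}

    def _descendant_events(self, focal: str) -> list[tuple[int, float]]:
        events = self._events.get(focal)
        if events is None:
            events = []
            for desc in nx.descendants(self.graph, focal):
                rec = self.table.record_or_ghost(desc)
                birth = rec.birth_month if rec else self.graph.nodes[desc].get("birth")
                if birth is None:
                    continue
                r = self.rel(focal, desc)
                if r > 0:
                    events.append((birth, r))
            events.sort()
            self._events[focal] = events
        return events

    def __call__(self, focal: str, start_month: int, end_month: int) -> float:
        """r_III accrued over the inclusive window [start_month, end_month]."""
        if start_month > end_month:
            raise ValueError(f"reversed window [{start_month}, {end_month}]")
        return sum(r for birth, r in self._descendant_events(focal)
                   if start_month <= birth <= end_month)

    def lifetime(self, focal: str) -> float:
        events = self._descendant_events(focal)
        return sum(r for _, r in events)


def reproductive_success(graph: nx.DiGraph, focal: str,
                         window: tuple[int, int],
                         table: Optional[StudbookTable] = None,
                         k: float = K_PARENT_CHILD,
                         max_len: int = DEFAULT_MAX_LEN) -> float:
    """r_III of ``focal`` over ``window = (start_month, end_month)`` inclusive.

    Descendants at any depth contribute their path-additive relatedness at
    the month of their own birth (a grandchild credits the focal when the
    grandchild is born, not when the child is).
    """
    table = table or StudbookTable()
    return ReproductiveSuccess(graph, table, k=k, max_len=max_len)(
        focal, window[0], window[1])


def _member_alive(table: StudbookTable, graph: nx.DiGraph,
                  member: str, month: int) -> bool:
    rec = table.record_or_ghost(member)
    if rec is not None:
        return rec.alive_at(month, table.data_end)
    birth = graph.nodes[member].get("birth")
    death = graph.nodes[member].get("death")
    if birth is None or month < birth:
        return False
    return death is None or month <= death


def kin_counts(sig: SIG, residency: ResidencyTable, table: StudbookTable,
               month: int, graph: Optional[nx.DiGraph] = None) -> KinCounts:
    """Partition living SIG members into local (alpha) and non-local (beta).

    Local membership is co-residency with the focal's institution at the
    month; a living member with no zoo residency that month (e.g. recorded
    only as a ghost parent) counts as non-local.
    """
    loc = residency.location_index(month)
    zoo = loc.get(sig.focal_id)
    if zoo is None:
        raise ValueError(
            f"focal {sig.focal_id!r} is not resident in any zoo at month {month}")
    counts = KinCounts()
    for key, members in sig.members.items():
        a = b = 0
        for m in members:
            if graph is not None and not _member_alive(table, graph, m, month):
                continue
            if graph is None:
                rec = table.record_or_ghost(m)
                if rec is None or not rec.alive_at(month, table.data_end):
                    continue
            if loc.get(m) == zoo:
                a += 1
            else:
                b += 1
        if a:
            counts.alpha[key] = a
        if b:
            counts.beta[key] = b
    return counts


def pseudo_kin_counts(sig: SIG, residency: ResidencyTable, table: StudbookTable,
                      month: int, graph: nx.DiGraph,
                      age_tolerance: int = DEFAULT_AGE_TOLERANCE,
                      rel: Optional[RelatednessCache] = None) -> dict[SIGClassKey, int]:
    """Pseudo-kin gamma per class key: unrelated cohabitants matching a member.

    For each class key, count individuals in the focal's zoo whose path
    relatedness to the focal is zero and whose sex and age (within the
    tolerance) match some living member of the class; each individual counts
    at most once per class.
    """
    focal = sig.focal_id
    zoo = residency.location_index(month).get(focal)
    if zoo is None:
        raise ValueError(
            f"focal {focal!r} is not resident in any zoo at month {month}")
    rel = rel or RelatednessCache(graph)
    cohabitants = [c for c in residency.occupants(zoo, month) if c != focal]
    unrelated = []
    for c in cohabitants:
        rec = table.records.get(c)
        if rec is None or rec.birth_month is None:
            continue
        if (c not in graph) or rel(focal, c) == 0.0:
            unrelated.append((c, rec.sex, month - rec.birth_month))

    gamma: dict[SIGClassKey, int] = {}
    for key, members in sig.members.items():
        profiles = []
        for m in members:
            rec = table.record_or_ghost(m)
            if rec is None or not rec.alive_at(month, table.data_end):
                continue
            if rec.birth_month is None:
                continue
            profiles.append((rec.sex, month - rec.birth_month))
        if not profiles:
            continue
        n = sum(1 for _, csex, cage in unrelated
                if any(csex == msex and abs(cage - mage) <= age_tolerance
                       for msex, mage in profiles))
        if n:
            gamma[key] = n
    return gamma


def _group_sizes(residency: ResidencyTable, table: StudbookTable,
                 zoo: str, month: int,
                 age_bins: tuple[int, ...]) -> dict[str, int]:
    """Female / male / total and age-binned group sizes (focal included)."""
    out = {"grp_f": 0, "grp_m": 0, "grp_t": 0}
    for i in range(len(age_bins) + 1):
        out[f"grp_age{i}"] = 0
    edges = list(age_bins)
    for member in residency.occupants(zoo, month):
        rec = table.records.get(member)
        if rec is None:
            continue
        out["grp_t"] += 1
        if rec.sex == FEMALE:
            out["grp_f"] += 1
        elif rec.sex == MALE:
            out["grp_m"] += 1
        if rec.birth_month is not None:
            age = month - rec.birth_month
            i = sum(age >= e for e in edges)
            out[f"grp_age{i}"] += 1
    return out


def select_focals(graph: nx.DiGraph, table: StudbookTable, d: int) -> list[str]:
    """Analyzable, determinate-sex individuals with a complete degree-d SIG."""
    out = []
    for rid, rec in table.records.items():
        if rec.sex not in (FEMALE, MALE) or rec.birth_month is None:
            continue
        if rid in graph and has_complete_sig(graph, rid, d):
            out.append(rid)
    return out


def build_design_matrix(graph: nx.DiGraph, table: StudbookTable,
                        residency: ResidencyTable, spec: ModelSpec,
                        mode: Literal["current", "forecast"] = "current",
                        horizon: Optional[int] = None,
                        month_step: int = 1,
                        focals: Optional[list[str]] = None,
                        rs: Optional[ReproductiveSuccess] = None) -> pd.DataFrame:
    """One row per (focal, month) with predictors and the r_III outcome.

    The outcome is cumulative r_III over the next ``horizon`` months (the
    window the fitted model predicts, and the window the group-structure
    optimizer maximizes).  ``forecast`` mode additionally feeds the focal's
    past r_III in as ``prev_rs`` and drops rows where the focal dies inside
    the horizon; ``current`` mode keeps all rows — death simply truncates
    accrual — and uses only current social conditions as predictors.
    """
    if horizon is None:
        horizon = spec.horizon
    if mode == "forecast" and horizon > 24:
        warnings.warn(f"forecast horizon {horizon} exceeds the tested 24-month range")
    if focals is None:
        focals = select_focals(graph, table, spec.d)
    rs = rs or ReproductiveSuccess(graph, table)
    rel = rs.rel
    keys = spec.class_keys()
    vset = spec.variable_set
    rows = []
    for focal in focals:
        rec = table.records[focal]
        sig = build_sig(graph, focal, spec.d, spec.cap)
        start = rec.birth_month
        end = min(rec.death_month if rec.death_month is not None else table.data_end,
                  table.data_end)
        for month in range(start, end + 1, month_step):
            zoo = residency.location_index(month).get(focal)
            if zoo is None:
                continue
            if mode == "forecast":
                if rec.death_month is not None and rec.death_month <= month + horizon:
                    continue
                if month + horizon > table.data_end:
                    continue
            y = rs(focal, month + 1, month + horizon)
            row = {"focal": focal, "month": month,
                   "age": float(month - start), "sex": SEX_CODE[rec.sex]}
            row.update(_group_sizes(residency, table, zoo, month, spec.age_bins))
            need_ab = vset in ("local", "nonlocal", "global", "sigma", "split")
            need_g = vset in ("pseudo", "sigma", "split")
            kc = kin_counts(sig, residency, table, month, graph) if need_ab else None
            gamma = (pseudo_kin_counts(sig, residency, table, month, graph,
                                       spec.age_tolerance, rel)
                     if need_g else {})
            for key in keys:
                lab = key.label()
                a = kc.alpha.get(key, 0) if kc else 0
                b = kc.beta.get(key, 0) if kc else 0
                g = gamma.get(key, 0)
                if vset == "local":
                    row["a_" + lab] = a
                elif vset == "nonlocal":
                    row["b_" + lab] = b
                elif vset == "global":
                    row["t_" + lab] = a + b
                elif vset == "pseudo":
                    row["g_" + lab] = g
                elif vset == "sigma":
                    row["s_" + lab] = a + g
                else:
                    row["a_" + lab] = a
                    row["g_" + lab] = g
            if mode == "forecast":
                row["prev_rs"] = rs(focal, start, month)
            row["y"] = y
            rows.append(row)
    base = ["age", "sex", "grp_f", "grp_m", "grp_t"] + \
        [f"grp_age{i}" for i in range(len(spec.age_bins) + 1)]
    cols = ["focal", "month"] + base + spec.kin_columns() + \
        (["prev_rs"] if mode == "forecast" else []) + ["y"]
    return pd.DataFrame(rows, columns=cols)


def to_sigma_design(split_design: pd.DataFrame) -> pd.DataFrame:
    """Collapse a split-spec design to the sigma spec: s = alpha + gamma.

    The sigma model is built from identical data with the kin / non-kin
    distinction erased, so each ``s_`` column is the exact sum of the
    corresponding ``a_`` and ``g_`` pair.
    """
    out = {}
    for col in split_design.columns:
        if col.startswith("a_"):
            lab = col[2:]
            out["s_" + lab] = split_design[col] + split_design["g_" + lab]
        elif col.startswith("g_"):
            continue
        else:
            out[col] = split_design[col]
    return pd.DataFrame(out)


def predictor_columns(df: pd.DataFrame) -> list[str]:
    """The predictor columns of a design matrix (everything but ids and y)."""
    return [c for c in df.columns if c not in ("focal", "month", "y")]
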