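"""Genetic/packing optimization of group structure across institutions.

Searches over reassignments of all living individuals to zoos, under packing
constraints (no zoo above its historic maximum group size over a trailing
window, none reduced below a minimum unless emptied), to maximize the
model-predicted per-capita reproductive success over a fixed horizon.  The
search runs many independent seed arrangements drawn uniformly at random;
each seed undergoes iterated mutation (random reassignment of a sampled
group of individuals, redrawn until the constraints hold) and elitist
selection of the best-scoring arrangement among the parent and its mutants.

Scoring rebuilds every individual's kin covariates as if the candidate
arrangement held at the evaluation month (ages and vital states fixed),
predicts each individual's horizon reproductive success with the fitted
regression tree — individuals without a complete SIG at the model's
diameter are scored by a fallback tree on the base variables — and averages
over the living population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .covariates import (ModelSpec, ReproductiveSuccess, SEX_CODE)
from .rprm import RegressionTree, predict
from .sig import build_sig, has_complete_sig
from .studbook_io import FEMALE, MALE, ResidencyTable, StudbookTable

log = logging.getLogger(__name__)


@dataclass
class ZooConstraints:
    """Per-institution (min_size, max_size) packing limits."""

    limits: dict[str, tuple[int, int]]

    @property
    def zoos(self) -> list[str]:
        return sorted(self.limits)

    def total_capacity(self) -> int:
        return sum(mx for _, mx in self.limits.values())

    def check_counts(self, counts: dict[str, int]) -> bool:
        for zoo, count in counts.items():
            if zoo not in self.limits:
                return False
            mn, mx = self.limits[zoo]
            if count > mx or 0 < count < mn:
                return False
        return True


@dataclass
class Arrangement:
    """A full assignment of living individuals to institutions."""

    assignment: dict[str, str]
    seed_index: int = -1
    iteration: int = -1

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for zoo in self.assignment.values():
            out[zoo] = out.get(zoo, 0) + 1
        return out


def capacity_constraints(residency: ResidencyTable, month: int,
                         window_years: int = 10, min_size: int = 2,
                         min_config: Optional[dict[str, int]] = None
                         ) -> ZooConstraints:
    """Historic-maximum capacities over the trailing window, plus minimums.

    ``max_size`` is the peak monthly occupancy of the zoo over the
    ``window_years`` ending at ``month`` (never below the current occupancy);
    ``min_size`` defaults to 2 for every zoo — singleton placements of an
    obligately social species are avoided, though emptying a zoo is allowed —
    and can be overridden per zoo via ``min_config``.  Zoos with no occupancy
    history in the window are excluded as assignment targets.
    """
    window = range(max(month - 12 * window_years + 1, residency.months()[0]),
                   month + 1)
    limits: dict[str, tuple[int, int]] = {}
    for zoo in residency.institutions():
        peak = max((residency.occupancy(zoo, m) for m in window), default=0)
        if peak == 0:
            log.warning("zoo %s has no occupancy in the window; excluded", zoo)
            continue
        peak = max(peak, residency.occupancy(zoo, month))
        mn = (min_config or {}).get(zoo, min_size)
        limits[zoo] = (min(mn, peak), peak)
    return ZooConstraints(limits)


def _counts_ok(z: np.ndarray, mins: np.ndarray, maxs: np.ndarray) -> bool:
    counts = np.bincount(z, minlength=len(mins))
    if (counts > maxs).any():
        return False
    small = (counts > 0) & (counts < mins)
    return not small.any()


def _zoo_weights(constraints: ZooConstraints, weights: str) -> np.ndarray:
    zoos = constraints.zoos
    if weights == "uniform":
        w = np.ones(len(zoos))
    elif weights == "capacity":
        w = np.array([constraints.limits[z][1] for z in zoos], dtype=float)
    else:
        raise ValueError(f"unknown weights {weights!r}")
    return w / w.sum()


def random_arrangement(living: Sequence[str], constraints: ZooConstraints,
                       rng: np.random.Generator,
                       weights: str = "capacity",
                       max_tries: int = 10_000) -> Arrangement:
    """Random institution per individual, rejection-sampled until valid.

    Destinations are drawn with replacement from the pool of zoo slots
    (probability proportional to capacity by default, so expected loads stay
    within historic peaks; ``weights="uniform"`` draws zoos equiprobably).
    """
    living = list(living)
    zoos = constraints.zoos
    if len(living) > constraints.total_capacity():
        raise ValueError("living population exceeds total zoo capacity")
    if len(zoos) == 1:
        return Arrangement({rid: zoos[0] for rid in living})
    mins = np.array([constraints.limits[z][0] for z in zoos])
    maxs = np.array([constraints.limits[z][1] for z in zoos])
    p = _zoo_weights(constraints, weights)
    for _ in range(max_tries):
        z = rng.choice(len(zoos), size=len(living), p=p)
        if _counts_ok(z, mins, maxs):
            return Arrangement({rid: zoos[zi] for rid, zi in zip(living, z)})
    raise RuntimeError(
        f"no constraint-satisfying arrangement in {max_tries} draws "
        f"(n={len(living)}, capacity={constraints.total_capacity()}, "
        f"zoos={len(zoos)}, weights={weights})")


def mutate(arrangement: Arrangement, constraints: ZooConstraints,
           rng: np.random.Generator, group_size: int = 50,
           n_mutants: int = 5, weights: str = "capacity",
           max_tries: int = 10_000) -> list[Arrangement]:
    """Mutants: a with-replacement sample of individuals randomly reassigned.

    Each mutant redraws until the packing constraints hold; an individual
    drawn twice keeps its last reassignment.  ``group_size=0`` returns copies
    of the parent.
    """
    ids = sorted(arrangement.assignment)
    zoos = constraints.zoos
    mins = np.array([constraints.limits[z][0] for z in zoos])
    maxs = np.array([constraints.limits[z][1] for z in zoos])
    zindex = {z: i for i, z in enumerate(zoos)}
    base = np.array([zindex[arrangement.assignment[rid]] for rid in ids])
    if group_size == 0:
        # a zero-size mutation changes nothing; return parent copies as-is
        return [Arrangement(dict(arrangement.assignment))
                for _ in range(n_mutants)]
    p = _zoo_weights(constraints, weights)
    mutants: list[Arrangement] = []
    tries = 0
    while len(mutants) < n_mutants:
        if tries >= max_tries:
            raise RuntimeError(
                f"mutation retry budget {max_tries} exhausted with "
                f"{len(mutants)}/{n_mutants} valid mutants")
        tries += 1
        z = base.copy()
        if group_size > 0:
            chosen = rng.integers(len(ids), size=min(group_size, len(ids)))
            z[chosen] = rng.choice(len(zoos), size=len(chosen), p=p)
        if _counts_ok(z, mins, maxs):
            mutants.append(Arrangement(
                {rid: zoos[zi] for rid, zi in zip(ids, z)}))
    return mutants


class ArrangementEvaluator:
    """Vectorized predicted per-capita reproductive success of an arrangement.

    Precomputes, at a fixed evaluation month, each living individual's static
    features and the identity of its SIG members and pseudo-kin candidates;
    scoring an arrangement then reduces to co-residency counting plus a tree
    prediction.  Vital states and ages are held fixed (a static
    counterfactual: the arrangement replaces residency for the evaluation
    month only).
    """

    def __init__(self, graph: nx.DiGraph, table: StudbookTable,
                 residency: ResidencyTable, month: int,
                 model: RegressionTree, spec: ModelSpec,
                 fallback: Optional[RegressionTree] = None,
                 rs: Optional[ReproductiveSuccess] = None):
        self.month = month
        self.spec = spec
        self.model = model
        self.fallback = fallback
        rs = rs or ReproductiveSuccess(graph, table)
        rel = rs.rel

        living = [rid for rid, rec in table.records.items()
                  if rec.alive_at(month, table.data_end)
                  and residency.at(rid, month) is not None]
        if not living:
            raise ValueError(f"no living resident individuals at month {month}")
        self.living = sorted(living)
        idx = {rid: i for i, rid in enumerate(self.living)}
        n = len(self.living)
        recs = [table.records[rid] for rid in self.living]
        self.ages = np.array([month - r.birth_month for r in recs], dtype=float)
        self.sexes = np.array([SEX_CODE[r.sex] for r in recs])
        self.is_f = np.array([r.sex == FEMALE for r in recs], dtype=float)
        self.is_m = np.array([r.sex == MALE for r in recs], dtype=float)
        edges = list(spec.age_bins)
        self.age_bin = np.array([sum(a >= e for e in edges) for a in self.ages])
        self.n_bins = len(edges) + 1
        self.prev_rs = np.array([rs(rid, table.records[rid].birth_month, month)
                                 for rid in self.living])
        self.status_quo = Arrangement(
            {rid: residency.at(rid, month) for rid in self.living})

        keys = spec.class_keys()
        self.key_labels = [k.label() for k in keys]
        kidx = {k: i for i, k in enumerate(keys)}
        self.complete = np.zeros(n, dtype=bool)
        mem_row, mem_key, mem_member = [], [], []
        self.beta_fixed = np.zeros((n, len(keys)))   # alive members w/o assignment
        cand_row, cand_key, cand_member = [], [], []
        for i, rid in enumerate(self.living):
            rec = recs[i]
            if rec.sex not in (FEMALE, MALE) or rid not in graph \
                    or not has_complete_sig(graph, rid, spec.d):
                continue
            self.complete[i] = True
            sig = build_sig(graph, rid, spec.d, spec.cap)
            living_members: dict = {}
            for key, members in sig.members.items():
                if key not in kidx:      # e.g. descendant classes excluded
                    continue
                for m in members:
                    mrec = table.record_or_ghost(m)
                    if mrec is None or not mrec.alive_at(month, table.data_end):
                        continue
                    if m in idx:
                        mem_row.append(i)
                        mem_key.append(kidx[key])
                        mem_member.append(idx[m])
                    else:
                        self.beta_fixed[i, kidx[key]] += 1
                    living_members.setdefault(key, []).append(
                        (mrec.sex, month - mrec.birth_month
                         if mrec.birth_month is not None else None))
            # pseudo-kin candidates: living, unrelated, profile-matched
            if spec.variable_set in ("pseudo", "sigma", "split"):
                for j, other in enumerate(self.living):
                    if other == rid:
                        continue
                    orec = recs[j]
                    if orec.birth_month is None:
                        continue
                    if other in graph and rel(rid, other) != 0.0:
                        continue
                    oage = month - orec.birth_month
                    for key, profiles in living_members.items():
                        if any(orec.sex == s and a is not None
                               and abs(oage - a) <= spec.age_tolerance
                               for s, a in profiles):
                            cand_row.append(i)
                            cand_key.append(kidx[key])
                            cand_member.append(j)
        self.mem = (np.array(mem_row, dtype=int), np.array(mem_key, dtype=int),
                    np.array(mem_member, dtype=int))
        self.cand = (np.array(cand_row, dtype=int), np.array(cand_key, dtype=int),
                     np.array(cand_member, dtype=int))
        self.n_keys = len(keys)
        self._zindex: Optional[dict[str, int]] = None

    def _as_z(self, arrangement: Arrangement) -> np.ndarray:
        zoos = sorted(set(arrangement.assignment.values()))
        self._zoos = zoos
        zindex = {z: i for i, z in enumerate(zoos)}
        try:
            return np.array([zindex[arrangement.assignment[rid]]
                             for rid in self.living])
        except KeyError as exc:
            raise ValueError(f"arrangement lacks living individual {exc}") from exc

    def feature_frame(self, arrangement: Arrangement) -> pd.DataFrame:
        z = self._as_z(arrangement)
        n = len(self.living)
        nz = z.max() + 1
        cols: dict[str, np.ndarray] = {
            "age": self.ages, "sex": self.sexes, "prev_rs": self.prev_rs}
        cols["grp_t"] = np.bincount(z, minlength=nz).astype(float)[z]
        cols["grp_f"] = np.bincount(z, weights=self.is_f, minlength=nz)[z]
        cols["grp_m"] = np.bincount(z, weights=self.is_m, minlength=nz)[z]
        for b in range(self.n_bins):
            w = (self.age_bin == b).astype(float)
            cols[f"grp_age{b}"] = np.bincount(z, weights=w, minlength=nz)[z]
        alpha = np.zeros((n, self.n_keys))
        rows, keys_, members = self.mem
        if len(rows):
            same = (z[members] == z[rows]).astype(float)
            np.add.at(alpha, (rows, keys_), same)
        alive_total = np.zeros((n, self.n_keys))
        if len(rows):
            np.add.at(alive_total, (rows, keys_), 1.0)
        beta = alive_total - alpha + self.beta_fixed
        gamma = np.zeros((n, self.n_keys))
        crows, ckeys, cmembers = self.cand
        if len(crows):
            csame = (z[cmembers] == z[crows]).astype(float)
            np.add.at(gamma, (crows, ckeys), csame)
        for ki, lab in enumerate(self.key_labels):
            cols["a_" + lab] = alpha[:, ki]
            cols["b_" + lab] = beta[:, ki]
            cols["t_" + lab] = alpha[:, ki] + beta[:, ki]
            cols["g_" + lab] = gamma[:, ki]
            cols["s_" + lab] = alpha[:, ki] + gamma[:, ki]
        return pd.DataFrame(cols)

    def score(self, arrangement: Arrangement) -> float:
        """Predicted per-capita horizon reproductive success under the model."""
        frame = self.feature_frame(arrangement)
        pred = np.empty(len(self.living))
        comp = self.complete
        if comp.any():
            pred[comp] = predict(self.model, frame.loc[comp, self.model.columns])
        if (~comp).any():
            if self.fallback is None:
                raise ValueError(
                    "individuals without complete SIGs present but no "
                    "fallback model supplied")
            pred[~comp] = predict(self.fallback,
                                  frame.loc[~comp, self.fallback.columns])
        return float(pred.mean())


def predicted_population_rs(arrangement: Arrangement,
                            evaluator: ArrangementEvaluator) -> float:
    return evaluator.score(arrangement)


def optimize(evaluator: ArrangementEvaluator, constraints: ZooConstraints,
             n_seeds: int = 1000, n_iter: int = 40, n_mutants: int = 5,
             group_size: int = 50,
             rng: np.random.Generator | int = 0) -> tuple[Arrangement, pd.DataFrame]:
    """Hill-climb each seed arrangement; return the global best and trajectory.

    Within each seed lineage the selected score is non-decreasing by
    construction (the parent competes with its mutants); this is asserted at
    every iteration.  The trajectory records (seed, iteration, score).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    living = evaluator.living
    best_arr: Optional[Arrangement] = None
    best_score = -np.inf
    rows = []
    for s in range(n_seeds):
        current = random_arrangement(living, constraints, rng)
        current.seed_index, current.iteration = s, 0
        score = evaluator.score(current)
        rows.append({"seed": s, "iteration": 0, "score": score})
        for it in range(1, n_iter + 1):
            candidates = [current] + mutate(
                current, constraints, rng, group_size=group_size,
                n_mutants=n_mutants)
            cand_scores = [score] + [evaluator.score(m)
                                     for m in candidates[1:]]
            pick = int(np.argmax(cand_scores))
            new_score = cand_scores[pick]
            assert new_score >= score - 1e-12, "selection must be monotone"
            current = candidates[pick]
            current.seed_index, current.iteration = s, it
            score = new_score
            rows.append({"seed": s, "iteration": it, "score": score})
        if score > best_score:
            best_score, best_arr = score, current
    assert best_arr is not None
    return best_arr, pd.DataFrame(rows)
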