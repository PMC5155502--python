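"""Shared fixtures: hand-built pedigrees and small simulated studbooks."""

import logging

import numpy as np
import pytest

from sigkin.pedigree import build_kdag
from sigkin.studbook_io import StudbookRecord, StudbookTable
from sigkin.synthetic_data import SimulationParams, simulate_studbook

logging.disable(logging.WARNING)


def make_table(rows, transfers=(), data_end=None):
    """rows: (id, sex, dam, sire, birth[, death]) tuples."""
    records = {}
    for row in rows:
        rid, sex, dam, sire = row[:4]
        birth = row[4] if len(row) > 4 else 0
        death = row[5] if len(row) > 5 else None
        records[rid] = StudbookRecord(
            rid, sex=sex, dam_id=dam, sire_id=sire,
            birth_month=birth, death_month=death,
            birth_institution="ZooA",
            disposition="alive" if death is None else "dead")
    return StudbookTable(records=records, transfers=list(transfers),
                         data_end=data_end)


@pytest.fixture
def trio_table():
    return make_table([("D", "F", None, None), ("S", "M", None, None),
                       ("C", "F", "D", "S", 10)])


@pytest.fixture
def trio_graph(trio_table):
    return build_kdag(trio_table)


@pytest.fixture
def family5_table():
    """Parents D, S; focal F1 with full sib B; F1's child K."""
    return make_table([("D", "F", None, None), ("S", "M", None, None),
                       ("F1", "F", "D", "S", 10), ("B", "M", "D", "S", 10),
                       ("K", "F", "F1", None, 40)])


@pytest.fixture
def family5_graph(family5_table):
    return build_kdag(family5_table)


@pytest.fixture
def inbred_table():
    """Grandparents G1/G2; parents A, B are full sibs; child C."""
    return make_table([("G1", "F", None, None), ("G2", "M", None, None),
                       ("A", "F", "G1", "G2", 10), ("B", "M", "G1", "G2", 10),
                       ("C", "F", "A", "B", 40)])


@pytest.fixture
def inbred_graph(inbred_table):
    return build_kdag(inbred_table)


def random_outbred_table(rng: np.random.Generator, n_founders=10,
                         n_generations=4, children_per_gen=8):
    """A random pedigree in which every mating pair is unrelated.

    Candidate pairs are rejected when any kinship path connects them, so all
    common ancestors are non-inbred and the path-additive rule coincides
    with the numerator relationship.
    """
    from sigkin.pedigree import RelatednessCache

    rows = []
    males, females = [], []
    for i in range(n_founders):
        sex = "F" if i % 2 == 0 else "M"
        rid = f"P{i:03d}"
        (females if sex == "F" else males).append(rid)
        rows.append((rid, sex, None, None, 0))
    table = make_table(rows)
    nxt = n_founders
    for gen in range(1, n_generations + 1):
        graph = build_kdag(table)
        rel = RelatednessCache(graph, max_len=2 * n_generations + 2)
        newly = []
        for _ in range(children_per_gen):
            for _ in range(30):
                dam = str(rng.choice(females))
                sire = str(rng.choice(males))
                if rel(dam, sire) == 0.0:
                    break
            else:
                continue
            rid = f"P{nxt:03d}"
            nxt += 1
            sex = "F" if rng.random() < 0.5 else "M"
            newly.append((rid, sex, dam, sire, 10 * gen))
        for row in newly:
            table.records[row[0]] = StudbookRecord(
                row[0], sex=row[1], dam_id=row[2], sire_id=row[3],
                birth_month=row[4], birth_institution="ZooA")
            (females if row[1] == "F" else males).append(row[0])
    return StudbookTable(records=table.records)


@pytest.fixture(scope="session")
def small_sim():
    """A small multi-zoo simulated studbook shared across tests."""
    params = SimulationParams(n_zoos=6, founders_per_zoo=4, months=120,
                              id_prefix="T")
    table, truth = simulate_studbook(params, seed=11)
    return params, table, truth
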