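"""r_III reproductive success, kin/pseudo-kin counts and design matrices."""

import pytest

from sigkin.covariates import (ModelSpec, ReproductiveSuccess,
                               build_design_matrix, kin_counts,
                               pseudo_kin_counts, reproductive_success,
                               select_focals, to_sigma_design)
from sigkin.pedigree import build_kdag
from sigkin.sig import SIGClassKey, build_sig
from sigkin.studbook_io import StudbookRecord, TransferEvent, monthly_residency
from sigkin.studies import prepare_population
from conftest import make_table


@pytest.fixture
def lineage():
    """Focal F with child C1 (born 20), grandchild G1 (born 30), child C2 (35)."""
    table = make_table([
        ("F", "F", None, None, 0), ("S", "M", None, None, 0),
        ("C1", "F", "F", "S", 20), ("SS", "M", None, None, 0),
        ("G1", "F", "C1", "SS", 30), ("C2", "M", "F", "S", 35)])
    return table, build_kdag(table)


class TestReproductiveSuccess:
    def test_child_plus_grandchild_in_window(self, lineage):
        """One child (r=0.5) and one grandchild (r=0.25) accrue 0.75."""
        table, graph = lineage
        assert reproductive_success(graph, "F", (20, 30), table) == 0.75

    def test_no_births_in_window_zero(self, lineage):
        table, graph = lineage
        assert reproductive_success(graph, "F", (0, 19), table) == 0.0

    def test_grandchild_credits_at_its_own_birth_month(self, lineage):
        table, graph = lineage
        assert reproductive_success(graph, "F", (25, 30), table) == 0.25

    def test_two_children_three_grandchildren(self):
        rows = [("F", "F", None, None, 0), ("S", "M", None, None, 0),
                ("SS", "M", None, None, 0), ("SD", "F", None, None, 0)]
        rows += [("C1", "F", "F", "S", 10), ("C2", "F", "F", "S", 12)]
        rows += [(f"G{i}", "M", "C1" if i < 2 else "C2", "SS", 40 + i)
                 for i in range(3)]
        table = make_table(rows)
        graph = build_kdag(table)
        assert reproductive_success(graph, "F", (0, 100), table) == \
            pytest.approx(2 * 0.5 + 3 * 0.25)

    def test_reversed_window_is_error(self, lineage):
        table, graph = lineage
        with pytest.raises(ValueError, match="window"):
            reproductive_success(graph, "F", (10, 5), table)

    def test_additive_over_disjoint_windows(self, lineage):
        table, graph = lineage
        rs = ReproductiveSuccess(graph, table)
        assert rs("F", 0, 50) == pytest.approx(
            rs("F", 0, 24) + rs("F", 25, 50))


@pytest.fixture
def two_zoo_family():
    """F1 and sib B share a zoo; their dam D lives in another zoo."""
    table = make_table([
        ("D", "F", None, None, 0), ("S", "M", None, None, 0, 30),
        ("F1", "F", "D", "S", 10), ("B", "F", "D", "S", 10),
        ("U", "F", None, None, 10)],
        transfers=[TransferEvent("D", 20, "ZooA", "ZooB")],
        data_end=60)
    return table, build_kdag(table)


class TestKinCounts:
    def test_local_vs_nonlocal_partition(self, two_zoo_family):
        table, graph = two_zoo_family
        res = monthly_residency(table)
        sig = build_sig(graph, "F1", 1)
        counts = kin_counts(sig, res, table, 25, graph)
        key_f = SIGClassKey("F", 0)
        assert counts.alpha.get(key_f, 0) == 0      # dam moved away
        assert counts.beta.get(key_f) == 1
        assert counts.alpha[SIGClassKey("F", 1)] == 1   # sib cohabits
        assert counts.global_count(key_f) == 1

    def test_dead_relatives_not_counted(self, two_zoo_family):
        table, graph = two_zoo_family
        res = monthly_residency(table)
        sig = build_sig(graph, "F1", 1)
        counts = kin_counts(sig, res, table, 40, graph)   # sire died at 30
        key_m = SIGClassKey("M", 0)
        assert counts.global_count(key_m) == 0

    def test_capacity_one_class_reciprocity(self, two_zoo_family):
        """Local presence of the dam implies non-local absence and vice versa."""
        table, graph = two_zoo_family
        res = monthly_residency(table)
        sig = build_sig(graph, "F1", 1)
        key_f = SIGClassKey("F", 0)
        for month in (15, 25):
            counts = kin_counts(sig, res, table, month, graph)
            assert counts.alpha.get(key_f, 0) + counts.beta.get(key_f, 0) == 1

    def test_nonresident_focal_errors(self, two_zoo_family):
        table, graph = two_zoo_family
        res = monthly_residency(table)
        sig = build_sig(graph, "F1", 1)
        with pytest.raises(ValueError, match="not resident"):
            kin_counts(sig, res, table, 5, graph)


class TestPseudoKinCounts:
    def test_matched_unrelated_cohabitant_counted_once(self, two_zoo_family):
        table, graph = two_zoo_family
        res = monthly_residency(table)
        sig = build_sig(graph, "F1", 1)
        gamma = pseudo_kin_counts(sig, res, table, 25, graph)
        # U matches sib B (same sex, same birth month) and cohabits
        assert gamma[SIGClassKey("F", 1)] == 1
        assert gamma[SIGClassKey("M", 1)] == 1   # B occupies both sib keys

    def test_relatives_never_pseudo_kin(self, two_zoo_family):
        table, graph = two_zoo_family
        res = monthly_residency(table)
        sig = build_sig(graph, "B", 1)
        gamma = pseudo_kin_counts(sig, res, table, 25, graph)
        # F1 is B's full sib: counted as kin, so only U can be pseudo
        assert all(v <= 1 for v in gamma.values())

    def test_kin_only_zoo_all_zero(self, family5_table, family5_graph):
        res = monthly_residency(family5_table)
        sig = build_sig(family5_graph, "F1", 1)
        gamma = pseudo_kin_counts(sig, res, family5_table, 40, family5_graph)
        assert gamma == {}

    def test_age_tolerance_respected(self, two_zoo_family):
        table, graph = two_zoo_family
        table.records["U"] = StudbookRecord(
            "U", sex="F", birth_month=2, birth_institution="ZooA")
        res = monthly_residency(table)
        sig = build_sig(graph, "F1", 1)
        gamma = pseudo_kin_counts(sig, res, table, 25, graph,
                                  age_tolerance=3)
        assert SIGClassKey("F", 1) not in gamma      # 8 months off
        gamma = pseudo_kin_counts(sig, res, table, 25, graph,
                                  age_tolerance=12)
        assert gamma[SIGClassKey("F", 1)] == 1


@pytest.fixture(scope="module")
def sim(small_sim):
    _, table, _ = small_sim
    graph, residency, rs = prepare_population(table)
    return table, graph, residency, rs


class TestDesignMatrix:
    def test_alpha_plus_beta_equals_global(self, sim):
        table, graph, residency, rs = sim
        focals = select_focals(graph, table, 1)[:25]
        kwargs = dict(mode="current", month_step=6, focals=focals, rs=rs)
        d_split = build_design_matrix(graph, table, residency,
                                      ModelSpec("split", d=1), **kwargs)
        d_glob = build_design_matrix(graph, table, residency,
                                     ModelSpec("global", d=1), **kwargs)
        d_nonloc = build_design_matrix(graph, table, residency,
                                       ModelSpec("nonlocal", d=1), **kwargs)
        for lab in ("F", "M", "F1", "M1", "D1"):
            assert (d_split["a_" + lab] + d_nonloc["b_" + lab]
                    == d_glob["t_" + lab]).all()

    def test_sigma_columns_are_sums_of_split_pairs(self, sim):
        table, graph, residency, rs = sim
        focals = select_focals(graph, table, 1)[:25]
        kwargs = dict(mode="current", month_step=6, focals=focals, rs=rs)
        d_split = build_design_matrix(graph, table, residency,
                                      ModelSpec("split", d=1), **kwargs)
        d_sigma = build_design_matrix(graph, table, residency,
                                      ModelSpec("sigma", d=1), **kwargs)
        assert len(d_split.columns) > len(d_sigma.columns)
        for lab in ("F", "M", "F1", "M1", "D1"):
            assert (d_split["a_" + lab] + d_split["g_" + lab]
                    == d_sigma["s_" + lab]).all()
        derived = to_sigma_design(d_split)
        assert (derived[d_sigma.columns] == d_sigma).all().all()

    def test_group_sizes_sum_and_include_focal(self, sim):
        table, graph, residency, rs = sim
        focals = select_focals(graph, table, 1)[:25]
        df = build_design_matrix(graph, table, residency, ModelSpec("local", d=1),
                                 mode="current", month_step=6,
                                 focals=focals, rs=rs)
        assert (df.grp_t >= df.grp_f + df.grp_m).all()
        assert (df.grp_t >= 1).all()
        assert (df.grp_age0 + df.grp_age1 + df.grp_age2 == df.grp_t).all()

    def test_forecast_drops_deaths_within_horizon(self, sim):
        table, graph, residency, rs = sim
        focals = select_focals(graph, table, 1)
        dead = [f for f in focals if table.records[f].death_month is not None]
        assert dead
        horizon = 12
        df = build_design_matrix(graph, table, residency,
                                 ModelSpec("local", d=1), mode="forecast",
                                 horizon=horizon, month_step=1,
                                 focals=dead[:10], rs=rs)
        for _, row in df.iterrows():
            death = table.records[row.focal].death_month
            assert death > row.month + horizon

    def test_forecast_outcome_telescopes_with_horizon(self, sim):
        table, graph, residency, rs = sim
        focals = select_focals(graph, table, 1)[:15]
        frames = {
            h: build_design_matrix(graph, table, residency,
                                   ModelSpec("local", d=1), mode="forecast",
                                   horizon=h, month_step=6,
                                   focals=focals, rs=rs).set_index(["focal", "month"])
            for h in (6, 12)}
        joined = frames[6].join(frames[12], how="inner", rsuffix="_12")
        assert len(joined) > 0
        assert (joined.y_12 >= joined.y).all()

    def test_current_mode_row_bookkeeping(self, sim):
        table, graph, residency, rs = sim
        focals = select_focals(graph, table, 1)[:20]
        df = build_design_matrix(graph, table, residency, ModelSpec("local", d=1),
                                 mode="current", month_step=1,
                                 focals=focals, rs=rs)
        expected = 0
        for f in focals:
            rec = table.records[f]
            end = rec.death_month if rec.death_month is not None else table.data_end
            expected += sum(residency.at(f, m) is not None
                            for m in range(rec.birth_month, end + 1))
        assert len(df) == expected

    def test_descendant_classes_can_be_excluded(self, sim):
        spec = ModelSpec("split", d=1, include_descendant_classes=False)
        assert all(not c.endswith("D1") for c in spec.kin_columns())
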