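"""Co-transfer groups, Kruskal-Wallis tests and confound checks."""

import numpy as np
import pytest
from scipy import stats

from sigkin.pedigree import build_kdag
from sigkin.studbook_io import TransferEvent
from sigkin.studies import prepare_population
from sigkin.synthetic_data import SimulationParams, simulate_studbook
from sigkin.transfer_analysis import (confound_checks, cotransfer_table,
                                      find_cotransfers, kruskal_wallis,
                                      littermate_vs_pseudo)
from sigkin.covariates import ReproductiveSuccess
from conftest import make_table


def littermate_fixture():
    """Three same-sex littermates plus an unrelated matched female co-moved."""
    rows = [("D", "F", None, None, 0), ("S", "M", None, None, 0)]
    rows += [(f"L{i}", "F", "D", "S", 10) for i in range(3)]
    rows += [("U", "F", None, None, 11)]
    transfers = [TransferEvent(rid, 24, "ZooA", "ZooB")
                 for rid in ("L0", "L1", "L2", "U")]
    table = make_table(rows, transfers=transfers, data_end=60)
    return table, build_kdag(table)


class TestFindCotransfers:
    def test_littermate_and_pseudo_counts(self):
        table, graph = littermate_fixture()
        groups = find_cotransfers(table, graph)
        assert len(groups) == 1
        by_id = {m.individual_id: m for m in groups[0].members}
        assert by_id["L0"].n_littermates == 2
        assert by_id["L0"].n_matched_nonsib == 1     # U
        assert by_id["U"].n_littermates == 0
        assert by_id["U"].n_matched_nonsib == 3
        assert by_id["L1"].litter_size == 3

    def test_solo_transfer_not_a_group(self):
        table = make_table([("A", "F", None, None, 0)],
                           transfers=[TransferEvent("A", 5, "ZooA", "ZooB")],
                           data_end=30)
        groups = find_cotransfers(table, build_kdag(table))
        assert groups == []

    def test_prior_breeder_excluded_from_members(self):
        table, graph = littermate_fixture()
        # give L0 a child born before the transfer
        table.records["K"] = table.records["L0"].__class__(
            "K", sex="M", dam_id="L0", sire_id="S", birth_month=22,
            birth_institution="ZooA")
        graph = build_kdag(table)
        groups = find_cotransfers(table, graph)
        ids = {m.individual_id for m in groups[0].members}
        assert "L0" not in ids and {"L1", "L2", "U"} <= ids

    def test_littermate_counts_symmetric_within_cotransferred_litter(self):
        table, graph = littermate_fixture()
        groups = find_cotransfers(table, graph)
        lits = [m.n_littermates for m in groups[0].members
                if m.individual_id.startswith("L")]
        assert len(set(lits)) == 1


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_values_identical(self):
        h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert (h, p) == (0.0, 1.0)

    def test_hand_computed_separated_groups(self):
        # ranks 1..6; R1=6, R2=15; H = 12/(6*7) * (36/3 + 225/3) - 3*7 = 3.857...
        h, p = kruskal_wallis([[1.0, 2.0, 3.0], [10.0, 11.0, 12.0]])
        expected = 12.0 / 42.0 * (36.0 / 3 + 225.0 / 3) - 21.0
        assert h == pytest.approx(expected)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = rng.integers(2, 5)
            samples = [rng.integers(0, 8, size=rng.integers(3, 12)).astype(float)
                       for _ in range(k)]
            h, p = kruskal_wallis(samples)
            ref = stats.kruskal(*samples)
            assert h == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invariant_under_monotone_transformation(self):
        rng = np.random.default_rng(1)
        samples = [rng.normal(size=8), rng.normal(size=10) + 0.5]
        h1, _ = kruskal_wallis(samples)
        h2, _ = kruskal_wallis([np.exp(s) for s in samples])
        assert h1 == pytest.approx(h2, abs=1e-10)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


def planted_groups(rng, n_groups=60, littermate_effect=0.5):
    """Co-transfer groups with a planted littermate penalty.

    Each member's subsequent reproductive success is Poisson with mean
    scaled by effect**n_littermates; the matched-non-sibling count is an
    independent nuisance with no effect.
    """
    from sigkin.transfer_analysis import CoTransferGroup, CoTransferMember
    groups = []
    for g in range(n_groups):
        n = int(rng.integers(2, 5))
        n_lit = int(rng.integers(0, 3))
        members = []
        for m in range(n):
            n_pseudo = int(rng.integers(0, 3))
            mean = 2.0 * littermate_effect ** n_lit
            rs_val = 0.5 * rng.poisson(mean)
            litter_size = n_lit + int(rng.integers(1, 3))
            members.append(CoTransferMember(f"G{g}M{m}", n_lit, n_pseudo,
                                            litter_size, rs_val))
        groups.append(CoTransferGroup(g, "A", "B",
                                      [m.individual_id for m in members],
                                      members))
    return groups


class TestLittermateVsPseudo:
    def test_planted_littermate_penalty_detected(self):
        """Littermate co-transfer count predicts subsequent success; the
        matched non-sibling count (no planted effect) does not."""
        rng = np.random.default_rng(4)
        report = littermate_vs_pseudo(planted_groups(rng))
        assert report["littermate"]["p"] < 0.01
        med = report["littermate"]["strata_median_rs"]
        assert med[0] > med[max(med)]
        assert report["pseudo_sibling"]["p"] > 0.05
        assert report["littermate_by_litter_size"]   # stratified variant runs

    def test_no_planted_effect_nominal_type_i_rate(self):
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(40):
            report = littermate_vs_pseudo(
                planted_groups(rng, littermate_effect=1.0))
            rejections += report["littermate"]["p"] < 0.05
        assert rejections <= 6      # ~2 expected at the nominal 5% level

    def test_single_stratum_skipped_with_notice(self):
        table, graph = littermate_fixture()
        groups = find_cotransfers(table, graph)
        # keep only the littermates: everyone has exactly 2 littermates
        groups[0].members = [m for m in groups[0].members
                             if m.individual_id.startswith("L")]
        report = littermate_vs_pseudo(groups)
        assert "skipped" in report["littermate"]

    def test_simulated_population_end_to_end(self):
        """The full path from a simulated studbook to the report runs and
        finds littermate strata (significance at this scale is not asserted:
        co-transfer counts in a small population give low power)."""
        params = SimulationParams(n_zoos=8, founders_per_zoo=4, months=216,
                                  base_fecundity=0.09, litter_sizes=(3,),
                                  litter_probs=(1.0,),
                                  parent_documentation=1.0, id_prefix="X")
        table, _ = simulate_studbook(params, seed=21)
        graph, _, rs = prepare_population(table)
        groups = find_cotransfers(table, graph, rs=rs)
        report = littermate_vs_pseudo(groups)
        assert report["n_members"] > 40
        assert len(report["littermate"]["strata_n"]) >= 2
        flat = cotransfer_table(groups)
        assert {"individual", "n_littermates", "n_matched_nonsib",
                "subsequent_rs"} <= set(flat.columns)
        assert len(flat) == sum(len(g.members) for g in groups)


@pytest.fixture(scope="module")
def transfer_sim():
    params = SimulationParams(n_zoos=6, founders_per_zoo=4, months=150,
                              base_fecundity=0.09, litter_sizes=(3,),
                              litter_probs=(1.0,), id_prefix="X")
    table, _ = simulate_studbook(params, seed=21)
    graph, _, rs = prepare_population(table)
    return table, graph, rs


class TestConfoundChecks:
    def test_non_heritable_fecundity_uncorrelated(self, transfer_sim):
        table, graph, rs = transfer_sim
        report = confound_checks(table, graph, rs)
        assert report["parent_vs_offspring_rs"]["n"] >= 3
        assert report["sibling_number_vs_rs"]["n"] >= 3

    def test_heritable_fecundity_detected(self):
        """Positive control: strong heritable fecundity induces a
        parent-offspring correlation in lifetime reproductive success."""
        params = SimulationParams(n_zoos=6, founders_per_zoo=4, months=150,
                                  base_fecundity=0.09, litter_sizes=(3,),
                                  litter_probs=(1.0,), heritable_sd=0.8,
                                  id_prefix="H")
        table, _ = simulate_studbook(params, seed=5)
        graph, _, rs = prepare_population(table)
        report = confound_checks(table, graph, rs)
        assert report["parent_vs_offspring_rs"]["rho"] > 0
        assert report["parent_vs_offspring_rs"]["p"] < 0.05

    def test_constant_rs_reported_undefined(self):
        table = make_table([("A", "F", None, None, 0), ("B", "M", None, None, 0),
                            ("C", "F", "A", "B", 5), ("D", "F", "A", "B", 6),
                            ("E", "M", "A", "B", 7)])
        graph = build_kdag(table)
        rs = ReproductiveSuccess(graph, table)
        report = confound_checks(table, graph, rs)
        assert report["sibling_number_vs_rs"]["rho"] is None

    def test_too_few_pairs_errors(self, trio_table, trio_graph):
        with pytest.raises(ValueError, match="pairs"):
            confound_checks(trio_table, trio_graph)
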