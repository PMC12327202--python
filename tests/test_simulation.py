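"""Delay-ordered firing semantics, trajectories, and engine invariants."""

import itertools
import math

import pytest
from conftest import small_random_grn
from netutils import check_conservation
from oracle import naive_simulate

from grnpetri import (
    SimulationConfig,
    ValidationError,
    build_grn,
    export_results,
    export_trajectory,
    fire,
    is_enabled,
    paper_fixture,
    simulate,
    step_cycle,
    transform,
)
from grnpetri.petrinet import PetriNet
from grnpetri.simulate import read_finals


def net_for(name):
    net, _ = transform(paper_fixture(name))
    return net


class TestEnablement:
    def test_process_inhibited_while_mirna_present(self, igfbp7_net):
        marking = igfbp7_net.initial_marking()
        assert marking["P_MIR_hsa-miR-1277-3p"] == 13
        assert not is_enabled(igfbp7_net, "T_MRNA_ENST00000512512", marking)

    def test_process_enabled_once_mirna_pools_empty(self, igfbp7_net):
        marking = igfbp7_net.initial_marking()
        marking["P_MIR_hsa-miR-1277-3p"] = 0
        marking["P_MIR_hsa-miR-24-1-5p"] = 0
        marking["P_DNA_IGFBP7"] = 116
        assert is_enabled(igfbp7_net, "T_MRNA_ENST00000512512", marking)

    def test_decay_disabled_by_empty_mirna_pool(self, igfbp7_net):
        """With the miRNA pool empty, the clamped weight max(min(0, d), 1) = 1
        exceeds the pool's 0 tokens, so the decay cannot fire for free."""
        marking = igfbp7_net.initial_marking()
        marking["P_MIR_hsa-miR-1277-3p"] = 0
        assert not is_enabled(igfbp7_net, "T_DECAY_hsa-miR-1277-3p_IGFBP7", marking)

    def test_process_disabled_by_empty_dna_pool(self, igfbp7_net):
        marking = {pid: 0 for pid in igfbp7_net.places}
        assert not is_enabled(igfbp7_net, "T_MRNA_ENST00000512512", marking)

    def test_inactive_transition_is_disabled(self, igfbp7_net):
        marking = igfbp7_net.initial_marking()
        igfbp7_net = igfbp7_net.copy()
        igfbp7_net.transitions["T_GEN_IGFBP7"].active = False
        assert not is_enabled(igfbp7_net, "T_GEN_IGFBP7", marking)


class TestFiring:
    def test_decay_binds_the_minimum_of_both_pools(self, igfbp7_net):
        marking = igfbp7_net.initial_marking()
        out = fire(igfbp7_net, "T_DECAY_hsa-miR-1277-3p_IGFBP7", marking)
        assert out["P_MIR_hsa-miR-1277-3p"] == 0
        assert out["P_DNA_IGFBP7"] == 166
        assert out["P_CNT_hsa-miR-1277-3p_IGFBP7"] == 13

    def test_process_moves_the_whole_remaining_pool(self, igfbp7_net):
        marking = igfbp7_net.initial_marking()
        marking.update({"P_MIR_hsa-miR-1277-3p": 0, "P_MIR_hsa-miR-24-1-5p": 0, "P_DNA_IGFBP7": 116})
        out = fire(igfbp7_net, "T_MRNA_ENST00000512512", marking)
        assert out["P_DNA_IGFBP7"] == 0
        assert out["P_IGFBP7_ENST00000512512_FINAL"] == 116

    def test_generation_adds_the_constant_rate(self, igfbp7_net):
        marking = igfbp7_net.initial_marking()
        out = fire(igfbp7_net, "T_GEN_IGFBP7", marking)
        assert out["P_DNA_IGFBP7"] == 179 + 179

    def test_firing_a_disabled_transition_is_a_contract_violation(self, igfbp7_net):
        with pytest.raises(ValidationError):
            fire(igfbp7_net, "T_MRNA_ENST00000512512", igfbp7_net.initial_marking())


class TestCycle:
    def test_igfbp7_cycle_produces_116_and_refills(self, igfbp7_net):
        config = SimulationConfig()
        marking = igfbp7_net.initial_marking()
        marking = step_cycle(igfbp7_net, marking, 0, config)
        assert marking["P_IGFBP7_ENST00000512512_FINAL"] == 179 - 13 - 50
        assert marking["P_DNA_IGFBP7"] == 179  # refilled by generation
        assert marking["P_MIR_hsa-miR-1277-3p"] == 13
        marking = step_cycle(igfbp7_net, marking, 1, config)
        assert marking["P_IGFBP7_ENST00000512512_FINAL"] == 2 * 116

    def test_excess_mirna_blocks_production_entirely(self):
        """ALKBH5-like: gene 388 vs miRNA 401; residual miRNA keeps the
        process inhibited, so the increment is zero."""
        net = net_for("alkbh5_d15p")
        marking = step_cycle(net, net.initial_marking(), 0, SimulationConfig())
        assert marking["P_ALKBH5_ALKBH5-201_FINAL"] == 0
        assert marking["P_MIR_hsa-miR-197-3p"] == 401 - 388 + 401

    def test_uninhibited_gene_increments_by_its_rate(self):
        grn = build_grn(
            [{"symbol": "G", "cpm": 42, "log2fc": 3.0}],
            [{"transcript_id": "G-201", "parent_symbol": "G"}],
            [],
            [],
            seed=0,
        )
        net, _ = transform(grn)
        marking = step_cycle(net, net.initial_marking(), 0, SimulationConfig())
        assert marking["P_G_G-201_FINAL"] == 42


class TestSimulate:
    def test_horizon_zero_keeps_result_places_empty(self, igfbp7_net):
        result = simulate(igfbp7_net, SimulationConfig(horizon=0))
        assert result.finals == {"IGFBP7_ENST00000512512_FINAL": 0}
        assert result.times == [0]

    def test_invalid_net_is_refused(self):
        from grnpetri import Arc, Place

        net = PetriNet(
            places={"a": Place(id="a", name="a"), "b": Place(id="b", name="b")},
            arcs=[Arc(source="a", target="b")],
        )
        with pytest.raises(ValidationError):
            simulate(net, SimulationConfig(horizon=1))

    def test_finals_monotone_and_markings_non_negative(self, igfbp7_result, igfbp7_net):
        result = igfbp7_result
        accumulating = [p.id for p in igfbp7_net.result_places()]
        accumulating += [p.id for p in igfbp7_net.counter_places()]
        for earlier, later in zip(result.trajectory, result.trajectory[1:]):
            for pid in accumulating:
                assert earlier[pid] <= later[pid]
            assert all(v >= 0 for v in later.values())

    def test_misordered_offsets_are_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(decay_offset=0.8)


class TestDecayOrderInvariance:
    def build(self, gene_cpm, mirna_cpms):
        genes = [{"symbol": "G", "cpm": gene_cpm, "log2fc": 3.0}]
        isoforms = [{"transcript_id": "G-201", "parent_symbol": "G"}]
        mirnas = [
            {"name": f"miR-{i}", "cpm": c, "log2fc": 2.5} for i, c in enumerate(mirna_cpms)
        ]
        targets = [{"mirna_name": m["name"], "transcript_id": "G-201"} for m in mirnas]
        net, _ = transform(build_grn(genes, isoforms, mirnas, targets, seed=0))
        return net

    @pytest.mark.parametrize(
        "gene_cpm, mirna_cpms",
        [
            (179, (13, 50)),
            (100, (10, 20, 200)),  # one miRNA exceeds the gene supply
            (50, (60, 70, 5)),
            (30, (10, 10, 10)),
        ],
    )
    def test_result_totals_invariant_under_decay_permutations(self, gene_cpm, mirna_cpms):
        net = self.build(gene_cpm, mirna_cpms)
        decay_ids = sorted(t.id for t in net.transitions.values() if t.role == "decay")
        finals = {
            simulate(
                net, SimulationConfig(horizon=10, priority=list(perm))
            ).finals["G_G-201_FINAL"]
            for perm in itertools.permutations(decay_ids)
        }
        assert len(finals) == 1


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "name",
        [
            "igfbp7_d15p",
            "aurkb_d15p",
            "fgfr1_d15p",
            "alkbh5_d15p",
            "mad2l2_sephs1_d9p",
            "aass_d4p_core",
        ],
    )
    def test_engine_matches_naive_stepper_on_fixtures(self, name):
        net = net_for(name)
        result = simulate(net, SimulationConfig(horizon=20))
        naive = naive_simulate(net, 20)
        assert result.trajectory[-1] == naive

    @pytest.mark.parametrize("seed", range(15))
    def test_engine_matches_naive_stepper_on_random_nets(self, seed):
        net, _ = transform(small_random_grn(seed))
        result = simulate(net, SimulationConfig(horizon=5))
        assert result.trajectory[-1] == naive_simulate(net, 5)


class TestConservation:
    @pytest.mark.parametrize("seed", range(10))
    def test_generated_equals_bound_plus_produced_plus_residual(self, seed):
        net, _ = transform(small_random_grn(seed))
        result = simulate(net, SimulationConfig(horizon=8))
        check_conservation(net, result)


class TestSteadyState:
    @pytest.mark.parametrize(
        "name, expected_increment",
        [("igfbp7_d15p", 116), ("aurkb_d15p", 24), ("alkbh5_d15p", 0)],
    )
    def test_per_cycle_increment_is_constant(self, name, expected_increment):
        """Every miRNA here targets isoforms of exactly one gene, so the
        result increment is the same each cycle and total = T x increment."""
        net = net_for(name)
        result = simulate(net, SimulationConfig(horizon=20))
        totals = [sum(m[p.id] for p in net.result_places()) for m in result.trajectory]
        increments = {b - a for a, b in zip(totals, totals[1:])}
        assert increments == {expected_increment}
        assert totals[-1] == 20 * expected_increment


class TestExport:
    def test_finals_and_counter_rows(self, igfbp7_result, tmp_path):
        path = tmp_path / "results.csv"
        export_results(igfbp7_result, path)
        finals = read_finals(path)
        assert finals["result"] == {"IGFBP7_ENST00000512512_FINAL": 2320}
        # counters accumulate 13 and 50 bound tokens per cycle over 20 cycles
        assert finals["counter"] == {
            "P_CNT_hsa-miR-1277-3p_IGFBP7": 260,
            "P_CNT_hsa-miR-24-1-5p_IGFBP7": 1000,
        }

    def test_trajectory_has_one_row_per_place_per_time(self, igfbp7_result, tmp_path):
        path = tmp_path / "traj.csv"
        export_trajectory(igfbp7_result, path)
        rows = path.read_text().strip().splitlines()
        assert rows[0] == "time,place,tokens"
        assert len(rows) - 1 == 21 * 6  # 21 snapshots x 6 places

    def test_empty_net_exports_header_only(self, tmp_path):
        result = simulate(PetriNet(), SimulationConfig(horizon=3))
        path = tmp_path / "empty.csv"
        export_results(result, path)
        assert path.read_text().strip() == "place,role,tokens"
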