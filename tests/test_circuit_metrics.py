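"""Connectivity metrics against brute-force oracles and worked examples."""

import numpy as np
import pytest

from circuitdiff.circuit_metrics import (
    GroupSpec,
    PartnerRecord,
    UndefinedFractionError,
    compare_volumes,
    fold_change,
    group_synapse_count,
    homolog_conservation,
    input_fraction,
    mean_fold_change,
    rank_partners,
    resolve_group,
    retention_stats,
    synapse_density_per_cable,
)
from circuitdiff.circuit_model import Box, CircuitError, cable_length, restrict_to_subvolume
from circuitdiff.stat_tests import chi_square_proportions
from circuitdiff.synthetic_data import CircuitDesign, generate_circuit

from conftest import build_circuit, random_circuit


@pytest.fixture(scope="module")
def wt_circuit():
    circuit, truth = generate_circuit(
        CircuitDesign(nodes_roster=25, n_background=6), seed=101
    )
    return circuit, truth


class TestResolveGroup:
    def test_roster_group_sizes(self, wt_circuit):
        """The default roster resolves the study's hemisegmental group sizes."""
        circuit, _ = wt_circuit
        for cell_type, side, expected in [
            ("Mechanosensory", "L", 8),
            ("Basin", "R", 4),
            ("Ladder", "L", 6),  # bilateral type belongs to both side groups
            ("Ladder", "R", 6),
            ("Nociceptive", "R", 3),
        ]:
            spec = GroupSpec(cell_type, cell_type, "A1", side, expected)
            assert len(resolve_group(circuit, spec)) == expected

    def test_expected_size_mismatch_is_error(self, wt_circuit):
        circuit, _ = wt_circuit
        with pytest.raises(CircuitError, match="expected 6 members, resolved 4"):
            resolve_group(circuit, GroupSpec("bad", "Basin", "A1", "L", 6))


class TestGroupSynapseCount:
    def test_hand_placed_links(self, two_neuron_circuit):
        assert group_synapse_count(two_neuron_circuit, "A", "B") == 7

    def test_compartment_filter_drops_link(self):
        nodes = {
            "A": [(0, None, 0, 0, 0, "axon"), (1, 0, 100, 0, 0, "dendrite")],
            "B": [(0, None, 0, 0, 0, "dendrite")],
        }
        links = [("c0", ("A", 0), [("B", 0)]), ("c1", ("A", 1), [("B", 0)])]
        c = build_circuit(nodes, links)
        assert group_synapse_count(c, "A", "B") == 2
        assert group_synapse_count(c, "A", "B", pre_compartment="axon") == 1

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            c = random_circuit(rng)
            pre = {s for s, m in c.metas.items() if m.cell_type == "Mechanosensory"}
            post = {s for s, m in c.metas.items() if m.cell_type == "Basin"}
            oracle = sum(
                1
                for conn in c.connectors.values()
                for p in conn.posts
                if conn.pre[0] in pre and p[0] in post
            )
            assert group_synapse_count(c, pre, post) == oracle


class TestInputFraction:
    def test_simple_fraction(self, two_neuron_circuit):
        f = input_fraction(two_neuron_circuit, "A", "B")
        assert (f.n_from_pre, f.n_total) == (7, 7)

    def test_dendritic_mode_ignores_axonal_totals(self):
        nodes = {
            "S": [(0, None, 0, 0, 0, "axon")],
            "X": [(0, None, 0, 0, 0, "axon")],
            "B": [(0, None, 0, 0, 0, "dendrite"), (1, 0, 10, 0, 0, "axon")],
        }
        links = (
            # 2 seed links onto B's dendrite, 3 other links onto B's axon
            [(f"s{i}", ("S", 0), [("B", 0)]) for i in range(2)]
            + [(f"x{i}", ("X", 0), [("B", 1)]) for i in range(3)]
        )
        c = build_circuit(nodes, links)
        whole = input_fraction(c, "S", "B", "whole")
        dend = input_fraction(c, "S", "B", "dendritic")
        assert whole.fraction == pytest.approx(2 / 5)
        assert (dend.n_from_pre, dend.n_total) == (2, 2)

    def test_zero_total_is_explicit_error(self, two_neuron_circuit):
        with pytest.raises(UndefinedFractionError):
            input_fraction(two_neuron_circuit, "B", "A")  # A receives nothing

    def test_subvolume_mode_equals_whole_on_restricted_circuit(self):
        rng = np.random.default_rng(8)
        c = random_circuit(rng, n_links=80)
        box = Box((-25_000, -25_000, -25_000), (5_000, 25_000, 25_000))
        pre = {s for s, m in c.metas.items() if m.cell_type == "Mechanosensory"}
        post = "s1"
        restricted = restrict_to_subvolume(c, box)
        expected = input_fraction(restricted, pre, post, "whole")
        got = input_fraction(c, pre, post, box)
        assert got == expected

    def test_partition_fractions_sum_to_one(self, wt_circuit):
        """Input fractions over a partition of all presynaptic groups sum to 1."""
        circuit, _ = wt_circuit
        basin = sorted(
            s for s, m in circuit.metas.items() if m.cell_type == "Basin"
        )[0]
        by_type: dict[str, set] = {}
        for sid, m in circuit.metas.items():
            by_type.setdefault(m.cell_type, set()).add(sid)
        total = 0.0
        for members in by_type.values():
            try:
                total += input_fraction(circuit, members, basin).fraction
            except UndefinedFractionError:
                pass
        assert total == pytest.approx(1.0)

    def test_invariant_under_rigid_translation(self, two_neuron_circuit):
        from dataclasses import replace
        from circuitdiff.circuit_model import Circuit, Skeleton

        c = two_neuron_circuit
        shifted = Circuit(
            {
                sid: Skeleton(
                    sid,
                    {
                        nid: replace(n, x=n.x + 9000, y=n.y - 4000)
                        for nid, n in sk.treenodes.items()
                    },
                )
                for sid, sk in c.skeletons.items()
            },
            c.connectors,
            c.metas,
            c.volume,
        )
        assert input_fraction(shifted, "A", "B") == input_fraction(c, "A", "B")


class TestDensityPerCable:
    def test_simple_density(self, two_neuron_circuit):
        # 7 links onto 7 um = 0.007 mm of cable -> 1000 synapses/mm
        assert synapse_density_per_cable(
            two_neuron_circuit, "A", "B"
        ) == pytest.approx(7 / 0.007)

    def test_density_halves_when_coordinates_double(self):
        from dataclasses import replace
        from circuitdiff.circuit_model import Circuit, Skeleton

        rng = np.random.default_rng(31)
        c = random_circuit(rng)
        doubled = Circuit(
            {
                sid: Skeleton(
                    sid,
                    {
                        nid: replace(n, x=2 * n.x, y=2 * n.y, z=2 * n.z)
                        for nid, n in sk.treenodes.items()
                    },
                )
                for sid, sk in c.skeletons.items()
            },
            c.connectors,
            c.metas,
            c.volume,
        )
        pre = {s for s, m in c.metas.items() if m.cell_type == "Mechanosensory"}
        d1 = synapse_density_per_cable(c, pre, "s1")
        d2 = synapse_density_per_cable(doubled, pre, "s1")
        assert d2 == pytest.approx(d1 / 2)

    def test_composition_of_oracles(self):
        rng = np.random.default_rng(32)
        c = random_circuit(rng)
        pre = {s for s, m in c.metas.items() if m.cell_type == "Basin"}
        count = sum(
            1
            for conn in c.connectors.values()
            for p in conn.posts
            if conn.pre[0] in pre and p[0] == "s0"
        )
        cable_mm = cable_length(c.skeletons["s0"]) / 1000.0
        assert synapse_density_per_cable(c, pre, "s0") == pytest.approx(
            count / cable_mm
        )


class TestRankPartners:
    def _circuit_with_counts(self, counts):
        nodes = {"seed": [(i, None if i == 0 else i - 1, 0, 0, 0, "axon")
                          for i in range(40)]}
        links = []
        for name, n in counts.items():
            nodes[name] = [(0, None, 0, 0, 0, "dendrite")]
            for i in range(n):
                links.append((f"{name}_{i}", ("seed", len(links) % 40), [(name, 0)]))
        metas = {sid: ("Mechanosensory" if sid == "seed" else "Partner",
                       "A1", "L", None, True) for sid in nodes}
        return build_circuit(nodes, links, metas)

    def test_threshold_classes(self):
        c = self._circuit_with_counts({"A": 20, "B": 16, "C": 5, "D": 2})
        records = rank_partners(c, "seed")
        assert [r.skeleton_id for r in records] == ["A", "B", "C"]
        assert [r.strength_class for r in records] == ["strong", "strong", "weak"]

    def test_boundary_counts_inclusive(self):
        c = self._circuit_with_counts({"A": 15, "B": 3, "C": 14})
        by_id = {r.skeleton_id: r for r in rank_partners(c, "seed")}
        assert by_id["A"].strength_class == "strong"  # exactly 15 -> strong
        assert by_id["C"].strength_class == "weak"
        assert "B" in by_id  # exactly 3 -> included

    def test_matches_sorted_enumeration_oracle(self):
        rng = np.random.default_rng(41)
        c = random_circuit(rng, n_links=120)
        seed = {s for s, m in c.metas.items() if m.cell_type == "Mechanosensory"}
        oracle: dict[str, int] = {}
        for conn in c.connectors.values():
            for p in conn.posts:
                if conn.pre[0] in seed and p[0] not in seed:
                    oracle[p[0]] = oracle.get(p[0], 0) + 1
        expected = sorted(
            ((s, n) for s, n in oracle.items() if n >= 3),
            key=lambda t: (-t[1], t[0]),
        )
        got = [(r.skeleton_id, r.synapse_count_from_seed) for r in rank_partners(c, seed)]
        assert got == expected


class TestHomologConservation:
    def _toy(self, pairs):
        """pairs: list of (left_count, right_count); partners have homologs."""
        nodes = {
            "seedL": [(i, None if i == 0 else i - 1, 0, 0, 0, "axon") for i in range(30)],
            "seedR": [(i, None if i == 0 else i - 1, 0, 0, 0, "axon") for i in range(30)],
        }
        metas = {
            "seedL": ("Mechanosensory", "A1", "L", "seedR", True),
            "seedR": ("Mechanosensory", "A1", "R", "seedL", True),
        }
        links = []
        for k, (cl, cr) in enumerate(pairs):
            for side, count, seed in (("L", cl, "seedL"), ("R", cr, "seedR")):
                sid = f"p{k}{side}"
                nodes[sid] = [(0, None, 0, 0, 0, "dendrite")]
                metas[sid] = ("Partner", "A1", side, f"p{k}{'R' if side == 'L' else 'L'}", True)
                for i in range(count):
                    links.append((f"{sid}_{i}", (seed, i % 30), [(sid, 0)]))
        return build_circuit(nodes, links, metas)

    def test_fully_conserved_toy(self):
        c = self._toy([(20, 18), (16, 16)])
        results = homolog_conservation(c, "seedL", "seedR", thresholds=[15], min_nodes=1)
        assert results[0].p_mean == 1.0
        assert results[0].n_eligible_left == 2

    def test_unconserved_pairs_lower_probability(self):
        # 2 conserved pairs + 2 left-only pairs at low strength
        c = self._toy([(20, 18), (16, 16), (4, 0), (3, 0)])
        res = {r.threshold: r for r in homolog_conservation(
            c, "seedL", "seedR", thresholds=[1, 15], min_nodes=1)}
        assert res[1].p_left == pytest.approx(2 / 4)
        assert res[1].p_right == pytest.approx(1.0)
        assert res[15].p_mean == 1.0

    def test_min_nodes_monotonicity_and_undefined_flag(self):
        c = self._toy([(20, 18)])
        defined = homolog_conservation(c, "seedL", "seedR", thresholds=[1], min_nodes=1)
        filtered = homolog_conservation(c, "seedL", "seedR", thresholds=[1], min_nodes=500)
        assert defined[0].p_mean == 1.0
        assert filtered[0].undefined  # 1-node partners fail the 500-node filter
        assert filtered[0].n_eligible_left <= defined[0].n_eligible_left


class TestFoldChange:
    def test_values(self):
        assert fold_change(0.02, 0.02) == pytest.approx(1.0)
        assert fold_change(0.03, 0.02) == pytest.approx(1.5)
        assert mean_fold_change([(1.0, 1.0), (1.2, 1.0)])[0] == pytest.approx(1.1)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            fold_change(0.1, 0.0)


class TestCompareVolumes:
    def test_identical_circuits_fold_one_chi_zero(self, wt_circuit):
        circuit, _ = wt_circuit
        me = GroupSpec("Me", "Mechanosensory", "A1", "L")
        basin = sorted(
            s for s, m in circuit.metas.items()
            if m.cell_type == "Basin" and m.side == "L"
        )[0]
        table = compare_volumes(circuit, circuit, [(me, basin, "whole")])
        row = table.iloc[0]
        assert row.fold_change == pytest.approx(1.0)
        assert row.chi2 == pytest.approx(0.0)
        assert row.p_value == pytest.approx(1.0)

    def test_delegates_to_chi_square(self):
        def mk(n_seed, n_other):
            nodes = {
                "S": [(0, None, 0, 0, 0, "axon")],
                "X": [(0, None, 0, 0, 0, "axon")],
                "B": [(0, None, 0, 0, 0, "dendrite")],
            }
            links = [(f"s{i}", ("S", 0), [("B", 0)]) for i in range(n_seed)] + [
                (f"x{i}", ("X", 0), [("B", 0)]) for i in range(n_other)
            ]
            return build_circuit(nodes, links)

        a, b = mk(30, 170), mk(60, 140)
        table = compare_volumes(a, b, [("S", "B", "whole")])
        row = table.iloc[0]
        assert row.fold_change == pytest.approx(2.0)
        oracle = chi_square_proportions([[30, 170], [60, 140]])
        assert row.p_value == pytest.approx(oracle.p_value)

    def test_unresolvable_pairing_flagged_not_crashing(self, wt_circuit):
        circuit, _ = wt_circuit
        table = compare_volumes(
            circuit, circuit, [("nonexistent_neuron", "also_missing", "whole")]
        )
        assert bool(table.iloc[0].flagged)


class TestRetentionStats:
    @staticmethod
    def _records(counts):
        return [
            PartnerRecord(f"w{i}", c, i + 1, "strong" if c >= 15 else "weak")
            for i, c in enumerate(counts)
        ]

    def test_printed_worked_example(self):
        """9 of 37 weak partners lost -> 24%; 1 of 23 strong lost -> 4%."""
        weak = [14 - (i % 12) for i in range(37)]  # counts 3..14
        strong = [15 + i for i in range(23)]
        ranking = self._records(weak + strong)
        matching = {r.skeleton_id: f"e{r.skeleton_id}" for r in ranking}
        exp_counts = {f"e{r.skeleton_id}": r.synapse_count_from_seed for r in ranking}
        # fail 9 weak and 1 strong: counterpart receives zero seed input
        for sid in [f"w{i}" for i in range(9)] + ["w37"]:
            exp_counts[f"e{sid}"] = 0
        summary = retention_stats(ranking, exp_counts, matching)
        assert summary.by_class["weak"].n_total == 37
        assert summary.by_class["weak"].n_unmatched == 9
        assert summary.by_class["weak"].failure_percent == 24
        assert summary.by_class["strong"].n_total == 23
        assert summary.by_class["strong"].n_unmatched == 1
        assert summary.by_class["strong"].failure_percent == 4

    def test_zero_unmatched_is_zero_percent(self):
        ranking = self._records([20, 10, 5])
        matching = {r.skeleton_id: r.skeleton_id for r in ranking}
        exp = {r.skeleton_id: r.synapse_count_from_seed for r in ranking}
        s = retention_stats(ranking, exp, matching)
        assert s.by_class["weak"].failure_percent == 0
        assert s.by_class["strong"].failure_percent == 0

    def test_new_partner_requires_bilateral_reproducibility(self):
        ranking = self._records([20])
        matching = {"w0": "e0"}
        exp_counts = {"e0": 18, "novel": 4, "weak_novel": 2}
        s = retention_stats(
            ranking, exp_counts, matching, exp_bilateral={"novel": True}
        )
        assert s.new_partners == ("novel",)  # weak_novel below 3-synapse threshold
        s2 = retention_stats(
            ranking, exp_counts, matching, exp_bilateral={"novel": False}
        )
        assert s2.new_partners == ()
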