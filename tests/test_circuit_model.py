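"""Circuit data model: I/O round-trips, validation, cable length, clipping."""

import math

import numpy as np
import pytest

from circuitdiff.circuit_model import (
    Box,
    CircuitError,
    Skeleton,
    Treenode,
    cable_length,
    load_circuit,
    node_count,
    restrict_to_subvolume,
    save_circuit,
    write_swc,
)
from circuitdiff.synthetic_data import CircuitDesign, generate_circuit

from conftest import build_circuit, random_circuit


class TestLoadCircuit:
    def test_minimal_swc_file_set(self, tmp_path):
        """A 2-node SWC plus an annotation table loads as a 1-skeleton circuit."""
        (tmp_path / "n1.swc").write_text(
            "# id type x y z radius parent\n1 0 0 0 0 1 -1\n2 3 3000 4000 0 1 1\n"
        )
        (tmp_path / "annotations.csv").write_text(
            "skeleton_id,cell_type,segment,side\nn1,Basin,A1,L\n"
        )
        c = load_circuit([tmp_path / "n1.swc", tmp_path / "annotations.csv"])
        assert len(c.skeletons) == 1 and len(c.connectors) == 0
        assert c.skeletons["n1"].treenodes["2"].compartment == "dendrite"
        assert cable_length(c.skeletons["n1"]) == pytest.approx(5.0)

    def test_dangling_synapse_reference_names_connector(self, tmp_path):
        (tmp_path / "n1.swc").write_text("1 0 0 0 0 1 -1\n")
        (tmp_path / "annotations.csv").write_text(
            "skeleton_id,cell_type,segment,side\nn1,Basin,A1,L\n"
        )
        (tmp_path / "synapses.csv").write_text(
            "connector_id,pre_skeleton,pre_node,post_skeleton,post_node,x,y,z\n"
            "c99,n1,1,n1,42,0,0,0\n"
        )
        with pytest.raises(CircuitError, match="c99"):
            load_circuit(sorted(tmp_path.iterdir()))

    def test_missing_annotation_columns_rejected(self, tmp_path):
        (tmp_path / "n1.swc").write_text("1 0 0 0 0 1 -1\n")
        (tmp_path / "annotations.csv").write_text("skeleton_id,cell_type\nn1,Basin\n")
        with pytest.raises(CircuitError, match="missing columns"):
            load_circuit(sorted(tmp_path.iterdir()))

    def test_json_round_trip_identity(self, tmp_path):
        """write -> read of a generated circuit reproduces it field by field."""
        circuit, _ = generate_circuit(
            CircuitDesign(nodes_roster=15, n_background=3), seed=7
        )
        path = tmp_path / "circuit.json"
        save_circuit(circuit, path)
        loaded = load_circuit(path)
        assert loaded.skeletons.keys() == circuit.skeletons.keys()
        for sid, skel in circuit.skeletons.items():
            assert loaded.skeletons[sid].treenodes == skel.treenodes
        assert loaded.connectors == circuit.connectors
        assert loaded.metas == circuit.metas
        assert loaded.volume == circuit.volume

    def test_swc_round_trip(self, tmp_path):
        circuit, _ = generate_circuit(
            CircuitDesign(nodes_roster=10, n_background=1), seed=3
        )
        skel = next(iter(circuit.skeletons.values()))
        path = tmp_path / f"{skel.skeleton_id}.swc"
        write_swc(skel, path)
        back = load_circuit(
            [path, _annotations_for(tmp_path, skel.skeleton_id)]
        ).skeletons[skel.skeleton_id]
        for nid, n in skel.treenodes.items():
            b = back.treenodes[nid]
            assert (b.parent_id, b.compartment) == (n.parent_id, n.compartment)
            assert math.dist((b.x, b.y, b.z), (n.x, n.y, n.z)) < 1e-2  # 3 decimals in SWC


def _annotations_for(tmp_path, sid):
    p = tmp_path / "annotations.csv"
    p.write_text(f"skeleton_id,cell_type,segment,side\n{sid},other,A1,L\n")
    return p


class TestValidation:
    def test_single_fault_mutations_rejected(self):
        """Each single structural fault is caught: dangling parent, duplicate id,
        cycle, empty posts, dangling connector endpoint, asymmetric homologs."""
        with pytest.raises(CircuitError, match="dangling parent"):
            Skeleton(
                "s", {"1": Treenode("1", "99", 0, 0, 0)}
            ).validate()
        with pytest.raises(CircuitError, match="no root"):
            Skeleton(
                "s",
                {
                    "1": Treenode("1", "2", 0, 0, 0),
                    "2": Treenode("2", "1", 0, 0, 0),
                },
            ).validate()
        with pytest.raises(CircuitError, match="2 roots"):
            Skeleton(
                "s",
                {
                    "1": Treenode("1", None, 0, 0, 0),
                    "2": Treenode("2", None, 0, 0, 0),
                },
            ).validate()
        with pytest.raises(CircuitError, match="empty post"):
            build_circuit(
                {"a": [(0, None, 0, 0, 0, "axon")]},
                links=[("c0", ("a", 0), [])],
            )
        with pytest.raises(CircuitError, match="dangling reference"):
            build_circuit(
                {"a": [(0, None, 0, 0, 0, "axon")]},
                links=[("c0", ("a", 0), [("ghost", 0)])],
            )
        with pytest.raises(CircuitError, match="not symmetric"):
            build_circuit(
                {
                    "a": [(0, None, 0, 0, 0, "axon")],
                    "b": [(0, None, 0, 0, 0, "axon")],
                },
                metas={
                    "a": ("Basin", "A1", "L", "b", True),
                    "b": ("Basin", "A1", "R", None, True),
                },
            )

    def test_generator_output_always_validates(self):
        for seed in range(3):
            circuit, _ = generate_circuit(
                CircuitDesign(nodes_roster=12, n_background=2), seed=seed
            )
            circuit.validate()  # no exception


class TestCableLength:
    def test_three_four_five_triangle(self):
        skel = Skeleton(
            "s",
            {
                "1": Treenode("1", None, 0, 0, 0),
                "2": Treenode("2", "1", 3000, 4000, 0),
            },
        )
        assert cable_length(skel) == pytest.approx(5.0)

    def test_single_node_is_zero(self):
        assert cable_length(Skeleton("s", {"1": Treenode("1", None, 0, 0, 0)})) == 0.0

    def test_matches_edge_sum_oracle_on_random_tree(self):
        rng = np.random.default_rng(11)
        c = random_circuit(rng, n_skeletons=1, n_nodes=50, n_links=0)
        skel = c.skeletons["s0"]
        oracle_nm = sum(
            math.dist(
                (n.x, n.y, n.z),
                (
                    skel.treenodes[n.parent_id].x,
                    skel.treenodes[n.parent_id].y,
                    skel.treenodes[n.parent_id].z,
                ),
            )
            for n in skel
            if n.parent_id is not None
        )
        assert cable_length(skel) == pytest.approx(oracle_nm / 1000.0)

    def test_compartment_lengths_partition_total(self):
        rng = np.random.default_rng(5)
        skel = random_circuit(rng, n_skeletons=1, n_nodes=40, n_links=0).skeletons["s0"]
        parts = sum(cable_length(skel, c) for c in ("axon", "dendrite", "other"))
        assert parts == pytest.approx(cable_length(skel, "all"))


class TestRestrictToSubvolume:
    def test_identity_box_preserves_counts(self):
        rng = np.random.default_rng(2)
        c = random_circuit(rng)
        big = Box((-1e9, -1e9, -1e9), (1e9, 1e9, 1e9))
        r = restrict_to_subvolume(c, big)
        assert sum(map(len, r.skeletons.values())) == sum(
            map(len, c.skeletons.values())
        )
        assert sum(len(x.posts) for x in r.connectors.values()) == sum(
            len(x.posts) for x in c.connectors.values()
        )

    def test_empty_box_empties_circuit(self):
        rng = np.random.default_rng(3)
        c = random_circuit(rng)
        r = restrict_to_subvolume(c, Box((1e8, 1e8, 1e8), (1e9, 1e9, 1e9)))
        assert not r.skeletons and not r.connectors

    def test_half_split_matches_containment_oracle(self):
        rng = np.random.default_rng(4)
        c = random_circuit(rng, n_links=60)
        box = Box((-25_000, -25_000, -25_000), (0, 25_000, 25_000))

        def inside(sid, nid):
            n = c.node(sid, str(nid))
            return box.contains(n.x, n.y, n.z)

        expected = sum(
            1
            for conn in c.connectors.values()
            for post in conn.posts
            if inside(*conn.pre) and inside(*post)
        )
        r = restrict_to_subvolume(c, box)
        assert sum(len(x.posts) for x in r.connectors.values()) == expected

    def test_idempotent_and_node_count_monotone(self):
        rng = np.random.default_rng(6)
        c = random_circuit(rng)
        for _ in range(10):
            lo = rng.uniform(-25_000, 0, 3)
            hi = lo + rng.uniform(0, 50_000, 3)
            box = Box(tuple(lo), tuple(hi))
            once = restrict_to_subvolume(c, box)
            twice = restrict_to_subvolume(once, box)
            assert {s: set(sk.treenodes) for s, sk in once.skeletons.items()} == {
                s: set(sk.treenodes) for s, sk in twice.skeletons.items()
            }
            assert once.connectors == twice.connectors
            for sid, skel in once.skeletons.items():
                assert node_count(skel) <= node_count(c.skeletons[sid])
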