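"""Shared fixtures: hand-built toy circuits and random-circuit builders."""

from __future__ import annotations

import numpy as np
import pytest

from circuitdiff.circuit_model import (
    Box,
    Circuit,
    Connector,
    NeuronMeta,
    Skeleton,
    Treenode,
    VolumeSpec,
)


def build_circuit(nodes, links=(), metas=None, volume=None) -> Circuit:
    """Construct a circuit from plain tuples.

    ``nodes``: {skeleton_id: [(node_id, parent_id|None, x, y, z, compartment), ...]}
    ``links``: [(connector_id, (pre_sid, pre_nid), [(post_sid, post_nid), ...]), ...]
    ``metas``: {skeleton_id: (cell_type, segment, side, homolog_id, identified)}
    """
    skeletons = {
        sid: Skeleton(
            sid,
            {
                str(nid): Treenode(
                    node_id=str(nid),
                    parent_id=None if parent is None else str(parent),
                    x=float(x), y=float(y), z=float(z),
                    compartment=compartment,
                )
                for nid, parent, x, y, z, compartment in rows
            },
        )
        for sid, rows in nodes.items()
    }
    metas = metas or {}
    meta_objs = {}
    for sid in skeletons:
        ct, seg, side, homolog, identified = metas.get(
            sid, ("other", "A1", "L", None, True)
        )
        meta_objs[sid] = NeuronMeta(sid, ct, seg, side, homolog, identified)
    connectors = {
        str(cid): Connector(
            connector_id=str(cid),
            pre=(str(pre[0]), str(pre[1])),
            posts=tuple((str(s), str(n)) for s, n in posts),
        )
        for cid, pre, posts in links
    }
    volume = volume or VolumeSpec(midline_x=0.0, neuropil_width=50_000.0)
    return Circuit(skeletons, connectors, meta_objs, volume).validate()


def random_circuit(rng: np.random.Generator, n_skeletons=8, n_nodes=12, n_links=40):
    """A small random (but always valid) circuit for oracle-equivalence tests."""
    nodes = {}
    for s in range(n_skeletons):
        rows = []
        for i in range(n_nodes):
            parent = None if i == 0 else int(rng.integers(0, i))
            rows.append(
                (
                    i,
                    parent,
                    rng.uniform(-25_000, 25_000),
                    rng.uniform(-25_000, 25_000),
                    rng.uniform(-25_000, 25_000),
                    ["axon", "dendrite", "other"][int(rng.integers(3))],
                )
            )
        nodes[f"s{s}"] = rows
    links = []
    for c in range(n_links):
        pre = (f"s{rng.integers(n_skeletons)}", int(rng.integers(n_nodes)))
        n_posts = int(rng.integers(1, 3))
        posts = set()
        while len(posts) < n_posts:
            posts.add((f"s{rng.integers(n_skeletons)}", int(rng.integers(n_nodes))))
        links.append((f"c{c}", pre, sorted(posts)))
    metas = {
        f"s{s}": (
            ["Mechanosensory", "Basin", "other"][s % 3],
            "A1",
            "L" if s % 2 == 0 else "R",
            None,
            True,
        )
        for s in range(n_skeletons)
    }
    return build_circuit(nodes, links, metas)


def enumerate_links(circuit):
    """Independent link-enumeration oracle: plain nested loops over connectors."""
    out = []
    for conn in circuit.connectors.values():
        for post in conn.posts:
            out.append((conn.pre, post))
    return out


@pytest.fixture
def two_neuron_circuit():
    """Neuron A (axonal) synapsing 7 times onto neuron B (dendritic)."""
    nodes = {
        "A": [(i, None if i == 0 else i - 1, 1000 * i, 0, 0, "axon") for i in range(8)],
        "B": [
            (i, None if i == 0 else i - 1, 1000 * i, 5000, 0, "dendrite")
            for i in range(8)
        ],
    }
    links = [(f"c{i}", ("A", i), [("B", i)]) for i in range(7)]
    metas = {
        "A": ("Mechanosensory", "A1", "L", None, True),
        "B": ("Basin", "A1", "L", None, True),
    }
    return build_circuit(nodes, links, metas)
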