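"""Data model and I/O for skeletonized neural circuits with polyadic synapses.

The in-memory representation mirrors the structure of CATMAID-style EM
reconstructions: each neuron is a rooted tree of 3-D treenodes (coordinates in
nanometres), chemical synapses are polyadic connectors (one presynaptic site,
one or more postsynaptic sites), and biological identity (cell type,
hemisegment, left/right homolog pairing) is carried as annotation rather than
computed from morphology.

Supported formats:

* SWC, one file per skeleton (columns ``id type x y z radius parent``;
  the type column encodes the compartment: 2 = axon, 3 = dendrite,
  anything else = other).
* A synapse table (CSV, one row per pre->post link of a connector) and an
  annotation table (CSV, one row per skeleton).
* A single-document JSON dialect bundling skeletons, connectors, annotations
  and volume geometry; see :func:`save_circuit` for the schema.

All user-facing lengths are reported in micrometres and densities per
millimetre of cable; coordinates are stored in nanometres throughout.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AXON",
    "DENDRITE",
    "OTHER",
    "COMPARTMENTS",
    "Box",
    "CircuitError",
    "Treenode",
    "Skeleton",
    "NeuronMeta",
    "Connector",
    "VolumeSpec",
    "Circuit",
    "load_circuit",
    "save_circuit",
    "write_swc",
    "cable_length",
    "node_count",
    "restrict_to_subvolume",
]

NM_PER_UM = 1_000.0
UM_PER_MM = 1_000.0

AXON = "axon"
DENDRITE = "dendrite"
OTHER = "other"
COMPARTMENTS = (AXON, DENDRITE, OTHER)

# SWC structure-type column <-> compartment label
_SWC_TYPE_TO_COMPARTMENT = {2: AXON, 3: DENDRITE}
_COMPARTMENT_TO_SWC_TYPE = {AXON: 2, DENDRITE: 3, OTHER: 0}


class CircuitError(ValueError):
    """Raised when circuit data violate a structural invariant."""


def _as_id(value) -> str:
    """Normalize an identifier to its string form (JSON keys, SWC ints, ...)."""
    if isinstance(value, float) and value.is_integer():
        value = int(value)
    return str(value)


@dataclass(frozen=True)
class Treenode:
    node_id: str
    parent_id: str | None
    x: float
    y: float
    z: float
    compartment: str = OTHER

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise CircuitError(
                f"treenode {self.node_id}: unknown compartment {self.compartment!r}"
            )
        if not all(math.isfinite(c) for c in (self.x, self.y, self.z)):
            raise CircuitError(f"treenode {self.node_id}: non-finite coordinates")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Skeleton:
    """A neuron skeleton: a tree (or, after subvolume restriction, a forest)."""

    skeleton_id: str
    treenodes: dict[str, Treenode] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.treenodes.values())

    def __len__(self):
        return len(self.treenodes)

    @property
    def roots(self) -> list[Treenode]:
        return [n for n in self if n.parent_id is None]

    def validate(self, single_tree: bool = True) -> None:
        sid = self.skeleton_id
        if not self.treenodes:
            raise CircuitError(f"skeleton {sid}: empty")
        for n in self:
            if n.parent_id is not None and n.parent_id not in self.treenodes:
                raise CircuitError(
                    f"skeleton {sid}: node {n.node_id} has dangling parent {n.parent_id}"
                )
        n_roots = len(self.roots)
        if n_roots == 0:
            raise CircuitError(f"skeleton {sid}: no root (cyclic parent links)")
        if single_tree and n_roots > 1:
            raise CircuitError(f"skeleton {sid}: {n_roots} roots, expected 1")
        # walk parent chains to catch cycles not involving a missing root
        seen_ok: set[str] = set()
        for n in self:
            chain = []
            cur = n
            while cur.node_id not in seen_ok:
                chain.append(cur.node_id)
                if cur.parent_id is None:
                    break
                if cur.parent_id in chain:
                    raise CircuitError(
                        f"skeleton {sid}: cycle through node {cur.parent_id}"
                    )
                cur = self.treenodes[cur.parent_id]
            seen_ok.update(chain)


@dataclass(frozen=True)
class NeuronMeta:
    skeleton_id: str
    cell_type: str
    segment: str
    side: str  # "L", "R", or "bilateral"
    homolog_id: str | None = None
    identified: bool = True


@dataclass(frozen=True)
class Connector:
    """One polyadic chemical synapse: a presynaptic site with >=1 targets."""

    connector_id: str
    pre: tuple[str, str]  # (skeleton_id, node_id)
    posts: tuple[tuple[str, str], ...]
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0

    def __post_init__(self):
        if not self.posts:
            raise CircuitError(f"connector {self.connector_id}: empty post list")
        if len(set(self.posts)) != len(self.posts):
            raise CircuitError(
                f"connector {self.connector_id}: duplicate pre->post pairing"
            )


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in nm, inclusive on both bounds."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self):
        if any(l > h for l, h in zip(self.lo, self.hi)):
            raise CircuitError(f"malformed box: lo {self.lo} exceeds hi {self.hi}")

    def contains(self, x: float, y: float, z: float) -> bool:
        return all(
            l <= c <= h for c, l, h in zip((x, y, z), self.lo, self.hi)
        )

    def to_json(self):
        return [list(self.lo), list(self.hi)]

    @classmethod
    def from_json(cls, obj) -> "Box":
        return cls(tuple(map(float, obj[0])), tuple(map(float, obj[1])))


@dataclass(frozen=True)
class VolumeSpec:
    """Geometry of the imaged volume.

    ``midline_x`` and ``neuropil_width`` (nm) define the mediolateral
    normalization used by the density profiles; by convention the mediolateral
    axis is x, anteroposterior y, dorsoventral z (``ml_axis`` is configurable
    for data that follow a different convention).
    """

    midline_x: float
    neuropil_width: float
    bounds: Box | None = None
    subvolume: Box | None = None
    ml_axis: int = 0

    def __post_init__(self):
        if self.neuropil_width <= 0:
            raise CircuitError("neuropil_width must be > 0")
        if (
            self.subvolume is not None
            and self.bounds is not None
            and not (
                all(b <= s for b, s in zip(self.bounds.lo, self.subvolume.lo))
                and all(s <= b for s, b in zip(self.subvolume.hi, self.bounds.hi))
            )
        ):
            raise CircuitError("subvolume not contained in bounds")


@dataclass
class Circuit:
    skeletons: dict[str, Skeleton]
    connectors: dict[str, Connector]
    metas: dict[str, NeuronMeta]
    volume: VolumeSpec

    def validate(self, single_tree: bool = True) -> "Circuit":
        for skel in self.skeletons.values():
            skel.validate(single_tree=single_tree)
        for sid in self.skeletons:
            if sid not in self.metas:
                raise CircuitError(f"skeleton {sid}: no annotation record")
        for sid, meta in self.metas.items():
            if meta.homolog_id is not None:
                if meta.homolog_id == sid:
                    raise CircuitError(f"skeleton {sid}: pairs itself as homolog")
                partner = self.metas.get(meta.homolog_id)
                if partner is not None and partner.homolog_id != sid:
                    raise CircuitError(
                        f"skeleton {sid}: homolog pairing with {meta.homolog_id} "
                        "is not symmetric"
                    )
        for conn in self.connectors.values():
            for sid, nid in (conn.pre, *conn.posts):
                skel = self.skeletons.get(sid)
                if skel is None or nid not in skel.treenodes:
                    raise CircuitError(
                        f"connector {conn.connector_id}: dangling reference "
                        f"to node {nid} of skeleton {sid}"
                    )
        return self

    def links(self) -> Iterable[tuple[Connector, tuple[str, str], tuple[str, str]]]:
        """Iterate (connector, pre, post) over every pre->post synaptic link."""
        for conn in self.connectors.values():
            for post in conn.posts:
                yield conn, conn.pre, post

    def node(self, sid: str, nid: str) -> Treenode:
        return self.skeletons[sid].treenodes[nid]


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def cable_length(skeleton: Skeleton, compartment: str = "all") -> float:
    """Summed Euclidean parent-edge length in micrometres.

    Each parent->child edge is attributed to the *child* node's compartment;
    with ``compartment="all"`` every edge is counted, so the per-compartment
    lengths partition the total.
    """
    total_nm = 0.0
    for n in skeleton:
        if n.parent_id is None:
            continue
        if compartment != "all" and n.compartment != compartment:
            continue
        p = skeleton.treenodes[n.parent_id]
        total_nm += math.dist((n.x, n.y, n.z), (p.x, p.y, p.z))
    return total_nm / NM_PER_UM


def node_count(skeleton: Skeleton) -> int:
    """Number of treenodes in the skeleton (the reconstruction-size filter unit)."""
    return len(skeleton)


def restrict_to_subvolume(circuit: Circuit, box: Box) -> Circuit:
    """Clip a circuit to an axis-aligned box.

    Treenodes outside the box are removed (surviving children of removed
    parents become new roots, so restricted skeletons may be forests).
    A connector loses any pre->post link whose post node was removed, and is
    dropped entirely if its presynaptic node was removed or no links survive.
    Skeletons left empty are dropped along with their annotations.
    """
    skeletons: dict[str, Skeleton] = {}
    for sid, skel in circuit.skeletons.items():
        kept = {
            nid: n for nid, n in skel.treenodes.items() if box.contains(n.x, n.y, n.z)
        }
        if not kept:
            continue
        nodes = {
            nid: (
                n
                if n.parent_id is None or n.parent_id in kept
                else replace(n, parent_id=None)
            )
            for nid, n in kept.items()
        }
        skeletons[sid] = Skeleton(sid, nodes)

    def alive(endpoint: tuple[str, str]) -> bool:
        sid, nid = endpoint
        return sid in skeletons and nid in skeletons[sid].treenodes

    connectors: dict[str, Connector] = {}
    for conn in circuit.connectors.values():
        if not alive(conn.pre):
            continue
        posts = tuple(p for p in conn.posts if alive(p))
        if posts:
            connectors[conn.connector_id] = replace(conn, posts=posts)

    metas = {sid: m for sid, m in circuit.metas.items() if sid in skeletons}
    return Circuit(skeletons, connectors, metas, circuit.volume)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

SYNAPSE_COLUMNS = [
    "connector_id",
    "pre_skeleton",
    "pre_node",
    "post_skeleton",
    "post_node",
    "x",
    "y",
    "z",
]
ANNOTATION_COLUMNS = ["skeleton_id", "cell_type", "segment", "side"]


def _read_swc(path: Path) -> Skeleton:
    sid = path.stem
    nodes: dict[str, Treenode] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise CircuitError(f"{path}:{lineno}: expected 7 SWC columns")
            nid, swc_type, x, y, z, _radius, parent = parts
            nid = _as_id(nid)
            if nid in nodes:
                raise CircuitError(f"{path}:{lineno}: duplicate node id {nid}")
            nodes[nid] = Treenode(
                node_id=nid,
                parent_id=None if parent == "-1" else _as_id(parent),
                x=float(x),
                y=float(y),
                z=float(z),
                compartment=_SWC_TYPE_TO_COMPARTMENT.get(int(swc_type), OTHER),
            )
    return Skeleton(sid, nodes)


def write_swc(skeleton: Skeleton, path: str | os.PathLike) -> None:
    """Write one skeleton as SWC (coordinates in nm, radius fixed at 0)."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in skeleton:
            fh.write(
                f"{n.node_id} {_COMPARTMENT_TO_SWC_TYPE[n.compartment]} "
                f"{n.x:.3f} {n.y:.3f} {n.z:.3f} 0 "
                f"{n.parent_id if n.parent_id is not None else -1}\n"
            )


def _require_columns(df: pd.DataFrame, needed: Sequence[str], what: str) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise CircuitError(f"{what}: missing columns {missing}")


def _connectors_from_table(df: pd.DataFrame) -> dict[str, Connector]:
    _require_columns(df, SYNAPSE_COLUMNS[:5], "synapse table")
    connectors: dict[str, Connector] = {}
    for cid, grp in df.groupby("connector_id", sort=False):
        cid = _as_id(cid)
        pres = {( _as_id(r.pre_skeleton), _as_id(r.pre_node)) for r in grp.itertuples()}
        if len(pres) != 1:
            raise CircuitError(f"connector {cid}: multiple presynaptic nodes")
        posts = tuple(
            (_as_id(r.post_skeleton), _as_id(r.post_node)) for r in grp.itertuples()
        )
        first = grp.iloc[0]
        connectors[cid] = Connector(
            connector_id=cid,
            pre=next(iter(pres)),
            posts=posts,
            x=float(first.get("x", 0.0)),
            y=float(first.get("y", 0.0)),
            z=float(first.get("z", 0.0)),
        )
    return connectors


def _metas_from_table(df: pd.DataFrame) -> dict[str, NeuronMeta]:
    _require_columns(df, ANNOTATION_COLUMNS, "annotation table")
    metas = {}
    for r in df.itertuples():
        sid = _as_id(r.skeleton_id)
        homolog = getattr(r, "homolog_id", None)
        if homolog is not None and (pd.isna(homolog) or homolog == ""):
            homolog = None
        identified = getattr(r, "identified", True)
        metas[sid] = NeuronMeta(
            skeleton_id=sid,
            cell_type=str(r.cell_type),
            segment=str(r.segment),
            side=str(r.side),
            homolog_id=None if homolog is None else _as_id(homolog),
            identified=bool(identified),
        )
    return metas


_DEFAULT_VOLUME = VolumeSpec(midline_x=0.0, neuropil_width=50_000.0)


def load_circuit(paths: str | os.PathLike | Iterable[str | os.PathLike]) -> Circuit:
    """Load and validate a circuit from a file set or a single JSON document.

    ``paths`` may be one JSON file in the circuitdiff dialect, or a mix of
    SWC files (one per skeleton), one synapse CSV, one annotation CSV, and
    optionally a JSON volume spec (``{"midline_x": ..., "neuropil_width": ...}``).
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    if len(paths) == 1 and paths[0].suffix == ".json":
        return _circuit_from_json(json.loads(paths[0].read_text()))

    skeletons: dict[str, Skeleton] = {}
    synapse_df = None
    annotation_df = None
    volume = _DEFAULT_VOLUME
    for p in paths:
        if p.suffix == ".swc":
            skel = _read_swc(p)
            if skel.skeleton_id in skeletons:
                raise CircuitError(f"duplicate skeleton id {skel.skeleton_id}")
            skeletons[skel.skeleton_id] = skel
        elif p.suffix == ".csv":
            df = pd.read_csv(p)
            if "connector_id" in df.columns:
                synapse_df = df
            else:
                annotation_df = df
        elif p.suffix == ".json":
            vol = json.loads(p.read_text())
            volume = _volume_from_json(vol)
        else:
            raise CircuitError(f"unrecognized circuit file {p}")
    if annotation_df is None:
        raise CircuitError("no annotation table in file set")
    connectors = (
        _connectors_from_table(synapse_df) if synapse_df is not None and len(synapse_df) else {}
    )
    circuit = Circuit(
        skeletons=skeletons,
        connectors=connectors,
        metas=_metas_from_table(annotation_df),
        volume=volume,
    )
    return circuit.validate()


def _volume_to_json(v: VolumeSpec):
    return {
        "midline_x": v.midline_x,
        "neuropil_width": v.neuropil_width,
        "bounds": v.bounds.to_json() if v.bounds else None,
        "subvolume": v.subvolume.to_json() if v.subvolume else None,
        "ml_axis": v.ml_axis,
    }


def _volume_from_json(obj: Mapping) -> VolumeSpec:
    return VolumeSpec(
        midline_x=float(obj["midline_x"]),
        neuropil_width=float(obj["neuropil_width"]),
        bounds=Box.from_json(obj["bounds"]) if obj.get("bounds") else None,
        subvolume=Box.from_json(obj["subvolume"]) if obj.get("subvolume") else None,
        ml_axis=int(obj.get("ml_axis", 0)),
    )


def save_circuit(circuit: Circuit, path: str | os.PathLike) -> None:
    """Write a circuit as one JSON document.

    Schema::

        {
          "volume":    {"midline_x", "neuropil_width", "bounds", "subvolume", "ml_axis"},
          "skeletons": {sid: [[node_id, parent_id|null, x, y, z, compartment], ...]},
          "metas":     {sid: {"cell_type", "segment", "side", "homolog_id", "identified"}},
          "connectors": [{"connector_id", "pre": [sid, nid],
                          "posts": [[sid, nid], ...], "x", "y", "z"}]
        }
    """
    doc = {
        "volume": _volume_to_json(circuit.volume),
        "skeletons": {
            sid: [
                [n.node_id, n.parent_id, n.x, n.y, n.z, n.compartment]
                for n in skel
            ]
            for sid, skel in circuit.skeletons.items()
        },
        "metas": {
            sid: {
                "cell_type": m.cell_type,
                "segment": m.segment,
                "side": m.side,
                "homolog_id": m.homolog_id,
                "identified": m.identified,
            }
            for sid, m in circuit.metas.items()
        },
        "connectors": [
            {
                "connector_id": c.connector_id,
                "pre": list(c.pre),
                "posts": [list(p) for p in c.posts],
                "x": c.x,
                "y": c.y,
                "z": c.z,
            }
            for c in circuit.connectors.values()
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def _circuit_from_json(doc: Mapping) -> Circuit:
    skeletons = {}
    for sid, rows in doc["skeletons"].items():
        sid = _as_id(sid)
        nodes = {}
        for nid, parent, x, y, z, compartment in rows:
            nid = _as_id(nid)
            if nid in nodes:
                raise CircuitError(f"skeleton {sid}: duplicate node id {nid}")
            nodes[nid] = Treenode(
                node_id=nid,
                parent_id=None if parent is None else _as_id(parent),
                x=float(x),
                y=float(y),
                z=float(z),
                compartment=compartment,
            )
        skeletons[sid] = Skeleton(sid, nodes)
    metas = {
        _as_id(sid): NeuronMeta(
            skeleton_id=_as_id(sid),
            cell_type=m["cell_type"],
            segment=m["segment"],
            side=m["side"],
            homolog_id=None if m.get("homolog_id") is None else _as_id(m["homolog_id"]),
            identified=bool(m.get("identified", True)),
        )
        for sid, m in doc["metas"].items()
    }
    connectors = {}
    for c in doc["connectors"]:
        cid = _as_id(c["connector_id"])
        connectors[cid] = Connector(
            connector_id=cid,
            pre=(_as_id(c["pre"][0]), _as_id(c["pre"][1])),
            posts=tuple((_as_id(s), _as_id(n)) for s, n in c["posts"]),
            x=float(c.get("x", 0.0)),
            y=float(c.get("y", 0.0)),
            z=float(c.get("z", 0.0)),
        )
    circuit = Circuit(
        skeletons=skeletons,
        connectors=connectors,
        metas=metas,
        volume=_volume_from_json(doc["volume"]),
    )
    return circuit.validate()
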