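"""Seeded generators for circuits, calcium trials and behavior tracks.

These emulate the statistical structure the analysis stages assume, with the
designed parameters recorded as ground truth so every stage can be tested by
parameter recovery:

* bilaterally mirrored hemisegmental circuits with the study's cell-type
  roster (8 mechanosensory axons, 4 Basins, 6 bilateral Ladders, 1 Griddle,
  1 Drunken, 3 nociceptive axons per hemisegment), input compositions drawn
  multinomially from a designed fraction matrix, and a homolog-pair partner
  pool whose left/right connection conservation follows designed per-strength
  probabilities;
* lateral-shift (guidance-receptor-style displacement toward the neuropil
  edge) and silencing-style rewiring perturbations (gain multipliers on
  connection fractions at the expense of background input, so totals are
  preserved);
* stimulus-locked calcium trials (baseline + Gaussian noise + exponential
  transient at stimulation offset, 6.61 frames/s, 30 s rest / brief stimulus /
  30 s rest protocol);
* behavior cohorts with Bernoulli responses at designed probabilities, bouts
  in the analysis window, and injected tracking gaps and collisions.

Skeleton geometry is deliberately schematic (random trees around a
mediolateral placement centroid): the analysis uses only positions and cable
length, never arbor shape. All generators are pure functions of
(config, seed); random streams are split per entity so subsets reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .circuit_model import (
    AXON,
    DENDRITE,
    OTHER,
    Box,
    Circuit,
    CircuitError,
    Connector,
    NeuronMeta,
    Skeleton,
    Treenode,
    VolumeSpec,
)

__all__ = [
    "DEFAULT_ROSTER",
    "DEFAULT_CONSERVATION",
    "CircuitDesign",
    "PerturbationSpec",
    "CalciumSimConfig",
    "BehaviorSimConfig",
    "CircuitGroundTruth",
    "generate_circuit",
    "apply_perturbation",
    "simulate_calcium",
    "simulate_behavior",
]

# per-hemisegment roster; Ladder is bilateral (6 per segment, serving both sides)
DEFAULT_ROSTER: dict[str, int] = {
    "Mechanosensory": 8,
    "Basin": 4,
    "Ladder": 6,
    "Griddle": 1,
    "Drunken": 1,
    "Nociceptive": 3,
}
BILATERAL_TYPES = frozenset({"Ladder"})
SENSORY_TYPES = frozenset({"Mechanosensory", "Nociceptive"})

# P(homolog connected with >=1 synapse | connected with count in bin)
DEFAULT_CONSERVATION: dict[tuple[int, int | None], float] = {
    (1, 5): 0.75,
    (5, 10): 0.89,
    (10, 15): 0.97,
    (15, None): 1.00,
}

DEFAULT_FRACTIONS: dict[tuple[str, str], float] = {
    ("Mechanosensory", "Basin"): 0.20,
    ("Nociceptive", "Basin"): 0.10,
    ("Ladder", "Basin"): 0.05,
    ("Mechanosensory", "Ladder"): 0.15,
    ("Mechanosensory", "Griddle"): 0.15,
    ("Mechanosensory", "Drunken"): 0.12,
}

DEFAULT_TOTAL_INPUTS: dict[str, int] = {
    "Basin": 400,
    "Ladder": 300,
    "Griddle": 200,
    "Drunken": 200,
}

# mediolateral placement: |x - midline| mean and SD in nm
DEFAULT_PLACEMENT: dict[str, tuple[float, float]] = {
    "Mechanosensory": (12_000.0, 1_500.0),
    "Nociceptive": (5_000.0, 1_500.0),
    "Basin": (8_000.0, 2_000.0),
    "Ladder": (6_000.0, 2_000.0),
    "Griddle": (10_000.0, 2_000.0),
    "Drunken": (10_000.0, 2_000.0),
    "other": (10_000.0, 4_000.0),
}


@dataclass(frozen=True)
class CircuitDesign:
    segments: tuple[str, ...] = ("A1",)
    roster: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_ROSTER))
    fraction_matrix: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    total_inputs: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TOTAL_INPUTS)
    )
    conservation: Mapping[tuple[int, int | None], float] = field(
        default_factory=lambda: dict(DEFAULT_CONSERVATION)
    )
    placement: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PLACEMENT)
    )
    n_background: int = 10  # unlabeled input-pool neurons per hemisegment
    n_conservation_pairs: int = 0  # homolog partner pairs in the conservation pool
    conservation_bin: tuple[int, int | None] | None = None  # restrict pool to one bin
    nodes_roster: int = 60
    nodes_partner: int = 500  # partner-pool size passes the 500-node filter
    neuropil_width_nm: float = 50_000.0
    midline_x_nm: float = 0.0

    def validate(self) -> "CircuitDesign":
        post_sums: dict[str, float] = {}
        for (pre, post), f in self.fraction_matrix.items():
            if not 0.0 <= f <= 1.0:
                raise CircuitError(f"fraction {pre}->{post} out of [0,1]: {f}")
            weight = 2.0 if post in BILATERAL_TYPES else 1.0
            post_sums[post] = post_sums.get(post, 0.0) + weight * f
        for post, s in post_sums.items():
            if s > 1.0 + 1e-9:
                raise CircuitError(f"designed fractions onto {post} sum to {s} > 1")
        for p in self.conservation.values():
            if not 0.0 <= p <= 1.0:
                raise CircuitError(f"conservation probability out of [0,1]: {p}")
        return self


@dataclass(frozen=True)
class ConservationDraw:
    left_id: str
    right_id: str
    bin: tuple[int, int | None]
    left_count: int  # 0 when the left member is unconnected
    right_count: int


@dataclass(frozen=True)
class CircuitGroundTruth:
    design: CircuitDesign
    realized_counts: dict[tuple[str, str], int]  # (pre group label, post id) -> links
    conservation_draws: tuple[ConservationDraw, ...]


@dataclass(frozen=True)
class PerturbationSpec:
    kind: str  # "lateral_shift" | "silencing_rewire"
    target_cell_type: str = "Mechanosensory"
    shift_mean_nm: float = 10_000.0
    shift_jitter_nm: float = 2_000.0
    gain: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def validate(self) -> "PerturbationSpec":
        if self.kind not in ("lateral_shift", "silencing_rewire"):
            raise CircuitError(f"unknown perturbation kind {self.kind!r}")
        if any(g < 0 for g in self.gain.values()):
            raise CircuitError("gains must be non-negative")
        return self


@dataclass(frozen=True)
class CalciumSimConfig:
    n_animals: int = 10
    trials_per_animal: int = 3
    f0: float = 100.0
    noise_sd: float = 2.0
    amplitude: float = 80.0  # transient amplitude in raw fluorescence units
    tau_s: float = 2.0
    frame_rate: float = 6.61
    rest_s: float = 30.0
    stim_duration_s: float = 0.1
    modality: str = "mechanosensory"


@dataclass(frozen=True)
class BehaviorSimConfig:
    n_animals: int = 100
    design_probability: float = 0.3
    behavior: str = "hunch"
    window_onset_s: float = 30.0
    window_length_s: float = 15.0
    bout_duration_mean_s: float = 2.0
    bout_duration_sd_s: float = 0.5
    gap_rate: float = 0.05  # fraction of animals with a coverage-breaking gap
    collision_rate: float = 0.05
    track_length_s: float = 75.0
    group: str = "experimental"


# ---------------------------------------------------------------------------
# circuit generation
# ---------------------------------------------------------------------------

def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _random_tree(
    rng: np.random.Generator,
    n_nodes: int,
    centroid: np.ndarray,
    step_nm: float = 600.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk tree: (positions (n,3), parent index array; -1 for root)."""
    pos = np.empty((n_nodes, 3))
    parents = np.full(n_nodes, -1, dtype=int)
    pos[0] = centroid
    if n_nodes > 1:
        parent_choice = rng.integers(0, np.arange(1, n_nodes))
        steps = rng.normal(0.0, step_nm, size=(n_nodes - 1, 3))
        for i in range(1, n_nodes):
            parents[i] = parent_choice[i - 1]
            pos[i] = pos[parents[i]] + steps[i - 1]
    return pos, parents


def _make_skeleton(
    rng: np.random.Generator,
    sid: str,
    cell_type: str,
    n_nodes: int,
    centroid: np.ndarray,
) -> Skeleton:
    pos, parents = _random_tree(rng, n_nodes, centroid)
    if cell_type in SENSORY_TYPES:
        compartments = [AXON] * n_nodes
    else:
        compartments = list(
            rng.choice([DENDRITE, AXON], size=n_nodes, p=[0.6, 0.4])
        )
        compartments[0] = OTHER
    nodes = {}
    for i in range(n_nodes):
        nid = f"n{i}"
        nodes[nid] = Treenode(
            node_id=nid,
            parent_id=None if parents[i] < 0 else f"n{parents[i]}",
            x=float(pos[i, 0]),
            y=float(pos[i, 1]),
            z=float(pos[i, 2]),
            compartment=compartments[i],
        )
    return Skeleton(sid, nodes)


def _centroid(
    rng: np.random.Generator,
    design: CircuitDesign,
    cell_type: str,
    side: str,
    seg_index: int,
) -> np.ndarray:
    mean, sd = design.placement.get(cell_type, design.placement["other"])
    sign = {"L": -1.0, "R": 1.0, "bilateral": 0.0}[side]
    if side == "bilateral":
        x = design.midline_x_nm + rng.normal(0.0, sd)
    else:
        x = design.midline_x_nm + sign * abs(rng.normal(mean, sd))
    y = seg_index * 30_000.0 + rng.normal(0.0, 5_000.0)
    z = rng.normal(0.0, 5_000.0)
    return np.array([x, y, z])


def _bin_of(count: int, bins) -> tuple[int, int | None] | None:
    for (lo, hi) in bins:
        if count >= lo and (hi is None or count < hi):
            return (lo, hi)
    return None


class _ConnectorFactory:
    """Builds polyadic connectors: links sharing a presynaptic node join an
    open connector at that node (up to a polyadicity cap, as one release site
    contacts a handful of targets); otherwise a new connector opens there."""

    MAX_POSTS = 4

    def __init__(self, circuit_nodes: dict[str, Skeleton]):
        self.skeletons = circuit_nodes
        self.by_pre: dict[tuple[str, str], list[list]] = {}

    def add_link(self, pre: tuple[str, str], post: tuple[str, str], rng) -> None:
        entries = self.by_pre.setdefault(pre, [])
        for posts in entries:
            # a pre->post pairing appears at most once within one connector
            if len(posts) < self.MAX_POSTS and post not in posts:
                posts.append(post)
                return
        entries.append([post])

    def build(self) -> dict[str, Connector]:
        connectors = {}
        i = 0
        for pre, entries in sorted(self.by_pre.items()):
            pre_node = self.skeletons[pre[0]].treenodes[pre[1]]
            for posts in entries:
                post_node = self.skeletons[posts[0][0]].treenodes[posts[0][1]]
                # connector sits at the pre/first-post node midpoint
                mid = (pre_node.xyz + post_node.xyz) / 2.0
                connectors[f"c{i}"] = Connector(
                    connector_id=f"c{i}",
                    pre=pre,
                    posts=tuple(posts),
                    x=float(mid[0]),
                    y=float(mid[1]),
                    z=float(mid[2]),
                )
                i += 1
        return connectors


def _nodes_of_compartment(skel: Skeleton, compartment: str) -> list[str]:
    nids = [n.node_id for n in skel if n.compartment == compartment]
    return nids or list(skel.treenodes)


def generate_circuit(
    design: CircuitDesign, seed: int = 0
) -> tuple[Circuit, CircuitGroundTruth]:
    """Generate a bilaterally mirrored circuit realizing the design.

    Per hemisegment the roster neurons are instantiated with mirrored homolog
    annotations; each postsynaptic neuron's input composition is drawn
    multinomially over the designed presynaptic fractions (the remainder comes
    from an unlabeled background pool), so measured input fractions estimate
    the design at the designed totals. When ``n_conservation_pairs`` > 0 a
    pool of identified homolog partner pairs downstream of the mechanosensory
    group is added; each pair's left/right connection presence is drawn so
    that the probability the contralateral homolog is connected, given a
    connection with strength in a bin, equals the designed conservation
    probability for that bin.
    """
    design.validate()
    master = _rng_for(seed, 0)
    skeletons: dict[str, Skeleton] = {}
    metas: dict[str, NeuronMeta] = {}
    groups: dict[tuple[str, str, str], list[str]] = {}  # (cell_type, segment, side)

    entity = 0
    for si, seg in enumerate(design.segments):
        for cell_type, count in design.roster.items():
            sides = ("bilateral",) if cell_type in BILATERAL_TYPES else ("L", "R")
            for side in sides:
                for k in range(count):
                    sid = f"{seg}_{side}_{cell_type}_{k}"
                    rng = _rng_for(seed, 1, entity)
                    entity += 1
                    skeletons[sid] = _make_skeleton(
                        rng,
                        sid,
                        cell_type,
                        design.nodes_roster,
                        _centroid(rng, design, cell_type, side, si),
                    )
                    if side == "bilateral":
                        homolog = f"{seg}_{side}_{cell_type}_{k + 1 if k % 2 == 0 else k - 1}"
                        if int(homolog.rsplit("_", 1)[1]) >= count:
                            homolog = None
                    else:
                        homolog = f"{seg}_{'R' if side == 'L' else 'L'}_{cell_type}_{k}"
                    metas[sid] = NeuronMeta(
                        skeleton_id=sid,
                        cell_type=cell_type,
                        segment=seg,
                        side=side,
                        homolog_id=homolog,
                        identified=True,
                    )
                    for s in ("L", "R") if side == "bilateral" else (side,):
                        groups.setdefault((cell_type, seg, s), []).append(sid)
        # unlabeled background input pool
        for side in ("L", "R"):
            for k in range(design.n_background):
                sid = f"{seg}_{side}_bg_{k}"
                rng = _rng_for(seed, 1, entity)
                entity += 1
                skeletons[sid] = _make_skeleton(
                    rng, sid, "other", design.nodes_roster,
                    _centroid(rng, design, "other", side, si),
                )
                metas[sid] = NeuronMeta(
                    skeleton_id=sid,
                    cell_type="other",
                    segment=seg,
                    side=side,
                    homolog_id=f"{seg}_{'R' if side == 'L' else 'L'}_bg_{k}",
                    identified=False,
                )
                groups.setdefault(("other", seg, side), []).append(sid)

    factory = _ConnectorFactory(skeletons)
    realized: dict[tuple[str, str], int] = {}

    def add_links(rng, pre_members: Sequence[str], post_sid: str, n_links: int, label: str):
        realized[(label, post_sid)] = realized.get((label, post_sid), 0) + n_links
        post_skel = skeletons[post_sid]
        post_nodes = (
            _nodes_of_compartment(post_skel, DENDRITE)
            if metas[post_sid].cell_type not in SENSORY_TYPES
            else list(post_skel.treenodes)
        )
        for _ in range(n_links):
            pre_sid = pre_members[rng.integers(len(pre_members))]
            pre_nodes = _nodes_of_compartment(skeletons[pre_sid], AXON)
            pre_nid = pre_nodes[rng.integers(len(pre_nodes))]
            post_nid = post_nodes[rng.integers(len(post_nodes))]
            factory.add_link((pre_sid, pre_nid), (post_sid, post_nid), rng)

    # roster input composition: multinomial over designed fractions
    for si, seg in enumerate(design.segments):
        for post_type, total in design.total_inputs.items():
            if post_type not in design.roster:
                continue
            pre_entries = [
                (pre_type, f)
                for (pre_type, pt), f in design.fraction_matrix.items()
                if pt == post_type
            ]
            post_sides = (
                ("bilateral",) if post_type in BILATERAL_TYPES else ("L", "R")
            )
            for post_side in post_sides:
                post_ids = [
                    sid
                    for sid, m in metas.items()
                    if m.cell_type == post_type and m.segment == seg and m.side == post_side
                ]
                for post_sid in post_ids:
                    rng = _rng_for(seed, 2, entity)
                    entity += 1
                    # bilateral posts draw the designed fraction from each side's pre group
                    sources = []
                    for pre_type, f in pre_entries:
                        for s in ("L", "R") if post_side == "bilateral" else (post_side,):
                            members = groups.get((pre_type, seg, s), [])
                            if members:
                                sources.append((f"{pre_type}_{s}", members, f))
                    probs = [f for (_, _, f) in sources]
                    bg_sides = ("L", "R") if post_side == "bilateral" else (post_side,)
                    bg_members = [
                        m for s in bg_sides for m in groups.get(("other", seg, s), [])
                    ]
                    probs.append(max(0.0, 1.0 - sum(probs)))
                    counts = rng.multinomial(total, probs)
                    for (label, members, _f), n in zip(sources, counts[:-1]):
                        add_links(rng, members, post_sid, int(n), label)
                    if counts[-1] and bg_members:
                        add_links(rng, bg_members, post_sid, int(counts[-1]), "background")

    # conservation pool: homolog partner pairs downstream of the mechanosensory group
    draws: list[ConservationDraw] = []
    if design.n_conservation_pairs:
        seg = design.segments[0]
        bins = list(design.conservation.keys())
        seeds = {s: groups[("Mechanosensory", seg, s)] for s in ("L", "R")}
        for k in range(design.n_conservation_pairs):
            rng = _rng_for(seed, 3, k)
            b = (
                design.conservation_bin
                if design.conservation_bin is not None
                else bins[rng.integers(len(bins))]
            )
            p = design.conservation[b]
            lo, hi = b
            hi_draw = (hi - 1) if hi is not None else lo + 5

            def draw_count() -> int:
                return int(rng.integers(lo, hi_draw + 1))

            # symmetric construction: P(both)=p/(2-p), P(one side only)=(1-p)/(2-p)
            # each, so P(conserved | connected on either side) = p exactly
            both = rng.random() < p / (2.0 - p)
            left_on = both or rng.random() < 0.5
            right_on = both or not left_on
            pair_ids = []
            for side, on in (("L", left_on), ("R", right_on)):
                sid = f"{seg}_{side}_partner_{k}"
                pair_ids.append(sid)
                skeletons[sid] = _make_skeleton(
                    rng, sid, "LocalPartner", design.nodes_partner,
                    _centroid(rng, design, "other", side, 0),
                )
            left_id, right_id = pair_ids
            metas[left_id] = NeuronMeta(left_id, "LocalPartner", seg, "L", right_id, True)
            metas[right_id] = NeuronMeta(right_id, "LocalPartner", seg, "R", left_id, True)
            c_l = draw_count() if left_on else 0
            c_r = draw_count() if right_on else 0
            if c_l:
                add_links(rng, seeds["L"], left_id, c_l, "Mechanosensory_L")
            if c_r:
                add_links(rng, seeds["R"], right_id, c_r, "Mechanosensory_R")
            draws.append(ConservationDraw(left_id, right_id, b, c_l, c_r))

    half = design.neuropil_width_nm / 2.0
    volume = VolumeSpec(
        midline_x=design.midline_x_nm,
        neuropil_width=design.neuropil_width_nm,
        bounds=Box(
            (design.midline_x_nm - half, -1e7, -1e7),
            (design.midline_x_nm + half, 1e7, 1e7),
        ),
    )
    circuit = Circuit(skeletons, factory.build(), metas, volume).validate()
    truth = CircuitGroundTruth(
        design=design,
        realized_counts=realized,
        conservation_draws=tuple(draws),
    )
    return circuit, truth


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def apply_perturbation(
    circuit: Circuit, spec: PerturbationSpec, seed: int = 0
) -> Circuit:
    """Return a perturbed copy of the circuit (annotations preserved).

    ``lateral_shift`` translates each target neuron's treenodes -- and the
    connectors it is presynaptic at -- laterally away from the midline by a
    per-axon offset (mean + Gaussian jitter). ``silencing_rewire`` rescales
    each designed connection by its gain multiplier at the expense of the
    unlabeled background input, keeping every target's total input count
    unchanged (the homeostatic reallocation the silencing experiments show).
    """
    spec.validate()
    if spec.kind == "lateral_shift":
        return _lateral_shift(circuit, spec, seed)
    return _silencing_rewire(circuit, spec, seed)


def _lateral_shift(circuit: Circuit, spec: PerturbationSpec, seed: int) -> Circuit:
    midline = circuit.volume.midline_x
    offsets: dict[str, float] = {}
    for i, (sid, meta) in enumerate(sorted(circuit.metas.items())):
        if meta.cell_type != spec.target_cell_type:
            continue
        rng = _rng_for(seed, 10, i)
        centroid_x = float(np.mean([n.x for n in circuit.skeletons[sid]]))
        sign = 1.0 if centroid_x >= midline else -1.0
        offsets[sid] = sign * (
            spec.shift_mean_nm + spec.shift_jitter_nm * rng.standard_normal()
        )
    skeletons = {}
    for sid, skel in circuit.skeletons.items():
        dx = offsets.get(sid, 0.0)
        if dx == 0.0:
            skeletons[sid] = skel
        else:
            skeletons[sid] = Skeleton(
                sid, {nid: replace(n, x=n.x + dx) for nid, n in skel.treenodes.items()}
            )
    connectors = {
        cid: (
            replace(c, x=c.x + offsets[c.pre[0]]) if c.pre[0] in offsets else c
        )
        for cid, c in circuit.connectors.items()
    }
    return Circuit(skeletons, connectors, dict(circuit.metas), circuit.volume)


def _silencing_rewire(circuit: Circuit, spec: PerturbationSpec, seed: int) -> Circuit:
    connectors = {cid: c for cid, c in circuit.connectors.items()}
    next_cid = [len(connectors)]

    def links_onto(post_sid: str):
        found = []
        for cid, c in connectors.items():
            for post in c.posts:
                if post[0] == post_sid:
                    found.append((cid, post))
        return found

    def remove_link(cid: str, post):
        c = connectors[cid]
        posts = tuple(p for p in c.posts if p != post)
        if posts:
            connectors[cid] = replace(c, posts=posts)
        else:
            del connectors[cid]

    def add_link(rng, pre_members, post_sid):
        pre_sid = pre_members[rng.integers(len(pre_members))]
        pre_nodes = _nodes_of_compartment(circuit.skeletons[pre_sid], AXON)
        pre_nid = pre_nodes[rng.integers(len(pre_nodes))]
        post_nodes = _nodes_of_compartment(circuit.skeletons[post_sid], DENDRITE)
        post_nid = post_nodes[rng.integers(len(post_nodes))]
        cid = f"rw{next_cid[0]}"
        next_cid[0] += 1
        pre_node = circuit.skeletons[pre_sid].treenodes[pre_nid]
        post_node = circuit.skeletons[post_sid].treenodes[post_nid]
        mid = (pre_node.xyz + post_node.xyz) / 2.0
        connectors[cid] = Connector(
            cid, (pre_sid, pre_nid), ((post_sid, post_nid),),
            float(mid[0]), float(mid[1]), float(mid[2]),
        )

    for gi, ((pre_type, post_type), g) in enumerate(sorted(spec.gain.items())):
        post_ids = [
            sid for sid, m in circuit.metas.items() if m.cell_type == post_type
        ]
        for pi, post_sid in enumerate(sorted(post_ids)):
            rng = _rng_for(seed, 20, gi, pi)
            links = links_onto(post_sid)
            seed_links = [
                (cid, post)
                for cid, post in links
                if circuit.metas.get(connectors[cid].pre[0], None)
                and circuit.metas[connectors[cid].pre[0]].cell_type == pre_type
            ]
            bg_links = [
                (cid, post)
                for cid, post in links
                if circuit.metas[connectors[cid].pre[0]].cell_type == "other"
            ]
            n_seed = len(seed_links)
            target = int(round(g * n_seed))
            delta = target - n_seed
            meta = circuit.metas[post_sid]
            pre_members = [
                sid
                for sid, m in circuit.metas.items()
                if m.cell_type == pre_type
                and m.segment == meta.segment
                and (meta.side == "bilateral" or m.side in (meta.side, "bilateral"))
            ]
            bg_members = [
                sid for sid, m in circuit.metas.items() if m.cell_type == "other"
            ]
            if delta > 0:
                delta = min(delta, len(bg_links))  # fraction clipped at what's available
                for idx in rng.choice(len(bg_links), size=delta, replace=False):
                    remove_link(*bg_links[idx])
                for _ in range(delta):
                    add_link(rng, pre_members, post_sid)
            elif delta < 0:
                for idx in rng.choice(len(seed_links), size=-delta, replace=False):
                    remove_link(*seed_links[idx])
                if bg_members:
                    for _ in range(-delta):
                        add_link(rng, bg_members, post_sid)
    return Circuit(dict(circuit.skeletons), connectors, dict(circuit.metas), circuit.volume)


# ---------------------------------------------------------------------------
# calcium and behavior simulation
# ---------------------------------------------------------------------------

def simulate_calcium(config: CalciumSimConfig, seed: int = 0):
    """Simulate stimulus-locked calcium trials.

    F(t) = F0 + noise + A.exp(-(t - t_peak)/tau) for frames from the first
    sample after stimulation offset (t_peak), so the noise-free peak dF/F0
    equals A/F0 exactly. Returns (trials, ground_truth) with the designed
    relative amplitude recorded.
    """
    from .calcium_scoring import CalciumTrial

    if config.tau_s <= 0 or config.noise_sd < 0:
        raise CircuitError("tau must be positive and noise SD non-negative")
    dt = 1.0 / config.frame_rate
    onset = config.rest_s
    offset = onset + config.stim_duration_s
    total = offset + config.rest_s
    times = np.arange(0.0, total, dt)
    post = times > offset
    t_peak = times[post][0] if post.any() else offset
    trials = []
    for a in range(config.n_animals):
        for t in range(config.trials_per_animal):
            rng = _rng_for(seed, 30, a, t)
            f = config.f0 + rng.normal(0.0, config.noise_sd, size=times.size)
            decay = np.zeros_like(times)
            decay[post] = config.amplitude * np.exp(
                -(times[post] - t_peak) / config.tau_s
            )
            trials.append(
                CalciumTrial(
                    times=times,
                    fluorescence=f + decay,
                    stim_onset=onset,
                    stim_offset=offset,
                    modality=config.modality,
                    animal_id=f"a{a}",
                    trial_id=f"a{a}_t{t}",
                )
            )
    truth = {"relative_amplitude": config.amplitude / config.f0, "t_peak": float(t_peak)}
    return trials, truth


def simulate_behavior(config: BehaviorSimConfig, seed: int = 0):
    """Simulate a behavior cohort with designed response probability.

    Each animal responds (gets 1-2 bouts intersecting the analysis window)
    with the design probability; tracking gaps that break the 95% coverage
    rule and collisions inside the window are injected at the designed rates.
    Returns (tracks, ground_truth) where the ground truth records each
    animal's response draw and injected exclusion.
    """
    from .behavior_scoring import AnimalTrack, AnalysisWindow, Bout

    if not 0.0 <= config.design_probability <= 1.0:
        raise CircuitError("design probability must be in [0,1]")
    window = AnalysisWindow(config.window_onset_s, config.window_length_s)
    tracks = []
    truth = {"design_probability": config.design_probability, "animals": {}}
    for a in range(config.n_animals):
        rng = _rng_for(seed, 40, a)
        aid = f"{config.group}_{a}"
        responds = rng.random() < config.design_probability
        gap = rng.random() < config.gap_rate
        collision = (not gap) and rng.random() < config.collision_rate
        if gap:
            # a mid-window gap removing 20% of the window breaks the 95% rule
            gap_start = window.onset_s + 0.2 * window.length_s
            gap_end = gap_start + 0.2 * window.length_s
            tracked = [(0.0, gap_start), (gap_end, config.track_length_s)]
        else:
            tracked = [(0.0, config.track_length_s)]
        collisions = (
            [(window.onset_s + 0.5, window.onset_s + 1.0)] if collision else []
        )
        bouts = []
        if responds:
            for _ in range(int(rng.integers(1, 3))):
                dur = max(0.2, rng.normal(config.bout_duration_mean_s,
                                          config.bout_duration_sd_s))
                start = window.onset_s + rng.uniform(0.0, window.length_s - 0.2)
                bouts.append(Bout(config.behavior, start, min(start + dur, window.end_s)))
        tracks.append(
            AnimalTrack(
                animal_id=aid,
                group=config.group,
                tracked_intervals=tracked,
                collision_intervals=collisions,
                bouts=bouts,
            )
        )
        truth["animals"][aid] = {
            "responds": responds,
            "gap": gap,
            "collision": collision,
        }
    return tracks, truth
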