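"""Connectivity statistics and cross-volume comparison.

The quantities here are the ones used to compare wild-type and perturbed EM
volumes of the larval mechanosensory circuit:

* grouped synapse counts between cell-type groups (one polyadic pre->post
  link counts as one synapse, so per-partner counts are additive over the
  presynaptic group),
* input fractions (synapses from a seed group divided by the target's total
  input, optionally restricted to dendrites or to an equivalent-coverage
  subvolume),
* synapse densities per millimetre of target cable,
* partner rankings with the field's significance threshold of 3 synapses and
  the strong/weak (preferred-partner) boundary at 15 synapses (both inclusive),
* left/right homolog conservation probabilities, and
* retention / new-partner bookkeeping for a perturbed volume against the
  wild-type partner ranking.

Absolute synapse counts are never compared across volumes (totals grow during
development); comparisons are always of fractions or densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .circuit_model import (
    Box,
    Circuit,
    CircuitError,
    cable_length,
    node_count,
    restrict_to_subvolume,
)
from . import stat_tests

__all__ = [
    "GroupSpec",
    "PartnerRecord",
    "ConservationResult",
    "ClassRetention",
    "RetentionSummary",
    "InputFraction",
    "UndefinedFractionError",
    "resolve_group",
    "group_synapse_count",
    "input_fraction",
    "synapse_density_per_cable",
    "rank_partners",
    "homolog_conservation",
    "fold_change",
    "mean_fold_change",
    "compare_volumes",
    "connectivity_table",
    "retention_stats",
]

SIGNIFICANT_SYNAPSES = 3  # minimum count treated as a real connection
STRONG_THRESHOLD = 15  # preferred-partner (strong/weak) boundary, inclusive


class UndefinedFractionError(CircuitError):
    """Raised when an input fraction has a zero denominator."""


@dataclass(frozen=True)
class GroupSpec:
    """A hemisegmental cell-type group (e.g. the 8 mechanosensory axons of A1 L)."""

    name: str
    cell_type: str
    segment: str
    side: str  # "L" or "R"
    expected_size: int | None = None


@dataclass(frozen=True)
class PartnerRecord:
    skeleton_id: str
    synapse_count_from_seed: int
    rank: int
    strength_class: str  # "strong" | "weak"
    bilateral_reproducible: bool | None = None
    matched_in_other_volume: bool | None = None


@dataclass(frozen=True)
class ConservationResult:
    threshold: int
    n_eligible_left: int
    n_eligible_right: int
    p_left: float | None
    p_right: float | None
    p_mean: float | None

    @property
    def undefined(self) -> bool:
        return self.p_mean is None


@dataclass(frozen=True)
class InputFraction:
    n_from_pre: int
    n_total: int
    fraction: float


@dataclass(frozen=True)
class ClassRetention:
    n_total: int
    n_unmatched: int
    failure_percent: int  # nearest-integer percent


@dataclass(frozen=True)
class RetentionSummary:
    by_class: dict[str, ClassRetention]
    new_partners: tuple[str, ...]


# ---------------------------------------------------------------------------
# group resolution and link counting
# ---------------------------------------------------------------------------

def resolve_group(circuit: Circuit, spec: GroupSpec) -> frozenset[str]:
    """Skeleton ids of the neurons matching a group spec.

    Bilateral cell types (side annotation "bilateral") belong to the group of
    either side; their per-side connectivity is attributed downstream from the
    unilateral partner's side.
    """
    members = frozenset(
        sid
        for sid, m in circuit.metas.items()
        if m.cell_type == spec.cell_type
        and m.segment == spec.segment
        and (m.side == spec.side or m.side == "bilateral")
    )
    if spec.expected_size is not None and len(members) != spec.expected_size:
        raise CircuitError(
            f"group {spec.name}: expected {spec.expected_size} members, "
            f"resolved {len(members)}"
        )
    return members


def _resolve(circuit: Circuit, obj) -> frozenset[str]:
    if isinstance(obj, GroupSpec):
        return resolve_group(circuit, obj)
    if isinstance(obj, str):
        return frozenset([obj])
    return frozenset(obj)


def _compartment_ok(circuit: Circuit, endpoint: tuple[str, str], compartment: str) -> bool:
    if compartment == "all":
        return True
    return circuit.node(*endpoint).compartment == compartment


def group_synapse_count(
    circuit: Circuit,
    pre,
    post,
    pre_compartment: str = "all",
    post_compartment: str = "all",
) -> int:
    """Number of pre->post synaptic links between two groups (or neurons).

    Each pre->post pairing of a polyadic connector counts once; compartment
    filters apply to the pre node and the post node independently.
    """
    pre_set = _resolve(circuit, pre)
    post_set = _resolve(circuit, post)
    n = 0
    for _conn, pre_ep, post_ep in circuit.links():
        if (
            pre_ep[0] in pre_set
            and post_ep[0] in post_set
            and _compartment_ok(circuit, pre_ep, pre_compartment)
            and _compartment_ok(circuit, post_ep, post_compartment)
        ):
            n += 1
    return n


def input_fraction(
    circuit: Circuit,
    pre,
    post,
    compartment_mode: str | Box = "whole",
) -> InputFraction:
    """Fraction of a target's synaptic input contributed by a seed group.

    ``compartment_mode`` selects the denominator: ``"whole"`` counts every
    input link onto the target, ``"dendritic"`` only links onto its dendrites
    (numerator restricted identically), and a :class:`Box` restricts both
    numerator and denominator to the equivalent-coverage subvolume before
    counting (the correction used for arbors that leave a 1.5-segment volume).
    """
    if isinstance(compartment_mode, Box):
        restricted = restrict_to_subvolume(circuit, compartment_mode)
        pre_ids = _resolve(circuit, pre)
        post_ids = _resolve(circuit, post)
        return _whole_fraction(restricted, pre_ids, post_ids)
    if compartment_mode == "whole":
        return _whole_fraction(circuit, _resolve(circuit, pre), _resolve(circuit, post))
    if compartment_mode == "dendritic":
        return _whole_fraction(
            circuit, _resolve(circuit, pre), _resolve(circuit, post),
            post_compartment="dendrite",
        )
    raise ValueError(f"unknown compartment_mode {compartment_mode!r}")


def _whole_fraction(
    circuit: Circuit,
    pre_set: frozenset[str],
    post_set: frozenset[str],
    post_compartment: str = "all",
) -> InputFraction:
    n_total = 0
    n_from_pre = 0
    for _conn, pre_ep, post_ep in circuit.links():
        if post_ep[0] not in post_set:
            continue
        if post_ep[0] in circuit.skeletons and not _compartment_ok(
            circuit, post_ep, post_compartment
        ):
            continue
        n_total += 1
        if pre_ep[0] in pre_set:
            n_from_pre += 1
    if n_total == 0:
        raise UndefinedFractionError(
            f"target {sorted(post_set)} has no input under the selected mode"
        )
    return InputFraction(n_from_pre, n_total, n_from_pre / n_total)


def synapse_density_per_cable(
    circuit: Circuit,
    pre,
    post: str,
    compartment: str = "all",
) -> float:
    """Synapses from a seed group onto one neuron per millimetre of its cable."""
    cable_mm = cable_length(circuit.skeletons[post], compartment) / 1_000.0
    if cable_mm <= 0:
        raise CircuitError(f"neuron {post}: zero cable in compartment {compartment}")
    count = group_synapse_count(
        circuit, pre, post, post_compartment=compartment
    )
    return count / cable_mm


# ---------------------------------------------------------------------------
# partner ranking and homolog conservation
# ---------------------------------------------------------------------------

def seed_partner_counts(circuit: Circuit, seed) -> dict[str, int]:
    """Summed link counts from all seed members onto each other neuron."""
    seed_set = _resolve(circuit, seed)
    counts: dict[str, int] = {}
    for _conn, pre_ep, post_ep in circuit.links():
        if pre_ep[0] in seed_set and post_ep[0] not in seed_set:
            counts[post_ep[0]] = counts.get(post_ep[0], 0) + 1
    return counts


def rank_partners(
    circuit: Circuit,
    seed,
    min_synapses: int = SIGNIFICANT_SYNAPSES,
    strong_threshold: int = STRONG_THRESHOLD,
    seed_other=None,
) -> list[PartnerRecord]:
    """Rank postsynaptic partners of a seed group by summed synapse count.

    Partners below ``min_synapses`` (inclusive threshold) are excluded; the
    strong/weak boundary at ``strong_threshold`` is inclusive, so a partner
    with exactly 15 synapses is strong. When the contralateral seed group is
    supplied, ``bilateral_reproducible`` marks partners whose left/right
    homolog also receives at least ``min_synapses`` links from it.
    """
    counts = seed_partner_counts(circuit, seed)
    other_counts = (
        seed_partner_counts(circuit, seed_other) if seed_other is not None else None
    )
    ordered = sorted(
        ((sid, c) for sid, c in counts.items() if c >= min_synapses),
        key=lambda item: (-item[1], item[0]),
    )
    records = []
    for rank, (sid, c) in enumerate(ordered, start=1):
        bilateral = None
        if other_counts is not None:
            homolog = circuit.metas[sid].homolog_id if sid in circuit.metas else None
            bilateral = (
                homolog is not None
                and other_counts.get(homolog, 0) >= min_synapses
            )
        records.append(
            PartnerRecord(
                skeleton_id=sid,
                synapse_count_from_seed=c,
                rank=rank,
                strength_class="strong" if c >= strong_threshold else "weak",
                bilateral_reproducible=bilateral,
            )
        )
    return records


def homolog_conservation(
    circuit: Circuit,
    seed_L,
    seed_R,
    thresholds: Sequence[int] = (1, 5, 10, 15),
    min_nodes: int = 500,
    identified_only: bool = True,
) -> list[ConservationResult]:
    """Probability that a partner's contralateral homolog is also connected.

    For each threshold t and each side: among partners receiving >= t links
    from that side's seed group -- restricted to identified neurons with at
    least ``min_nodes`` treenodes and an annotated homolog -- the fraction
    whose homolog receives >= 1 link from the opposite seed group. The
    reported probability is the average of the left and right calculations;
    sides with no eligible partner are undefined at that threshold.
    """
    counts = {
        "L": seed_partner_counts(circuit, seed_L),
        "R": seed_partner_counts(circuit, seed_R),
    }

    def eligible(sid: str, t: int, side: str) -> bool:
        if counts[side].get(sid, 0) < t:
            return False
        meta = circuit.metas.get(sid)
        if meta is None or meta.homolog_id is None:
            return False
        if identified_only and not meta.identified:
            return False
        return node_count(circuit.skeletons[sid]) >= min_nodes

    results = []
    for t in thresholds:
        per_side: dict[str, tuple[int, float | None]] = {}
        for side, opposite in (("L", "R"), ("R", "L")):
            members = [sid for sid in counts[side] if eligible(sid, t, side)]
            if not members:
                per_side[side] = (0, None)
                continue
            conserved = sum(
                1
                for sid in members
                if counts[opposite].get(circuit.metas[sid].homolog_id, 0) >= 1
            )
            per_side[side] = (len(members), conserved / len(members))
        (n_l, p_l), (n_r, p_r) = per_side["L"], per_side["R"]
        p_mean = (p_l + p_r) / 2.0 if p_l is not None and p_r is not None else None
        results.append(
            ConservationResult(
                threshold=t,
                n_eligible_left=n_l,
                n_eligible_right=n_r,
                p_left=p_l,
                p_right=p_r,
                p_mean=p_mean,
            )
        )
    return results


# ---------------------------------------------------------------------------
# fold changes and cross-volume comparison
# ---------------------------------------------------------------------------

def fold_change(f_a: float, f_b: float) -> float:
    """Ratio of two input fractions (f_a relative to f_b)."""
    if f_b == 0:
        raise ZeroDivisionError("fold change undefined for zero reference fraction")
    return f_a / f_b


def mean_fold_change(pairs: Iterable[tuple[float, float]]) -> tuple[float, float]:
    """Mean and sample SD of per-connection fold changes."""
    ratios = np.array([fold_change(a, b) for a, b in pairs], dtype=float)
    if ratios.size == 0:
        raise ValueError("no fold changes to average")
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return float(ratios.mean()), sd


def compare_volumes(
    circuit_a: Circuit,
    circuit_b: Circuit,
    pairings: Sequence[tuple],
    continuity: bool = False,
) -> pd.DataFrame:
    """Compare input fractions between two volumes, pairing by spec.

    Each pairing is ``(pre, post, compartment_mode)``. Fractions are tested
    with a chi-square test of proportions on the 2x2 table
    ``[[from_seed_a, other_a], [from_seed_b, other_b]]``; fold change is
    volume b relative to volume a. Pairings that do not resolve or have an
    undefined fraction in either volume are flagged and left untested.
    """
    rows = []
    for pre, post, mode in pairings:
        row = {
            "pre": getattr(pre, "name", str(pre)),
            "post": getattr(post, "name", str(post)),
            "mode": "subvolume" if isinstance(mode, Box) else str(mode),
            "flagged": False,
        }
        try:
            fa = input_fraction(circuit_a, pre, post, mode)
            fb = input_fraction(circuit_b, pre, post, mode)
        except (CircuitError, KeyError) as exc:
            row.update(flagged=True, note=str(exc))
            rows.append(row)
            continue
        table = [
            [fa.n_from_pre, fa.n_total - fa.n_from_pre],
            [fb.n_from_pre, fb.n_total - fb.n_from_pre],
        ]
        try:
            test = stat_tests.chi_square_proportions(table, continuity=continuity)
            chi2, p = test.statistic, test.p_value
        except ValueError:
            chi2, p = np.nan, np.nan
        row.update(
            n_from_pre_a=fa.n_from_pre,
            n_total_a=fa.n_total,
            fraction_a=fa.fraction,
            n_from_pre_b=fb.n_from_pre,
            n_total_b=fb.n_total,
            fraction_b=fb.fraction,
            fold_change=fold_change(fb.fraction, fa.fraction)
            if fa.fraction > 0
            else np.nan,
            chi2=chi2,
            p_value=p,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def connectivity_table(
    circuit: Circuit,
    pairings: Sequence[tuple],
) -> pd.DataFrame:
    """Per-pairing counts, fractions and densities for one circuit.

    Each pairing is ``(pre, post, compartment_mode)`` with ``post`` a single
    neuron or a group; density per cable is reported only for single-neuron
    targets (the cable denominator of a group is not a quantity the analysis
    uses).
    """
    rows = []
    for pre, post, mode in pairings:
        frac = input_fraction(circuit, pre, post, mode)
        compartment = "dendrite" if mode == "dendritic" else "all"
        if isinstance(post, str):
            cable_mm = cable_length(circuit.skeletons[post], compartment) / 1_000.0
            density = frac.n_from_pre / cable_mm if cable_mm > 0 else np.nan
        else:
            cable_mm = np.nan
            density = np.nan
        rows.append(
            {
                "pre_group": getattr(pre, "name", str(pre)),
                "post_target": getattr(post, "name", str(post)),
                "synapse_count": frac.n_from_pre,
                "total_input": frac.n_total,
                "input_fraction": frac.fraction,
                "cable_mm": cable_mm,
                "density_per_mm": density,
                "compartment_mode": "subvolume" if isinstance(mode, Box) else str(mode),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# retention and new partners
# ---------------------------------------------------------------------------

def _nearest_percent(numerator: int, denominator: int) -> int:
    return int(np.floor(100.0 * numerator / denominator + 0.5))


def retention_stats(
    wt_ranking: Sequence[PartnerRecord],
    exp_seed_counts: Mapping[str, int],
    matching: Mapping[str, str | None],
    exp_bilateral: Mapping[str, bool] | None = None,
    strong_threshold: int = STRONG_THRESHOLD,
    min_synapses: int = SIGNIFICANT_SYNAPSES,
    unmatched_below: int = 1,
) -> RetentionSummary:
    """Partner retention of a perturbed volume against the wild-type ranking.

    ``matching`` maps wild-type partner ids to their identified counterpart in
    the experimental volume (or None when no counterpart was found);
    ``exp_seed_counts`` gives each experimental neuron's summed links from the
    seed group. A wild-type partner "failed to receive input" when its
    counterpart receives fewer than ``unmatched_below`` seed links (default:
    zero links). Failure percentages are reported per strength class, rounded
    to the nearest integer percent.

    New partners are experimental neurons with at least ``min_synapses`` seed
    links -- reproducibly on both sides when ``exp_bilateral`` flags are
    supplied -- that are not the counterpart of any wild-type partner.
    """
    by_class: dict[str, ClassRetention] = {}
    for cls in ("strong", "weak"):
        in_class = [
            r
            for r in wt_ranking
            if (r.synapse_count_from_seed >= strong_threshold) == (cls == "strong")
        ]
        unmatched = 0
        for r in in_class:
            counterpart = matching.get(r.skeleton_id)
            if counterpart is None or exp_seed_counts.get(counterpart, 0) < unmatched_below:
                unmatched += 1
        by_class[cls] = ClassRetention(
            n_total=len(in_class),
            n_unmatched=unmatched,
            failure_percent=_nearest_percent(unmatched, len(in_class))
            if in_class
            else 0,
        )
    matched_exp = {v for v in matching.values() if v is not None}
    new_partners = tuple(
        sorted(
            sid
            for sid, c in exp_seed_counts.items()
            if c >= min_synapses
            and sid not in matched_exp
            and (exp_bilateral is None or exp_bilateral.get(sid, False))
        )
    )
    return RetentionSummary(by_class=by_class, new_partners=new_partners)
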