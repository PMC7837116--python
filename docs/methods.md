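# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical decisions that make results reproducible
bit-for-bit.

## Circuit data model

Skeletons are rooted trees of treenodes with coordinates in nanometres (the
convention of CATMAID exports; the source EM volumes have 3.8 × 3.8 × 40 nm
voxels, so nm is the natural integer-free unit). All user-facing lengths are
micrometres and densities synapses/mm. Chemical synapses are polyadic
connectors: one presynaptic site with one or more postsynaptic sites, and
**each pre→post pairing counts as one synapse**. This is the convention that
makes per-partner counts additive over a presynaptic group.

Compartment labels (axon / dendrite / other) are input annotations, as is
cell identity, hemisegment, and left-right homolog pairing; no axon/dendrite
split or morphological matching is computed (those steps are expert manual
work upstream of this package). A parent→child edge belongs to the child
node's compartment, which makes per-compartment cable lengths an exact
partition of the total.

`restrict_to_subvolume` clips to an axis-aligned box (closed bounds): nodes
outside are removed, surviving orphans become roots (so restricted skeletons
may be forests), a connector loses links whose post node was removed and is
dropped if its pre node was. The operation is idempotent and monotone in
every count, and the subvolume input-fraction mode simply computes the
whole-neuron fraction on the restricted circuit — the correction used when a
target's arbor (Ladder) leaves a 1.5-segment volume.

Axis convention: mediolateral = x, anteroposterior = y, dorsoventral = z,
configurable on `VolumeSpec`.

## Connectivity statistics

- **Thresholds.** ≥3 synapses marks a significant connection; ≥15 marks the
  strong ("preferred partner") class. Both thresholds are inclusive — a
  partner at exactly 15 is strong, at exactly 3 is included.
- **Input fraction modes.** `whole` counts every input link onto the target;
  `dendritic` restricts numerator and denominator to links onto dendrite
  nodes (used for Basin, Griddle, Drunken, whose mechanosensory input is
  dendritic); a `Box` restricts both to the subvolume. A zero denominator is
  an explicit error, never reported as 0.
- **Homolog conservation.** For threshold t and each side, eligible partners
  are those with ≥t seed links, an annotated homolog, ≥500 reconstruction
  nodes, and (by default) identified status; the conservation probability is
  the fraction whose homolog receives ≥1 link from the opposite seed, and the
  left/right average is reported. Sides with no eligible partner are flagged
  undefined rather than zero.
- **Side attribution for bilateral types.** Ladder interneurons are
  annotated `bilateral` and belong to both side groups; a connection's
  hemisegment is attributed from the unilateral partner's side, because the
  left/right difference of a bilateral neuron's connectivity lives in its
  unilateral presynaptic partners.
- **Cross-volume comparison.** Only fractions and densities are compared
  (totals grow with development); the chi-square table is
  `[[from-seed, other-input] per volume]`, Yates correction off by default
  (configurable). Fold change is the ratio of the two fractions; mean fold
  change reports the sample SD of per-connection ratios.
- **Retention.** Failure percentages (wild-type partners whose experimental
  counterpart receives no seed input — "no input" defaults to zero links,
  configurable) are rounded to the nearest integer percent. New partners
  require ≥3 seed links reproducibly in left and right hemisegments and no
  wild-type counterpart.

## Density profiles and smoothing

Node or synapse positions are counted in a 2.5 μm sliding window along the
mediolateral axis; positions are reported as (x − midline)/width so profiles
from different volumes are comparable, and densities are normalized to the
cell type's maximum. Window boundaries are closed (±1.25 μm inclusive) —
symmetric and deterministic. The grid step is 1% of the neuropil width: the
window size is prescribed, the step is not, and 1% is dense enough for
span-0.1 smoothing at negligible cost. Normalization order is count →
max-normalize → smooth.

LOESS is implemented directly (no installed package provides R-style
degree-2 local regression): at each grid point the span-fraction nearest
neighbors (⌊span·n⌋) receive tricube weights scaled by the furthest selected
neighbor's distance, and a weighted quadratic is fitted and evaluated there;
no robustness iterations. This reproduces constants exactly, degree-2
polynomials exactly when the span covers all points, and agrees with R's
`loess(span = 0.1, degree = 2, surface = "direct")` to ≤1e-6 on a frozen
fixture (`tests/data/loess_r_reference.csv`, computed once with R 4.3).

The exploration-area ratio is 100 × |union of mask pixels over time| /
|mature mask pixels| (the final frame is the mature arbor), so it is ≥100%
and monotone as frames accumulate. The membrane profile binarizes a 3-D
stack at an explicit threshold (≥, mirroring a manually chosen mask), sums
over Z and averages over rows, one value per mediolateral column.

## Calcium scoring

F₀ is the median of the whole trace — robust to transients occupying a small
fraction of the trial. Windows are half-open: response window
(offset, offset + 4.5 s], recent baseline [onset − 3 s, onset); at
6.61 frames/s this prevents boundary frames from being counted twice. The
"4.5 s following stimulation" of the rejection rule is anchored at
stimulation **offset**, consistent with the peak window; onset anchoring is
available. The rejection band uses the sample SD (n − 1) of per-frame ΔF/F₀
over the 3 s baseline (the estimator is otherwise unspecified); a
zero-variance baseline responds iff the window mean differs at all. Animals
whose trials all fail the band are excluded from per-animal averages and
reported. Group comparisons use the one-sided Wilcoxon rank-sum test.

## Behavior scoring

An animal is valid iff tracked time overlapping the analysis window is
≥95% of the window and no collision interval intersects it (any overlap
excludes). A bout counts toward the response probability if it intersects
the window at all; durations are per-animal total bout time clipped to the
window (per-bout aggregation is a plausible alternative the source data do
not disambiguate; per-animal totals pair naturally with per-animal response
flags). CIs are Wilson score intervals (well-behaved at 0 and n; Wald
available); duration comparisons use the Welch two-sided t test (pooled
available), probability comparisons the chi-square test of proportions.

## Statistical tests

All results carry method metadata (alternative, correction, exact vs.
approximate) so any reported comparison can be reproduced. Chi-square and t
tests delegate to scipy; zero-variance t inputs follow the convention
p = 1 for zero effect, p → 0 (flagged) otherwise.

The Wilcoxon rank-sum test uses midranks, an exact distribution when
m + n ≤ 12 without ties, and otherwise a refined normal approximation:
continuity correction, tie-corrected variance, a one-term Edgeworth
correction with the exact fourth cumulant of the null
(γ₂ = −6(m² + n² + mn + m + n)/(5mn(N + 1))), and exact tail probabilities
within 10 steps of the support boundary computed from bounded-partition
counts (exact at any sample size when tie-free — precisely the region where
the normal body is weakest). Exhaustive enumeration over every tie-free
configuration with m = n ≤ 6 puts the approximation within 0.002 of the
exact p for all alternatives (identical for m ≤ 4). With ties, the Edgeworth
term keeps the tie-free fourth cumulant; the term is O(1/n) and insensitive
to moderate ties.

## Synthetic data: what it emulates and what it does not

The circuit generator realizes the study conditions directly: the
hemisegmental roster (8 mechanosensory, 4 Basin, 6 bilateral Ladder,
1 Griddle, 1 Drunken, 3 nociceptive), designed input-fraction matrices drawn
multinomially at designed totals (mechanosensory→Basin 0.20 at 400 inputs
per Basin by default, remainder from an unlabeled background pool), mirrored
homolog annotations, and a partner pool whose left/right connection
conservation follows the designed per-strength-bin probabilities
(0.75 / 0.89 / 0.97 / 1.00 for counts in [1,5), [5,10), [10,15), [15,∞)).
Pairs are drawn symmetrically — P(both sides) = p/(2−p), P(one side only) =
(1−p)/(2−p) each — so that the conditional conservation probability equals
the design on both sides. Because the threshold-t estimate is the cumulative
P(conserved | count ≥ t), single-bin recovery is measured on pools
concentrated in one bin with t at the bin's lower edge.

Skeleton geometry is deliberately schematic: random-walk trees around a
mediolateral placement centroid, 60 nodes for roster neurons and 500 for
conservation-pool partners (so they pass the reconstruction-size filter at
its default). The analysis never uses geometry beyond positions and cable
length, so realistic arborization, tiling and neuropil boundaries are not
emulated — passing tests certify the statistics, not morphological realism.
Polyadic connectors arise by letting links that share a presynaptic node
join the same connector (up to 4 targets); synthetic connectors sit at the
pre/post midpoint.

Perturbations: `lateral_shift` translates each target axon (and the
connectors it is presynaptic at) away from the midline by a per-axon offset
(default 10 ± 2 μm — from the intermediate tract to near the neuropil edge
of a 50 μm-wide neuropil); `silencing_rewire` rescales designed connections
by gain multipliers at the expense of background input so each target's
total input is preserved, emulating the reallocation between excitatory and
inhibitory partners that developmental silencing produces — it is a
statistical emulation, not a plasticity model.

Calcium trials are baseline + Gaussian noise + exponential decay
(τ = 2 s) from the first frame after stimulation offset, so the noise-free
peak ΔF/F₀ equals A/F₀ exactly; the protocol is 30 s rest, 100 ms stimulus,
30 s rest at 6.61 frames/s. Behavior cohorts draw Bernoulli responses at the
design probability, give responders 1–2 in-window bouts, and inject
coverage-breaking gaps and in-window collisions at design rates. All
generators are pure functions of (config, seed), with per-entity substreams.

## Problem sizes and runtime

The test suite and acceptance script run on one CPU in well under their
budgets with: 100 random circuits of ≤12 neurons for oracle equivalence;
600 homolog pairs per conservation bin (≈950–1200 eligible partners per
estimate, giving ±0.03 sampling error on a 0.75 probability); 10,000 null
2×2 tables at n = 300/group for chi-square calibration; 2,000 simulated
trials for the false-positive band ordering; 1,000 animals for behavior
recovery. These sizes keep every recovery check inside its stated sampling
interval while the full suite completes in about half a minute.

## Known limitations

- Homology across volumes is annotation-driven; there is no morphological
  matching, neurotransmitter inference, or cell typing.
- The conservation computation reproduces the procedure, not the published
  eligible-partner counts, which depend on the original volumes'
  identification status.
- Generator realism is statistical only (see above); LOESS matches the R
  default algorithm but not its interpolated (`surface="interpolate"`)
  fast path.
- With heavy ties the Wilcoxon Edgeworth term is approximate (the variance
  tie correction is exact).
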