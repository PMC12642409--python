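# Methods

This note records the models implemented in `synpid`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want to know.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Information measures

All information quantities are in bits (log base 2), estimated by the
plug-in method: the empirical distribution over the 16 joint outcomes
`(X_t, Y_t, X_{t+τ}, Y_{t+τ})` is tabulated from the `T − τ` aligned
4-tuples and entropies are computed directly, with the `0·log 0 = 0`
convention. The lag defaults to τ = 1 frame.

The TDMI `I(X_t, Y_t ; X_{t+τ}, Y_{t+τ})` is decomposed with the
minimum-mutual-information (MMI) redundancy,
`RI = min(I(X_t;F), I(Y_t;F))` with `F` the joint future. MMI guarantees
all four components are non-negative and forces at least one unique
component to zero; the implementation clips components at zero after a
1e-9 tolerance check and verifies the decomposition identity. Pairs with
constant series carry zero TDMI; they are flagged and excluded from
normalisation downstream.

No small-sample bias correction (e.g. Miller–Madow) is applied to the
plug-in estimates: bias handling is delegated entirely to the null-model
normalisation, which sees the same estimator. Mixing a corrected estimate
with an uncorrected null would double-count the correction.

## Null-model normalisation

A pair's PID components are Z-scored against an ensemble of null
processes matched on TDMI. Each null is built as:

1. a random 4-state transition kernel for the pair state, rows drawn
   Dirichlet (concentration 0.3; after sustained rejection the
   concentration is halved, because near-deterministic kernels are needed
   to reach targets above ~1 bit);
2. independent per-bit flip noise at rate η applied to both neurons;
3. η calibrated by bisection on [0, 0.5] against the *analytic*
   stationary TDMI of the noisy process until it matches the empirical
   TDMI to 1% relative (TDMI is strictly decreasing in η). Kernels whose
   noiseless TDMI falls short of the target are redrawn, with a capped
   retry budget.

By default the null PID is the analytic (infinite-sample) decomposition
of the calibrated process, which removes one Monte-Carlo noise source. A
`finite_sample` switch instead simulates a series of the empirical length
and uses its plug-in PID, so estimator bias is reflected in the null as
well; the default keeps the two behaviours separable rather than
asserting which better matches any particular reference analysis.

The ensemble default is `n_null = 100`. Null statistics for the two
unique components are pooled across the null's two (arbitrary) source
labels, making Z-scores exactly invariant under relabelling of the
empirical pair up to the `z_ui_x`/`z_ui_y` swap. Pairs with TDMI below
1e-6 bits cannot be matched and get NaN Z-scores, which later stages
treat as undefined and exclude.

## Synthetic data generator

The generator emulates the statistical skeleton of a binarized mesoscale
recording: N neurons uniform in a 3 mm × 3 mm field, binary activity at a
nominal 7.5 Hz with per-frame activation probability `firing_prob`
(default 0.05), lag-1 temporal persistence, and pairwise Pearson
correlations decaying as `c_inf + (c0 − c_inf)·exp(−d/λ)`.

Mechanism: a dichotomized Gaussian. A latent unit-variance AR(1) process
with spatial cross-correlation is thresholded at the quantile giving the
target rate. The latent correlations are obtained by numerically
inverting the thresholded-bivariate-normal correlation map on a monotone
grid (tetrachoric-style inversion), so the *binary* correlations land on
the planted kernel rather than only approximating it through the latent
one. The resulting matrix can be indefinite (exponential kernel on an
arbitrary point set plus a constant offset); it is projected to the
nearest PSD matrix by eigenvalue clipping and re-standardised, which
perturbs the planted kernel slightly — recovery tests therefore target
the fitted λ (20% tolerance) and the asymptote (±0.01), not exact
equality.

XOR triplets `(a, b, t)` overwrite neuron t's state at `s+1` with
`XOR(a_s, b_s)`, corrupted at flip probability 0.05 by default (pure
determinism would leave joint states unobserved and plug-in estimators
degenerate). When `t = b` the update is recursive — the target feeds back
into its own next state — and the pair `(a, t)` is then the canonical
purely synergistic pair: each past state alone carries no information
about the target's future. With `firing_prob = 0.5` and no spatial
coupling this is exact; at sparse rates the XOR output is biased toward
the more frequent source symbol and synergy is only dominant, not pure.

What the generator does *not* emulate: calcium indicator kinetics, photon
noise, neuropil contamination, motion, spike-train temporal structure
beyond lag-1 persistence, and — importantly — spatially graded synergy.
The dichotomized Gaussian plants correlation (which loads mostly on
redundancy and self-persistence); synergy enters only through discrete
planted motifs. Consequently Z-scored redundancy decays with distance on
synthetic data when `c0` is well above `c_inf`, but Z-scored synergy has
no built-in spatial decay, and passing tests say nothing about whether
real cortical synergy decays spatially.

The continuous-trace emulator (`traces_from_raster`) is deliberately
minimal — amplitude on active frames plus clipped Gaussian noise — and
exists to exercise the HMM binarizer against known states, not to mimic
deconvolution output.

## HMM binarization

Each neuron's nonnegative trace is fitted with a 2-state Gaussian-emission
HMM by EM (`hmmlearn`), initialised deterministically from the trace
(state means at the 20th/95th percentiles, SD = trace SD / 4, 0.95
self-transition, uniform start), tolerance 1e-4 nats, max 200 iterations.
The binary state is the argmax of the forward–backward posterior marginal
at each timepoint — the most probable *state per timepoint*, not the
Viterbi path — and the higher-mean state is Active. Zero-variance traces
return a flagged degenerate model decoded all-quiet rather than raising,
so one dead ROI cannot abort a batch. Already-binary input bypasses
fitting entirely.

## Spatial curves, λ and λ_eff

Per-pair scalars are averaged in 20 logarithmically spaced distance bins
(defaults: 10 µm to the maximum pair distance); bins with fewer than
`min_pairs_per_bin` pairs (default 50) are retained but unoccupied.
Constant neurons have undefined Pearson r; their pairs are excluded with
a logged count. The exponential decay is fitted to the occupied bin
means, unweighted, by `scipy.optimize.curve_fit`, with initial guesses
(first mean, last mean, span/3) and λ bounded in (1, 10·span]. A
pair-count-weighted fit is available by option. Flat curves (spread below
1e-12) are flagged unidentifiable.

λ_eff is computed by adaptive quadrature of the fitted curve over
[d0, dmax] = [100, 1500] µm divided by the fitted C0, with the closed
form enforced as a 1e-9 consistency check. For Z-scored curves each curve
is normalised by its own fitted C0. Because at reduced synthetic scales
the Z-curves can be too flat for the three-parameter fit to stay
identifiable on every recording, a model-free variant integrates the
binned curve directly by the trapezoid rule, normalised by the curve's
value at the window's left edge (there is no model to extrapolate to
d = 0). The two variants agree for cleanly decaying curves up to that
normalisation-point difference; for flat or rising curves the trapezoid
value is well-defined but should not be read as a decay length — on the
demo conditions the synergy curve is of this kind.

## Two-layer networks and path classification

From the Z-scored table, each layer keeps every neuron's k strongest
partners (default k = 10; the paths demonstration uses k = 2 so that a
100-neuron graph has path lengths up to 5–6). Edges are unweighted and
symmetrized by the union of directed selections — every neuron's top-k is
preserved — with mutual-kNN as an option; ties break toward the smaller
neuron id. Pairs with undefined Z-scores are excluded before selection.

For each pair reachable in the union of the two layers, hop counts
`dA, dB, dAuB` classify it as complementary (`dAuB < min(dA, dB)`),
shared (`dAuB = max(dA, dB)`), or unique to the closer layer. Infinite
layer distances participate through the min/max rules; union-unreachable
pairs are excluded and counted. The tabulation axis is the union hop
count by default, with `min(dA, dB)` as an option (pairs connected only
through the union have no finite value on that axis and are dropped from
it). The long-path aggregate uses lengths ≥ 4.

The planted-motif demonstration (100 neurons, 3000 frames, 15 XOR pairs
spanning > 1.5 mm over a 300 µm redundant background at fair activation)
yields a synergy layer dominated by long-range planted edges and a
spatially local redundancy layer; the median complementary-path
proportion is non-decreasing over lengths 1–5, the package's qualitative
analogue of cooperative long-distance routing.

## Group statistics

Recording-level summaries are compared with a two-sided label-permutation
test on the difference of group means (Welch-t statistic by option).
With ≤ 20,000 label partitions the test enumerates all of them exactly —
at 5 + 5 recordings that is 252 partitions and a two-sided floor of
2/252 ≈ 0.0079, which is surfaced in the output — otherwise Monte-Carlo
with the add-one correction. Effect sizes are Hedges' g with the
small-sample correction J = 1 − 3/(4n − 9). No correction for multiple
summaries and no modelling of repeated recordings from one animal is
applied.

## Problem sizes

The validation suite and acceptance script run at deliberately reduced
scales chosen as the package's own demonstration conditions:
correlation-length recovery at 200 neurons × 20,000 frames (three planted
λ values); the two-condition experiment at 5 + 5 recordings of 100
neurons × 3,000 frames with 2,000 subsampled pairs and 40 null draws per
pair; the motif demonstration at 100 neurons × 3,000 frames. The
two-condition demo plants *only* a correlation-length difference
(400 vs 900 µm), so the λ comparison is the one with a designed effect;
the λ_eff and path-proportion comparisons exercise the machinery on
honest nulls and their signs are not meaningful. Defaults scale to larger
inputs; the `max_pairs` cap (500,000, seeded uniform subsample) bounds
the pair enumeration for recordings with thousands of neurons.

## Known limitations

- Bivariate decomposition only (two neurons, lag 1); no higher-order
  decompositions and no integrated-information atoms.
- MMI redundancy is an upper bound among PID redundancies; conclusions
  about the redundancy/synergy split are tied to that choice.
- The null-model family (random pair-kernel + flip noise) is one concrete
  choice of TDMI-matched null; Z-scores are interpretable relative to it.
- The generator's correlation targets are planted through a Gaussian
  latent field; binary attainability limits very high correlations at
  sparse rates, and the PSD projection slightly deforms the kernel.
- Distances are 2-D Euclidean in the imaging plane; no depth term.
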