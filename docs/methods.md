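# Methods

This note records the model as implemented, the parameter choices that
matter, and the places where the design was genuinely open together with
how they were resolved.

## Reservoir units and replication

Each unit is a rate network of `n_neuron` neurons with unit time constant,

    dx/dt = -x + Q r + B y,     r = tanh(x),     y = F r,

integrated by forward Euler with step `dt`.  `Q` is sparse (each
off-diagonal entry present with probability `p`, zero diagonal) with
Gaussian entries of standard deviation `g / sqrt(p · n_neuron)`; `B` is
dense with the same scale; `F` starts uniform on (−1, 1).  At the defaults
(`n_neuron = 1000`, `p = 0.1`, `g = 1.5`) the untrained network is
spontaneously, weakly chaotic.

Replication trains the learner's readout on the teacher's stored trace in
one full-length pass (`t_train = 300`, i.e. 3000 steps) using recursive
least squares: at every step the readout error `e = y − y_target` updates

    F ← F − e (P r) / (1 + rᵀ P r),
    P ← P − (P r)(P r)ᵀ / (1 + rᵀ P r),        P(0) = I / α,

with `α = 1`.  `P` is re-initialised for every training episode; readout
weights and internal state persist across a unit's lifetime.  After each
update the *corrected* readout is fed back into the network, so the
feedback loop carries a near-target signal throughout training — with the
error-bearing pre-update readout in the loop the chaotic state is never
entrained and tracking fails entirely.  Update cadence is every step
(`rls_every = 1`); thinning updates measurably degrades copy fidelity at
these signal bandwidths.

**What a copy is.**  A learner's new stored trace is the readout it emitted
while tracking the teacher, not a subsequent autonomous re-generation.
Two reasons.  First, phase: an autonomous continuation picks up where
training ended, so each copy would advance the signal's phase by
`t_signal mod period`, scrambling the decoded genotype every generation
and destroying heritability.  The training-pass readout is time-aligned
with the teacher, so lineages share one time grid and copies are
genotype-faithful up to the tracking error.  Second, stability: with the
feedback scale prescribed by the weight ensemble above (std ≈ 0.15 at
n = 1000 — several times weaker than the order-one feedback of standard
FORCE setups), the trained attractor is not reliably autonomously stable;
the tracking readout is well defined regardless.  Copy fidelity is
therefore quantified throughout as the RMS tracking error over the final
evaluation window, as a fraction of the target's peak-to-peak range.
Typical fidelity is 5–12% of range at `n_neuron = 300–1000`; the residual
floor comes from the random initial readout, which ridge-regularised RLS
only partially unlearns.

## Signals

Seed signals are truncated Fourier series with `n_fourier = 5` sine and 5
cosine coefficients drawn uniformly from [−0.5, 0.5], rescaled to
peak-to-peak range 2.  The fundamental period of the seed signals used by
the evolutionary loop equals the evaluation window (`t_evaluation = 30`
time units), so that exactly one period is evaluated, the N decoding bins
tile one full period, and every harmonic (angular frequencies up to
`2π·5/30 ≈ 1`) lies within the bandwidth that unit-time-constant neurons
can track.  The canonical `sin(mt)` form (period 2π) would put most
harmonics far above that bandwidth and would repeat ≈ 4.8 times inside the
evaluation window, collapsing the effective genotype space; the
`FourierSpec.period` field keeps both conventions available.

Mutation noise is white Gaussian, added to the whole freshly copied trace
and rescaled so the discrete energy `Σ η² dt` over the evaluation window
equals the amplitude `A` *exactly* — the sweep's control variable is
itself noiseless.  Sites that keep their own trace receive no noise;
mutation acts on transmission.

## Decoding and landscapes

Amplitudes are sampled at N regular bin edges of the evaluation window
(nearest grid index, for bit reproducibility) and decoded by thresholding
at 0 (binary strings; 0 is the symmetry point of the zero-mean seed
signals) or by stable ascending argsort (permutations).

NK landscapes use the canonical `m = N` construction: component i depends
on coordinate i plus K−1 distinct others drawn uniformly, with iid U[0,1]
tables over all `2^K` restrictions — K counts the *total* coordinates per
component.  Exact information gain enumerates all `2^N` fitnesses (guarded
to N ≤ 24) and uses the greater-or-equal convention, so `q_f > 0` always;
the sampled estimator adds one pseudo-count, `q̂ = (1+#{≥f})/(1+n)`, to
stay finite above the sample maximum.  TSP fitness is the negated closed
tour length; only fitness comparisons enter selection, so any monotone
decreasing transform yields identical dynamics.

## The generation loop

All teacher assignments are computed from the generation-start traces
before any copying (synchronous update).  Ranks within a closed
neighbourhood (3 sites on the ring, 5 on the torus) break ties by lower
site index.  At temperature 0 a site adopts a neighbour only if that
neighbour is *strictly* fitter; otherwise it keeps its own trace.  This
makes an equal-fitness population a true fixed point — with ties resolved
purely by site index, converged populations would re-copy identical traces
forever — and it is also what makes deterministic no-noise dynamics
exactly elitist.  At τ > 0 the teacher is sampled with probability
∝ exp(−rank/τ) over the closed neighbourhood; the sign convention follows
the stated τ = 0 (argmax) and τ → ∞ (uniform) limits.

A unit whose training diverges (internal activity beyond 1e6) keeps its
previous trace, keeps its pre-training readout weights, has its state
redrawn, and is flagged — such sites behave as the transient "walls"
visible in phylogeny heatmaps.

Randomness is organised as named child streams (weights, signals,
landscape, noise, selection, recovery) spawned from one master seed; runs
are bit-reproducible on a platform.  Sweeps key each (parameter value,
run) cell's stream by the value's bit pattern, so results are invariant to
the order in which grid cells execute.

## Sweep instruments

Error-threshold sweeps vary the noise amplitude over a linear grid on
[0, 147]; selection-strength sweeps vary τ over a geometric grid
(0 and `42.75/4^k`, k = 4..0).  The geometric spacing is deliberate:
with ranks 0–2 in a ring neighbourhood, selection is effectively random
already for τ ≳ 8, so a linear grid would place every nonzero point in the
random regime and hide the gradual decline the instrument is meant to
resolve.  Final-generation information-gain distributions are retained in
full and pooled across runs (they can be multimodal; a mean would hide
that); "sharp versus smooth" is quantified by the maximum successive drop
of the pooled median across the grid.  At desk scale the collapsed
high-noise tail consists of statistically equivalent points, so
monotonicity along the noise grid is asserted as a negative Spearman rank
correlation rather than sample-path monotonicity.

## Representation bias

Signal-space sampling draws Fourier coefficient vectors from the same
prior that seeds runs, evaluates them at the N bin-edge times and decodes
(rescaling is monotone and cannot change either map's output, so it is
skipped); solution-space sampling is uniform over all `2^N` strings or
`N!` permutations.  Reported are rarefaction curves (distinct types versus
samples) and token-frequency spectra; skew is summarised by the Gini
coefficient of token counts over the full type space (unsampled types
count zero).

## Scale of the shipped experiments

The full-scale system (100–400 reservoirs of 1000 neurons, 100–500
generations, five runs per sweep column) is far beyond a desk budget; the
package's experiments use reduced but structurally identical conditions,
chosen once: fidelity at 300–1000 neurons; elitism on 16-site rings over
50 generations; the threshold contrast on a ring of 20 units of 300
neurons over 40 generations with a 6-point grid per parameter and one run
per cell; the TSP demonstration with 7 cities, verbatim copying, noise
amplitude 1.08 and 60 generations.  What the scaled experiments show is
the *mechanism* — accumulation, maintenance, abrupt versus gradual
breakdown — not the paper-scale magnitudes.

## The population training engine

Training a whole lattice per generation dominates runtime, so the
generation loop calls a numba kernel that trains all learners of a
generation in lock step, one unit after another (each unit's `P` then
stays cache-resident for its episode).  The kernel's arithmetic is
identical to the plain float64 reference loop — the test suite asserts
elementwise agreement at 1e-9 — with two purely numerical choices: single
precision by default (RLS at these sizes is insensitive to it; fidelity
agrees with float64 to four decimals) and rank-1 downdates of `P` buffered
and merged in blocks of 8 (algebraically exact; the per-step product `P r`
is corrected by the buffered terms).  The recurrent matrices are densified
inside the kernel: at connection density 0.1 a contiguous matrix-vector
product outruns indexed sparse gathers.

## Known limitations

- Autonomous long-term stability of trained attractors is not guaranteed
  under the prescribed weight ensemble; the package's replication
  semantics (training-pass readout) does not depend on it.
- Copy fidelity, and hence the intrinsic mutation rate of the force
  backend, varies noticeably between weight draws; a minority of units are
  persistently poor learners (the "walls" phenomenology).
- The error-threshold location depends on the signal range, the decoding
  threshold and the noise calibration window jointly; the shipped grids
  resolve the transition's shape, not its precise critical value.
- Synthetic seed signals are band-limited and stationary; real neural
  recordings are neither, and nothing here models spiking, adaptation of
  recurrent weights, or multi-dimensional readouts.
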