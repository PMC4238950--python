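# Methods

## The model

`esmnet` simulates the propagation and deposition of misfolded proteins
(MP) — amyloid-β being the motivating case — across a structural brain
connectome, treating inter-regional spread as an epidemic process.  Each of
N gray-matter regions carries a probability `P_i(t) ∈ [0, 1]` of MP burden.
On a daily grid the state evolves as

    P_i(t+dt) = clip[0,1]( P_i(t)
                + dt·[ (1 − P_i)·R_i(t) − P_i·δ_i(t) ]
                + μ·dt + σ·√dt·Z_i ),

an Euler–Maruyama step with optional additive Gaussian noise (Z standard
normal per region and step).  The gain term is the probability of receiving
infectious-like agents while non-infested; the loss term the probability of
clearance while infested.

**Reception.**  Agents accumulate probabilistically from every connected
sender and from within the region itself:

    R_i = 1 − (1 − β_i^int) · Π_{j≠i} (1 − ACP_ji · β_j^ext(t − τ_ji)),

where `ACP_ji ∈ [0, 1]` is the anatomical connection probability and
`τ_ji = fiber_length_ji / V_MP` the axonal travel delay of soluble MP at
velocity `V_MP`.  States before t = 0 are taken to be the initial
condition, so a seed region transmits its initial load from the first step.

**Production.**  The total infection rate of a region is a normalized
logistic function of its own deposition,

    β_total(P) = min(β₀, 1) · [s(P) − s(0)] / [s(1) − s(0)],
    s(P) = 1 / (1 + exp(−k·(P − P_half))),

anchored so that zero deposition produces nothing and full deposition
produces the clamped amplitude β₀.  Shape constants default to k = 10,
P_half = 0.5 and are fixed, not fitted.

**Extrinsic/intrinsic split.**  Soluble MP diffuses down concentration
gradients, so inter-regional inequality drives export.  The Gini
coefficient g(t) of the current deposition vector splits the rate:
`β^ext = g·β_total`, `β^int = (1 − g)·β_total`.

**Clearance.**  Deposition impairs the clearance machinery:
`δ(P) = min(δ₀, 1) · exp(−ρ·P)` with ρ = 1 fixed.

Each subject therefore has four free parameters — β₀, δ₀, μ, σ — of which
μ defaults to 0 and σ is estimated from fit residuals rather than fitted
dynamically.  The per-subject summaries `β_eff, δ_eff` marginalize the rate
functions over all deposition levels by trapezoidal quadrature on a fixed
1001-point grid.

## Dynamical regime and the default study conditions

With the production sigmoid anchored at zero and its knee at P = 0.5, a
region below the knee produces almost nothing, so clearance rates
δ₀ ≥ 0.1/day extinguish any epidemic started from a near-zero seed: the
system is effectively bistable per region.  Two consequences shape the
default synthetic study conditions (`SyntheticSpec`):

- the outbreak region starts heavily infested (`p_seed_init = 0.9`, above
  the knee), so transmission ignites rather than decays;
- the propagation velocity is slow (`V_MP = 0.004 mm/day` by default in the
  generator), so with centimetre-scale fiber lengths the transmission
  delays are years and the cascade unfolds across the 50-year (18 250-day)
  horizon instead of equilibrating in weeks.  This is an *effective*
  velocity for the whole trans-synaptic seeding cascade, chosen so
  simulated natural histories span decades as amyloid deposition does; it
  is not an axonal-transport measurement.

Within a region, arrival of input produces a fast rise to a
(β₀, δ₀)-dependent equilibrium; globally the deposition pattern advances as
a wave quantized by the delay structure: bursts of arrival separated by
static plateaus.  Mid-life snapshots of such trajectories carry enough
information to recover β₀ and δ₀, which is the premise of the fitting
pipeline.  Cohort priors default to β₀ ~ U(0.3, 0.9), δ₀ ~ U(0.1, 0.5),
snapshot day ~ U(2000, 12000), noiseless patterns; connectomes default to
connected 3-D geometric-random graphs (density 0.5) with ACP weights
U(0.5, 0.9) and unit self-connections.

## Effective anatomical distance

Connection probabilities are converted to path lengths by
`len(p) = 1 − ln p` (a probability-1 link has length 1; rare links are
long), and the effective distance of a region to the outbreak set is the
multi-source shortest-path length by Dijkstra, excluding self-loops, with
+∞ for unreachable regions.  The alternatives `−ln p` and `1/p` are
selectable.  Weighted degree is the off-diagonal row sum of ACP.

## PET calibration

Regional deposition probabilities are derived from raw voxel signals by
reference-region extreme-value calibration: 40 000 bootstrap sub-samples
(default size 100) of the reference (cerebellar) voxel values yield an
empirical distribution of sub-sample maxima, fitted with a Gumbel law by
maximum likelihood (`scipy.stats.gumbel_r.fit`).  A voxel's deposition
probability is the Gumbel CDF of its signal — the probability of exceeding
a typical reference maximum — and a region's probability is the mean over
its voxels (a max aggregation is available behind a flag).  Rank recovery
through this chain is only defined up to distinguishable deposition
levels: regions with identical true deposition get identical expected
probabilities, so round-trip checks use graded patterns.

## Fitting by trajectory matching

For a candidate (β₀, δ₀) the deterministic model (σ = 0) is simulated once
from the seed set; the subject's best day is
`t_opt = argmin_t ‖P(t) − pattern‖₂` (earliest day on ties), and the outer
search over (β₀, δ₀) runs on a 12×12 log-spaced grid over [10⁻³, 1]²
followed by Nelder–Mead refinement in log-space.  Because the trajectory
depends only on the seed set and the constants, cohort fits share
simulations; a bounded cache keeps memory flat.

The single-day objective is globally awkward: a trajectory can sweep
*transiently* past the observed pattern, creating decoy local minima whose
floors undercut the immediate surroundings of the true optimum, which
itself sits at the bottom of a needle-thin valley aligned with proportional
rescalings of (β₀, δ₀).  Refinement therefore proceeds in three phases,
each only if the previous one has not reached the distance tolerance
(10⁻⁴): (1) shrinking-window log-grid zoom plus simplex on the single-day
objective from diverse top grid cells; (2) the same machinery guided by a
*persistence surrogate* — the minimum over t of the worse of the distances
at t and t + 150 days — which leaves quasi-stationary matches untouched
but erases transient decoys, with starts drawn from a finer streamed
24×24 grid; (3) dense diagonal scans of the surrogate through the best
point at small ratio offsets, exploiting the valley's orientation.  The
surrogate only selects starting points; reported `fit_distance`, `t_opt`
and parameters always come from the single-day objective.  The 150-day
window encodes the assumption that a PET snapshot reflects a
quasi-stationary deposition state, which holds for amyloid on clinical
timescales.

Identifiability caveat: on plateaus only the pattern, not the day, is
identifiable, and the earliest-tie rule snaps `t_opt` to the plateau start;
on synthetic cohorts ~85% of matched days land within 10% of the 50-year
horizon of their true snapshot day.  `onset_age = age − t_opt/365.25`
inherits this resolution.

**Seed search** scores a candidate outbreak set by the cohort-mean fit
distance, either exhaustively over all sets up to `max_k` regions (guarded
by an enumeration budget; C(78, 6) = 256 851 595 shows why) or greedily by
best augmentation.  Scoring uses a refinement-free 8×8 grid: relative
ranking needs far less precision than parameter recovery, and a 6×6 grid
proved too coarse (the planted pair could rank below its own singletons).
The epicenter scan correlates a deposition pattern with the effective
distances from each candidate region over the remaining regions; the most
negative correlation flags the likeliest outbreak origin.

## Analyses

- **Arrival times**: first day a region reaches a deposition threshold
  (0.1/0.5/0.9), +∞ if never.
- **Distance–time regression**: OLS of arrival times on effective
  distances (`scipy.stats.linregress`), non-finite pairs excluded pairwise.
- **Hub vulnerability**: Pearson correlation of weighted degree with
  arrival time, seeds excluded.
- **Null-model contrast**: the randomization null preserves the binary
  degree sequence exactly (Maslov–Sneppen double-edge swaps via networkx)
  and the multiset of (weight, fiber-length) edge pairs exactly; node
  strengths are preserved approximately by assigning the largest weights to
  the rewired edges whose endpoints had the largest original strengths
  (rank correlation ≥ 0.99 on 50-node graphs).  The empirical p-value uses
  the add-one convention (1 + #{null ≥ true})/(n + 1) and is never 0.
- **Split-half cross-validation**: group parameters are the medians of
  training-half fits (median for robustness; the aggregation rule is
  otherwise unconstrained); the test score is the mean explained variance
  (100·r²) of the group-parameter trajectory snapshot at each held-out
  subject's best-matching day.

## Numerical choices

- Integrator loop JIT-compiled with numba; states clipped to [0, 1] after
  every step; non-finite states raise.
- Delays rounded to the nearest whole step; dt default 1 day.  Halving dt
  leaves settled deterministic patterns unchanged to < 0.01 max-abs.
- Gini computed by the sorted-vector identity, O(N log N) per step,
  returning 0 for an all-zero state.
- Matrices are symmetrized by averaging only when max asymmetry ≤ 1e-9;
  anything larger is an error.
- Randomization retries are bounded; graphs too small or dense to swap
  raise instead of looping.

## Problem sizes

Default experiment scales — 10-node connectomes and 20-subject cohorts for
parameter recovery, 12 nodes for seed search, 15 nodes with 19
randomizations for the null contrast, 8-node chains and stars for the
arrival-time analyses, 500 voxels/region for PET round trips — are the
package's reference synthetic conditions; every number reported by
`scripts/acceptance.py` is recomputed at these scales at run time.

## What the synthetic generators do and do not emulate

Generated connectomes reproduce the structural facts the model consumes
(symmetry, [0, 1] weights, unit self-connections, millimetre lengths,
connectedness) but not the lognormal weight distributions, modularity or
hemispheric symmetry of real tractography connectomes.  Voxel tables have
independent Gaussian noise with a linear deposition-to-signal shift
(3·sd·P), no spatial autocorrelation or partial-volume effects.  Cohorts
share one connectome and one true seed set with independent per-subject
constants.  Passing tests therefore demonstrate internal consistency of
model, calibration and estimation machinery — not that real amyloid PET
data satisfy the model's assumptions.

## Known limitations

- The symmetric ACP matrix cannot represent anterograde/retrograde
  asymmetries; β₀ and δ₀ are global per subject, not regional.
- Fitting assumes the observed pattern arose from the modelled dynamics on
  the supplied connectome with the supplied seed set; model mismatch shows
  up only as a large residual distance.
- The stochastic integrator's clipping at the [0, 1] bounds makes extreme
  noise (σ ~ 1) a censored process; parameter estimates under large σ are
  best interpreted through the deterministic skeleton plus residual σ.
- `t_opt` is identifiable only up to the plateau containing the snapshot
  (see above).
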