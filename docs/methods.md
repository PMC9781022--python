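# Methods

## Model

The package studies escape (release) kinetics of a single coordinate
`y(t)` undergoing overdamped Langevin dynamics on a 1D potential `U(y)`:

    dy = -(D0/kT) dU/dy dt + sqrt(2 D0) dW

integrated with Euler–Maruyama, reflecting boundaries by position
mirroring, and escape defined as the *first touch* of an absorbing
threshold (no persistence or commitment window).  All internal units are
reduced: kT = 1, D0 = 1, lengths dimensionless; a converter maps to
physical units (angstrom, picosecond, kcal/mol at 310 K, where kT =
0.616 kcal/mol) at the configuration boundary only, so that
literature-style inputs such as a 7 kcal/mol bias cutoff or a ±8.5 Å
excluded region can be written verbatim.  The first-touch convention is
chosen because it makes the simulated observable identical to the one
the quadrature oracle computes, so oracle comparisons carry no
definitional slack.

Overdamped (rather than underdamped) dynamics is used because the
time-rescaling formalism is agnostic to the underlying dynamics while
the mean-first-passage-time (MFPT) quadrature is exact only in the
overdamped limit; the oracle is the point of the exercise.

## Surfaces and scenarios

* **Double well** `U = B (1 - (y/a)^2)^2`, minima at ±a, barrier B at 0.
  The validation landscape: runs start in the left well and are absorbed
  at the right minimum (one-sided absorption), matching the classic
  barrier-crossing set-up of the oracle.
* **Interlayer surrogate**: for |y| ≤ y_edge,
  `U = A sin^2(pi y / L)` — periodic binding sites standing in for the
  discrete contacts a guest makes while diffusing between host layers —
  and beyond the edge a logistic descent by ΔU_solv over a width w into
  a flat solvent region.  The surface is even in y (two symmetric
  exits), continuous and differentiable everywhere.
* **Surface well**: a Gaussian well of depth 3 kT, the fast-desorption
  case needing no bias.

Shipped defaults: corrugation depth 4 kT, period 1, edge at 6, solvation
drop 2 kT, edge width 1; absorbing threshold |y| = 8.5; start positions
0 (center), 3 (mid-way) and 5.8 (edge).  These values were chosen once
so that (i) every scenario's ground truth is computable by quadrature
and reachable by desk-scale brute force, and (ii) the release-time
ordering T(center) > T(mid) > T(edge) of the real layered system is
preserved (oracle values ≈ 99.9, 76.5 and 7.1 reduced time units).  No
free-energy profile along the release coordinate is available for the
real system; the surrogate's shape is a modeling choice, not a fit.

## Bias construction

**GAMBES (static).**  Bound-state samples come from a 2×10⁵-step
unbiased run subsampled every 10 steps, confined by reflection to the
scenario's bound region (the left well for the double well, |y| ≤ edge
for the interlayer).  Confinement matters: at an 8 kT barrier roughly a
third of unconfined fitting runs would cross into the product state and
the mixture would flood the transition region.  The density is an EM
Gaussian-mixture fit (scikit-learn, 5 seeded restarts, tolerance 1e-8,
≤500 iterations, default 3 components; components with variance below
1e-12 are pruned with a warning).  The bias is

    V(d) = kT log((P(d) + eps) / eps),   eps = P_max e^{-E_cut/kT},

i.e. the smoothed log-density shifted so V = 0 where P = 0.  The eps
rule makes the energy cutoff E_cut the effective bias ceiling: the exact
supremum is E_cut + kT log(1 + e^{-E_cut/kT}), within one part in a
thousand of E_cut for the defaults.  The shift is essential: an
unshifted bias would add a constant kT log eps everywhere, contaminating
the acceleration average with bias at the transition state.

**OPES flooding (on the fly).**  Every `pace` engine steps (default
500) a Gaussian kernel of fixed bandwidth σ is deposited at the current
CV value with weight `w = e^{V/kT}` evaluated under the bias in force
before the update, except inside the excluded region, where deposition
is forbidden (the bias still exerts force everywhere — only deposition
is excluded).  The density estimate and bias are

    P_n(s) = sum_k w_k G(s, s_k) / sum_k w_k,
    V_n(s) = (1 - 1/gamma) kT log((r + eps)/eps),   r = min(P_n/Z_n, 1),
    eps    = exp(-E_cut / ((1 - 1/gamma) kT)),

with γ = 10 by default and Z_n recomputed at every update as the mean of
P_n over the deposited kernel centers (quadratic in the kernel count,
negligible at desk scale).  The density ratio is saturated at 1 so that
E_cut is a hard ceiling on the deposited bias; in the saturated plateau
the bias force is zero.  Without the clamp the ceiling would float with
the peak-to-mean ratio of the kernel density, and the barrier parameter
would lose its meaning as a guaranteed flooding cap.  The bandwidth rule
is σ = 0.5 × the standard deviation of a short (2000-step) unbiased
bound run; the run is deliberately short so it samples a single local
well and σ resolves the finest feature of the landscape.  There is no
kernel merging or adaptive bandwidth shrinking: the estimator stays
transparent and oracle comparisons interpretable.

For the double-well validation runs the excluded region is y > -a/2
(everything from half-way up the barrier onward), which keeps the bias
at the barrier top below 10⁻⁴ E_cut; for interlayer runs the
paper-facing default |y| > 8.5 applies.

## Time rescaling and statistics

The acceleration factor is accumulated as the mean of `e^{V/kT}` over
every recorded step up to and including escape, using the instantaneous
bias at the visited point at the step when it is visited (for the static
GAMBES bias this coincides with re-evaluation under the final bias; for
OPES it is a convention, and the natural one for an evolving bias).
Biased production runs therefore record every step.

`tau` is estimated by least squares of the empirical CDF (plotting
positions i/n at the sorted times) against `1 - exp(-t/tau)`, with the
sample mean μ and standard deviation σ (n−1 denominator) reported
alongside — the two estimators differ and both are informative.  The
Poisson check is a one-sample KS test against the fitted exponential;
scipy's small-sample exact p-value is used for small n (the asymptotic
Kolmogorov distribution for large n).  Testing against a τ estimated
from the same data is mildly anti-conservative; a parametric bootstrap
(`n_bootstrap`, e.g. 200) that re-fits τ on each synthetic ensemble is
available behind a flag.  Under the null with τ known, the nominal 5%
test rejects 4–5% of the time (calibration is re-measured by the
acceptance script).  Runs that fail to escape within the step budget are
excluded from the fit, the censoring count is always reported, and a
warning is raised when it exceeds 20%.

The two-depth diffusion estimate `D ~ (y2 - y1)^2 / (t2 - t1)` converts
two release times measured from two starting depths into a rough
diffusion constant; it is deliberately crude (no geometry factor, no
distribution over exits) and is exposed as exactly that.

## The oracle

For reflecting boundary a and absorbing boundary b the MFPT from x0 is
the classical double quadrature

    T(x0) = (1/D0) ∫_{x0}^{b} e^{U(y)/kT} [∫_{a}^{y} e^{-U(z)/kT} dz] dy,

evaluated by composite trapezoids on 20 001 points with the max-U
subtracted before exponentiation (lossless rescaling) and a Richardson
error estimate from grid halving.  Trapezoid rather than adaptive
quadrature: predictable cost and a trivially verifiable convergence
order.  Asymmetric starts between two exits use the two-absorbing-
boundary solution; symmetric two-exit scenarios starting at the midpoint
reduce by symmetry to reflecting at 0 and absorbing at one exit (the
two-exit escape rate is twice the one-sided rate, verified against the
two-absorbing formula).

A note on Arrhenius checks: for the quartic family both well and barrier
curvatures scale with B, so the Kramers prefactor carries a 1/B factor
and the raw slope of ln T versus B is 1 − 1/B (≈0.86–0.88 over B = 6–10),
not 1.  The test suite therefore checks the slope of ln(T·B), which is
1/kT to within 5%.

## Synthetic fixtures

`generate_fixture` writes COLVAR-dialect ensembles whose *rescaled* exit
times are exponential with a known mean by construction: a physical time
is drawn first, then the apparent duration is found by accumulating
`e^{V/kT} dt` along a bias profile (zero, constant V0, or a bias trace
replayed from a real seeded flooding run) until the physical clock
reaches the draw.  The fixtures encode exactly the null hypothesis the
KS check tests, so failures in the analysis pipeline separate statistics
bugs from dynamics bugs.  Files are byte-reproducible from the manifest
seeds.

## What the surrogate does and does not show

Passing tests demonstrate that the bias construction, time rescaling,
exit-time statistics and oracle agree with each other on landscapes
where the truth is known, at the ensemble sizes a real study would use
(25 biased, 10 unbiased runs).  They do not validate force fields,
multidimensional effects (orientation, gating, solvent structure),
CV quality, or the absolute time scales of any atomistic system: the
surrogate's barriers (4–8 kT) were chosen for exact verifiability, not
realism.  Scenario escape from the layer edge is not barrier-limited, so
its exit times are visibly non-exponential — the fitted τ then sits
below the mean, a behaviour the real fast-release cases share.

## Problem sizes and numerical choices

Defaults: dt = 10⁻³ (validated against the harmonic-variance and
Einstein-relation tests), engine noise in blocks of 8192 from one
seeded generator per run (run i of an ensemble uses seed base + i),
record stride 1 for biased runs.  The test suite runs unbiased oracle
cross-checks at barriers 3–4 kT with 50–200 runs and biased recovery at
8 kT with 25 runs per method; these sizes keep a full run of suite plus
acceptance script under a minute each on a single core while leaving
every statistical tolerance at 3 standard errors or wider.  Quadrature
uses 20 001 grid points (relative error below 10⁻⁴ everywhere it is
used).  Tie-breaks and degenerate inputs: equal exit times yield σ = 0
and a finite fitted τ; a zero-kernel OPES state has V ≡ 0; a mixture
component collapsing to zero variance is pruned, never inverted.
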