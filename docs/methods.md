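# Methods

## The optimizers

Both algorithms evolve an `N x D` *pattern matrix* `P` of candidate solutions
inside a box `[low_j, up_j]`, tracking the best-so-far pair
`(best_sol, best_PV)`.  Each generation builds a trial matrix `T`, repairs any
out-of-bounds entry by uniform resampling inside its interval, evaluates, and
applies greedy one-to-one selection (`fitT <= fitP` accepts the trial, so ties
move to the trial).  The best record is therefore monotone and every trace is
non-increasing.

### Crossover ratio and activation matrix

Per individual a ratio `rho in [0, 1]` decides how many dimensions may change:
`max(1, ceil(rho * D))` distinct columns are activated in the binary mask `M`
(at least one, so no trial wastes an evaluation by duplicating its parent;
`[rho . D]` is read as a ceiling).

* **BSD** draws `rho` by picking one of the three 2nd-degree Bernstein
  polynomials `(1-b)^2, 2b(1-b), b^2` uniformly and evaluating it at
  `b ~ U(0,1)`.  This concentrates `rho` near small values (about 78 % of
  draws fall at or below 0.5).
* **NVSA** draws `rho` from the *normal vibration distribution*

      rho = e^(1/G) + 2 k1 (1 - k1) - e^(1 / (G (k4 - k5)^2 + P))

  with `k1..k5 ~ U(0,1)`, `G ~ U(a, b)` and `P ~ U(c, d)`.  Defaults
  `a, b, c, d = 1000, 10000, 3, 5`.  `G` sets the width of the subtractive
  "vibration" dip (larger `G` = narrower dip), `P` its depth scale, and `k5`
  places the dip.  When `k4 ~ k5` the dip term dominates and `rho` would go
  negative; the formula can leave `[0, 1]`, so values are clipped (the source
  description never defines out-of-range behaviour; clipping keeps `rho` a
  valid fraction, and the minimum-activation floor above handles `rho = 0`).
  The empirical mean at defaults is ~0.31 versus ~0.33 for the Bernstein
  scheme, with a fatter mid-range — more dimensions change per trial on
  average, which is the intended exploration boost.

### Search scale

* BSD broadcasts a single row (`eta^3 |lambda^3|`, nonnegative) or a single
  column (`lambda^3`) across the population, branch chosen once per
  generation by `u < v` with `u, v ~ U(0,1)`.
* NVSA draws a full independent `N x D` matrix: cubed uniforms when
  `u^3 < v` (small, strictly positive steps, probability 3/4), standard
  normals otherwise (signed, occasionally large steps).  `u, v` are drawn
  once per generation: the printed recipe presents a single branch for the
  whole matrix.

### Trial construction

Two permutations `L1, L2` of the population (elementwise `L1[i] != i`,
`L1[i] != L2[i]`, obtained by rejection sampling; this requires `N >= 4`)
pick donor individuals.

    BSD :  E = W o P[L1] + (1 - W) o P[L2]
           T = P + M o F o (w*^3 o E + (1 - w*^3) o best_PV - P)
    NVSA:  T = P + M o (F o (s o (w1 o P[L1]) + w2 o P[L2])
                        + w3 o best_PV - P)

with `W, s, w1, w2, w3` full `N x D` matrices (`s` standard normal, the rest
uniform) and `w*` an N-vector broadcast across columns.  The printed form of
both update rules drops one opening parenthesis; the implementations use the
unique placement (after `M`) that balances them.  The readings differ in one
important way: in BSD the mask scales a *difference from the parent*, so BSD
trials are classic DE perturbations, while in NVSA the mask *selects between
parent and a rebuilt coordinate* `F(s w1 P_L1 + w2 P_L2) + w3 best`.  Active
NVSA coordinates are not anchored on their parent; the `w3 o best` term
proposes randomly shrunken copies of the incumbent, giving a per-coordinate
multiplicative contraction whenever contraction pays off.  On benchmark
functions whose optimum sits at the origin this contraction proceeds
geometrically until the objective underflows — sphere runs routinely end at
exactly 0.0 in double precision, and Rastrigin/Griewank reach exact zeros
once all coordinates drop below ~1e-9 (where `10(1 - cos 2*pi*x)` rounds to
zero).  The flip side is an origin bias on problems whose optimum lies far
from zero (Rosenbrock, Schwefel 2.26); the same behaviour is visible in the
published comparison tables this package mirrors.

Randomness: one `numpy.random.Generator` per `optimize()` call; draw order
per generation is activation matrix (one `rho` per row, then the column
shuffle), search scale, permutations, trial weights, boundary repairs.  Runs
are bit-reproducible from the seed.  Maximisation is implemented by negating
the objective; non-finite objective values become `+inf` fitness with a
warning and are never selected.  Total objective calls are exactly
`N (epochs + 1)`.

## Benchmark suite

The 23 classic test functions (sphere, Schwefel 2.22/1.2/2.21, Rosenbrock,
step, quartic-with-noise, Schwefel 2.26, Rastrigin, Ackley, Griewank, the two
penalized functions, Shekel foxholes, Kowalik, six-hump camel, Branin,
Goldstein-Price, Hartmann 3/6, Shekel 5/7/10) in their standard Yao-style
forms and boxes, D = 30 for the scalable ones.  The quartic function's
additive `U(0,1)` noise comes from the run's seeded stream so suites are
reproducible; suite runs use seeds `base + run_index`.  The full protocol is
50 particles, 1000 iterations, 30 runs, mean and standard deviation reported.
Several published fixed-dimension reference values are inconsistent with the
classic forms (they come from a platform's variants); only the zero-optimum
targets are treated as reproducible.

## Registration pipeline

Intensities are affinely rescaled to `[0, 256]`.  The objective is normalised
mutual information `NMI = (H(M) + H(F)) / (2 H(M,F))`, computed from a
`bins x bins` equal-width joint histogram over `[0, 256]` (default 64 bins:
a full 256^2 histogram is badly undersampled for 256 x 256 slices; the bin
count is configurable).  `NMI = 1` for identical images, -> 0.5 for
independent ones; the log base cancels.  RMSE is the auxiliary metric.

Transforms: similarity `(theta [deg], scale, tx, ty)` or affine
`(a11, a12, a21, a22, tx, ty)`, acting about the image centre
`((W-1)/2, (H-1)/2)` on 0-based pixel-centre coordinates (x = column,
y = row).  The 2x3 matrix is used as the output-to-input sample map of an
inverse-mapping bilinear warp; out-of-frame samples are zero-filled and those
pixels *are* included in the histogram (configurable semantics would change
the overlap-area meaning, so this is fixed and documented).  If fewer than
25 % of output samples land inside the moving frame the objective returns its
worst value, which removes the trivial everything-out-of-frame optimum.

Search bounds: rotation `[0, 360]` degrees and translation `[-30, 30]` px
(the comparison protocol), scale `[0.5, 1.5]` (unstated in the protocol;
wide enough to cover a CT-to-MR half-size factor).  The optimizer runs with
population 30 and 100 generations, maximising NMI by negation; reported NMI
is recomputed from the final transform.  The two-stage IST mode first fits a
similarity transform, then an affine refinement whose coefficient bounds are
the stage-1 matrix +-0.3 (linear part) and +-15 px (translation), with the
stage-1 solution injected into the initial population; stage 2 can therefore
never score below stage 1, and zero deltas return the stage-1 transform
unchanged.  Optional preprocessing mirrors the cross-tool protocol: bicubic
half-size downsampling and a central 208 x 208 crop.

## Phantom generator

Real CT-MR slice pairs are emulated by seeded synthetic pairs: an anatomy of
soft-edged (~1.5 px anti-aliasing) ellipses and rectangles with distinct
intensities over a gentle background ramp, lightly Gaussian-smoothed; the
fixed and moving images view it through different monotone gamma curves with
optional inversion (defaults: identity for fixed, gamma 2.2 + inversion for
moving), so intensities disagree — aligned pairs are anticorrelated — while
structure agrees.  The ground-truth transform displaces the anatomy *before*
the moving-side remap and Gaussian noise (default sigma 4 on the 0-256 scale,
~1.5 % — a realistic acquisition-noise level), so registration recovers
exactly the ground-truth parameters.  Difficulty tiers: easy (similarity,
|t| <= 15 px, |theta| <= 15 deg, scale 1), medium (|t| <= 20, |theta| <= 30,
scale 0.9-1.1), hard (affine with shear up to 0.1).

What the phantoms do not emulate: modality physics (Hounsfield/relaxation
contrast), anatomy-dependent texture, bias fields, partial-volume effects and
slice-selection differences.  Passing recovery tests therefore demonstrates
the optimizer/metric machinery, not clinical-grade accuracy on real scans.

Recovery is scored by per-parameter deltas (angles wrapped to `[0, 180]`) and
a target registration error: the mean displacement of the four image corners
under `recovered o gt^-1`.

## Comparison statistics

Results are long-format records `(algorithm, scenario, run, metric, value)`.
Friedman mean ranks rank algorithms 1..k within each scenario ascending in
value with average-rank ties (so the best NMI receives rank k and the best
RMSE rank 1) and average over scenarios; mean ranks always sum to
`k(k+1)/2`.  The pairwise two-tailed Wilcoxon signed-rank test drops zero
differences, uses average ranks on `|d|` and the normal approximation
`z = (min(R+, R-) - m(m+1)/4) / sqrt(m(m+1)(2m+1)/24)` *without* continuity
correction — this convention reproduces the reference value p = 1.73e-6 for
30 one-signed differences (the exact-distribution p at n = 30 would be
~1.9e-9).  For n <= 10 the approximation sits within ~10 % of the exact
distribution for mid-range statistics but is materially anticonservative in
the far tails.  Bonferroni adjustment is `min(1, m p)` with `m = 15` for the
six-algorithm pairwise family (consistent with the published
0.013 -> 0.198 and 0.001 -> 0.018 adjustments).  A transcribed 41-scenario,
six-algorithm NMI/RMSE table ships as the reference fixture; absolute
re-registration of those values is out of scope (it would require the
original clinical data and unstated histogram settings).

## Problem sizes used by the shipped tests

Unit and acceptance tests pick sizes that exercise the full protocol while
staying desk-scale: benchmark zero-mean checks run 15 seeds per function
(each run individually reaches exactly 0, so the mean is unchanged from the
30-run protocol; the acceptance script uses the full 30), sphere deep
convergence runs the full 30 x (50 x 1000) protocol, similarity recovery uses
one 256 x 256 easy phantom with 20 optimizer seeds, the IST check a 192 x 192
affine phantom, and the corner-error sweep twenty 128 x 128 medium phantoms.
At 128 x 128 and 64 bins the NMI plateau leaves the rotation estimate
~1.5 deg of slack, which is why the 1-degree recovery check uses the full
256 x 256 rendering.

## Known limitations

* The NVSA trial rule's origin bias means parameterisations should place
  "no change" near zero (the registration translations do; rotation uses
  degrees in [0, 360] where the pull toward 0 is equivalent to a pull toward
  the identity for small rotations).
* The Wilcoxon p-values are normal approximations by design (see above).
* Registration is 2D, linear (similarity/affine), single-metric (NMI with
  RMSE reporting); no deformable models, no 3D, no other similarity measures.
* Wall-clock timings are logged by the CLI but never asserted anywhere.
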