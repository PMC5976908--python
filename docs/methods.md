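# Methods

## Model and assumptions

The package models an expanding MSC culture as two well-mixed compartments:
dividing cells `x1` and nondividing cells `x2` (mostly replicatively
senescent; spontaneous differentiation in plain expansion medium is
negligible). Three biological rates are encoded:

- `r1` (1/day) — net expansion rate of dividing cells. Division and death of
  dividing cells are not separately identifiable from total-count data, so
  they are collapsed into their difference.
- `r20` (1/day) — death rate of nondividing cells.
- `r12(t)` (1/day) — the dividing→nondividing transition rate. Senescence is
  irreversible (no back-transition) and, at the population level, gradual:
  `r12` is a logistic function of culture time with upper bound `L`,
  steepness `k`, and midpoint `T` (days). `T` is the model's indicator of
  senescence pace.

Constant `r1` and `r20` are the usual simplification for rates that change
little over a culture's life; all time dependence is concentrated in
`r12(t)`. The feasibility box `0 < r1 < 1`, `0 < r20 < 1`, `r1 < L < 1`,
`0 ≤ k < 1`, `T > 0` keeps rates biologically plausible; `L > r1` makes the
dividing pool eventually shrink (`r1 − r12(t) < 0` past
`t_c = T − ln(L/r1 − 1)/k`), so cumulative population doublings
`PD = log2(y/y0)` plateau at a finite value. `k = 0` is admitted as the
constant-rate special case `r12 ≡ L/2`, which has a closed-form solution and
serves as an integration oracle. PD is scale invariant, so simulations run
from a normalized population `y(0) = 1`; absolute counts are never needed.

Measurements enter as `(time, cumulative PD)` pairs or as per-passage fold
increases, accumulated via `PD(t_k) = Σ_{i≤k} log2 f(t_i)`.

## Numerics

Two forward evaluators agree to ~1e-10 relative error and are cross-checked
in the test suite:

- `simulate` — adaptive explicit Runge-Kutta (scipy RK45) with rel_tol 1e-8
  / abs_tol 1e-10; the system is smooth, nonstiff, and two-dimensional.
  Excursions of a state below zero at the solver's output points are
  integration noise near the origin (the exact solution is nonnegative) and
  are clipped to zero; excursions beyond 1e3·abs_tol raise instead.
- `semi_analytic_states` — the dividing compartment has the closed form
  `x1(t) = x1(0) exp(r1 t − R(t))` with the transition exposure
  `R(t) = ∫ r12 = (L/k)[softplus(k(t−T)) − softplus(−kT)]`; the nondividing
  compartment is the convolution `∫ e^{−r20(t−s)} r12(s) x1(s) ds`,
  evaluated by composite 12-node Gauss-Legendre quadrature on subintervals
  of ≤ 2 days. This path is ~40× faster than stepwise integration and backs
  the repeated evaluations inside fitting and sensitivity scans; it falls
  back to Runge-Kutta when its intermediate exponentials would overflow
  (horizons beyond ~600/(r1+r20) days).

Other numerical choices: the half-dividing time is located on a 0.1-day grid
and refined by bracketing on the solver's continuous output (well inside
0.01 days); "stationary-phase PD" is read as the maximum of PD over a dense
grid on `[0, t_eval]` (default 200 days, 0.25-day spacing) because the total
population drains slowly after the plateau, making "PD at stationary phase"
ambiguous — the maximum is the plateau value and insensitive to the horizon.

A nuance the dividing-fraction analysis exposed: past the plateau the
fraction `x1/y` tends to zero only when `L − r1 > r20` (the dividing pool
shrinks faster than the nondividing pool dies). The experiment-A hypoxia
parameters satisfy this; the normoxia column has `r20` slightly larger than
`L − r1`, so its dividing fraction bottoms out near zero around day 300 and
then creeps back up. The headline half-crossing times are unaffected.

## Fitting

The cost is the plain sum of squared residuals on the PD scale — growth
curves are reported in PD, and fitting raw counts instead would let the last
few of 20+ doublings dominate the objective. The initial composition is
assumed all-dividing (`x2(0) = 0`), matching how cultures are seeded;
a nonzero starting fraction is exposed as a configuration knob, and fits are
insensitive to a 10% nondividing start (all parameters move < 10%, most
< 2%, in the noiseless check).

The box constraints are handled by a trust-region-reflective least-squares
solver (scipy) on the internal coordinates `(r1, r20, δ, k, T)` with
`L = r1 + δ(1 − r1)`, `δ ∈ (1e-6, 1 − 1e-6)`, which makes `r1 < L < 1`
strict by construction. Finite-difference steps are 1e-5 relative so the
jacobian stays above forward-model noise. The problem is nonconvex, so the
fit is multistarted deterministically: the cost is screened on a full grid
(default 3 points per free parameter at 25/50/75% of each range, 243
starts), and the best 8 starts are refined; ties within 1e-9 break toward
the lower start index, so results are reproducible bit for bit. Refining
every start was ~100× more expensive without ever changing the returned
minimum in development runs. The upper bound `ts` for `T` defaults to 1.2×
the last measurement time. Datasets with fewer points than free parameters
fit anyway but carry an "under-determined" warning.

The exponential-phase anchor uses ordinary least squares of PD on time with
a free intercept (ideal data pass through the origin, measured data need
not); the slope `s` gives `r1 = s / log2(e)`.

### Hybrid procedure for exponential-phase-only pairs

When both conditions were only observed while still growing exponentially
(the 84-day experiment-B design): anchor `r1` from the hypoxic slope, fit
the remaining four parameters to the normoxic curve with `r1` fixed, then
build hypoxic parameter sets with `r20` and `L` copied from the normoxic
fit, a manually chosen steepness (`k = 0.15`), and a swept midpoint `T`.
Every parameter carries a provenance flag
(fitted/fixed/anchored/copied/swept).

Two identifiability facts, both reproduced by tests, shape how the sweep
should be read. First, `r20` is essentially unidentifiable from pre-plateau
data (it only acts on the still-small nondividing pool): with a slightly
biased anchor the normoxic fit pushes `r20` to its lower bound while `T`,
`k`, `L` stay within ~1%, and with an exact anchor all four recover exactly.
Second, the candidate-cost curve over `T` is one-sided: candidates earlier
than the truth are rejected sharply (their senescence drag bends the curve
away from the data), while candidates later than the truth are nearly
indistinguishable — the anchored slope absorbs part of the drag, slightly
favouring larger `T`. The sweep therefore brackets `T` from below but cannot
pin it from above, which is exactly why a delay of `T` must be reported as a
family of equally well-fitting curves rather than a point estimate. The
plateau consequence is sharp nonetheless: each 10-day delay of `T` adds
`≈ r1·log2(e)·10 ≈ 6.8` doublings.

## Sensitivity analysis

One-at-a-time scan: each parameter in turn is multiplied by `1 + ε`,
`ε ~ U(−h, h)` with `h = 0.10` by default, others held at their nominal
values; the output is the plateau PD (`t_eval = 200` days) and the score is
the K−1-denominator standard deviation over `K = 1000` draws. Perturbations
are multiplicative because the parameters span two orders of magnitude.
Draws violating feasibility (e.g. pushing `L` under `r1`) are redrawn rather
than clipped — clipping would pile probability on the boundary — and the
redraw count is reported; each parameter uses its own seeded stream
(`seed + parameter index`) so results do not depend on evaluation order.
`h = 0` is admitted and yields exactly zero scores.

Redrawing has a visible consequence when `L` sits close above `r1` (the
experiment-A normoxia column: 3.3% apart): upward `r1` perturbations beyond
that gap are redrawn, truncating the effective distribution, so scores for
`r1` and `L` there grow sublinearly in `h`. The linear-scaling check
(doubling `h` doubles the scores, within 25%) therefore uses the hypoxia
column, where ±10% is feasible throughout.

## Synthetic data

The generator simulates the model at sparse design times and adds
independent Gaussian noise on the PD scale (default σ = 0.3 PD), a stand-in
for counting plus figure-digitization error, which is roughly multiplicative
in cell number; σ is exposed because the true extraction error of digitized
growth curves is unknown. Fold-mode output differences the noisy PD into
per-passage fold increases, the exact inverse of the accumulation formula.
Two deterministic, noiseless fixtures emulate the published designs: six
20-day-spaced points over 120 days (experiment A) and seven 12-day passages
over 84 days (experiment B, hypoxic series within the exponential phase).
Real digitized data differ from these fixtures in having unknown,
possibly time-correlated measurement error and unevenly spaced sampling, so
passing recovery tests here demonstrates correctness of the machinery, not
field accuracy on any particular published dataset.

## Problem sizes in the test suite

Unit tests use scaled-down Monte-Carlo sizes (K = 200–400 per parameter for
ranking stability and convergence checks; 20 seeds × 12 points for the noisy
recovery study); the end-to-end checks in `tests/test_acceptance.py` run the
full K = 1000 sensitivity scan. All randomness is seeded; the whole suite is
deterministic.

## Known limitations

- Oxygen enters only as two discrete conditions (parameter sets), not as a
  continuous input; no intracellular mechanism (HIF-1, p16/p21/p53, ROS) is
  represented.
- No uncertainty quantification on fitted parameters (point estimates and
  multistart diagnostics only).
- The hybrid procedure's `k` for the second condition is an input, not
  estimated; `T` is deliberately reported as a swept family (see above).
- The plateau-PD readout depends mildly on the `t_eval` convention when
  `r20` is large (faster post-plateau drainage).
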