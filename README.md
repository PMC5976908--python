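# mscgrowth

Kinetics of human mesenchymal stem cell (MSC) long-term expansion, for
researchers who grow MSCs ex vivo and want to quantify how culture
conditions — in particular oxygen tension — change the pace of replicative
senescence and the eventual cell yield.

## The model

A culture is split into dividing cells `x1` and nondividing (predominantly
senescent) cells `x2`. Dividing cells expand at a constant net rate `r1`
(division minus death) and irreversibly become nondividing at a time-varying
rate `r12(t)`; nondividing cells die at rate `r20`:

```
dx1/dt = (r1 − r12(t)) · x1
dx2/dt = r12(t) · x1 − r20 · x2
y(t)   = x1(t) + x2(t)
```

Senescence accumulates gradually with culture age, so the transition rate is
logistic in time,

```
r12(t) = L / (1 + exp(−k (t − T))),
```

with upper bound `L` (required to exceed `r1`, so growth eventually stops),
steepness `k`, and midpoint `T` — the package's central readout for how fast
a culture senesces. Cell yield is reported as cumulative population
doublings, `PD(t) = log2(y(t)/y(0))`.

The package provides:

- **model** — simulation (adaptive Runge-Kutta plus a semi-analytic fast
  path), PD arithmetic, dividing-fraction analysis, half-dividing time,
  plateau PD, stability onset, and constant-rate closed-form oracles;
- **fitting** — constrained multistart nonlinear least squares on the PD
  scale (box constraints `0 < r1 < 1`, `0 < r20 < 1`, `r1 < L < 1`,
  `0 < k < 1`, `0 < T < ts`), an exponential-phase slope anchor
  (`PD ≈ r1·log2(e)·t`), and a hybrid procedure for paired conditions when
  only the exponential phase was observed;
- **sensitivity** — one-at-a-time ±10% perturbation scans scored by the
  standard deviation of the plateau PD;
- **synthetic** — a growth-curve generator (model + Gaussian PD-scale noise)
  and deterministic fixtures emulating two published long-term expansion
  experiments (~120 days at 3% vs 20% O2; 84 days at 1% vs 21% O2);
- a thin `mscgrowth` CLI (`simulate`, `fit`, `fit-expb`, `sensitivity`,
  `synth`) over the same API.

## Worked example

```python
import numpy as np
from mscgrowth import InitialComposition, half_dividing_time, simulate
from mscgrowth.presets import EXPERIMENT_A

grid = np.linspace(0.0, 120.0, 241)
for condition, params in EXPERIMENT_A.items():
    traj = simulate(params, InitialComposition(), grid)
    print(condition, round(traj.pd[-1], 2), round(half_dividing_time(params), 1))
```

prints

```
normoxia 27.11 51.3
hypoxia 38.63 75.5
```

— by day 120 the hypoxic culture has reached 38.6 cumulative doublings
against 27.1 under normoxia, and its dividing fraction does not drop to one
half until day 75.5 versus day 51.3: with near-identical division and death
rates, the ~25-day delay of the senescence midpoint `T` alone accounts for
the extra yield. The scripts in `examples/` walk through each capability
(simulation, noisy-data fitting, the hybrid exponential-phase procedure, and
sensitivity ranking) and print what the numbers mean.

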