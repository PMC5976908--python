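"""Hybrid fitting when only the exponential growth phase was observed.

Experiment-B-style data stop at 84 days, before senescence plateaus the
growth curve.  The hypoxic series is then an almost perfect straight line in
PD, so: r1 is anchored from its slope, the normoxic curve is fitted over the
remaining four parameters, and the hypoxic condition inherits r20 and L from
the normoxic fit while the undetermined midpoint T is swept over candidates.
The printed candidate costs are nearly flat for T >= 100 — the
non-identifiability that motivates the sweep — while each 10-day delay of T
adds ~6.8 PD to the eventual plateau.
"""

from mscgrowth import fit_experiment_b, make_fixture_experiment_b, stationary_pd
from mscgrowth.presets import experiment_b_hypoxia

hypoxic, normoxic = make_fixture_experiment_b()
result = fit_experiment_b(hypoxic, normoxic, T_candidates=(100.0, 110.0, 120.0))

s = result.slope_fit
print(f"hypoxic slope: {s.slope:.4f} PD/day  (r^2 = {s.r_squared:.6f})")
print(f"anchored r1 = slope / log2(e) = {s.r1:.4f} 1/day")
print("\nnormoxic fit (r1 fixed):")
for name, how in result.normoxic.provenance.items():
    print(f"  {name:>3} = {getattr(result.normoxic.params, name):8.4f}  [{how}]")

print("\nhypoxic midpoint candidates:")
for fit in result.hypoxic:
    plateau = stationary_pd(experiment_b_hypoxia(fit.params.T), t_eval=200.0)
    print(f"  T = {fit.params.T:5.1f} d: cost on 7 points = {fit.cost:8.4f}, "
          f"plateau PD = {plateau:5.1f}")
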