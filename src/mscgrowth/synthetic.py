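"""Synthetic growth curves with the statistical structure of real data.

Long-term MSC expansion datasets are sparse (half a dozen measurements
over 80-120 days) and reported as cumulative population doublings or as
per-passage fold increases.  The generator simulates the two-compartment
model, samples the PD curve at the design times, and adds independent
Gaussian noise on the PD scale (default sd 0.3 PD), mimicking counting
and figure-digitization error that is roughly multiplicative in cell
number.

Two deterministic, noiseless fixtures stand in for the published growth
curves of the two source experiments:

* experiment A — six measurements per oxygen condition at 20-day spacing
  over 120 days of culture (3% vs 20% O2);
* experiment B — seven measurements at 12-day passage intervals over
  84 days (1% vs 21% O2), with the hypoxic series still in the
  exponential growth phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

from .datasets import GrowthDataset
from .model import (
    DEFAULT_SOLVER,
    InitialComposition,
    ModelParameters,
    SolverSettings,
)
from .fitting import model_pd
from .presets import EXPERIMENT_A, experiment_b_hypoxia, EXPERIMENT_B

__all__ = [
    "SyntheticDesign",
    "generate_growth_curve",
    "make_fixture_experiment_a",
    "make_fixture_experiment_b",
]


@dataclass(frozen=True)
class SyntheticDesign:
    """Sampling plan and noise model for one synthetic growth curve."""

    sampling_times: Sequence[float]
    noise_sd: float = 0.3
    seed: int = 0
    representation: str = "pd"
    init_fraction: float = 0.0
    condition_label: str = ""
    solver: SolverSettings = DEFAULT_SOLVER

    def __post_init__(self) -> None:
        times = np.asarray(self.sampling_times, dtype=float)
        if times.size < 1 or times[0] < 0:
            raise ValueError("sampling times must be nonnegative, at least one")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("sampling times must be strictly increasing")
        object.__setattr__(self, "sampling_times", times)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.representation not in ("pd", "fold"):
            raise ValueError("representation must be 'pd' or 'fold'")
        if not (0.0 <= self.init_fraction < 1.0):
            raise ValueError("init_fraction must lie in [0, 1)")


def generate_growth_curve(
    params: ModelParameters, design: SyntheticDesign
) -> GrowthDataset:
    """Simulate, sample, and perturb one growth curve.

    Noise is additive Gaussian on the cumulative-PD scale, independent per
    time point, and deterministic per seed.  For ``representation="fold"``
    the noisy cumulative PD is differenced back into per-passage fold
    increases (``f_k = 2^(PD_k - PD_{k-1})``), the exact inverse of the
    PD accumulation formula, so the round trip is lossless.
    """
    times = np.asarray(design.sampling_times, dtype=float)
    pd = model_pd(params, times, design.init_fraction, design.solver)
    if design.noise_sd > 0:
        rng = np.random.default_rng(design.seed)
        pd = pd + rng.normal(0.0, design.noise_sd, size=pd.size)
    if design.representation == "pd":
        return GrowthDataset(
            times=times, pd_values=pd, condition_label=design.condition_label
        )
    folds = 2.0 ** np.diff(np.concatenate(([0.0], pd)))
    return GrowthDataset(
        times=times, fold_values=folds, condition_label=design.condition_label
    )


_EXP_A_TIMES = (20.0, 40.0, 60.0, 80.0, 100.0, 120.0)
_EXP_B_TIMES = (12.0, 24.0, 36.0, 48.0, 60.0, 72.0, 84.0)


def make_fixture_experiment_a() -> Tuple[GrowthDataset, GrowthDataset]:
    """Noiseless 6-point growth curves (hypoxia, normoxia) over 120 days."""
    out = []
    for label in ("hypoxia", "normoxia"):
        design = SyntheticDesign(
            sampling_times=_EXP_A_TIMES, noise_sd=0.0, condition_label=label
        )
        out.append(generate_growth_curve(EXPERIMENT_A[label], design))
    return tuple(out)


def make_fixture_experiment_b(
    T_hypoxia: float = 110.0,
) -> Tuple[GrowthDataset, GrowthDataset]:
    """Noiseless 7-point growth curves (hypoxia, normoxia) over 84 days.

    The hypoxic series uses the hybrid parameter set with the chosen
    midpoint time (default 110 days) and lies in the exponential phase
    throughout the sampled window.
    """
    hyp = generate_growth_curve(
        experiment_b_hypoxia(T_hypoxia),
        SyntheticDesign(
            sampling_times=_EXP_B_TIMES, noise_sd=0.0, condition_label="hypoxia"
        ),
    )
    norm = generate_growth_curve(
        EXPERIMENT_B["normoxia"],
        SyntheticDesign(
            sampling_times=_EXP_B_TIMES, noise_sd=0.0, condition_label="normoxia"
        ),
    )
    return hyp, norm
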