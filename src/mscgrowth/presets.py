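"""Published parameter sets for two long-term MSC expansion studies.

Experiment A: bone-marrow MSCs cultured ~120 days at 3% O2 (hypoxia) vs
20% O2 (normoxia); all five parameters were fitted per condition.

Experiment B: MSCs cultured 84 days at 1% O2 vs 21% O2. Only the
exponential growth phase was observed, so the hypoxic parameters are a
hybrid: r1 anchored from the hypoxic growth slope, r20 and L copied from
the normoxic fit, k set manually to 0.15, and the midpoint time T left
undetermined (values of 100-120 days fit the data equally well; 110 is
used as the default stand-in).
"""

from .model import ModelParameters

__all__ = [
    "EXPERIMENT_A",
    "EXPERIMENT_B",
    "EXPERIMENT_B_HYPOXIA_K",
    "EXPERIMENT_B_HYPOXIA_DEFAULT_T",
    "experiment_b_hypoxia",
    "preset",
]

EXPERIMENT_A = {
    "normoxia": ModelParameters(r1=0.3472, r20=0.0133, L=0.3588, k=0.3169, T=47.3494),
    "hypoxia": ModelParameters(r1=0.3505, r20=0.0183, L=0.3967, k=0.3944, T=72.3664),
}

EXPERIMENT_B = {
    "normoxia": ModelParameters(r1=0.4679, r20=0.0286, L=0.5864, k=0.0404, T=79.0046),
}

#: Manually tuned steepness for the experiment-B hypoxic condition.
EXPERIMENT_B_HYPOXIA_K = 0.15

#: Stand-in midpoint time for the experiment-B hypoxic condition (days).
EXPERIMENT_B_HYPOXIA_DEFAULT_T = 110.0


def experiment_b_hypoxia(T: float = EXPERIMENT_B_HYPOXIA_DEFAULT_T) -> ModelParameters:
    """Experiment-B hypoxic parameter set with a chosen midpoint time."""
    n = EXPERIMENT_B["normoxia"]
    return ModelParameters(r1=n.r1, r20=n.r20, L=n.L, k=EXPERIMENT_B_HYPOXIA_K, T=T)


_PRESETS = {
    "expA-normoxia": lambda: EXPERIMENT_A["normoxia"],
    "expA-hypoxia": lambda: EXPERIMENT_A["hypoxia"],
    "expB-normoxia": lambda: EXPERIMENT_B["normoxia"],
    "expB-hypoxia": experiment_b_hypoxia,
}


def preset(name: str) -> ModelParameters:
    """Look up a named condition, e.g. ``"expA-normoxia"``."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
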