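"""Model parameters, defaults, and validity-range warnings.

Defaults follow the reference parameterization of the circuit family: all
intrinsic time constants 1 ms, derivative-coupling coefficient alpha = 10,
semisaturation constant sigma = 0.07, input gain beta = 1, feedback gain
gamma = 1.  Values outside the tested stability ranges trigger a warning,
not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "AreaParameters",
    "GainState",
    "ParameterRangeWarning",
    "INHIBITORY_FEEDBACK_FRACTION",
    "MODULATORY_INPUT_FRACTION",
    "VALID_RANGES",
]

#: Fixed fraction of the feedback drive routed to the inhibitory modulators.
INHIBITORY_FEEDBACK_FRACTION = 0.50
#: Fixed input gain of the modulatory excitatory population.
MODULATORY_INPUT_FRACTION = 0.50

#: Tested stability ranges; outside these the circuit is not guaranteed stable.
VALID_RANGES = {
    "gamma": (0.0, 1.1),
    "beta": (0.0, 2.5),
    "alpha": (7.5, 50.0),
    "sigma": (0.035, 0.14),
}


class ParameterRangeWarning(UserWarning):
    """A parameter lies outside the tested stability range."""


def warn_if_outside(name: str, value: float) -> None:
    lo, hi = VALID_RANGES[name]
    if not (lo <= value <= hi):
        warnings.warn(
            f"{name}={value} outside tested stability range [{lo}, {hi}]",
            ParameterRangeWarning,
            stacklevel=3,
        )


@dataclass(frozen=True)
class AreaParameters:
    """Intrinsic per-area parameters.

    Time constants are in milliseconds; ``alpha`` (derivative coupling of the
    inhibitory modulators to the excitatory-modulator dynamics) and ``sigma``
    (semisaturation constant of normalization) are dimensionless.
    """

    tau_y: float = 1.0
    tau_u: float = 1.0
    tau_a: float = 1.0
    tau_q: float = 1.0
    alpha: float = 10.0
    sigma: float = 0.07
    pool_rate: float = 2.0

    def __post_init__(self) -> None:
        for name in ("tau_y", "tau_u", "tau_a", "tau_q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        warn_if_outside("alpha", self.alpha)
        warn_if_outside("sigma", self.sigma)


@dataclass(frozen=True)
class GainState:
    """Input gain (beta) and feedback gain (gamma) of one area / edge.

    The two fixed fractions are constants of the model: the feedback drive to
    the inhibitory modulators and the input gain of the excitatory modulators
    are both pinned at 0.50, so beta and gamma set the *relative* gain to the
    principal cells.
    """

    beta: float = 1.0
    gamma: float = 1.0
    inhibitory_feedback_fraction: float = INHIBITORY_FEEDBACK_FRACTION
    modulatory_input_fraction: float = MODULATORY_INPUT_FRACTION

    def __post_init__(self) -> None:
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be >= 0")
        warn_if_outside("beta", self.beta)
        warn_if_outside("gamma", self.gamma)
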