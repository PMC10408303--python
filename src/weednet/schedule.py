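"""Learning-rate control: untuned exponential warmup x cosine annealing.

The warmup factor is tied to the optimiser's second-momentum coefficient:

    warmup_period = 2 / (1 - beta2)
    omega(t)      = 1 - exp(-(1 - beta2) * t)

so no warmup length has to be tuned; omega saturates naturally (it is
within 1 - e^-2 of 1 at the nominal period) and stays active for the whole
run.  The annealing factor is the standard half-cosine spanning the entire
run, and the applied rate is the product

    lr(t) = lr_init * omega(t) * 0.5 * (1 + cos(pi * t / T)).

The curve therefore rises from zero while warmup dominates and decays to
zero at t = T under the cosine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def warmup_period(beta2: float) -> float:
    """Nominal number of steps consumed by the untuned exponential warmup."""
    if not 0.0 < beta2 < 1.0:
        raise ValueError(f"beta2 must lie in (0, 1), got {beta2}")
    return 2.0 / (1.0 - beta2)


def warmup_factor(t: int, beta2: float = 0.999) -> float:
    """omega(t) = 1 - exp(-(1-beta2) t), strictly increasing on [0, 1)."""
    if t < 0:
        raise ValueError(f"step index must be non-negative, got {t}")
    if not 0.0 < beta2 < 1.0:
        raise ValueError(f"beta2 must lie in (0, 1), got {beta2}")
    return 1.0 - math.exp(-(1.0 - beta2) * t)


@dataclass(frozen=True)
class ScheduleConfig:
    """lr_init: peak-scale initial rate; beta2: Adam second-momentum
    coefficient (also sets the warmup time constant); total_steps: T."""

    lr_init: float = 1e-4
    beta2: float = 0.999
    total_steps: int = 1

    def __post_init__(self):
        if self.lr_init <= 0:
            raise ValueError("lr_init must be positive")
        if not 0.0 < self.beta2 < 1.0:
            raise ValueError("beta2 must lie in (0, 1)")
        if self.total_steps < 1:
            raise ValueError("total_steps must be a positive integer")


def lr_at(t: int, config: ScheduleConfig, cosine: bool = True) -> float:
    """Learning rate at step ``t`` in [0, T].

    ``cosine=False`` disables the annealing factor, leaving the pure warmup
    curve lr_init * omega(t).
    """
    if t > config.total_steps:
        raise ValueError(f"step {t} exceeds total_steps {config.total_steps}")
    lr = config.lr_init * warmup_factor(t, config.beta2)
    if cosine:
        lr *= 0.5 * (1.0 + math.cos(math.pi * t / config.total_steps))
    return lr
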