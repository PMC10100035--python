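"""Design parameters of the POCRM dose-finding design.

Defaults reproduce the calibrated trial design: skeleton built from an
arithmetic spacing of 0.04 over the first 18 ranks with a separately tuned
(0.75, 0.80) tail, a N(1.50, 1.00) prior on the model parameter, overdose
threshold 0.25, target toxicity range 20-35% (midpoint gamma = 0.275),
asymmetry b = 0.60, cohorts of 3 patients up to 48, starting at regimen 18.

The published account of the calibration states the prior variance both as
1.00 (the chosen calibration option) and 1.50 (the accompanying text), and
the calibration itself is defined by binding first-cohort requirements
(escalate to 19 but not 20 after 0/3 DLTs at the start; de-escalate off 18,
with 14 and 17 admissible, after 1/3).  Under this package's deterministic
posterior neither printed value satisfies the 0-DLT requirement, while
reading the text value 1.50 as a precision -- the trial's simulations were
run in JAGS, which parametrises the normal by precision -- gives
sigma^2 = 1/1.50 and satisfies every published first-cohort decision.  That
value is the default; both printed alternatives remain selectable via
``DesignParams(sigma2=...)``.  See docs/methods.md for the full account.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Skeleton", "skeleton_from_spacing", "default_skeleton", "DesignParams"]


@dataclass(frozen=True)
class Skeleton:
    """Standardised toxicity values assigned to toxicity ranks 1..K."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.size == 0:
            raise ValueError("skeleton must be non-empty")
        if np.any(v <= 0) or np.any(v >= 1):
            raise ValueError("skeleton values must lie strictly in (0, 1)")
        if np.any(np.diff(v) <= 0):
            raise ValueError("skeleton values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def skeleton_from_spacing(
    nu: float, k_linear: int, tail: tuple[float, ...] = ()
) -> Skeleton:
    """Skeleton 0.01 + nu*i for i = 0..k_linear-1, then the tuned tail values."""
    values = tuple(0.01 + nu * i for i in range(k_linear)) + tuple(tail)
    return Skeleton(values=values)


def default_skeleton() -> Skeleton:
    """The calibrated 20-value skeleton (spacing 0.04, tail 0.75, 0.80)."""
    return skeleton_from_spacing(0.04, 18, (0.75, 0.80))


@dataclass(frozen=True)
class DesignParams:
    """All tunable parameters of the escalation design."""

    skeleton: Skeleton = field(default_factory=default_skeleton)
    mu: float = 1.50  # prior mean of the model parameter alpha
    sigma2: float = 1.0 / 1.50  # prior variance of alpha (see module docstring)
    c_overdose: float = 0.25  # overdose-control probability threshold
    target_lower: float = 0.20
    target_upper: float = 0.35
    gamma: float = 0.275  # target toxicity (middle of the range)
    b: float = 0.60  # asymmetry of the allocation criterion
    cohort_size: int = 3
    max_n: int = 48
    start_regimen: int = 18

    def __post_init__(self) -> None:
        if not 0 < self.target_lower < self.gamma < self.target_upper < 1:
            raise ValueError("need 0 < lower < gamma < upper < 1")
        if not 0 < self.c_overdose < 1:
            raise ValueError("c_overdose must lie in (0, 1)")
        if not 0 < self.b < 2:
            raise ValueError("asymmetry b must lie in (0, 2)")
        if self.sigma2 <= 0:
            raise ValueError("prior variance must be positive")
        if self.cohort_size < 1:
            raise ValueError("cohort size must be at least 1")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))

    def replace(self, **kwargs) -> "DesignParams":
        return replace(self, **kwargs)
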