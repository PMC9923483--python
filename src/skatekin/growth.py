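"""Von Bertalanffy growth: length-at-age, age-from-length, cohort assignment.

Field surveys measure total length, not age, so ages are assigned by
analytically inverting the von Bertalanffy growth curve

    L(t) = L_inf * (1 - exp(-k * (t - t0)))

and rounding down to whole years.  The default parameters are a published
age-at-length key for the blue skate (*Dipturus batis*):
L_inf = 149 cm, k = 0.18 / yr, t0 = -0.49 yr.  Birth cohorts follow as
capture year minus estimated age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["GrowthParams", "DEFAULT_GROWTH", "length_at_age",
           "age_from_length", "assign_cohort"]


@dataclass(frozen=True)
class GrowthParams:
    """Von Bertalanffy parameters.

    l_inf : asymptotic length (cm), > 0
    k     : growth coefficient (1/yr), > 0
    t0    : theoretical age at zero length (yr); negative for species
            born at positive length
    """

    l_inf: float = 149.0
    k: float = 0.18
    t0: float = -0.49

    def __post_init__(self) -> None:
        if not (self.l_inf > 0 and self.k > 0):
            raise ValueError("require l_inf > 0 and k > 0")


DEFAULT_GROWTH = GrowthParams()


def length_at_age(age, params: GrowthParams = DEFAULT_GROWTH):
    """Expected total length (cm) at ``age`` years (scalar or array)."""
    a = np.asarray(age, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(a < 0):
        raise ValueError("age must be finite and >= 0")
    out = params.l_inf * (1.0 - np.exp(-params.k * (a - params.t0)))
    return out if out.ndim else float(out)


def age_from_length(length: float, params: GrowthParams = DEFAULT_GROWTH) -> int:
    """Integer age (floor of the exact inverse) for a length in cm.

    Lengths at or above ``l_inf`` have no finite age on the curve and
    raise ``ValueError`` so that upstream data problems surface instead
    of silently clamping.
    """
    if not 0.0 < length < params.l_inf:
        raise ValueError(
            f"length {length} cm outside the invertible range "
            f"(0, {params.l_inf})"
        )
    exact = -math.log(1.0 - length / params.l_inf) / params.k + params.t0
    # nudge so lengths that are exact curve values invert to whole years
    return max(0, math.floor(exact + 1e-9))


def assign_cohort(sample_year: int, age: int) -> int:
    """Birth year = capture year minus integer age."""
    if age < 0:
        raise ValueError("age must be >= 0")
    return int(sample_year) - int(age)
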