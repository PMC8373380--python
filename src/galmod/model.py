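"""Phenomenological two-threshold model of GAL pathway glucose inhibition.

Glucose inhibits the yeast galactose (GAL) regulon in two separable ways:
indirectly, by lowering intracellular galactose and hence the *fraction* of
cells that commit to induction, and directly, through Mig1p repression of
GAL4, which lowers the *expression level* of the cells that do induce.  Both
effects are described as Hill functions that decrease with glucose, each
parameterized by a single experimentally motivated threshold:

* ``E10`` — glucose concentration (% w/v) at which the induced
  subpopulation's mean expression has fallen to 10% of its maximum.
* ``F90`` — glucose concentration (% w/v) at which the induced fraction has
  fallen to 90%.

The Hill midpoints are obtained from these thresholds by the conversion
factors ``beta(n) = (0.6/0.4)**(1/n)`` and ``alpha(n) = (0.9/0.1)**(1/n)``,
chosen so that the level curve passes through 10%-of-maximal at ``E10`` and
the fraction curve through 0.9 at ``F90`` exactly.

The mean induced level is carried in log10 relative expression, scaled over
[-3, -0.5]; the uninduced subpopulation sits at a constant 10**-3.  Cell-to-
cell spread in log10 expression follows an empirical quadratic in the mean
level, ``sd(x) = -0.2*(x + 1.75)**2 + 0.4``, floored at a small positive
value outside its positive range.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np

__all__ = [
    "alpha",
    "beta",
    "InductionModel",
    "REFERENCE_PARAMS",
    "LEVEL_HILL_MEAN",
    "FRACTION_HILL_MEAN",
    "LEVEL_HILL_RANGE",
    "FRACTION_HILL_RANGE",
]

#: Mean Hill coefficients fitted to natural-isolate induction curves; consumed
#: as constants (the fits themselves are outside this package's scope).
LEVEL_HILL_MEAN = 1.15
FRACTION_HILL_MEAN = 1.69
#: Extreme fitted Hill coefficients across the isolate panel, used by the
#: phase-diagram scan.
LEVEL_HILL_RANGE = (0.84, 1.50)
FRACTION_HILL_RANGE = (0.75, 2.95)


def beta(n_level: float) -> float:
    """Conversion from the 10%-of-maximal-level threshold to the Hill midpoint.

    The level curve's midpoint (on the scaled log axis) is ``beta * E10``;
    with this factor the linear-scale level at ``glucose == E10`` is exactly
    10% of the zero-glucose level.
    """
    if n_level <= 0:
        raise ValueError(f"n_level must be > 0, got {n_level}")
    return (0.6 / 0.4) ** (1.0 / n_level)


def alpha(n_frac: float) -> float:
    """Conversion from the 90%-induced threshold to the Hill midpoint.

    The fraction curve's midpoint is ``alpha * F90``; with this factor the
    induced fraction at ``glucose == F90`` is exactly 0.9.
    """
    if n_frac <= 0:
        raise ValueError(f"n_frac must be > 0, got {n_frac}")
    return (0.9 / 0.1) ** (1.0 / n_frac)


def _hill(glucose, midpoint: float, n: float):
    """Decreasing Hill term ``K**n / (g**n + K**n)``; equals 1 at ``g == 0``."""
    g = np.asarray(glucose, dtype=float)
    if np.any(g < 0):
        raise ValueError("glucose concentration must be >= 0")
    kn = midpoint**n
    out = kn / (g**n + kn)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class InductionModel:
    """Parameterization of the two glucose-inhibition curves and the noise model.

    Parameters
    ----------
    E10 : float
        Glucose (% w/v) where the induced level is 10% of maximal.
    F90 : float
        Glucose (% w/v) where 90% of cells are induced.
    n_level, n_frac : float
        Hill coefficients of the level and fraction curves.
    log_level_max, log_level_min : float
        Scaled range of the mean induced level, in log10 relative expression.
    log_level_uninduced : float
        Constant mean of the uninduced subpopulation (log10 of 10**-3).
    sd_a, sd_c, sd_b : float
        Quadratic noise model ``sd(x) = sd_a*(x + sd_c)**2 + sd_b``.
    sd_floor : float
        Positive clamp applied where the quadratic goes non-positive.
    """

    E10: float
    F90: float
    n_level: float = LEVEL_HILL_MEAN
    n_frac: float = FRACTION_HILL_MEAN
    log_level_max: float = -0.5
    log_level_min: float = -3.0
    log_level_uninduced: float = -3.0
    sd_a: float = -0.2
    sd_c: float = 1.75
    sd_b: float = 0.4
    sd_floor: float = 0.01

    def __post_init__(self) -> None:
        for name in ("E10", "F90", "n_level", "n_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.log_level_min < self.log_level_max:
            raise ValueError("log_level_min must be < log_level_max")
        if self.sd_floor <= 0:
            raise ValueError("sd_floor must be > 0")

    # -- response curves ---------------------------------------------------

    def mean_induced_log_level(self, glucose):
        """Mean log10 relative expression of the induced subpopulation.

        A decreasing Hill term with midpoint ``beta(n_level) * E10``, scaled
        onto [log_level_min, log_level_max]; equals ``log_level_max`` at zero
        glucose and passes through 10%-of-maximal (linear scale) at ``E10``.
        """
        h = _hill(glucose, beta(self.n_level) * self.E10, self.n_level)
        return self.log_level_min + h * (self.log_level_max - self.log_level_min)

    def induced_fraction(self, glucose):
        """Fraction of cells in the induced subpopulation, in [0, 1].

        Decreasing Hill term with midpoint ``alpha(n_frac) * F90``; equals 1
        at zero glucose and 0.9 at ``F90``.
        """
        return _hill(glucose, alpha(self.n_frac) * self.F90, self.n_frac)

    def sd_of_log_level(self, log_level):
        """Standard deviation of log10 expression at a given mean level.

        Evaluates the empirical quadratic and clamps at ``sd_floor`` where it
        is non-positive (the quadratic is only positive for mean levels in
        roughly (-3.16, -0.34)).
        """
        x = np.asarray(log_level, dtype=float)
        sd = self.sd_a * (x + self.sd_c) ** 2 + self.sd_b
        out = np.maximum(sd, self.sd_floor)
        return out if out.ndim else float(out)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "InductionModel":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown model parameters: {sorted(unknown)}")
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "InductionModel":
        return cls.from_dict(json.loads(s))

    def replace(self, **changes) -> "InductionModel":
        return dataclasses.replace(self, **changes)


#: Default constants of the published parameterization; combine with a
#: strain's (E10, F90) via ``InductionModel(E10=..., F90=..., **REFERENCE_PARAMS)``.
REFERENCE_PARAMS: dict[str, float] = {
    "n_level": LEVEL_HILL_MEAN,
    "n_frac": FRACTION_HILL_MEAN,
    "log_level_max": -0.5,
    "log_level_min": -3.0,
    "log_level_uninduced": -3.0,
    "sd_a": -0.2,
    "sd_c": 1.75,
    "sd_b": 0.4,
    "sd_floor": 0.01,
}
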