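"""Forward simulation of flow-cytometry-style single-cell expression samples.

Each condition's population is the induced-fraction-weighted mixture of two
normal distributions in log10 relative expression: an uninduced component at
the constant baseline (10**-3) and an induced component whose mean follows
the model's level curve, both with spreads from the quadratic noise model.
Profiles assemble one sample per glucose concentration of a titration,
together with the two reference samples used by empirical metric extraction:
an uninduced reference (2% glucose) and a maximal-induction reference
(2% galactose, no glucose).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import InductionModel

__all__ = [
    "Condition",
    "PopulationSample",
    "InductionProfile",
    "make_glucose_titration",
    "simulate_population",
    "simulate_reference",
    "simulate_profile",
    "DEFAULT_GALACTOSE",
    "UNINDUCED_REF_GLUCOSE",
    "MAX_INDUCTION_REF_GALACTOSE",
]

#: Galactose held constant across the titrations (% w/v); metadata only — the
#: model's curves depend on glucose alone.
DEFAULT_GALACTOSE = 0.25
UNINDUCED_REF_GLUCOSE = 2.0
MAX_INDUCTION_REF_GALACTOSE = 2.0


@dataclass(frozen=True)
class Condition:
    """A sugar environment: glucose drives the model, galactose is metadata."""

    glucose: float
    galactose: float = DEFAULT_GALACTOSE
    label: str = ""

    def __post_init__(self) -> None:
        if self.glucose < 0 or self.galactose < 0:
            raise ValueError("sugar concentrations must be non-negative")


@dataclass
class PopulationSample:
    """Per-cell log10 relative expression values for one condition."""

    log_expression: np.ndarray
    condition: Condition
    seed: int | None = None
    true_induced_fraction: float | None = None

    def __post_init__(self) -> None:
        self.log_expression = np.asarray(self.log_expression, dtype=float)
        if self.log_expression.ndim != 1:
            raise ValueError("log_expression must be a 1-D vector")
        if not np.all(np.isfinite(self.log_expression)):
            raise ValueError("log_expression must be finite")

    @property
    def n_cells(self) -> int:
        return self.log_expression.size


@dataclass
class InductionProfile:
    """Ordered samples over a glucose titration plus the two references."""

    samples: list[PopulationSample]
    uninduced_ref: PopulationSample | None = None
    max_induction_ref: PopulationSample | None = None
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        glucose = [s.condition.glucose for s in self.samples]
        if sorted(glucose) != glucose and sorted(glucose, reverse=True) != glucose:
            raise ValueError("profile samples must be ordered by glucose")

    @property
    def glucose_grid(self) -> np.ndarray:
        return np.array([s.condition.glucose for s in self.samples])


def make_glucose_titration(
    top: float = 1.0, bottom: float = 0.0039, factor: float = 2.0
) -> list[float]:
    """Descending geometric glucose series from ``top`` down to ``bottom``.

    Continues in steps of ``1/factor`` while the value stays at or above
    ``bottom`` (within a small relative tolerance, so an endpoint that is
    exactly reachable is included).  The published titration
    ``make_glucose_titration(1, 0.0039, 2)`` gives nine concentrations.
    """
    if not (top > 0 and bottom > 0 and top >= bottom):
        raise ValueError("need top >= bottom > 0")
    if factor <= 1:
        raise ValueError("factor must be > 1")
    tol = 1e-9
    series: list[float] = []
    g = float(top)
    while g >= bottom * (1 - tol):
        series.append(g)
        g /= factor
    return series


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def simulate_population(
    model: InductionModel,
    condition: Condition,
    n_cells: int = 20_000,
    seed: int | None = None,
    induced_fraction: float | None = None,
) -> PopulationSample:
    """Draw one condition's mixture sample of ``n_cells`` cells.

    The induced count is ``round(f * n_cells)`` (half-up) with ``f`` from the
    model's fraction curve, or from ``induced_fraction`` when given (used for
    the pure references).  Induced cells are normal around the level curve's
    mean with the quadratic-model spread; uninduced cells are normal around
    the 10**-3 baseline.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    f = (
        float(model.induced_fraction(condition.glucose))
        if induced_fraction is None
        else float(induced_fraction)
    )
    if not 0.0 <= f <= 1.0:
        raise ValueError("induced_fraction must be in [0, 1]")
    n_induced = _round_half_up(f * n_cells)
    rng = np.random.default_rng(seed)
    mu_ind = float(model.mean_induced_log_level(condition.glucose))
    sd_ind = float(model.sd_of_log_level(mu_ind))
    mu_un = model.log_level_uninduced
    sd_un = float(model.sd_of_log_level(mu_un))
    induced = rng.normal(mu_ind, sd_ind, n_induced)
    uninduced = rng.normal(mu_un, sd_un, n_cells - n_induced)
    return PopulationSample(
        log_expression=np.concatenate([induced, uninduced]),
        condition=condition,
        seed=seed,
        true_induced_fraction=n_induced / n_cells,
    )


def simulate_reference(
    model: InductionModel,
    kind: str,
    n_cells: int = 20_000,
    seed: int | None = None,
) -> PopulationSample:
    """Simulate a reference sample.

    ``kind='uninduced'``: 2% glucose, fraction forced to 0 (fully repressed).
    ``kind='max_induction'``: 2% galactose without glucose, fraction forced
    to 1, so the sample sits at the level curve's maximum.
    """
    if kind == "uninduced":
        cond = Condition(glucose=UNINDUCED_REF_GLUCOSE, galactose=0.0, label="uninduced_ref")
        frac = 0.0
    elif kind == "max_induction":
        cond = Condition(
            glucose=0.0, galactose=MAX_INDUCTION_REF_GALACTOSE, label="max_induction_ref"
        )
        frac = 1.0
    else:
        raise ValueError(f"unknown reference kind: {kind!r}")
    return simulate_population(model, cond, n_cells=n_cells, seed=seed, induced_fraction=frac)


def simulate_profile(
    model: InductionModel,
    glucose_grid: Sequence[float] | None = None,
    galactose: float = DEFAULT_GALACTOSE,
    n_cells: int = 20_000,
    seed: int = 0,
    replicate_id: str = "rep1",
    with_references: bool = True,
) -> InductionProfile:
    """Simulate a full titration profile (default: nine twofold conditions).

    Per-condition seeds are ``seed + index`` so a profile is reproducible
    from its master seed while conditions stay independent; the references
    use the two indices past the grid.
    """
    if glucose_grid is None:
        glucose_grid = make_glucose_titration()
    glucose_grid = list(glucose_grid)
    if not glucose_grid:
        raise ValueError("glucose_grid must be non-empty")
    samples = [
        simulate_population(
            model,
            Condition(glucose=g, galactose=galactose, label=f"glu{g:g}"),
            n_cells=n_cells,
            seed=None if seed is None else seed + i,
        )
        for i, g in enumerate(glucose_grid)
    ]
    uninduced = max_ind = None
    if with_references:
        base = len(glucose_grid)
        uninduced = simulate_reference(
            model, "uninduced", n_cells=n_cells, seed=None if seed is None else seed + base
        )
        max_ind = simulate_reference(
            model,
            "max_induction",
            n_cells=n_cells,
            seed=None if seed is None else seed + base + 1,
        )
    return InductionProfile(
        samples=samples,
        uninduced_ref=uninduced,
        max_induction_ref=max_ind,
        replicate_id=replicate_id,
    )
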