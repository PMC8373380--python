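"""Phase-diagram scan of modality over (F90, E10, Hill-coefficient) space.

Every grid combination is simulated as a full nine-condition titration at
20,000 cells, classified with the Gaussian-curve rule, and re-measured with
the empirical E10/F90 metrics.  In log10(F90)-log10(E10) space the unimodal
and bimodal regimes are delineated by slope-1 bounding lines: each line has
the extreme intercept that still captures every simulation of its class on
one side.  The band between the two lines is the ambiguous regime where
both behaviors occur.

Bimodality requires a glucose concentration where the induced fraction is
intermediate (glucose above ~F90) while the induced level is still well
separated from baseline (glucose below a few-fold E10); the bimodal regime
therefore lies at high E10/F90, and the unimodal regime at low E10/F90.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import MetricValue, compute_metrics
from .modality import ModalityThresholds, classify_profile
from .model import FRACTION_HILL_RANGE, FRACTION_HILL_MEAN, LEVEL_HILL_MEAN, LEVEL_HILL_RANGE, InductionModel
from .simulate import simulate_profile

__all__ = [
    "THRESHOLD_GRID",
    "THRESHOLD_GRID_TWOFOLD",
    "N_LEVEL_SCAN",
    "N_FRAC_SCAN",
    "PhaseGridPoint",
    "PhaseDiagram",
    "scan_grid",
    "delineate_regimes",
    "predict_modality",
    "plot_phase_diagram",
]

#: Threshold grid as printed in the source protocol.  The value 0.156 breaks
#: the surrounding twofold series (almost certainly a typo for 0.0156) but is
#: kept verbatim; the regularized variant is THRESHOLD_GRID_TWOFOLD.
THRESHOLD_GRID = (1.0, 0.5, 0.25, 0.125, 0.0625, 0.0313, 0.156, 0.0078, 0.0039, 0.0020, 0.0010)
THRESHOLD_GRID_TWOFOLD = (
    1.0, 0.5, 0.25, 0.125, 0.0625, 0.0313, 0.0156, 0.0078, 0.0039, 0.0020, 0.0010,
)

#: Hill coefficients scanned: the extreme fitted values plus the mean.
N_LEVEL_SCAN = (LEVEL_HILL_RANGE[0], LEVEL_HILL_MEAN, LEVEL_HILL_RANGE[1])
N_FRAC_SCAN = (FRACTION_HILL_RANGE[0], FRACTION_HILL_MEAN, FRACTION_HILL_RANGE[1])


@dataclass
class PhaseGridPoint:
    """One scanned parameter combination with its simulated outcome."""

    E10_in: float
    F90_in: float
    n_level: float
    n_frac: float
    modality: str  # "unimodal" | "bimodal" | "unclassifiable"
    E10_out: MetricValue | None = None
    F90_out: MetricValue | None = None
    seed: int | None = None

    @property
    def log_ratio(self) -> float:
        """log10(E10_in) - log10(F90_in): the regime-driving coordinate."""
        return float(np.log10(self.E10_in) - np.log10(self.F90_in))


def scan_grid(
    E10_values=THRESHOLD_GRID,
    F90_values=THRESHOLD_GRID,
    n_level_values=N_LEVEL_SCAN,
    n_frac_values=N_FRAC_SCAN,
    n_cells: int = 20_000,
    seed: int = 0,
    thresholds: ModalityThresholds | None = None,
    gate_quantile: float = 0.99,
    measure_metrics: bool = True,
    model_params: dict | None = None,
) -> list[PhaseGridPoint]:
    """Simulate and classify every (E10, F90, n_level, n_frac) combination.

    Per-point seeds are derived deterministically from the master seed so the
    scan is reproducible and points are independent.
    """
    if not (len(E10_values) and len(F90_values) and len(n_level_values) and len(n_frac_values)):
        raise ValueError("all scan grids must be non-empty")
    params = model_params or {}
    points: list[PhaseGridPoint] = []
    idx = 0
    for e10 in E10_values:
        for f90 in F90_values:
            for nl in n_level_values:
                for nf in n_frac_values:
                    point_seed = (seed + 7919 * idx) % 2**31
                    idx += 1
                    model = InductionModel(E10=e10, F90=f90, n_level=nl, n_frac=nf, **params)
                    profile = simulate_profile(
                        model, n_cells=n_cells, seed=point_seed,
                        with_references=measure_metrics,
                    )
                    call = classify_profile(profile, thresholds)
                    if call.status != "ok":
                        modality = "unclassifiable"
                    else:
                        modality = "bimodal" if call.profile_is_bimodal else "unimodal"
                    e10_out = f90_out = None
                    if measure_metrics:
                        ms = compute_metrics(
                            profile, gate_quantile,
                            is_bimodal=call.profile_is_bimodal,
                        )
                        e10_out, f90_out = ms.E10, ms.F90
                    points.append(
                        PhaseGridPoint(
                            E10_in=e10, F90_in=f90, n_level=nl, n_frac=nf,
                            modality=modality, E10_out=e10_out, F90_out=f90_out,
                            seed=point_seed,
                        )
                    )
    return points


def points_table(points: list[PhaseGridPoint]) -> pd.DataFrame:
    rows = []
    for p in points:
        rows.append(
            {
                "E10_in": p.E10_in,
                "F90_in": p.F90_in,
                "n_level": p.n_level,
                "n_frac": p.n_frac,
                "modality": p.modality,
                "E10_out": p.E10_out.value if p.E10_out else np.nan,
                "E10_out_flag": p.E10_out.flag if p.E10_out else "",
                "F90_out": p.F90_out.value if p.F90_out else np.nan,
                "F90_out_flag": p.F90_out.flag if p.F90_out else "",
                "seed": p.seed,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PhaseDiagram:
    """Slope-1 regime boundaries in log10(F90) (x) vs log10(E10) (y) space.

    A boundary line ``y = x + c`` is summarized by its intercept ``c``,
    equal to log10(E10) - log10(F90) on the line.  ``unimodal_intercept``
    captures all unimodal points on one side, ``bimodal_intercept`` all
    bimodal points on the other; which side is which is determined from the
    data (``orientation``), so the geometry does not presuppose the regime
    direction.  Points whose intercept falls between the two lines
    (inclusive) are ambiguous.
    """

    points: list[PhaseGridPoint]
    unimodal_intercept: float
    bimodal_intercept: float
    orientation: str  # "unimodal_low" (unimodal at low E10/F90) or "unimodal_high"
    degenerate: bool = False
    degenerate_class: str | None = None

    @property
    def ambiguous_band(self) -> tuple[float, float]:
        lo = min(self.unimodal_intercept, self.bimodal_intercept)
        hi = max(self.unimodal_intercept, self.bimodal_intercept)
        return (lo, hi)

    @property
    def has_overlap(self) -> bool:
        """True when the two captured half-planes overlap (classes intermix)."""
        if self.degenerate:
            return False
        if self.orientation == "unimodal_low":
            return self.bimodal_intercept <= self.unimodal_intercept
        return self.unimodal_intercept <= self.bimodal_intercept

    def predict(self, E10: float, F90: float) -> str:
        return predict_modality(self, E10, F90)

    def to_dict(self) -> dict:
        return {
            "unimodal_intercept": self.unimodal_intercept,
            "bimodal_intercept": self.bimodal_intercept,
            "orientation": self.orientation,
            "degenerate": self.degenerate,
            "degenerate_class": self.degenerate_class,
            "ambiguous_band": list(self.ambiguous_band) if not self.degenerate else None,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def delineate_regimes(points: list[PhaseGridPoint]) -> PhaseDiagram:
    """Fit the two slope-1 bounding lines exactly (extreme intercepts)."""
    uni = [p.log_ratio for p in points if p.modality == "unimodal"]
    bi = [p.log_ratio for p in points if p.modality == "bimodal"]
    if not uni and not bi:
        raise ValueError("no classifiable points to delineate")
    if not uni or not bi:
        cls = "bimodal" if bi else "unimodal"
        vals = bi or uni
        c = float(np.median(vals))
        return PhaseDiagram(
            points=points, unimodal_intercept=c, bimodal_intercept=c,
            orientation="unimodal_low", degenerate=True, degenerate_class=cls,
        )
    if np.median(uni) <= np.median(bi):
        # unimodal occupies the low-E10/F90 side (the model's actual regime)
        orientation = "unimodal_low"
        c_uni = max(uni)  # all unimodal at d <= c_uni
        c_bi = min(bi)  # all bimodal at d >= c_bi
    else:
        orientation = "unimodal_high"
        c_uni = min(uni)
        c_bi = max(bi)
    return PhaseDiagram(
        points=points,
        unimodal_intercept=float(c_uni),
        bimodal_intercept=float(c_bi),
        orientation=orientation,
    )


def predict_modality(diagram: PhaseDiagram, E10: float, F90: float) -> str:
    """Side-of-line test; between the boundaries (inclusive) is ambiguous."""
    if E10 <= 0 or F90 <= 0:
        raise ValueError("E10 and F90 must be > 0")
    d = float(np.log10(E10) - np.log10(F90))
    if diagram.degenerate:
        return diagram.degenerate_class
    lo, hi = diagram.ambiguous_band
    if lo <= d <= hi:
        return "ambiguous"
    low_class = "unimodal" if diagram.orientation == "unimodal_low" else "bimodal"
    high_class = "bimodal" if diagram.orientation == "unimodal_low" else "unimodal"
    return low_class if d < lo else high_class


def plot_phase_diagram(diagram: PhaseDiagram, ax=None):
    """Scatter the scanned points over the regime bands (matplotlib axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    colors = {"unimodal": "tab:blue", "bimodal": "tab:red", "unclassifiable": "gray"}
    for modality, color in colors.items():
        xs = [np.log10(p.F90_in) for p in diagram.points if p.modality == modality]
        ys = [np.log10(p.E10_in) for p in diagram.points if p.modality == modality]
        if xs:
            ax.scatter(xs, ys, s=14, c=color, label=modality, alpha=0.7)
    xlim = np.array(ax.get_xlim())
    for c, style in ((diagram.unimodal_intercept, "b--"), (diagram.bimodal_intercept, "r--")):
        ax.plot(xlim, xlim + c, style, lw=1)
    lo, hi = diagram.ambiguous_band
    ax.fill_between(xlim, xlim + lo, xlim + hi, color="gold", alpha=0.2, label="ambiguous")
    ax.set_xlabel("log10 F90 (% w/v glucose)")
    ax.set_ylabel("log10 E10 (% w/v glucose)")
    ax.legend(fontsize=8)
    return ax
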