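"""Empirical E10/F90 metric extraction from induction profiles.

The induced subpopulation of each condition is gated against an uninduced
reference grown in 2% glucose: cells above the reference's 99th percentile
of log10 expression count as induced.  From the gated per-condition table,

* ``F90`` is the glucose concentration where the induced fraction crosses
  0.9 (log-linear interpolation between bracketing conditions), and
* ``E10`` is the glucose concentration where the induced subpopulation's
  mean log10 level crosses 10% of the maximal level measured in the
  2%-galactose reference.

For strains whose expression level shuts off below the fraction threshold
(unimodal strains), gated induction under-reports the true induced fraction,
so the measured F90 is only a lower bound; that caveat is carried as a flag.
Hill-coefficient fitting to empirical curves reuses the model's two closed
forms through a small least-squares model object.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .model import InductionModel, alpha, beta
from .simulate import InductionProfile, PopulationSample

__all__ = [
    "SubpopulationSplit",
    "split_subpopulations",
    "MetricValue",
    "MetricSet",
    "induction_table",
    "compute_F90",
    "compute_E10",
    "compute_metrics",
    "HillCurveModel",
    "HillFitResults",
    "fit_hill_coefficient",
]

DEFAULT_GATE_QUANTILE = 0.99


@dataclass
class SubpopulationSplit:
    """Gated induced/uninduced split of one sample."""

    induced_mask: np.ndarray
    induced_fraction: float
    induced_mean_log_level: float  # nan when no cell passes the gate
    gate_threshold: float


def split_subpopulations(
    sample: PopulationSample,
    uninduced_ref: PopulationSample,
    gate_quantile: float = DEFAULT_GATE_QUANTILE,
) -> SubpopulationSplit:
    """Gate cells above the uninduced reference's ``gate_quantile`` quantile."""
    if uninduced_ref is None or uninduced_ref.n_cells == 0:
        raise ValueError("uninduced reference sample is required and must be non-empty")
    if not 0.0 < gate_quantile < 1.0:
        raise ValueError("gate_quantile must be in (0, 1)")
    gate = float(np.quantile(uninduced_ref.log_expression, gate_quantile))
    mask = sample.log_expression > gate
    frac = float(mask.mean())
    mean_level = float(sample.log_expression[mask].mean()) if mask.any() else math.nan
    return SubpopulationSplit(
        induced_mask=mask,
        induced_fraction=frac,
        induced_mean_log_level=mean_level,
        gate_threshold=gate,
    )


@dataclass(frozen=True)
class MetricValue:
    """A threshold metric with its measurability flag.

    ``flag`` is ``"ok"`` for an interpolated crossing, ``"lower_bound"`` when
    the true value can only be bounded from below (fraction never drops
    below 0.9 on the grid, or level-suppressed induction in a unimodal
    strain), and ``"not_reached"`` when there is no crossing at all
    (``value`` is then nan).
    """

    value: float
    flag: str = "ok"

    @property
    def reached(self) -> bool:
        return self.flag != "not_reached"

    def __repr__(self) -> str:  # compact, notebook-friendly
        if not self.reached:
            return "MetricValue(not reached)"
        suffix = " (lower bound)" if self.flag == "lower_bound" else ""
        return f"MetricValue({self.value:.4g}{suffix})"


def induction_table(
    profile: InductionProfile, gate_quantile: float = DEFAULT_GATE_QUANTILE
) -> pd.DataFrame:
    """Per-condition gated fractions and induced mean levels, ascending glucose."""
    if profile.uninduced_ref is None:
        raise ValueError("profile lacks an uninduced reference")
    rows = []
    for s in profile.samples:
        sp = split_subpopulations(s, profile.uninduced_ref, gate_quantile)
        rows.append(
            {
                "glucose": s.condition.glucose,
                "induced_fraction": sp.induced_fraction,
                "induced_mean_log_level": sp.induced_mean_log_level,
            }
        )
    return pd.DataFrame(rows).sort_values("glucose", ignore_index=True)


def _highest_glucose_crossing(glucose: np.ndarray, y: np.ndarray, target: float) -> float:
    """Glucose where ``y`` crosses ``target``, interpolated linearly in log10(g).

    ``glucose`` ascending.  With sampling noise the empirical curve need not
    be monotone; the crossing at the highest glucose is taken, matching a
    threshold read off the monotone underlying curve.  Returns nan when no
    bracketing pair exists.
    """
    logg = np.log10(glucose)
    for i in range(len(y) - 2, -1, -1):
        y0, y1 = y[i], y[i + 1]
        if np.isnan(y0) or np.isnan(y1):
            continue
        if (y0 - target) * (y1 - target) <= 0 and y0 != y1:
            x = logg[i] + (target - y0) * (logg[i + 1] - logg[i]) / (y1 - y0)
            return float(10**x)
    return math.nan


def compute_F90(
    profile: InductionProfile,
    gate_quantile: float = DEFAULT_GATE_QUANTILE,
    table: pd.DataFrame | None = None,
) -> MetricValue:
    """Glucose where the gated induced fraction reaches 0.9."""
    tab = induction_table(profile, gate_quantile) if table is None else table
    g = tab["glucose"].to_numpy()
    frac = tab["induced_fraction"].to_numpy()
    if np.all(frac < 0.9):
        return MetricValue(math.nan, "not_reached")
    if np.all(frac >= 0.9):
        # still >= 90% induced at the strongest repression tested
        return MetricValue(float(g.max()), "lower_bound")
    value = _highest_glucose_crossing(g, frac, 0.9)
    if math.isnan(value):
        return MetricValue(math.nan, "not_reached")
    return MetricValue(value, "ok")


def compute_E10(
    profile: InductionProfile,
    gate_quantile: float = DEFAULT_GATE_QUANTILE,
    table: pd.DataFrame | None = None,
) -> MetricValue:
    """Glucose where the induced subpopulation's level is 10% of maximal.

    The maximal level is the induced mean of the 2%-galactose reference; the
    target is that level minus one decade (10% on the linear scale).
    """
    if profile.max_induction_ref is None:
        raise ValueError("profile lacks a maximal-induction reference")
    tab = induction_table(profile, gate_quantile) if table is None else table
    ref_split = split_subpopulations(
        profile.max_induction_ref, profile.uninduced_ref, gate_quantile
    )
    max_level = ref_split.induced_mean_log_level
    if math.isnan(max_level):
        raise ValueError("maximal-induction reference has no cells above the gate")
    target = max_level + math.log10(0.10)
    levels = tab["induced_mean_log_level"].to_numpy()
    if np.count_nonzero(~np.isnan(levels)) < 2:
        return MetricValue(math.nan, "not_reached")
    value = _highest_glucose_crossing(tab["glucose"].to_numpy(), levels, target)
    if math.isnan(value):
        return MetricValue(math.nan, "not_reached")
    return MetricValue(value, "ok")


@dataclass
class MetricSet:
    """E10/F90 summary of one profile plus the gated per-condition table."""

    E10: MetricValue
    F90: MetricValue
    max_level_log: float
    per_condition: pd.DataFrame
    fitted_n_level: float | None = None
    fitted_n_frac: float | None = None
    replicate_id: str = "rep1"

    def to_dict(self) -> dict:
        return {
            "replicate_id": self.replicate_id,
            "E10": {"value": self.E10.value, "flag": self.E10.flag},
            "F90": {"value": self.F90.value, "flag": self.F90.flag},
            "max_level_log": self.max_level_log,
            "fitted_n_level": self.fitted_n_level,
            "fitted_n_frac": self.fitted_n_frac,
            "per_condition": self.per_condition.to_dict(orient="records"),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_row(self, strain: str = "") -> dict:
        """Flat CSV row (one strain-replicate per line)."""
        return {
            "strain": strain,
            "replicate": self.replicate_id,
            "E10": self.E10.value,
            "E10_flag": self.E10.flag,
            "F90": self.F90.value,
            "F90_flag": self.F90.flag,
        }


def compute_metrics(
    profile: InductionProfile,
    gate_quantile: float = DEFAULT_GATE_QUANTILE,
    is_bimodal: bool | None = None,
    fit_hill: bool = False,
) -> MetricSet:
    """Extract the full metric set from one profile.

    When the profile is known to be unimodal (``is_bimodal=False``) the F90
    is downgraded to a lower bound: level-suppressed induction hides cells
    from the gate, so the crossing happens at artificially low glucose.
    """
    tab = induction_table(profile, gate_quantile)
    f90 = compute_F90(profile, gate_quantile, table=tab)
    e10 = compute_E10(profile, gate_quantile, table=tab)
    if is_bimodal is False and f90.flag == "ok":
        f90 = MetricValue(f90.value, "lower_bound")
    ref_split = split_subpopulations(
        profile.max_induction_ref, profile.uninduced_ref, gate_quantile
    )
    n_level = n_frac = None
    if fit_hill:
        ok = ~tab["induced_mean_log_level"].isna()
        if ok.sum() >= 4:
            res = HillCurveModel(
                tab.loc[ok, "glucose"], tab.loc[ok, "induced_mean_log_level"], kind="level"
            ).fit()
            n_level = res.n if res.converged else None
        res = HillCurveModel(tab["glucose"], tab["induced_fraction"], kind="fraction").fit()
        n_frac = res.n if res.converged else None
    return MetricSet(
        E10=e10,
        F90=f90,
        max_level_log=ref_split.induced_mean_log_level,
        per_condition=tab,
        fitted_n_level=n_level,
        fitted_n_frac=n_frac,
        replicate_id=profile.replicate_id,
    )


# -- Hill-curve fitting ----------------------------------------------------


@dataclass
class HillFitResults:
    """Least-squares estimates of (Hill coefficient, threshold) for one curve."""

    kind: str
    n: float
    threshold: float  # E10 for a level curve, F90 for a fraction curve
    bse: np.ndarray  # standard errors of (threshold, n)
    cov: np.ndarray
    converged: bool

    def summary(self) -> str:
        name = "E10" if self.kind == "level" else "F90"
        return (
            f"Hill {self.kind} curve fit (converged={self.converged})\n"
            f"  {name} = {self.threshold:.5g} +/- {self.bse[0]:.2g}\n"
            f"  n    = {self.n:.5g} +/- {self.bse[1]:.2g}"
        )


class HillCurveModel:
    """Fit the model's level or fraction Hill form to an empirical curve.

    For ``kind='level'`` the response is the induced mean in log10 relative
    expression (scaled over the standard [-3, -0.5] range); for
    ``kind='fraction'`` it is the induced fraction in [0, 1].  Parameters
    are the threshold (E10 or F90) and the Hill coefficient n.
    """

    def __init__(self, glucose, response, kind: str = "level",
                 log_level_min: float = -3.0, log_level_max: float = -0.5):
        self.glucose = np.asarray(glucose, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if self.glucose.size != self.response.size:
            raise ValueError("glucose and response must have equal length")
        if self.glucose.size < 4:
            raise ValueError("need at least 4 points spanning the transition")
        if kind not in ("level", "fraction"):
            raise ValueError("kind must be 'level' or 'fraction'")
        self.kind = kind
        self.log_level_min = log_level_min
        self.log_level_max = log_level_max

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, kind: str = "level",
        glucose_col: str = "glucose", response_col: str | None = None
    ) -> "HillCurveModel":
        if response_col is None:
            response_col = "induced_mean_log_level" if kind == "level" else "induced_fraction"
        return cls(df[glucose_col], df[response_col], kind=kind)

    def _predict(self, g, threshold, n):
        if self.kind == "level":
            mid = beta(n) * threshold
            h = mid**n / (g**n + mid**n)
            return self.log_level_min + h * (self.log_level_max - self.log_level_min)
        mid = alpha(n) * threshold
        return mid**n / (g**n + mid**n)

    def fit(self, p0: tuple[float, float] | None = None) -> HillFitResults:
        if p0 is None:
            p0 = (float(np.median(self.glucose)), 1.0)
        try:
            popt, pcov = curve_fit(
                self._predict,
                self.glucose,
                self.response,
                p0=p0,
                bounds=([1e-8, 0.05], [1e4, 50.0]),
                maxfev=20_000,
            )
        except (RuntimeError, ValueError):
            return HillFitResults(
                kind=self.kind,
                n=math.nan,
                threshold=math.nan,
                bse=np.array([math.nan, math.nan]),
                cov=np.full((2, 2), math.nan),
                converged=False,
            )
        bse = np.sqrt(np.diag(pcov))
        return HillFitResults(
            kind=self.kind,
            n=float(popt[1]),
            threshold=float(popt[0]),
            bse=bse,
            cov=pcov,
            converged=True,
        )


def fit_hill_coefficient(glucose, response, kind: str = "level") -> HillFitResults:
    """Convenience wrapper: fit one curve, return the results object."""
    return HillCurveModel(glucose, response, kind=kind).fit()
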