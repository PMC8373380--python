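"""Unimodal/bimodal classification of expression distributions.

The decision procedure mirrors how flow-cytometry induction histograms are
scored by curve fitting rather than likelihood-based mixture modelling:

1. Fit a single Gaussian curve to the binned density of log10 expression.
2. If the degree-of-freedom-adjusted R-squared of that fit is below 0.99,
   fit a two-Gaussian curve.
3. Call the condition bimodal iff the two fitted means are more than twice
   the larger fitted standard deviation apart AND the smaller component's
   weight exceeds 0.15.

A titration profile is bimodal if at least one of its conditions is; across
replicates a strain is bimodal only if every replicate's profile is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .simulate import InductionProfile, PopulationSample

__all__ = [
    "FitError",
    "ModalityThresholds",
    "GaussianFitResults",
    "HistogramGaussianModel",
    "fit_gaussians",
    "ConditionCall",
    "ModalityCall",
    "classify_condition",
    "classify_profile",
    "aggregate_modality",
]

MIN_CELLS = 100


class FitError(RuntimeError):
    """Raised when a Gaussian curve fit cannot be performed or converge."""


@dataclass(frozen=True)
class ModalityThresholds:
    """Decision thresholds of the classification rule."""

    r2_threshold: float = 0.99
    separation_multiplier: float = 2.0
    min_fraction: float = 0.15
    n_bins: int = 64


def _gaussian_sum(x, *params):
    y = np.zeros_like(x)
    for i in range(len(params) // 3):
        amp, mean, sd = params[3 * i : 3 * i + 3]
        y = y + amp * np.exp(-((x - mean) ** 2) / (2.0 * sd**2))
    return y


@dataclass
class GaussianFitResults:
    """Fitted k-component Gaussian curve on a binned density.

    ``weights`` are component areas (amplitude x sd) normalized to 1;
    ``adj_r2`` is 1 - (1-R^2)(N-1)/(N-p-1) with N bins and p = 3k fitted
    parameters.  A non-convergent fit is flagged with ``converged=False``
    and ``adj_r2 = -inf`` so it always takes the "worse fit" branch.
    """

    k: int
    amplitudes: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    adj_r2: float
    n_bins: int
    converged: bool = True

    @property
    def separation_over_maxsd(self) -> float:
        if self.k != 2:
            raise ValueError("separation is defined for two-component fits only")
        return float(abs(self.means[0] - self.means[1]) / self.sds.max())

    @property
    def minor_fraction(self) -> float:
        if self.k != 2:
            raise ValueError("minor fraction is defined for two-component fits only")
        return float(self.weights.min())

    def summary(self) -> str:
        lines = [
            f"Gaussian curve fit: k={self.k}, bins={self.n_bins}, "
            f"adj R2={self.adj_r2:.5f}, converged={self.converged}",
            f"{'component':>10} {'weight':>8} {'mean':>9} {'sd':>8}",
        ]
        for i in range(self.k):
            lines.append(
                f"{i:>10d} {self.weights[i]:>8.3f} {self.means[i]:>9.3f} {self.sds[i]:>8.3f}"
            )
        return "\n".join(lines)


class HistogramGaussianModel:
    """Least-squares k-component Gaussian model of a binned expression density.

    Parameters
    ----------
    data : array-like or PopulationSample
        Per-cell log10 expression values.
    n_components : int
        1 or 2.
    n_bins : int
        Equal-width bins spanning the sample range.

    ``fit()`` is deterministic: initialization follows a fixed ladder
    (moment start for k=1; percentile split then half-range density-argmax
    split for k=2) and the best-SSE convergent fit is kept.
    """

    def __init__(self, data, n_components: int = 1, n_bins: int = 64):
        if isinstance(data, PopulationSample):
            data = data.log_expression
        self.data = np.asarray(data, dtype=float)
        if self.data.ndim != 1 or self.data.size < MIN_CELLS:
            raise ValueError(f"need a 1-D sample of at least {MIN_CELLS} cells")
        if n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if np.ptp(self.data) == 0:
            raise FitError("degenerate sample: zero variance")
        self.k = n_components
        self.n_bins = int(n_bins)
        self.density, edges = np.histogram(self.data, bins=self.n_bins, density=True)
        self.bin_centers = 0.5 * (edges[:-1] + edges[1:])

    # -- initialization ladder --------------------------------------------

    def _starts(self) -> list[list[float]]:
        x = self.data
        dens, c = self.density, self.bin_centers
        peak = float(dens.max())
        if self.k == 1:
            return [[peak, float(x.mean()), float(x.std())]]
        q25, q75 = np.percentile(x, [25, 75])
        pooled = max(float(x.std()) / 2.0, 1e-3)
        starts = [[peak, float(q25), pooled, peak, float(q75), pooled]]
        # density argmax in each half of the range: robust when one mode is
        # small (percentiles can both land inside the major mode)
        mid = self.n_bins // 2
        lo_i, hi_i = int(np.argmax(dens[:mid])), mid + int(np.argmax(dens[mid:]))
        starts.append(
            [
                max(float(dens[lo_i]), 1e-3 * peak),
                float(c[lo_i]),
                pooled,
                max(float(dens[hi_i]), 1e-3 * peak),
                float(c[hi_i]),
                pooled,
            ]
        )
        return starts

    def fit(self) -> GaussianFitResults:
        x, y = self.bin_centers, self.density
        span = float(np.ptp(self.data))
        lo = [0.0, float(self.data.min()) - span, span / 1e4] * self.k
        hi = [np.inf, float(self.data.max()) + span, 2 * span] * self.k
        best = None
        for p0 in self._starts():
            p0 = [min(max(v, l), h) for v, l, h in zip(p0, lo, hi)]
            try:
                popt, _ = curve_fit(
                    _gaussian_sum, x, y, p0=p0, bounds=(lo, hi), maxfev=20_000
                )
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((y - _gaussian_sum(x, *popt)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
        if best is None:
            return GaussianFitResults(
                k=self.k,
                amplitudes=np.full(self.k, np.nan),
                means=np.full(self.k, np.nan),
                sds=np.full(self.k, np.nan),
                weights=np.full(self.k, np.nan),
                adj_r2=-np.inf,
                n_bins=self.n_bins,
                converged=False,
            )
        sse, popt = best
        amps = np.abs(popt[0::3])
        means = np.asarray(popt[1::3])
        sds = np.abs(popt[2::3])
        areas = amps * sds
        total = areas.sum()
        weights = areas / total if total > 0 else np.full(self.k, np.nan)
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else -np.inf
        n, p = self.n_bins, 3 * self.k
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
        return GaussianFitResults(
            k=self.k,
            amplitudes=amps,
            means=means,
            sds=sds,
            weights=weights,
            adj_r2=float(adj_r2),
            n_bins=self.n_bins,
        )


def fit_gaussians(sample, k: int, n_bins: int = 64) -> GaussianFitResults:
    """Fit a k-component Gaussian curve to a sample's binned log10 density."""
    return HistogramGaussianModel(sample, n_components=k, n_bins=n_bins).fit()


@dataclass
class ConditionCall:
    """Per-condition classification outcome with its decision quantities."""

    is_bimodal: bool | None
    status: str  # "ok" or "unclassifiable"
    fit: GaussianFitResults | None
    fit2: GaussianFitResults | None = None
    separation_over_maxsd: float | None = None
    minor_fraction: float | None = None
    condition: object | None = None

    def to_dict(self) -> dict:
        d = {
            "status": self.status,
            "is_bimodal": self.is_bimodal,
            "separation_over_maxsd": self.separation_over_maxsd,
            "minor_fraction": self.minor_fraction,
        }
        if self.condition is not None:
            d["glucose"] = self.condition.glucose
            d["label"] = self.condition.label
        if self.fit is not None:
            d["adj_r2_single"] = self.fit.adj_r2
        if self.fit2 is not None and self.fit2.converged:
            d["means"] = self.fit2.means.tolist()
            d["sds"] = self.fit2.sds.tolist()
            d["weights"] = self.fit2.weights.tolist()
        return d


@dataclass
class ModalityCall:
    """Profile-level modality with per-condition detail and a rule trace."""

    per_condition: list[ConditionCall]
    profile_is_bimodal: bool | None
    status: str  # "ok" or "unclassifiable"
    rule_trace: str = ""
    replicate_id: str = "rep1"

    def to_dict(self) -> dict:
        return {
            "replicate_id": self.replicate_id,
            "status": self.status,
            "profile_is_bimodal": self.profile_is_bimodal,
            "rule_trace": self.rule_trace,
            "per_condition": [c.to_dict() for c in self.per_condition],
        }


def classify_condition(
    sample: PopulationSample, thresholds: ModalityThresholds | None = None
) -> ConditionCall:
    """Classify one condition's distribution as unimodal or bimodal.

    Fit failures yield an "unclassifiable" status rather than a silent call.
    """
    t = thresholds or ModalityThresholds()
    cond = getattr(sample, "condition", None)
    try:
        fit1 = fit_gaussians(sample, k=1, n_bins=t.n_bins)
    except (FitError, ValueError):
        return ConditionCall(is_bimodal=None, status="unclassifiable", fit=None, condition=cond)
    if not fit1.converged:
        return ConditionCall(is_bimodal=None, status="unclassifiable", fit=fit1, condition=cond)
    if fit1.adj_r2 >= t.r2_threshold:
        return ConditionCall(is_bimodal=False, status="ok", fit=fit1, condition=cond)
    fit2 = fit_gaussians(sample, k=2, n_bins=t.n_bins)
    if not fit2.converged:
        return ConditionCall(
            is_bimodal=None, status="unclassifiable", fit=fit1, fit2=fit2, condition=cond
        )
    sep = fit2.separation_over_maxsd
    minor = fit2.minor_fraction
    bimodal = sep > t.separation_multiplier and minor > t.min_fraction
    return ConditionCall(
        is_bimodal=bimodal,
        status="ok",
        fit=fit1,
        fit2=fit2,
        separation_over_maxsd=sep,
        minor_fraction=minor,
        condition=cond,
    )


def classify_profile(
    profile: InductionProfile, thresholds: ModalityThresholds | None = None
) -> ModalityCall:
    """Profile is bimodal iff at least one classifiable condition is bimodal."""
    if not profile.samples:
        raise ValueError("profile has no samples")
    calls = [classify_condition(s, thresholds) for s in profile.samples]
    classifiable = [c for c in calls if c.status == "ok"]
    if not classifiable:
        return ModalityCall(
            per_condition=calls,
            profile_is_bimodal=None,
            status="unclassifiable",
            rule_trace="no classifiable condition",
            replicate_id=profile.replicate_id,
        )
    bimodal_idx = [i for i, c in enumerate(calls) if c.is_bimodal]
    is_bi = bool(bimodal_idx)
    trace = (
        f"bimodal at condition indices {bimodal_idx}"
        if is_bi
        else f"all {len(classifiable)} classifiable conditions unimodal"
    )
    n_bad = len(calls) - len(classifiable)
    if n_bad:
        trace += f"; {n_bad} unclassifiable condition(s) excluded"
    return ModalityCall(
        per_condition=calls,
        profile_is_bimodal=is_bi,
        status="ok",
        rule_trace=trace,
        replicate_id=profile.replicate_id,
    )


def aggregate_modality(calls: list[ModalityCall]) -> bool:
    """Strain-level call across replicates: bimodal iff every replicate is."""
    if not calls:
        raise ValueError("need at least one replicate's ModalityCall")
    if any(c.status != "ok" for c in calls):
        raise ValueError("cannot aggregate: unclassifiable replicate present")
    return all(c.profile_is_bimodal for c in calls)
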