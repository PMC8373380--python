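"""Synthetic strain panels and on-disk fixture sets.

Emulates the statistical structure of a natural-isolate panel: each strain
is a (E10, F90, n_level, n_frac) parameter set; pre-induction carbon-source
"history" acts as a multiplicative shift of F90 (and optionally E10),
mirroring the observation that history moves the induced-fraction threshold
far more than the level threshold (fold changes ~8.6 vs ~1.8).  Fixtures
are directories of event tables with a JSON manifest carrying full ground
truth, so the whole pipeline is testable without any external download.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import read_profile, write_profile
from .model import FRACTION_HILL_RANGE, LEVEL_HILL_RANGE, InductionModel
from .simulate import InductionProfile, simulate_profile

__all__ = [
    "SyntheticStrainSpec",
    "FixtureSet",
    "make_strain_panel",
    "emit_fixture",
    "F90_HISTORY_FOLD",
    "E10_HISTORY_FOLD",
]

#: Fold changes of the two thresholds between pre-induction carbon sources
#: used as the default emulated history effect.
F90_HISTORY_FOLD = 8.6
E10_HISTORY_FOLD = 1.8


@dataclass
class SyntheticStrainSpec:
    """Ground-truth parameters of one synthetic strain."""

    name: str
    E10: float
    F90: float
    n_level: float
    n_frac: float
    #: per-history multiplicative factor on F90 (missing label -> 1.0)
    history_shift: dict = field(default_factory=dict)
    #: per-history multiplicative factor on E10 (default 1.0: history acts
    #: mainly through the induced-fraction threshold)
    e10_history_shift: dict = field(default_factory=dict)
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.E10, self.F90, self.n_level, self.n_frac) <= 0:
            raise ValueError("thresholds and Hill coefficients must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def model_for(self, history: str | None = None, **params) -> InductionModel:
        f_shift = self.history_shift.get(history, 1.0) if history else 1.0
        e_shift = self.e10_history_shift.get(history, 1.0) if history else 1.0
        return InductionModel(
            E10=self.E10 * e_shift,
            F90=self.F90 * f_shift,
            n_level=self.n_level,
            n_frac=self.n_frac,
            **params,
        )


def make_strain_panel(n_strains: int, seed: int = 0) -> list[SyntheticStrainSpec]:
    """Draw a reproducible panel of strain parameter sets.

    E10 and F90 are log-uniform over [0.001, 1] % w/v and the Hill
    coefficients uniform over the observed fitted ranges.  The draw is
    stratified so the panel always spans both regimes: the first strain has
    E10/F90 < 0.1 (unimodal side) and the second E10/F90 > 10 (bimodal
    side) whenever n_strains >= 2.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    rng = np.random.default_rng(seed)
    specs: list[SyntheticStrainSpec] = []
    for i in range(n_strains):
        if i == 0 and n_strains >= 2:
            f90 = 10 ** rng.uniform(-1.0, 0.0)
            e10 = f90 * 10 ** rng.uniform(-2.0, -1.0)  # ratio in (0.01, 0.1)
        elif i == 1:
            e10 = 10 ** rng.uniform(-1.0, 0.0)
            f90 = e10 * 10 ** rng.uniform(-2.0, -1.0)  # ratio in (10, 100)
        else:
            e10 = 10 ** rng.uniform(-3.0, 0.0)
            f90 = 10 ** rng.uniform(-3.0, 0.0)
        specs.append(
            SyntheticStrainSpec(
                name=f"synth{i:02d}",
                E10=float(e10),
                F90=float(f90),
                n_level=float(rng.uniform(*LEVEL_HILL_RANGE)),
                n_frac=float(rng.uniform(*FRACTION_HILL_RANGE)),
                history_shift={"raffinose": 1.0, "mannose": F90_HISTORY_FOLD},
                e10_history_shift={"raffinose": 1.0, "mannose": 1.0},
                seed=int(rng.integers(0, 2**31 - 10_000)),
            )
        )
    return specs


@dataclass
class FixtureSet:
    """An on-disk fixture: event-table tree plus a ground-truth manifest."""

    root: Path
    manifest: dict

    @classmethod
    def load(cls, root) -> "FixtureSet":
        root = Path(root)
        return cls(root=root, manifest=json.loads((root / "manifest.json").read_text()))

    def profile(self, strain: str, history: str, replicate: int) -> InductionProfile:
        for entry in self.manifest["profiles"]:
            if (
                entry["strain"] == strain
                and entry["history"] == history
                and entry["replicate"] == replicate
            ):
                return read_profile(self.root / entry["path"])
        raise KeyError(f"no profile for ({strain}, {history}, {replicate})")


def emit_fixture(
    specs: list[SyntheticStrainSpec],
    out_dir,
    histories: list[str] | None = None,
    n_cells: int = 20_000,
    glucose_grid=None,
) -> FixtureSet:
    """Simulate and write every (strain, history, replicate) profile.

    Each profile directory holds the nine titration event tables plus the
    uninduced and maximal-induction references; ``manifest.json`` records
    the ground truth (shifted E10/F90, Hill coefficients, per-profile seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if histories is None:
        labels = {h for s in specs for h in s.history_shift}
        histories = sorted(labels) or ["raffinose"]
    manifest: dict = {
        "strains": [dataclasses.asdict(s) for s in specs],
        "histories": histories,
        "n_cells": n_cells,
        "profiles": [],
    }
    for s_idx, spec in enumerate(specs):
        for h_idx, history in enumerate(histories):
            model = spec.model_for(history)
            for rep in range(1, spec.replicates + 1):
                rel = Path(spec.name) / history / f"rep{rep}"
                profile_seed = (
                    spec.seed + 1_000 * (h_idx * spec.replicates + rep)
                ) % 2**31
                profile = simulate_profile(
                    model,
                    glucose_grid=glucose_grid,
                    n_cells=n_cells,
                    seed=profile_seed,
                    replicate_id=f"rep{rep}",
                )
                write_profile(profile, out_dir / rel)
                manifest["profiles"].append(
                    {
                        "strain": spec.name,
                        "history": history,
                        "replicate": rep,
                        "path": str(rel),
                        "seed": profile_seed,
                        "true_E10": model.E10,
                        "true_F90": model.F90,
                        "n_level": model.n_level,
                        "n_frac": model.n_frac,
                        "true_induced_fraction": [
                            s.true_induced_fraction for s in profile.samples
                        ],
                    }
                )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return FixtureSet(root=out_dir, manifest=manifest)
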