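"""Event-table I/O: delimited-text stand-in for flow-cytometry exports.

A sample is one CSV with one row per cell (``label, glucose, galactose,
log_expression``); a profile is a directory of such tables plus a
``profile.json`` sidecar holding ordering, seeds and simulation ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import Condition, InductionProfile, PopulationSample

__all__ = ["write_sample", "read_sample", "write_profile", "read_profile"]

_PROFILE_META = "profile.json"


def write_sample(sample: PopulationSample, path: str | Path) -> Path:
    """Write one event table (one row per cell) as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cond = sample.condition
    pd.DataFrame(
        {
            "label": cond.label,
            "glucose": cond.glucose,
            "galactose": cond.galactose,
            "log_expression": sample.log_expression,
        }
    ).to_csv(path, index=False)
    return path


def read_sample(path: str | Path) -> PopulationSample:
    df = pd.read_csv(path)
    required = {"glucose", "log_expression"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    cond = Condition(
        glucose=float(df["glucose"].iloc[0]),
        galactose=float(df["galactose"].iloc[0]) if "galactose" in df else 0.0,
        label=str(df["label"].iloc[0]) if "label" in df else "",
    )
    return PopulationSample(log_expression=df["log_expression"].to_numpy(), condition=cond)


def _sample_meta(sample: PopulationSample) -> dict:
    return {
        "seed": sample.seed,
        "true_induced_fraction": sample.true_induced_fraction,
    }


def write_profile(profile: InductionProfile, out_dir: str | Path) -> Path:
    """Write a profile as a directory of event tables plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta: dict = {"replicate_id": profile.replicate_id, "conditions": [], "references": {}}
    for i, sample in enumerate(profile.samples):
        name = f"condition_{i:02d}.csv"
        write_sample(sample, out_dir / name)
        meta["conditions"].append({"file": name, **_sample_meta(sample)})
    for key, ref in (
        ("uninduced", profile.uninduced_ref),
        ("max_induction", profile.max_induction_ref),
    ):
        if ref is not None:
            name = f"{key}_ref.csv"
            write_sample(ref, out_dir / name)
            meta["references"][key] = {"file": name, **_sample_meta(ref)}
    (out_dir / _PROFILE_META).write_text(json.dumps(meta, indent=2))
    return out_dir


def read_profile(in_dir: str | Path) -> InductionProfile:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / _PROFILE_META).read_text())

    def load(entry: dict) -> PopulationSample:
        s = read_sample(in_dir / entry["file"])
        s.seed = entry.get("seed")
        s.true_induced_fraction = entry.get("true_induced_fraction")
        return s

    refs = meta.get("references", {})
    return InductionProfile(
        samples=[load(e) for e in meta["conditions"]],
        uninduced_ref=load(refs["uninduced"]) if "uninduced" in refs else None,
        max_induction_ref=load(refs["max_induction"]) if "max_induction" in refs else None,
        replicate_id=meta.get("replicate_id", "rep1"),
    )
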