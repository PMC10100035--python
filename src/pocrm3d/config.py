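"""Run configuration, bundled fixtures and reproducibility manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .design import DesignParams, Skeleton, skeleton_from_spacing
from .grid import RegimenGrid, build_default_grid
from .orderings import OrderingSet, default_orderings, default_pair_constraints
from .simulate import Scenario, default_scenarios, load_scenarios, scenarios_to_csv

__all__ = ["RunConfig", "load_config", "make_fixtures", "write_manifest"]

_DESIGN_FIELDS = {
    "nu": 0.04,
    "k_linear": 18,
    "skeleton_tail": [0.75, 0.80],
    "mu": 1.50,
    "sigma2": 1.0 / 1.50,
    "c_overdose": 0.25,
    "target_lower": 0.20,
    "target_upper": 0.35,
    "gamma": 0.275,
    "b": 0.60,
    "cohort_size": 3,
    "max_n": 48,
    "start_regimen": 18,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a reproducible run.

    File paths may be None, in which case the bundled defaults (the trial
    grid, the reconstructed orderings, the twenty scenarios) are used.
    """

    design: DesignParams
    grid_file: str | None = None
    orderings_file: str | None = None
    scenarios_file: str | None = None
    allocation_rule: str = "next_best"
    n_sim: int = 2000
    seed: int = 0
    outdir: str = "pocrm3d_output"

    def load_grid(self) -> RegimenGrid:
        if self.grid_file is None:
            return build_default_grid()
        return RegimenGrid.from_csv(self.grid_file)

    def load_orderings(self) -> OrderingSet:
        if self.orderings_file is None:
            return default_orderings()
        return OrderingSet.from_csv(self.orderings_file)

    def load_scenarios(self) -> list[Scenario]:
        if self.scenarios_file is None:
            return default_scenarios()
        return load_scenarios(self.scenarios_file)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "grid_file",
                "orderings_file",
                "scenarios_file",
                "allocation_rule",
                "n_sim",
                "seed",
                "outdir",
            )
        }
        design = self.design
        d.update(
            {
                "mu": design.mu,
                "sigma2": design.sigma2,
                "c_overdose": design.c_overdose,
                "target_lower": design.target_lower,
                "target_upper": design.target_upper,
                "gamma": design.gamma,
                "b": design.b,
                "cohort_size": design.cohort_size,
                "max_n": design.max_n,
                "start_regimen": design.start_regimen,
                "skeleton": list(design.skeleton.values),
            }
        )
        return d


def _design_from_mapping(raw: dict) -> DesignParams:
    vals = dict(_DESIGN_FIELDS)
    for k in list(raw):
        if k in vals:
            vals[k] = raw.pop(k)
    if "skeleton" in raw:
        skeleton = Skeleton(values=tuple(raw.pop("skeleton")))
    else:
        skeleton = skeleton_from_spacing(
            vals["nu"], vals["k_linear"], tuple(vals["skeleton_tail"])
        )
    return DesignParams(
        skeleton=skeleton,
        mu=vals["mu"],
        sigma2=vals["sigma2"],
        c_overdose=vals["c_overdose"],
        target_lower=vals["target_lower"],
        target_upper=vals["target_upper"],
        gamma=vals["gamma"],
        b=vals["b"],
        cohort_size=int(vals["cohort_size"]),
        max_n=int(vals["max_n"]),
        start_regimen=int(vals["start_regimen"]),
    )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Read a YAML/JSON config; every omitted field takes the trial default.

    Unknown keys raise a ValueError naming them, so typos do not silently
    fall back to defaults.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
    raw = dict(raw)
    design = _design_from_mapping(raw)
    run_fields = {
        "grid_file",
        "orderings_file",
        "scenarios_file",
        "allocation_rule",
        "n_sim",
        "seed",
        "outdir",
    }
    kwargs = {k: raw.pop(k) for k in list(raw) if k in run_fields}
    if raw:
        raise ValueError(f"unknown config fields: {sorted(raw)}")
    return RunConfig(design=design, **kwargs)


def make_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the bundled inputs as editable plain-text fixtures.

    Produces the regimen grid, the elicited pair-probability constraints,
    the reconstructed ordering set with its priors, and one CSV per
    toxicity scenario (plus a combined file)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    grid_path = outdir / "regimen_grid.csv"
    build_default_grid().to_csv(grid_path)
    written["grid"] = grid_path

    orderings_path = outdir / "orderings_reconstructed.csv"
    default_orderings().to_csv(str(orderings_path))
    written["orderings"] = orderings_path

    pairs_path = outdir / "pair_constraints.csv"
    with open(pairs_path, "w") as fh:
        fh.write("a,b,prob_b_more_toxic\n")
        for c in default_pair_constraints():
            fh.write(f"{c.a},{c.b},{c.target_prob}\n")
    written["pair_constraints"] = pairs_path

    scenarios = default_scenarios()
    scen_dir = outdir / "scenarios"
    scen_dir.mkdir(exist_ok=True)
    for sc in scenarios:
        p = scen_dir / f"scenario_{sc.name.replace('.', '_')}.csv"
        scenarios_to_csv([sc], p)
        written[f"scenario_{sc.name}"] = p
    combined = outdir / "scenarios.csv"
    scenarios_to_csv(scenarios, combined)
    written["scenarios"] = combined
    return written


def write_manifest(config: RunConfig, outdir: str | Path) -> Path:
    """Record config hash, seed and package version next to the outputs."""
    from . import __version__

    payload = config.to_dict()
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "config": payload,
        "config_sha256": digest,
        "seed": config.seed,
        "package_version": __version__,
    }
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
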