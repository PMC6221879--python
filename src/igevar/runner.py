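"""Reproducible scenario orchestration: seeds, configs, manifests.

``run_scenario`` drives the whole per-replicate pipeline (base population →
pairing → growth → summary statistics) with one independent random stream
per replicate, spawned from the master seed and the replicate index so that
results never depend on execution order.  Every output directory receives a
JSON manifest (version, resolved parameters, seed, output checksums);
re-running with the same manifest parameters reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .model_core import SCENARIO_B_BARS, SimParams, scenario_params
from .population import sample_base_population, simulate_cohort
from .summary_stats import ScenarioResult, replicate_statistics

__all__ = [
    "replicate_rng",
    "load_scenarios",
    "run_scenario",
    "run_replicate",
    "RunManifest",
]


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Independent stream for one replicate, order-independent by construction."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(replicate,)))


def load_scenarios(path: str | Path | None = None) -> dict[int, SimParams]:
    """Scenario configurations from a YAML file (shipped defaults if None).

    Layout: a ``defaults`` mapping of SimParams fields plus a ``scenarios``
    mapping of scenario id -> field overrides.  The shipped file encodes the
    five standard scenarios.
    """
    if path is None:
        text = resources.files("igevar.data").joinpath("scenarios.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "scenarios" not in raw:
        raise ConfigError("config must contain a 'scenarios' mapping")
    defaults = raw.get("defaults", {})
    valid = {f.name for f in dataclasses.fields(SimParams)}
    out: dict[int, SimParams] = {}
    for key, overrides in raw["scenarios"].items():
        merged = {**defaults, **(overrides or {})}
        unknown = set(merged) - valid
        if unknown:
            raise ConfigError(f"unknown parameter(s) in scenario {key}: {sorted(unknown)}")
        out[int(key)] = SimParams(**merged)
    return out


def run_replicate(params: SimParams, rng: np.random.Generator):
    """One replicate: fresh base population, pairing, and full growth."""
    return simulate_cohort(sample_base_population(params, rng), params, rng)


def run_scenario(
    scenario: int | SimParams,
    n_replicates: int | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> ScenarioResult:
    """Simulate a scenario over replicates and collect summary statistics.

    ``scenario`` is a standard scenario id (1..5) or an explicit parameter
    set.  With ``out_dir`` the per-replicate summary table and a manifest
    are written there.
    """
    params = scenario_params(scenario) if isinstance(scenario, int) else scenario
    n_rep = params.n_replicates if n_replicates is None else n_replicates
    rows = [
        replicate_statistics(run_replicate(params, replicate_rng(seed, r)), replicate=r)
        for r in range(n_rep)
    ]
    result = ScenarioResult(b_bar=params.b_bar, replicates=pd.DataFrame(rows))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table = out_dir / "summary.tsv"
        result.write(table)
        RunManifest.for_run(params, seed, list(range(n_rep)), [table]).write(
            out_dir / "manifest.json"
        )
    return result


@dataclass
class RunManifest:
    """Record of one run: enough to reproduce it and verify its outputs."""

    version: str
    params: dict
    seed: int
    replicates: list[int]
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    @staticmethod
    def checksum(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    @classmethod
    def for_run(
        cls, params: SimParams, seed: int, replicates: list[int], outputs
    ) -> "RunManifest":
        return cls(
            version=__version__,
            params=dataclasses.asdict(params),
            seed=seed,
            replicates=replicates,
            outputs={str(p): cls.checksum(p) for p in outputs},
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
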