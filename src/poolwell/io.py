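"""Configuration parsing, growth-table I/O, result serialization, manifests.

Strain order in every mask, vector and CSV column is fixed as
ADE↑, TRP↑, HIS↑, LYS↑; ecology indices are the canonical 1..16.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    GrowthModelParams,
    Metabolite,
    Strain,
    default_params,
    mask_members,
)
from .distributions import (
    EcologyDistribution,
    poisson_distribution,
    restrict_distribution,
    uniform_distribution,
)
from .engine import (
    ConstantSchedule,
    CycleConfig,
    DistributionSchedule,
    FeedbackSchedule,
)

__all__ = [
    "ConfigError",
    "LoadedConfig",
    "RunManifest",
    "load_config",
    "dump_config",
    "read_growth_table",
    "write_growth_table",
    "default_growth_table_path",
    "build_schedule",
    "write_summary",
]

_GROWTH_KEYS = {
    "base_rates",
    "crossfeed_factor",
    "death_rate",
    "pool_rates",
    "overrides_file",
}
_DIST_KEYS = {"kind", "mu", "weighting", "feedback_scaling", "ban_metabolite",
              "feedback_start_cycle"}
_CONFIG_KEYS = {f.name for f in dataclasses.fields(CycleConfig)}


class ConfigError(ValueError):
    """A configuration file violated the schema."""


@dataclasses.dataclass
class LoadedConfig:
    """Everything a run needs, parsed from one file."""

    config: CycleConfig
    params: GrowthModelParams
    distribution: dict[str, Any]

    def schedule(self) -> DistributionSchedule:
        return build_schedule(self.distribution)


def _strain_from_name(name: str, where: str) -> Strain:
    key = name.strip().rstrip("↑").upper()
    try:
        return Strain[key]
    except KeyError:
        raise ConfigError(f"{where}: unknown strain {name!r}") from None


def read_growth_table(path) -> dict[tuple[int, str, Strain], float]:
    """Parse a growth-rate override CSV.

    Columns: ``ecology_index, membership_mask, strain, rate`` with a
    header row; masks are 4-char 0/1 strings in canonical strain order.
    Duplicate (ecology, mask, strain) keys are rejected.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    required = ["ecology_index", "membership_mask", "strain", "rate"]
    if list(df.columns) != required:
        raise ConfigError(
            f"growth table must have columns {required}, got {list(df.columns)}"
        )
    overrides: dict[tuple[int, str, Strain], float] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        where = f"{path} row {i}"
        try:
            idx = int(row.ecology_index)
        except ValueError:
            raise ConfigError(f"{where}: non-integer ecology_index") from None
        if not 1 <= idx <= 16:
            raise ConfigError(f"{where}: ecology_index must be in 1..16")
        mask = str(row.membership_mask)
        try:
            mask_members(mask)
        except ValueError as e:
            raise ConfigError(f"{where}: {e}") from None
        strain = _strain_from_name(str(row.strain), where)
        try:
            rate = float(row.rate)
        except ValueError:
            raise ConfigError(f"{where}: non-numeric rate {row.rate!r}") from None
        key = (idx, mask, strain)
        if key in overrides:
            raise ConfigError(f"{where}: duplicate override key {key}")
        overrides[key] = rate
    return overrides


def write_growth_table(overrides, path) -> None:
    rows = [
        {
            "ecology_index": idx,
            "membership_mask": mask,
            "strain": strain.name,
            "rate": rate,
        }
        for (idx, mask, strain), rate in sorted(
            overrides.items(), key=lambda kv: (kv[0][0], kv[0][1], int(kv[0][2]))
        )
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def default_growth_table_path() -> Path:
    """Path of the shipped override table (the published rate vector)."""
    return Path(resources.files("poolwell") / "data" / "default_growth_overrides.csv")


def _build_params(section: dict[str, Any], base_dir: Path) -> GrowthModelParams:
    unknown = set(section) - _GROWTH_KEYS
    if unknown:
        raise ConfigError(
            f"growth_model: unknown keys {sorted(unknown)}; allowed {sorted(_GROWTH_KEYS)}"
        )
    defaults = default_params()
    base_rates = tuple(section.get("base_rates", defaults.base_rates))
    if len(base_rates) != 4:
        raise ConfigError("growth_model.base_rates: need 4 values")
    pool_rates = tuple(section.get("pool_rates", defaults.pool_rates))
    if len(pool_rates) != 4:
        raise ConfigError("growth_model.pool_rates: need 4 values")
    overrides = dict(defaults.overrides)
    if "overrides_file" in section and section["overrides_file"]:
        overrides = read_growth_table(base_dir / section["overrides_file"])
    try:
        return GrowthModelParams(
            base_rates=base_rates,
            crossfeed_factor=float(
                section.get("crossfeed_factor", defaults.crossfeed_factor)
            ),
            death_rate=float(section.get("death_rate", defaults.death_rate)),
            pool_rates=pool_rates,
            overrides=overrides,
        )
    except ValueError as e:
        raise ConfigError(f"growth_model: {e}") from None


def build_schedule(spec: dict[str, Any]) -> DistributionSchedule:
    """Construct a per-cycle ecology-distribution schedule from config keys."""
    unknown = set(spec) - _DIST_KEYS
    if unknown:
        raise ConfigError(
            f"ecology_distribution: unknown keys {sorted(unknown)}"
        )
    kind = spec.get("kind", "uniform")
    if kind == "uniform":
        base: EcologyDistribution = uniform_distribution()
    elif kind == "poisson":
        if "mu" not in spec:
            raise ConfigError("ecology_distribution: poisson requires 'mu'")
        base = poisson_distribution(
            float(spec["mu"]), weighting=spec.get("weighting", "index")
        )
    elif kind == "feedback":
        base = uniform_distribution()
    else:
        raise ConfigError(f"ecology_distribution.kind: unknown kind {kind!r}")
    ban = spec.get("ban_metabolite")
    if ban:
        try:
            banned = Metabolite[str(ban).upper()]
        except KeyError:
            raise ConfigError(
                f"ecology_distribution.ban_metabolite: unknown metabolite {ban!r}"
            ) from None
        base = restrict_distribution(base, banned)
    if kind == "feedback":
        scaling = {"identity": "identity", "4x": "4x"}.get(
            spec.get("feedback_scaling", "identity")
        )
        if scaling is None:
            raise ConfigError(
                "ecology_distribution.feedback_scaling: must be identity or 4x"
            )
        return FeedbackSchedule(
            base,
            start_cycle=int(spec.get("feedback_start_cycle", 1)),
            scaling=scaling,
        )
    return ConstantSchedule(base)


def load_config(path) -> LoadedConfig:
    """Parse and validate a YAML run configuration.

    Omitted keys fall back to the study defaults (K = 10, d = -2,
    t_wells = 20, 96 wells, uniform ecologies); unknown keys are
    rejected with the offending name.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    growth_section = raw.pop("growth_model", {}) or {}
    dist_section = raw.pop("ecology_distribution", {}) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(
            f"{path}: unknown keys {sorted(unknown)}; allowed "
            f"{sorted(_CONFIG_KEYS | {'growth_model', 'ecology_distribution'})}"
        )
    if "initial_proportions" in raw and isinstance(raw["initial_proportions"], list):
        raw["initial_proportions"] = tuple(raw["initial_proportions"])
    try:
        config = CycleConfig(**raw)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{path}: {e}") from None
    params = _build_params(growth_section, path.parent)
    return LoadedConfig(config=config, params=params, distribution=dict(dist_section))


def dump_config(loaded: LoadedConfig, path) -> None:
    """Serialize a loaded configuration back to YAML (round-trippable)."""
    cfg = dataclasses.asdict(loaded.config)
    if isinstance(cfg["initial_proportions"], tuple):
        cfg["initial_proportions"] = list(cfg["initial_proportions"])
    doc = dict(cfg)
    doc["growth_model"] = {
        "base_rates": list(loaded.params.base_rates),
        "crossfeed_factor": loaded.params.crossfeed_factor,
        "death_rate": loaded.params.death_rate,
        "pool_rates": list(loaded.params.pool_rates),
    }
    doc["ecology_distribution"] = dict(loaded.distribution)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


@dataclasses.dataclass
class RunManifest:
    """Snapshot of everything needed to reproduce a batch of runs."""

    config: dict[str, Any]
    master_seed: int
    n_runs: int
    package_version: str = __version__
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
    )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def write_summary(summary, outdir, config: Optional[CycleConfig] = None,
                  seed: int = 0) -> None:
    """Write summary.csv, runs.csv (if runs were kept) and config.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary.to_dataframe().to_csv(outdir / "summary.csv", index=False)
    if summary.runs:
        frames = []
        for i, run in enumerate(summary.runs):
            df = run.to_dataframe()
            df.insert(0, "run", i)
            frames.append(df)
        pd.concat(frames).to_csv(outdir / "runs.csv", index=False)
    cfg = dataclasses.asdict(config) if config is not None else {}
    if isinstance(cfg.get("initial_proportions"), tuple):
        cfg["initial_proportions"] = list(cfg["initial_proportions"])
    RunManifest(config=cfg, master_seed=seed, n_runs=summary.n_runs).to_json(
        outdir / "config.json"
    )
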