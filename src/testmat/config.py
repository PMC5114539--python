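"""Run configuration, validation and result writing.

Configs are YAML, validated strictly (unknown keys rejected, field-level
errors) before any computation; result tables are CSV with a fixed column
order and three-decimal floats, accompanied by a manifest recording the
root seed, a hash of the normalised config and the package version, so any
run can be reconstructed from its output directory.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .estimation import ChainConfig, PriorSpec
from .study import ConditionSpec

__all__ = ["ChainSettings", "RunConfig", "load_config", "write_results"]


class ChainSettings(BaseModel):
    """Sampler schedule of the final scaling (see :class:`~testmat.ChainConfig`)."""

    model_config = ConfigDict(extra="forbid")

    min_burn_in: int = Field(1000, ge=1)
    burn_in_cap: int = Field(5000, ge=1)
    check_interval: int = Field(500, ge=1)
    retain: int = Field(500, ge=1)
    adapt_interval: int = Field(100, ge=1)

    def to_chain_config(self) -> ChainConfig:
        return ChainConfig(
            min_burn_in=self.min_burn_in,
            burn_in_cap=self.burn_in_cap,
            check_interval=self.check_interval,
            retain=self.retain,
            adapt_interval=self.adapt_interval,
        )


class RunConfig(BaseModel):
    """Validated study configuration.

    The defaults are the scaled-down profile (500 persons, 2 replications,
    burn-in capped at 5,000); the published full-scale design uses 5,000
    persons, 10 replications and a far higher cap.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 1
    n_persons: int = Field(500, ge=1)
    replications: int = Field(2, ge=1)
    sigma2_gamma: list[float] = [0.0, 0.5, 1.0, 1.5]
    testlet_sizes: list[int] = [3, 6, 9]
    models: list[str] = ["MTIRT", "MIRT"]
    algorithms: list[str] = ["MAT", "RAN"]
    max_items: int = Field(54, ge=1)
    shrinkage_n: int = Field(5000, ge=10)
    min_exposure: int = Field(20, ge=1)
    wishart_df: float = 9.0
    ig_shape: float = Field(1e-3, gt=0)
    ig_scale: float = Field(1e-3, gt=0)
    chain: ChainSettings = ChainSettings()

    @field_validator("sigma2_gamma")
    @classmethod
    def _nonnegative_variances(cls, v: list[float]) -> list[float]:
        if any(s < 0 for s in v):
            raise ValueError("testlet effect variances must be non-negative")
        return v

    @field_validator("testlet_sizes")
    @classmethod
    def _positive_sizes(cls, v: list[int]) -> list[int]:
        if any(s < 1 for s in v):
            raise ValueError("testlet sizes must be positive")
        return v

    @field_validator("models")
    @classmethod
    def _known_models(cls, v: list[str]) -> list[str]:
        bad = set(v) - {"MTIRT", "MIRT"}
        if bad:
            raise ValueError(f"unknown models: {sorted(bad)}")
        return v

    @field_validator("algorithms")
    @classmethod
    def _known_algorithms(cls, v: list[str]) -> list[str]:
        bad = set(v) - {"MAT", "RAN"}
        if bad:
            raise ValueError(f"unknown algorithms: {sorted(bad)}")
        return v

    def conditions(self) -> list[ConditionSpec]:
        """The full factorial grid of this configuration."""
        return [
            ConditionSpec(
                sigma2_gamma=s2,
                testlet_size=size,
                model=model,
                algorithm=algo,
                n_persons=self.n_persons,
                replications=self.replications,
                max_items=self.max_items,
            )
            for size in self.testlet_sizes
            for s2 in self.sigma2_gamma
            for model in self.models
            for algo in self.algorithms
        ]

    def prior_spec(self) -> PriorSpec:
        return PriorSpec(
            wishart_df=self.wishart_df,
            ig_shape=self.ig_shape,
            ig_scale=self.ig_scale,
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> list[Path]:
    """Write result tables as CSV plus a manifest sidecar.

    Floats are rendered at three decimals (the precision the study tables
    are reported at); an empty table still produces its header row.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.3f")
        written.append(path)
    manifest = {
        "tables": sorted(t.name for t in written),
    }
    if config is not None:
        from importlib.metadata import PackageNotFoundError, version

        try:
            pkg_version = version("testmat")
        except PackageNotFoundError:
            pkg_version = "unknown"
        manifest.update(
            {
                "seed": config.seed,
                "config_hash": config.config_hash(),
                "config": config.model_dump(),
                "version": pkg_version,
            }
        )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    written.append(manifest_path)
    return written
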