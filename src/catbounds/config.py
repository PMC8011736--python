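"""Run configuration: validated JSON in, result bundle out."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .densities import AttributeDensity, make_density

__all__ = ["DensitySpec", "DynamicsSpec", "RunConfig", "load_config", "ValidationError"]


class DensitySpec(BaseModel):
    """JSON specification of an attribute density."""

    model_config = ConfigDict(extra="forbid")

    family: str
    a: float = 0.0
    b: float = 1.0
    alpha: Optional[float] = Field(default=None, gt=0)
    beta: Optional[float] = Field(default=None, gt=0)
    samples_csv: Optional[str] = None  # empirical family only
    fit_method: str = "histogram"  # histogram | beta_moments
    bins: int = 64

    @model_validator(mode="after")
    def _family_params(self):
        if self.family in ("beta", "bimodal_beta") and (self.alpha is None or self.beta is None):
            raise ValueError(f"family {self.family!r} requires alpha and beta")
        if self.family == "empirical" and self.samples_csv is None:
            raise ValueError("family 'empirical' requires samples_csv")
        if self.family not in ("uniform", "beta", "bimodal_beta", "empirical"):
            raise ValueError(f"unknown family {self.family!r}")
        return self

    def build(self) -> AttributeDensity:
        if self.family == "uniform":
            return make_density("uniform", self.a, self.b)
        if self.family in ("beta", "bimodal_beta"):
            return make_density(self.family, self.a, self.b, alpha=self.alpha, beta=self.beta)
        from .densities import fit_from_samples

        samples = _read_samples(Path(self.samples_csv))
        return fit_from_samples(samples, self.a, self.b, method=self.fit_method, bins=self.bins)


def _read_samples(path: Path):
    """One-column CSV of attribute values; an optional 'x' header is allowed."""
    import pandas as pd

    df = pd.read_csv(path, header=None)
    first = df.iloc[0, 0]
    if isinstance(first, str):
        df = pd.read_csv(path)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected a one-column CSV, got {df.shape[1]} columns")
    return df.iloc[:, 0].to_numpy(dtype=float)


class DynamicsSpec(BaseModel):
    """JSON view of :class:`catbounds.collective_dynamics.DynamicsConfig`."""

    model_config = ConfigDict(extra="forbid")

    k: float = Field(default=1.0, gt=0)
    z0: Optional[float] = None
    t_max: Optional[float] = Field(default=None, gt=0)
    convergence_tol: float = Field(default=1e-8, gt=0)
    edge_margin: Optional[float] = Field(default=None, gt=0)


class RunConfig(BaseModel):
    """Top-level run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    density: DensitySpec
    dynamics: DynamicsSpec = DynamicsSpec()
    output_dir: str = "catbounds_out"
    seed: int = 0
    figure: bool = True


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a JSON run configuration file."""
    with open(path) as fh:
        raw = json.load(fh)
    return RunConfig.model_validate(raw)
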