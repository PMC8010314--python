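"""Pipeline configuration.

All tunables of the ranking model live in :class:`PipelineConfig`.  Defaults
are the operating point reported for the method: beta=0.5 mixes expression/
topology similarity into edge weights; phi/theta/tau weight the subcellular,
triangle and orthology features (printed values 0.25/0.35/0.45, which sum to
1.05 — kept verbatim, with ``renormalize_features`` to rescale them to sum 1);
omega mixes the domain-derived score against the feature score; mu is the
propagation damping of the iterative ranker and rho the row mass of the
weight-allocation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    beta: float = 0.5
    phi: float = 0.25
    theta: float = 0.35
    tau: float = 0.45
    omega: float = 0.7
    mu: float = 0.4
    rho: float = 0.85
    epsilon: float = 1e-6
    #: DFT length N; None means "use the series length M" (the canonical DFT).
    dft_length: int | None = None
    alpha_prime: float = 1.0
    delta_prime: float = 1.0
    renormalize_features: bool = False
    max_iter: int = 10_000
    random_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ConfigError(f"beta must be in [0, 1], got {self.beta}")
        if not 0.0 < self.rho <= 1.0:
            raise ConfigError(f"rho must be in (0, 1], got {self.rho}")
        if not 0.0 < self.mu < 1.0:
            raise ConfigError(f"mu must be in (0, 1), got {self.mu}")
        if self.epsilon <= 0:
            raise ConfigError(f"epsilon must be > 0, got {self.epsilon}")
        for name in ("phi", "theta", "tau", "omega"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.alpha_prime <= 0 or self.delta_prime <= 0:
            raise ConfigError("kernel bandwidth numerators must be > 0")
        if self.dft_length is not None and self.dft_length < 1:
            raise ConfigError("dft_length must be >= 1")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        # mu * rho < 1 guarantees the score iteration contracts.
        if self.mu * self.rho >= 1.0:
            raise ConfigError(
                f"mu * rho must be < 1 for convergence, got {self.mu * self.rho}"
            )

    def feature_weights(self) -> tuple[float, float, float]:
        """(phi, theta, tau), rescaled to sum 1 if renormalize_features."""
        w = (self.phi, self.theta, self.tau)
        if self.renormalize_features:
            s = sum(w)
            if s > 0:
                w = tuple(x / s for x in w)
        return w

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key: value`` YAML mapping or ``key=value`` lines."""
        text = Path(path).read_text()
        body = [
            ln.strip()
            for ln in text.splitlines()
            if ln.strip() and not ln.strip().startswith("#")
        ]
        if body and all("=" in ln and ":" not in ln for ln in body):
            mapping = {}
            for line in body:
                key, _, val = line.partition("=")
                mapping[key.strip()] = yaml.safe_load(val.strip())
        else:
            loaded = yaml.safe_load(text) or {}
            if not isinstance(loaded, dict):
                raise ConfigError(f"config file {path} is not a mapping")
            mapping = loaded
        return cls.from_mapping(mapping)
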