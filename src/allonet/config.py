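"""Run configuration: every tunable of the pipeline in one place.

Defaults are the documented study conditions; a config can be loaded
from a flat ``key = value`` file and overridden by CLI flags. The
serialized config (and its hash) is embedded in every output header.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .errors import ConfigError


@dataclass
class RunConfig:
    # inputs
    msa: str | None = None
    ensemble: str | None = None
    outdir: str = "allonet_run"
    # alignment / coevolution
    min_coverage: float = 0.8
    identity_threshold: float = 0.62
    pseudocount: float = 0.05
    n_shuffles: int = 100
    t_cmi: float = 6.5
    cmi_matrix: str = "z"
    # dynamics
    gnm_cutoff: float = 7.3
    gnm_modes: int = 3
    # coupling
    t_pmi: float = 5.0
    pmi_aggregate: str = "mean"
    estimator: str = "gaussian"
    # network
    contact_distance: float = 4.5
    I_min: float = 1.0
    persistence: float = 0.75
    community_frames: int = 10
    # pathways
    w1: float = 0.5
    w2: float = 0.5
    temperature: float = 300.0
    source: int | None = None
    sink: int | None = None
    path_mode: str = "frames"
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.min_coverage <= 1:
            raise ConfigError("min_coverage must be in (0, 1]")
        if not 0 < self.identity_threshold < 1:
            raise ConfigError("identity_threshold must be in (0, 1)")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be nonnegative")
        if self.n_shuffles < 10:
            raise ConfigError("n_shuffles must be >= 10")
        if self.gnm_cutoff <= 0:
            raise ConfigError("gnm_cutoff must be positive")
        if self.t_pmi <= 0:
            raise ConfigError("t_pmi must be positive")
        if self.contact_distance <= 0:
            raise ConfigError("contact_distance must be positive")
        if self.I_min < 0:
            raise ConfigError("I_min must be nonnegative")
        if not 0 < self.persistence <= 1:
            raise ConfigError("persistence must be in (0, 1]")
        if self.community_frames < 2:
            raise ConfigError("community_frames must be >= 2")
        if self.w1 < 0 or self.w2 < 0:
            raise ConfigError("w1 and w2 must be nonnegative")
        if self.pmi_aggregate not in ("mean", "sum"):
            raise ConfigError("pmi_aggregate must be 'mean' or 'sum'")
        if self.estimator not in ("gaussian", "knn"):
            raise ConfigError("estimator must be 'gaussian' or 'knn'")
        if self.path_mode not in ("frames", "mean"):
            raise ConfigError("path_mode must be 'frames' or 'mean'")
        if self.seed < 0:
            raise ConfigError("seed must be nonnegative")

    def items(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def hash(self) -> str:
        text = "\n".join(f"{k}={v}" for k, v in sorted(self.items().items()))
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from a flat ``key = value`` file; later kwargs override."""
        values: dict = {}
        known = {f.name: f for f in fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"malformed config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ConfigError(f"unknown config key: {key}")
            values[key] = _coerce(val)
        values.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**values)
        cfg.validate()
        return cfg


def _coerce(val: str):
    if val.lower() in ("none", ""):
        return None
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    return val
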