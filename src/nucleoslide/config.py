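"""Flat key=value run configuration.

A run configuration collects the physical parameters shared by the CLI
commands.  Files are plain ``key = value`` lines (``#`` comments);
unknown keys are rejected so typos fail loudly.  CLI flags override
file values.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields

from .errors import NucleoslideError


class ConfigError(NucleoslideError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    temperature: float = 300.0       # K
    ionic_strength: float = 0.2      # mol/L
    hb_epsilon: float = 1.2          # kBT
    hb_sigma: float = 1.0            # Angstrom
    hb_delta_phi: float = 10.0       # degrees
    contact_cutoff: float = 12.0     # Angstrom
    bp_bin: float = 0.25             # bp
    eta_bin: float = 9.0             # degrees
    smooth_window: int = 0           # moving-average window (0 = off)
    seed: int = 0
    dyad_bp: int = -1                # -1: use the central base pair

    _POSITIVE = ("temperature", "ionic_strength", "hb_epsilon", "hb_sigma",
                 "hb_delta_phi", "contact_cutoff", "bp_bin", "eta_bin")

    def __post_init__(self):
        self.validate()

    def validate(self):
        for name in self._POSITIVE:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive "
                                  f"(got {getattr(self, name)})")
        if self.smooth_window < 0 or self.seed < 0:
            raise ConfigError("smooth_window and seed must be non-negative")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        known = {f.name: f.type for f in fields(cls)}
        values = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected key = value")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
                caster = int if known[key] in ("int", int) else float
                try:
                    values[key] = caster(val)
                except ValueError:
                    raise ConfigError(
                        f"{path}:{lineno}: bad value {val!r} for {key}") from None
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def digest(self) -> str:
        body = ";".join(f"{f.name}={getattr(self, f.name)}"
                        for f in fields(self))
        return hashlib.md5(body.encode()).hexdigest()[:12]
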