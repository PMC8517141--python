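"""Experiment configuration: schema, defaults, loading and resolved dumps.

Configurations are plain mappings (YAML or JSON on disk).  Loading resolves
every default explicitly so a dumped resolved config fully determines a run;
a short hash of the resolved config is carried into result tables as
provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["ExperimentConfig", "load_config", "resolve_config"]

_EXPERIMENTS = ("run", "coupling", "subtype", "size", "location", "multiosc")
_VARIANTS = ("HH", "HH-50", "HH-500")
_COUPLING_MODELS = ("static", "cx40", "cx43", "cx45", "cx45-swapped")
_SITES = ("center", "vertex", "edge", "surface")


@dataclass(frozen=True)
class PacemakerConfig:
    """Pacemaker placement: either a named cube site or an explicit cell id.

    ``gbar_na=None`` defers to the experiment's default oscillator strength
    (the chain and cube protocols use different values)."""

    site: str | None = None
    cell: int | None = None
    gbar_na: float | None = None

    def __post_init__(self) -> None:
        if (self.site is None) == (self.cell is None):
            raise ValueError("specify exactly one of site or cell")
        if self.site is not None and self.site not in _SITES:
            raise ValueError(f"unknown site {self.site!r}; choose from {_SITES}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved, schema-checked configuration of one experiment or sweep."""

    experiment: str = "run"
    topology: str = "chain"              # chain | cube
    size: int = 181                      # cells in chain / cube side
    ap_variant: str = "HH"
    coupling_model: str = "static"
    coupling_nS: tuple[float, ...] = (50.0,)
    pacemakers: tuple[PacemakerConfig, ...] = (
        PacemakerConfig(site=None, cell=-1),)  # -1 = the central cell
    duration: float = 300.0              # ms
    dt: float = 0.025                    # ms
    sample_every: int = 1
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.experiment not in _EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.topology not in ("chain", "cube"):
            raise ValueError("topology must be 'chain' or 'cube'")
        if self.ap_variant not in _VARIANTS:
            raise ValueError(f"ap_variant must be one of {_VARIANTS}")
        if self.coupling_model not in _COUPLING_MODELS:
            raise ValueError(f"coupling_model must be one of {_COUPLING_MODELS}")
        if self.size < 1 or self.duration < 0 or self.dt <= 0:
            raise ValueError("size must be >= 1, duration >= 0, dt > 0")
        if not self.coupling_nS:
            raise ValueError("at least one coupling strength is required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coupling_nS"] = list(self.coupling_nS)
        d["pacemakers"] = [asdict(p) for p in self.pacemakers]
        return d

    def dump(self, path) -> None:
        """Write the fully resolved config (all defaults explicit)."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def digest(self) -> str:
        """Short provenance hash of the resolved config."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def resolve_config(raw: dict) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a raw mapping, applying
    defaults and normalising shorthand (scalar coupling, pacemaker dicts)."""
    raw = dict(raw)
    if "coupling_nS" in raw and not isinstance(raw["coupling_nS"], (list, tuple)):
        raw["coupling_nS"] = [raw["coupling_nS"]]
    if "coupling_nS" in raw:
        raw["coupling_nS"] = tuple(float(g) for g in raw["coupling_nS"])
    if "pacemakers" in raw:
        raw["pacemakers"] = tuple(
            p if isinstance(p, PacemakerConfig) else PacemakerConfig(**p)
            for p in raw["pacemakers"]
        )
    return ExperimentConfig(**raw)


def load_config(path) -> ExperimentConfig:
    """Load a YAML or JSON config file and resolve all defaults."""
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return resolve_config(raw)
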