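"""Run configuration: thresholds, bin sizes, paths, seed.

Config files are TOML (preferred) or YAML; CLI flags override file values.
Every pipeline run writes a resolved copy of its configuration next to the
outputs so a run is reproducible from one artifact.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All tunables of the analysis pipeline, with their standard defaults.

    Thresholds are weighted-methylation levels in [0, 1]:
    ``te_filter_chg``/``te_filter_chh`` guard recovery ratios against
    near-zero backgrounds; ``mcg_presence`` is the epiallele
    presence/absence boundary; ``misannotated_chg`` is the wild-type mCHG
    level above which a "gene" is treated as a mis-annotated TE.
    """

    outdir: str = "methcross_out"
    context: str = "CHG"
    te_filter_chg: float = 0.1
    te_filter_chh: float = 0.03
    mcg_presence: float = 0.05
    misannotated_chg: float = 0.05
    delta_chg: float = 0.1
    delta_chh: float = 0.03
    q_threshold: float = 0.05
    decile_count: int = 10
    window: int = 100
    curve_bin: int = 50
    body_segments: int = 20
    flank_segments: int = 10
    flank_bp: int = 2000
    min_te_length: int = 1000
    coverage: float = 20.0
    seed: int = 0
    inputs: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        for name in ("te_filter_chg", "te_filter_chh", "mcg_presence",
                     "misannotated_chg", "delta_chg", "delta_chh", "q_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("decile_count", "window", "curve_bin", "body_segments",
                     "flank_segments", "flank_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.context not in {"CG", "CHG", "CHH"}:
            raise ValueError(f"unknown context {self.context!r}")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        return self

    def write_resolved(self, outdir) -> Path:
        path = Path(outdir) / "config.resolved.yaml"
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional TOML/YAML file plus overrides.

    Overrides with value ``None`` are ignored (unset CLI flags).
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        if path.suffix in {".yaml", ".yml"}:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        else:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data).validate()
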