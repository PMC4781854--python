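"""Run configuration: every analysis parameter in one typed document.

Numeric defaults are the analysis constants of the method (artifact
thresholds, band table, permutation count, buffers, RT cap and bins, FDR
level); simulation fields control the synthetic cohort.  Unknown keys in a
config file are errors, so misspelled parameters cannot be silently
ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    seed: int = 0
    fs: float = 250.0
    notch_band: tuple[float, float] = (48.0, 52.0)

    # artifact detection and exclusion
    amplitude_sd: float = 4.0
    kurtosis_threshold: float = 4.5
    variance_sd: float = 1.75
    trial_channel_frac: float = 0.5
    channel_trial_frac: float = 0.5
    min_correct_per_class: int = 20
    rt_cap: float = 2.5

    # features and regressors
    buffer: float = 0.3
    ter_mode: str = "ez"  # "ez" | "supplied" | "zero"
    ter_supplied: float | None = None

    # statistics
    n_perm: int = 1000
    run_cca: bool = True
    cca_mode: str = "whole_brain"  # or "per_area"
    fdr_q: float = 0.05
    min_electrodes_per_area: int = 10
    exclude_downramp_ties: bool = True

    # time courses
    rt_bin_edges: tuple[float, float] = (0.9, 1.7)
    evidence_levels: int = 5

    # synthetic cohort (used when no input sessions are given)
    n_subjects: int = 8
    n_channels: int = 40
    areas: tuple[str, ...] = ("BA9", "BA19", "BA37", "BA7", "BA40")
    n_blocks: int = 2
    trials_per_block: int = 30
    planted_effects: tuple[dict, ...] = ()
    artifact_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)
    carrier_amplitude: float = 0.5
    pink_sd: float = 1.0
    pink_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.ter_mode not in ("ez", "supplied", "zero"):
            raise ValueError("ter_mode must be 'ez', 'supplied', or 'zero'")
        if self.ter_mode == "supplied" and self.ter_supplied is None:
            raise ValueError("ter_mode 'supplied' requires ter_supplied")
        if self.cca_mode not in ("whole_brain", "per_area"):
            raise ValueError("cca_mode must be 'whole_brain' or 'per_area'")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


_TUPLE_FIELDS = {
    "notch_band",
    "rt_bin_edges",
    "areas",
    "artifact_rates",
    "planted_effects",
}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for k in _TUPLE_FIELDS & set(raw):
        raw[k] = tuple(raw[k])
    return RunConfig(**raw)
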