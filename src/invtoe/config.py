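"""Structured run configuration for the pipeline.

Defaults are the workflow's standard operating point: 2 flank mismatches,
Q30 minimum base quality, 18-of-22 poly-A rejection, region of interest
24–47 nt, cleavage offset 17, 150-count well-measured threshold, pause
strength cutoff 0.25, drug/no-drug PS ratio 1.5, log2 fold-change cutoff
0.5 and variant fold-change cutoff 2.0.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from ._genetics import FLANK3_DEFAULT, FLANK5_DEFAULT
from .simulate import CleavageModel, ConfigurationError, PauseModel, SampleConfig


def _default_conditions() -> dict:
    return {
        "noab": {"default_pause": 0.02, "stop_pause": 0.4},
        "drug": {"default_pause": 0.02, "stop_pause": 0.4},
    }


@dataclass
class RunConfig:
    out_dir: str = "invtoe_out"
    seed: int = 0

    # simulation
    design: str = "nns15"
    n_events: int = 20_000
    replicates: int = 2
    wt_region: str | None = None
    mutation_rate: float = 0.07
    offset_sim: int = 17
    jitter_probs: tuple[float, float, float] = (0.70, 0.20, 0.10)
    conditions: dict[str, dict] = field(default_factory=_default_conditions)
    foreground: str = "drug"
    background: str = "noab"

    # read processing
    flank5: str = FLANK5_DEFAULT
    flank3: str = FLANK3_DEFAULT
    max_mismatch: int = 2
    min_q: int = 30
    polya_count: int = 18
    polya_window: int = 22
    quality_window: tuple[int, int] = (24, 47)
    end_window: tuple[int, int] | None = (24, 47)

    # mapping + statistics
    offset_mode: str = "fixed"  # "fixed" | "auto"
    offset: int = 17
    motif_kind: str = "aa3"
    min_counts: int = 150
    ps_min: float = 0.25
    ps_ratio: float = 1.5
    log2fc_min: float = 0.5
    fc_min: float = 2.0

    def validate(self) -> None:
        if self.offset_mode not in ("fixed", "auto"):
            raise ConfigurationError(f"offset_mode {self.offset_mode!r}")
        if self.motif_kind not in ("aa3", "codon3"):
            raise ConfigurationError(f"motif_kind {self.motif_kind!r}")
        for name in (self.foreground, self.background):
            if name not in self.conditions:
                raise ConfigurationError(f"condition {name!r} not configured")
        lo, hi = self.quality_window
        if lo < 1 or hi < lo:
            raise ConfigurationError("quality_window must be 1-based and ordered")
        if self.end_window is not None:
            lo, hi = self.end_window
            if lo < 1 or hi < lo:
                raise ConfigurationError("end_window must be 1-based and ordered")
        if self.replicates < 1 or self.n_events < 1:
            raise ConfigurationError("replicates and n_events must be >= 1")
        for thr in (self.ps_min, self.ps_ratio, self.log2fc_min, self.fc_min):
            if thr < 0:
                raise ConfigurationError("thresholds must be non-negative")

    # -- construction -------------------------------------------------

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("quality_window", "end_window", "jitter_probs"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML superset also reads JSON
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_mapping(data)

    # -- derived objects ----------------------------------------------

    def pause_model(self, condition: str) -> PauseModel:
        spec = dict(self.conditions[condition])
        spec.pop("library", None)
        spec["variant_pause"] = {
            k: tuple(v) for k, v in spec.get("variant_pause", {}).items()
        }
        return PauseModel(**spec)

    def sample_config(self, condition: str) -> SampleConfig:
        is_library = bool(self.conditions[condition].get("library", False))
        return SampleConfig(
            name=condition,
            design=self.design,
            n_events=self.n_events,
            replicates=self.replicates,
            wt_region=self.wt_region,
            mutation_rate=self.mutation_rate,
            pause=self.pause_model(condition),
            cleavage=CleavageModel(self.offset_sim, self.jitter_probs),
            library_sample=is_library,
            flank5=self.flank5,
            flank3=self.flank3,
        )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
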