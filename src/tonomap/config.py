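"""Run configuration: analysis windows, criteria and cohort settings.

The resolved configuration is echoed as JSON into every output directory so a
run can be reproduced from its artifacts alone.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

from .errors import ValidationError


@dataclass
class RunConfig:
    """All tunable analysis knobs.

    Defaults implement the mapping study's conventions: per-cell responses are
    counted 5-50 ms after tone onset against a 50-ms pre-stimulus baseline,
    per-cell significance is a Poisson upper tail at p < 0.01 with a >= 3-cell
    4-connected cluster requirement, onset latency is the first run of two
    consecutive PSTH bins exceeding baseline mean + 4 SD, receptive fields
    with irregularity index above 2 count as irregular, and the frequency
    bands are 1-4.3, 4.3-10, 10-50 and 50-70 kHz.
    """

    seed: int = 0
    # per-cell significance
    alpha: float = 0.01
    min_cluster_size: int = 3
    response_window_ms: tuple[float, float] = (5.0, 50.0)
    # latency
    latency_window_ms: tuple[float, float] = (5.0, 50.0)
    latency_sd_criterion: float = 4.0
    latency_min_consecutive_bins: int = 2
    # receptive-field summary
    irregularity_cutoff: float = 2.0
    apex_prominence_db: float = 10.0
    apex_min_separation_oct: float = 0.3
    flat_plateau_oct: float = 1.0
    # AI delineation
    ai_threshold_db: float = 50.0
    ai_min_qualifying_neighbors: int = 2
    vaf_intensity_db: float = 30.0
    # tonotopy
    axis_fit: str = "tls"  # "tls" (principal axis) or "ols" (y-on-x, axis swap)
    cf_norm_range_khz: tuple[float, float] = (1.0, 63.0)
    # cohort summaries
    band_edges_khz: tuple[float, ...] = (1.0, 4.3, 10.0, 50.0, 70.0)
    hi_threshold_db: float = 50.0
    per_animal_percentages: bool = True
    verbosity: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha: must be in (0, 1)")
        if self.min_cluster_size < 1:
            raise ValidationError("min_cluster_size: must be >= 1")
        for name in ("response_window_ms", "latency_window_ms"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name}: window start must precede end")
        if self.latency_min_consecutive_bins < 1:
            raise ValidationError("latency_min_consecutive_bins: must be >= 1")
        edges = tuple(float(e) for e in self.band_edges_khz)
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValidationError("band_edges_khz: must be strictly increasing")
        self.band_edges_khz = edges
        if self.axis_fit not in ("tls", "ols"):
            raise ValidationError("axis_fit: must be 'tls' or 'ols'")
        lo, hi = self.cf_norm_range_khz
        if not 0 < lo < hi:
            raise ValidationError("cf_norm_range_khz: must satisfy 0 < low < high")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        allowed = {f.name for f in fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("response_window_ms", "latency_window_ms",
                    "band_edges_khz", "cf_norm_range_khz"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
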