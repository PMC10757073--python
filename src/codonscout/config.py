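"""Run configuration: defaults, YAML file loading, flag overrides.

Defaults are the pipeline's operating constants: distance band 10-60 %,
2..16 selected homologs, 1000 bp windows with 300 bp overlap, E-value
cutoff 0.01, up to 10,000 hits per search round, display cutoff p < 0.05,
custom database capped at 300 sequences expanded to 5x query length.
Precedence: built-in defaults < config file < explicit flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .pairwise import ScoringModel
from .records import InputError
from .search import SearchConfig, SearchSchedule
from .selection import DistanceBand, SelectionLimits
from .windows import WindowingConfig


class ConfigError(ValueError):
    """A configuration key failed validation."""


# flat keys accepted in config files and as CLI overrides
_FLAT_KEYS = {
    "min_dist": float,
    "max_dist": float,
    "min_seqs": int,
    "max_seqs": int,
    "chunk_len": int,
    "overlap": int,
    "long_query_threshold": int,
    "evalue": float,
    "max_hits": int,
    "p_cutoff": float,
    "customdb_max_seqs": int,
    "customdb_expansion": int,
    "min_pair_dist": float,
    "seed": int,
}


@dataclass
class RunConfig:
    band: DistanceBand = field(default_factory=DistanceBand)
    limits: SelectionLimits = field(default_factory=SelectionLimits)
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    evalue_cutoff: float = 0.01
    max_hits: int = 10_000
    p_display_cutoff: float = 0.05
    customdb_max_seqs: int = 300
    customdb_expansion: int = 5
    min_pair_dist: Optional[float] = None  # default: band.min_dist
    schedule: SearchSchedule = field(default_factory=SearchSchedule)
    model: ScoringModel = field(default_factory=ScoringModel)
    backend: str = "mock"
    aligner: str = "stub"
    scorer: str = "stub"
    seed: int = 0
    outdir: Path = Path("codonscout_out")

    def __post_init__(self) -> None:
        if self.evalue_cutoff < 0:
            raise ConfigError("evalue: cutoff must be non-negative")
        if self.max_hits < 1:
            raise ConfigError("max_hits: must be at least 1")
        if not 0 < self.p_display_cutoff <= 1:
            raise ConfigError("p_cutoff: must be in (0, 1]")
        if self.customdb_max_seqs < 1:
            raise ConfigError("customdb_max_seqs: must be at least 1")
        if self.customdb_expansion < 1:
            raise ConfigError("customdb_expansion: must be at least 1")

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            evalue_cutoff=self.evalue_cutoff,
            max_hits=self.max_hits,
            band=self.band,
            limits=self.limits,
            min_pair_dist=(
                self.min_pair_dist
                if self.min_pair_dist is not None
                else self.band.min_dist
            ),
            schedule=self.schedule,
            model=self.model,
            customdb_max_seqs=self.customdb_max_seqs,
            customdb_expansion=self.customdb_expansion,
        )

    def effective(self) -> dict[str, Any]:
        """Flat view of the effective configuration for the run summary."""
        return {
            "min_dist": self.band.min_dist,
            "max_dist": self.band.max_dist,
            "min_seqs": self.limits.min_n,
            "max_seqs": self.limits.max_n,
            "chunk_len": self.windowing.chunk_len,
            "overlap": self.windowing.overlap,
            "long_query_threshold": self.windowing.long_query_threshold,
            "evalue": self.evalue_cutoff,
            "max_hits": self.max_hits,
            "p_cutoff": self.p_display_cutoff,
            "customdb_max_seqs": self.customdb_max_seqs,
            "customdb_expansion": self.customdb_expansion,
            "min_pair_dist": (
                self.min_pair_dist
                if self.min_pair_dist is not None
                else self.band.min_dist
            ),
            "backend": self.backend,
            "aligner": self.aligner,
            "scorer": self.scorer,
            "seed": self.seed,
        }


def _build(flat: dict[str, Any]) -> RunConfig:
    try:
        band = DistanceBand(
            min_dist=float(flat.get("min_dist", 10.0)),
            max_dist=float(flat.get("max_dist", 60.0)),
        )
        limits = SelectionLimits(
            min_n=int(flat.get("min_seqs", 2)), max_n=int(flat.get("max_seqs", 16))
        )
        windowing = WindowingConfig(
            chunk_len=int(flat.get("chunk_len", 1000)),
            overlap=int(flat.get("overlap", 300)),
            long_query_threshold=int(
                flat.get("long_query_threshold", flat.get("chunk_len", 1000))
            ),
        )
    except InputError as exc:
        raise ConfigError(str(exc)) from exc
    mpd = flat.get("min_pair_dist")
    return RunConfig(
        band=band,
        limits=limits,
        windowing=windowing,
        evalue_cutoff=float(flat.get("evalue", 0.01)),
        max_hits=int(flat.get("max_hits", 10_000)),
        p_display_cutoff=float(flat.get("p_cutoff", 0.05)),
        customdb_max_seqs=int(flat.get("customdb_max_seqs", 300)),
        customdb_expansion=int(flat.get("customdb_expansion", 5)),
        min_pair_dist=float(mpd) if mpd is not None else None,
        backend=str(flat.get("backend", "mock")),
        aligner=str(flat.get("aligner", "stub")),
        scorer=str(flat.get("scorer", "stub")),
        seed=int(flat.get("seed", 0)),
        outdir=Path(flat.get("outdir", "codonscout_out")),
    )


def load_config(
    path: str | Path | None = None, overrides: dict[str, Any] | None = None
) -> RunConfig:
    """Build a RunConfig from defaults <- YAML file <- overrides."""
    flat: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        for key, value in data.items():
            if key not in _FLAT_KEYS and key not in (
                "backend",
                "aligner",
                "scorer",
                "outdir",
            ):
                raise ConfigError(f"unknown config key {key!r}")
            flat[key] = value
    for key, value in (overrides or {}).items():
        if value is not None:
            flat[key] = value
    for key, caster in _FLAT_KEYS.items():
        if key in flat:
            try:
                flat[key] = caster(flat[key])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid value for {key!r}: {flat[key]!r}") from exc
    return _build(flat)
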