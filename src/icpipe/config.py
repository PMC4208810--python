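"""Pipeline configuration.

All statistical knobs of the pipeline live in one flat dataclass so that a
run is fully described by (input files, config, seed).  The on-disk format
is deliberately plain: ``key = value`` lines, ``#`` comments; every CLI flag
overrides the file, and the effective configuration is echoed to the log.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

__all__ = ["PipelineConfig"]

log = logging.getLogger("icpipe")


@dataclass
class PipelineConfig:
    """Thresholds and sizes for every pipeline stage.

    Attributes
    ----------
    driver_p_threshold
        Two-sided Mann-Whitney p-value cut-off for CNV-expression drivers.
    driver_rho_threshold
        Spearman rho cut-off (dose vs expression) for drivers; both filters
        must pass jointly.
    n_clusters
        Number of integrative clusters (k) cut from the consensus tree.
    consensus_n_resamples, consensus_subsample_fraction
        Resampling design of the consensus-clustering stage.
    sam_n_permutations
        Label permutations for SAM q-values (all distinct permutations are
        enumerated when fewer exist).
    signature_q_threshold
        SAM q cut-off for the subtype expression signature (0.02 = 2% FDR).
    pathway_q_threshold, pathway_fc_up, pathway_fc_down
        Cut-offs for subtype-specific pathway calls on ssGSEA scores.
    ssgsea_alpha
        Rank-weighting exponent of the single-sample enrichment score.
    sam_s0_percentiles
        Candidate percentiles of the per-feature scatter s at which the SAM
        fudge factor s0 is evaluated.
    min_group_size
        Minimum samples per group for any two-group rank test.
    """

    driver_p_threshold: float = 0.05
    driver_rho_threshold: float = 0.6
    n_clusters: int = 2
    consensus_n_resamples: int = 500
    consensus_subsample_fraction: float = 0.8
    sam_n_permutations: int = 1000
    signature_q_threshold: float = 0.02
    pathway_q_threshold: float = 0.2
    pathway_fc_up: float = 2.0
    pathway_fc_down: float = 0.5
    ssgsea_alpha: float = 0.25
    sam_s0_percentiles: tuple[int, ...] = tuple(range(0, 101, 5))
    rng_seed: int = 0
    min_group_size: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.driver_p_threshold <= 1:
            raise ValueError("driver_p_threshold must be in (0, 1]")
        if not -1 <= self.driver_rho_threshold < 1:
            raise ValueError("driver_rho_threshold must be in [-1, 1)")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if not 0 < self.consensus_subsample_fraction <= 1:
            raise ValueError("consensus_subsample_fraction must be in (0, 1]")
        if self.consensus_n_resamples < 1 or self.sam_n_permutations < 1:
            raise ValueError("resample/permutation counts must be positive")
        for name in ("signature_q_threshold", "pathway_q_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.pathway_fc_up <= 0 or self.pathway_fc_down <= 0:
            raise ValueError("fold-change thresholds must be positive")
        if self.ssgsea_alpha < 0:
            raise ValueError("ssgsea_alpha must be >= 0")
        if self.min_group_size < 2:
            raise ValueError("min_group_size must be >= 2")
        self.sam_s0_percentiles = tuple(int(p) for p in self.sam_s0_percentiles)

    # -- flat key=value persistence -------------------------------------
    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        """Load a flat ``key = value`` config file; ``overrides`` win."""
        values: dict[str, Any] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = _parse_value(key, raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k} = {_format_value(v)}" for k, v in self.as_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **changes: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **changes)

    def log_effective(self) -> None:
        for k, v in self.as_dict().items():
            log.info("config %s = %s", k, _format_value(v))


def _parse_value(key: str, raw: str) -> Any:
    if key == "sam_s0_percentiles":
        return tuple(int(tok) for tok in raw.replace(",", " ").split())
    if key in ("n_clusters", "consensus_n_resamples", "sam_n_permutations",
               "rng_seed", "min_group_size"):
        return int(raw)
    return float(raw)


def _format_value(v: Any) -> str:
    if isinstance(v, tuple):
        return ",".join(str(x) for x in v)
    return str(v)
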