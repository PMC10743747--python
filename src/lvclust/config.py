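"""Tunable parameters for cluster generation and selection, YAML-loadable."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["ClusterConfig", "SelectionConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class ClusterConfig:
    """Parameters of the per-slice cluster-generation stage.

    top_k: how many largest connected components to keep (3).
    connectivity: pixel adjacency, 4 or 8 (8: diagonal contact counts).
    merge_fraction: fragments below this fraction of the largest cluster are
        merged into their nearest neighbour (0.05).
    """

    top_k: int = 3
    connectivity: int = 8
    merge_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not (0 < self.merge_fraction < 1):
            raise ValueError("merge_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the cross-slice cluster-selection stage.

    overlap_threshold_percent: adjacent clusters overlapping less than this
        (percent of the smaller cluster) flag the sequence as suspect (20).
    max_passes: the selection runs at most two passes (fixed).
    """

    overlap_threshold_percent: float = 20.0
    max_passes: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_threshold_percent <= 100):
            raise ValueError("overlap_threshold_percent must lie in [0, 100]")
        if self.max_passes != 2:
            raise ValueError("max_passes is fixed at 2")


def load_config(path) -> tuple[ClusterConfig, SelectionConfig]:
    """Read a YAML/JSON file with optional `cluster:` and `selection:` blocks."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return (ClusterConfig(**data.get("cluster", {})),
            SelectionConfig(**data.get("selection", {})))


def save_config(path, cluster: ClusterConfig, selection: SelectionConfig) -> None:
    Path(path).write_text(yaml.safe_dump(
        {"cluster": asdict(cluster), "selection": asdict(selection)}, sort_keys=False))
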