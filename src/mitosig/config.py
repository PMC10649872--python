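"""Structured run configuration with lossless YAML round-trips."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Knobs shared by the CLI subcommands.

    ``auc_reference`` names the normalization policy: ``comparison_set_max``
    anchors normalized AUC at the least potent condition of the comparison
    set (the only policy currently implemented, kept explicit so configs
    are self-describing).
    """

    seed: int = 0
    alpha: float = 0.05
    lod: float = 24.0
    k_clusters: int = 3
    auc_reference: str = "comparison_set_max"
    paths: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
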