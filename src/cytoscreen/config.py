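"""Run configuration: one TOML file drives every pipeline stage.

Flags given on the command line override config values.  Artifacts carry a
provenance header (config hash + seed) so a run can be identified from its
outputs alone.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

from .discrimination import DEFAULT_FORCE_INCLUDE
from .lattice import DEFAULT_PANEL, Phenotype
from .partition import DEFAULT_POOLED_MARKERS

DEFAULT_AGREE_POPULATIONS = (
    "CD4+", "CD8+", "CD25+", "Foxp3+", "IFNg+", "IL10+", "IL17A+",
)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: Path = Path("cytoscreen_out")
    events_dir: Path | None = None  # default: <out>/events
    metadata_path: Path | None = None  # default: <out>/metadata.csv
    panel: tuple[str, ...] = DEFAULT_PANEL
    simulate: dict[str, Any] = field(default_factory=dict)
    pregate: dict[str, Any] = field(default_factory=dict)
    partition: dict[str, Any] = field(default_factory=dict)
    score: dict[str, Any] = field(default_factory=dict)
    hierarchy: dict[str, Any] = field(default_factory=dict)
    agree: dict[str, Any] = field(default_factory=dict)
    raw: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if self.events_dir is None:
            self.events_dir = self.out_dir / "events"
        if self.metadata_path is None:
            self.metadata_path = self.out_dir / "metadata.csv"
        self.validate()

    # -- derived settings with defaults -----------------------------------
    @property
    def pooled_markers(self) -> tuple[str, ...]:
        return tuple(self.partition.get("pooled_markers",
                                        DEFAULT_POOLED_MARKERS))

    @property
    def manual_thresholds(self) -> dict[str, float]:
        return dict(self.partition.get("manual", {}))

    @property
    def cutoff(self) -> float:
        return float(self.score.get("cutoff", 0.9))

    @property
    def force_include(self) -> tuple[str, ...]:
        return tuple(self.score.get("force_include", DEFAULT_FORCE_INCLUDE))

    @property
    def group_b(self) -> str | None:
        return self.score.get("group_b")

    @property
    def sample_filter(self) -> dict[str, Any]:
        return dict(self.score.get("sample_filter", {}))

    @property
    def n_paths(self) -> int:
        return int(self.hierarchy.get("n_paths", 1))

    @property
    def score_mode(self) -> str:
        return str(self.hierarchy.get("score_mode", "cumulative"))

    @property
    def agree_populations(self) -> tuple[str, ...]:
        return tuple(self.agree.get("populations", DEFAULT_AGREE_POPULATIONS))

    @property
    def agree_scale(self) -> str:
        return str(self.agree.get("scale", "raw"))

    @property
    def m_tests(self) -> int:
        return int(self.agree.get("m_tests", 24))

    # -- validation / provenance ------------------------------------------
    def validate(self) -> None:
        """Fail fast on references to markers outside the panel."""
        for code in (*self.force_include, *self.agree_populations):
            try:
                Phenotype.from_code(code, self.panel)
            except ValueError as exc:
                raise ValueError(
                    f"config references phenotype {code!r} not expressible "
                    f"over panel {self.panel}"
                ) from exc
        for marker in (*self.pooled_markers, *self.manual_thresholds):
            if marker not in self.panel:
                raise ValueError(
                    f"config references marker {marker!r} not in panel"
                )

    def config_hash(self) -> str:
        payload = dict(self.raw)
        payload["seed"] = self.seed
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def provenance(self) -> str:
        return f"cytoscreen config={self.config_hash()} seed={self.seed}"


def load_config(path: str | Path | None, seed: int | None = None,
                out: str | Path | None = None) -> RunConfig:
    data: dict[str, Any] = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    paths = data.get("paths", {})
    cfg = RunConfig(
        seed=int(seed if seed is not None else data.get("seed", 0)),
        out_dir=Path(out if out is not None else paths.get("out", "cytoscreen_out")),
        events_dir=Path(paths["events"]) if "events" in paths else None,
        metadata_path=Path(paths["metadata"]) if "metadata" in paths else None,
        panel=tuple(data.get("panel", {}).get("markers", DEFAULT_PANEL)),
        simulate=dict(data.get("simulate", {})),
        pregate=dict(data.get("pregate", {})),
        partition=dict(data.get("partition", {})),
        score=dict(data.get("score", {})),
        hierarchy=dict(data.get("hierarchy", {})),
        agree=dict(data.get("agree", {})),
        raw=data,
    )
    return cfg
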