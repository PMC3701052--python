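"""Pre-gating: reduce each sample to live, singlet, CD3+ T cells.

Gates are applied in a fixed, documented order — debris (scatter-area box),
doublets (scatter area/height ratio), live (amine-reactive viability dye:
dead cells stain bright, so live = below threshold), CD3+ — and per-gate
retention counts are reported for QC.  A sample-level QC rule mirrors an
acquisition stopping gate: samples with fewer than ``min_live_cd4`` live
CD4+ T cells fail QC and should be excluded from analysis.

Boundary conventions: the live gate is strict (value < threshold); interval
and positivity gates are closed at the lower edge and open at the upper
(scatter box: min <= value < max; doublet ratio: ratio < max; CD3/CD4:
value >= threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .events import (
    EventMatrix,
    MARKER,
    SCATTER_AREA,
    SCATTER_HEIGHT,
    VIABILITY,
)

GATE_ORDER = ("debris", "doublet", "live", "cd3")


@dataclass(frozen=True)
class PregateConfig:
    viability_threshold: float
    cd3_threshold: float
    scatter_min: float = -np.inf
    scatter_max: float = np.inf
    max_doublet_ratio: float = np.inf
    cd4_threshold: float | None = None
    min_live_cd4: int = 40_000

    def __post_init__(self):
        if not np.isfinite(self.viability_threshold):
            raise ValueError("viability_threshold must be finite")
        if not np.isfinite(self.cd3_threshold):
            raise ValueError("cd3_threshold must be finite")
        if self.min_live_cd4 < 0:
            raise ValueError("min_live_cd4 must be >= 0")


def _require_channel(events: EventMatrix, role: str) -> np.ndarray:
    try:
        ch = events.single_channel(role)
    except KeyError as exc:
        raise KeyError(
            f"pregating sample {events.sample_id!r}: missing {role} channel"
        ) from exc
    return events.get(ch.name)


def pregate(
    events: EventMatrix, cfg: PregateConfig
) -> tuple[EventMatrix, dict[str, int]]:
    """Apply the four pre-gates; return the subset and retention counts.

    Retention counts are reported in application order (events surviving
    each gate cumulatively), keyed ``input``, ``debris``, ``doublet``,
    ``live``, ``cd3``.  The output is a pure row subset of the input.
    """
    if events.transform != "arcsinh":
        raise ValueError(
            f"sample {events.sample_id!r}: pregate expects arcsinh-transformed data"
        )
    fsc_a = _require_channel(events, SCATTER_AREA)
    viability = _require_channel(events, VIABILITY)
    try:
        cd3 = events.marker_values("CD3")
    except KeyError as exc:
        raise KeyError(
            f"pregating sample {events.sample_id!r}: missing CD3 channel"
        ) from exc

    mask = np.ones(events.n_events, dtype=bool)
    retention: dict[str, int] = {"input": events.n_events}

    # debris: scatter-area box, closed lower / open upper
    mask &= (fsc_a >= cfg.scatter_min) & (fsc_a < cfg.scatter_max)
    retention["debris"] = int(mask.sum())

    # doublets: area/height ratio below the cutoff (open upper)
    if np.isfinite(cfg.max_doublet_ratio):
        fsc_h = _require_channel(events, SCATTER_HEIGHT)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(fsc_h > 0, fsc_a / np.maximum(fsc_h, 1e-300), np.inf)
        mask &= ratio < cfg.max_doublet_ratio
    retention["doublet"] = int(mask.sum())

    # live: viability dye strictly below threshold (dead cells stain bright)
    mask &= viability < cfg.viability_threshold
    retention["live"] = int(mask.sum())

    # CD3+: closed lower
    mask &= cd3 >= cfg.cd3_threshold
    retention["cd3"] = int(mask.sum())

    return events.subset(mask), retention


def qc_pass(pregated: EventMatrix, cfg: PregateConfig) -> bool:
    """True iff the live CD4+ event count reaches ``min_live_cd4``.

    Expects the output of :func:`pregate` (already live/singlet/CD3+), so
    only CD4 positivity is evaluated here.
    """
    if cfg.min_live_cd4 == 0:
        return True
    if cfg.cd4_threshold is None:
        raise ValueError("qc_pass requires cd4_threshold in the PregateConfig")
    cd4 = pregated.marker_values("CD4")
    return int((cd4 >= cfg.cd4_threshold).sum()) >= cfg.min_live_cd4


def qc_report(
    retention_by_sample: Mapping[str, Mapping[str, int]],
    qc_by_sample: Mapping[str, bool],
) -> pd.DataFrame:
    """Per-sample QC table: counts per gate plus the pass flag."""
    rows = []
    for sample_id, retention in retention_by_sample.items():
        row = {"sample_id": sample_id}
        row.update({k: retention.get(k, 0) for k in ("input", *GATE_ORDER)})
        row["qc_pass"] = bool(qc_by_sample[sample_id])
        rows.append(row)
    return pd.DataFrame(rows)
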