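"""High-level orchestration of the screening stages.

``run_screen`` takes event matrices plus their metadata and runs the full
chain: pre-gating and QC, marker partitioning, lattice counting,
replicate-averaged frequencies, and the ROC/AUC screen.  It is the single
path used by the command-line interface, the examples, and the acceptance
computations, so every consumer exercises the same code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .discrimination import (
    DEFAULT_FORCE_INCLUDE,
    mark_selected,
    score_all,
    select_candidates,
)
from .events import EventMatrix, check_group_labels
from .lattice import PhenotypeFrequencyTable, build_frequency_table
from .partition import (
    DEFAULT_POOLED_MARKERS,
    MarkerPartition,
    call_positivity,
    fit_partitions,
)
from .pregating import PregateConfig, pregate, qc_pass, qc_report


@dataclass
class ScreenResult:
    """Everything the screening chain produces for one cohort."""

    panel: tuple[str, ...]
    qc: pd.DataFrame  # per-sample gate retention + qc_pass
    partitions: dict[str, list[MarkerPartition]]
    table: PhenotypeFrequencyTable  # per physical sample
    averaged: pd.DataFrame  # phenotype x donor/group mean frequencies
    averaged_labels: dict[str, str]  # averaged column -> group level
    scores: pd.DataFrame  # per-phenotype AUC etc., selection flagged
    selected: list[str]
    group_levels: tuple[str, str]


def run_screen(
    samples: Sequence[EventMatrix],
    metadata: pd.DataFrame,
    pregate_cfg: PregateConfig,
    panel: Sequence[str],
    pooled_markers: Sequence[str] = DEFAULT_POOLED_MARKERS,
    manual_thresholds: Mapping[str, float] | None = None,
    cutoff: float = 0.9,
    force_include: Sequence[str] = DEFAULT_FORCE_INCLUDE,
    group_b: str | None = None,
    average_replicates: bool = True,
    sample_filter: Mapping[str, object] | None = None,
) -> ScreenResult:
    """Run pre-gating, partitioning, counting and the AUC screen.

    ``sample_filter`` restricts the analysis set by metadata columns, e.g.
    ``{"stimulation": "stimulated"}``.  Samples failing the stopping-gate QC
    are excluded before partition fitting and scoring.
    """
    panel = tuple(panel)
    meta = metadata.copy()
    if sample_filter:
        for col, val in sample_filter.items():
            meta = meta[meta[col] == val]
    keep_ids = set(meta["sample_id"])
    selected_samples = [s for s in samples if s.sample_id in keep_ids]
    if not selected_samples:
        raise ValueError("no samples left after metadata filtering")
    group_levels = check_group_labels(meta)
    if group_b is None:
        group_b = group_levels[1]

    # 1. pre-gate + QC
    pregated: dict[str, EventMatrix] = {}
    retention: dict[str, dict[str, int]] = {}
    qc_flags: dict[str, bool] = {}
    for em in selected_samples:
        sub, counts = pregate(em, pregate_cfg)
        pregated[em.sample_id] = sub
        retention[em.sample_id] = counts
        qc_flags[em.sample_id] = (
            qc_pass(sub, pregate_cfg) if pregate_cfg.min_live_cd4 > 0 else True
        )
    qc = qc_report(retention, qc_flags)
    passing = [pregated[s] for s in pregated if qc_flags[s]]
    if not passing:
        raise ValueError("every sample failed the stopping-gate QC")

    # 2. marker partitions on QC-passing, pre-gated samples
    partitions = fit_partitions(
        passing, panel, pooled_markers=pooled_markers, manual=manual_thresholds
    )

    # 3. positivity calls + lattice counting
    positivity = {
        em.sample_id: call_positivity(em, partitions[em.sample_id])
        for em in passing
    }
    denominators = {em.sample_id: em.n_events for em in passing}
    table = build_frequency_table(positivity, denominators, panel)

    # 4. replicate averaging then scoring
    meta_pass = meta[meta["sample_id"].isin(table.sample_ids)]
    if average_replicates:
        averaged = table.average_replicates(meta_pass, by=("donor", "group"))
        pair_groups = (
            meta_pass[["donor", "group"]].drop_duplicates()
        )
        averaged_labels = {
            f"{d}/{g}": g for d, g in pair_groups.itertuples(index=False)
        }
    else:
        averaged = table.frequencies
        averaged_labels = dict(
            zip(meta_pass["sample_id"], meta_pass["group"])
        )

    scores = score_all(averaged, averaged_labels, group_b=group_b)
    selected = select_candidates(scores, cutoff=cutoff,
                                 force_include=force_include)
    scores = mark_selected(scores, selected)

    return ScreenResult(
        panel=panel, qc=qc, partitions=partitions, table=table,
        averaged=averaged, averaged_labels=averaged_labels, scores=scores,
        selected=selected, group_levels=group_levels,
    )
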