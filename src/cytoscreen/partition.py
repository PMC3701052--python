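"""Per-marker positivity thresholds.

Each marker gets a single threshold on the transformed intensity scale,
derived either per sample (two-centre 1-D partition of that sample's
intensities) or from a pooled static gate (all samples concatenated, for
rare populations that are invisible sample by sample), or supplied manually.
An event is called positive when its intensity is strictly above the
threshold.

The two-centre partition is 1-D k-means (k=2) solved exactly: optimal 1-D
clusters are contiguous in sorted order, so scanning every split point of
the sorted values (with prefix sums) finds the global minimum of the
within-cluster sum of squares deterministically — no seeding or restarts
needed.  The threshold is the midpoint of the two centres.  This is a
deliberate simplification of
multivariate clustering tools used for the same task: the phenotype lattice
is defined marker-wise, so one axis at a time is what the downstream
analysis consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .events import EventMatrix

CLUSTER = "cluster"
POOLED_STATIC = "pooled-static"
MANUAL = "manual"

#: markers whose positive populations are typically too small for per-sample
#: clustering; pooled static gating is the default for these
DEFAULT_POOLED_MARKERS = ("IL10", "IL17A", "Foxp3")

#: separation (Ashman's D) below which a fit is flagged low-confidence
BIMODALITY_FLOOR = 2.0
#: minority-cluster weight below which a fit is flagged low-confidence
MIN_CLUSTER_WEIGHT = 0.005


@dataclass(frozen=True)
class MarkerPartition:
    """A positivity threshold for one marker, with its provenance."""

    marker: str
    method: str  # cluster | pooled-static | manual
    threshold: float
    provenance: str  # sample_id, "pooled", or "config"
    low_confidence: bool = False

    def __post_init__(self):
        if not np.isfinite(self.threshold):
            raise ValueError(f"non-finite threshold for {self.marker!r}")
        if self.method not in (CLUSTER, POOLED_STATIC, MANUAL):
            raise ValueError(f"unknown partition method {self.method!r}")


@dataclass(frozen=True)
class ClusterFit:
    """Result of the two-centre 1-D partition."""

    threshold: float
    centers: tuple[float, float]  # (low, high)
    bimodality: float  # Ashman's D; inf when both clusters are degenerate
    minority_weight: float
    low_confidence: bool

    def __float__(self) -> float:
        return self.threshold


def fit_cluster_threshold(values: Sequence[float]) -> ClusterFit:
    """Two-centre partition of 1-D intensities; threshold = centre midpoint.

    Raises ``ValueError`` for degenerate input (fewer than two distinct
    values).  Poorly separated fits are returned but flagged (and a warning
    emitted): low Ashman's D, or a minority cluster too small to trust.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("degenerate marker: fewer than two distinct values")

    lo, hi = _exact_two_means(x)
    assign_hi = x > (lo + hi) / 2.0
    w_hi = assign_hi.mean()
    minority = min(w_hi, 1.0 - w_hi)
    s_lo = x[~assign_hi].std() if (~assign_hi).any() else 0.0
    s_hi = x[assign_hi].std() if assign_hi.any() else 0.0
    # Ashman's D = |mu1 - mu2| / sqrt((s1^2 + s2^2)/2)  (two-Gaussian overlap)
    denom = np.sqrt((s_lo ** 2 + s_hi ** 2) / 2.0)
    bimodality = np.inf if denom == 0 else float((hi - lo) / denom)
    low_conf = bimodality < BIMODALITY_FLOOR or minority < MIN_CLUSTER_WEIGHT
    if low_conf:
        warnings.warn(
            f"weakly bimodal marker distribution (D={bimodality:.2f}, "
            f"minority weight={minority:.4f}); threshold retained but "
            "low-confidence",
            stacklevel=2,
        )
    return ClusterFit(
        threshold=float((lo + hi) / 2.0),
        centers=(float(lo), float(hi)),
        bimodality=bimodality,
        minority_weight=float(minority),
        low_confidence=bool(low_conf),
    )


def _exact_two_means(x: np.ndarray) -> tuple[float, float]:
    """Globally optimal 1-D 2-means centres via the sorted split scan.

    Optimal clusters are contiguous in sorted order; with prefix sums every
    split is evaluated in O(1), giving the exact optimum in O(n log n).
    Ties between splits break toward the smaller low-cluster, making the
    result fully deterministic.
    """
    xs = np.sort(x)
    n = xs.size
    csum = np.cumsum(xs)
    csq = np.cumsum(xs ** 2)
    i = np.arange(1, n)  # low cluster = xs[:i]
    sum_lo, sum_hi = csum[i - 1], csum[-1] - csum[i - 1]
    sq_lo, sq_hi = csq[i - 1], csq[-1] - csq[i - 1]
    inertia = (sq_lo - sum_lo ** 2 / i) + (sq_hi - sum_hi ** 2 / (n - i))
    best = int(np.argmin(inertia)) + 1
    return float(csum[best - 1] / best), \
        float((csum[-1] - csum[best - 1]) / (n - best))


def fit_pooled_threshold(
    samples: Iterable[EventMatrix], marker: str
) -> ClusterFit:
    """Static gate: two-centre partition of the marker pooled over samples.

    Equivalent to :func:`fit_cluster_threshold` on the concatenation of the
    marker's intensities across all samples, hence invariant to sample
    order.
    """
    chunks = [em.marker_values(marker) for em in samples]
    if not chunks:
        raise ValueError("no samples provided for pooled threshold")
    pooled = np.concatenate(chunks)
    if pooled.size == 0:
        raise ValueError(f"no events available to pool for marker {marker!r}")
    return fit_cluster_threshold(pooled)


def fit_partitions(
    samples: Sequence[EventMatrix],
    panel: Sequence[str],
    pooled_markers: Sequence[str] = DEFAULT_POOLED_MARKERS,
    manual: Mapping[str, float] | None = None,
    rare_fraction: float = 0.01,
) -> dict[str, list[MarkerPartition]]:
    """Derive one partition per marker per sample.

    Markers listed in ``pooled_markers`` — plus any marker whose per-sample
    positive fraction under its own cluster fit falls below
    ``rare_fraction`` in a majority of samples — share a pooled static gate;
    the rest are clustered per sample.  ``manual`` overrides both with
    config-supplied thresholds.  Returns sample_id -> partition list in
    panel order.
    """
    manual = dict(manual or {})
    panel = list(panel)
    pooled_set = {m for m in pooled_markers if m in panel}

    per_sample_fits: dict[str, dict[str, ClusterFit]] = {}
    for marker in panel:
        if marker in manual or marker in pooled_set:
            continue
        rare_votes = 0
        fits = {}
        for em in samples:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_cluster_threshold(em.marker_values(marker))
            fits[em.sample_id] = fit
            pos_frac = np.mean(em.marker_values(marker) > fit.threshold)
            if pos_frac < rare_fraction:
                rare_votes += 1
        if rare_votes > len(samples) / 2:
            pooled_set.add(marker)
        else:
            per_sample_fits[marker] = fits

    pooled_fits = {
        m: fit_pooled_threshold(samples, m) for m in sorted(pooled_set)
    }

    out: dict[str, list[MarkerPartition]] = {}
    for em in samples:
        parts = []
        for marker in panel:
            if marker in manual:
                parts.append(MarkerPartition(marker, MANUAL,
                                             float(manual[marker]), "config"))
            elif marker in pooled_fits:
                fit = pooled_fits[marker]
                parts.append(MarkerPartition(marker, POOLED_STATIC,
                                             fit.threshold, "pooled",
                                             fit.low_confidence))
            else:
                fit = per_sample_fits[marker][em.sample_id]
                parts.append(MarkerPartition(marker, CLUSTER, fit.threshold,
                                             em.sample_id,
                                             fit.low_confidence))
        out[em.sample_id] = parts
    return out


def call_positivity(
    events: EventMatrix, partitions: Sequence[MarkerPartition]
) -> np.ndarray:
    """Boolean events x markers matrix: intensity strictly above threshold.

    Columns follow the order of ``partitions``; every partition's marker
    must exist in the event matrix.
    """
    cols = []
    for part in partitions:
        values = events.marker_values(part.marker)
        cols.append(values > part.threshold)
    if not cols:
        return np.empty((events.n_events, 0), dtype=bool)
    return np.column_stack(cols)


def partitions_to_rows(
    partitions: Mapping[str, Sequence[MarkerPartition]]
) -> "list[dict]":
    """Flatten a sample -> partitions mapping for CSV export."""
    rows = []
    for sample_id in partitions:
        for p in partitions[sample_id]:
            rows.append(
                {
                    "sample_id": sample_id,
                    "marker": p.marker,
                    "method": p.method,
                    "threshold": p.threshold,
                    "provenance": p.provenance,
                    "low_confidence": p.low_confidence,
                }
            )
    return rows
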