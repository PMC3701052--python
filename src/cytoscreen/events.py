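"""Event-level data containers and intensity transforms.

An :class:`EventMatrix` is the per-sample unit of data: a dense matrix of
events (rows) by channels (columns), where each channel carries a role
(scatter, viability, or antibody marker).  Fluorescence values are analysed
on an inverse-hyperbolic-sine (arcsinh) scale, the conventional
variance-stabilising transform for cytometry; the transform state is recorded
on the matrix so it is applied exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# channel roles
SCATTER_AREA = "scatter-area"
SCATTER_HEIGHT = "scatter-height"
VIABILITY = "viability"
MARKER = "marker"
ROLES = (SCATTER_AREA, SCATTER_HEIGHT, VIABILITY, MARKER)

#: default arcsinh cofactor for organic-dye fluorescence channels
DEFAULT_COFACTOR = 150.0


@dataclass(frozen=True)
class Channel:
    """A named measurement channel.

    ``marker`` is the biological marker name when ``role == "marker"``
    (e.g. ``"CD4"``); for scatter/viability channels it is ``None``.
    ``mapped`` is False for channels retained from a file but not matched by
    the user's channel map.
    """

    name: str
    role: str = MARKER
    marker: str | None = None
    mapped: bool = True

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")


@dataclass
class EventMatrix:
    """Events x channels matrix for one physical sample."""

    sample_id: str
    channels: list[Channel]
    values: np.ndarray  # shape (n_events, n_channels), float
    transform: str = "none"  # "none" or "arcsinh"
    cofactors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D events x channels matrix")
        if self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.values.shape[1]} value columns but "
                f"{len(self.channels)} channel descriptors"
            )
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("event values must be finite")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel_index(self, name: str) -> int:
        for i, c in enumerate(self.channels):
            if c.name == name:
                return i
        raise KeyError(f"sample {self.sample_id!r} has no channel {name!r}")

    def marker_index(self, marker: str) -> int:
        """Column index of the channel measuring ``marker``."""
        for i, c in enumerate(self.channels):
            if c.role == MARKER and c.marker == marker:
                return i
        raise KeyError(f"sample {self.sample_id!r} has no marker {marker!r}")

    def get(self, name: str) -> np.ndarray:
        """1-D values of a channel by channel name."""
        return self.values[:, self.channel_index(name)]

    def marker_values(self, marker: str) -> np.ndarray:
        """1-D values of the channel mapped to a marker name."""
        return self.values[:, self.marker_index(marker)]

    def role_channels(self, role: str) -> list[Channel]:
        return [c for c in self.channels if c.role == role]

    def single_channel(self, role: str) -> Channel:
        found = self.role_channels(role)
        if len(found) != 1:
            raise KeyError(
                f"sample {self.sample_id!r}: expected exactly one {role} "
                f"channel, found {len(found)}"
            )
        return found[0]

    # -- construction helpers ---------------------------------------------
    def subset(self, rows: np.ndarray) -> "EventMatrix":
        """Row subset (boolean mask or index array); channels unchanged."""
        return replace(self, values=self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channel_names)


def transform(
    events: EventMatrix,
    cofactor: float | dict[str, float] = DEFAULT_COFACTOR,
) -> EventMatrix:
    """arcsinh-transform fluorescence channels: x -> asinh(x / cofactor).

    Applies to marker and viability channels; scatter channels are left on
    the linear scale.  ``cofactor`` may be a single positive number or a
    mapping from channel name to cofactor.  Transforming an
    already-transformed matrix is an error (the transform state is recorded
    precisely so it cannot be applied twice).
    """
    if events.transform != "none":
        raise ValueError(
            f"sample {events.sample_id!r} is already {events.transform}-transformed"
        )
    values = events.values.copy()
    cofactors: dict[str, float] = {}
    for j, ch in enumerate(events.channels):
        if ch.role not in (MARKER, VIABILITY):
            continue
        cf = cofactor[ch.name] if isinstance(cofactor, dict) else float(cofactor)
        if not cf > 0:
            raise ValueError(f"cofactor for {ch.name!r} must be positive")
        values[:, j] = np.arcsinh(values[:, j] / cf)
        cofactors[ch.name] = cf
    return replace(events, values=values, transform="arcsinh", cofactors=cofactors)


def inverse_transform(events: EventMatrix) -> EventMatrix:
    """Undo an arcsinh transform: x -> sinh(x) * cofactor."""
    if events.transform != "arcsinh":
        raise ValueError("matrix is not arcsinh-transformed")
    values = events.values.copy()
    for j, ch in enumerate(events.channels):
        if ch.name in events.cofactors:
            values[:, j] = np.sinh(values[:, j]) * events.cofactors[ch.name]
    return replace(events, values=values, transform="none", cofactors={})


@dataclass(frozen=True)
class SampleMetadata:
    """One metadata row per physical sample."""

    sample_id: str
    donor: str
    group: str
    stimulation: str = "stimulated"
    replicate: int = 1
    timepoint: int = 1
    control: bool = False


METADATA_COLUMNS = [
    "sample_id",
    "donor",
    "group",
    "stimulation",
    "replicate",
    "timepoint",
    "control",
]


def metadata_frame(rows: Iterable[SampleMetadata]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in rows], columns=METADATA_COLUMNS)
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in metadata")
    return df


def check_group_labels(metadata: pd.DataFrame) -> tuple[str, str]:
    """Validate the two-level group factor; returns the sorted level pair."""
    levels = sorted(metadata["group"].unique())
    if len(levels) != 2:
        raise ValueError(
            f"group label must have exactly two levels, found {levels}"
        )
    return levels[0], levels[1]
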