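"""The 3-state immunophenotype lattice.

Every phenotype assigns each panel marker one of three states: positive
(``+``), negative (``-``), or neutral (unconstrained).  A panel of *k*
markers therefore spans 3^k phenotypes; excluding the root (all-neutral)
leaves 3^k - 1, e.g. 6560 for the 8-marker T-cell panel used throughout this
package.  Restricting to fully specified +/- combinations gives the familiar
2^k count (1024 for a ten-colour panel).

Counting all phenotypes naively would scan the event matrix 3^k times.
Instead the fully-specified 2^k contingency table is tallied once per sample
and the neutral states are obtained by summing sibling pairs marker by
marker — each neutral count reuses its children, the lattice analogue of
recursive bisection.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NEUTRAL, NEG, POS = 0, 1, 2
_STATE_SIGN = {NEG: "-", POS: "+"}

#: the 8 lattice markers of the default T-cell panel (CD3 is consumed by
#: pre-gating and frequencies are expressed per live T cell, so it is not a
#: lattice dimension)
DEFAULT_PANEL = (
    "CD4", "CD8", "CD45RO", "CD25", "Foxp3", "IFNg", "IL10", "IL17A",
)

ROOT_CODE = "*"


@dataclass(frozen=True)
class Phenotype:
    """An assignment of each panel marker to POS, NEG, or NEUTRAL."""

    panel: tuple[str, ...]
    states: tuple[int, ...]

    def __post_init__(self):
        if len(self.panel) != len(self.states):
            raise ValueError("states length must match panel length")
        if len(set(self.panel)) != len(self.panel):
            raise ValueError("duplicate marker names in panel")
        if any(s not in (NEUTRAL, NEG, POS) for s in self.states):
            raise ValueError("states must be NEUTRAL, NEG or POS")

    @property
    def code(self) -> str:
        """Canonical string code: markers in panel order, neutrals omitted."""
        parts = [
            m + _STATE_SIGN[s]
            for m, s in zip(self.panel, self.states)
            if s != NEUTRAL
        ]
        return "".join(parts) if parts else ROOT_CODE

    @property
    def is_root(self) -> bool:
        return all(s == NEUTRAL for s in self.states)

    @property
    def n_specified(self) -> int:
        return sum(s != NEUTRAL for s in self.states)

    def specified(self) -> dict[str, int]:
        """marker -> state for the non-neutral markers."""
        return {
            m: s for m, s in zip(self.panel, self.states) if s != NEUTRAL
        }

    def with_state(self, marker: str, state: int) -> "Phenotype":
        idx = self.panel.index(marker)
        states = list(self.states)
        states[idx] = state
        return Phenotype(self.panel, tuple(states))

    @classmethod
    def root(cls, panel: Sequence[str]) -> "Phenotype":
        panel = tuple(panel)
        return cls(panel, (NEUTRAL,) * len(panel))

    @classmethod
    def from_code(cls, code: str, panel: Sequence[str]) -> "Phenotype":
        """Parse a canonical code; markers must appear in panel order."""
        panel = tuple(panel)
        states = [NEUTRAL] * len(panel)
        if code == ROOT_CODE:
            return cls(panel, tuple(states))
        pos = 0
        for i, marker in enumerate(panel):
            token_len = len(marker) + 1
            if code.startswith(marker, pos) and pos + token_len <= len(code):
                sign = code[pos + len(marker)]
                if sign in "+-":
                    states[i] = POS if sign == "+" else NEG
                    pos += token_len
        if pos != len(code):
            raise ValueError(
                f"cannot parse phenotype code {code!r} against panel {panel}"
            )
        return cls(panel, tuple(states))

    def __str__(self) -> str:
        return self.code


def enumerate_phenotypes(
    panel: Sequence[str], include_root: bool = False
) -> list[Phenotype]:
    """All 3^k phenotypes of a panel in deterministic lattice order.

    Order: markers in panel order, states ordered NEUTRAL < NEG < POS, first
    marker varying slowest.  The root (all-neutral) comes first when
    included.
    """
    panel = tuple(panel)
    if len(panel) < 1:
        raise ValueError("panel must contain at least one marker")
    if len(set(panel)) != len(panel):
        raise ValueError("duplicate marker names in panel")
    out = [
        Phenotype(panel, states)
        for states in itertools.product((NEUTRAL, NEG, POS), repeat=len(panel))
    ]
    return out if include_root else out[1:]


def count_fully_specified(k: int, states_per_marker: int = 2) -> int:
    """Number of fully specified phenotypes for a k-marker panel."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return states_per_marker ** k


def count_phenotype(phenotype: Phenotype, positivity: np.ndarray) -> int:
    """Events satisfying every non-neutral constraint of one phenotype.

    ``positivity`` is a boolean events x markers matrix in panel order.
    """
    positivity = np.asarray(positivity, dtype=bool)
    if positivity.ndim != 2 or positivity.shape[1] != len(phenotype.panel):
        raise ValueError("positivity matrix does not match the panel")
    mask = np.ones(positivity.shape[0], dtype=bool)
    for j, state in enumerate(phenotype.states):
        if state == POS:
            mask &= positivity[:, j]
        elif state == NEG:
            mask &= ~positivity[:, j]
    return int(mask.sum())


def count_all_phenotypes(positivity: np.ndarray, k: int | None = None) -> np.ndarray:
    """Counts for the full 3-state lattice as an array of shape (3,)*k.

    Index order per axis is (NEUTRAL, NEG, POS); axis *i* is panel marker
    *i*.  ``counts[phenotype.states]`` gives the event count of a phenotype.
    """
    positivity = np.asarray(positivity, dtype=bool)
    if k is None:
        k = positivity.shape[1]
    if positivity.shape[1] != k:
        raise ValueError("positivity matrix width does not match panel size")
    if k > 12:
        raise ValueError("lattice counting supports at most 12 markers")
    # base-2 event codes, marker 0 most significant
    weights = 1 << np.arange(k - 1, -1, -1)
    codes = positivity.astype(np.int64) @ weights
    table = np.bincount(codes, minlength=2 ** k).reshape((2,) * k)
    # axis by axis, prepend the neutral plane = NEG plane + POS plane
    for ax in range(k):
        both = table.sum(axis=ax, keepdims=True)
        table = np.concatenate([both, table], axis=ax)
    return table


@dataclass
class PhenotypeFrequencyTable:
    """Phenotype x sample count and frequency tables.

    ``counts``/``frequencies`` are DataFrames indexed by phenotype code with
    one column per sample; ``denominators`` holds each sample's live T-cell
    count.  frequency = count / denominator exactly.
    """

    panel: tuple[str, ...]
    counts: pd.DataFrame
    denominators: pd.Series

    @property
    def frequencies(self) -> pd.DataFrame:
        return self.counts / self.denominators

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def phenotype_codes(self) -> list[str]:
        return list(self.counts.index)

    def phenotype(self, code: str) -> Phenotype:
        return Phenotype.from_code(code, self.panel)

    def average_replicates(self, metadata: pd.DataFrame,
                           by: Sequence[str] = ("donor", "group")) -> pd.DataFrame:
        """Frequencies averaged over experimental replicates.

        Returns phenotypes x (by-key) frequency means; column labels are
        '/'-joined key tuples.
        """
        meta = metadata.set_index("sample_id").loc[self.sample_ids]
        freq = self.frequencies
        groups = meta.groupby(list(by), sort=True).groups
        cols = {}
        for key, sample_ids in groups.items():
            label = "/".join(str(x) for x in (key if isinstance(key, tuple) else (key,)))
            cols[label] = freq[list(sample_ids)].mean(axis=1)
        return pd.DataFrame(cols)

    # -- serialisation -----------------------------------------------------
    def to_wide_csv(self, path, provenance: str | None = None) -> None:
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"#{provenance}\n")
            fh.write(f"#panel,{','.join(self.panel)}\n")
            fh.write(
                "#denominators," +
                ",".join(str(int(d)) for d in self.denominators) + "\n"
            )
            self.counts.rename_axis("phenotype").to_csv(fh)

    @classmethod
    def from_wide_csv(cls, path) -> "PhenotypeFrequencyTable":
        panel: tuple[str, ...] = ()
        denoms: list[int] = []
        with open(path) as fh:
            rows = []
            for line in fh:
                if line.startswith("#panel,"):
                    panel = tuple(line.rstrip("\n").split(",")[1:])
                elif line.startswith("#denominators,"):
                    denoms = [int(x) for x in line.rstrip("\n").split(",")[1:]]
                elif not line.startswith("#"):
                    rows.append(line)
        counts = pd.read_csv(
            _io_stringio("".join(rows)), index_col="phenotype"
        ).rename_axis(None)
        denominators = pd.Series(denoms, index=counts.columns)
        return cls(panel=panel, counts=counts, denominators=denominators)


def _io_stringio(text: str):
    import io

    return io.StringIO(text)


def build_frequency_table(
    positivity: Mapping[str, np.ndarray],
    denominators: Mapping[str, int],
    panel: Sequence[str],
    phenotypes: Sequence[Phenotype] | None = None,
) -> PhenotypeFrequencyTable:
    """Tally the whole lattice for every sample.

    ``positivity`` maps sample_id -> boolean events x markers matrix (panel
    order); ``denominators`` maps sample_id -> live T-cell count.  Samples
    with a zero denominator are dropped with a warning.  ``phenotypes``
    restricts the rows (default: the full lattice including the root).
    """
    panel = tuple(panel)
    if phenotypes is None:
        phenotypes = enumerate_phenotypes(panel, include_root=True)
    codes = [p.code for p in phenotypes]
    state_idx = tuple(
        np.array([p.states[j] for p in phenotypes]) for j in range(len(panel))
    )
    columns = {}
    denoms = {}
    for sample_id, mat in positivity.items():
        denom = int(denominators[sample_id])
        if denom <= 0:
            warnings.warn(
                f"sample {sample_id!r} has zero denominator; excluded",
                stacklevel=2,
            )
            continue
        lattice = count_all_phenotypes(np.asarray(mat, dtype=bool), len(panel))
        columns[sample_id] = lattice[state_idx]
        denoms[sample_id] = denom
    counts = pd.DataFrame(columns, index=codes)
    return PhenotypeFrequencyTable(
        panel=panel,
        counts=counts,
        denominators=pd.Series(denoms, dtype=float)[counts.columns],
    )
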