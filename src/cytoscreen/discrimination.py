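"""ROC/AUC screening of phenotypes as two-group discriminators.

Each phenotype's per-sample frequency is treated as a classifier score for
the binary group label.  The AUC is the rank (Mann–Whitney) statistic — the
probability that a randomly chosen group-B sample has a higher frequency
than a group-A sample, ties credited one half — folded to the [0.5, 1]
range, recording which orientation was kept.  Sensitivity, specificity and
accuracy are reported at the Youden-optimal frequency threshold
(sens = TP/(TP+FN), spec = TN/(TN+FP), acc = (TP+TN)/(TP+TN+FP+FN)).

Candidate phenotypes are those with AUC strictly above a cutoff (default
0.9); single-marker phenotypes of interest may be force-included regardless
of score.  A replication step re-scores the selection on an independent
cohort and confirms a phenotype only if it clears the cutoff again.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .lattice import Phenotype, PhenotypeFrequencyTable

HIGHER_IN_B = "higher-in-B"
LOWER_IN_B = "lower-in-B"

#: the single-marker populations added to the candidate list by hand in the
#: original screen, regardless of their own score
DEFAULT_FORCE_INCLUDE = ("CD4+", "Foxp3+", "IL17A+", "CD8+")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else float("nan")


@dataclass(frozen=True)
class ScoredPhenotype:
    code: str
    auc: float  # orientation-corrected, in [0.5, 1]
    orientation: str  # higher-in-B | lower-in-B
    threshold: float  # Youden-optimal frequency threshold
    sensitivity: float
    specificity: float
    accuracy: float
    degenerate: bool = False
    selected: bool = False


def _raw_auc(a: np.ndarray, b: np.ndarray) -> float:
    """P(B > A) + 0.5 P(B = A) via midranks."""
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    rank_sum_b = ranks[len(a):].sum()
    u_b = rank_sum_b - len(b) * (len(b) + 1) / 2.0
    return float(u_b / (len(a) * len(b)))


def roc_auc(
    frequencies: Sequence[float],
    labels: Sequence[str],
    group_b: str | None = None,
    code: str = "",
) -> ScoredPhenotype:
    """Score one phenotype's per-sample frequencies against group labels.

    ``group_b`` names the level treated as the positive class (default: the
    lexicographically larger of the two levels).  Constant frequencies give
    AUC 0.5 and a degenerate flag.
    """
    freq = np.asarray(frequencies, dtype=float)
    labels = np.asarray(labels)
    levels = sorted(np.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, found {levels}")
    if group_b is None:
        group_b = levels[1]
    if group_b not in levels:
        raise ValueError(f"group_b {group_b!r} not among levels {levels}")
    is_b = labels == group_b
    a, b = freq[~is_b], freq[is_b]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must contain at least one sample")

    if np.all(freq == freq[0]):
        return ScoredPhenotype(
            code=code, auc=0.5, orientation=HIGHER_IN_B,
            threshold=float(freq[0]), sensitivity=float("nan"),
            specificity=float("nan"), accuracy=float("nan"), degenerate=True,
        )

    raw = _raw_auc(a, b)
    orientation = HIGHER_IN_B if raw >= 0.5 else LOWER_IN_B
    auc = max(raw, 1.0 - raw)

    threshold, confusion = _youden(a, b, orientation)
    return ScoredPhenotype(
        code=code, auc=auc, orientation=orientation, threshold=threshold,
        sensitivity=confusion.sensitivity, specificity=confusion.specificity,
        accuracy=confusion.accuracy,
    )


def _youden(a: np.ndarray, b: np.ndarray, orientation: str
            ) -> tuple[float, ConfusionCounts]:
    """Best sens+spec threshold; B samples are the actual positives."""
    values = np.unique(np.concatenate([a, b]))
    cuts = np.concatenate(
        [[values[0] - 1.0], (values[:-1] + values[1:]) / 2.0, [values[-1] + 1.0]]
    )
    best: tuple[float, float, ConfusionCounts] | None = None
    for t in cuts:
        if orientation == HIGHER_IN_B:
            pred_b_a, pred_b_b = a > t, b > t
        else:
            pred_b_a, pred_b_b = a < t, b < t
        cc = ConfusionCounts(
            tp=int(pred_b_b.sum()), fn=int((~pred_b_b).sum()),
            fp=int(pred_b_a.sum()), tn=int((~pred_b_a).sum()),
        )
        youden = cc.sensitivity + cc.specificity - 1.0
        if best is None or youden > best[0] + 1e-12:
            best = (youden, float(t), cc)
    assert best is not None
    return best[1], best[2]


def score_all(
    table: PhenotypeFrequencyTable | pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    group_b: str | None = None,
) -> pd.DataFrame:
    """Score every phenotype row; returns a tidy DataFrame plus flags.

    ``table`` may be a PhenotypeFrequencyTable (raw per-sample frequencies)
    or a phenotypes x samples frequency DataFrame (e.g. replicate-averaged).
    ``labels`` maps column label -> group level.  Degenerate phenotypes are
    flagged, not dropped.
    """
    freq = (
        table.frequencies if isinstance(table, PhenotypeFrequencyTable) else table
    )
    if freq.empty:
        raise ValueError("empty frequency table")
    label_arr = np.asarray([labels[c] for c in freq.columns])
    rows = []
    values = freq.to_numpy(dtype=float)
    for i, code in enumerate(freq.index):
        sp = roc_auc(values[i], label_arr, group_b=group_b, code=code)
        rows.append(sp)
    df = pd.DataFrame([vars(s) for s in rows]).set_index("code")
    return df.sort_values("auc", ascending=False, kind="mergesort")


def auc_cdf(scores: pd.DataFrame) -> pd.DataFrame:
    """Empirical CDF of the AUC values (non-decreasing, ending at 1)."""
    auc = np.sort(scores["auc"].to_numpy())
    return pd.DataFrame(
        {"auc": auc, "cdf": np.arange(1, len(auc) + 1) / len(auc)}
    )


def select_candidates(
    scores: pd.DataFrame,
    cutoff: float = 0.9,
    force_include: Sequence[str] = (),
) -> list[str]:
    """Phenotype codes with AUC strictly above the cutoff, plus forced ones.

    The inequality is strict: a phenotype at exactly the cutoff is not
    selected.  Forced codes absent from the score table raise.
    """
    missing = [c for c in force_include if c not in scores.index]
    if missing:
        raise KeyError(f"force_include codes not in score table: {missing}")
    selected = set(scores.index[scores["auc"] > cutoff])
    selected.update(force_include)
    # preserve score-table (rank) order
    return [c for c in scores.index if c in selected]


def mark_selected(scores: pd.DataFrame, selected: Iterable[str]) -> pd.DataFrame:
    out = scores.copy()
    out["selected"] = out.index.isin(set(selected))
    return out


def replicate(
    selected: Sequence[str],
    cohort2_freq: pd.DataFrame,
    cohort2_labels: Mapping[str, str] | pd.Series,
    cutoff: float = 0.9,
    group_b: str | None = None,
) -> pd.DataFrame:
    """Re-score selected phenotypes on an independent cohort.

    A phenotype is ``confirmed`` iff its cohort-2 AUC is strictly above the
    cutoff.  Raises if a selected phenotype is absent from the cohort-2
    table.
    """
    missing = [c for c in selected if c not in cohort2_freq.index]
    if missing:
        raise KeyError(f"phenotypes absent from replication cohort: {missing}")
    columns = ["auc", "orientation", "degenerate", "confirmed"]
    if not selected:
        return pd.DataFrame(columns=columns).rename_axis("code")
    label_arr = np.asarray([cohort2_labels[c] for c in cohort2_freq.columns])
    rows = []
    for code in selected:
        sp = roc_auc(cohort2_freq.loc[code].to_numpy(dtype=float), label_arr,
                     group_b=group_b, code=code)
        rows.append(
            {"code": code, "auc": sp.auc, "orientation": sp.orientation,
             "degenerate": sp.degenerate, "confirmed": sp.auc > cutoff}
        )
    return pd.DataFrame(rows).set_index("code")


def permutation_null(
    freq: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    n_permutations: int = 20,
    cutoff: float = 0.9,
    seed: int | None = None,
    group_b: str | None = None,
) -> pd.DataFrame:
    """Diagnostic: fraction of phenotypes above the cutoff under label
    permutation, per permutation."""
    rng = np.random.default_rng(seed)
    cols = list(freq.columns)
    base = np.asarray([labels[c] for c in cols])
    out = []
    for i in range(n_permutations):
        perm = rng.permutation(base)
        scores = score_all(freq, dict(zip(cols, perm)), group_b=group_b)
        out.append(
            {"permutation": i,
             "fraction_above_cutoff": float((scores["auc"] > cutoff).mean())}
        )
    return pd.DataFrame(out)
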