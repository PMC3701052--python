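"""Between-platform agreement statistics.

Implements the manual-analysis toolkit for comparing two measurement
platforms on the same donors: Bland–Altman bias and 95% limits of agreement
(mean difference +/- 1.96 x SD of the differences, method A minus method B),
normality-gated paired tests (paired t when the D'Agostino–Pearson omnibus
test does not reject normality of the differences, Wilcoxon signed-rank
otherwise) with a Bonferroni-corrected significance threshold, intra-assay
coefficient of variation over experimental triplicates, and the stain index
SI = D/W with D the positive-negative median difference and W twice the
robust SD of the negative population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

RSD_DEFINITION = "1.4826*MAD"

#: differences below the D'Agostino-Pearson sample-size floor fall through
#: to the Wilcoxon branch, flagged
_NORMALITY_MIN_N = 8


@dataclass(frozen=True)
class AgreementResult:
    n: int
    bias: float  # mean(A - B), on the analysis scale
    sd: float  # SD of the differences (n-1 denominator)
    loa_lower: float  # bias - 1.96 sd
    loa_upper: float  # bias + 1.96 sd
    scale: str  # raw | log
    percent_bias: float | None = None  # log scale: 100*(1 - exp(bias))


@dataclass(frozen=True)
class PairedTestResult:
    n: int
    normality_p: float  # NaN when untestable
    test: str  # paired-t | wilcoxon | none
    p: float
    alpha: float
    m_tests: int
    threshold: float  # alpha / m_tests
    significant: bool
    note: str = ""


@dataclass(frozen=True)
class StainIndexResult:
    d: float  # median(pos) - median(neg)
    w: float  # 2 * rSD(neg)
    si: float  # d / w
    rsd_definition: str = RSD_DEFINITION


def bland_altman(
    a: Sequence[float], b: Sequence[float], scale: str = "raw"
) -> AgreementResult:
    """Bland–Altman agreement between paired measurements a and b.

    Differences are a - b.  On the ``log`` scale both series are
    natural-log transformed first and the bias is additionally reported as a
    percent difference of method A relative to B: 100*(1 - exp(bias)) — a
    positive value means A reads lower than B on average.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and paired")
    if len(a) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    if scale not in ("raw", "log"):
        raise ValueError(f"unknown scale {scale!r}")
    percent_bias = None
    if scale == "log":
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("log-scale Bland-Altman requires positive values")
        a, b = np.log(a), np.log(b)
    diffs = a - b
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if scale == "log":
        percent_bias = float(100.0 * (1.0 - np.exp(bias)))
    return AgreementResult(
        n=len(diffs), bias=bias, sd=sd,
        loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd,
        scale=scale, percent_bias=percent_bias,
    )


def bonferroni_threshold(alpha: float = 0.05, m_tests: int = 24) -> float:
    """Corrected per-test significance threshold alpha / m."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return alpha / m_tests


def paired_test(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    m_tests: int = 24,
) -> PairedTestResult:
    """Normality-gated paired comparison of two platforms.

    D'Agostino–Pearson omnibus normality test on the differences decides
    the branch: p >= 0.05 -> paired two-tailed t test; p < 0.05 -> Wilcoxon
    signed-rank (exact distribution for n <= 25 without ties/zeros, normal
    approximation with continuity correction otherwise).  Fewer than 8
    pairs cannot support the omnibus test; the Wilcoxon branch is taken and
    flagged.  Significance is declared at the Bonferroni-corrected
    threshold alpha/m_tests.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and paired")
    diffs = a - b
    threshold = bonferroni_threshold(alpha, m_tests)

    if np.all(diffs == 0):
        return PairedTestResult(
            n=len(diffs), normality_p=float("nan"), test="none",
            p=float("nan"), alpha=alpha, m_tests=m_tests, threshold=threshold,
            significant=False, note="all differences zero",
        )

    note = ""
    if len(diffs) >= _NORMALITY_MIN_N:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normality_p = float(stats.normaltest(diffs).pvalue)
        use_t = normality_p >= 0.05
    else:
        normality_p = float("nan")
        use_t = False
        note = f"n < {_NORMALITY_MIN_N}: normality untestable, Wilcoxon used"

    if use_t:
        test = "paired-t"
        p = float(stats.ttest_rel(a, b).pvalue)
    else:
        test = "wilcoxon"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.wilcoxon(a, b, method="auto").pvalue)
    return PairedTestResult(
        n=len(diffs), normality_p=normality_p, test=test, p=p, alpha=alpha,
        m_tests=m_tests, threshold=threshold,
        significant=bool(p < threshold), note=note,
    )


def cv_triplicates(
    values: Sequence[float], donors: Sequence[str]
) -> pd.DataFrame:
    """Per-donor replicate statistics: mean, SD (n-1), CV percent.

    CV = 100 * sd / mean; donors with zero mean get CV NaN and a flag.
    Requires at least two replicate values per donor.
    """
    df = pd.DataFrame({"donor": donors, "value": np.asarray(values, float)})
    rows = []
    for donor, grp in df.groupby("donor", sort=True):
        vals = grp["value"].to_numpy()
        if len(vals) < 2:
            raise ValueError(f"donor {donor!r}: need >= 2 replicate values")
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        undefined = mean == 0
        rows.append(
            {"donor": donor, "n": len(vals), "mean": mean, "sd": sd,
             "cv_percent": float("nan") if undefined else 100.0 * sd / mean,
             "undefined": undefined}
        )
    return pd.DataFrame(rows).set_index("donor")


def robust_sd(values: Sequence[float]) -> float:
    """rSD = 1.4826 x median absolute deviation (consistent for a normal)."""
    x = np.asarray(values, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def stain_index(
    positive: Sequence[float], negative: Sequence[float]
) -> StainIndexResult:
    """SI = D / W with D = median(pos) - median(neg), W = 2 x rSD(neg)."""
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both populations must be nonempty")
    w = 2.0 * robust_sd(neg)
    if w <= 0:
        raise ValueError("negative population has zero robust spread")
    d = float(np.median(pos) - np.median(neg))
    return StainIndexResult(d=d, w=w, si=d / w)


def agreement_report(
    populations: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    scale: str = "raw",
    alpha: float = 0.05,
    m_tests: int = 24,
) -> pd.DataFrame:
    """One agreement row per population: Bland-Altman + paired test.

    ``populations`` maps a population name to its paired (method A, method
    B) frequency vectors.
    """
    rows = []
    for name, (a, b) in populations.items():
        ba = bland_altman(a, b, scale=scale)
        pt = paired_test(a, b, alpha=alpha, m_tests=m_tests)
        rows.append(
            {"population": name, "n": ba.n, "scale": ba.scale,
             "bias": ba.bias, "sd": ba.sd,
             "loa_lower": ba.loa_lower, "loa_upper": ba.loa_upper,
             "percent_bias": ba.percent_bias,
             "test": pt.test, "p": pt.p, "threshold": pt.threshold,
             "significant": pt.significant}
        )
    return pd.DataFrame(rows).set_index("population")
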