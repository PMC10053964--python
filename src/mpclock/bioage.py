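"""DeltaAge, deviation summaries and age-acceleration classification.

DeltaAge is the simple difference DNAmAge - chronological age.  The
median absolute deviation (MAD) of DeltaAge defines the band of normal
biological aging: samples with |DeltaAge| <= h are "normal", below -h
"decelerated", above +h "accelerated".  The published band half-widths
are 2.78 years (blood) and 3.46 years (heart).  The MAD is the raw
median of absolute deviations — no 1.4826 normal-consistency factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CLASS_LABELS",
    "DeviationSummary",
    "delta_age",
    "mad",
    "classify",
    "summarize_deviations",
    "delta_age_table",
]

CLASS_LABELS = ("decelerated", "normal", "accelerated")


def delta_age(dnam: pd.Series, chrono: pd.Series) -> pd.Series:
    """Elementwise DNAmAge minus chronological age over aligned samples."""
    if set(dnam.index) != set(chrono.index):
        only_d = sorted(set(dnam.index) - set(chrono.index))
        only_c = sorted(set(chrono.index) - set(dnam.index))
        raise KeyError(
            f"sample sets differ: only in predictions {only_d}, only in ages {only_c}"
        )
    out = dnam - chrono.reindex(dnam.index)
    out.name = "delta_age"
    return out


def mad(deviations, centered: bool = True) -> float:
    """Median absolute deviation in years, without consistency scaling.

    ``centered=True`` (classical) takes deviations from their median;
    ``centered=False`` takes the median of raw absolute values.
    """
    arr = np.asarray(deviations, dtype=float)
    if arr.size == 0:
        raise ValueError("mad of empty input")
    if centered:
        return float(np.median(np.abs(arr - np.median(arr))))
    return float(np.median(np.abs(arr)))


def classify(delta, halfwidth: float):
    """Label each DeltaAge against the +/- halfwidth normality band.

    The boundary is inclusive: |delta| == halfwidth is "normal".
    """
    if not halfwidth > 0:
        raise ValueError(f"halfwidth must be > 0, got {halfwidth}")
    arr = np.asarray(delta, dtype=float)
    labels = np.where(
        arr < -halfwidth, "decelerated", np.where(arr > halfwidth, "accelerated", "normal")
    )
    if isinstance(delta, pd.Series):
        return pd.Series(labels, index=delta.index, name="class")
    return labels


@dataclass(frozen=True)
class DeviationSummary:
    """Location and spread of prediction deviations, plus the paired test."""

    n: int
    mean: float
    sd: float
    median: float
    trimmed_mean: float
    trim_fraction: float
    mad: float
    mad_centered: bool
    paired_t_p: float


def summarize_deviations(
    deviations, trim_fraction: float = 0.1, centered: bool = True
) -> DeviationSummary:
    """Mean/SD/median/trimmed-mean/MAD of deviations plus the two-sided
    paired t-test of chronological vs predicted age (mean deviation = 0).

    A degenerate paired test (zero variance in the deviations) reports
    p = 1: identical predictions are maximal evidence of no difference.
    """
    arr = np.asarray(deviations, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 deviations for sd and the paired test")
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        p = 1.0
    else:
        p = float(stats.ttest_1samp(arr, popmean=0.0).pvalue)
    return DeviationSummary(
        n=int(arr.size),
        mean=float(np.mean(arr)),
        sd=sd,
        median=float(np.median(arr)),
        trimmed_mean=float(stats.trim_mean(arr, trim_fraction)),
        trim_fraction=float(trim_fraction),
        mad=mad(arr, centered=centered),
        mad_centered=centered,
        paired_t_p=p,
    )


def delta_age_table(
    dnam: pd.Series, chrono: pd.Series, halfwidth: float
) -> pd.DataFrame:
    """Per-sample DNAmAge, chronological age, DeltaAge and band class."""
    delta = delta_age(dnam, chrono)
    return pd.DataFrame(
        {
            "dnam_age": dnam,
            "chronological_age": chrono.reindex(dnam.index),
            "delta_age": delta,
            "class": classify(delta, halfwidth),
        }
    )
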