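"""Cross-platform agreement statistics.

With UPLC-MS as the analytical reference (ground truth) and AEMS as the
test platform, this module computes confusion matrices and their derived
rates, two library-stability estimates — conservative (detected by both
platforms) and permissive (detected by either) — percent summaries with
half-up whole-percent rendering, and Pearson correlation of per-compound
AUC values with compounds absent from every adduct stripped from the
correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "CorrelationResult",
    "StabilityEstimate",
    "confusion",
    "pearson_auc",
    "percent_round_half_up",
    "rate",
    "stability_estimates",
]


def percent_round_half_up(fraction: float) -> int:
    """Render a fraction as a whole percent, rounding half-up."""
    return int(math.floor(100.0 * fraction + 0.5))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "n": self.n, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        }


@dataclass(frozen=True)
class StabilityEstimate:
    n: int
    conservative: float  # fraction detected by both platforms
    permissive: float    # fraction detected by either platform

    def __post_init__(self) -> None:
        if not 0 <= self.conservative <= self.permissive <= 1:
            raise ValueError("requires 0 <= conservative <= permissive <= 1")

    @property
    def conservative_pct(self) -> int:
        return percent_round_half_up(self.conservative)

    @property
    def permissive_pct(self) -> int:
        return percent_round_half_up(self.permissive)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n_used: int
    n_excluded: int


def _align(reference: Mapping[object, bool], test: Mapping[object, bool]):
    ref_keys, test_keys = set(reference), set(test)
    if ref_keys != test_keys:
        only_ref = sorted(map(str, ref_keys - test_keys))[:10]
        only_test = sorted(map(str, test_keys - ref_keys))[:10]
        raise ValueError(
            f"compound sets differ: only in reference {only_ref}, "
            f"only in test {only_test}"
        )
    keys = sorted(ref_keys, key=str)
    a = np.array([bool(reference[k]) for k in keys])
    b = np.array([bool(test[k]) for k in keys])
    return a, b


def confusion(
    reference: Mapping[object, bool], test: Mapping[object, bool]
) -> ConfusionMatrix:
    """Confusion counts of a test platform against the reference platform.

    Keys may be compound ids (compound-level agreement) or
    (compound, adduct) tuples (adduct-level agreement).
    """
    ref, tst = _align(reference, test)
    return ConfusionMatrix(
        tp=int(np.sum(ref & tst)),
        fn=int(np.sum(ref & ~tst)),
        fp=int(np.sum(~ref & tst)),
        tn=int(np.sum(~ref & ~tst)),
    )


def stability_estimates(
    flags_a: Mapping[object, bool], flags_b: Mapping[object, bool]
) -> StabilityEstimate:
    """Conservative (both platforms) and permissive (either) detection rates."""
    a, b = _align(flags_a, flags_b)
    n = len(a)
    if n == 0:
        raise ValueError("stability estimates need at least one compound")
    return StabilityEstimate(
        n=n,
        conservative=float(np.sum(a & b)) / n,
        permissive=float(np.sum(a | b)) / n,
    )


def rate(flags) -> tuple[float, int]:
    """(raw fraction, whole-percent half-up) of true flags."""
    arr = np.asarray(list(flags), dtype=bool)
    if arr.size == 0:
        raise ValueError("rate needs at least one flag")
    frac = float(arr.mean())
    return frac, percent_round_half_up(frac)


def pearson_auc(auc_a, auc_b, present) -> CorrelationResult:
    """Pearson r between platform AUCs, excluding absent compounds.

    ``present`` is False for compounds seen in no adduct on either
    platform; those pairs are stripped before correlating.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    keep = np.asarray(present, dtype=bool)
    if not (len(a) == len(b) == len(keep)):
        raise ValueError("auc_a, auc_b and present must be aligned")
    n_excluded = int(np.sum(~keep))
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError(f"need >= 3 compounds after exclusion, have {len(a)}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: zero variance in AUC values")
    r = float(stats.pearsonr(a, b).statistic)
    return CorrelationResult(r=r, n_used=len(a), n_excluded=n_excluded)
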