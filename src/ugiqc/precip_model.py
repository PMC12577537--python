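"""Precipitation-outcome labelling and descriptor-based modelling.

Reaction outcomes follow the green/red/black taxonomy: black = no
precipitate; green = precipitated and pure by NMR (purity strictly above
80%); red = precipitated but with an inconsistent NMR spectrum,
operationalized here as purity <= 80% (the only computable surrogate for
spectral inconsistency). The feature-importance model is an
ensemble-of-decision-trees classifier scored by cross-validated balanced
accuracy, with permutation importance measured on held-out folds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from .chem_enum import DESCRIPTOR_NAMES, DescriptorVector, normalize_01

__all__ = [
    "FeatureImportanceReport",
    "LabeledReaction",
    "OutcomeLabel",
    "class_distributions",
    "fit_outcome_model",
    "label_outcome",
    "retained_count",
]

PURITY_THRESHOLD = 80.0  # percent, strictly greater-than for "green"


class OutcomeLabel(str, enum.Enum):
    GREEN = "green"   # precipitated, purity > 80%
    RED = "red"       # precipitated, purity <= 80% (inconsistent NMR)
    BLACK = "black"   # no precipitate


def label_outcome(precipitated: bool, purity_pct: float | None) -> OutcomeLabel:
    if not precipitated:
        return OutcomeLabel.BLACK
    if purity_pct is None or (isinstance(purity_pct, float) and np.isnan(purity_pct)):
        raise ValueError("precipitated reaction requires a purity value")
    return OutcomeLabel.GREEN if purity_pct > PURITY_THRESHOLD else OutcomeLabel.RED


@dataclass(frozen=True)
class LabeledReaction:
    product_id: str
    descriptors: DescriptorVector
    precipitated: bool
    purity_pct: float | None
    label: OutcomeLabel

    @classmethod
    def build(cls, product_id, descriptors, precipitated, purity_pct):
        return cls(
            product_id=product_id,
            descriptors=descriptors,
            precipitated=precipitated,
            purity_pct=purity_pct if precipitated else None,
            label=label_outcome(precipitated, purity_pct),
        )


def retained_count(reactions: list[LabeledReaction]) -> int:
    """Size of the retained library: reactions labelled green."""
    return sum(r.label is OutcomeLabel.GREEN for r in reactions)


def label_frame(reactions: list[LabeledReaction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "product_id": r.product_id,
                "precipitated": r.precipitated,
                "purity_pct": r.purity_pct,
                "label": r.label.value,
            }
            for r in reactions
        ]
    )


def class_distributions(
    reactions: list[LabeledReaction], n_kde_points: int = 32
) -> pd.DataFrame:
    """Per-class, per-descriptor summaries on 0-1 normalized values.

    Returns tidy rows (class, descriptor, statistic, value) with min,
    quartiles, median, max, n, and ``n_kde_points`` Gaussian kernel-density
    samples on an even grid over [0, 1] (statistic ``kde@<grid point>``).
    Classes with fewer than two members are omitted with a warning.
    """
    import warnings

    desc = pd.DataFrame(
        [r.descriptors.as_dict() for r in reactions],
        index=[r.product_id for r in reactions],
    )
    z = normalize_01(desc[list(DESCRIPTOR_NAMES)])
    labels = pd.Series([r.label.value for r in reactions], index=z.index)

    rows = []
    for cls in ("green", "red", "black"):
        members = z[labels == cls]
        if len(members) < 2:
            warnings.warn(f"class {cls!r} has <2 members; omitted", stacklevel=2)
            continue
        for d in DESCRIPTOR_NAMES:
            v = members[d].to_numpy()
            stats_map = {
                "min": v.min(),
                "q1": np.quantile(v, 0.25),
                "median": np.median(v),
                "q3": np.quantile(v, 0.75),
                "max": v.max(),
                "n": float(len(v)),
            }
            if np.ptp(v) > 0:
                grid = np.linspace(0, 1, n_kde_points)
                dens = stats.gaussian_kde(v)(grid)
                stats_map.update(
                    {f"kde@{x:.4f}": y for x, y in zip(grid, dens)}
                )
            for name, val in stats_map.items():
                rows.append(
                    {"class": cls, "descriptor": d, "statistic": name,
                     "value": float(val)}
                )
    return pd.DataFrame(rows, columns=["class", "descriptor", "statistic", "value"])


@dataclass(frozen=True)
class FeatureImportanceReport:
    """Descriptor importances (normalized to sum 1) with model quality."""

    ranking: tuple[tuple[str, float], ...]  # descending, ties alphabetical
    balanced_accuracy: float                # cross-validated
    n_folds: int
    seed: int

    def importance(self, name: str) -> float:
        return dict(self.ranking)[name]

    def as_dict(self) -> dict:
        return {
            "ranking": [{"descriptor": d, "importance": v} for d, v in self.ranking],
            "balanced_accuracy": self.balanced_accuracy,
            "n_folds": self.n_folds,
            "seed": self.seed,
        }


def fit_outcome_model(
    X: pd.DataFrame,
    y,
    seed: int = 0,
    n_folds: int = 5,
    n_estimators: int = 200,
    n_permutation_repeats: int = 10,
) -> FeatureImportanceReport:
    """Rank descriptors by held-out permutation importance.

    A seeded random forest is fit on each training fold; permutation
    importance (balanced-accuracy drop, averaged over repeats) is measured
    on the matching held-out fold and averaged across folds. Negative mean
    importances are clipped to zero before normalizing to sum 1 (a uniform
    ranking is returned if every importance is zero). Note that perfectly
    duplicated feature columns share their signal, so permutation
    importance splits between them.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=bool)
    if len(X) < 50:
        raise ValueError("need at least 50 rows to fit the outcome model")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate outcome: only one class present in y")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    importances = np.zeros(X.shape[1])
    accuracies = []
    for fold, (train, test) in enumerate(skf.split(X, y)):
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed + fold, n_jobs=1
        )
        clf.fit(X.iloc[train], y[train])
        accuracies.append(
            balanced_accuracy_score(y[test], clf.predict(X.iloc[test]))
        )
        perm = permutation_importance(
            clf, X.iloc[test], y[test],
            scoring="balanced_accuracy",
            n_repeats=n_permutation_repeats,
            random_state=seed + fold,
        )
        importances += perm.importances_mean
    importances = np.clip(importances / n_folds, 0.0, None)
    total = importances.sum()
    if total == 0:
        norm = np.full_like(importances, 1.0 / len(importances))
    else:
        norm = importances / total
    ranked = sorted(
        zip(X.columns, norm), key=lambda kv: (-kv[1], kv[0])
    )
    return FeatureImportanceReport(
        ranking=tuple((str(k), float(v)) for k, v in ranked),
        balanced_accuracy=float(np.mean(accuracies)),
        n_folds=n_folds,
        seed=seed,
    )
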