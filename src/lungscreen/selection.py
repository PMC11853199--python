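"""Feature ranking and selection with the Kruskal-Wallis H test.

Each feature's relevance to the four-class label is scored by the
Kruskal-Wallis statistic

    H = 12 / (N (N + 1)) * sum_i R_i^2 / n_i  -  3 (N + 1)

where N is the pooled sample size, n_i the size of class i, and R_i the sum
of the pooled ranks falling in class i (midranks for ties). A feature is
accepted when H exceeds the upper-tail chi-squared critical value at k - 1
degrees of freedom; features are ranked by H descending.

The statistic above carries no tie-correction divisor; the standard
correction 1 - sum(t^3 - t) / (N^3 - N) is available behind the
``tie_correction`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lungscreen.classifier import ModelConfig, evaluate_accuracy, split_dataset, train
from lungscreen.errors import ContractError
from lungscreen.features import FEATURE_NAMES

#: Feature subset used by default when a user skips ranking on their own
#: data: the 10-feature combination that maximizes held-out accuracy in the
#: incremental evaluation on the reference corpus.
DEFAULT_SELECTED_FEATURES = (
    "Entropy",
    "RMScD9",
    "Spec.Entropy",
    "RMScD10",
    "RMScD3",
    "RMScD2",
    "RMScD4",
    "RMScD8",
    "RMScA",
    "RMScD5",
)


@dataclass(frozen=True)
class RankedFeature:
    name: str
    h_value: float
    accepted: bool


@dataclass(frozen=True)
class FeatureRanking:
    """Features sorted by H descending, with the acceptance threshold used."""

    entries: tuple[RankedFeature, ...]
    alpha: float
    critical_value: float

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    @property
    def accepted_names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries if e.accepted)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.name, e.h_value, e.accepted) for e in self.entries],
            columns=["feature", "h_value", "accepted"],
        )


def kruskal_wallis_h(
    groups: Sequence[Sequence[float]], tie_correction: bool = False
) -> float:
    """Kruskal-Wallis H over k >= 2 groups, midranks for ties.

    By default no tie-correction divisor is applied; with
    ``tie_correction=True`` H is divided by 1 - sum(t^3 - t)/(N^3 - N),
    matching the conventional corrected statistic.
    """
    if len(groups) < 2:
        raise ContractError("Kruskal-Wallis requires at least 2 groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ContractError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)  # midranks
    h = 0.0
    start = 0
    for a in arrays:
        r_i = float(np.sum(ranks[start : start + a.size]))
        h += r_i**2 / a.size
        start += a.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    if tie_correction:
        _, counts = np.unique(pooled, return_counts=True)
        correction = 1.0 - float(np.sum(counts**3 - counts)) / (n_total**3 - n_total)
        if correction <= 0.0:
            raise ContractError("all pooled values identical: corrected H undefined")
        h /= correction
    return float(h)


def chi2_critical(alpha: float, df: int) -> float:
    """Upper-tail chi-squared critical value at significance ``alpha``."""
    if not 0.0 < alpha < 1.0:
        raise ContractError("alpha must lie in (0, 1)")
    if df < 1:
        raise ContractError("degrees of freedom must be >= 1")
    return float(stats.chi2.ppf(1.0 - alpha, df))


def rank_features(
    table: pd.DataFrame,
    alpha: float = 0.05,
    feature_names: Sequence[str] = FEATURE_NAMES,
    tie_correction: bool = False,
) -> FeatureRanking:
    """Rank every feature by its H value over the label groups.

    ``table`` must hold the feature columns plus a ``label`` column with at
    least two distinct classes. A feature is accepted when its H exceeds
    the chi-squared critical value at (#classes - 1) degrees of freedom.
    Ties in H are broken by canonical feature order, so the ranking is
    invariant to row permutation.
    """
    if "label" not in table.columns:
        raise ContractError("feature table needs a 'label' column")
    classes = sorted(table["label"].unique())
    if len(classes) < 2:
        raise ContractError("ranking requires at least 2 classes in the table")
    missing = [f for f in feature_names if f not in table.columns]
    if missing:
        raise ContractError(f"feature table missing columns: {missing}")
    critical = chi2_critical(alpha, df=len(classes) - 1)
    scored = []
    for name in feature_names:
        groups = [table.loc[table["label"] == c, name].to_numpy() for c in classes]
        h = kruskal_wallis_h(groups, tie_correction=tie_correction)
        scored.append(RankedFeature(name=name, h_value=h, accepted=h > critical))
    scored.sort(key=lambda e: (-e.h_value, feature_names.index(e.name)))
    return FeatureRanking(entries=tuple(scored), alpha=alpha, critical_value=critical)


@dataclass(frozen=True)
class SubsetAccuracy:
    features: tuple[str, ...]
    train_accuracy: float
    test_accuracy: float


def incremental_feature_evaluation(
    table: pd.DataFrame,
    ranking: FeatureRanking,
    model_config: ModelConfig,
    test_fraction: float = 0.2,
    split_seed: int = 0,
) -> tuple[list[SubsetAccuracy], tuple[str, ...]]:
    """Greedy accuracy curve over H-ordered feature subsets.

    For m = 1 .. #ranked features, train the classifier on the top-m
    features and record train/test accuracy, using the same stratified split
    and training seed for every m so the curve is comparable across subset
    sizes. Returns the curve and the selected subset: the argmax of test
    accuracy, ties broken toward the smaller subset.
    """
    names = ranking.names
    missing = [f for f in names if f not in table.columns]
    if missing:
        raise ContractError(f"table missing ranked features: {missing}")
    train_tbl, test_tbl = split_dataset(table, test_fraction=test_fraction, seed=split_seed)
    curve: list[SubsetAccuracy] = []
    best: Optional[tuple[str, ...]] = None
    best_acc = -1.0
    for m in range(1, len(names) + 1):
        subset = names[:m]
        model = train(train_tbl, model_config, feature_names=subset)
        curve.append(
            SubsetAccuracy(
                features=subset,
                train_accuracy=evaluate_accuracy(model, train_tbl),
                test_accuracy=evaluate_accuracy(model, test_tbl),
            )
        )
        if curve[-1].test_accuracy > best_acc:  # strict: ties keep the smaller set
            best_acc = curve[-1].test_accuracy
            best = subset
    return curve, best


def curve_to_frame(curve: Sequence[SubsetAccuracy]) -> pd.DataFrame:
    """Accuracy curve as a DataFrame (one row per subset size)."""
    return pd.DataFrame(
        [
            ("+".join(c.features), c.train_accuracy, c.test_accuracy)
            for c in curve
        ],
        columns=["features", "train_accuracy", "test_accuracy"],
    )
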