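"""Bootstrap evaluation harness for tree classifiers.

Protocol: the data set is split once into stratified train/test partitions;
then, per bootstrap replicate, the training partition is resampled with
replacement, the model is refitted on the resample, and the fixed test
partition is scored at the chosen probability threshold.  Accuracy,
specificity, sensitivity and precision are reported as percentages with
95% percentile confidence intervals across replicates.

All randomness flows from a single seed through counter-based substreams
(one per replicate), so a report is exactly reproducible from its seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .core_tree import FPTError, build_tree
from .fuzzy import discretize
from .prediction import (
    DEFAULT_THRESHOLD,
    FuzzyConfig,
    patient_from_row,
    predict,
)

logger = logging.getLogger("fptree")

METRICS = ("accuracy", "specificity", "sensitivity", "precision")


def stratified_split(
    records: pd.DataFrame,
    target: str,
    test_fraction: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class-proportion-preserving train/test split, deterministic in seed."""
    if not 0.0 < test_fraction < 1.0:
        raise FPTError(f"test_fraction {test_fraction} outside (0, 1)")
    labels = records[target].astype(str)
    if labels.nunique() < 2:
        raise FPTError("both classes must be present for a stratified split")
    try:
        train, test = train_test_split(
            records,
            test_size=test_fraction,
            stratify=labels,
            random_state=seed,
        )
    except ValueError as exc:  # a class too small to appear in both partitions
        raise FPTError(f"stratified split impossible: {exc}") from exc
    return train, test


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Accuracy, specificity, sensitivity, precision from a 2x2 table.

    A metric with a zero denominator is undefined and returned as NaN; the
    bootstrap aggregation excludes such replicates from that metric's CI.
    """
    if min(tp, fp, fn, tn) < 0:
        raise FPTError("confusion counts must be nonnegative")
    n = tp + fp + fn + tn
    out = {
        "accuracy": (tp + tn) / n if n else math.nan,
        "sensitivity": tp / (tp + fn) if tp + fn else math.nan,
        "specificity": tn / (tn + fp) if tn + fp else math.nan,
        "precision": tp / (tp + fp) if tp + fp else math.nan,
    }
    return out


@dataclass
class MetricCI:
    point: float   # mean over defined replicates, percent
    lower: float   # 2.5 percentile, percent
    upper: float   # 97.5 percentile, percent
    n_defined: int


@dataclass
class MetricReport:
    """Point estimates and 95% CIs (percent scale) over bootstrap replicates."""

    metrics: dict[str, MetricCI]
    n_bootstraps: int
    threshold: float
    seed: int
    n_skipped: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metric": name,
                "estimate_pct": ci.point,
                "ci95_lower_pct": ci.lower,
                "ci95_upper_pct": ci.upper,
                "n_defined": ci.n_defined,
            }
            for name, ci in self.metrics.items()
        ]
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        lines = [
            f"bootstrap replicates: {self.n_bootstraps} "
            f"(skipped: {self.n_skipped}), threshold: {self.threshold}, "
            f"seed: {self.seed}"
        ]
        for name, ci in self.metrics.items():
            lines.append(
                f"  {name:<12s} {ci.point:6.1f}%  "
                f"[{ci.lower:.1f}-{ci.upper:.1f}]  (n={ci.n_defined})"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Model interface
# ---------------------------------------------------------------------------

class FPTClassifier:
    """The probability-tree model behind the harness interface.

    ``fit(records)`` discretizes the fuzzy variables at their crisp cuts,
    induces the tree on the declared feature order, and ``predict_proba``
    returns the positive-class probability per row — fuzzily (raw values
    weight all compatible branches) or crisply (``mode='crisp'``, single
    path per patient).
    """

    def __init__(
        self,
        feature_order: list[str],
        target: str,
        fuzzy_config: FuzzyConfig | None = None,
        crisp_cuts: dict[str, float] | None = None,
        positive_label: str | None = None,
        mode: str = "fuzzy",
    ) -> None:
        if mode not in ("fuzzy", "crisp"):
            raise FPTError(f"unknown mode {mode!r}")
        self.feature_order = list(feature_order)
        self.target = target
        self.fuzzy_config = fuzzy_config or {}
        self.crisp_cuts = crisp_cuts or {}
        self.positive_label = positive_label
        self.mode = mode
        self.tree_ = None

    def fit(self, records: pd.DataFrame) -> "FPTClassifier":
        discrete = discretize(records, self.fuzzy_config, self.crisp_cuts)
        self.tree_ = build_tree(discrete, self.feature_order, self.target)
        return self

    def _predict_config(self) -> FuzzyConfig:
        if self.mode == "crisp":
            from .fuzzy import crisp_variant

            return {
                name: crisp_variant(var, self.crisp_cuts[name])
                for name, var in self.fuzzy_config.items()
            }
        return self.fuzzy_config

    def predict_proba(self, records: pd.DataFrame) -> np.ndarray:
        if self.tree_ is None:
            raise FPTError("classifier is not fitted")
        config = self._predict_config()
        positive = self.positive_label or self.tree_.class_labels[-1]
        probs = np.empty(len(records))
        for i, (_, row) in enumerate(records.iterrows()):
            patient = patient_from_row(row, self.feature_order, self.fuzzy_config)
            result = predict(self.tree_, config, patient,
                             positive_label=positive)
            probs[i] = result.prob_positive
        return probs


class ScikitAdapter:
    """Benchmark plug-in: wraps any scikit-learn probabilistic classifier.

    Categorical columns are one-hot encoded; numeric columns pass through
    unchanged (baselines use the raw continuous values, not the linguistic
    terms).
    """

    def __init__(self, estimator, feature_order: list[str], target: str,
                 positive_label: str | None = None) -> None:
        self.estimator = estimator
        self.feature_order = list(feature_order)
        self.target = target
        self.positive_label = positive_label
        self.pipeline_ = None

    def fit(self, records: pd.DataFrame) -> "ScikitAdapter":
        from sklearn.compose import ColumnTransformer
        from sklearn.base import clone
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import OneHotEncoder

        X = records[self.feature_order]
        y = records[self.target].astype(str)
        categorical = [c for c in self.feature_order
                       if X[c].dtype == object or str(X[c].dtype) == "category"]
        transform = ColumnTransformer(
            [("onehot", OneHotEncoder(handle_unknown="ignore"), categorical)],
            remainder="passthrough",
        )
        self.pipeline_ = Pipeline(
            [("columns", transform), ("model", clone(self.estimator))]
        )
        self.pipeline_.fit(X, y)
        return self

    def predict_proba(self, records: pd.DataFrame) -> np.ndarray:
        classes = list(self.pipeline_.named_steps["model"].classes_)
        positive = self.positive_label or sorted(classes)[-1]
        column = classes.index(positive)
        return self.pipeline_.predict_proba(records[self.feature_order])[:, column]


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_evaluate(
    model,
    records: pd.DataFrame,
    target: str,
    n_bootstraps: int,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
    test_fraction: float = 0.3,
    positive_label: str | None = None,
) -> MetricReport:
    """Bootstrap the four classification metrics with 95% percentile CIs.

    ``model`` is any object with ``fit(records)`` and
    ``predict_proba(records) -> positive-class probabilities`` (e.g.
    :class:`FPTClassifier` or a :class:`ScikitAdapter` baseline).
    Replicates whose resample lacks a class are skipped and logged;
    replicate metrics that are undefined (zero denominator) are excluded
    from that metric's aggregation.
    """
    if n_bootstraps < 2:
        raise FPTError("n_bootstraps must be at least 2")
    train, test = stratified_split(records, target, test_fraction, seed)
    truth = test[target].astype(str).to_numpy()
    if positive_label is None:
        positive_label = sorted(pd.unique(records[target].astype(str)))[-1]
    truth_pos = truth == positive_label
    logger.info(
        "bootstrap_evaluate: %d train / %d test records, %d replicates, "
        "threshold %.2f, seed %d",
        len(train), len(test), n_bootstraps, threshold, seed,
    )

    samples: dict[str, list[float]] = {m: [] for m in METRICS}
    n_skipped = 0
    for b in range(n_bootstraps):
        rng = np.random.default_rng([seed, b])  # counter-based substream
        idx = rng.integers(0, len(train), size=len(train))
        resample = train.iloc[idx]
        if resample[target].astype(str).nunique() < 2:
            n_skipped += 1
            logger.info("replicate %d skipped: a class is missing", b)
            continue
        model.fit(resample)
        probs = np.asarray(model.predict_proba(test))
        pred_pos = probs >= threshold
        tp = int(np.sum(pred_pos & truth_pos))
        fp = int(np.sum(pred_pos & ~truth_pos))
        fn = int(np.sum(~pred_pos & truth_pos))
        tn = int(np.sum(~pred_pos & ~truth_pos))
        for name, value in confusion_metrics(tp, fp, fn, tn).items():
            if math.isnan(value):
                logger.info("replicate %d: %s undefined, excluded", b, name)
            else:
                samples[name].append(value)

    metrics: dict[str, MetricCI] = {}
    for name in METRICS:
        values = np.array(samples[name]) * 100.0
        if len(values) == 0:
            metrics[name] = MetricCI(math.nan, math.nan, math.nan, 0)
            continue
        metrics[name] = MetricCI(
            point=float(values.mean()),
            lower=float(np.percentile(values, 2.5)),
            upper=float(np.percentile(values, 97.5)),
            n_defined=len(values),
        )
    return MetricReport(
        metrics=metrics,
        n_bootstraps=n_bootstraps,
        threshold=threshold,
        seed=seed,
        n_skipped=n_skipped,
    )
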