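"""Five-fold cross-validated evaluation, metrics, and lag optimization.

The evaluation protocol mirrors the model-building pipeline end to end:
encode each protein pair with the six techniques, train the GRU reducers,
fit the boosted-tree classifier on the merged hidden states of the training
split, and score the held-out split.  By default the reducers themselves
are re-trained inside every fold so the held-out pairs never influence the
learned representation; a ``train-once`` leakage policy trains them on the
full set before cross-validation for faithfulness experiments.

Reported metrics: ACC, PRE, SE, SP, F1 (fractions in [0, 1]), MCC, AUC and
AUPR.  Ratios with zero denominators are reported as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .aaprops import ClassMap, PropertyTable
from .classify import ClassifierConfig, LightGBMClassifier, PredictionSet, predict
from .encoders import LAGGED_TECHNIQUES, TECHNIQUES, encode_pair_matrix
from .reduction import REDUCE_STRATEGIES

METRIC_NAMES = ("ACC", "PRE", "SE", "SP", "F1", "MCC", "AUC", "AUPR")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricReport:
    """One evaluation's metric values, with degenerate-ratio bookkeeping."""

    values: dict[str, float]
    counts: ConfusionCounts | None = None
    undefined: tuple[str, ...] = ()
    omitted: tuple[str, ...] = ()

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def confusion(truth: np.ndarray, hard: np.ndarray) -> ConfusionCounts:
    truth = np.asarray(truth).astype(int)
    hard = np.asarray(hard).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((truth == 1) & (hard == 1))),
        FP=int(np.sum((truth == 0) & (hard == 1))),
        TN=int(np.sum((truth == 0) & (hard == 0))),
        FN=int(np.sum((truth == 1) & (hard == 0))),
    )


def _ratio(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(truth: np.ndarray, predictions: PredictionSet) -> MetricReport:
    """Threshold metrics from the confusion matrix plus AUC/AUPR from scores."""
    truth = np.asarray(truth).astype(int)
    probs = predictions.probabilities
    if truth.shape[0] != probs.shape[0]:
        raise ValueError("truth/prediction length mismatch")
    c = confusion(truth, predictions.hard_labels)
    flags: list[str] = []
    acc = _ratio(c.TP + c.TN, c.n, flags, "ACC")
    pre = _ratio(c.TP, c.TP + c.FP, flags, "PRE")
    se = _ratio(c.TP, c.TP + c.FN, flags, "SE")
    sp = _ratio(c.TN, c.TN + c.FP, flags, "SP")
    f1 = _ratio(2 * pre * se, pre + se, flags, "F1")
    mcc_den = np.sqrt(
        float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    mcc = _ratio(c.TP * c.TN - c.FP * c.FN, mcc_den, flags, "MCC")
    single_class = np.unique(truth).size < 2
    if single_class:
        flags.extend(["AUC", "AUPR"])
        auc = aupr = 0.0
    else:
        auc = float(roc_auc_score(truth, probs))
        aupr = float(average_precision_score(truth, probs))
    return MetricReport(
        values={"ACC": acc, "PRE": pre, "SE": se, "SP": sp, "F1": f1,
                "MCC": mcc, "AUC": auc, "AUPR": aupr},
        counts=c,
        undefined=tuple(flags),
    )


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 1) -> np.ndarray:
    """Fold id (0..k-1) per pair; sizes within 1, class ratio preserved."""
    labels = np.asarray(labels).astype(int)
    n = labels.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} pairs, got {n}")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present for stratified folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), labels)):
        assignment[test_idx] = fold
    return assignment


@dataclass(frozen=True)
class PipelineConfig:
    """Everything run_cv needs besides the data itself."""

    lags: dict = field(default_factory=lambda: {"pseaac": 8, "ad": 7, "ac": 9})
    strategy: str = "multiens"
    direction: str = "bidirectional"
    epochs: int = 5
    pseaac_weight: float = 0.05
    reducer_seed: int = 0
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    cv_seed: int = 1
    n_folds: int = 5
    leakage_policy: str = "per-fold"  # or "train-once" or "split"
    reduction_fraction: float = 0.4   # reducer-training share under "split"
    techniques: tuple[str, ...] = TECHNIQUES

    def __post_init__(self) -> None:
        if self.strategy not in REDUCE_STRATEGIES:
            raise ValueError(f"unknown strategy '{self.strategy}'")
        if self.leakage_policy not in ("per-fold", "train-once", "split"):
            raise ValueError(
                "leakage_policy must be 'per-fold', 'train-once' or 'split'")
        if not 0 < self.reduction_fraction < 1:
            raise ValueError("reduction_fraction must lie in (0, 1)")
        for t in LAGGED_TECHNIQUES:
            if t in self.techniques and not 1 <= self.lags[t]:
                raise ValueError(f"lag for {t} must be >= 1")


@dataclass
class CVResult:
    fold_reports: list[MetricReport]
    fold_assignment: np.ndarray
    merged_width: int
    config: PipelineConfig

    @property
    def mean(self) -> dict[str, float]:
        return {
            m: float(np.mean([r[m] for r in self.fold_reports]))
            for m in METRIC_NAMES
        }

    @property
    def std(self) -> dict[str, float]:
        return {
            m: float(np.std([r[m] for r in self.fold_reports], ddof=1))
            for m in METRIC_NAMES
        }


def encode_blocks(
    proteins, pairs, props: PropertyTable, cmap: ClassMap, config: PipelineConfig
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-technique pair feature matrices for the configured techniques."""
    blocks = {}
    labels = None
    for tech in config.techniques:
        lag = config.lags.get(tech) if tech in LAGGED_TECHNIQUES else None
        blocks[tech], labels = encode_pair_matrix(
            proteins, pairs, tech, props, cmap, lag=lag,
            weight=config.pseaac_weight,
        )
    return blocks, labels


def _reduce(blocks, labels, config: PipelineConfig, train_index, seed_shift=0,
            apply_to=None):
    reducer_fn = REDUCE_STRATEGIES[config.strategy]
    kwargs = dict(direction=config.direction, epochs=config.epochs,
                  train_index=train_index, apply_to=apply_to)
    if config.strategy == "multicon":
        kwargs["seed"] = config.reducer_seed + seed_shift
    else:
        kwargs["seeds"] = config.reducer_seed + seed_shift
    return reducer_fn(blocks, labels, **kwargs)


def run_cv(proteins, pairs, props, cmap, config: PipelineConfig) -> CVResult:
    """Full pipeline under k-fold cross-validation.

    Leakage policies:

    * ``per-fold`` (default): reducers are re-trained on each fold's
      training rows and applied to the held-out rows — no information from
      a test fold ever reaches the representation.
    * ``train-once``: reducers train on the full set before CV; cheap and
      faithful to a train-once protocol, but on small data the wider
      reducers can partially encode held-out labels.
    * ``split``: reducers train once on a disjoint stratified subset
      (``reduction_fraction`` of the pairs) and the classifier is
      cross-validated on the remaining rows only — leakage-free at a
      single reducer training per strategy, which makes matched-seed
      strategy comparisons affordable.
    """
    blocks, labels = encode_blocks(proteins, pairs, props, cmap, config)
    reports: list[MetricReport] = []
    merged_width = 0

    if config.leakage_policy == "split":
        red_idx, eval_idx = _reduction_split(labels, config)
        merged, _ = _reduce(blocks, labels, config, train_index=red_idx,
                            apply_to=eval_idx)
        H = merged.hidden_states
        merged_width = H.shape[1]
        eval_labels = labels[eval_idx]
        folds = stratified_kfold(eval_labels, k=config.n_folds,
                                 seed=config.cv_seed)
        for fold in range(config.n_folds):
            tr = np.flatnonzero(folds != fold)
            te = np.flatnonzero(folds == fold)
            clf = LightGBMClassifier(config.classifier).fit(H[tr], eval_labels[tr])
            reports.append(compute_metrics(eval_labels[te], predict(clf, H[te])))
        return CVResult(reports, folds, merged_width, config)

    folds = stratified_kfold(labels, k=config.n_folds, seed=config.cv_seed)
    if config.leakage_policy == "train-once":
        merged, _ = _reduce(blocks, labels, config, train_index=None)
        H = merged.hidden_states
        merged_width = H.shape[1]

    for fold in range(config.n_folds):
        test_mask = folds == fold
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        if config.leakage_policy == "per-fold":
            merged, _ = _reduce(
                blocks, labels, config, train_index=train_idx,
                seed_shift=10 * fold,
            )
            H = merged.hidden_states
            merged_width = H.shape[1]
        clf = LightGBMClassifier(config.classifier).fit(H[train_idx], labels[train_idx])
        preds = predict(clf, H[test_idx])
        reports.append(compute_metrics(labels[test_idx], preds))
    return CVResult(reports, folds, merged_width, config)


def _reduction_split(labels: np.ndarray, config: PipelineConfig):
    """Disjoint stratified (reduction, evaluation) row indices."""
    from sklearn.model_selection import train_test_split

    idx = np.arange(labels.shape[0])
    red_idx, eval_idx = train_test_split(
        idx, train_size=config.reduction_fraction, stratify=labels,
        random_state=config.cv_seed, shuffle=True,
    )
    return np.sort(red_idx), np.sort(eval_idx)


def optimize_lag(
    proteins, pairs, props, cmap, technique: str,
    lag_range=range(1, 12), seed: int = 1,
    classifier: ClassifierConfig | None = None,
    n_folds: int = 5,
):
    """Per-lag 5-fold CV of raw technique features through the classifier.

    The lag search feeds the raw (unreduced) pair features to the boosted
    trees, which keeps the search cheap and isolates the effect of the lag
    itself.  Ties are broken toward the smallest lag (cheaper features).
    Returns (best_lag, {lag: CVResult-like mean ACC table}).
    """
    if technique not in LAGGED_TECHNIQUES:
        raise ValueError(f"technique '{technique}' takes no lag")
    shortest = min((len(p.sequence), p.id) for p in proteins.values())
    max_lag = max(lag_range)
    if shortest[0] <= max_lag:
        raise ValueError(
            f"lag range up to {max_lag} infeasible: shortest sequence "
            f"'{shortest[1]}' has length {shortest[0]}"
        )
    classifier = classifier or ClassifierConfig()
    per_lag: dict[int, dict[str, float]] = {}
    for lag in lag_range:
        X, y = encode_pair_matrix(proteins, pairs, technique, props, cmap, lag=lag)
        folds = stratified_kfold(y, k=n_folds, seed=seed)
        accs = []
        reports = []
        for fold in range(n_folds):
            tr = folds != fold
            te = ~tr
            clf = LightGBMClassifier(classifier).fit(X[tr], y[tr])
            rep = compute_metrics(y[te], predict(clf, X[te]))
            reports.append(rep)
            accs.append(rep["ACC"])
        per_lag[lag] = {
            m: float(np.mean([r[m] for r in reports])) for m in METRIC_NAMES
        }
    best = max(per_lag, key=lambda lag: (per_lag[lag]["ACC"], -lag))
    return best, per_lag


@dataclass
class TrainedPipeline:
    """Frozen reducers + classifier, ready for external test sets."""

    config: PipelineConfig
    props: PropertyTable
    cmap: ClassMap
    reducers: dict
    classifier: LightGBMClassifier
    merged_width: int


def fit_pipeline(proteins, pairs, props, cmap, config: PipelineConfig) -> TrainedPipeline:
    """Train reducers and classifier once on a full training set."""
    blocks, labels = encode_blocks(proteins, pairs, props, cmap, config)
    merged, reducers = _reduce(blocks, labels, config, train_index=None)
    clf = LightGBMClassifier(config.classifier).fit(merged.hidden_states, labels)
    return TrainedPipeline(config, props, cmap, reducers,
                           clf, merged.hidden_states.shape[1])


def _apply_reducers(pipeline: TrainedPipeline, blocks: dict) -> np.ndarray:
    from .reduction import MULTISEP_GROUPS, TECHNIQUE_ORDER

    cfg = pipeline.config
    if cfg.strategy == "multiens":
        parts = [
            pipeline.reducers[t].transform(blocks[t])
            for t in TECHNIQUE_ORDER if t in blocks
        ]
    elif cfg.strategy == "multicon":
        X = np.concatenate(
            [blocks[t] for t in TECHNIQUE_ORDER if t in blocks], axis=1
        )
        parts = [pipeline.reducers["all"].transform(X)]
    else:
        parts = []
        for group, techs in MULTISEP_GROUPS.items():
            X = np.concatenate([blocks[t] for t in techs if t in blocks], axis=1)
            parts.append(pipeline.reducers[group].transform(X))
    return np.concatenate(parts, axis=1)


def cross_dataset_test(pipeline: TrainedPipeline, proteins, pairs) -> MetricReport:
    """Apply a frozen pipeline to an external pair set.

    Pairs whose sequences are too short for the trained lags are skipped
    (the skip count is recorded on the report).  On positive-only sets
    specificity is undefined and is omitted with a flag.
    """
    if not pairs:
        raise ValueError("empty external test set")
    cfg = pipeline.config
    max_lag = max(cfg.lags[t] for t in LAGGED_TECHNIQUES if t in cfg.techniques)
    usable, skipped = [], 0
    for a, b, lab in pairs:
        if len(proteins[a].sequence) > max_lag and len(proteins[b].sequence) > max_lag:
            usable.append((a, b, lab))
        else:
            skipped += 1
    if not usable:
        raise ValueError("no external pair passes the lag length constraint")
    blocks, labels = encode_blocks(proteins, usable, pipeline.props,
                                   pipeline.cmap, cfg)
    H = _apply_reducers(pipeline, blocks)
    preds = predict(pipeline.classifier, H)
    report = compute_metrics(labels, preds)
    if np.unique(labels).size < 2:
        omitted = ("SP", "AUC", "AUPR") if labels[0] == 1 else ("SE", "AUC", "AUPR")
        report.omitted = omitted
    report.values["skipped_pairs"] = float(skipped)
    return report
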