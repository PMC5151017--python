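"""Nested repeated cross-validation, hyperparameter search and metrics.

The evaluation design mirrors a repeated nested cross-validation: the
cohort is shuffled and split into 3 stratified folds, five times.  Per
fold, two folds train the model, and the held-out fold is split 50/50
at random into a validation half (drives the hyperparameter search)
and a test half (touched exactly once, by the final retrained model).
SCZ is the positive class throughout.

The hyperparameter search is a mixture of three proposal strategies
chosen per iteration: a Tree-of-Parzen-Estimators-style density-ratio
proposal (70% of iterations), an annealing-style perturbation of the
incumbent best (20%), and uniform random search (10%).  The Parzen
proposal is a deliberately simple reference implementation — top-25%
vs rest split with a per-dimension Gaussian KDE ratio — whose job is
to beat random search on smooth objectives, not to replicate any
particular optimizer library.

Hyperparameters searched (per depth sweep): units per hidden layer,
quantized-uniform integer in [10, 200]; RBM pretraining learning rate
and fine-tuning learning rate, both uniform in [1e-4, 1e-1].

The linear baseline is a soft-margin SVM with C selected on the
validation half from the grid {0.001, 0.1, 1, 10, 100, 1000}; when all
grid values tie, C = 1 is adopted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import gaussian_kde, rankdata
from sklearn.svm import SVC

from .dbn import (
    DBNModel,
    FineTuneConfig,
    FineTunedNetwork,
    fine_tune,
    initialize_network,
    predict,
    predict_proba,
    pretrain_dbn,
)
from .io import MorphometryTable
from .rbm import CDTrainingConfig

C_GRID: tuple[float, ...] = (0.001, 0.1, 1.0, 10.0, 100.0, 1000.0)


# ---------------------------------------------------------------------------
# Metrics

@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with SCZ as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray
                         ) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def compute_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity, balanced accuracy and error rate (%).

    A rate whose denominator is zero is reported as None, never as 0.
    """
    if counts.total == 0:
        raise ValueError("no evaluated subjects")
    pos = counts.TP + counts.FN
    neg = counts.TN + counts.FP
    sens = 100.0 * counts.TP / pos if pos else None
    spec = 100.0 * counts.TN / neg if neg else None
    bal = (sens + spec) / 2.0 if sens is not None and spec is not None else None
    err = 100.0 * (counts.FP + counts.FN) / counts.total
    return {"sensitivity": sens, "specificity": spec,
            "balanced_accuracy": bal, "error_rate": err}


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Cross-validation plan

@dataclass
class FoldSplit:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


@dataclass
class CVPlan:
    """Per-repeat, per-fold train/validation/test index assignments."""

    repeats: list[list[FoldSplit]]
    seed: int

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    @property
    def n_folds(self) -> int:
        return len(self.repeats[0]) if self.repeats else 0

    def all_folds(self) -> list[tuple[int, int, FoldSplit]]:
        return [(r, f, split)
                for r, folds in enumerate(self.repeats)
                for f, split in enumerate(folds)]


def make_cv_plan(labels: Sequence[str] | np.ndarray, n_repeats: int = 5,
                 n_folds: int = 3, seed: int = 0,
                 stratified: bool = True) -> CVPlan:
    """Repeated k-fold plan with a 50/50 validation/test split per fold.

    Each repeat reshuffles; folds are stratified by class by default so
    that no training partition loses a class.  Within each held-out
    fold, subjects are split at random into validation and test halves
    (stratified under the same flag).
    """
    y = np.asarray(labels)
    n = y.shape[0]
    classes, counts = np.unique(y, return_counts=True)
    if stratified and counts.min() < n_folds:
        raise ValueError("each class needs at least n_folds subjects")
    rng = np.random.default_rng(seed)
    repeats: list[list[FoldSplit]] = []
    for _ in range(n_repeats):
        fold_of = np.empty(n, dtype=int)
        if stratified:
            for cls in classes:
                idx = rng.permutation(np.flatnonzero(y == cls))
                for k, i in enumerate(idx):
                    fold_of[i] = k % n_folds
        else:
            idx = rng.permutation(n)
            for k, i in enumerate(idx):
                fold_of[i] = k % n_folds
        folds: list[FoldSplit] = []
        for f in range(n_folds):
            held = np.flatnonzero(fold_of == f)
            train = np.flatnonzero(fold_of != f)
            if stratified:
                val_parts, test_parts = [], []
                n_val = n_test = 0
                for cls in classes:
                    sub = rng.permutation(held[y[held] == cls])
                    half = len(sub) // 2
                    if len(sub) % 2:
                        # keep overall halves balanced: odd remainders go to
                        # the smaller side (coin flip on exact ties)
                        if n_val < n_test:
                            half += 1
                        elif n_val == n_test and rng.random() < 0.5:
                            half += 1
                    val_parts.append(sub[:half])
                    test_parts.append(sub[half:])
                    n_val += half
                    n_test += len(sub) - half
                val = np.sort(np.concatenate(val_parts))
                test = np.sort(np.concatenate(test_parts))
            else:
                sub = rng.permutation(held)
                val = np.sort(sub[: len(sub) // 2])
                test = np.sort(sub[len(sub) // 2:])
            folds.append(FoldSplit(train=np.sort(train), validation=val,
                                   test=test))
        repeats.append(folds)
    return CVPlan(repeats=repeats, seed=seed)


# ---------------------------------------------------------------------------
# Hyperparameter search

@dataclass
class SearchSpace:
    """Search ranges for the per-depth hyperparameter optimisation."""

    units_min: int = 10
    units_max: int = 200
    pretrain_lr_min: float = 1e-4
    pretrain_lr_max: float = 1e-1
    finetune_lr_min: float = 1e-4
    finetune_lr_max: float = 1e-1
    n_hidden_layers: int = 3

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        return {
            "units": int(rng.integers(self.units_min, self.units_max + 1)),
            "pretrain_lr": float(rng.uniform(self.pretrain_lr_min,
                                             self.pretrain_lr_max)),
            "finetune_lr": float(rng.uniform(self.finetune_lr_min,
                                             self.finetune_lr_max)),
        }

    def clip(self, point: dict[str, float]) -> dict[str, float]:
        return {
            "units": int(np.clip(round(point["units"]), self.units_min,
                                 self.units_max)),
            "pretrain_lr": float(np.clip(point["pretrain_lr"],
                                         self.pretrain_lr_min,
                                         self.pretrain_lr_max)),
            "finetune_lr": float(np.clip(point["finetune_lr"],
                                         self.finetune_lr_min,
                                         self.finetune_lr_max)),
        }

    def contains(self, point: dict[str, float]) -> bool:
        return (self.units_min <= point["units"] <= self.units_max
                and self.pretrain_lr_min <= point["pretrain_lr"] <= self.pretrain_lr_max
                and self.finetune_lr_min <= point["finetune_lr"] <= self.finetune_lr_max)


_DIMS = ("units", "pretrain_lr", "finetune_lr")
DEFAULT_MIXTURE = (0.7, 0.2, 0.1)  # parzen, annealing, random
_PARZEN_GAMMA = 0.25
_PARZEN_MIN_TRIALS = 10
_PARZEN_CANDIDATES = 20


def _kde(values: np.ndarray) -> gaussian_kde | None:
    if values.size < 2 or np.ptp(values) == 0:
        return None
    try:
        return gaussian_kde(values)
    except np.linalg.LinAlgError:
        return None


def _parzen_proposal(space: SearchSpace, trials: list[dict],
                     rng: np.random.Generator) -> dict[str, float]:
    """Density-ratio proposal: sample from the 'good' KDE, score by g/b."""
    scores = np.array([t["score"] for t in trials])
    order = np.argsort(-scores)
    n_good = max(2, int(np.ceil(_PARZEN_GAMMA * len(trials))))
    good = [trials[i] for i in order[:n_good]]
    bad = [trials[i] for i in order[n_good:]]
    spans = {
        "units": space.units_max - space.units_min,
        "pretrain_lr": space.pretrain_lr_max - space.pretrain_lr_min,
        "finetune_lr": space.finetune_lr_max - space.finetune_lr_min,
    }
    cands = []
    log_ratio = np.zeros(_PARZEN_CANDIDATES)
    for dim in _DIMS:
        gvals = np.array([t["params"][dim] for t in good], dtype=float)
        bvals = np.array([t["params"][dim] for t in bad], dtype=float)
        gk = _kde(gvals)
        bk = _kde(bvals)
        if gk is None:
            draws = gvals[rng.integers(0, len(gvals), _PARZEN_CANDIDATES)] \
                + rng.normal(0, 0.1 * spans[dim], _PARZEN_CANDIDATES)
        else:
            draws = gk.resample(_PARZEN_CANDIDATES, seed=rng)[0]
        draws = np.clip(draws, *{
            "units": (space.units_min, space.units_max),
            "pretrain_lr": (space.pretrain_lr_min, space.pretrain_lr_max),
            "finetune_lr": (space.finetune_lr_min, space.finetune_lr_max),
        }[dim])
        if gk is not None:
            log_ratio += np.log(gk(draws) + 1e-12)
        if bk is not None:
            log_ratio -= np.log(bk(draws) + 1e-12)
        cands.append(draws)
    best = int(np.argmax(log_ratio))
    point = {dim: float(cands[i][best]) for i, dim in enumerate(_DIMS)}
    return space.clip(point)


def _annealing_proposal(space: SearchSpace, trials: list[dict], t: int,
                        n_iter: int, rng: np.random.Generator
                        ) -> dict[str, float]:
    """Gaussian perturbation of the incumbent, shrinking with progress."""
    best = max(trials, key=lambda tr: tr["score"])["params"]
    scale = 0.25 * max(0.1, 1.0 - t / max(n_iter, 1))
    point = {
        "units": best["units"] + rng.normal(
            0, scale * (space.units_max - space.units_min)),
        "pretrain_lr": best["pretrain_lr"] + rng.normal(
            0, scale * (space.pretrain_lr_max - space.pretrain_lr_min)),
        "finetune_lr": best["finetune_lr"] + rng.normal(
            0, scale * (space.finetune_lr_max - space.finetune_lr_min)),
    }
    return space.clip(point)


def search(objective: Callable[[dict[str, float]], float],
           space: SearchSpace, n_iter: int = 50,
           mixture: tuple[float, float, float] = DEFAULT_MIXTURE,
           seed: int = 0) -> tuple[dict[str, float], list[dict]]:
    """Maximize ``objective`` over the space; returns (best params, trace).

    Per iteration the proposal strategy is drawn from ``mixture`` =
    (parzen, annealing, random); the first strategies fall back to
    random until enough trials have accumulated.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if abs(sum(mixture) - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    rng = np.random.default_rng(seed)
    trials: list[dict] = []
    for t in range(n_iter):
        strategy = rng.choice(3, p=mixture)
        if strategy == 0 and len(trials) >= _PARZEN_MIN_TRIALS:
            params = _parzen_proposal(space, trials, rng)
            how = "parzen"
        elif strategy == 1 and trials:
            params = _annealing_proposal(space, trials, t, n_iter, rng)
            how = "annealing"
        else:
            params = space.sample(rng)
            how = "random"
        score = float(objective(params))
        trials.append({"params": params, "score": score, "strategy": how,
                       "iteration": t})
    best = max(trials, key=lambda tr: tr["score"])
    return dict(best["params"]), trials


# ---------------------------------------------------------------------------
# Model training helpers

def train_dbn_classifier(X: np.ndarray, y: np.ndarray, units: int,
                         n_hidden_layers: int, pretrain_lr: float,
                         finetune_lr: float, seed: int,
                         pretrain_epochs: int = 10,
                         finetune_epochs: int = 200) -> FineTunedNetwork:
    """Pretrain a DBN and fine-tune the derived classifier."""
    layer_sizes = [X.shape[1]] + [units] * n_hidden_layers
    cd = CDTrainingConfig(learning_rate=pretrain_lr, rng_seed=seed,
                          epochs=pretrain_epochs)
    dbn = pretrain_dbn(X, layer_sizes, cd_config=cd)
    ft = FineTuneConfig(learning_rate=finetune_lr, rng_seed=seed,
                        epochs=finetune_epochs)
    net = initialize_network(dbn, ft)
    return fine_tune(net, X, y, ft)


def optimize_hyperparameters(train_X: np.ndarray, train_y: np.ndarray,
                             val_X: np.ndarray, val_y: np.ndarray,
                             space: SearchSpace, n_iter: int = 50,
                             mixture: tuple[float, float, float] = DEFAULT_MIXTURE,
                             seed: int = 0,
                             finetune_epochs: int = 200,
                             ) -> tuple[dict[str, float], list[dict]]:
    """Search DBN hyperparameters by validation AUC."""

    def objective(params: dict[str, float]) -> float:
        net = train_dbn_classifier(
            train_X, train_y, units=int(params["units"]),
            n_hidden_layers=space.n_hidden_layers,
            pretrain_lr=params["pretrain_lr"],
            finetune_lr=params["finetune_lr"], seed=seed,
            finetune_epochs=finetune_epochs)
        scores = np.atleast_2d(predict_proba(net, val_X))[:, 1]
        return auc_roc(scores, val_y)

    return search(objective, space, n_iter=n_iter, mixture=mixture, seed=seed)


# ---------------------------------------------------------------------------
# Reports

@dataclass
class FoldResult:
    repeat: int
    fold: int
    counts: ConfusionCounts
    metrics: dict[str, float | None]
    auc: float
    best_params: dict[str, float] | None = None
    validation_auc: float | None = None


@dataclass
class PerformanceReport:
    """Per-fold and aggregate metrics over repeats x folds."""

    folds: list[FoldResult]
    model_family: str

    def aggregate(self) -> dict[str, tuple[float, float]]:
        """Mean and sd (ddof=1) of each metric over the fold evaluations."""
        out: dict[str, tuple[float, float]] = {}
        for key in ("balanced_accuracy", "sensitivity", "specificity",
                    "error_rate"):
            vals = np.array([f.metrics[key] for f in self.folds
                             if f.metrics[key] is not None], dtype=float)
            out[key] = (float(vals.mean()),
                        float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
        aucs = np.array([f.auc for f in self.folds])
        out["auc_roc"] = (float(aucs.mean()),
                          float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0)
        return out

    def summary_rows(self) -> str:
        agg = self.aggregate()
        head = ("Classifier\tBalanced accuracy (%)\tSensitivity (%)\t"
                "Specificity (%)\tError rate (%)\tAUC-ROC")
        row = "\t".join(
            [self.model_family]
            + [f"{agg[k][0]:.2f} ± {agg[k][1]:.2f}"
               for k in ("balanced_accuracy", "sensitivity", "specificity",
                         "error_rate")]
            + [f"{agg['auc_roc'][0]:.4f} ± {agg['auc_roc'][1]:.4f}"])
        return head + "\n" + row


# ---------------------------------------------------------------------------
# Baseline SVM

def baseline_linear(train_X: np.ndarray, train_y: np.ndarray,
                    val_X: np.ndarray, val_y: np.ndarray,
                    test_X: np.ndarray, test_y: np.ndarray,
                    C_grid: Sequence[float] = C_GRID,
                    ) -> tuple[dict[str, float | None], float, float,
                               ConfusionCounts]:
    """Linear soft-margin SVM with C selected by validation AUC.

    Ties on validation AUC resolve to C = 1 when it is among the tied
    values (otherwise to the smallest tied C).  Returns (test metrics,
    test AUC, chosen C, test confusion counts).
    """
    if len(np.unique(train_y)) < 2:
        raise ValueError("baseline requires both classes in training data")
    val_scores = {}
    for C in C_grid:
        clf = SVC(kernel="linear", C=C)
        clf.fit(train_X, train_y)
        val_scores[C] = auc_roc(clf.decision_function(val_X), val_y)
    best_auc = max(val_scores.values())
    tied = [C for C, s in val_scores.items() if s >= best_auc - 1e-12]
    chosen = 1.0 if 1.0 in tied else min(tied)
    clf = SVC(kernel="linear", C=chosen)
    clf.fit(train_X, train_y)
    scores = clf.decision_function(test_X)
    preds = (scores > 0).astype(int)
    counts = ConfusionCounts.from_predictions(test_y, preds)
    return compute_metrics(counts), auc_roc(scores, test_y), chosen, counts


# ---------------------------------------------------------------------------
# Nested evaluation

def run_nested_evaluation(table: MorphometryTable, model_family: str,
                          plan: CVPlan, space: SearchSpace | None = None,
                          n_iter: int = 50, seed: int = 0,
                          finetune_epochs: int = 200,
                          ) -> tuple[PerformanceReport, list[FineTunedNetwork]]:
    """Full nested CV: per fold, search, retrain best, score the test half.

    ``model_family`` is ``"dbn"`` or ``"baseline"``.  Returns the report
    and, for the DBN family, the per-fold retrained best networks (used
    for the external-cohort evaluation); the list is empty for the
    baseline.
    """
    if model_family not in ("dbn", "baseline"):
        raise ValueError("model_family must be 'dbn' or 'baseline'")
    if space is None:
        space = SearchSpace()
    X = table.features
    y = table.binary_labels()
    results: list[FoldResult] = []
    nets: list[FineTunedNetwork] = []
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(len(plan.all_folds()))
    for (repeat, fold, split), fold_seed in zip(plan.all_folds(), fold_seeds):
        fold_seed = int(fold_seed % (2 ** 31))
        tr, va, te = split.train, split.validation, split.test
        if model_family == "baseline":
            metrics, auc, _, counts = baseline_linear(
                X[tr], y[tr], X[va], y[va], X[te], y[te])
            results.append(FoldResult(repeat, fold, counts, metrics, auc))
            continue
        best, trace = optimize_hyperparameters(
            X[tr], y[tr], X[va], y[va], space, n_iter=n_iter,
            seed=fold_seed, finetune_epochs=finetune_epochs)
        net = train_dbn_classifier(
            X[tr], y[tr], units=int(best["units"]),
            n_hidden_layers=space.n_hidden_layers,
            pretrain_lr=best["pretrain_lr"], finetune_lr=best["finetune_lr"],
            seed=fold_seed, finetune_epochs=finetune_epochs)
        scores = np.atleast_2d(predict_proba(net, X[te]))[:, 1]
        preds = predict(net, X[te])
        counts = ConfusionCounts.from_predictions(y[te], preds)
        best_val = max(t["score"] for t in trace)
        results.append(FoldResult(repeat, fold, counts,
                                  compute_metrics(counts),
                                  auc_roc(scores, y[te]),
                                  best_params=best, validation_auc=best_val))
        nets.append(net)
    return PerformanceReport(folds=results, model_family=model_family), nets


def sweep_layers(table: MorphometryTable, plan: CVPlan,
                 layer_counts: Sequence[int] = (1, 2, 3, 4, 5),
                 n_iter: int = 50, seed: int = 0,
                 finetune_epochs: int = 200) -> dict[int, tuple[float, float]]:
    """Depth sweep: mean +/- sd validation AUC per hidden-layer count.

    Reproduces the experimental design of selecting the network depth
    by repeated cross-validated search, one search per fold per depth.
    """
    X = table.features
    y = table.binary_labels()
    out: dict[int, tuple[float, float]] = {}
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(len(plan.all_folds()) * len(layer_counts))
    k = 0
    for depth in layer_counts:
        space = SearchSpace(n_hidden_layers=depth)
        vals = []
        for repeat, fold, split in plan.all_folds():
            fold_seed = int(fold_seeds[k] % (2 ** 31))
            k += 1
            _, trace = optimize_hyperparameters(
                X[split.train], y[split.train], X[split.validation],
                y[split.validation], space, n_iter=n_iter, seed=fold_seed,
                finetune_epochs=finetune_epochs)
            vals.append(max(t["score"] for t in trace))
        arr = np.array(vals)
        out[depth] = (float(arr.mean()),
                      float(arr.std(ddof=1)) if arr.size > 1 else 0.0)
    return out


def evaluate_external_cohort(nets: Sequence[FineTunedNetwork],
                             cohort: MorphometryTable | np.ndarray
                             ) -> dict[str, float]:
    """Fraction of an external cohort classified SCZ (and HC).

    Each trained network classifies every cohort subject; the reported
    fractions are the mean and sd over the networks.  The cohort must
    have been excluded from all training and search.
    """
    if isinstance(cohort, MorphometryTable):
        X = cohort.features
    else:
        X = np.asarray(cohort, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty external cohort")
    if not nets:
        raise ValueError("no trained networks supplied")
    fracs = np.array([predict(net, X).mean() for net in nets])
    return {
        "fraction_scz": float(fracs.mean()),
        "fraction_scz_sd": float(fracs.std(ddof=1)) if fracs.size > 1 else 0.0,
        "fraction_hc": float(1.0 - fracs.mean()),
    }
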