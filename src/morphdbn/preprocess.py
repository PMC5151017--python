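"""Confound removal and normalisation of morphometric features.

Each of the 113 features is regressed on age and sex (one joint
ordinary-least-squares fit of ``feature ~ 1 + age + sex`` per feature)
and replaced by its residual, then z-score normalised.  By default both
transforms are estimated across all subjects, the procedure used when
the cohort is analysed as a single sample; passing ``fit_rows``
restricted to a training fold gives a leakage-free variant in which
held-out subjects never influence the fitted coefficients or the
normalisation statistics.

The standard-deviation convention is the sample (n-1) denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import MorphometryTable


@dataclass
class PreprocessModel:
    """Per-feature confound regression and z-scoring parameters.

    ``coef`` has one row per feature: (intercept, beta_age, beta_sex).
    ``mean``/``sd`` are the residual statistics used for z-scoring,
    present only after :func:`fit_zscore`.
    """

    coef: np.ndarray
    fit_rows: np.ndarray
    feature_names: tuple[str, ...]
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "coef": self.coef.tolist(),
            "fit_rows": self.fit_rows.tolist(),
            "mean": None if self.mean is None else self.mean.tolist(),
            "sd": None if self.sd is None else self.sd.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            coef=np.asarray(payload["coef"], dtype=float),
            fit_rows=np.asarray(payload["fit_rows"], dtype=int),
            feature_names=tuple(payload["feature_names"]),
            mean=None if payload["mean"] is None else np.asarray(payload["mean"]),
            sd=None if payload["sd"] is None else np.asarray(payload["sd"]),
        )


def _design(table: MorphometryTable, rows: np.ndarray) -> np.ndarray:
    return np.column_stack([
        np.ones(len(rows)),
        table.age[rows],
        table.sex[rows].astype(float),
    ])


def fit_residualizer(table: MorphometryTable,
                     fit_rows: np.ndarray | None = None) -> PreprocessModel:
    """OLS fit of ``feature ~ 1 + age + sex`` for every feature.

    Raises on a rank-deficient design (fewer than 3 rows, constant age,
    or age collinear with sex).
    """
    if fit_rows is None:
        fit_rows = np.arange(table.n_subjects)
    fit_rows = np.asarray(fit_rows, dtype=int)
    if len(fit_rows) < 3:
        raise ValueError("need at least 3 rows to fit the confound regression")
    X = _design(table, fit_rows)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient confound design (constant or collinear age/sex)"
        )
    Y = table.features[fit_rows]
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return PreprocessModel(coef=coef.T, fit_rows=fit_rows,
                           feature_names=table.schema.canonical_order)


def apply_residualizer(model: PreprocessModel,
                       table: MorphometryTable) -> MorphometryTable:
    """Replace each feature by its residual from the fitted regression."""
    if model.feature_names != table.schema.canonical_order:
        raise ValueError("schema mismatch between model and table")
    X = _design(table, np.arange(table.n_subjects))
    predicted = X @ model.coef.T
    return table.with_features(table.features - predicted, "residualized")


def fit_zscore(model: PreprocessModel, table: MorphometryTable,
               fit_rows: np.ndarray | None = None) -> PreprocessModel:
    """Augment the model with per-feature mean/sd estimated on fit rows.

    ``table`` should hold the residualized values.  A feature with zero
    standard deviation on the fit rows is an error naming the feature.
    """
    if fit_rows is None:
        fit_rows = model.fit_rows
    fit_rows = np.asarray(fit_rows, dtype=int)
    vals = table.features[fit_rows]
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    # constant columns can carry O(eps) round-off in the mean subtraction
    zero = np.flatnonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(mean)))
    if zero.size:
        raise ValueError(
            f"zero standard deviation for feature {model.feature_names[zero[0]]!r}"
        )
    model.mean = mean
    model.sd = sd
    return model


def apply_zscore(model: PreprocessModel,
                 table: MorphometryTable) -> MorphometryTable:
    """Standardize each feature with the model's stored mean and sd."""
    if model.mean is None or model.sd is None:
        raise ValueError("model has no z-score statistics; call fit_zscore first")
    z = (table.features - model.mean) / model.sd
    return table.with_features(z, "zscored")


def preprocess_table(table: MorphometryTable,
                     fit_rows: np.ndarray | None = None
                     ) -> tuple[MorphometryTable, PreprocessModel]:
    """Residualize then z-score in one call; returns (table, model)."""
    model = fit_residualizer(table, fit_rows)
    resid = apply_residualizer(model, table)
    model = fit_zscore(model, resid)
    return apply_zscore(model, resid), model
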