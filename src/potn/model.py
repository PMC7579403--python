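"""The immunogenicity classifier: an RBF-kernel SVM over selected features.

The regularization parameter C is chosen from a small grid by
leave-one-out cross-validation on the training set; ties are broken
toward the smaller (more strongly regularized) C. The fitted model
bundles everything needed to score a raw nonamer end to end: the
propensity matrix fitted on the training data, the property tables, the
retained feature names, the scaler, and the SVM itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from . import feature_engine as fe
from .feature_engine import (
    DEFAULT_PHYSCHEM_SPEC,
    FeatureSelectionResult,
    PropensityMatrix,
    PropertyTable,
    Scaler,
)
from .peptide_io import LabeledPeptideSet

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

DEFAULT_C_GRID: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class SvmConfig:
    """SVM hyperparameters.

    ``C=None`` requests leave-one-out tuning over ``C_grid``. The kernel
    width defaults to scikit-learn's "scale" heuristic
    (1 / (n_features * Var(X))); the resolved numeric value is recorded in
    the fitted model so results are reproducible from the model file.
    """

    C: float | None = None
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma: float | str = "scale"
    class_weight: str | None = None
    seed: int = 0


def _make_svc(C: float, config: SvmConfig) -> SVC:
    # tight tolerance keeps the fit independent of row order to high precision
    return SVC(C=C, kernel="rbf", gamma=config.gamma, tol=1e-6,
               class_weight=config.class_weight, random_state=config.seed)


def loo_accuracy(X: np.ndarray, y: np.ndarray, C: float,
                 config: SvmConfig = SvmConfig()) -> float:
    """Leave-one-out accuracy: n fits on n-1 rows, one held-out prediction each."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 rows")
    correct = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = _make_svc(C, config).fit(X[mask], y[mask])
        correct += int(clf.predict(X[i:i + 1])[0] == y[i])
        mask[i] = True
    return correct / n


def tune_C(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[float] = DEFAULT_C_GRID,
    config: SvmConfig = SvmConfig(),
) -> tuple[float, dict[float, float]]:
    """Pick C from the grid by leave-one-out accuracy.

    Returns the best C (ties broken toward the smallest candidate) and the
    per-C accuracy table.
    """
    if not len(grid):
        raise ValueError("C grid must be non-empty")
    table = {float(C): loo_accuracy(X, y, C, config) for C in grid}
    best = max(sorted(table), key=lambda C: (table[C], -C))
    return best, table


@dataclass
class PredictionScore:
    peptide: str
    score: float
    probability: float | None = None


@dataclass
class PotnModel:
    """A fitted immunogenicity model, self-contained for end-to-end scoring."""

    svc: SVC
    config: SvmConfig
    scaler: Scaler
    propensity: PropensityMatrix
    tables: Mapping[str, PropertyTable]
    physchem_spec: tuple[tuple[str, int], ...]
    selection: FeatureSelectionResult
    feature_names: list[str]
    mode: str                      # "core" or "full"
    gamma_value: float             # resolved kernel width
    metadata: dict = field(default_factory=dict)
    version: int = MODEL_FORMAT_VERSION

    def _features(self, sequences: Sequence[str],
                  external: pd.DataFrame | None) -> pd.DataFrame:
        if self.mode == "full" and external is None:
            raise ValueError(
                "model was trained with external predictor columns; "
                "supply them for scoring (no silent imputation)")
        table = fe.build_feature_table(
            sequences, self.propensity, self.tables,
            spec=self.physchem_spec,
            external=external if self.mode == "full" else None)
        table = table[self.feature_names]
        if table.isna().any().any():
            bad = table.index[table.isna().any(axis=1)].tolist()
            raise ValueError(f"missing feature values for peptides {bad[:5]}")
        return self.scaler.transform(table)

    def predict_scores(
        self,
        sequences: Sequence[str],
        external: pd.DataFrame | None = None,
    ) -> list[PredictionScore]:
        """Signed decision values; larger means more likely immunogenic."""
        X = self._features(sequences, external)
        scores = self.svc.decision_function(X.to_numpy())
        return [PredictionScore(peptide=s, score=float(v))
                for s, v in zip(sequences, scores)]

    def save(self, path: str | Path) -> None:
        joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": self},
                    path)

    @classmethod
    def load(cls, path: str | Path) -> "PotnModel":
        try:
            payload = joblib.load(path)
        except Exception as exc:  # corrupt / truncated / wrong format
            raise ValueError(f"cannot read model file {path}: {exc}") from exc
        if not isinstance(payload, dict) or "format_version" not in payload:
            raise ValueError(f"{path} is not a model file")
        if payload["format_version"] > MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model file {path} has format version "
                f"{payload['format_version']}; this build reads up to "
                f"{MODEL_FORMAT_VERSION}")
        return payload["model"]


save_model = PotnModel.save
load_model = PotnModel.load


def classify(scores: Sequence[float], threshold: float = 0.0) -> np.ndarray:
    """Binarize decision values: positive iff score > threshold (strict)."""
    return (np.asarray(scores, dtype=float) > threshold).astype(int)


def train(
    features: pd.DataFrame,
    labels: Sequence[int],
    config: SvmConfig = SvmConfig(),
) -> tuple[SVC, float, dict[float, float] | None]:
    """Fit the SVM on standardized features, tuning C if not fixed.

    Returns the fitted classifier, the C used, and the per-C leave-one-out
    accuracy table (None when C was fixed).
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if features.isna().any().any():
        raise ValueError("training features contain missing values")
    X = features.to_numpy(dtype=float)
    loo_table = None
    C = config.C
    if C is None:
        C, loo_table = tune_C(X, y, config.C_grid, config)
        logger.info("leave-one-out selected C=%g (accuracies: %s)", C, loo_table)
    svc = _make_svc(C, config).fit(X, y)
    return svc, float(C), loo_table


def fit_potn(
    train_set: LabeledPeptideSet,
    external: pd.DataFrame | None = None,
    tables: Mapping[str, PropertyTable] | None = None,
    physchem_spec: Sequence[tuple[str, int]] = DEFAULT_PHYSCHEM_SPEC,
    alpha: float = 0.05,
    config: SvmConfig = SvmConfig(),
    propensity_pseudocount: float = 0.0,
) -> PotnModel:
    """End-to-end training: propensity fit, feature assembly, t-test
    selection, standardization, C tuning, and the final SVM fit.

    The propensity matrix and all selection/scaling statistics are
    computed from the training set only.
    """
    if tables is None:
        tables = fe.load_property_tables()
    matrix = fe.fit_propensity(train_set, pseudocount=propensity_pseudocount)
    mode = "full" if external is not None else "core"
    features = fe.build_feature_table(
        train_set.sequences, matrix, tables, spec=tuple(physchem_spec),
        external=external)
    if features.isna().any().any():
        raise ValueError(
            "external predictor columns do not cover the whole training set")
    selection = fe.select_features(features, train_set.labels, alpha=alpha)
    selected = selection.selected_features
    if not selected:
        raise ValueError(f"no feature passed the p < {alpha} filter")
    scaled, scaler = fe.standardize(features[selected])
    svc, C_used, loo_table = train(scaled, train_set.labels, config)
    gamma_value = float(svc._gamma)
    return PotnModel(
        svc=svc,
        config=replace(config, C=C_used),
        scaler=scaler,
        propensity=matrix,
        tables=dict(tables),
        physchem_spec=tuple(physchem_spec),
        selection=selection,
        feature_names=selected,
        mode=mode,
        gamma_value=gamma_value,
        metadata={
            "n_positive": train_set.n_positive,
            "n_negative": train_set.n_negative,
            "alpha": alpha,
            "seed": config.seed,
            "loo_accuracy_by_C": loo_table,
            "table_provenance": {k: v.provenance for k, v in tables.items()},
        },
    )
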