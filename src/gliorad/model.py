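"""Nested cross-validated L1 logistic regression for IDH-status prediction.

The in-fold pipeline is: (1) robust standardization (median/IQR), with
training-fold median imputation of flagged-missing values; (2) exclusion of
zero-variance features; (3) optional feature selection — either keeping the
nonzero-coefficient features of a preliminary L1 fit and then appending the
clinical covariates, or keeping the n features with highest univariate AUC
per modality; (4) L1-penalized logistic regression in balanced mode
(liblinear). Every statistic is computed on the training fold only.

Performance is estimated with stratified five-fold cross-validation
repeated 50 times (250 outer evaluations); hyperparameters (C, and n for
multimodal runs) are tuned in an inner stratified five-fold loop
maximizing mean inner AUC, with ties broken toward smaller C, then smaller
n (prefer stronger regularization / sparser models). The positive class is
IDH wild-type throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

__all__ = [
    "POSITIVE_LABEL",
    "HyperparameterGrid",
    "CVScheme",
    "CVResult",
    "univariate_auc",
    "RobustScaler",
    "zero_variance_filter",
    "select_features",
    "fit_l1_logistic",
    "PipelineModel",
    "stratified_folds",
    "nested_cv",
    "subgroup_evaluate",
    "design_matrix",
]

POSITIVE_LABEL = "IDH_wildtype"

SUBGROUP_FILTERS = ("none", "exclude_ring_enhancing", "female_only", "male_only")


@dataclass(frozen=True)
class HyperparameterGrid:
    n_top_per_modality: tuple[int, ...] = (3, 5, 10)
    C: tuple[float, ...] = (0.1, 0.3, 0.5, 0.8, 1.0)

    def __post_init__(self) -> None:
        if not self.C or not self.n_top_per_modality:
            raise ValueError("hyperparameter grids must be nonempty")
        if any(c <= 0 for c in self.C):
            raise ValueError("C must be positive")


@dataclass(frozen=True)
class CVScheme:
    outer_folds: int = 5
    repeats: int = 50
    inner_folds: int = 5
    base_seed: int = 0


@dataclass
class CVResult:
    """Per-split outer-test AUCs with the tuning and fit record."""

    aucs: np.ndarray
    chosen_params: list[dict]
    coefficients: list[dict]
    positive_label: str = POSITIVE_LABEL
    subgroup: str = "none"

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.aucs, ddof=1))

    def summary(self) -> dict:
        return {
            "n_splits": int(len(self.aucs)),
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "positive_label": self.positive_label,
            "subgroup": self.subgroup,
        }


def univariate_auc(values: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC of a single feature, ties credited 0.5.

    ``y`` is boolean (True = positive class). Raises on single-class input.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"both classes required (got {n_pos} positive, {n_neg} negative)")
    ranks = rankdata(values)  # average ranks -> 0.5 credit for ties
    r_pos = ranks[y].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


class RobustScaler:
    """(x - median) / IQR, statistics from the training fold only.

    Zero-IQR features are centered but not scaled (they fall to the
    zero-variance filter next). NaNs are ignored when fitting and imputed
    with the scaled training median afterwards.
    """

    def fit(self, X: np.ndarray) -> "RobustScaler":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            self.median_ = np.nanmedian(X, axis=0)
            q75 = np.nanpercentile(X, 75, axis=0)
            q25 = np.nanpercentile(X, 25, axis=0)
        self.median_ = np.where(np.isfinite(self.median_), self.median_, 0.0)
        iqr = q75 - q25
        iqr = np.where(np.isfinite(iqr), iqr, 1.0)
        self.scale_ = np.where(iqr > 0, iqr, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.median_) / self.scale_
        return np.where(np.isfinite(Z), Z, 0.0)  # median imputation post-scale


def zero_variance_filter(X_train: np.ndarray) -> np.ndarray:
    """Boolean column keep-mask: drops training-constant columns."""
    keep = np.nanstd(X_train, axis=0) > 0
    if not keep.any():
        raise RuntimeError("all features have zero training variance")
    return keep


def fit_l1_logistic(X: np.ndarray, y: np.ndarray, C: float,
                    balanced: bool = True) -> LogisticRegression:
    """Balanced L1 logistic regression (liblinear); unpenalized intercept.

    Non-convergence is logged and the best iterate returned.
    """
    classes = np.unique(y)
    if len(classes) < 2 or min(np.sum(y == c) for c in classes) < 2:
        raise ValueError("need at least 2 samples per class")
    model = LogisticRegression(
        penalty="l1",
        C=C,
        solver="liblinear",
        class_weight="balanced" if balanced else None,
        random_state=0,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(X, y.astype(int))
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            logger.warning("L1 logistic regression did not converge (C=%g); "
                           "returning best iterate", C)
    return model


def _modality_of(column: str) -> str | None:
    return column.split("__")[0] if "__" in column else None


def select_features(
    X_train: np.ndarray,
    y_train: np.ndarray,
    columns: list[str],
    mode: str,
    clinical_cols: list[str] | None = None,
    n_top: int | None = None,
    C: float = 1.0,
) -> list[str]:
    """Return the retained column names for the given selection mode.

    ``l1_nonzero_then_add_clinical``: preliminary balanced L1 fit on the
    radiomic columns; keep nonzero-coefficient columns, then append the
    clinical columns.  ``top_n_per_modality``: per modality prefix keep the
    ``n_top`` columns with highest orientation-invariant univariate AUC
    score |AUC - 0.5| (n larger than a modality's column count keeps them
    all).  ``none``: keep everything.
    """
    clinical_cols = list(clinical_cols or [])
    radiomic = [c for c in columns if c not in clinical_cols]
    if mode == "none":
        return list(columns)
    if mode == "l1_nonzero_then_add_clinical":
        idx = [columns.index(c) for c in radiomic]
        model = fit_l1_logistic(X_train[:, idx], y_train, C=C)
        nonzero = [radiomic[j] for j in range(len(radiomic)) if model.coef_[0, j] != 0]
        return nonzero + clinical_cols
    if mode == "top_n_per_modality":
        if n_top is None:
            raise ValueError("top_n_per_modality requires n_top")
        by_modality: dict[str, list[str]] = {}
        for c in radiomic:
            m = _modality_of(c)
            if m is not None:
                by_modality.setdefault(m, []).append(c)
        if not by_modality:
            raise ValueError("no modality-prefixed columns for top-n selection")
        selected: list[str] = []
        for m, cols in by_modality.items():
            scores = [
                abs(univariate_auc(X_train[:, columns.index(c)], y_train) - 0.5)
                for c in cols
            ]
            order = np.argsort(-np.asarray(scores), kind="stable")
            selected.extend(cols[j] for j in order[: min(n_top, len(cols))])
        return selected + clinical_cols
    raise ValueError(f"unknown selection mode {mode!r}")


class PipelineModel:
    """The 4-step in-fold pipeline, fit on training rows only."""

    def __init__(self, columns: list[str], mode: str = "none",
                 clinical_cols: list[str] | None = None,
                 n_top: int | None = None, C: float = 1.0):
        self.columns = list(columns)
        self.mode = mode
        self.clinical_cols = list(clinical_cols or [])
        self.n_top = n_top
        self.C = C

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PipelineModel":
        self.scaler_ = RobustScaler().fit(X)
        Z = self.scaler_.transform(X)
        self.keep_ = zero_variance_filter(Z)
        kept_cols = [c for c, k in zip(self.columns, self.keep_) if k]
        Zk = Z[:, self.keep_]
        clinical = [c for c in self.clinical_cols if c in kept_cols]
        self.selected_ = select_features(
            Zk, y, kept_cols, self.mode, clinical, self.n_top, self.C
        )
        self.sel_idx_ = [kept_cols.index(c) for c in self.selected_]
        if not self.sel_idx_:  # heavy penalty emptied the model: intercept only
            self.model_ = None
            return self
        self.model_ = fit_l1_logistic(Zk[:, self.sel_idx_], y, self.C)
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler_.transform(X)[:, self.keep_]
        if self.model_ is None:
            return np.zeros(len(X))
        return self.model_.decision_function(Z[:, self.sel_idx_])

    def coefficients(self) -> dict[str, float]:
        if self.model_ is None:
            return {}
        return {c: float(v) for c, v in zip(self.selected_, self.model_.coef_[0])}


def stratified_folds(y: np.ndarray, n_folds: int,
                     rng: np.random.Generator) -> list[np.ndarray]:
    """Deterministic stratified fold assignment; each fold holds >= 1 sample
    of each class (error otherwise, naming the class counts)."""
    y = np.asarray(y, dtype=bool)
    counts = (int((~y).sum()), int(y.sum()))
    if min(counts) < n_folds:
        raise ValueError(
            f"stratification infeasible: class counts {counts} with {n_folds} folds"
        )
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            folds[j % n_folds].append(int(i))
    return [np.sort(np.array(f)) for f in folds]


def _candidate_grid(mode: str, grid: HyperparameterGrid) -> list[dict]:
    # sorted so the first optimum encountered is the smallest C, then n
    if mode == "top_n_per_modality":
        return [
            {"C": C, "n_top": n}
            for C in sorted(grid.C)
            for n in sorted(grid.n_top_per_modality)
        ]
    return [{"C": C} for C in sorted(grid.C)]


def _drop_mostly_missing(X: pd.DataFrame, max_missing_frac: float = 0.2) -> pd.DataFrame:
    frac = X.isna().mean()
    return X.loc[:, frac <= max_missing_frac]


def nested_cv(
    features: pd.DataFrame,
    feature_cols: list[str],
    grid: HyperparameterGrid = HyperparameterGrid(),
    scheme: CVScheme = CVScheme(),
    selection_mode: str = "none",
    clinical_cols: list[str] | None = None,
    target_col: str = "label",
    subgroup: str = "none",
) -> CVResult:
    """Stratified 5x50 nested cross-validation of the full pipeline.

    Repeat ``r`` uses seed ``base_seed + r`` for its outer split, so any
    single repeat is independently reproducible. Returns one test AUC per
    outer split (outer_folds x repeats in total) with the chosen
    hyperparameters and fitted coefficients per split.
    """
    clinical_cols = list(clinical_cols or [])
    cols = list(feature_cols) + [c for c in clinical_cols if c not in feature_cols]
    Xdf = _drop_mostly_missing(features[cols])
    cols = list(Xdf.columns)
    X = Xdf.to_numpy(dtype=float)
    y = (features[target_col] == POSITIVE_LABEL).to_numpy()

    aucs: list[float] = []
    chosen: list[dict] = []
    coefs: list[dict] = []
    candidates = _candidate_grid(selection_mode, grid)
    for r in range(scheme.repeats):
        outer = stratified_folds(y, scheme.outer_folds,
                                 np.random.default_rng(scheme.base_seed + r))
        for k, test_idx in enumerate(outer):
            train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
            X_tr, y_tr = X[train_idx], y[train_idx]
            if len(candidates) > 1:
                best = None
                inner = stratified_folds(
                    y_tr, scheme.inner_folds,
                    np.random.default_rng([scheme.base_seed + r, k]),
                )
                for cand in candidates:
                    inner_aucs = []
                    for v_idx in inner:
                        t_idx = np.setdiff1d(np.arange(len(y_tr)), v_idx)
                        m = PipelineModel(cols, selection_mode, clinical_cols,
                                          cand.get("n_top"), cand["C"])
                        m.fit(X_tr[t_idx], y_tr[t_idx])
                        inner_aucs.append(
                            univariate_auc(m.decision_scores(X_tr[v_idx]), y_tr[v_idx])
                        )
                    score = float(np.mean(inner_aucs))
                    if best is None or score > best[0]:  # ties keep first = smallest
                        best = (score, cand)
                params = best[1]
            else:
                params = candidates[0]
            final = PipelineModel(cols, selection_mode, clinical_cols,
                                  params.get("n_top"), params["C"])
            final.fit(X_tr, y_tr)
            aucs.append(univariate_auc(final.decision_scores(X[test_idx]), y[test_idx]))
            chosen.append(dict(params))
            coefs.append(final.coefficients())
    return CVResult(np.asarray(aucs), chosen, coefs, subgroup=subgroup)


def subgroup_evaluate(
    features: pd.DataFrame,
    subgroup: str,
    feature_cols: list[str],
    min_per_class: int = 5,
    **kwargs,
) -> CVResult:
    """Re-run nested CV on a cohort filter (non-ring-enhancing, or one sex)."""
    if subgroup not in SUBGROUP_FILTERS:
        raise ValueError(f"unknown subgroup filter {subgroup!r}; expected {SUBGROUP_FILTERS}")
    if subgroup == "exclude_ring_enhancing":
        rows = features[~features["ring_enhancing"].astype(bool)]
    elif subgroup == "female_only":
        rows = features[features["sex"] == "f"]
    elif subgroup == "male_only":
        rows = features[features["sex"] == "m"]
    else:
        rows = features
    y = rows["label"] == POSITIVE_LABEL
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if min(n_pos, n_neg) < min_per_class:
        raise ValueError(
            f"subgroup {subgroup!r} too small: {n_pos} wild-type, {n_neg} mutant"
        )
    return nested_cv(rows.reset_index(drop=True), feature_cols,
                     subgroup=subgroup, **kwargs)


def design_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Numeric copy of a feature table: sex encoded as ``sex_m`` in {0, 1}."""
    out = features.copy()
    if "sex" in out.columns:
        out["sex_m"] = (out["sex"] == "m").astype(float)
    if "age_years" in out.columns:
        out["age_years"] = out["age_years"].astype(float)
    return out
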