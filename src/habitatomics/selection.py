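"""Feature selection and radscore construction.

The selection chain, fitted on training data only:

1. min-max scale each feature to [0, 1] using train-set bounds (test data
   pass through the same bounds unclamped);
2. Spearman redundancy filter: among any pair with |rho| > 0.9, drop the
   feature with the larger mean absolute correlation to the remainder;
3. LASSO with 5-fold cross-validation (mean-squared-error loss on the
   binary grade label; logistic deviance available as an option), the
   penalty chosen to minimize mean CV loss over a log-spaced path;
4. radscore = intercept + sum of selected features times coefficients;
5. Youden-index cutoff on training radscores dichotomizes patients into
   high-risk (score >= cutoff) and low-risk groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.linear_model import LassoCV, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "RadscoreModel",
    "normalize_minmax",
    "spearman_redundancy_filter",
    "lasso_cv",
    "lasso_path_coefficients",
    "LassoResult",
    "radscore",
    "youden_cutoff",
    "fit_radscore",
]


@dataclass
class RadscoreModel:
    """A fitted radscore: selected features, LASSO weights and risk cutoff."""

    selected_features: list[str]
    coefficients: np.ndarray
    intercept: float
    lambda_selected: float
    #: per-feature (min, max) train-set normalization bounds
    bounds: dict[str, tuple[float, float]]
    cutoff: float | None = None

    def scale(self, table: pd.DataFrame) -> pd.DataFrame:
        """Apply the stored train-set min-max bounds (no clamping)."""
        out = table.copy()
        for c, (lo, hi) in self.bounds.items():
            if c not in out.columns:
                continue
            out[c] = 0.0 if hi == lo else (out[c] - lo) / (hi - lo)
        return out

    def score(self, table: pd.DataFrame, scaled: bool = False) -> pd.Series:
        """Radscore per row; ``table`` holds raw features unless ``scaled``."""
        missing = [f for f in self.selected_features if f not in table.columns]
        if missing:
            raise KeyError(f"missing selected feature(s): {', '.join(missing)}")
        x = table if scaled else self.scale(table)
        vals = x[self.selected_features].to_numpy(dtype=float)
        return pd.Series(
            self.intercept + vals @ self.coefficients, index=table.index, name="radscore"
        )

    def risk_group(self, scores: pd.Series) -> pd.Series:
        if self.cutoff is None:
            raise ValueError("no cutoff fitted")
        return pd.Series(
            np.where(scores >= self.cutoff, "high_risk", "low_risk"),
            index=scores.index,
            name="risk_group",
        )


def normalize_minmax(
    train: pd.DataFrame, *apply_to: pd.DataFrame
) -> tuple[dict[str, tuple[float, float]], pd.DataFrame, list[pd.DataFrame]]:
    """Scale features to [0,1] by train-set min/max; apply bounds elsewhere.

    Constant train columns map to 0 (with a warning). Values outside the
    train range are deliberately not clamped.
    """
    if train.empty:
        raise ValueError("train table is empty")
    bounds: dict[str, tuple[float, float]] = {}
    for c in train.columns:
        lo, hi = float(train[c].min()), float(train[c].max())
        bounds[c] = (lo, hi)
        if hi == lo:
            warnings.warn(f"constant training column {c!r}; scaled to 0")

    def _apply(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c, (lo, hi) in bounds.items():
            if c in out.columns:
                out[c] = 0.0 if hi == lo else (out[c] - lo) / (hi - lo)
        return out

    return bounds, _apply(train), [_apply(df) for df in apply_to]


def spearman_redundancy_filter(
    table: pd.DataFrame, r_threshold: float = 0.9
) -> list[str]:
    """Drop one of each feature pair with |Spearman rho| > threshold.

    Features are processed in sorted-name order; the victim of a redundant
    pair is the feature with the larger mean absolute correlation to all
    other retained features (ties drop the lexicographically later name),
    making the output deterministic and row-order independent.
    """
    cols = sorted(table.columns)
    if len(cols) < 2:
        return cols
    mat = table[cols].to_numpy(dtype=float)
    rho = spearmanr(mat).statistic
    rho = np.atleast_2d(rho)
    rho = np.nan_to_num(np.abs(rho), nan=0.0)
    np.fill_diagonal(rho, 0.0)

    retained = list(cols)
    idx = {c: i for i, c in enumerate(cols)}
    while True:
        victim = None
        for a_pos in range(len(retained)):
            for b_pos in range(a_pos + 1, len(retained)):
                a, b = retained[a_pos], retained[b_pos]
                if rho[idx[a], idx[b]] > r_threshold:
                    others = [idx[c] for c in retained]
                    mean_a = rho[idx[a], others].sum() / max(len(others) - 1, 1)
                    mean_b = rho[idx[b], others].sum() / max(len(others) - 1, 1)
                    victim = b if mean_b >= mean_a else a
                    break
            if victim:
                break
        if victim is None:
            return retained
        retained.remove(victim)


def lasso_path_coefficients(
    X: np.ndarray,
    y: np.ndarray,
    n_lambdas: int = 100,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Coefficients along the full penalty path on centered data.

    Returns (alphas descending from lambda_max, coefficients with shape
    (n_features, n_alphas), feature means, label mean). The path starts at
    the smallest penalty that zeroes every coefficient.
    """
    from sklearn.linear_model import lasso_path

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    alphas, coefs, _ = lasso_path(Xc, yc, alphas=n_lambdas, tol=tol)
    return alphas, coefs, x_mean, y_mean


@dataclass
class LassoResult:
    alphas: np.ndarray
    mean_cv_loss: np.ndarray
    alpha_selected: float
    coefficients: np.ndarray
    intercept: float
    feature_names: list[str] = field(default_factory=list)

    @property
    def selected_features(self) -> list[str]:
        return [f for f, c in zip(self.feature_names, self.coefficients) if c != 0.0]


def lasso_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 100,
    loss: str = "mse",
) -> LassoResult:
    """LASSO over a log-spaced penalty path with stratified K-fold CV.

    ``loss='mse'`` is plain LASSO on the 0/1 label (penalty path starts at
    the smallest lambda zeroing every coefficient); ``loss='logistic'``
    uses L1-penalized logistic regression. The selected penalty minimizes
    the mean cross-validated loss, and the returned coefficients are the
    full-training-data fit at that penalty. Folds shrink (to >= 2) when
    the minority class is smaller than ``folds``.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("y must contain both classes")
    k = min(folds, int(counts.min()))
    if k < folds:
        warnings.warn(f"reducing CV folds from {folds} to {k} (minority class size)")
    k = max(k, 2)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    yf = y.astype(float)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xa = np.asarray(X, dtype=float)

    if loss == "mse":
        model = LassoCV(
            alphas=n_lambdas, cv=splits, tol=1e-10, max_iter=200000
        ).fit(Xa, yf)
        return LassoResult(
            alphas=model.alphas_,
            mean_cv_loss=model.mse_path_.mean(axis=1),
            alpha_selected=float(model.alpha_),
            coefficients=model.coef_.copy(),
            intercept=float(model.intercept_),
            feature_names=names,
        )
    if loss == "logistic":
        model = LogisticRegressionCV(
            Cs=n_lambdas,
            cv=splits,
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            max_iter=5000,
        ).fit(Xa, y)
        cs = model.Cs_
        scores = -np.mean(list(model.scores_.values())[0], axis=0)
        return LassoResult(
            alphas=1.0 / cs,
            mean_cv_loss=scores,
            alpha_selected=float(1.0 / model.C_[0]),
            coefficients=model.coef_.ravel().copy(),
            intercept=float(model.intercept_[0]),
            feature_names=names,
        )
    raise ValueError("loss must be 'mse' or 'logistic'")


def radscore(model: RadscoreModel, x: pd.Series | pd.DataFrame) -> float | pd.Series:
    """Radscore for one (scaled) feature row or table: intercept + x . coef."""
    if isinstance(x, pd.Series):
        return float(model.score(x.to_frame().T, scaled=True).iloc[0])
    return model.score(x, scaled=True)


def youden_cutoff(scores, labels) -> tuple[float, float, float, float]:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints of adjacent sorted unique scores;
    ties in J break toward the lower cutoff. The classification rule is
    high-risk iff score >= cutoff. Returns (cutoff, sensitivity,
    specificity, J).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        cands = np.array([uniq[0]])
    else:
        cands = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best = None
    for c in cands:  # ascending: first max wins -> lower cutoff on ties
        pred = scores >= c
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[3] + 1e-15:
            best = (float(c), float(sens), float(spec), float(j))
    assert best is not None
    return best


def fit_radscore(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    spearman_threshold: float = 0.9,
    loss: str = "mse",
) -> tuple[RadscoreModel, pd.Series]:
    """Full training-only selection chain; returns the model and train scores."""
    bounds, scaled, _ = normalize_minmax(X_train)
    keep = spearman_redundancy_filter(scaled, spearman_threshold)
    lres = lasso_cv(scaled[keep], y_train, folds=folds, seed=seed, loss=loss)
    sel = lres.selected_features
    coefs = np.array(
        [lres.coefficients[lres.feature_names.index(f)] for f in sel], dtype=float
    )
    model = RadscoreModel(
        selected_features=sel,
        coefficients=coefs,
        intercept=lres.intercept,
        lambda_selected=lres.alpha_selected,
        bounds={f: bounds[f] for f in bounds},
    )
    train_scores = model.score(X_train)
    cutoff, _, _, _ = youden_cutoff(train_scores.to_numpy(), y_train)
    model.cutoff = cutoff
    return model, train_scores
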