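"""Random-forest regression of convergence strength on similarity features.

Features: BP/CC/MF semantic similarity, brain expression correlation,
number of knockout genes, and cell type (one-hot).  Defaults follow the
classic regression-forest convention: 500 trees, mtry = ceil(p/3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

NUMERIC_FEATURES = ["bp_score", "cc_score", "mf_score", "brain_expr_corr", "n_kos"]


@dataclass
class PredictorMetrics:
    pct_var_explained: float
    rmse: float
    pearson_r: float
    pearson_p: float = float("nan")
    importances: pd.DataFrame | None = None  # index feature; pct_inc_mse, node_purity
    degenerate: bool = False


@dataclass
class ConvergenceModel:
    """Fitted forest plus the feature schema needed to apply it."""

    forest: RandomForestRegressor
    feature_columns: list[str]
    cell_levels: list[str]
    medians: pd.Series
    train_target_range: tuple[float, float]
    level: str = "gene"
    seed: int | None = None
    _train_index: pd.Index | None = field(default=None, repr=False)


def _encode(data: pd.DataFrame, cell_levels: list[str]) -> pd.DataFrame:
    unknown = set(data["cell_type"]) - set(cell_levels)
    if unknown:
        raise ValueError(f"unknown cell_type level(s): {sorted(unknown)}")
    x = data[NUMERIC_FEATURES].astype(float).copy()
    for level in cell_levels:
        x[f"cell_type={level}"] = (data["cell_type"] == level).astype(float)
    return x


def train_convergence_model(
    data: pd.DataFrame,
    train_frac: float = 0.70,
    n_trees: int = 500,
    seed: int | None = None,
    level: str = "gene",
) -> tuple[ConvergenceModel, PredictorMetrics]:
    """Train the convergence forest on a feature table.

    ``data`` needs columns ``bp_score, cc_score, mf_score, brain_expr_corr,
    n_kos, cell_type, convergence``; rows with missing features are refused
    for training.  The split is seeded and stratified by cell type; metrics
    report out-of-bag %variance explained plus held-out RMSE/Pearson r and
    permutation (pct_inc_mse) and impurity (node_purity) importances.
    """
    required = NUMERIC_FEATURES + ["cell_type", "convergence"]
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if data[NUMERIC_FEATURES + ["convergence"]].isna().any().any():
        raise ValueError("training rows must not contain missing features")
    if len(data) < 30:
        raise ValueError("need >= 30 rows to train")

    cell_levels = sorted(data["cell_type"].unique())
    strat = data["cell_type"] if data["cell_type"].value_counts().min() >= 2 else None
    train, test = train_test_split(
        data, train_size=train_frac, random_state=seed, stratify=strat
    )

    x_train = _encode(train, cell_levels)
    y_train = train["convergence"].to_numpy(float)
    degenerate = bool(np.ptp(y_train) == 0)
    if degenerate:
        logger.warning("constant training target; model flagged degenerate")

    p = x_train.shape[1]
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, int(np.ceil(p / 3))),
        oob_score=not degenerate,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(x_train.to_numpy(), y_train)

    model = ConvergenceModel(
        forest=forest,
        feature_columns=list(x_train.columns),
        cell_levels=cell_levels,
        medians=x_train.median(),
        train_target_range=(float(y_train.min()), float(y_train.max())),
        level=level,
        seed=seed,
        _train_index=train.index,
    )

    metrics = evaluate_model(model, test)
    metrics.degenerate = degenerate
    metrics.pct_var_explained = (
        100.0 * forest.oob_score_ if not degenerate else 0.0
    )

    x_test = _encode(test, cell_levels)
    y_test = test["convergence"].to_numpy(float)
    perm = permutation_importance(
        forest, x_test.to_numpy(), y_test, n_repeats=10, random_state=seed,
        scoring="neg_mean_squared_error",
    )
    base_mse = float(np.mean((forest.predict(x_test.to_numpy()) - y_test) ** 2))
    denom = base_mse if base_mse > 0 else 1.0
    metrics.importances = pd.DataFrame(
        {
            "pct_inc_mse": 100.0 * perm.importances_mean / denom,
            "node_purity": forest.feature_importances_,
        },
        index=x_train.columns,
    )
    return model, metrics


def evaluate_model(model: ConvergenceModel, holdout: pd.DataFrame) -> PredictorMetrics:
    """RMSE and Pearson r (with two-sided p) of predictions on a holdout set."""
    if model._train_index is not None:
        overlap = holdout.index.intersection(model._train_index)
        if len(overlap):
            logger.warning("%d holdout rows overlap the training set", len(overlap))
    y = holdout["convergence"].to_numpy(float)
    pred = predict_convergence(model, holdout)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    if len(y) < 3 or np.std(y) == 0 or np.std(pred) == 0:
        r, pv = float("nan"), float("nan")
    else:
        res = stats.pearsonr(pred, y)
        r, pv = float(res.statistic), float(res.pvalue)
    return PredictorMetrics(
        pct_var_explained=float("nan"), rmse=rmse, pearson_r=r, pearson_p=pv
    )


def predict_convergence(model: ConvergenceModel, features: pd.DataFrame) -> np.ndarray:
    """Predict convergence for feature rows; NaNs imputed by training medians."""
    x = _encode(features, model.cell_levels)
    if x.isna().any().any():
        logger.info("imputing missing features with training medians")
        x = x.fillna(model.medians)
    return model.forest.predict(x[model.feature_columns].to_numpy())
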