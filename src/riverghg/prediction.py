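"""Random-forest learning and evaluation of water-quality/GHG responses.

Implements the reconstruction protocol: a single random 70/30 train/test
split over all site x date rows, mtry (``max_features``) tuned by 10-fold
cross-validated MAE over a grid of 10 values, a fixed seed (default 142),
natural-log transformation of skewed responses with plain exponential
back-transform, and evaluation by test R2, MAE, MAE as % of the observed
mean, and per-site Kling-Gupta efficiency. Daily-trained models are then
applied to annual-mean predictor tables to reconstruct per-catchment annual
states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold

from .synthetic_data import PREDICTOR_COLUMNS

__all__ = [
    "ModelSpec",
    "FittedModel",
    "PerformanceReport",
    "split_train_test",
    "tune_and_train",
    "kge",
    "evaluate",
    "reconstruct_annual",
    "LOG_EXEMPT_RESPONSES",
]

#: Responses modeled on their natural scale; everything else is log-transformed.
LOG_EXEMPT_RESPONSES = {"DO", "pH", "water_temperature"}

#: Remote-sensing feature set used by the learners (land use is *not* a feature).
DEFAULT_FEATURES = [c for c in PREDICTOR_COLUMNS if c != "precipitation"]


@dataclass
class ModelSpec:
    """Training protocol for one response."""

    response_name: str
    log_transform: bool | None = None  # None: infer from LOG_EXEMPT_RESPONSES
    train_fraction: float = 0.70
    cv_folds: int = 10
    mtry_grid_size: int = 10
    seed: int = 142
    n_estimators: int = 150
    features: list[str] = field(default_factory=lambda: list(DEFAULT_FEATURES))

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.log_transform is None:
            self.log_transform = self.response_name not in LOG_EXEMPT_RESPONSES


@dataclass
class FittedModel:
    spec: ModelSpec
    estimator: RandomForestRegressor
    mtry: int
    features: list[str]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Predict on the natural response scale (exp back-transform if logged)."""
        missing = [c for c in self.features if c not in table.columns]
        if missing:
            raise ValueError(f"missing predictor columns: {missing}")
        raw = self.estimator.predict(table[self.features].to_numpy())
        return np.exp(raw) if self.spec.log_transform else raw

    def predict_model_scale(self, table: pd.DataFrame) -> np.ndarray:
        raw = self.estimator.predict(table[self.features].to_numpy())
        return raw


@dataclass
class PerformanceReport:
    """Held-out-test skill of one response model.

    ``r2_test`` is computed on the model (possibly log) scale; MAE is on the
    natural scale, and ``mae_pct_of_mean`` expresses it relative to the
    observed test mean. Per-site KGE is computed on the natural scale for
    sites with at least two test observations.
    """

    response_name: str
    r2_test: float
    mae_test: float
    mae_pct_of_mean: float
    kge_per_site: dict[str, float]

    @property
    def kge_median(self) -> float:
        if not self.kge_per_site:
            return float("nan")
        return float(np.median(list(self.kge_per_site.values())))


def split_train_test(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random row partition into train/test, reproducible for a fixed seed.

    The split ignores site and date structure (rows are exchangeable), and
    train/test sizes are within one row of the configured fraction.
    """
    if len(table) == 0:
        raise ValueError("cannot split an empty table")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(table))
    n_train = round(spec.train_fraction * len(table))
    train = table.iloc[np.sort(perm[:n_train])]
    test = table.iloc[np.sort(perm[n_train:])]
    return train, test


def _model_xy(table: pd.DataFrame, spec: ModelSpec):
    missing = [c for c in spec.features if c not in table.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    y = table[spec.response_name]
    if not pd.api.types.is_numeric_dtype(y):
        raise ValueError(f"response {spec.response_name!r} is not numeric")
    y = y.to_numpy(dtype=float)
    if spec.log_transform:
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive response values")
        y = np.log(y)
    return table[spec.features].to_numpy(dtype=float), y


def _mtry_grid(n_features: int, size: int) -> list[int]:
    """``size`` evenly spaced integers from 2 to the number of features."""
    lo = min(2, n_features)
    return sorted(set(np.linspace(lo, n_features, size).round().astype(int)))


def tune_and_train(train: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Fit a random forest with mtry chosen by cross-validated MAE."""
    if len(train) < spec.cv_folds:
        raise ValueError(
            f"need at least {spec.cv_folds} rows for {spec.cv_folds}-fold CV, got {len(train)}"
        )
    x, y = _model_xy(train, spec)
    grid = _mtry_grid(x.shape[1], spec.mtry_grid_size)
    search = GridSearchCV(
        RandomForestRegressor(
            n_estimators=spec.n_estimators, random_state=spec.seed, n_jobs=1
        ),
        param_grid={"max_features": grid},
        scoring="neg_mean_absolute_error",
        cv=KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed),
        refit=True,
    )
    search.fit(x, y)
    return FittedModel(
        spec=spec,
        estimator=search.best_estimator_,
        mtry=int(search.best_params_["max_features"]),
        features=list(spec.features),
    )


def kge(observed, predicted) -> float:
    """Kling-Gupta efficiency (2009 form): 1 is perfect agreement.

    KGE = 1 - sqrt((r-1)^2 + (alpha-1)^2 + (beta-1)^2) with r the Pearson
    correlation, alpha the SD ratio predicted/observed and beta the mean
    ratio. Undefined (ValueError) when the observed series has zero variance
    or zero mean.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need equal-length series of at least 2 points")
    sd_obs = obs.std(ddof=1)
    if sd_obs == 0 or obs.mean() == 0:
        raise ValueError("KGE undefined for constant or zero-mean observations")
    sd_pred = pred.std(ddof=1)
    if sd_pred == 0:
        r = 0.0  # correlation undefined for a constant prediction; no linear skill
    else:
        r = float(np.corrcoef(obs, pred)[0, 1])
    alpha = sd_pred / sd_obs
    beta = pred.mean() / obs.mean()
    return float(1.0 - np.sqrt((r - 1.0) ** 2 + (alpha - 1.0) ** 2 + (beta - 1.0) ** 2))


def kge_2012(observed, predicted) -> float:
    """KGE with the variability term as a ratio of coefficients of variation."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.std(ddof=1) == 0 or obs.mean() == 0 or pred.mean() == 0:
        raise ValueError("KGE-2012 undefined for constant or zero-mean series")
    r = float(np.corrcoef(obs, pred)[0, 1]) if pred.std(ddof=1) > 0 else 0.0
    gamma = (pred.std(ddof=1) / pred.mean()) / (obs.std(ddof=1) / obs.mean())
    beta = pred.mean() / obs.mean()
    return float(1.0 - np.sqrt((r - 1.0) ** 2 + (gamma - 1.0) ** 2 + (beta - 1.0) ** 2))


def evaluate(
    model: FittedModel, test: pd.DataFrame, site_column: str = "catchment_id"
) -> PerformanceReport:
    """Score a fitted model on a held-out table."""
    if len(test) == 0:
        raise ValueError("empty test set")
    spec = model.spec
    obs_natural = test[spec.response_name].to_numpy(dtype=float)
    pred_natural = model.predict(test)
    if spec.log_transform:
        r2 = r2_score(np.log(obs_natural), model.predict_model_scale(test))
    else:
        r2 = r2_score(obs_natural, pred_natural)
    mae = mean_absolute_error(obs_natural, pred_natural)
    mean_obs = obs_natural.mean()
    mae_pct = 100.0 * mae / mean_obs if mean_obs != 0 else float("nan")

    kge_per_site: dict[str, float] = {}
    if site_column in test.columns:
        pred_series = pd.Series(pred_natural, index=test.index)
        for site, group in test.groupby(site_column, observed=True):
            if len(group) < 2:
                continue
            obs_g = group[spec.response_name].to_numpy(dtype=float)
            if obs_g.std(ddof=1) == 0 or obs_g.mean() == 0:
                continue
            kge_per_site[str(site)] = kge(obs_g, pred_series.loc[group.index].to_numpy())
    return PerformanceReport(
        response_name=spec.response_name,
        r2_test=float(r2),
        mae_test=float(mae),
        mae_pct_of_mean=float(mae_pct),
        kge_per_site=kge_per_site,
    )


def reconstruct_annual(
    models: dict[str, FittedModel],
    annual_predictors: pd.DataFrame,
    years: tuple[int, int] = (2002, 2022),
) -> pd.DataFrame:
    """Predict annual states for every catchment x year x response.

    ``annual_predictors`` holds one row per (catchment_id, year) of annual
    catchment-mean predictors. Returns a tidy frame (catchment_id, year,
    response, value) with log-modeled responses back-transformed to the
    natural scale (hence strictly positive).
    """
    mask = annual_predictors["year"].between(*years)
    table = annual_predictors.loc[mask]
    frames = []
    for name, model in models.items():
        frames.append(
            pd.DataFrame(
                {
                    "catchment_id": table["catchment_id"].to_numpy(),
                    "year": table["year"].to_numpy(),
                    "response": name,
                    "value": model.predict(table),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
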