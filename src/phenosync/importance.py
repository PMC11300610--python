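"""Relative importance of biome, site, species and study year for peak timing.

A random-forest regression of peak day of year on the categorical
predictors, with importance measured as %IncMSE: the mean percent increase
in out-of-bag (OOB) mean squared error when a predictor's values are
permuted.  Categorical predictors are one-hot encoded for the learner, but
permutation is applied to all of a predictor's columns jointly (the same
row permutation), so "site" remains one predictor regardless of how many
levels it has.

Model quality is reported as the OOB percent variance explained, train/test
R² on an 80/20 split, test RMSE, and repeated-k-fold cross-validated RMSE/R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import _generate_unsampled_indices, _get_n_samples_bootstrap
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import RepeatedKFold, train_test_split

__all__ = ["ImportanceResult", "run_importance"]

PREDICTORS = ("biome", "site_id", "species", "year")


@dataclass
class ImportanceResult:
    importance: dict[str, float]  # predictor -> %IncMSE
    variance_explained: float  # OOB, percent
    r2_train: float
    r2_test: float
    rmse_test: float
    cv_rmse: float | None = None
    cv_r2: float | None = None
    n_records: int = 0
    dropped_predictors: tuple[str, ...] = field(default_factory=tuple)

    @property
    def ranking(self) -> list[str]:
        return sorted(self.importance, key=self.importance.get, reverse=True)


def _encode(records: pd.DataFrame, predictors: list[str]):
    """One-hot encode; return (X, mapping predictor -> column index array)."""
    blocks = []
    col_groups: dict[str, np.ndarray] = {}
    start = 0
    for p in predictors:
        dummies = pd.get_dummies(records[p].astype(str), prefix=p, dtype=float)
        blocks.append(dummies.values)
        col_groups[p] = np.arange(start, start + dummies.shape[1])
        start += dummies.shape[1]
    return np.hstack(blocks), col_groups


def _oob_perm_importance(
    forest: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    col_groups: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[dict[str, float], float]:
    """Per-tree OOB permutation %IncMSE and aggregate OOB variance explained."""
    n = len(y)
    n_boot = _get_n_samples_bootstrap(n, forest.max_samples, None)
    inc = {p: [] for p in col_groups}
    oob_pred_sum = np.zeros(n)
    oob_pred_cnt = np.zeros(n)
    for tree in forest.estimators_:
        oob = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        if len(oob) < 2:
            continue
        Xo, yo = X[oob], y[oob]
        base_pred = tree.predict(Xo)
        oob_pred_sum[oob] += base_pred
        oob_pred_cnt[oob] += 1
        mse0 = mean_squared_error(yo, base_pred)
        if mse0 <= 0:
            mse0 = 1e-12
        for p, cols in col_groups.items():
            perm = rng.permutation(len(oob))
            Xp = Xo.copy()
            Xp[:, cols] = Xo[perm][:, cols]
            mse_p = mean_squared_error(yo, tree.predict(Xp))
            inc[p].append(100.0 * (mse_p - mse0) / mse0)
    importance = {p: float(np.mean(v)) if v else 0.0 for p, v in inc.items()}
    seen = oob_pred_cnt > 0
    mse_oob = mean_squared_error(y[seen], oob_pred_sum[seen] / oob_pred_cnt[seen])
    var_y = float(np.var(y[seen]))
    var_expl = 100.0 * (1.0 - mse_oob / var_y) if var_y > 0 else 0.0
    return importance, var_expl


def run_importance(
    records: pd.DataFrame,
    response: str = "peak_doy",
    predictors: tuple[str, ...] = PREDICTORS,
    split_fraction: float = 0.8,
    cv: tuple[int, int] | None = (5, 5),
    trees: int = 500,
    seed: int = 0,
) -> ImportanceResult:
    """Fit the forest and compute permutation importance of each predictor.

    ``records`` needs one row per fitted peak with the response column and
    the categorical predictor columns.  ``cv=(folds, repeats)`` controls the
    repeated cross-validation on the training split; ``cv=None`` skips it.
    """
    records = records.reset_index(drop=True)
    if len(records) < 30:
        raise ValueError(f"need >= 30 records, got {len(records)}")
    if records[response].isna().any():
        raise ValueError("missing response values")
    y_all = records[response].to_numpy(dtype=float)

    used, dropped = [], []
    for p in predictors:
        if p not in records.columns or records[p].nunique() < 2:
            dropped.append(p)
            warnings.warn(f"predictor '{p}' has < 2 levels; dropped", stacklevel=2)
        else:
            used.append(p)
    if not used:
        raise ValueError("no usable predictors")

    X_all, col_groups = _encode(records, used)
    rng = np.random.default_rng(seed)
    idx_train, idx_test = train_test_split(
        np.arange(len(records)),
        train_size=split_fraction,
        random_state=seed,
        shuffle=True,
    )
    X_tr, X_te = X_all[idx_train], X_all[idx_test]
    y_tr, y_te = y_all[idx_train], y_all[idx_test]

    forest = RandomForestRegressor(
        n_estimators=trees, random_state=seed, bootstrap=True, n_jobs=1
    )
    forest.fit(X_tr, y_tr)
    importance, var_expl = _oob_perm_importance(forest, X_tr, y_tr, col_groups, rng)

    r2_train = float(r2_score(y_tr, forest.predict(X_tr)))
    pred_te = forest.predict(X_te)
    r2_test = float(r2_score(y_te, pred_te))
    rmse_test = float(np.sqrt(mean_squared_error(y_te, pred_te)))

    cv_rmse = cv_r2 = None
    if cv is not None:
        folds, repeats = cv
        rkf = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
        rmses, r2s = [], []
        for tr, va in rkf.split(X_tr):
            m = RandomForestRegressor(
                n_estimators=trees, random_state=seed, bootstrap=True, n_jobs=1
            )
            m.fit(X_tr[tr], y_tr[tr])
            p = m.predict(X_tr[va])
            rmses.append(np.sqrt(mean_squared_error(y_tr[va], p)))
            r2s.append(r2_score(y_tr[va], p))
        cv_rmse = float(np.mean(rmses))
        cv_r2 = float(np.mean(r2s))

    return ImportanceResult(
        importance=importance,
        variance_explained=var_expl,
        r2_train=r2_train,
        r2_test=r2_test,
        rmse_test=rmse_test,
        cv_rmse=cv_rmse,
        cv_r2=cv_r2,
        n_records=len(records),
        dropped_predictors=tuple(dropped),
    )
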