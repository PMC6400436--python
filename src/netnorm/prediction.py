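"""Out-of-bag random-forest prediction of the continuous outcome.

The predictive score is the *fractional variation explained* (FVE):

    fve = 1 - MSE_oob / Var(outcome)

where each subject's prediction averages only the trees whose bootstrap
sample omitted that subject (out-of-bag).  The constant predictor scores
exactly 0; negative values are reported as-is.

Feature relevance uses out-of-bag permutation importance: the increase in
OOB mean-squared error when one feature's column is permuted, averaged over
several permutations.  The magnitude of the most *negative* importance
defines a noise floor; features with importance above that floor are
flagged as significant.

A covariates-only control model (age, gender, cortical volume, node count,
motion) runs the identical machinery without any network metric, and
ordinary least squares covers the pairwise covariate checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from ._seeds import derive, rng_from

#: Covariate columns used by the control model.
COVARIATE_COLUMNS = (
    "age",
    "gender",
    "cortical_volume",
    "n_nodes",
    "motion_rotational",
    "motion_translational",
)


@dataclass
class PredictionResult:
    """Out-of-bag predictions and scores for one feature set."""

    oob_predictions: np.ndarray
    fve: float
    fve_ci: tuple[float, float] | None
    importances: dict[str, float]
    noise_floor: float
    significant_features: list[str]
    feature_set: list[str] = field(default_factory=list)
    n_trees: int = 0
    seed: int = 0

    @property
    def fve_display(self) -> float:
        """FVE floored at 0 for reporting (matching the usual table style)."""
        return max(0.0, self.fve)


class OOBForest:
    """Bagged regression trees with explicit bootstrap bookkeeping.

    Keeps the in-bag mask of every tree so that out-of-bag purity (no
    subject predicted by a tree that trained on it) is verifiable, and so
    permutation importances can be computed on strictly out-of-bag rows.
    """

    def __init__(self, n_trees: int = 500, seed: int = 0, max_extra_trees: int = 4000):
        self.n_trees = int(n_trees)
        self.seed = int(seed)
        self.max_extra_trees = int(max_extra_trees)
        self.trees: list[DecisionTreeRegressor] = []
        self.inbag: np.ndarray | None = None  # (n_trees, n) counts

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OOBForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        rng = rng_from(self.seed, 31)
        self.trees, inbag_rows = [], []
        total = self.n_trees
        while True:
            for t in range(len(self.trees), total):
                idx = rng.integers(0, n, size=n)
                counts = np.bincount(idx, minlength=n)
                tree = DecisionTreeRegressor(random_state=derive(self.seed, 37, t))
                tree.fit(X[idx], y[idx])
                self.trees.append(tree)
                inbag_rows.append(counts)
            inbag = np.array(inbag_rows)
            oob_counts = (inbag == 0).sum(axis=0)
            if oob_counts.min() > 0 or total >= self.n_trees + self.max_extra_trees:
                break
            warnings.warn(
                "some subjects were never out-of-bag; growing extra trees"
            )
            total += max(50, total // 2)
        self.inbag = inbag
        self._X, self._y = X, y
        return self

    def oob_predict(self, X: np.ndarray | None = None) -> np.ndarray:
        """Per-subject prediction from out-of-bag trees only."""
        assert self.inbag is not None, "fit first"
        X = self._X if X is None else np.asarray(X, dtype=float)
        n = X.shape[0]
        sums = np.zeros(n)
        counts = np.zeros(n)
        for t, tree in enumerate(self.trees):
            oob = self.inbag[t] == 0
            if not oob.any():
                continue
            sums[oob] += tree.predict(X[oob])
            counts[oob] += 1
        if (counts == 0).any():
            raise RuntimeError("a subject was never out-of-bag")
        return sums / counts

    def oob_mse(self, X: np.ndarray | None = None) -> float:
        pred = self.oob_predict(X)
        return float(np.mean((pred - self._y) ** 2))


def fve_score(y: np.ndarray, oob_predictions: np.ndarray) -> float:
    """Fractional variation explained, 1 - MSE_oob / Var(y)."""
    y = np.asarray(y, dtype=float)
    var = float(np.mean((y - y.mean()) ** 2))
    if var == 0:
        raise ValueError("outcome has zero variance")
    mse = float(np.mean((oob_predictions - y) ** 2))
    return 1.0 - mse / var


def fit_oob_forest(
    table: pd.DataFrame,
    feature_set: list[str],
    n_trees: int = 500,
    seed: int = 0,
    outcome_column: str = "outcome",
    n_permutations: int = 50,
    n_boot: int = 0,
    compute_importance: bool = True,
) -> PredictionResult:
    """Fit the OOB forest on ``feature_set`` and score it with FVE.

    ``n_boot > 0`` adds subject-bootstrap percentile confidence limits for
    the FVE (the forest is refit on every resample).
    """
    if not feature_set:
        raise ValueError("feature_set must not be empty")
    if outcome_column not in table:
        raise ValueError(f"missing outcome column {outcome_column!r}")
    if table[outcome_column].isna().any():
        raise ValueError("missing outcome values")
    X = table[list(feature_set)].to_numpy(dtype=float)
    y = table[outcome_column].to_numpy(dtype=float)
    forest = OOBForest(n_trees=n_trees, seed=seed).fit(X, y)
    oob_pred = forest.oob_predict()
    fve = fve_score(y, oob_pred)

    importances: dict[str, float] = {}
    noise_floor = 0.0
    significant: list[str] = []
    if compute_importance:
        importances, noise_floor, significant = permutation_importance(
            forest, list(feature_set), seed=seed, n_permutations=n_permutations
        )

    ci = None
    if n_boot > 0:
        ci = fve_confidence_limits(
            table,
            list(feature_set),
            n_trees=n_trees,
            seed=seed,
            n_boot=n_boot,
            outcome_column=outcome_column,
        )
    return PredictionResult(
        oob_predictions=oob_pred,
        fve=fve,
        fve_ci=ci,
        importances=importances,
        noise_floor=noise_floor,
        significant_features=significant,
        feature_set=list(feature_set),
        n_trees=len(forest.trees),
        seed=seed,
    )


def permutation_importance(
    forest: OOBForest,
    feature_names: list[str],
    seed: int = 0,
    n_permutations: int = 50,
) -> tuple[dict[str, float], float, list[str]]:
    """OOB permutation importance with the most-negative-value noise floor.

    Importance of a feature is the OOB MSE after permuting its column
    minus the baseline OOB MSE, averaged over ``n_permutations``
    permutations.  Features whose importance exceeds the magnitude of the
    most negative importance are flagged significant.
    """
    base_mse = forest.oob_mse()
    X = forest._X
    n = X.shape[0]
    rng = rng_from(seed, 41)
    importances: dict[str, float] = {}
    for f, name in enumerate(feature_names):
        deltas = np.empty(n_permutations)
        for p in range(n_permutations):
            Xp = X.copy()
            Xp[:, f] = Xp[rng.permutation(n), f]
            deltas[p] = forest.oob_mse(Xp) - base_mse
        importances[name] = float(deltas.mean())
    values = np.array(list(importances.values()))
    most_negative = values.min()
    if len(feature_names) == 1:
        warnings.warn("single-feature model: the noise floor is undefined; using 0")
        noise_floor = 0.0
    else:
        noise_floor = float(abs(min(most_negative, 0.0)))
    significant = [name for name, v in importances.items() if v > noise_floor]
    return importances, noise_floor, significant


def fve_confidence_limits(
    table: pd.DataFrame,
    feature_set: list[str],
    n_trees: int = 500,
    seed: int = 0,
    n_boot: int = 1000,
    outcome_column: str = "outcome",
    level: float = 0.95,
) -> tuple[float, float]:
    """Subject-bootstrap percentile interval for the FVE."""
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; interval will be unstable")
    X = table[list(feature_set)].to_numpy(dtype=float)
    y = table[outcome_column].to_numpy(dtype=float)
    n = len(y)
    rng = rng_from(seed, 43)
    scores = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if np.all(yb == yb[0]):
            scores[b] = 0.0
            continue
        forest = OOBForest(n_trees=n_trees, seed=derive(seed, 47, b)).fit(X[idx], yb)
        scores[b] = fve_score(yb, forest.oob_predict())
    alpha = (1 - level) / 2
    return (float(np.quantile(scores, alpha)), float(np.quantile(scores, 1 - alpha)))


def control_model(
    table: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 500,
    covariate_columns: tuple[str, ...] = COVARIATE_COLUMNS,
    **kwargs,
) -> PredictionResult:
    """Confounder-only model: identical forest, covariate features only."""
    missing = [c for c in covariate_columns if c not in table]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    return fit_oob_forest(
        table, list(covariate_columns), n_trees=n_trees, seed=seed, **kwargs
    )


def covariate_regressions(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """OLS slope and two-sided p-value for each (x, y) covariate pair."""
    import statsmodels.api as sm

    if len(table) < 3:
        raise ValueError("need at least 3 subjects for regression")
    if pairs is None:
        pairs = [
            ("age", "outcome"),
            ("cortical_volume", "outcome"),
            ("n_nodes", "outcome"),
            ("age", "cortical_volume"),
            ("age", "n_nodes"),
        ]
    rows = []
    for x, y in pairs:
        xv = table[x].to_numpy(dtype=float)
        yv = table[y].to_numpy(dtype=float)
        if np.all(xv == xv[0]):
            rows.append(
                {"x": x, "y": y, "slope": np.nan, "p_value": np.nan, "constant_x": True}
            )
            continue
        model = sm.OLS(yv, sm.add_constant(xv)).fit()
        rows.append(
            {
                "x": x,
                "y": y,
                "slope": float(model.params[1]),
                "p_value": float(model.pvalues[1]),
                "constant_x": False,
            }
        )
    return pd.DataFrame(rows)
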