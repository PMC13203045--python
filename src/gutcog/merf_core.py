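"""Mixed-effects random forest with subject random intercepts.

The model is ``y_ij = f(x_ij) + b_i + e_ij`` with ``b_i ~ N(0, sigma2_b)``
and ``e_ij ~ N(0, sigma2_e)``.  Fitting alternates, EM-style:

1. subtract the current random intercepts from ``y`` and refit a random
   forest on the result (the fixed part ``f``), using out-of-bag
   predictions for the in-sample fixed-part estimates by default;
2. closed-form random-intercept update per cluster,
   ``b_i = n_i * sigma2_b / (n_i * sigma2_b + sigma2_e) * mean(residual_i)``;
3. moment/EM variance-component updates (random intercept only, Z = 1):
   ``sigma2_e <- (1/n) * sum_i [eps_i'eps_i + sigma2_e*(n_i - sigma2_e*tr(V_i^-1))]``
   and
   ``sigma2_b <- (1/m) * sum_i [b_i^2 + sigma2_b - sigma2_b^2 * (1'V_i^-1 1)]``
   with ``V_i = sigma2_b*J + sigma2_e*I`` and ``eps_i = y_i - f_i - b_i``;
4. generalized log-likelihood trace
   ``GLL = sum_i [eps_i'eps_i/sigma2_e + b_i^2/sigma2_b + log sigma2_b
   + n_i*log sigma2_e]``; stop on small relative change.

Prediction adds the learned intercept for clusters seen in training
("personalized prediction": a subject's accumulated history is used to
forecast their own trajectory) and falls back to the fixed part alone for
unseen clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor

__all__ = ["MERFConfig", "MERFModel", "fit_merf", "predict_merf"]

_VAR_FLOOR = 1e-8
_SCHEMA_VERSION = 1


@dataclass
class MERFConfig:
    n_trees: int = 300
    max_em_iterations: int = 30
    gll_tolerance: float = 1e-4  # relative change in GLL
    max_features: str | float = 1.0 / 3.0  # features-per-split rule
    min_leaf: int = 5
    use_oob_for_fixed_part: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.gll_tolerance <= 0:
            raise ValueError("gll_tolerance must be > 0")
        if self.max_em_iterations < 1:
            raise ValueError("max_em_iterations must be >= 1")


@dataclass
class MERFModel:
    forest: RandomForestRegressor
    b: dict[str, float]
    sigma2_b: float
    sigma2_e: float
    gll_trace: list[float]
    converged: bool
    feature_names: list[str]
    config: MERFConfig

    def save(self, path: str) -> None:
        joblib.dump(
            {
                "schema_version": _SCHEMA_VERSION,
                "forest": self.forest,
                "b": self.b,
                "sigma2_b": self.sigma2_b,
                "sigma2_e": self.sigma2_e,
                "gll_trace": self.gll_trace,
                "converged": self.converged,
                "feature_names": self.feature_names,
                "config": self.config,
            },
            path,
        )

    @classmethod
    def load(cls, path: str) -> "MERFModel":
        payload = joblib.load(path)
        version = payload.pop("schema_version", None)
        if version != _SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema version {version}")
        return cls(**payload)


def _fixed_part_estimates(
    forest: RandomForestRegressor, X: np.ndarray, use_oob: bool
) -> np.ndarray:
    """In-sample fixed-part estimates; OOB where available, in-bag fallback.

    OOB predictions are aggregated from ``estimators_samples_`` directly:
    sklearn's ``oob_prediction_`` silently reports 0.0 for samples that are
    in-bag in every tree, which corrupts the residuals at small tree counts.
    """
    if not use_oob:
        return forest.predict(X)
    n = len(X)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    sums = np.zeros(n)
    counts = np.zeros(n)
    for tree, samples in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), np.unique(samples))
        if oob.size == 0:
            continue
        try:
            preds = np.asarray(tree.tree_.predict(X32[oob])).reshape(oob.size)
        except Exception:  # pragma: no cover - private-API fallback
            preds = tree.predict(X[oob])
        sums[oob] += preds
        counts[oob] += 1
    covered = counts > 0
    out = np.zeros(n)
    out[covered] = sums[covered] / counts[covered]
    if not covered.all():
        out[~covered] = forest.predict(X[~covered])
    return out


def fit_merf(
    X: np.ndarray,
    y: np.ndarray,
    clusters: "list[str] | np.ndarray",
    config: MERFConfig | None = None,
    feature_names: "list[str] | None" = None,
) -> MERFModel:
    """Fit the mixed-effects random forest by EM-style alternation."""
    config = config or MERFConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    clusters = np.asarray([str(c) for c in clusters])
    n = len(y)
    if X.ndim != 2 or X.shape[0] != n or len(clusters) != n:
        raise ValueError("X / y / clusters shape mismatch")
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values not supported; impute first")
    cluster_ids = np.unique(clusters)
    if len(cluster_ids) < 2:
        raise ValueError("need >= 2 clusters")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    if len(feature_names) != X.shape[1]:
        raise ValueError("feature_names length mismatch")

    members = {cid: np.where(clusters == cid)[0] for cid in cluster_ids}
    n_i = np.array([len(members[cid]) for cid in cluster_ids], dtype=float)
    m = len(cluster_ids)

    b = np.zeros(m)
    var_y = max(float(np.var(y)), _VAR_FLOOR)
    sigma2_e = var_y
    sigma2_b = var_y / 2.0

    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        min_samples_leaf=config.min_leaf,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )

    gll_trace: list[float] = []
    converged = False
    b_map_index = {cid: k for k, cid in enumerate(cluster_ids)}
    cluster_pos = np.array([b_map_index[c] for c in clusters])

    for _ in range(config.max_em_iterations):
        y_star = y - b[cluster_pos]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sparse-OOB warning at small n_trees
            forest.fit(X, y_star)
        f_hat = _fixed_part_estimates(forest, X, config.use_oob_for_fixed_part)

        resid = y - f_hat
        mean_resid = np.array([resid[members[cid]].mean() for cid in cluster_ids])
        shrink = n_i * sigma2_b / (n_i * sigma2_b + sigma2_e)
        b = shrink * mean_resid

        eps = resid - b[cluster_pos]
        sse = np.array(
            [float(eps[members[cid]] @ eps[members[cid]]) for cid in cluster_ids]
        )
        # V_i^-1 identities for the random-intercept structure
        denom = sigma2_e + n_i * sigma2_b
        tr_vinv = (n_i / sigma2_e) * (1.0 - sigma2_b / denom)
        one_vinv_one = n_i / denom

        sigma2_e_new = float(
            np.sum(sse + sigma2_e * (n_i - sigma2_e * tr_vinv)) / n
        )
        sigma2_b_new = float(
            np.mean(b**2 + sigma2_b - sigma2_b**2 * one_vinv_one)
        )
        sigma2_e = max(sigma2_e_new, _VAR_FLOOR)
        sigma2_b = max(sigma2_b_new, _VAR_FLOOR)
        if sigma2_e_new < _VAR_FLOOR or sigma2_b_new < _VAR_FLOOR:
            warnings.warn("variance iterate floored at 1e-8", RuntimeWarning)

        gll = float(
            np.sum(sse) / sigma2_e
            + float(b @ b) / sigma2_b
            + m * np.log(sigma2_b)
            + np.sum(n_i) * np.log(sigma2_e)
        )
        gll_trace.append(gll)
        if len(gll_trace) >= 2:
            prev = gll_trace[-2]
            if abs(gll - prev) < config.gll_tolerance * max(abs(prev), 1.0):
                converged = True
                break

    return MERFModel(
        forest=forest,
        b={cid: float(b[b_map_index[cid]]) for cid in cluster_ids},
        sigma2_b=sigma2_b,
        sigma2_e=sigma2_e,
        gll_trace=gll_trace,
        converged=converged,
        feature_names=list(feature_names),
        config=config,
    )


def predict_merf(
    model: MERFModel,
    X: np.ndarray,
    clusters: "list[str] | np.ndarray",
    feature_names: "list[str] | None" = None,
) -> np.ndarray:
    """``f(X) + b_cluster`` for known clusters, ``f(X)`` otherwise."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"feature count mismatch: model has {len(model.feature_names)}, "
            f"got {X.shape[1]}"
        )
    if feature_names is not None and list(feature_names) != list(model.feature_names):
        raise ValueError("feature names do not match training")
    fixed = model.forest.predict(X)
    offsets = np.array([model.b.get(str(c), 0.0) for c in clusters])
    return fixed + offsets
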