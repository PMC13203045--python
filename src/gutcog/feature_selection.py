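"""Boruta all-relevant feature selection.

Each iteration appends a shuffled "shadow" copy of every still-undecided
feature, fits a random forest on the augmented matrix, and scores each
real feature a hit when its importance Z-score exceeds the maximum shadow
Z-score.  One-sided binomial tests (p = 0.5, Bonferroni-corrected over
the initial feature count) then confirm features with significantly more
hits than chance and reject those with significantly fewer; the loop runs
until every feature is decided or ``max_runs`` is reached, leaving the
remainder tentative.

The importance measure is per-tree out-of-bag permutation importance
(mean decrease in accuracy, Z = mean / SD over trees), matching the
original algorithm; Gini importance is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

__all__ = ["BorutaResult", "boruta_select"]


@dataclass
class BorutaResult:
    feature_names: list[str]
    status: dict[str, str]  # confirmed | tentative | rejected
    hits: dict[str, int]
    iterations: dict[str, int]  # iterations each feature participated in
    n_iterations: int
    importance_history: list[dict[str, float]]
    seed: int

    @property
    def confirmed(self) -> list[str]:
        return [f for f in self.feature_names if self.status[f] == "confirmed"]

    @property
    def tentative(self) -> list[str]:
        return [f for f in self.feature_names if self.status[f] == "tentative"]

    @property
    def rejected(self) -> list[str]:
        return [f for f in self.feature_names if self.status[f] == "rejected"]


def _per_tree_mda_zscores(
    forest: RandomForestRegressor, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Z-scores of per-tree OOB permutation importance (MSE increase)."""
    n, p = X.shape
    all_idx = np.arange(n)
    # trees store float32 internally; feeding tree_.predict directly skips
    # per-call validation/conversion of the large stacked matrix (~6x faster)
    X32 = np.ascontiguousarray(X, dtype=np.float32)

    def _tree_predict(tree, arr32: np.ndarray) -> np.ndarray:
        try:
            return np.asarray(tree.tree_.predict(arr32)).reshape(len(arr32))
        except Exception:  # pragma: no cover - private-API fallback
            return tree.predict(arr32.astype(np.float64))

    imps = np.full((len(forest.estimators_), p), np.nan)
    for t, (tree, samples) in enumerate(
        zip(forest.estimators_, forest.estimators_samples_)
    ):
        oob = np.setdiff1d(all_idx, np.unique(samples))
        if oob.size < 2:
            continue
        X_oob = X32[oob]
        y_oob = y[oob]
        base_err = float(np.mean((y_oob - _tree_predict(tree, X_oob)) ** 2))
        stacked = np.repeat(X_oob[None, :, :], p, axis=0)
        for j in range(p):
            stacked[j, :, j] = X_oob[rng.permutation(oob.size), j]
        preds = _tree_predict(tree, stacked.reshape(p * oob.size, p)).reshape(
            p, oob.size
        )
        perm_err = np.mean((y_oob[None, :] - preds) ** 2, axis=1)
        imps[t] = perm_err - base_err
    mean = np.nanmean(imps, axis=0)
    sd = np.nanstd(imps, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, mean / sd, 0.0)
    return z


def boruta_select(
    X: np.ndarray,
    y: np.ndarray,
    max_runs: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
    n_trees: int = 100,
    importance: str = "mda",
    feature_names: "list[str] | None" = None,
    min_leaf: int = 5,
) -> BorutaResult:
    """Run Boruta on pooled samples (subject clustering is ignored here by
    design; selection precedes the mixed model)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if max_runs < 1:
        raise ValueError("max_runs must be >= 1")
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need at least one feature")
    n, p = X.shape
    if n < 20:
        raise ValueError(f"need at least 20 samples, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("constant outcome")
    if importance not in {"mda", "gini"}:
        raise ValueError(f"unknown importance measure {importance!r}")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    if len(feature_names) != p:
        raise ValueError("feature_names length mismatch")

    rng = np.random.default_rng(seed)
    status = np.array(["tentative"] * p, dtype=object)
    hits = np.zeros(p, dtype=int)
    iters = np.zeros(p, dtype=int)
    history: list[dict[str, float]] = []
    threshold = alpha / p  # Bonferroni over the initial feature count

    n_iterations = 0
    for _ in range(max_runs):
        undecided = np.where(status == "tentative")[0]
        if undecided.size == 0:
            break
        n_iterations += 1
        X_real = X[:, undecided]
        # pad to >= 5 shadows: with few undecided features the max-shadow
        # bar is too easy to clear and weak noise gets confirmed
        shadow_src = undecided
        while shadow_src.size < 5:
            shadow_src = np.concatenate([shadow_src, undecided])
        X_shadow = X[:, shadow_src].copy()
        for j in range(X_shadow.shape[1]):
            X_shadow[:, j] = X_shadow[rng.permutation(n), j]
        X_aug = np.hstack([X_real, X_shadow])

        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            min_samples_leaf=min_leaf,
            bootstrap=True,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(X_aug, y)
        if importance == "mda":
            z = _per_tree_mda_zscores(forest, X_aug, y, rng)
        else:
            z = forest.feature_importances_
        k = undecided.size
        real_z, shadow_z = z[:k], z[k:]
        shadow_max = float(np.max(shadow_z))
        hits[undecided] += real_z > shadow_max
        iters[undecided] += 1
        history.append(
            {feature_names[f]: float(real_z[i]) for i, f in enumerate(undecided)}
        )

        for i, f in enumerate(undecided):
            p_more = stats.binom.sf(hits[f] - 1, iters[f], 0.5)
            p_fewer = stats.binom.cdf(hits[f], iters[f], 0.5)
            if p_more < threshold:
                status[f] = "confirmed"
            elif p_fewer < threshold:
                status[f] = "rejected"

    return BorutaResult(
        feature_names=list(feature_names),
        status={feature_names[f]: str(status[f]) for f in range(p)},
        hits={feature_names[f]: int(hits[f]) for f in range(p)},
        iterations={feature_names[f]: int(iters[f]) for f in range(p)},
        n_iterations=n_iterations,
        importance_history=history,
        seed=seed,
    )
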