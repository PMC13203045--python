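"""Permutation variable importance with empirical-null significance,
Spearman/FDR feature annotation and KO-term enrichment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .merf_core import MERFConfig, MERFModel, fit_merf, predict_merf

__all__ = [
    "ImportanceTable",
    "EnrichmentResult",
    "permutation_importance",
    "importance_pvalues",
    "altmann_importance_pvalues",
    "spearman_with_fdr",
    "bh_fdr",
    "ko_enrichment",
    "build_importance_table",
]


@dataclass
class ImportanceTable:
    """Annotated per-feature importance ranking.

    ``strong`` marks |spearman rho| >= the strength threshold (default 0.4)
    and ``significant`` marks spearman p <= 0.05 with FDR < 0.1, matching
    the annotation rules applied to final-model rankings.
    """

    frame: pd.DataFrame  # feature, importance, rank, p/q, rho, rho p/q, flags
    importance_p_method: str
    strong_threshold: float = 0.4
    p_threshold: float = 0.05
    fdr_threshold: float = 0.1

    def top(self, k: int = 15) -> pd.DataFrame:
        return self.frame.nsmallest(k, "rank").reset_index(drop=True)


@dataclass
class EnrichmentResult:
    frame: pd.DataFrame  # pathway, overlap, pathway_size, selection_size, background_size, p, q


# ---------------------------------------------------------------------------
# permutation importance
# ---------------------------------------------------------------------------


def _grouped_folds(
    clusters: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Cluster-grouped fold assignment (whole clusters per fold)."""
    ids = np.unique(clusters)
    if n_folds > len(ids):
        raise ValueError(
            f"holdout_folds={n_folds} exceeds cluster count {len(ids)}"
        )
    order = rng.permutation(len(ids))
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for k, cid in enumerate(ids[order]):
        folds[k % n_folds].extend(np.where(clusters == cid)[0])
    return [np.array(sorted(f)) for f in folds]


def permutation_importance(
    model: MERFModel,
    X: np.ndarray,
    y: np.ndarray,
    clusters: "list[str] | np.ndarray",
    n_repeats: int = 10,
    holdout_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Cross-validated held-out permutation importance of each feature.

    Samples are split into cluster-grouped folds (whole subjects per
    fold).  For each fold the model is refit on the complement with the
    given model's configuration; the increase in held-out squared error
    when one feature's column is permuted within the fold is averaged
    over ``n_repeats`` repeats, then over folds.  Refitting per fold is
    what makes the importance genuinely held-out (an in-sample forest
    memorizes noise, inflating every feature's importance), and grouping
    folds by cluster prevents repeated-measures leakage.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    clusters = np.asarray([str(c) for c in clusters])
    rng = np.random.default_rng(seed)
    folds = _grouped_folds(clusters, holdout_folds, rng)

    p = X.shape[1]
    fold_imp = np.zeros((len(folds), p))
    for fi, idx in enumerate(folds):
        train = np.setdiff1d(np.arange(len(y)), idx)
        fold_model = fit_merf(
            X[train], y[train], clusters[train], model.config,
            feature_names=model.feature_names,
        )
        X_f, y_f, c_f = X[idx], y[idx], clusters[idx]
        base_err = float(np.mean((y_f - predict_merf(fold_model, X_f, c_f)) ** 2))
        n_f = len(idx)
        # one batched predict per fold: (feature x repeat) stacked copies
        stacked = np.repeat(X_f[None, :, :], p * n_repeats, axis=0).reshape(
            p, n_repeats, n_f, p
        )
        for j in range(p):
            for r in range(n_repeats):
                stacked[j, r, :, j] = X_f[rng.permutation(n_f), j]
        preds = predict_merf(
            fold_model,
            stacked.reshape(p * n_repeats * n_f, p),
            np.tile(c_f, p * n_repeats),
        ).reshape(p, n_repeats, n_f)
        errs = np.mean((y_f[None, None, :] - preds) ** 2, axis=2)
        fold_imp[fi] = errs.mean(axis=1) - base_err
    return fold_imp.mean(axis=0)


def importance_pvalues(raw_importances: np.ndarray) -> np.ndarray:
    """Mirrored-null p-values for permutation importances.

    The empirical null is the set of non-positive importances together
    with their reflections about zero; each feature's p-value is the
    upper-tail probability of its observed importance under that null.
    Requires at least 10 non-positive importances (otherwise use the
    Altmann-style outcome-permutation fallback).
    """
    imp = np.asarray(raw_importances, dtype=float)
    nonpos = imp[imp <= 0]
    if nonpos.size < 10:
        raise ValueError(
            f"only {nonpos.size} non-positive importances (< 10); "
            "use altmann_importance_pvalues instead"
        )
    null = np.concatenate([nonpos, -nonpos])
    return np.array([(null >= v).mean() for v in imp])


def altmann_importance_pvalues(
    X: np.ndarray,
    y: np.ndarray,
    clusters: "list[str] | np.ndarray",
    observed_importances: np.ndarray,
    merf_config: MERFConfig,
    n_perm: int = 50,
    n_repeats: int = 3,
    holdout_folds: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Outcome-permutation importance p-values (small-model fallback).

    The outcome is permuted ``n_perm`` times, the mixed-effects forest is
    refit on each permuted outcome, and the per-feature null distribution
    of importances is accumulated; p is the upper-tail frequency with an
    add-one correction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    clusters = np.asarray([str(c) for c in clusters])
    rng = np.random.default_rng(seed)
    observed = np.asarray(observed_importances, dtype=float)
    exceed = np.zeros_like(observed)
    for k in range(n_perm):
        y_perm = y[rng.permutation(len(y))]
        model = fit_merf(X, y_perm, clusters, merf_config)
        null_imp = permutation_importance(
            model,
            X,
            y_perm,
            clusters,
            n_repeats=n_repeats,
            holdout_folds=holdout_folds,
            seed=int(rng.integers(2**31 - 1)),
        )
        exceed += null_imp >= observed
    return (exceed + 1.0) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# correlation annotation
# ---------------------------------------------------------------------------


def spearman_with_fdr(
    feature_columns: np.ndarray,
    outcome: np.ndarray,
    feature_names: "list[str] | None" = None,
) -> pd.DataFrame:
    """Spearman rho (average ranks for ties, t-approximation p) per feature
    column, with BH q-values across the testable set.

    Constant columns have undefined rho; they are flagged (``defined`` is
    False, NaN rho/p/q) and excluded from the FDR set.
    """
    X = np.asarray(feature_columns, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != len(y):
        raise ValueError("feature/outcome length mismatch")
    if X.shape[0] < 3:
        raise ValueError("need >= 3 paired observations")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]

    rho = np.full(X.shape[1], np.nan)
    pval = np.full(X.shape[1], np.nan)
    defined = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0 or np.ptp(y) == 0:
            continue
        r, p = stats.spearmanr(X[:, j], y)
        rho[j], pval[j], defined[j] = r, p, True
    q = np.full(X.shape[1], np.nan)
    if defined.any():
        q[defined] = bh_fdr(pval[defined])
    return pd.DataFrame(
        {
            "feature": feature_names,
            "spearman_rho": rho,
            "spearman_p": pval,
            "spearman_q": q,
            "defined": defined,
        }
    )


def bh_fdr(p_values: "np.ndarray | list[float]") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p-rank)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def ko_enrichment(
    selected: "set[str] | list[str]",
    background: "set[str] | list[str]",
    ko_to_pathways: "dict[str, set[str] | list[str]]",
) -> EnrichmentResult:
    """One-sided hypergeometric enrichment of ``selected`` KO terms over
    pathways, BH-corrected across pathways.

    The background is the model feature space (all KO terms entering the
    model matrix), not the full KEGG; unmapped terms count toward the
    background but no pathway.
    """
    selected = set(selected)
    background = set(background)
    if not selected:
        raise ValueError("empty selection")
    if not selected <= background:
        raise ValueError(
            f"selection not contained in background: "
            f"{sorted(selected - background)[:5]}"
        )
    pathways: dict[str, set[str]] = {}
    for ko, paths in ko_to_pathways.items():
        if ko not in background:
            continue
        for pw in paths:
            pathways.setdefault(pw, set()).add(ko)

    N, n = len(background), len(selected)
    rows = []
    for pw in sorted(pathways):
        members = pathways[pw]
        K = len(members)
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "pathway": pw,
                "overlap": k,
                "pathway_size": K,
                "selection_size": n,
                "background_size": N,
                "p_value": p,
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["q_value"] = bh_fdr(frame["p_value"].to_numpy())
    else:
        frame["q_value"] = []
    return EnrichmentResult(frame=frame)


# ---------------------------------------------------------------------------
# assembled annotation table
# ---------------------------------------------------------------------------


def build_importance_table(
    feature_names: "list[str]",
    importances: np.ndarray,
    importance_p: "np.ndarray | None",
    spearman_frame: pd.DataFrame,
    importance_p_method: str,
    strong_threshold: float = 0.4,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.1,
) -> ImportanceTable:
    """Merge importances, importance p/q and Spearman annotation into the
    ranked table; rank 1 = most important."""
    imp = np.asarray(importances, dtype=float)
    order = np.argsort(-imp, kind="stable")
    rank = np.empty(len(imp), dtype=int)
    rank[order] = np.arange(1, len(imp) + 1)

    frame = pd.DataFrame({"feature": feature_names, "importance": imp, "rank": rank})
    if importance_p is not None:
        frame["p_value"] = np.asarray(importance_p, dtype=float)
        frame["q_value"] = bh_fdr(frame["p_value"].to_numpy())
    else:
        frame["p_value"] = np.nan
        frame["q_value"] = np.nan
    frame = frame.merge(spearman_frame, on="feature", how="left")
    frame["strong"] = np.abs(frame["spearman_rho"]) >= strong_threshold
    frame["significant"] = (frame["spearman_p"] <= p_threshold) & (
        frame["spearman_q"] < fdr_threshold
    )
    frame = frame.sort_values("rank").reset_index(drop=True)
    return ImportanceTable(
        frame=frame,
        importance_p_method=importance_p_method,
        strong_threshold=strong_threshold,
        p_threshold=p_threshold,
        fdr_threshold=fdr_threshold,
    )
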