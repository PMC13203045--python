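"""End-to-end orchestration of the cognitive-score prediction pipeline,
the per-species clinical-covariate screen and cross-outcome ranking
comparison.

The cognitive pipeline, per seed: split longitudinal samples by leaving
one sample per multi-sample subject out for testing, Boruta-select
features on the training split (microbiome features competing with the
eight minimal clinical covariates; medications are never included here),
fit a mixed-effects random forest with a subject random intercept, and
correlate actual vs predicted scores on the test split.  A final model is
then fit on all samples using the union of the per-seed selections and
annotated with permutation importance, importance p/q values, and
Spearman rho/p/q with strength (|rho| >= 0.4) and significance
(p <= 0.05, FDR < 0.1) flags for the top-k rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_prep import classify_subjects, composite_zscore
from .feature_selection import boruta_select
from .importance_stats import (
    ImportanceTable,
    altmann_importance_pvalues,
    bh_fdr,
    build_importance_table,
    importance_pvalues,
    permutation_importance,
    spearman_with_fdr,
)
from .io_formats import AbundanceTable, VisitRecord
from .merf_core import MERFConfig, MERFModel, fit_merf, predict_merf

__all__ = [
    "SplitPlan",
    "SeedRun",
    "PipelineReport",
    "PipelineConfig",
    "MINIMAL_COVARIATES",
    "longitudinal_split",
    "run_cognitive_pipeline",
    "covariate_screen",
    "compare_rankings",
    "covariate_matrix",
    "outcome_values",
]

#: the eight minimal clinical covariates admitted to the cognitive models
MINIMAL_COVARIATES = (
    "sex",
    "age",
    "antibiotics_6mo",
    "hospitalized_6mo",
    "mis",
    "cfs",
    "polypharmacy",
    "education_years",
)

OUTCOMES = ("adas_cog_13", "memory_z", "ef_z")


@dataclass(frozen=True)
class SplitPlan:
    seed: int
    test_samples: frozenset[str]
    train_samples: frozenset[str]


@dataclass
class SeedRun:
    seed: int
    selected_features: list[str]
    model: MERFModel
    test_pearson: float
    test_spearman: float
    n_train: int
    n_test: int


@dataclass
class PipelineConfig:
    n_seeds: int = 10
    prevalence_min: float = 0.10
    top_k: int = 15
    strong_threshold: float = 0.4
    p_threshold: float = 0.05
    fdr_threshold: float = 0.1
    hc_report_threshold: float = 0.7  # below: flagged "not examined further"
    always_keep_covariates: bool = False
    boruta_max_runs: int = 50
    boruta_alpha: float = 0.01
    boruta_trees: int = 100
    merf: MERFConfig = field(default_factory=lambda: MERFConfig(n_trees=150, max_em_iterations=10))
    importance_repeats: int = 5
    importance_folds: int = 5
    altmann_n_perm: int = 50
    importance_p_method: str = "auto"  # auto | mirrored | altmann | none


@dataclass
class PipelineReport:
    group: str
    outcome: str
    feature_kind: str
    seed_runs: list[SeedRun]
    final_features: list[str]
    final_model: MERFModel | None
    importance_table: ImportanceTable | None
    feature_universe: list[str]
    master_seed: int
    examined_further: bool = True

    @property
    def per_seed_correlations(self) -> list[float]:
        return [r.test_pearson for r in self.seed_runs]

    @property
    def mean_correlation(self) -> float:
        return float(np.mean(self.per_seed_correlations))

    @property
    def sd_correlation(self) -> float:
        return float(np.std(self.per_seed_correlations, ddof=1))

    def per_seed_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seed": [r.seed for r in self.seed_runs],
                "n_train": [r.n_train for r in self.seed_runs],
                "n_test": [r.n_test for r in self.seed_runs],
                "n_selected": [len(r.selected_features) for r in self.seed_runs],
                "test_pearson": [r.test_pearson for r in self.seed_runs],
                "test_spearman": [r.test_spearman for r in self.seed_runs],
            }
        )


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def longitudinal_split(records: Sequence[VisitRecord], seed: int) -> SplitPlan:
    """One uniformly chosen sample per multi-sample subject goes to test;
    single-sample subjects stay entirely in training."""
    by_subject: dict[str, list[str]] = {}
    for r in records:
        if r.sample_id is not None:
            by_subject.setdefault(r.subject_id, []).append(r.sample_id)
    if not by_subject:
        raise ValueError("empty cohort: no records with samples")
    rng = np.random.default_rng(seed)
    test: set[str] = set()
    train: set[str] = set()
    for subject in sorted(by_subject):
        samples = sorted(by_subject[subject])
        if len(samples) >= 2:
            held = samples[int(rng.integers(len(samples)))]
            test.add(held)
            train.update(s for s in samples if s != held)
        else:
            train.update(samples)
    return SplitPlan(seed=seed, test_samples=frozenset(test), train_samples=frozenset(train))


# ---------------------------------------------------------------------------
# design-matrix assembly
# ---------------------------------------------------------------------------


def covariate_matrix(
    records: Sequence[VisitRecord],
    include_medications: bool = False,
    extra_clinical: bool = False,
) -> pd.DataFrame:
    """Numeric covariate matrix indexed by sample id.

    The default is the eight minimal covariates; ``include_medications``
    adds one indicator per drug class (plus CDR when ``extra_clinical``),
    which is only legitimate for the species-composition screen.
    """
    rows = {}
    med_classes: set[str] = set()
    if include_medications:
        for r in records:
            med_classes.update(r.medications)
    for r in records:
        if r.sample_id is None:
            continue
        row = {
            "sex": 1.0 if r.sex == "female" else 0.0,
            "age": r.age,
            "antibiotics_6mo": float(r.antibiotics_6mo),
            "hospitalized_6mo": float(r.hospitalized_6mo),
            "mis": r.mis,
            "cfs": r.cfs,
            "polypharmacy": float(r.polypharmacy),
            "education_years": r.education_years,
        }
        if include_medications:
            for m in sorted(med_classes):
                row[f"med_{m}"] = float(m in r.medications)
        if extra_clinical:
            row["cdr"] = r.cdr
        rows[r.sample_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def outcome_values(
    records: Sequence[VisitRecord], outcome: str
) -> dict[str, float]:
    """Outcome value per sample id.

    Composite z-scores are standardized per visit across ALL supplied
    records (standardization precedes any group restriction).
    """
    if outcome == "adas_cog_13":
        return {r.sample_id: r.adas_total for r in records if r.sample_id}
    domain = {"memory_z": "memory", "ef_z": "executive_function"}.get(outcome)
    if domain is None:
        raise ValueError(f"unknown outcome {outcome!r}")
    scores = composite_zscore(records, domain, on_small_group="drop")
    z = {(s.subject_id, s.visit_index): s.z for s in scores}
    return {
        r.sample_id: z[(r.subject_id, r.visit_index)]
        for r in records
        if r.sample_id and (r.subject_id, r.visit_index) in z
    }


def _prevalence_filter(
    table: AbundanceTable, sample_ids: Sequence[str], min_prevalence: float
) -> list[str]:
    sub = table.subset_samples(list(sample_ids))
    keep = (sub.values > 0).mean(axis=0) >= min_prevalence
    return [f for f, k in zip(table.feature_ids, keep) if k]


def _safe_corr(a: np.ndarray, b: np.ndarray, method: str = "pearson") -> float:
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(a, b)[0])
    return float(stats.spearmanr(a, b)[0])


# ---------------------------------------------------------------------------
# cognitive pipeline
# ---------------------------------------------------------------------------


def run_cognitive_pipeline(
    group: str,
    outcome: str,
    feature_table: AbundanceTable,
    records: Sequence[VisitRecord],
    config: PipelineConfig | None = None,
    master_seed: int = 0,
    annotate_final: bool = True,
) -> PipelineReport:
    """Run the per-group cognitive-score prediction pipeline."""
    config = config or PipelineConfig()
    statuses = {s.subject_id: s.status for s in classify_subjects(records)}
    y_by_sample = outcome_values(records, outcome)

    table_samples = set(feature_table.sample_ids)
    group_records = [
        r
        for r in records
        if statuses[r.subject_id] == group
        and r.sample_id in table_samples
        and r.sample_id in y_by_sample
    ]
    if not group_records:
        raise ValueError(f"no usable samples for group {group!r}")
    n_subjects = len({r.subject_id for r in group_records})
    if n_subjects < 10:
        warnings.warn(
            f"group {group} has only {n_subjects} subjects; proceeding", RuntimeWarning
        )

    sample_ids = [r.sample_id for r in group_records]
    clusters = np.array([r.subject_id for r in group_records])
    y = np.array([y_by_sample[s] for s in sample_ids])

    kept_features = _prevalence_filter(feature_table, sample_ids, config.prevalence_min)
    feat_frame = feature_table.subset_samples(sample_ids).to_dataframe()[kept_features]
    cov_frame = covariate_matrix(group_records).loc[sample_ids]
    X_frame = pd.concat([feat_frame, cov_frame], axis=1)
    universe = list(X_frame.columns)
    X = X_frame.to_numpy(dtype=float)
    sample_pos = {s: i for i, s in enumerate(sample_ids)}

    seed_seq = np.random.SeedSequence(master_seed)
    seed_runs: list[SeedRun] = []
    union: dict[str, None] = {}
    for child in seed_seq.spawn(config.n_seeds):
        seed = int(child.generate_state(1)[0] % (2**31 - 1))
        plan = longitudinal_split(group_records, seed)
        train_idx = np.array(sorted(sample_pos[s] for s in plan.train_samples))
        test_idx = np.array(sorted(sample_pos[s] for s in plan.test_samples))

        if len(train_idx) >= 20:
            boruta = boruta_select(
                X[train_idx],
                y[train_idx],
                max_runs=config.boruta_max_runs,
                alpha=config.boruta_alpha,
                seed=seed,
                n_trees=config.boruta_trees,
                feature_names=universe,
            )
            selected = list(boruta.confirmed)
        else:  # too few training samples for selection; keep covariates
            warnings.warn(
                f"training split has {len(train_idx)} samples; skipping Boruta",
                RuntimeWarning,
            )
            selected = []
        if config.always_keep_covariates:
            selected += [c for c in MINIMAL_COVARIATES if c not in selected]
        if not selected:  # fall back to the minimal covariates
            selected = list(MINIMAL_COVARIATES)
        cols = [universe.index(f) for f in selected]

        merf_cfg = _reseed(config.merf, seed)
        model = fit_merf(
            X[np.ix_(train_idx, cols)], y[train_idx], clusters[train_idx],
            merf_cfg, feature_names=selected,
        )
        preds = predict_merf(model, X[np.ix_(test_idx, cols)], clusters[test_idx])
        seed_runs.append(
            SeedRun(
                seed=seed,
                selected_features=selected,
                model=model,
                test_pearson=_safe_corr(y[test_idx], preds, "pearson"),
                test_spearman=_safe_corr(y[test_idx], preds, "spearman"),
                n_train=len(train_idx),
                n_test=len(test_idx),
            )
        )
        for f in selected:
            union.setdefault(f, None)

    final_features = [f for f in universe if f in union]
    final_seed = int(seed_seq.generate_state(1)[0] % (2**31 - 1))
    cols = [universe.index(f) for f in final_features]
    final_model = fit_merf(
        X[:, cols], y, clusters, _reseed(config.merf, final_seed),
        feature_names=final_features,
    )

    importance_table = None
    if annotate_final:
        folds = min(config.importance_folds, len(np.unique(clusters)))
        raw_imp = permutation_importance(
            final_model, X[:, cols], y, clusters,
            n_repeats=config.importance_repeats,
            holdout_folds=folds,
            seed=final_seed,
        )
        imp_p, method = _importance_p(
            raw_imp, X[:, cols], y, clusters, config, final_seed
        )
        spearman = spearman_with_fdr(X[:, cols], y, feature_names=final_features)
        importance_table = build_importance_table(
            final_features, raw_imp, imp_p, spearman, method,
            strong_threshold=config.strong_threshold,
            p_threshold=config.p_threshold,
            fdr_threshold=config.fdr_threshold,
        )

    mean_corr = float(np.mean([r.test_pearson for r in seed_runs]))
    return PipelineReport(
        group=group,
        outcome=outcome,
        feature_kind=feature_table.feature_kind,
        seed_runs=seed_runs,
        final_features=final_features,
        final_model=final_model,
        importance_table=importance_table,
        feature_universe=universe,
        master_seed=master_seed,
        examined_further=not (group == "HC" and mean_corr < config.hc_report_threshold),
    )


def _reseed(merf_config: MERFConfig, seed: int) -> MERFConfig:
    from dataclasses import replace

    return replace(merf_config, seed=seed)


def _importance_p(
    raw_imp: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    clusters: np.ndarray,
    config: PipelineConfig,
    seed: int,
) -> tuple["np.ndarray | None", str]:
    method = config.importance_p_method
    if method in ("auto", "mirrored"):
        try:
            return importance_pvalues(raw_imp), "mirrored_null"
        except ValueError:
            if method == "mirrored":
                raise
    if method in ("auto", "altmann") and config.altmann_n_perm >= 1:
        from dataclasses import replace

        null_cfg = replace(config.merf, max_em_iterations=min(config.merf.max_em_iterations, 5))
        p = altmann_importance_pvalues(
            X, y, clusters, raw_imp, null_cfg,
            n_perm=config.altmann_n_perm, seed=seed,
        )
        return p, "altmann"
    return None, "none"


# ---------------------------------------------------------------------------
# covariate screen
# ---------------------------------------------------------------------------

_COVARIATE_CATEGORY = {
    "sex": "demographic",
    "age": "demographic",
    "education_years": "demographic",
    "polypharmacy": "medication",
    "antibiotics_6mo": "clinical",
    "hospitalized_6mo": "clinical",
    "mis": "clinical",
    "cfs": "clinical",
    "cdr": "clinical",
}


def _covariate_category(name: str) -> str:
    if name.startswith("med_"):
        return "medication"
    return _COVARIATE_CATEGORY.get(name, "clinical")


def covariate_screen(
    species_table: AbundanceTable,
    records: Sequence[VisitRecord],
    config: PipelineConfig | None = None,
    master_seed: int = 0,
    transform: str = "none",
    fdr_alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species clinical-covariate screen.

    For every species passing the prevalence filter, its relative
    abundance is predicted from the full covariate set — demographics,
    clinical scores, comorbidity flags and one indicator per medication
    class (this screen deliberately INCLUDES medications, unlike the
    cognitive pipeline) — with the subject as random effect; per-covariate
    permutation-importance p-values are FDR-adjusted within each model.

    Returns (long results table, covariate frequency/category ranking).
    """
    config = config or PipelineConfig()
    usable = [r for r in records if r.sample_id in set(species_table.sample_ids)]
    if not usable:
        raise ValueError("no records match species table samples")
    cov = covariate_matrix(usable, include_medications=True, extra_clinical=True)
    sample_ids = list(cov.index)
    clusters = np.array(
        [r.subject_id for r in usable if r.sample_id in set(sample_ids)]
    )
    sub = species_table.subset_samples(sample_ids)
    kept = _prevalence_filter(species_table, sample_ids, config.prevalence_min)
    covariates = list(cov.columns)
    X = cov.to_numpy(dtype=float)

    seed_seq = np.random.SeedSequence(master_seed)
    long_rows = []
    n_models = 0
    for species, child in zip(kept, seed_seq.spawn(len(kept))):
        y = sub.values[:, sub.feature_ids.index(species)].astype(float)
        if transform == "arcsine_sqrt":
            y = np.arcsin(np.sqrt(np.clip(y, 0, 1)))
        if np.ptp(y) == 0:
            warnings.warn(f"species {species} has zero variance; skipped", RuntimeWarning)
            continue
        seed = int(child.generate_state(1)[0] % (2**31 - 1))
        model = fit_merf(X, y, clusters, _reseed(config.merf, seed), feature_names=covariates)
        folds = min(config.importance_folds, len(np.unique(clusters)))
        raw_imp = permutation_importance(
            model, X, y, clusters,
            n_repeats=config.importance_repeats, holdout_folds=folds, seed=seed,
        )
        p, method = _importance_p(raw_imp, X, y, clusters, config, seed)
        if p is None:
            p = np.full(len(covariates), np.nan)
        q = bh_fdr(p) if np.isfinite(p).all() else np.full(len(covariates), np.nan)
        n_models += 1
        for j, c in enumerate(covariates):
            long_rows.append(
                {
                    "species": species,
                    "covariate": c,
                    "importance": float(raw_imp[j]),
                    "p_value": float(p[j]),
                    "q_value": float(q[j]),
                    "significant": bool(q[j] < fdr_alpha) if np.isfinite(q[j]) else False,
                    "p_method": method,
                }
            )

    long = pd.DataFrame(long_rows)
    if long.empty:
        raise ValueError("no species passed the screen")
    freq = (
        long.groupby("covariate")["significant"]
        .mean()
        .rename("frequency")
        .reset_index()
        .sort_values(["frequency", "covariate"], ascending=[False, True])
        .reset_index(drop=True)
    )
    freq["n_models"] = n_models
    freq["category"] = [_covariate_category(c) for c in freq["covariate"]]
    return long, freq


# ---------------------------------------------------------------------------
# cross-outcome comparison
# ---------------------------------------------------------------------------


def compare_rankings(reports: Sequence[PipelineReport], top_k: int = 15) -> pd.DataFrame:
    """Rank/correlation matrix over the union of top-k features.

    One row per feature in the union of the reports' top-k tables; per
    report, the feature's importance rank (NaN when absent from that
    report's top-k) and its Spearman rho.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    universe = set(reports[0].feature_universe)
    for rep in reports[1:]:
        if set(rep.feature_universe) != universe:
            raise ValueError("reports do not share a feature universe")
    for rep in reports:
        if rep.importance_table is None:
            raise ValueError(f"report {rep.outcome} has no importance table")

    tops = {rep.outcome: rep.importance_table.top(top_k) for rep in reports}
    union: list[str] = []
    for rep in reports:
        for f in tops[rep.outcome]["feature"]:
            if f not in union:
                union.append(f)

    out = pd.DataFrame({"feature": union})
    for rep in reports:
        top = tops[rep.outcome].set_index("feature")
        full = rep.importance_table.frame.set_index("feature")
        out[f"rank_{rep.outcome}"] = [
            float(top.loc[f, "rank"]) if f in top.index else np.nan for f in union
        ]
        out[f"rho_{rep.outcome}"] = [
            float(full.loc[f, "spearman_rho"]) if f in full.index else np.nan
            for f in union
        ]
    return out
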