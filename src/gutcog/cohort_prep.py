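"""Subject classification, composite cognitive z-scores, alpha diversity
and random-intercept linear mixed models.

Cognitive status is assigned once per subject from the baseline visit:
a dementia diagnosis gives AD; otherwise CDR < 1, preserved daily
function and a word-list delayed-recall score of at least 4 give MCI;
everyone else is a healthy control.

Composite scores sum named subtests per visit (memory: word recall, word
recognition, orientation, remembering recognition instructions, delayed
recall; executive function: maze time, maze mistakes, and the two
NIH-toolbox speed tasks sign-flipped so that higher always means worse)
and are z-standardized within each visit index across all subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    EF_ADAS_SUBTESTS,
    EF_TOOLBOX_SUBTESTS,
    MEMORY_SUBTESTS,
    AbundanceTable,
    VisitRecord,
)

__all__ = [
    "CognitiveStatus",
    "CompositeScore",
    "LMMFit",
    "classify_subjects",
    "composite_zscore",
    "inverse_simpson",
    "diversity_per_sample",
    "fit_random_intercept_lmm",
    "diversity_lmm",
    "cognitive_stability_lmm",
    "GROUPS",
]

GROUPS = ("HC", "MCI", "AD")


@dataclass(frozen=True)
class CognitiveStatus:
    subject_id: str
    status: str  # HC | MCI | AD
    basis: str  # rule identifier


@dataclass(frozen=True)
class CompositeScore:
    subject_id: str
    visit_index: int
    domain: str  # memory | executive_function
    raw_sum: float
    z: float


@dataclass
class LMMFit:
    """Random-intercept LMM summary (REML)."""

    fixed_names: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    sigma2_b: float
    sigma2_e: float
    log_likelihood: float
    converged: bool

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.fixed_names,
                "estimate": self.estimates,
                "std_error": self.std_errors,
                "p_value": self.p_values,
            }
        )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_subjects(records: Sequence[VisitRecord]) -> list[CognitiveStatus]:
    """Assign exactly one HC/MCI/AD status per subject from baseline data."""
    baselines: dict[str, VisitRecord] = {}
    subjects: set[str] = set()
    for r in records:
        subjects.add(r.subject_id)
        if r.visit_index == 1:
            baselines[r.subject_id] = r
    missing = sorted(subjects - set(baselines))
    if missing:
        raise ValueError(f"subject(s) without baseline visit: {missing[:5]}")

    out = []
    for subject in sorted(baselines):
        b = baselines[subject]
        if b.dementia_diagnosis:
            out.append(CognitiveStatus(subject, "AD", "dementia_diagnosis"))
            continue
        recall = b.adas_subtests.get("delayed_recall")
        if recall is None:
            raise ValueError(
                f"missing delayed_recall at baseline for non-AD subject {subject}"
            )
        if b.cdr < 1 and b.normal_daily_function and recall >= 4:
            out.append(CognitiveStatus(subject, "MCI", "cdr<1+function+recall>=4"))
        else:
            out.append(CognitiveStatus(subject, "HC", "default"))
    return out


# ---------------------------------------------------------------------------
# composite z-scores
# ---------------------------------------------------------------------------


def _raw_sum(record: VisitRecord, domain: str) -> float:
    if domain == "memory":
        try:
            return float(sum(record.adas_subtests[k] for k in MEMORY_SUBTESTS))
        except KeyError as exc:
            raise ValueError(
                f"missing memory subtest {exc} for {record.subject_id} "
                f"visit {record.visit_index}"
            ) from exc
    if domain == "executive_function":
        try:
            adas = sum(record.adas_subtests[k] for k in EF_ADAS_SUBTESTS)
            # toolbox tasks score higher = better; flip so higher = worse
            toolbox = sum(record.toolbox_subtests[k] for k in EF_TOOLBOX_SUBTESTS)
        except KeyError as exc:
            raise ValueError(
                f"missing executive-function subtest {exc} for "
                f"{record.subject_id} visit {record.visit_index}"
            ) from exc
        return float(adas - toolbox)
    raise ValueError(f"unknown domain {domain!r}")


def composite_zscore(
    records: Sequence[VisitRecord],
    domain: str,
    ddof: int = 1,
    on_small_group: str = "error",
) -> list[CompositeScore]:
    """Per-visit standardized composite scores; higher z = worse performance.

    Standardization pools all subjects sharing a visit index (sample SD by
    default).  A visit group of size one or with zero spread has no defined
    z; ``on_small_group`` chooses between raising (default) and silently
    dropping such visits (the pipeline drops — deep follow-up visits often
    hold a single subject).
    """
    if on_small_group not in {"error", "drop"}:
        raise ValueError("on_small_group must be 'error' or 'drop'")
    sums = [(r, _raw_sum(r, domain)) for r in records]
    by_visit: dict[int, list[tuple[VisitRecord, float]]] = {}
    for r, s in sums:
        by_visit.setdefault(r.visit_index, []).append((r, s))

    out: list[CompositeScore] = []
    for visit in sorted(by_visit):
        group = by_visit[visit]
        vals = np.array([s for _, s in group], dtype=float)
        sd = vals.std(ddof=ddof) if len(vals) > 1 else 0.0
        if len(vals) < 2 or sd == 0:
            if on_small_group == "drop":
                continue
            if len(vals) < 2:
                raise ValueError(
                    f"visit group {visit} has {len(vals)} record(s); z undefined"
                )
            raise ValueError(f"visit group {visit} has zero SD; z undefined")
        mean = vals.mean()
        for (r, s) in group:
            out.append(
                CompositeScore(
                    subject_id=r.subject_id,
                    visit_index=visit,
                    domain=domain,
                    raw_sum=s,
                    z=(s - mean) / sd,
                )
            )
    return out


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def inverse_simpson(p: Sequence[float] | np.ndarray) -> float:
    """Inverse Simpson index ``1 / sum(p_k^2)`` of a closed proportion vector."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty proportion vector")
    if np.any(p < 0):
        raise ValueError("negative proportion")
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"proportions sum to {total}, not 1")
    return float(1.0 / np.sum(p**2))


def diversity_per_sample(table: AbundanceTable) -> pd.Series:
    div = 1.0 / np.sum(table.values**2, axis=1)
    return pd.Series(div, index=list(table.sample_ids), name="inverse_simpson")


# ---------------------------------------------------------------------------
# linear mixed models
# ---------------------------------------------------------------------------


def fit_random_intercept_lmm(
    response: Sequence[float] | np.ndarray,
    fixed_terms: pd.DataFrame,
    cluster_ids: Sequence[str],
    reml: bool = True,
) -> LMMFit:
    """REML fit of ``response ~ fixed_terms + (1 | cluster)``.

    Categorical (object/category/bool) columns are treatment-coded with the
    first sorted level as reference ("HC" forced as reference for a
    ``cog_status`` column).  Wald z-tests per fixed effect.
    """
    y = np.asarray(response, dtype=float)
    clusters = pd.Series([str(c) for c in cluster_ids], name="cluster")
    if clusters.nunique() < 2:
        raise ValueError("need >= 2 clusters for a random-intercept model")
    if len(y) != len(fixed_terms) or len(y) != len(clusters):
        raise ValueError("response / fixed_terms / cluster_ids length mismatch")

    X_frame = _encode_design(fixed_terms)
    X_frame.insert(0, "Intercept", 1.0)
    X = X_frame.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient")

    members = [np.where((clusters == cid).to_numpy())[0] for cid in clusters.unique()]
    return _profiled_reml(y, X, list(X_frame.columns), members, reml=reml)


def _profiled_reml(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str],
    members: list[np.ndarray],
    reml: bool = True,
) -> LMMFit:
    """Exact profiled (RE)ML for the random-intercept model.

    With ``V*(lam) = I + lam*J`` per cluster, beta and sigma2_e have closed
    forms given the variance ratio ``lam = sigma2_b / sigma2_e``; the REML
    criterion is minimized over ``lam`` by bounded scalar search, with the
    ``lam = 0`` boundary evaluated explicitly (so OLS is recovered exactly
    when the between-cluster variance vanishes).
    """
    from scipy.optimize import minimize_scalar

    n, p = X.shape
    dof = n - p if reml else n
    n_i = np.array([len(idx) for idx in members], dtype=float)

    def _assemble(lam: float):
        a = lam / (1.0 + n_i * lam)
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        for i, idx in enumerate(members):
            Xi, yi = X[idx], y[idx]
            x_sum = Xi.sum(axis=0)
            y_sum = yi.sum()
            xtvx += Xi.T @ Xi - a[i] * np.outer(x_sum, x_sum)
            xtvy += Xi.T @ yi - a[i] * x_sum * y_sum
        beta = np.linalg.solve(xtvx, xtvy)
        rss = 0.0
        for i, idx in enumerate(members):
            r = y[idx] - X[idx] @ beta
            rss += float(r @ r) - a[i] * float(r.sum()) ** 2
        return beta, xtvx, rss

    def deviance(lam: float) -> float:
        _, xtvx, rss = _assemble(lam)
        d = float(np.sum(np.log1p(n_i * lam))) + dof * np.log(rss)
        if reml:
            d += float(np.linalg.slogdet(xtvx)[1])
        return d

    result = minimize_scalar(
        deviance, bounds=(0.0, 1e4), method="bounded",
        options={"xatol": 1e-10, "maxiter": 500},
    )
    lam = float(result.x)
    if deviance(0.0) <= deviance(lam):
        lam = 0.0
    converged = bool(getattr(result, "success", True))

    beta, xtvx, rss = _assemble(lam)
    sigma2_e = rss / dof
    sigma2_b = lam * sigma2_e
    cov_beta = np.linalg.inv(xtvx) * sigma2_e
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p_values = 2.0 * stats.norm.sf(np.abs(z))

    llf = -0.5 * (
        dof * np.log(2.0 * np.pi * sigma2_e)
        + float(np.sum(np.log1p(n_i * lam)))
        + rss / sigma2_e
    )
    if reml:
        llf -= 0.5 * float(np.linalg.slogdet(xtvx / sigma2_e)[1])

    return LMMFit(
        fixed_names=names,
        estimates=beta,
        std_errors=se,
        p_values=p_values,
        sigma2_b=float(sigma2_b),
        sigma2_e=float(sigma2_e),
        log_likelihood=float(llf),
        converged=converged,
    )


def _encode_design(fixed_terms: pd.DataFrame) -> pd.DataFrame:
    if fixed_terms.shape[1] == 0:  # intercept-only model
        return pd.DataFrame(index=fixed_terms.index)
    cols = []
    for name in fixed_terms.columns:
        col = fixed_terms[name]
        if col.dtype == bool:
            cols.append(col.astype(float).rename(name))
        elif col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.astype(str).unique())
            if name == "cog_status" and "HC" in levels:
                levels = ["HC"] + [l for l in levels if l != "HC"]
            for level in levels[1:]:
                cols.append(
                    (col.astype(str) == level).astype(float).rename(f"{name}[{level}]")
                )
        else:
            cols.append(col.astype(float).rename(name))
    return pd.concat(cols, axis=1)


def _records_frame(
    records: Sequence[VisitRecord], statuses: Mapping[str, str]
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "sample_id": [r.sample_id for r in records],
            "sex": [r.sex for r in records],
            "age": [r.age for r in records],
            "education_years": [r.education_years for r in records],
            "antibiotics_6mo": [r.antibiotics_6mo for r in records],
            "time_days": [r.days_since_enrollment for r in records],
            "cog_status": [statuses[r.subject_id] for r in records],
        }
    )


def diversity_lmm(
    records: Sequence[VisitRecord],
    table: AbundanceTable,
    statuses: Mapping[str, str],
) -> tuple[pd.DataFrame, LMMFit]:
    """Inverse-Simpson diversity regressed on sex, age, education,
    antibiotic use, days since enrollment and cognitive status, with a
    subject random intercept.  Returns (per-sample diversity frame, fit)."""
    div = diversity_per_sample(table)
    with_samples = [r for r in records if r.sample_id in div.index]
    if not with_samples:
        raise ValueError("no records match table samples")
    frame = _records_frame(with_samples, statuses)
    frame["inverse_simpson"] = [div[r.sample_id] for r in with_samples]
    fit = fit_random_intercept_lmm(
        frame["inverse_simpson"].to_numpy(),
        frame[["sex", "age", "education_years", "antibiotics_6mo", "time_days", "cog_status"]],
        frame["subject_id"].tolist(),
    )
    return frame, fit


def cognitive_stability_lmm(
    records: Sequence[VisitRecord],
    scores: Mapping[tuple[str, int], float],
    statuses: Mapping[str, str],
) -> LMMFit:
    """Cognitive score regressed on days since enrollment and cognitive
    status with a subject random intercept.

    ``scores`` maps (subject_id, visit_index) to the score being modeled.
    """
    rows = [r for r in records if (r.subject_id, r.visit_index) in scores]
    if not rows:
        raise ValueError("no records match the provided scores")
    frame = _records_frame(rows, statuses)
    y = np.array([scores[(r.subject_id, r.visit_index)] for r in rows])
    return fit_random_intercept_lmm(
        y, frame[["time_days", "cog_status"]], frame["subject_id"].tolist()
    )
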