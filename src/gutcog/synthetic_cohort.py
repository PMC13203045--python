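"""Synthetic longitudinal cohorts with planted microbiome-cognition effects.

The generator emulates the statistical structure the analysis assumes:
three cognitive-status groups with group-specific covariate
distributions, repeated visits on a 90-day cadence with overdispersed
per-subject visit counts, compositional feature tables (species,
pathways, KO terms) built from log-normal latents with subject-specific
offsets, and a cognitive outcome driven by a configurable set of planted
features plus a subject random intercept and residual noise.  Full
ground truth (planted effects, intercepts, noiseless outcomes, feature
prevalence) is returned for recovery tests.

Outcome scale: the per-group latent outcome is normal with parameters
pre-adjusted (fixed point on censored-normal moments) so that after
clipping to the 0-85 assessment scale the group mean/SD match the
configured values; the subject-level SD is reduced by the configured
random-intercept and residual variances so the total marginal SD stays
on target.  Subtest decomposition is an arbitrary, documented fixed-
proportion split of the total (plus noise) whose only purpose is to
exercise the composite-score code paths; baseline delayed-recall values
are nudged across the MCI rule threshold and CDR / dementia / daily-
function fields are set per group so that subject classification
reconstructs the configured groups.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .io_formats import (
    EF_ADAS_SUBTESTS,
    EF_TOOLBOX_SUBTESTS,
    MEMORY_SUBTESTS,
    AbundanceTable,
    VisitRecord,
    write_humann_table,
    write_metadata,
    write_metaphlan_profiles,
)

__all__ = [
    "GroupCovariateParams",
    "PlantedEffect",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "simulate_cohort",
    "null_cohort",
    "DEFAULT_COVARIATE_PARAMS",
]


@dataclass(frozen=True)
class GroupCovariateParams:
    age_mean: float
    age_sd: float
    adas_mean: float
    adas_sd: float
    cfs_mean: float
    cfs_sd: float
    mis_mean: float
    mis_sd: float
    p_female: float
    p_polypharmacy: float
    p_antibiotics: float
    p_hospitalized: float

    def __post_init__(self) -> None:
        for name in ("p_female", "p_polypharmacy", "p_antibiotics", "p_hospitalized"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")


# Cohort-table defaults: per-group age / sex / polypharmacy / antibiotics /
# hospitalization / CFS / MIS / total-score distributions.
DEFAULT_COVARIATE_PARAMS: dict[str, GroupCovariateParams] = {
    "HC": GroupCovariateParams(70.2, 7.46, 9.01, 4.42, 2.07, 1.02, 1.21, 0.470,
                               0.690, 0.272, 0.177, 0.082),
    "MCI": GroupCovariateParams(75.1, 7.22, 21.0, 12.8, 2.54, 0.942, 1.28, 0.510,
                                0.525, 0.400, 0.225, 0.100),
    "AD": GroupCovariateParams(73.9, 5.75, 32.3, 20.1, 3.52, 1.53, 1.68, 0.627,
                               0.480, 0.680, 0.080, 0.040),
}

MEDICATION_CLASSES = (
    "antihypertensive",
    "psychoactive",
    "statin",
    "ppi",
    "nsaid",
    "metformin",
    "anticoagulant",
    "levothyroxine",
    "antihistamine",
    "bisphosphonate",
)


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth effect of one feature on the cognitive outcome.

    ``effect_size`` multiplies the standardized arcsine-sqrt abundance
    (bounded leverage); shapes: ``linear``, ``threshold`` (indicator of an
    above-average transform) and ``interaction`` (transform times the
    subject's standardized age).
    """

    feature_id: str
    effect_size: float
    feature_kind: str = "species"
    shape: str = "linear"

    def __post_init__(self) -> None:
        if self.shape not in {"linear", "threshold", "interaction"}:
            raise ValueError(f"unknown planted-effect shape {self.shape!r}")
        if self.feature_kind not in {"species", "pathway", "ko"}:
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")


@dataclass
class SimulationConfig:
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 158, "MCI": 40, "AD": 25}
    )
    visits_mean: float = 3.8
    visits_sd: float = 2.4
    visit_spacing_days: float = 90.0
    n_species: int = 150
    n_pathways: int = 80
    n_ko: int = 120
    planted: list[PlantedEffect] = field(default_factory=list)
    sigma_b: float = 1.0
    sigma_e: float = 1.0
    covariate_params: dict[str, GroupCovariateParams] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS)
    )
    subject_offset_sd: float = 0.8  # latent log-abundance subject offset
    within_visit_sd: float = 0.6  # latent log-abundance per-visit noise
    base_spread: float = 1.5  # SD of per-feature baseline log abundance
    prevalence_range: tuple[float, float] = (0.3, 1.0)
    planted_min_prevalence: float = 0.9
    p_missing_sample: float = 0.0
    education_mean: float = 16.0
    education_sd: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"n_per_group[{g}] must be >= 1")
            if g not in self.covariate_params:
                raise ValueError(f"no covariate_params for group {g!r}")
        if self.sigma_b < 0 or self.sigma_e < 0:
            raise ValueError("sigma_b and sigma_e must be >= 0")
        for n in (self.n_species, self.n_pathways, self.n_ko):
            if n < 1:
                raise ValueError("feature counts must be >= 1")
        if not 0 <= self.p_missing_sample <= 1:
            raise ValueError("p_missing_sample must lie in [0, 1]")


@dataclass
class GroundTruth:
    planted: list[PlantedEffect]
    b: dict[str, float]  # subject random intercepts
    subject_level: dict[str, float]  # c_i, fixed subject cognitive level
    noiseless_outcome: dict[tuple[str, int], float]  # (subject, visit) -> value
    unclipped_outcome: dict[tuple[str, int], float]  # before the 0-85 clip
    prevalence: dict[str, dict[str, float]]  # kind -> feature -> fraction nonzero
    group: dict[str, str]  # subject -> configured group
    null: bool = False
    seed: int = 0


@dataclass
class SyntheticCohort:
    records: list[VisitRecord]
    tables: dict[str, AbundanceTable]  # keys: species, pathway, ko
    truth: GroundTruth
    ko_pathway_map: dict[str, list[str]]

    def write(self, outdir: str) -> dict[str, str]:
        """Write metadata + tables in the dialects the readers consume."""
        import json
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "metadata": os.path.join(outdir, "metadata.tsv"),
            "species": os.path.join(outdir, "species.tsv"),
            "pathway": os.path.join(outdir, "pathways.tsv"),
            "ko": os.path.join(outdir, "ko.tsv"),
            "ko_pathway_map": os.path.join(outdir, "ko_pathway_map.tsv"),
            "ground_truth": os.path.join(outdir, "ground_truth.json"),
        }
        write_metadata(self.records, paths["metadata"])
        write_metaphlan_profiles(self.tables["species"], paths["species"])
        write_humann_table(self.tables["pathway"], paths["pathway"], scale=1e6)
        write_humann_table(self.tables["ko"], paths["ko"], scale=1e6)
        with open(paths["ko_pathway_map"], "w") as fh:
            fh.write("ko\tpathway\n")
            for ko in sorted(self.ko_pathway_map):
                for pw in sorted(self.ko_pathway_map[ko]):
                    fh.write(f"{ko}\t{pw}\n")
        truth = {
            "null": self.truth.null,
            "seed": self.truth.seed,
            "planted": [
                {
                    "feature_id": p.feature_id,
                    "feature_kind": p.feature_kind,
                    "effect_size": p.effect_size,
                    "shape": p.shape,
                }
                for p in self.truth.planted
            ],
            "b": self.truth.b,
            "subject_level": self.truth.subject_level,
            "group": self.truth.group,
            "noiseless_outcome": {
                f"{s}:{v}": val for (s, v), val in self.truth.noiseless_outcome.items()
            },
            "unclipped_outcome": {
                f"{s}:{v}": val for (s, v), val in self.truth.unclipped_outcome.items()
            },
            "prevalence": self.truth.prevalence,
        }
        with open(paths["ground_truth"], "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        return paths


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _censored_normal_params(
    target_mean: float, target_sd: float, lo: float = 0.0, hi: float = 85.0
) -> tuple[float, float]:
    """Latent N(m, s) such that clip(X, lo, hi) has the target mean/SD."""
    m, s = target_mean, target_sd
    for _ in range(60):
        a, b = (lo - m) / s, (hi - m) / s
        z = stats.norm.cdf(b) - stats.norm.cdf(a)
        if z <= 1e-12:
            break
        pa, pb = stats.norm.pdf(a), stats.norm.pdf(b)
        mean_trunc = m + s * (pa - pb) / z
        var_trunc = s**2 * (
            1 + (a * pa - b * pb) / z - ((pa - pb) / z) ** 2
        )
        ey = lo * stats.norm.cdf(a) + hi * stats.norm.sf(b) + z * mean_trunc
        ey2 = (
            lo**2 * stats.norm.cdf(a)
            + hi**2 * stats.norm.sf(b)
            + z * (var_trunc + mean_trunc**2)
        )
        sd_y = float(np.sqrt(max(ey2 - ey**2, 1e-12)))
        m += target_mean - ey
        s *= target_sd / sd_y
    return m, s


def _visit_counts(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    """Truncated (min 1) negative-binomial visit counts, overdispersed."""
    var = sd**2
    if var <= mean:  # fall back to Poisson when not overdispersed
        draws = rng.poisson(mean, size=n)
    else:
        r = mean**2 / (var - mean)
        p = r / (r + mean)
        draws = rng.negative_binomial(r, p, size=n)
    return np.maximum(draws, 1)


def _compositional_table(
    rng: np.random.Generator,
    sample_subject_idx: np.ndarray,
    n_subjects: int,
    feature_ids: list[str],
    sample_ids: list[str],
    feature_kind: str,
    config: SimulationConfig,
    prevalence: np.ndarray,
) -> AbundanceTable:
    """Log-normal latents + subject offsets + structural zeros + closure."""
    n_samples = len(sample_ids)
    p = len(feature_ids)
    base = rng.normal(0.0, config.base_spread, size=p)
    subject_offset = rng.normal(0.0, config.subject_offset_sd, size=(n_subjects, p))
    noise = rng.normal(0.0, config.within_visit_sd, size=(n_samples, p))
    present = rng.random((n_subjects, p)) < prevalence[None, :]
    latent = np.exp(base[None, :] + subject_offset[sample_subject_idx] + noise)
    latent *= present[sample_subject_idx]
    # guard: a sample with no present features keeps its most prevalent one
    empty = latent.sum(axis=1) == 0
    if empty.any():
        j = int(np.argmax(prevalence))
        latent[empty, j] = np.exp(base[j])
    return AbundanceTable.from_counts(
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        counts=latent,
        feature_kind=feature_kind,
    )


def _species_clade(k: int) -> str:
    return (
        f"k__Bacteria|p__Simphyla|c__Simclass|o__Simorder|"
        f"f__Simfam{k % 7}|g__Simgenus{k % 23}|s__Sim_species_{k:04d}"
    )


_SUBTEST_SPLIT = {
    # subtest: (share of total score, noise SD, max score)
    "word_recall": (0.18, 0.7, 10.0),
    "word_recognition": (0.14, 0.7, 12.0),
    "orientation": (0.10, 0.5, 8.0),
    "remember_instructions": (0.06, 0.4, 5.0),
    "delayed_recall": (0.19, 0.7, 10.0),
    "maze_time": (0.08, 0.5, 10.0),
    "maze_mistakes": (0.05, 0.4, 5.0),
}


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one longitudinal cohort; all randomness flows from the seed."""
    rng = np.random.default_rng(config.seed)

    # ---- subjects ----------------------------------------------------
    subjects: list[str] = []
    groups: dict[str, str] = {}
    for g in sorted(config.n_per_group):
        for k in range(config.n_per_group[g]):
            sid = f"{g}{k + 1:04d}"
            subjects.append(sid)
            groups[sid] = g
    n_subjects = len(subjects)
    subject_idx = {s: i for i, s in enumerate(subjects)}

    visit_counts = _visit_counts(rng, n_subjects, config.visits_mean, config.visits_sd)

    # ---- per-subject covariates -------------------------------------
    params = {s: config.covariate_params[groups[s]] for s in subjects}
    age0 = np.array([rng.normal(params[s].age_mean, params[s].age_sd) for s in subjects])
    sex = np.array(
        [
            "female" if rng.random() < params[s].p_female else "male"
            for s in subjects
        ]
    )
    education = np.clip(
        rng.normal(config.education_mean, config.education_sd, n_subjects), 8, 22
    )
    polypharmacy = np.array(
        [rng.random() < params[s].p_polypharmacy for s in subjects]
    )
    medications: list[frozenset[str]] = []
    for i in range(n_subjects):
        k = int(rng.integers(5, 9)) if polypharmacy[i] else int(rng.integers(0, 5))
        medications.append(
            frozenset(rng.choice(MEDICATION_CLASSES, size=k, replace=False))
        )
    cfs = np.array(
        [
            float(np.clip(np.round(rng.normal(params[s].cfs_mean, params[s].cfs_sd)), 1, 7))
            for s in subjects
        ]
    )
    mis = np.array(
        [max(0.0, rng.normal(params[s].mis_mean, params[s].mis_sd)) for s in subjects]
    )

    # ---- outcome components -----------------------------------------
    subject_level = np.empty(n_subjects)
    latent_params = {
        g: _censored_normal_params(p.adas_mean, p.adas_sd)
        for g, p in config.covariate_params.items()
    }
    for i, s in enumerate(subjects):
        m_star, s_star = latent_params[groups[s]]
        var_subj = s_star**2 - config.sigma_b**2 - config.sigma_e**2
        if var_subj < 0:
            warnings.warn(
                f"group {groups[s]}: sigma_b^2+sigma_e^2 exceeds outcome variance; "
                "subject-level SD floored at 0",
                RuntimeWarning,
            )
            var_subj = 0.0
        subject_level[i] = rng.normal(m_star, np.sqrt(var_subj))
    b = rng.normal(0.0, config.sigma_b, n_subjects)

    # ---- visit skeleton ---------------------------------------------
    visit_rows: list[dict] = []
    for i, s in enumerate(subjects):
        for v in range(1, int(visit_counts[i]) + 1):
            days = 0.0 if v == 1 else (v - 1) * config.visit_spacing_days + float(
                rng.normal(0.0, 3.0)
            )
            days = max(days, 0.0)
            has_sample = rng.random() >= config.p_missing_sample
            visit_rows.append(
                {
                    "subject": s,
                    "visit": v,
                    "days": days,
                    "sample_id": f"{s}_V{v:02d}" if has_sample else None,
                }
            )
    # keep day ordering monotone within subject despite jitter
    for s in subjects:
        rows = [r for r in visit_rows if r["subject"] == s]
        days_sorted = sorted(r["days"] for r in rows)
        for r, d in zip(sorted(rows, key=lambda r: r["visit"]), days_sorted):
            r["days"] = d

    sampled = [r for r in visit_rows if r["sample_id"] is not None]
    sample_ids = [r["sample_id"] for r in sampled]
    sample_subject_idx = np.array([subject_idx[r["subject"]] for r in sampled])

    # ---- feature tables ---------------------------------------------
    feature_ids = {
        "species": [_species_clade(k) for k in range(config.n_species)],
        "pathway": [
            f"PWY-{1000 + k}: synthetic pathway {k}" for k in range(config.n_pathways)
        ],
        "ko": [f"K{k + 1:05d}" for k in range(config.n_ko)],
    }
    planted_by_kind: dict[str, set[str]] = {"species": set(), "pathway": set(), "ko": set()}
    for eff in config.planted:
        if eff.feature_id not in feature_ids[eff.feature_kind]:
            raise ValueError(
                f"planted feature {eff.feature_id!r} not in generated "
                f"{eff.feature_kind} table"
            )
        planted_by_kind[eff.feature_kind].add(eff.feature_id)

    tables: dict[str, AbundanceTable] = {}
    prevalence_truth: dict[str, dict[str, float]] = {}
    lo, hi = config.prevalence_range
    for kind in ("species", "pathway", "ko"):
        ids = feature_ids[kind]
        prevalence = rng.uniform(lo, hi, size=len(ids))
        for j, fid in enumerate(ids):
            if fid in planted_by_kind[kind]:
                prevalence[j] = max(prevalence[j], config.planted_min_prevalence)
        tables[kind] = _compositional_table(
            rng, sample_subject_idx, n_subjects, ids, sample_ids, kind, config, prevalence
        )
        prevalence_truth[kind] = {
            fid: float((tables[kind].values[:, j] > 0).mean())
            for j, fid in enumerate(ids)
        }

    # ---- planted fixed effects --------------------------------------
    planted_contrib = np.zeros(len(sampled))
    age_z_all = (age0 - age0.mean()) / (age0.std(ddof=0) or 1.0)
    for eff in config.planted:
        table = tables[eff.feature_kind]
        col = table.values[:, table.feature_ids.index(eff.feature_id)]
        t = np.arcsin(np.sqrt(np.clip(col, 0.0, 1.0)))
        sd = t.std(ddof=0)
        z = (t - t.mean()) / (sd if sd > 0 else 1.0)
        if eff.shape == "linear":
            planted_contrib += eff.effect_size * z
        elif eff.shape == "threshold":
            planted_contrib += eff.effect_size * (z > 0).astype(float)
        else:  # interaction with standardized age
            planted_contrib += eff.effect_size * z * age_z_all[sample_subject_idx]

    planted_by_visit = {
        (r["subject"], r["visit"]): planted_contrib[k] for k, r in enumerate(sampled)
    }

    # ---- assemble visit records -------------------------------------
    records: list[VisitRecord] = []
    noiseless: dict[tuple[str, int], float] = {}
    unclipped: dict[tuple[str, int], float] = {}
    for r in visit_rows:
        i = subject_idx[r["subject"]]
        g = groups[r["subject"]]
        fixed = subject_level[i] + planted_by_visit.get((r["subject"], r["visit"]), 0.0)
        noiseless[(r["subject"], r["visit"])] = fixed + b[i]
        outcome = fixed + b[i] + rng.normal(0.0, config.sigma_e)
        unclipped[(r["subject"], r["visit"])] = float(outcome)
        adas_total = float(np.clip(outcome, 0.0, 85.0))

        adas_subtests = {}
        for name, (share, noise_sd, max_score) in _SUBTEST_SPLIT.items():
            adas_subtests[name] = float(
                np.clip(share * adas_total + rng.normal(0.0, noise_sd), 0.0, max_score)
            )
        toolbox = {
            "card_sort": float(
                np.clip(8.0 - 0.07 * adas_total + rng.normal(0.0, 0.7), 0.0, 10.0)
            ),
            "pattern_comparison": float(
                np.clip(9.0 - 0.08 * adas_total + rng.normal(0.0, 0.8), 0.0, 12.0)
            ),
        }
        # group-consistent classification fields (baseline rule inputs)
        if g == "AD":
            dementia, cdr, normal_fn = True, float(rng.choice([1.0, 2.0])), False
        elif g == "MCI":
            dementia, cdr, normal_fn = False, 0.5, True
            if r["visit"] == 1:
                adas_subtests["delayed_recall"] = max(4.0, adas_subtests["delayed_recall"])
        else:
            dementia, cdr, normal_fn = False, 0.0, True
            if r["visit"] == 1:
                adas_subtests["delayed_recall"] = min(3.5, adas_subtests["delayed_recall"])

        records.append(
            VisitRecord(
                subject_id=r["subject"],
                visit_index=r["visit"],
                days_since_enrollment=r["days"],
                sample_id=r["sample_id"],
                sex=str(sex[i]),
                age=float(age0[i] + r["days"] / 365.25),
                education_years=float(education[i]),
                antibiotics_6mo=bool(rng.random() < params[r["subject"]].p_antibiotics),
                hospitalized_6mo=bool(rng.random() < params[r["subject"]].p_hospitalized),
                polypharmacy=bool(polypharmacy[i]),
                medications=medications[i],
                cfs=float(cfs[i]),
                mis=float(mis[i]),
                cdr=cdr,
                dementia_diagnosis=dementia,
                normal_daily_function=normal_fn,
                adas_subtests=adas_subtests,
                toolbox_subtests=toolbox,
                adas_total=adas_total,
            )
        )

    # ---- KO -> pathway map ------------------------------------------
    pathway_groups = [f"map{10 + k:05d}" for k in range(max(6, config.n_ko // 12))]
    ko_pathway_map: dict[str, list[str]] = {}
    for ko in feature_ids["ko"]:
        k = int(rng.integers(1, 4))
        ko_pathway_map[ko] = sorted(
            str(x) for x in rng.choice(pathway_groups, size=k, replace=False)
        )

    truth = GroundTruth(
        planted=list(config.planted),
        b={s: float(b[subject_idx[s]]) for s in subjects},
        subject_level={s: float(subject_level[subject_idx[s]]) for s in subjects},
        noiseless_outcome=noiseless,
        unclipped_outcome=unclipped,
        prevalence=prevalence_truth,
        group=dict(groups),
        null=False,
        seed=config.seed,
    )
    return SyntheticCohort(
        records=records, tables=tables, truth=truth, ko_pathway_map=ko_pathway_map
    )


def null_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Same cohort with the cognitive outcome permuted across visits.

    The permutation is within each configured group (the pipeline is run
    per group, so the within-group shuffle is the matching negative
    control) and uses its own derived seed.  Baseline delayed-recall
    values are re-nudged across the MCI rule threshold afterward so
    classification still reconstructs the configured groups; the
    ``adas_total`` multiset is untouched.
    """
    cohort = simulate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6E756C6C]))

    by_group: dict[str, list[int]] = {}
    for k, rec in enumerate(cohort.records):
        by_group.setdefault(cohort.truth.group[rec.subject_id], []).append(k)

    records = list(cohort.records)
    for g in sorted(by_group):
        idx = by_group[g]
        perm = rng.permutation(len(idx))
        blocks = [
            (records[i].adas_total, records[i].adas_subtests, records[i].toolbox_subtests)
            for i in idx
        ]
        for slot, src in zip(idx, perm):
            total, adas, toolbox = blocks[src]
            rec = records[slot]
            adas = dict(adas)
            if rec.visit_index == 1:
                if g == "MCI":
                    adas["delayed_recall"] = max(4.0, adas["delayed_recall"])
                elif g == "HC":
                    adas["delayed_recall"] = min(3.5, adas["delayed_recall"])
            records[slot] = replace(
                rec,
                adas_total=total,
                adas_subtests=adas,
                toolbox_subtests=dict(toolbox),
            )

    truth = copy.deepcopy(cohort.truth)
    truth.null = True
    return SyntheticCohort(
        records=records,
        tables=cohort.tables,
        truth=truth,
        ko_pathway_map=cohort.ko_pathway_map,
    )
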