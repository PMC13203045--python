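"""Readers and writers for microbiome feature tables and cohort metadata.

Two table dialects are supported:

* MetaPhlAn-style taxonomic profiles: one row per clade, pipe-delimited
  lineage strings, abundances either in percent (0-100) or already as
  proportions (the scale is auto-detected per sample).
* HUMAnN-style functional tables (pathway or KO abundance): one row per
  feature, optional stratified rows carrying a ``|<taxon>`` suffix.

All downstream modules consume the :class:`AbundanceTable` /
:class:`VisitRecord` types produced here; per-sample closure (proportions
summing to one) is enforced at read time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "VisitRecord",
    "read_metaphlan_profiles",
    "read_humann_table",
    "read_metadata",
    "write_metaphlan_profiles",
    "write_humann_table",
    "write_metadata",
    "MEMORY_SUBTESTS",
    "EF_ADAS_SUBTESTS",
    "EF_TOOLBOX_SUBTESTS",
]

CLOSURE_TOL = 1e-6

#: canonical subtest keys used throughout the package
MEMORY_SUBTESTS = (
    "word_recall",
    "word_recognition",
    "orientation",
    "remember_instructions",
    "delayed_recall",
)
EF_ADAS_SUBTESTS = ("maze_time", "maze_mistakes")
EF_TOOLBOX_SUBTESTS = ("card_sort", "pattern_comparison")

_ADAS_COLUMNS = tuple(f"adas_{k}" for k in MEMORY_SUBTESTS + EF_ADAS_SUBTESTS)
_TOOLBOX_COLUMNS = tuple(f"tb_{k}" for k in EF_TOOLBOX_SUBTESTS)

_MANDATORY_METADATA_COLUMNS = (
    "subject_id",
    "days_since_enrollment",
    "sex",
    "age",
    "education_years",
    "antibiotics_6mo",
    "hospitalized_6mo",
    "polypharmacy",
    "cfs",
    "mis",
    "cdr",
    "dementia_diagnosis",
    "normal_daily_function",
    "adas_total",
)


@dataclass
class AbundanceTable:
    """Samples x features compositional matrix.

    ``values[i, j]`` is the proportion of feature ``feature_ids[j]`` in
    sample ``sample_ids[i]``; every row sums to one (within ``1e-6``).
    ``stratified_contributions`` optionally maps
    ``feature_id -> taxon -> per-sample contribution fractions`` (aligned
    with ``sample_ids``); stratified rows never enter ``values``.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    feature_kind: str = "species"
    stratified_contributions: dict[str, dict[str, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if self.feature_kind not in {"species", "pathway", "ko"}:
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if np.any(self.values < 0):
            raise ValueError("negative abundance values")
        sums = self.values.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > CLOSURE_TOL)[0]
        if bad.size:
            raise ValueError(
                f"sample(s) not closed to 1: {[self.sample_ids[i] for i in bad[:5]]}"
            )

    # -- construction -------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        sample_ids: Sequence[str],
        feature_ids: Sequence[str],
        counts: np.ndarray,
        feature_kind: str = "species",
        stratified_contributions: dict[str, dict[str, np.ndarray]] | None = None,
    ) -> "AbundanceTable":
        """Build a table from non-negative counts/abundances, closing each sample."""
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValueError("negative abundance values")
        totals = counts.sum(axis=1)
        zero = np.where(totals == 0)[0]
        if zero.size:
            raise ValueError(
                f"sample(s) with zero total abundance: "
                f"{[sample_ids[i] for i in zero[:5]]}"
            )
        return cls(
            sample_ids=list(sample_ids),
            feature_ids=list(feature_ids),
            values=counts / totals[:, None],
            feature_kind=feature_kind,
            stratified_contributions=stratified_contributions,
        )

    # -- accessors ----------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        """Samples x features DataFrame view (copy)."""
        return pd.DataFrame(
            self.values.copy(), index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        strat = None
        if self.stratified_contributions is not None:
            strat = {
                f: {t: v[rows].copy() for t, v in contrib.items()}
                for f, contrib in self.stratified_contributions.items()
            }
        return AbundanceTable(
            sample_ids=list(sample_ids),
            feature_ids=list(self.feature_ids),
            values=self.values[rows],
            feature_kind=self.feature_kind,
            stratified_contributions=strat,
        )

    def feature_vector(self, feature_id: str) -> np.ndarray:
        return self.values[:, self.feature_ids.index(feature_id)].copy()


@dataclass
class VisitRecord:
    """One subject-visit: covariates, cognitive subtests, sample linkage."""

    subject_id: str
    visit_index: int
    days_since_enrollment: float
    sample_id: str | None
    sex: str
    age: float
    education_years: float
    antibiotics_6mo: bool
    hospitalized_6mo: bool
    polypharmacy: bool
    medications: frozenset[str]
    cfs: float
    mis: float
    cdr: float
    dementia_diagnosis: bool
    normal_daily_function: bool
    adas_subtests: dict[str, float]
    toolbox_subtests: dict[str, float]
    adas_total: float

    def __post_init__(self) -> None:
        if self.sex not in {"female", "male"}:
            raise ValueError(f"sex must be female/male, got {self.sex!r}")
        if not 0 <= self.adas_total <= 85:
            raise ValueError(
                f"adas_total {self.adas_total} outside [0, 85] "
                f"({self.subject_id} visit {self.visit_index})"
            )
        if not 1 <= self.cfs <= 7:
            raise ValueError(
                f"cfs {self.cfs} outside [1, 7] ({self.subject_id})"
            )
        if self.days_since_enrollment < 0:
            raise ValueError("days_since_enrollment must be >= 0")
        if self.visit_index < 1:
            raise ValueError("visit_index must be >= 1")
        if self.cdr < 0:
            raise ValueError("cdr must be >= 0")


# ---------------------------------------------------------------------------
# MetaPhlAn-style profiles
# ---------------------------------------------------------------------------


def _deepest_clade(clade: str) -> str:
    return clade.split("|")[-1]


def read_metaphlan_profiles(
    paths: Sequence[str | os.PathLike],
    taxonomic_level: str = "s__",
) -> AbundanceTable:
    """Read one or more MetaPhlAn-style TSVs into a species-level table.

    Each file holds a clade column followed by one or more numeric sample
    columns (a single-sample profile whose value column is not a sample
    name is keyed by the file stem).  Only rows whose deepest clade starts
    with ``taxonomic_level`` are retained; percent-scale files are detected
    per sample and divided by 100 before per-sample renormalization.
    """
    frames: list[pd.Series] = []
    for path in paths:
        try:
            df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
        except (OSError, pd.errors.EmptyDataError) as exc:
            raise ValueError(f"unreadable MetaPhlAn profile {path}: {exc}") from exc
        # re-read with header if the first row is non-numeric (merged table)
        first_vals = df.iloc[0, 1:]
        has_header = not all(_is_number(v) for v in first_vals)
        df = pd.read_csv(
            path, sep="\t", comment="#", header=0 if has_header else None, dtype=str
        )
        clade_col = df.columns[0]
        value_cols = list(df.columns[1:])
        # drop non-abundance helper columns some dialects carry
        value_cols = [
            c
            for c in value_cols
            if str(c).lower() not in {"ncbi_tax_id", "additional_species", "taxid"}
        ]
        if not value_cols:
            raise ValueError(f"no abundance columns in {path}")
        stem = os.path.splitext(os.path.basename(os.fspath(path)))[0]
        for col in value_cols:
            name = str(col)
            if not has_header or name.lower() in {"relative_abundance", "abundance"}:
                name = stem
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                raise ValueError(f"non-numeric abundance in {path}, column {col}")
            series = pd.Series(vals.to_numpy(), index=df[clade_col].astype(str), name=name)
            frames.append(series)

    names = [s.name for s in frames]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")

    merged = pd.concat(frames, axis=1).fillna(0.0)
    keep = [c for c in merged.index if _deepest_clade(c).startswith(taxonomic_level)]
    merged = merged.loc[keep]
    if np.any(merged.to_numpy() < 0):
        raise ValueError("negative abundance value in MetaPhlAn input")

    totals = merged.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValueError(
            f"sample(s) with zero total abundance at level {taxonomic_level!r}: {zero}"
        )
    # percent (0-100) vs proportion (0-1) dialect, per sample
    scaled = merged / totals
    return AbundanceTable(
        sample_ids=[str(c) for c in merged.columns],
        feature_ids=[str(i) for i in merged.index],
        values=scaled.to_numpy().T,
        feature_kind="species",
    )


def _is_number(v: object) -> bool:
    try:
        float(v)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


def write_metaphlan_profiles(table: AbundanceTable, path: str | os.PathLike) -> None:
    """Write a merged MetaPhlAn-style table (percent scale, clade rows)."""
    df = pd.DataFrame(
        table.values.T * 100.0,
        index=list(table.feature_ids),
        columns=list(table.sample_ids),
    )
    df.index.name = "clade_name"
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# HUMAnN-style tables
# ---------------------------------------------------------------------------

DEFAULT_EXCLUDE = frozenset({"UNMAPPED", "UNINTEGRATED"})


def read_humann_table(
    path: str | os.PathLike,
    exclude_features: Iterable[str] = DEFAULT_EXCLUDE,
    keep_stratified: bool = True,
    feature_kind: str = "pathway",
) -> AbundanceTable:
    """Read a HUMAnN-style feature x sample TSV.

    Unstratified rows form the model matrix (closed to proportions after
    removing ``exclude_features``); rows with a ``|taxon`` suffix are, when
    ``keep_stratified``, recorded as per-feature contribution fractions
    relative to the unstratified row and never enter the model matrix.
    """
    exclude = set(exclude_features)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"unreadable HUMAnN table {path}: {exc}") from exc
    values = df.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise ValueError(f"non-numeric cell in {path} (header/sample mismatch?)")
    if (values.to_numpy() < 0).any():
        raise ValueError(f"negative value in {path}")

    is_strat = values.index.to_series().astype(str).str.contains(r"\|")
    unstrat = values.loc[~is_strat]
    unstrat = unstrat.loc[[f for f in unstrat.index if str(f) not in exclude]]
    if unstrat.empty:
        raise ValueError("no unstratified features left after exclusion")

    table = AbundanceTable.from_counts(
        sample_ids=[str(c) for c in unstrat.columns],
        feature_ids=[str(i) for i in unstrat.index],
        counts=unstrat.to_numpy().T,
        feature_kind=feature_kind,
    )

    if keep_stratified:
        contributions: dict[str, dict[str, np.ndarray]] = {}
        strat = values.loc[is_strat.to_numpy()]
        for row_name, row in strat.iterrows():
            feat, taxon = str(row_name).split("|", 1)
            if feat in exclude or feat not in set(table.feature_ids):
                continue
            base = unstrat.loc[feat].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(base > 0, row.to_numpy(dtype=float) / base, 0.0)
            contributions.setdefault(feat, {})[taxon] = frac
        table.stratified_contributions = contributions or None
    return table


def write_humann_table(
    table: AbundanceTable, path: str | os.PathLike, scale: float = 1.0
) -> None:
    """Write a HUMAnN-style table, appending stratified rows when present."""
    rows: dict[str, np.ndarray] = {
        f: table.values[:, j] * scale for j, f in enumerate(table.feature_ids)
    }
    if table.stratified_contributions:
        for feat, contrib in table.stratified_contributions.items():
            base = rows[feat]
            for taxon, frac in contrib.items():
                rows[f"{feat}|{taxon}"] = base * frac
    df = pd.DataFrame(rows, index=list(table.sample_ids)).T
    df.index.name = f"# {table.feature_kind}"
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# Cohort metadata
# ---------------------------------------------------------------------------


def read_metadata(path: str | os.PathLike) -> list[VisitRecord]:
    """Read a per-visit metadata TSV into typed :class:`VisitRecord` rows.

    Required columns: ``subject_id, days_since_enrollment, sex, age,
    education_years, antibiotics_6mo, hospitalized_6mo, polypharmacy, cfs,
    mis, cdr, dementia_diagnosis, normal_daily_function, adas_total`` plus
    the ``adas_*`` / ``tb_*`` subtest columns present in the file.
    ``visit_index`` is derived from within-subject day order when absent;
    ``sample_id`` and ``medications`` (semicolon-joined) are optional.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MANDATORY_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory metadata column(s): {missing}")

    if "visit_index" not in df.columns:
        df["visit_index"] = (
            df.groupby("subject_id")["days_since_enrollment"]
            .transform(lambda s: s.astype(float).rank(method="first").astype(int))
        )
    dup = df.duplicated(subset=["subject_id", "visit_index"])
    if dup.any():
        pairs = df.loc[dup, ["subject_id", "visit_index"]].to_records(index=False)
        raise ValueError(f"duplicate (subject, visit) pair(s): {list(pairs)[:5]}")

    records = []
    for _, row in df.iterrows():
        meds = row.get("medications")
        med_set = (
            frozenset(m for m in str(meds).split(";") if m)
            if isinstance(meds, str) and meds
            else frozenset()
        )
        sample = row.get("sample_id")
        if not isinstance(sample, str) or sample == "" or sample.lower() == "nan":
            sample = None
        adas = {
            k: float(row[f"adas_{k}"])
            for k in MEMORY_SUBTESTS + EF_ADAS_SUBTESTS
            if f"adas_{k}" in df.columns and not pd.isna(row[f"adas_{k}"])
        }
        toolbox = {
            k: float(row[f"tb_{k}"])
            for k in EF_TOOLBOX_SUBTESTS
            if f"tb_{k}" in df.columns and not pd.isna(row[f"tb_{k}"])
        }
        records.append(
            VisitRecord(
                subject_id=str(row["subject_id"]),
                visit_index=int(float(row["visit_index"])),
                days_since_enrollment=float(row["days_since_enrollment"]),
                sample_id=sample,
                sex=str(row["sex"]),
                age=float(row["age"]),
                education_years=float(row["education_years"]),
                antibiotics_6mo=_as_bool(row["antibiotics_6mo"]),
                hospitalized_6mo=_as_bool(row["hospitalized_6mo"]),
                polypharmacy=_as_bool(row["polypharmacy"]),
                medications=med_set,
                cfs=float(row["cfs"]),
                mis=float(row["mis"]),
                cdr=float(row["cdr"]),
                dementia_diagnosis=_as_bool(row["dementia_diagnosis"]),
                normal_daily_function=_as_bool(row["normal_daily_function"]),
                adas_subtests=adas,
                toolbox_subtests=toolbox,
                adas_total=float(row["adas_total"]),
            )
        )
    _check_visit_order(records)
    return records


def _check_visit_order(records: Sequence[VisitRecord]) -> None:
    by_subject: dict[str, list[VisitRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    for subject, recs in by_subject.items():
        recs = sorted(recs, key=lambda r: r.visit_index)
        days = [r.days_since_enrollment for r in recs]
        if any(b < a for a, b in zip(days, days[1:])):
            raise ValueError(
                f"visit_index inconsistent with day ordering for subject {subject}"
            )


def _as_bool(v: object) -> bool:
    s = str(v).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f"}:
        return False
    raise ValueError(f"cannot parse boolean value {v!r}")


def write_metadata(records: Sequence[VisitRecord], path: str | os.PathLike) -> None:
    """Write records to the TSV dialect :func:`read_metadata` consumes."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "subject_id": r.subject_id,
            "visit_index": r.visit_index,
            "days_since_enrollment": f"{r.days_since_enrollment:.10g}",
            "sample_id": r.sample_id if r.sample_id is not None else "",
            "sex": r.sex,
            "age": f"{r.age:.10g}",
            "education_years": f"{r.education_years:.10g}",
            "antibiotics_6mo": r.antibiotics_6mo,
            "hospitalized_6mo": r.hospitalized_6mo,
            "polypharmacy": r.polypharmacy,
            "medications": ";".join(sorted(r.medications)),
            "cfs": f"{r.cfs:.10g}",
            "mis": f"{r.mis:.10g}",
            "cdr": f"{r.cdr:.10g}",
            "dementia_diagnosis": r.dementia_diagnosis,
            "normal_daily_function": r.normal_daily_function,
            "adas_total": f"{r.adas_total:.10g}",
        }
        for k in MEMORY_SUBTESTS + EF_ADAS_SUBTESTS:
            if k in r.adas_subtests:
                row[f"adas_{k}"] = f"{r.adas_subtests[k]:.10g}"
        for k in EF_TOOLBOX_SUBTESTS:
            if k in r.toolbox_subtests:
                row[f"tb_{k}"] = f"{r.toolbox_subtests[k]:.10g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
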