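"""Data preparation: raw per-day clinical records to clean patient-day tables.

Covers daily aggregation of repeated measurements, unit harmonization,
exit-status derivation, dropping of uninformative columns, median/mode
imputation, pathogen binarization, and the continuous/discrete feature split
by the number of distinct observed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .cohort import EXIT_ALIVE, EXIT_DEAD, META_COLUMNS

#: Columns with more distinct observed values than this are continuous.
DEFAULT_UNIQUENESS_THRESHOLD = 11

#: Columns missing more than this fraction are dropped outright.
DEFAULT_DROP_MISSING_FRACTION = 0.5

#: Columns may be imputed only when missing at most this fraction.
DEFAULT_IMPUTE_MISSING_FRACTION = 0.05

PATHOGEN_PREFIX = "path"


@dataclass(frozen=True)
class FeatureSchema:
    """Feature kind assignment: continuous / discrete / pathogen."""

    continuous: tuple[str, ...]
    discrete: tuple[str, ...]
    pathogen: tuple[str, ...]

    @property
    def all_features(self) -> tuple[str, ...]:
        return self.continuous + self.discrete + self.pathogen

    def kind_of(self, feature: str) -> str:
        for kind in ("continuous", "discrete", "pathogen"):
            if feature in getattr(self, kind):
                return kind
        raise KeyError(feature)

    def to_dict(self) -> dict:
        return {
            "continuous": list(self.continuous),
            "discrete": list(self.discrete),
            "pathogen": list(self.pathogen),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(
            tuple(d["continuous"]), tuple(d["discrete"]), tuple(d["pathogen"])
        )


def aggregate_daily(
    records: pd.DataFrame, mean_features: set[str] | None = None
) -> pd.DataFrame:
    """Collapse repeated same-day entries to one value per (patient, day, feature).

    Features in ``mean_features`` (default: all) use the arithmetic mean of
    their same-day entries; single entries pass through unchanged.  A
    non-numeric entry inside a mean-aggregated duplicated cell is an error
    naming the offending cell.
    """
    required = {"patient_id", "day", "feature", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")

    def _agg(group: pd.Series):
        if len(group) == 1:
            return group.iloc[0]
        name = group.name
        feature = name[2]
        if mean_features is not None and feature not in mean_features:
            return group.iloc[0]
        numeric = pd.to_numeric(group, errors="coerce")
        if numeric.isna().sum() > group.isna().sum():
            raise ValueError(
                f"non-numeric entry in mean-aggregated cell "
                f"(patient={name[0]}, day={name[1]}, feature={feature})"
            )
        return numeric.mean()

    grouped = records.groupby(
        ["patient_id", "day", "feature"], sort=True, dropna=False
    )["value"].apply(_agg)
    out = grouped.reset_index()
    extra = [
        c for c in records.columns
        if c not in ("patient_id", "day", "feature", "value", "unit")
    ]
    if extra:
        meta = records.drop_duplicates(["patient_id", "day", "feature"])[
            ["patient_id", "day", "feature"] + extra
        ]
        out = out.merge(meta, on=["patient_id", "day", "feature"], how="left")
    return out


def harmonize_units(
    records: pd.DataFrame, unit_map: dict[str, float]
) -> pd.DataFrame:
    """Rescale values to canonical units and drop the unit tag column.

    ``unit_map`` maps a unit tag to the multiplicative factor converting it
    to the canonical unit (canonical tags map to 1).  Rows without a tag are
    assumed canonical.
    """
    if "unit" not in records.columns:
        return records.copy()
    out = records.copy()
    tags = out["unit"].dropna().unique()
    unknown = [t for t in tags if t not in unit_map]
    if unknown:
        raise ValueError(f"unknown unit tags: {sorted(unknown)}")
    factors = out["unit"].map(unit_map).fillna(1.0)
    out["value"] = pd.to_numeric(out["value"], errors="coerce") * factors
    return out.drop(columns=["unit"])


def derive_exit_flags(
    records: pd.DataFrame,
    death_markers: list[tuple[str, object]],
    alive_markers: list[tuple[str, object]] | None = None,
) -> pd.DataFrame:
    """Assign each patient an exit status and exit day from marker records.

    A patient is flagged dead iff any (feature, value) record matches a
    death marker; the exit day is the last observed day.  Conflicting
    alive/dead evidence warns, and dead wins.
    """
    death_set = {(f, str(v)) for f, v in death_markers}
    alive_set = {(f, str(v)) for f, v in (alive_markers or [])}
    out = []
    for pid, group in records.groupby("patient_id", sort=True):
        pairs = set(
            zip(group["feature"].astype(str), group["value"].astype(str))
        )
        dead = bool(pairs & death_set)
        alive = bool(pairs & alive_set)
        if dead and alive:
            warnings.warn(
                f"patient {pid}: conflicting alive/dead markers; dead wins",
                stacklevel=2,
            )
        status = EXIT_DEAD if dead else EXIT_ALIVE
        out.append(
            {
                "patient_id": pid,
                "exit_status": status,
                "exit_day": int(group["day"].max()),
            }
        )
    return pd.DataFrame(out)


def drop_uninformative(
    table: pd.DataFrame,
    max_missing_fraction: float = DEFAULT_DROP_MISSING_FRACTION,
    protect: tuple[str, ...] = META_COLUMNS,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Drop zero-variance and high-missingness columns; log every drop."""
    drop_log: list[tuple[str, str]] = []
    keep = []
    for col in table.columns:
        if col in protect:
            keep.append(col)
            continue
        series = table[col]
        miss = series.isna().mean()
        if miss > max_missing_fraction:
            drop_log.append((col, f"missing fraction {miss:.3f}"))
            continue
        observed = series.dropna()
        if observed.nunique() <= 1:
            drop_log.append((col, "zero variance"))
            continue
        keep.append(col)
    return table[keep].copy(), drop_log


def impute(
    table: pd.DataFrame, protect: tuple[str, ...] = META_COLUMNS
) -> pd.DataFrame:
    """Fill numeric holes with the column median, categorical with the mode.

    Mode ties break lexicographically.  An all-missing column here is an
    error — it should have been dropped upstream.
    """
    out = table.copy()
    for col in out.columns:
        if col in protect or not out[col].isna().any():
            continue
        observed = out[col].dropna()
        if observed.empty:
            raise ValueError(f"column {col!r} is entirely missing")
        if pd.api.types.is_numeric_dtype(out[col]):
            fill = observed.median()
        else:
            counts = observed.value_counts()
            top = counts.max()
            fill = sorted(counts[counts == top].index)[0]
        out[col] = out[col].fillna(fill)
    return out


def binarize_pathogens(
    records: pd.DataFrame,
    vocabulary: list,
    patient_ids: list | None = None,
) -> pd.DataFrame:
    """Expand pathogen records into presence/sepsis/resistance flags.

    ``records`` needs columns patient_id, pathogen, and optionally
    sepsis_causing and resistant (truthy).  Each vocabulary code yields
    three binary columns; patients without records get all zeros.
    """
    vocab = [str(v) for v in vocabulary]
    codes = records["pathogen"].astype(str)
    unknown = sorted(set(codes) - set(vocab))
    if unknown:
        raise ValueError(f"pathogen codes outside vocabulary: {unknown}")
    if patient_ids is None:
        patient_ids = sorted(records["patient_id"].unique())
    columns = []
    for code in vocab:
        columns += [
            f"pathogen_{code}_present",
            f"pathogen_{code}_sepsis",
            f"pathogen_{code}_resistant",
        ]
    out = pd.DataFrame(
        0, index=pd.Index(patient_ids, name="patient_id"), columns=columns
    )
    for _, row in records.iterrows():
        code = str(row["pathogen"])
        pid = row["patient_id"]
        out.loc[pid, f"pathogen_{code}_present"] = 1
        if bool(row.get("sepsis_causing", False)):
            out.loc[pid, f"pathogen_{code}_sepsis"] = 1
        if bool(row.get("resistant", False)):
            out.loc[pid, f"pathogen_{code}_resistant"] = 1
    return out.reset_index()


def split_feature_kinds(
    table: pd.DataFrame,
    uniqueness_threshold: int = DEFAULT_UNIQUENESS_THRESHOLD,
    pathogen_prefix: str = PATHOGEN_PREFIX,
) -> FeatureSchema:
    """Assign feature kinds by distinct observed value counts.

    Columns with more than ``uniqueness_threshold`` distinct observed values
    are continuous, the rest discrete; pathogen-derived columns (by name
    prefix) are always pathogen regardless of their value count.
    """
    continuous, discrete, pathogen = [], [], []
    for col in table.columns:
        if col in META_COLUMNS:
            continue
        if col.startswith(pathogen_prefix):
            pathogen.append(col)
        elif table[col].dropna().nunique() > uniqueness_threshold:
            continuous.append(col)
        else:
            discrete.append(col)
    return FeatureSchema(tuple(continuous), tuple(discrete), tuple(pathogen))


def prepare_cohort(
    df: pd.DataFrame,
    max_missing_fraction: float = DEFAULT_DROP_MISSING_FRACTION,
    uniqueness_threshold: int = DEFAULT_UNIQUENESS_THRESHOLD,
) -> tuple[pd.DataFrame, FeatureSchema, list[tuple[str, str]]]:
    """Drop + impute + kind-split convenience pipeline on a wide cohort."""
    reduced, drop_log = drop_uninformative(df, max_missing_fraction)
    clean = impute(reduced)
    schema = split_feature_kinds(clean, uniqueness_threshold)
    return clean, schema, drop_log
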