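"""Preprocessing of the record-level tables into the municipality table A0.

Two streams are combined:

* births + population -> per-municipality preterm municipal rate,
  ``PMR = NNP / NP`` where NNP counts births with gestation strictly below
  37 weeks and NP is the municipality's total population (not its birth
  count: tiny birth denominators make the ratio wildly unstable);
* person + household SES microdata -> filtered to women of fertile age
  (14-40 inclusive), one-hot encoded, household features joined onto each
  person through the household ID, then averaged by municipality.

The two streams are inner-joined on the municipality code, yielding one row
per municipality with its PMR and the municipality means of every SES
feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MicrodataSchema",
    "DEFAULT_SCHEMA",
    "compute_pmr",
    "filter_fertile_women",
    "one_hot_encode",
    "aggregate_education",
    "build_a0",
    "build_municipality_table",
]


@dataclass(frozen=True)
class MicrodataSchema:
    """Column roles of the four input tables.

    ``education_levels`` annotates each education category with the level
    it belongs to; one-hot columns sharing a level are merged.  Codes are
    opaque strings compared for exact equality (6- vs 7-digit municipal
    code dialects must be normalised by the caller).
    """

    code_col: str = "municipality_code"
    weeks_col: str = "weeks"
    pop_col: str = "population"
    gender_col: str = "gender"
    age_col: str = "age"
    female_value: str = "female"
    household_id_col: str = "household_id"
    person_categorical: tuple[str, ...] = (
        "race",
        "education",
        "employment",
        "income_bracket",
    )
    household_categorical: tuple[str, ...] = (
        "water_supply",
        "sewage",
        "garbage",
        "lighting",
        "rooms_band",
    )
    education_col: str = "education"
    education_levels: Mapping[str, str] = field(
        default_factory=lambda: {
            "none": "none",
            "basic": "basic",
            "secondary": "secondary",
            "higher": "higher",
        }
    )
    drop_person_cols: tuple[str, ...] = ("person_id",)


DEFAULT_SCHEMA = MicrodataSchema()


def compute_pmr(
    births: pd.DataFrame,
    population: pd.DataFrame,
    *,
    code_col: str = "municipality_code",
    weeks_col: str = "weeks",
    pop_col: str = "population",
) -> pd.DataFrame:
    """Per-municipality preterm counts and rates (intermediate I1).

    Every municipality present in the births table gets NNP = number of its
    births with gestation < 37 weeks (possibly zero: a true-zero rate is
    informative) and PMR = NNP / population.  A municipality that appears
    in births but not in the population table is a hard error.
    """
    if births.empty:
        return pd.DataFrame(columns=[code_col, "NNP", "NP", "PMR"])

    weeks = pd.to_numeric(births[weeks_col])
    nnp = (
        births.assign(_pre=(weeks < 37).astype(int))
        .groupby(code_col, sort=True)["_pre"]
        .sum()
        .rename("NNP")
    )
    pop = population.set_index(code_col)[pop_col]
    missing = nnp.index.difference(pop.index)
    if len(missing):
        raise ValueError(
            "municipalities present in births but absent from population: "
            + ", ".join(map(str, missing.tolist()))
        )
    out = nnp.to_frame()
    out["NP"] = pop.reindex(nnp.index)
    if (out["NP"] <= 0).any():
        bad = out.index[out["NP"] <= 0].tolist()
        raise ValueError(f"non-positive population for municipalities: {bad}")
    out["PMR"] = out["NNP"] / out["NP"]
    return out.reset_index()


def filter_fertile_women(
    persons: pd.DataFrame,
    *,
    gender_col: str = "gender",
    age_col: str = "age",
    female_value: str = "female",
    age_min: int = 14,
    age_max: int = 40,
) -> pd.DataFrame:
    """Keep only women aged 14-40 inclusive (under-14 and over-40 removed).

    Rows with a missing age are dropped and counted in the log.
    """
    age = pd.to_numeric(persons[age_col], errors="coerce")
    n_missing = int(age.isna().sum())
    if n_missing:
        logger.info("filter_fertile_women: dropped %d rows with missing age", n_missing)
    mask = (
        (persons[gender_col] == female_value)
        & age.notna()
        & (age >= age_min)
        & (age <= age_max)
    )
    return persons.loc[mask].copy()


def one_hot_encode(
    table: pd.DataFrame,
    categorical_columns: Sequence[str],
    *,
    sep: str = "=",
) -> pd.DataFrame:
    """Replace each listed column by one binary column per observed category.

    For every row the binary columns derived from one source column sum to
    1, or to 0 when the value was missing (missing encodes as all-zeros,
    not as its own category).
    """
    out = pd.get_dummies(
        table,
        columns=list(categorical_columns),
        prefix_sep=sep,
        dtype=float,
        dummy_na=False,
    )
    return out


def aggregate_education(
    table: pd.DataFrame,
    education_columns: Sequence[str],
    level_map: Mapping[str, str],
    *,
    sep: str = "=",
    out_prefix: str = "education_level",
) -> pd.DataFrame:
    """Merge one-hot education columns annotated with the same level.

    ``level_map`` maps each education one-hot column name to its level; an
    education column without an annotation is a configuration error.  The
    merged column is the sum of its members, which stays binary because the
    source columns are mutually exclusive.
    """
    missing = [c for c in education_columns if c not in level_map]
    if missing:
        raise ValueError(f"education columns without a level annotation: {missing}")
    out = table.copy()
    levels: dict[str, list[str]] = {}
    for col in education_columns:
        levels.setdefault(level_map[col], []).append(col)
    for level, cols in levels.items():
        merged = out[cols].sum(axis=1)
        out = out.drop(columns=cols)
        out[f"{out_prefix}{sep}{level}"] = merged
    return out


def build_a0(
    i1: pd.DataFrame,
    persons: pd.DataFrame,
    households: pd.DataFrame,
    *,
    code_col: str = "municipality_code",
    household_id_col: str = "household_id",
) -> pd.DataFrame:
    """Join household features onto persons, average by municipality, and
    inner-join with the PMR table I1 (output A0).

    ``persons`` is expected to be already filtered and one-hot encoded;
    non-numeric columns (other than the keys) are ignored in the averaging.
    Persons whose household ID does not resolve are dropped with a logged
    count.  Municipalities lacking either stream are absent from A0.
    """
    hh = households.drop(columns=[code_col], errors="ignore")
    joined = persons.merge(hh, on=household_id_col, how="left", indicator=True)
    n_orphans = int((joined["_merge"] == "left_only").sum())
    if n_orphans:
        logger.info("build_a0: dropped %d persons with unresolvable household", n_orphans)
    joined = joined.loc[joined["_merge"] == "both"].drop(columns="_merge")

    feature_cols = [
        c
        for c in joined.columns
        if c not in (code_col, household_id_col)
        and pd.api.types.is_numeric_dtype(joined[c])
    ]
    i2 = joined.groupby(code_col, sort=True)[feature_cols].mean().reset_index()

    a0 = i1[[code_col, "PMR"]].merge(i2, on=code_col, how="inner")
    return a0.sort_values(code_col, ignore_index=True)


def build_municipality_table(
    births: pd.DataFrame,
    population: pd.DataFrame,
    persons: pd.DataFrame,
    households: pd.DataFrame,
    schema: MicrodataSchema = DEFAULT_SCHEMA,
) -> pd.DataFrame:
    """Full preprocessing chain from the four record tables to A0."""
    i1 = compute_pmr(
        births,
        population,
        code_col=schema.code_col,
        weeks_col=schema.weeks_col,
        pop_col=schema.pop_col,
    )
    women = filter_fertile_women(
        persons,
        gender_col=schema.gender_col,
        age_col=schema.age_col,
        female_value=schema.female_value,
    )
    women = women.drop(
        columns=[schema.gender_col, schema.age_col, *schema.drop_person_cols],
        errors="ignore",
    )
    women = one_hot_encode(women, schema.person_categorical)
    edu_cols = [
        f"{schema.education_col}={cat}" for cat in schema.education_levels
    ]
    edu_cols = [c for c in edu_cols if c in women.columns]
    level_map = {
        f"{schema.education_col}={cat}": lvl
        for cat, lvl in schema.education_levels.items()
    }
    women = aggregate_education(women, edu_cols, level_map)
    hh = one_hot_encode(households, schema.household_categorical)
    return build_a0(
        i1,
        women,
        hh,
        code_col=schema.code_col,
        household_id_col=schema.household_id_col,
    )
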