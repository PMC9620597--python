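"""Demographic deduplication: adjudicate matched records, build the
aggregated vs de-duplicated patient characteristics table.

The analysis team joins per-site demographic extracts (age group, sex,
race — never dates of birth, never names) to the token-free Match Index.
Each MATCH_ID cluster is consolidated into one record by adjudication:
uninformative values (missing / "Other/Missing") are dropped first, a
single surviving distinct value wins, and genuinely conflicting informative
values become "Discordant" for sex and race, or resolve to the oldest
category for age (age has no discordant bucket — an age-group disagreement
across encounters is expected, not an identity conflict).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import pandas as pd

from .match import INDEX_COLUMNS, RefID

AGE_GROUPS = ["0-11", "12-19", "20-34", "35-49", "50-64", "65-74", ">=75"]
SEX_VALUES = ["Female", "Male", "Other/Missing"]
RACE_VALUES = [
    "American Indian or Alaska Native",
    "Asian",
    "Black or African American",
    "Native Hawaiian or Other Pacific Islander",
    "White",
    "Other/Missing",
]
DISCORDANT = "Discordant"
OTHER_MISSING = "Other/Missing"

# PCORnet CDM codes accepted in extracts, mapped to table labels.
SEX_CODE_MAP = {"F": "Female", "M": "Male", "OT": OTHER_MISSING,
                "UN": OTHER_MISSING, "NI": OTHER_MISSING, "": OTHER_MISSING}
RACE_CODE_MAP = {
    "01": RACE_VALUES[0], "02": RACE_VALUES[1], "03": RACE_VALUES[2],
    "04": RACE_VALUES[3], "05": RACE_VALUES[4],
    "OT": OTHER_MISSING, "NI": OTHER_MISSING, "UN": OTHER_MISSING,
    "06": OTHER_MISSING, "07": OTHER_MISSING, "": OTHER_MISSING,
}

DEMOGRAPHIC_COLUMNS = ["DMID", "PATID", "AGE_GROUP", "SEX", "RACE"]


class VocabularyError(ValueError):
    """A demographic value outside the closed vocabulary."""


def _map_code(value: str, label_values: list[str], code_map: dict[str, str],
              column: str) -> str:
    if value in label_values:
        return value
    if value in code_map:
        return code_map[value]
    raise VocabularyError(f"unknown {column} value {value!r}")


def read_demographic_extract(path) -> pd.DataFrame:
    """Read a demographic extract, mapping CDM codes to table labels."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DEMOGRAPHIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"demographic extract missing columns: {missing}")
    df = df[DEMOGRAPHIC_COLUMNS].copy()
    df["AGE_GROUP"] = [
        v if v in AGE_GROUPS or v == "" else _raise_age(v) for v in df["AGE_GROUP"]
    ]
    df["SEX"] = [_map_code(v, SEX_VALUES, SEX_CODE_MAP, "SEX") for v in df["SEX"]]
    df["RACE"] = [_map_code(v, RACE_VALUES, RACE_CODE_MAP, "RACE") for v in df["RACE"]]
    df["DMID_PATID"] = [
        RefID(dmid=d, patid=p).render() for d, p in zip(df["DMID"], df["PATID"])
    ]
    if df["DMID_PATID"].duplicated().any():
        raise ValueError("duplicate (DMID, PATID) in demographic extract")
    return df


def _raise_age(v: str) -> str:
    raise VocabularyError(f"unknown AGE_GROUP value {v!r}")


def adjudicate_category(values: list[str], policy: str) -> str:
    """Consolidate one demographic dimension across a matched cluster.

    ``policy='sex_race'``: >= 2 distinct informative values → Discordant.
    ``policy='age'``: >= 2 distinct informative values → oldest category.
    Missing / Other-Missing values are uninformative and never outvote an
    informative one.
    """
    if not values:
        raise ValueError("adjudication needs at least one value")
    if policy not in ("sex_race", "age"):
        raise ValueError(f"unknown policy {policy!r}")
    vocab = set(AGE_GROUPS) if policy == "age" else set(SEX_VALUES) | set(RACE_VALUES)
    informative = set()
    for v in values:
        if v in ("", OTHER_MISSING):
            continue
        if v not in vocab:
            raise VocabularyError(f"value {v!r} outside vocabulary for policy {policy}")
        informative.add(v)
    if not informative:
        return OTHER_MISSING
    if len(informative) == 1:
        return next(iter(informative))
    if policy == "age":
        return max(informative, key=AGE_GROUPS.index)
    return DISCORDANT


@dataclass
class CharacteristicsTable:
    """Aggregated vs de-duplicated N (and %) per demographic category."""

    aggregated_total: int
    deduplicated_total: int
    # per dimension: {category: (agg_n, agg_pct, dedup_n, dedup_pct)}
    age: dict[str, tuple[int, float, int, float]]
    sex: dict[str, tuple[int, float, int, float]]
    race: dict[str, tuple[int, float, int, float]]
    unmatched_refs: list[str]

    def to_json(self) -> str:
        doc = {
            "aggregated_total": self.aggregated_total,
            "deduplicated_total": self.deduplicated_total,
            "total_percent_reduction": percent_reduction(
                self.aggregated_total, self.deduplicated_total, mode="round", decimals=2
            ),
            "unmatched_refs": self.unmatched_refs,
        }
        for dim in ("age", "sex", "race"):
            doc[dim] = {
                cat: {"aggregated_n": a, "aggregated_pct": ap,
                      "deduplicated_n": d, "deduplicated_pct": dp}
                for cat, (a, ap, d, dp) in getattr(self, dim).items()
            }
        return json.dumps(doc, indent=2)

    def to_text(self) -> str:
        lines = [
            "category\taggregated_n\taggregated_pct\tdeduplicated_n\tdeduplicated_pct",
            f"Number of Patients\t{self.aggregated_total}\t\t{self.deduplicated_total}\t",
        ]
        for title, dim in (("Age", self.age), ("Sex", self.sex), ("Race", self.race)):
            lines.append(f"# By {title}")
            for cat, (a, ap, d, dp) in dim.items():
                lines.append(f"{cat}\t{a}\t{ap}%\t{d}\t{dp}%")
        return "\n".join(lines) + "\n"


def percent_reduction(before: int, after: int, mode: str = "round",
                      decimals: int = 2) -> float:
    """``100 * (before - after) / before`` rounded or truncated.

    Truncation keeps the figure conservative (17.676… → 17.6 at 1 decimal);
    rounding is the default headline convention.
    """
    if before <= 0:
        raise ValueError("percent_reduction undefined for before <= 0")
    if not before >= after >= 0:
        raise ValueError("need before >= after >= 0")
    raw = 100.0 * (before - after) / before
    scale = 10 ** decimals
    if mode == "round":
        return float(round(raw, decimals))
    if mode == "truncate":
        return math.floor(raw * scale) / scale
    raise ValueError(f"unknown mode {mode!r}")


def _tabulate(series: pd.Series, categories: list[str], total: int) -> dict[str, tuple[int, float]]:
    counts = series.value_counts()
    out = {}
    for cat in categories:
        n = int(counts.get(cat, 0))
        out[cat] = (n, float(round(100.0 * n / total, 1)) if total else 0.0)
    return out


def build_characteristics_table(demographics: pd.DataFrame, mi: pd.DataFrame,
                                strict: bool = False) -> CharacteristicsTable:
    """Aggregated (raw records) vs de-duplicated (one adjudicated record per
    MATCH_ID) characteristics table.

    ``demographics`` is the concatenation of per-site extracts (as returned
    by :func:`read_demographic_extract`); ``mi`` is the token-free Match
    Index.  Records absent from the index are reported in
    ``unmatched_refs`` and, under ``strict``, excluded from the
    de-duplicated column.
    """
    missing_cols = [c for c in INDEX_COLUMNS if c not in mi.columns]
    if missing_cols:
        raise ValueError(f"match index missing columns: {missing_cols}")
    merged = demographics.merge(
        mi[INDEX_COLUMNS], on="DMID_PATID", how="left", validate="one_to_one"
    )
    unmatched = sorted(merged.loc[merged["MATCH_ID"].isna(), "DMID_PATID"])
    if unmatched and strict:
        merged = merged[merged["MATCH_ID"].notna()].copy()
    else:
        # an unmatched record is its own singleton cluster
        mask = merged["MATCH_ID"].isna()
        merged.loc[mask, "MATCH_ID"] = "U:" + merged.loc[mask, "DMID_PATID"]

    agg_total = len(demographics)
    dedup = merged.groupby("MATCH_ID").agg(
        AGE_GROUP=("AGE_GROUP", lambda v: adjudicate_category(list(v), "age")),
        SEX=("SEX", lambda v: adjudicate_category(list(v), "sex_race")),
        RACE=("RACE", lambda v: adjudicate_category(list(v), "sex_race")),
    )
    dedup_total = len(dedup)

    def both(col: str, cats: list[str]) -> dict[str, tuple[int, float, int, float]]:
        agg = _tabulate(demographics[col].replace("", OTHER_MISSING), cats, agg_total)
        ded = _tabulate(dedup[col], cats, dedup_total)
        return {c: (*agg.get(c, (0, 0.0)), *ded.get(c, (0, 0.0))) for c in cats}

    age_cats = AGE_GROUPS + [OTHER_MISSING]
    sex_cats = SEX_VALUES + [DISCORDANT]
    race_cats = RACE_VALUES + [DISCORDANT]
    return CharacteristicsTable(
        aggregated_total=agg_total,
        deduplicated_total=dedup_total,
        age=both("AGE_GROUP", age_cats),
        sex=both("SEX", sex_cats),
        race=both("RACE", race_cats),
        unmatched_refs=unmatched,
    )
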