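"""Overlap statistics from a token-free Match Index.

Everything here is computable from (MATCH_ID, DMID_PATID) pairs alone —
deliberately, since the analysis team never sees token bytes.  Reported:
the site-multiplicity distribution (how many unique patients appear in 1,
2, 3, or >= 4 sites), per-site within-site duplicate rates, and pairwise
shared-patient percentages with min/max/mean/median summaries.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .match import INDEX_COLUMNS, RefID

logger = logging.getLogger(__name__)

MULTIPLICITY_BINS = ("1", "2", "3", ">=4")


@dataclass
class OverlapReport:
    site_counts: dict[str, int]
    n_unique_patients: int
    multiplicity_counts: dict[str, int]
    multiplicity_pct: dict[str, float]
    within_site_duplicate_pct: dict[str, float]
    pairwise: list[dict]  # one entry per ordered site pair
    summary: dict[str, float]  # min/max/mean/median over ordered-pair pcts

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    def to_text(self) -> str:
        lines = ["# Site counts"]
        lines += [f"{s}\t{n}" for s, n in sorted(self.site_counts.items())]
        lines.append(f"\n# Unique patients\t{self.n_unique_patients}")
        lines.append("\n# Patients by number of sites\nsites\tn\tpct")
        for b in MULTIPLICITY_BINS:
            lines.append(f"{b}\t{self.multiplicity_counts[b]}\t{self.multiplicity_pct[b]}")
        lines.append("\n# Within-site duplicate percentage\nsite\tpct")
        lines += [f"{s}\t{p}" for s, p in sorted(self.within_site_duplicate_pct.items())]
        lines.append("\n# Pairwise overlap\nsite\tother\toverlap_n\tpct_of_site")
        for row in self.pairwise:
            lines.append(f"{row['site']}\t{row['other']}\t{row['overlap_n']}\t{row['pct']}")
        lines.append("\n# Pairwise percentage summary")
        lines += [f"{k}\t{v}" for k, v in self.summary.items()]
        return "\n".join(lines) + "\n"


def _round1(x: float) -> float:
    return float(round(x, 1))


def _parse_index(mi: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in INDEX_COLUMNS if c not in mi.columns]
    if missing:
        raise ValueError(f"match index missing columns: {missing}")
    parsed = mi[INDEX_COLUMNS].copy()
    parsed["DMID"] = [RefID.parse(r).dmid for r in parsed["DMID_PATID"]]
    return parsed


def site_multiplicity(mi: pd.DataFrame) -> tuple[dict[str, int], dict[str, float]]:
    """Distribution of unique patients over the number of distinct sites.

    Per MATCH_ID the number of *distinct* DMIDs is counted, so a patient
    with only within-site duplicates still counts as a one-site patient.
    """
    parsed = _parse_index(mi)
    per_patient = parsed.groupby("MATCH_ID")["DMID"].nunique()
    counts = dict.fromkeys(MULTIPLICITY_BINS, 0)
    for k, n in per_patient.value_counts().items():
        counts[str(k) if k < 4 else ">=4"] += int(n)
    total = int(per_patient.size)
    pct = {
        b: _round1(100.0 * c / total) if total else 0.0
        for b, c in counts.items()
    }
    return counts, pct


def within_site_duplicates(mi: pd.DataFrame) -> tuple[dict[str, int], dict[str, float]]:
    """Per site: records belonging to a cluster with >= 2 records at that site.

    The denominator is the site's *record* count, matching how a duplicate
    inflates a site's patient table.
    """
    parsed = _parse_index(mi)
    grp = parsed.groupby(["MATCH_ID", "DMID"]).size().rename("n").reset_index()
    dup_counts: dict[str, int] = {}
    site_counts = parsed.groupby("DMID").size().to_dict()
    for dmid in site_counts:
        dups = grp[(grp["DMID"] == dmid) & (grp["n"] >= 2)]["n"].sum()
        dup_counts[dmid] = int(dups)
    pct = {
        dmid: _round1(100.0 * dup_counts[dmid] / site_counts[dmid]) if site_counts[dmid] else 0.0
        for dmid in site_counts
    }
    return dup_counts, pct


def pairwise_overlap(mi: pd.DataFrame) -> tuple[list[dict], dict[str, float]]:
    """Shared unique patients per site pair, as counts and two percentages.

    Each unordered pair yields two ordered percentages — the shared-patient
    count divided by each site's own patient count in turn — and the summary
    (min, max, mean, median) spans all ordered percentages.
    """
    parsed = _parse_index(mi)
    sites = sorted(parsed["DMID"].unique())
    if len(sites) < 2:
        warnings.warn("single-site index: pairwise overlap section empty", stacklevel=2)
        return [], {}
    site_counts = parsed.groupby("DMID").size().to_dict()
    patient_sites = parsed.groupby("MATCH_ID")["DMID"].agg(frozenset)
    rows = []
    pcts = []
    for s1, s2 in combinations(sites, 2):
        overlap_n = int(sum(1 for ss in patient_sites if s1 in ss and s2 in ss))
        for a, b in ((s1, s2), (s2, s1)):
            pct = _round1(100.0 * overlap_n / site_counts[a])
            rows.append({"site": a, "other": b, "overlap_n": overlap_n, "pct": pct})
            pcts.append(100.0 * overlap_n / site_counts[a])
    summary = {
        "min": _round1(min(pcts)),
        "max": _round1(max(pcts)),
        "mean": _round1(float(np.mean(pcts))),
        "median": _round1(float(np.median(pcts))),
    }
    return rows, summary


def overlap_report(mi: pd.DataFrame) -> OverlapReport:
    """Full overlap analysis of a token-free Match Index."""
    parsed = _parse_index(mi)
    counts, mult_pct = site_multiplicity(mi)
    _, dup_pct = within_site_duplicates(mi)
    pairwise, summary = pairwise_overlap(mi) if parsed["DMID"].nunique() >= 2 else ([], {})
    report = OverlapReport(
        site_counts={k: int(v) for k, v in parsed.groupby("DMID").size().items()},
        n_unique_patients=int(parsed["MATCH_ID"].nunique()),
        multiplicity_counts=counts,
        multiplicity_pct=mult_pct,
        within_site_duplicate_pct=dup_pct,
        pairwise=pairwise,
        summary=summary,
    )
    logger.info(
        "overlap report: %d records, %d unique patients across %d sites",
        len(parsed), report.n_unique_patients, len(report.site_counts),
    )
    return report
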