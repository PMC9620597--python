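"""Synthetic multi-site populations with ground-truth linkage.

Real linkage data cannot ship with a linkage tool, so every stage of the
pipeline is exercised on generated populations instead: a configurable
number of sites, planted pairwise person overlap, within-site duplicate
records, per-site SSN availability, and PII corruption (name typos split
into soundex-preserving and soundex-breaking events, day/month date swaps).
Shared persons carry identical base PII at every site *before* corruption,
so with corruption rates at zero the matcher must recover the planted
equivalence classes exactly.

The generator emulates the structure that matters to token matching —
field availability, typo behaviour, demographic discordance across sites —
not clinical realism: there is no encounter history, geography, or
family structure.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from ._names import FIRST_NAMES, LAST_NAMES
from .dedup import AGE_GROUPS, OTHER_MISSING
from .pii import PIIRecord, soundex

GENDER_PRIORS = {"F": 0.52, "M": 0.47, "OT": 0.005, "UN": 0.005}
RACE_PRIORS = {
    "American Indian or Alaska Native": 0.002,
    "Asian": 0.032,
    "Black or African American": 0.19,
    "Native Hawaiian or Other Pacific Islander": 0.001,
    "White": 0.62,
    "Other/Missing": 0.155,
}

_AGE_REFERENCE = date(2019, 6, 30)  # encounter-period midpoint for age groups


class SimConfigError(ValueError):
    """Infeasible or invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for one synthetic population.

    ``sites`` maps DMID → record count (duplicates included).  ``overlaps``
    maps an unordered site pair to the fraction of the smaller site's
    record count that is shared persons.  ``ssn_availability`` is per-site
    (default 0.66, the typical mid-range of observed availability).
    """

    sites: dict[str, int]
    overlaps: dict[tuple[str, str], float] = field(default_factory=dict)
    duplicate_rate: float = 0.0
    ssn_availability: dict[str, float] | float = 0.66
    name_typo_rate: float = 0.0
    dob_error_rate: float = 0.0
    demographic_discordance_rate: float = 0.0
    seed: int = 0

    def ssn_rate(self, dmid: str) -> float:
        if isinstance(self.ssn_availability, dict):
            return self.ssn_availability.get(dmid, 0.66)
        return float(self.ssn_availability)

    def validate(self) -> None:
        if not self.sites:
            raise SimConfigError("at least one site required")
        rates = [self.duplicate_rate, self.name_typo_rate, self.dob_error_rate,
                 self.demographic_discordance_rate]
        rates += [self.ssn_rate(s) for s in self.sites]
        rates += list(self.overlaps.values())
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise SimConfigError("all rates and fractions must lie in [0, 1]")
        for pair in self.overlaps:
            if len(set(pair)) != 2 or any(s not in self.sites for s in pair):
                raise SimConfigError(f"overlap pair {pair} must name two distinct known sites")
        for dmid, n in self.sites.items():
            n_dup = round(self.duplicate_rate * n)
            shared = sum(
                self._pair_count(p) for p in self.overlaps if dmid in p
            )
            if shared > n - n_dup:
                raise SimConfigError(
                    f"site {dmid}: {shared} shared persons exceed "
                    f"{n - n_dup} unique-person slots"
                )

    def _pair_count(self, pair: tuple[str, str]) -> int:
        s1, s2 = pair
        return round(self.overlaps[pair] * min(self.sites[s1], self.sites[s2]))


@dataclass
class LinkTruth:
    """Ground-truth equivalence classes: person → (dmid, patid) appearances."""

    appearances: dict[int, set[tuple[str, str]]]

    def label_of(self) -> dict[tuple[str, str], int]:
        return {
            ref: person
            for person, refs in self.appearances.items()
            for ref in refs
        }

    def n_persons(self) -> int:
        return len(self.appearances)


@dataclass
class Population:
    pii: dict[str, list[PIIRecord]]
    demographics: dict[str, pd.DataFrame]
    truth: LinkTruth
    corruption_log: list[dict]

    def write_extracts(self, outdir: str | Path) -> dict[str, dict[str, Path]]:
        """Write per-site PII and demographic extracts; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, dict[str, Path]] = {}
        for dmid, records in self.pii.items():
            pii_path = outdir / f"pii_{dmid}.csv"
            pd.DataFrame(
                [
                    {
                        "PATID": r.patid,
                        "FIRST_NAME": r.first_name or "",
                        "LAST_NAME": r.last_name or "",
                        "GENDER": r.gender or "",
                        "DOB": r.dob or "",
                        "ZIP5": r.zip5 or "",
                        "SSN": r.ssn or "",
                    }
                    for r in records
                ],
                columns=["PATID", "FIRST_NAME", "LAST_NAME", "GENDER", "DOB", "ZIP5", "SSN"],
            ).to_csv(pii_path, index=False)
            demo_path = outdir / f"demo_{dmid}.csv"
            self.demographics[dmid].to_csv(demo_path, index=False)
            paths[dmid] = {"pii": pii_path, "demographics": demo_path}
        return paths


def _stable_int(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big")


def _site_rng(seed: int, dmid: str) -> np.random.Generator:
    return np.random.default_rng([seed, _stable_int(dmid)])


def _pair_rng(seed: int, s1: str, s2: str) -> np.random.Generator:
    a, b = sorted([s1, s2])
    return np.random.default_rng([seed, _stable_int(a), _stable_int(b)])


@dataclass
class _Person:
    pid: int
    first: str
    last: str
    gender: str
    dob: date
    zip5: str
    ssn: str
    race: str


def _draw_person(pid: int, rng: np.random.Generator,
                 used: set[tuple[str, str, str, str]] | None = None) -> _Person:
    # rejection-sample the (first, last, gender, dob) key so distinct
    # persons can never share all name-based token constituents — the
    # clean-data exactness guarantees depend on it
    genders = list(GENDER_PRIORS)
    races = list(RACE_PRIORS)
    while True:
        dob = date(1925, 1, 1) + timedelta(days=int(rng.integers(0, 34000)))
        first = FIRST_NAMES[int(rng.integers(0, len(FIRST_NAMES)))]
        last = LAST_NAMES[int(rng.integers(0, len(LAST_NAMES)))]
        gender = str(rng.choice(genders, p=list(GENDER_PRIORS.values())))
        key = (first, last, gender, dob.isoformat())
        if used is None or key not in used:
            break
    if used is not None:
        used.add(key)
    return _Person(
        pid=pid,
        first=first,
        last=last,
        gender=gender,
        dob=dob,
        zip5=f"{int(rng.integers(1000, 99999)):05d}",
        ssn=f"{100000000 + pid:09d}",  # unique per person by construction
        race=str(rng.choice(races, p=list(RACE_PRIORS.values()))),
    )


def _age_group(dob: date) -> str:
    age = (_AGE_REFERENCE - dob).days // 365
    for label, upper in zip(AGE_GROUPS, (11, 19, 34, 49, 64, 74)):
        if age <= upper:
            return label
    return AGE_GROUPS[-1]


def corrupt_pii(record: PIIRecord, name_typo_rate: float, dob_error_rate: float,
                rng: np.random.Generator,
                log: list[dict] | None = None) -> PIIRecord:
    """Apply per-appearance corruption: name typos and day/month dob swaps.

    Typos are single-character substitutions or adjacent transpositions;
    whether an event preserved the soundex code is recorded in *log* so
    evaluation can distinguish recoverable from token-breaking errors.
    At rate zero this is the identity.
    """
    first, last, dob = record.first_name, record.last_name, record.dob
    if name_typo_rate > 0 and rng.random() < name_typo_rate:
        target = "first" if rng.random() < 0.5 else "last"
        name = first if target == "first" else last
        if name and len(name) >= 2:
            pos = int(rng.integers(0, len(name)))
            if rng.random() < 0.5 or pos == len(name) - 1:
                letter = chr(ord("A") + int(rng.integers(0, 26)))
                mutated = name[:pos] + letter + name[pos + 1:]
                kind = "substitution"
            else:
                mutated = name[:pos] + name[pos + 1] + name[pos] + name[pos + 2:]
                kind = "transposition"
            if log is not None:
                log.append({
                    "patid": record.patid,
                    "event": f"name_typo_{kind}",
                    "field": target,
                    "soundex_preserved": soundex(mutated) == soundex(name),
                })
            if target == "first":
                first = mutated
            else:
                last = mutated
    if dob_error_rate > 0 and dob and rng.random() < dob_error_rate:
        y, m, d = (int(p) for p in dob.split("-"))
        if d <= 12 and d != m:
            dob = f"{y:04d}-{d:02d}-{m:02d}"  # day/month swap, always valid
            event = "dob_daymonth_swap"
        else:
            dob = (date(y, m, d) + timedelta(days=1)).isoformat()
            event = "dob_offby_one"
        if log is not None:
            log.append({"patid": record.patid, "event": event, "field": "dob",
                        "soundex_preserved": True})
    if (first, last, dob) == (record.first_name, record.last_name, record.dob):
        return record
    return PIIRecord(
        patid=record.patid, first_name=first, last_name=last,
        gender=record.gender, dob=dob, zip5=record.zip5, ssn=record.ssn,
    )


def generate_population(cfg: SimConfig) -> Population:
    """Generate per-site PII and demographic extracts plus ground truth.

    Deterministic given ``cfg.seed``.  Each site draws from its own seeded
    substream (keyed on the DMID), so adding a site leaves the other sites'
    extracts byte-identical; shared persons are drawn from a pair-keyed
    substream for the same reason.
    """
    cfg.validate()
    sites = list(cfg.sites)
    # person ids: pair-shared persons first (pair order stable), then
    # site-unique persons, then duplicates reuse existing persons.
    persons: dict[int, _Person] = {}
    site_person_ids: dict[str, list[int]] = {s: [] for s in sites}
    used_keys: set[tuple[str, str, str, str]] = set()
    next_pid = 0
    for pair in sorted(cfg.overlaps, key=lambda p: tuple(sorted(p))):
        k = cfg._pair_count(pair)
        prng = _pair_rng(cfg.seed, *pair)
        for _ in range(k):
            person = _draw_person(next_pid, prng, used_keys)
            persons[next_pid] = person
            for s in pair:
                site_person_ids[s].append(next_pid)
            next_pid += 1
    for dmid in sites:
        n = cfg.sites[dmid]
        n_dup = round(cfg.duplicate_rate * n)
        n_unique = n - n_dup
        srng = _site_rng(cfg.seed, dmid)
        while len(site_person_ids[dmid]) < n_unique:
            persons[next_pid] = _draw_person(next_pid, srng, used_keys)
            site_person_ids[dmid].append(next_pid)
            next_pid += 1
        # within-site duplicates: re-list existing persons at this site
        if n_dup:
            dup_choices = srng.integers(0, n_unique, size=n_dup)
            site_person_ids[dmid].extend(site_person_ids[dmid][i] for i in dup_choices)

    pii: dict[str, list[PIIRecord]] = {}
    demographics: dict[str, pd.DataFrame] = {}
    truth_map: dict[int, set[tuple[str, str]]] = {}
    log: list[dict] = []
    sex_label = {"F": "Female", "M": "Male", "OT": OTHER_MISSING, "UN": OTHER_MISSING}
    for dmid in sites:
        crng = _site_rng(cfg.seed, dmid + "/corruption")
        ssn_rate = cfg.ssn_rate(dmid)
        records = []
        demo_rows = []
        order = crng.permutation(len(site_person_ids[dmid]))
        for row_idx, person_idx in enumerate(order):
            pid = site_person_ids[dmid][person_idx]
            person = persons[pid]
            patid = f"P{row_idx + 1:06d}"
            truth_map.setdefault(pid, set()).add((dmid, patid))
            base = PIIRecord(
                patid=patid,
                first_name=person.first,
                last_name=person.last,
                gender=person.gender,
                dob=person.dob.isoformat(),
                zip5=person.zip5,
                ssn=person.ssn if crng.random() < ssn_rate else None,
            )
            records.append(
                corrupt_pii(base, cfg.name_typo_rate, cfg.dob_error_rate, crng, log)
            )
            race = person.race
            if (cfg.demographic_discordance_rate > 0
                    and crng.random() < cfg.demographic_discordance_rate):
                race = str(crng.choice(list(RACE_PRIORS), p=list(RACE_PRIORS.values())))
            demo_rows.append({
                "DMID": dmid,
                "PATID": patid,
                "AGE_GROUP": _age_group(person.dob),
                "SEX": sex_label[person.gender],
                "RACE": race,
            })
        pii[dmid] = records
        demographics[dmid] = pd.DataFrame(
            demo_rows, columns=["DMID", "PATID", "AGE_GROUP", "SEX", "RACE"]
        )
    return Population(
        pii=pii,
        demographics=demographics,
        truth=LinkTruth(appearances=truth_map),
        corruption_log=log,
    )


def _pair_counts(labels: list[int]) -> int:
    from collections import Counter

    return sum(n * (n - 1) // 2 for n in Counter(labels).values())


def evaluate_linkage(mi: pd.DataFrame, truth: LinkTruth) -> dict[str, float]:
    """Pairwise precision/recall of the inferred partition against truth.

    With zero predicted (or true) pairs the corresponding ratio is reported
    as 1.0 — an empty prediction makes no false claims.
    """
    from collections import Counter

    truth_label = truth.label_of()
    refs = [tuple(r.split("_", 1)) for r in mi["DMID_PATID"]]
    if set(refs) != set(truth_label):
        raise ValueError("match index and ground truth cover different records")
    pred = list(mi["MATCH_ID"])
    true = [truth_label[r] for r in refs]
    pred_pairs = _pair_counts(pred)
    true_pairs = _pair_counts(true)
    joint = Counter(zip(pred, true))
    tp = sum(n * (n - 1) // 2 for n in joint.values())
    return {
        "precision": tp / pred_pairs if pred_pairs else 1.0,
        "recall": tp / true_pairs if true_pairs else 1.0,
        "true_pairs": float(true_pairs),
        "predicted_pairs": float(pred_pairs),
    }
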