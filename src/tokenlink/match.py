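"""Majority-vote matching over cc-stage tokens and Match Index construction.

Two records match when, among the token slots present in *both* records,
strictly more than half carry equal values.  Matched pairs are clustered by
transitive closure (union-find) and each connected component receives one
MATCH_ID — the master patient identifier.  The resulting Match Index maps
MATCH_IDs to site-qualified reference IDs (``DMID_PATID``); a token-free
variant of it is the only artifact that crosses the privacy boundary to the
analysis team.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .tokens import N_TOKENS, TOKEN_COLUMNS, TokenSet

INDEX_COLUMNS = ["MATCH_ID", "DMID_PATID"]
REF_DELIM = "_"


@dataclass(frozen=True)
class RefID:
    """Site-qualified patient reference: DataMart ID + site-local PATID."""

    dmid: str
    patid: str

    def __post_init__(self) -> None:
        if not self.dmid or not self.patid:
            raise ValueError("dmid and patid must be non-empty")
        if REF_DELIM in self.dmid:
            raise ValueError(f"dmid may not contain {REF_DELIM!r}")

    def render(self) -> str:
        return f"{self.dmid}{REF_DELIM}{self.patid}"

    @classmethod
    def parse(cls, text: str) -> "RefID":
        dmid, _, patid = text.partition(REF_DELIM)
        return cls(dmid=dmid, patid=patid)


def pair_is_match(a: TokenSet, b: TokenSet, min_available: int = 1) -> bool:
    """Majority rule over the mutually available token slots.

    Let A be the slots non-missing in both records and m the number of those
    slots where the values agree; the pair matches iff ``|A| >= min_available``
    and ``m > |A|/2`` (strict majority — a 2-of-4 split is a non-match).
    """
    if a.stage != b.stage:
        raise ValueError(f"stage mismatch: {a.stage!r} vs {b.stage!r}")
    available = 0
    equal = 0
    for ta, tb in zip(a.tokens, b.tokens):
        if ta is not None and tb is not None:
            available += 1
            if ta == tb:
                equal += 1
    return available >= min_available and 2 * equal > available


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _candidate_pairs(tokensets: list[TokenSet]):
    """Pairs of record indices sharing at least one token value.

    Complete for the majority rule: a matching pair has >= 1 equal mutually
    available slot, so it shares a value in at least one per-slot block.
    """
    seen: set[tuple[int, int]] = set()
    for slot in range(N_TOKENS):
        blocks: dict[bytes, list[int]] = defaultdict(list)
        for idx, ts in enumerate(tokensets):
            t = ts.tokens[slot]
            if t is not None:
                blocks[t].append(idx)
        for members in blocks.values():
            for i_pos in range(len(members) - 1):
                for j_pos in range(i_pos + 1, len(members)):
                    pair = (members[i_pos], members[j_pos])
                    if pair not in seen:
                        seen.add(pair)
                        yield pair


def match_partition(site_tokensets: dict[str, list[TokenSet]],
                    min_available: int = 1) -> list[tuple[RefID, int]]:
    """Cluster all records (within-site pairs included) into components.

    Returns ``(ref_id, component)`` per record; component labels are
    arbitrary but consistent.  Within-site pairs are compared too — the
    pipeline deliberately measures within-site duplicates.
    """
    refs: list[RefID] = []
    flat: list[TokenSet] = []
    seen_refs: set[str] = set()
    for dmid, tokensets in site_tokensets.items():
        for ts in tokensets:
            ref = RefID(dmid=dmid, patid=ts.patid)
            rendered = ref.render()
            if rendered in seen_refs:
                raise ValueError(f"duplicate reference ID {rendered!r}")
            seen_refs.add(rendered)
            refs.append(ref)
            flat.append(ts)
    uf = _UnionFind(len(flat))
    for i, j in _candidate_pairs(flat):
        if uf.find(i) != uf.find(j) and pair_is_match(flat[i], flat[j], min_available):
            uf.union(i, j)
    return [(ref, uf.find(i)) for i, ref in enumerate(refs)]


def build_match_index(site_tokensets: dict[str, list[TokenSet]],
                      min_available: int = 1,
                      include_tokens: bool = True) -> pd.DataFrame:
    """Build the Match Index table (Match-ID ↔ DMID_PATID, plus tokens).

    MATCH_ID assignment is deterministic and independent of input order:
    components are numbered after sorting by their lexicographically
    smallest member reference ID.
    """
    labelled = match_partition(site_tokensets, min_available)
    components: dict[int, list[RefID]] = defaultdict(list)
    for ref, comp in labelled:
        components[comp].append(ref)
    ordered = sorted(components.values(), key=lambda refs: min(r.render() for r in refs))
    token_lookup = {}
    if include_tokens:
        for dmid, tokensets in site_tokensets.items():
            for ts in tokensets:
                token_lookup[(dmid, ts.patid)] = ts
    rows = []
    for comp_idx, members in enumerate(ordered):
        match_id = f"M{comp_idx + 1:09d}"
        for ref in sorted(members, key=RefID.render):
            row = {"MATCH_ID": match_id, "DMID_PATID": ref.render()}
            if include_tokens:
                ts = token_lookup[(ref.dmid, ref.patid)]
                for col, t in zip(TOKEN_COLUMNS, ts.tokens):
                    row[col] = "" if t is None else t.hex()
            rows.append(row)
    columns = INDEX_COLUMNS + (TOKEN_COLUMNS if include_tokens else [])
    return pd.DataFrame(rows, columns=columns)


def strip_tokens(match_index: pd.DataFrame) -> pd.DataFrame:
    """Token-free Match Index: identical rows, MATCH_ID and DMID_PATID only.

    This is the artifact that crosses the privacy boundary; it is idempotent
    and sufficient for every downstream statistic.
    """
    missing = [c for c in INDEX_COLUMNS if c not in match_index.columns]
    if missing:
        raise ValueError(f"match index missing columns: {missing}")
    return match_index[INDEX_COLUMNS].copy()


def has_token_columns(df: pd.DataFrame) -> bool:
    return any(c in df.columns for c in TOKEN_COLUMNS)


def read_match_index(path: str | Path, forbid_tokens: bool = False) -> pd.DataFrame:
    """Read a Match Index file; optionally enforce the privacy boundary."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in INDEX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"match index missing columns: {missing}")
    if forbid_tokens and has_token_columns(df):
        raise PrivacyBoundaryError(
            "token-bearing Match Index refused: analysis-side operations "
            "accept only the token-free variant"
        )
    return df


class PrivacyBoundaryError(RuntimeError):
    """An analysis-side operation was offered token bytes or PII."""
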