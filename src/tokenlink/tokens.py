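"""Token generation and the three-stage encryption lifecycle.

Six de-identified tokens are derived per patient, each a keyed hash of a
fixed recipe of normalized PII fields:

========  =====================================================
token 1   last name | first initial | gender | date of birth
token 2   last name soundex | first name soundex | gender | dob
token 3   last name | first name | dob | 3-digit zip
token 4   last name | first name | gender | dob
token 5   SSN | gender | dob
token 6   SSN | first name
========  =====================================================

A token slot is missing exactly when any of its constituent fields is
missing, and that missingness mask never changes across encryption stages.

The lifecycle mirrors a hub-and-spoke deployment: the shared-salt hash
(``master_hash``) is immediately wrapped in a *site* layer (each site's
tokens are unique, so a breach at one site exposes nothing comparable),
re-wrapped in a *transit* layer specific to one recipient for the wire, and
finally rewritten at the coordinating center into a common *cc* scheme in
which — and only in which — tokens from different sites are comparable.
"""

from __future__ import annotations

import secrets
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .crypto import TOKEN_BYTES, decrypt_block, encrypt_block, hash_preimage
from .pii import NormalizedPII, PIIRecord, normalize_pii

N_TOKENS = 6
STAGES = ("master_hash", "site", "transit", "cc")
TOKEN_COLUMNS = [f"TOKEN_{i:02d}" for i in range(1, N_TOKENS + 1)]
PII_COLUMNS = ["PATID", "FIRST_NAME", "LAST_NAME", "GENDER", "DOB", "ZIP5", "SSN"]

_DELIM = "|"


class TokenFormatError(ValueError):
    """Malformed token file or token byte string."""


@dataclass(frozen=True)
class TokenSet:
    """The six token slots for one patient record at one lifecycle stage."""

    patid: str
    stage: str
    tokens: tuple[bytes | None, ...]

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if len(self.tokens) != N_TOKENS:
            raise ValueError(f"expected {N_TOKENS} token slots")
        for t in self.tokens:
            if t is not None and len(t) != TOKEN_BYTES:
                raise TokenFormatError(f"token must be {TOKEN_BYTES} bytes")

    @property
    def missing_mask(self) -> tuple[bool, ...]:
        return tuple(t is None for t in self.tokens)


@dataclass
class KeyRing:
    """All secret key material for one deployment.

    ``master_salt`` is shared by every tokenizing site (it is what makes the
    underlying hashes comparable); ``site_keys`` are per-site; ``transit_keys``
    are per (site, recipient) channel; ``cc_key`` is the coordinating
    center's common scheme.  Keys never appear in token files.
    """

    master_salt: bytes
    site_keys: dict[str, bytes] = field(default_factory=dict)
    transit_keys: dict[tuple[str, str], bytes] = field(default_factory=dict)
    cc_key: bytes = b""

    @classmethod
    def generate(cls, sites: list[str], recipient: str = "CC",
                 seed: int | None = None) -> "KeyRing":
        """Generate keys for *sites* and one recipient.

        Without *seed* the keys are cryptographically random; with *seed*
        they are derived deterministically (for reproducible test runs —
        never for a real deployment).
        """
        if seed is None:
            def key(_label: str) -> bytes:
                return secrets.token_bytes(32)
        else:
            def key(label: str) -> bytes:
                import hashlib
                return hashlib.sha256(f"keyring:{seed}:{label}".encode()).digest()
        return cls(
            master_salt=key("master_salt"),
            site_keys={s: key(f"site:{s}") for s in sites},
            transit_keys={(s, recipient): key(f"transit:{s}:{recipient}") for s in sites},
            cc_key=key("cc"),
        )

    def save(self, path: str | Path) -> None:
        doc = {
            "master_salt": self.master_salt.hex(),
            "site_keys": {s: k.hex() for s, k in self.site_keys.items()},
            "transit_keys": {f"{s}:{r}": k.hex() for (s, r), k in self.transit_keys.items()},
            "cc_key": self.cc_key.hex(),
        }
        Path(path).write_text(yaml.safe_dump(doc))

    @classmethod
    def load(cls, path: str | Path) -> "KeyRing":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            master_salt=bytes.fromhex(doc["master_salt"]),
            site_keys={s: bytes.fromhex(k) for s, k in doc["site_keys"].items()},
            transit_keys={
                tuple(name.split(":", 1)): bytes.fromhex(k)
                for name, k in doc["transit_keys"].items()
            },
            cc_key=bytes.fromhex(doc["cc_key"]),
        )


def token_preimages(n: NormalizedPII) -> tuple[str | None, ...]:
    """Build the six preimage strings; a missing constituent kills the slot.

    Fields are joined with ``|``, which normalization guarantees can never
    occur inside a field, so distinct field tuples yield distinct preimages.
    """
    recipes = (
        (n.last_name, n.first_initial, n.gender, n.dob_iso),
        (n.last_soundex, n.first_soundex, n.gender, n.dob_iso),
        (n.last_name, n.first_name, n.dob_iso, n.zip3),
        (n.last_name, n.first_name, n.gender, n.dob_iso),
        (n.ssn, n.gender, n.dob_iso),
        (n.ssn, n.first_name),
    )
    return tuple(
        None if any(f is None for f in recipe) else _DELIM.join(recipe)  # type: ignore[arg-type]
        for recipe in recipes
    )


def hash_tokens(n: NormalizedPII, master_salt: bytes) -> TokenSet:
    """Hash the six preimages under the shared master salt."""
    pre = token_preimages(n)
    return TokenSet(
        patid=n.patid,
        stage="master_hash",
        tokens=tuple(
            None if p is None else hash_preimage(f"T{i + 1}{_DELIM}{p}", master_salt)
            for i, p in enumerate(pre)
        ),
    )


_NEXT_STAGE = {"master_hash": "site", "site": "transit", "transit": "cc"}
_PREV_STAGE = {v: k for k, v in _NEXT_STAGE.items()}


def encrypt_stage(ts: TokenSet, key: bytes) -> TokenSet:
    """Add one encryption layer, advancing to the next stage."""
    if ts.stage not in _NEXT_STAGE:
        raise ValueError(f"no stage after {ts.stage!r}")
    return replace(
        ts,
        stage=_NEXT_STAGE[ts.stage],
        tokens=tuple(None if t is None else encrypt_block(t, key) for t in ts.tokens),
    )


def decrypt_stage(ts: TokenSet, key: bytes) -> TokenSet:
    """Remove one encryption layer (inverse of :func:`encrypt_stage`)."""
    if ts.stage not in _PREV_STAGE:
        raise ValueError(f"no stage before {ts.stage!r}")
    return replace(
        ts,
        stage=_PREV_STAGE[ts.stage],
        tokens=tuple(None if t is None else decrypt_block(t, key) for t in ts.tokens),
    )


def transform_to_cc(ts: TokenSet, keyring: KeyRing, site_id: str, recipient: str = "CC") -> TokenSet:
    """Rewrite a transit-stage TokenSet into the common cc scheme.

    Peels the transit and site layers and applies the cc layer, so the same
    underlying hash lands on the same cc bytes regardless of origin site.
    """
    if ts.stage != "transit":
        raise ValueError(f"expected transit stage, got {ts.stage!r}")
    try:
        transit_key = keyring.transit_keys[(site_id, recipient)]
        site_key = keyring.site_keys[site_id]
    except KeyError as exc:
        raise KeyError(f"no key for site {site_id!r}") from exc
    master = decrypt_stage(decrypt_stage(ts, transit_key), site_key)
    return encrypt_stage(
        replace(master, stage="transit"), keyring.cc_key
    )


# ---------------------------------------------------------------------------
# file-level pipeline operations (HASH_TOKEN extract dialect)


def read_pii_extract(path: str | Path) -> list[PIIRecord]:
    """Read a headered comma-separated PII extract; empty string = missing."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PII_COLUMNS if c not in df.columns]
    if missing:
        raise TokenFormatError(f"PII extract missing columns: {missing}")

    def opt(v: str) -> str | None:
        return v if v != "" else None

    return [
        PIIRecord(
            patid=row.PATID,
            first_name=opt(row.FIRST_NAME),
            last_name=opt(row.LAST_NAME),
            gender=opt(row.GENDER),
            dob=opt(row.DOB),
            zip5=opt(row.ZIP5),
            ssn=opt(row.SSN),
        )
        for row in df.itertuples(index=False)
    ]


def tokensets_to_frame(tokensets: list[TokenSet]) -> pd.DataFrame:
    """Render TokenSets as a HASH_TOKEN table (lowercase hex, '' = missing)."""
    rows = [
        {
            "PATID": ts.patid,
            **{
                col: "" if t is None else t.hex()
                for col, t in zip(TOKEN_COLUMNS, ts.tokens)
            },
        }
        for ts in tokensets
    ]
    return pd.DataFrame(rows, columns=["PATID"] + TOKEN_COLUMNS)


def frame_to_tokensets(df: pd.DataFrame, stage: str) -> list[TokenSet]:
    missing = [c for c in ["PATID"] + TOKEN_COLUMNS if c not in df.columns]
    if missing:
        raise TokenFormatError(f"HASH_TOKEN table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        toks = []
        for col in TOKEN_COLUMNS:
            h = getattr(row, col)
            if h == "":
                toks.append(None)
            else:
                try:
                    b = bytes.fromhex(h)
                except ValueError as exc:
                    raise TokenFormatError(f"invalid hex token in {col}") from exc
                toks.append(b)
        out.append(TokenSet(patid=row.PATID, stage=stage, tokens=tuple(toks)))
    return out


def read_token_file(path: str | Path, stage: str) -> list[TokenSet]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return frame_to_tokensets(df, stage)


def write_token_file(tokensets: list[TokenSet], path: str | Path) -> None:
    tokensets_to_frame(tokensets).to_csv(path, index=False)


def tokenize_records(records: list[PIIRecord], site_id: str, keyring: KeyRing) -> list[TokenSet]:
    """Normalize, hash, and site-encrypt a site's PII records.

    PATID must be unique within the site (it is the CDM pseudo-identifier);
    duplicates are a hard error, not a merge.
    """
    seen: set[str] = set()
    for r in records:
        if r.patid in seen:
            raise TokenFormatError(f"duplicate PATID {r.patid!r} in site {site_id!r} extract")
        seen.add(r.patid)
    try:
        site_key = keyring.site_keys[site_id]
    except KeyError as exc:
        raise KeyError(f"no site key for {site_id!r}") from exc
    return [
        encrypt_stage(hash_tokens(normalize_pii(r), keyring.master_salt), site_key)
        for r in records
    ]


def tokenize_site_file(pii_path: str | Path, site_id: str, keyring: KeyRing,
                       out_path: str | Path) -> int:
    """PII extract → site-stage HASH_TOKEN file; returns the row count."""
    records = read_pii_extract(pii_path)
    tokensets = tokenize_records(records, site_id, keyring)
    write_token_file(tokensets, out_path)
    return len(tokensets)


def transform_site_file(token_path: str | Path, site_id: str, keyring: KeyRing,
                        out_path: str | Path, direction: str,
                        recipient: str = "CC") -> int:
    """Apply one lifecycle transform to a whole HASH_TOKEN file.

    ``direction='to'``: site → transit (for the wire).
    ``direction='from'``: transit → cc (at the coordinating center).
    """
    if direction == "to":
        tokensets = read_token_file(token_path, "site")
        key = keyring.transit_keys.get((site_id, recipient))
        if key is None:
            raise KeyError(f"no transit key for ({site_id!r}, {recipient!r})")
        out = [encrypt_stage(ts, key) for ts in tokensets]
    elif direction == "from":
        tokensets = read_token_file(token_path, "transit")
        out = [transform_to_cc(ts, keyring, site_id, recipient) for ts in tokensets]
    else:
        raise ValueError("direction must be 'to' or 'from'")
    write_token_file(out, out_path)
    return len(out)
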