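"""Canonical PII representation, normalization, and phonetic encoding.

Raw per-site extracts carry free-form identifiers (names with mixed case and
punctuation, dates in several layouts, SSNs with or without dashes).  Because
the downstream tokens are *exact* keyed hashes, normalization is the only
tolerance mechanism short of the soundex token: two sites must serialize the
same person identically or every name-bearing token slot will differ.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from datetime import date, datetime

logger = logging.getLogger(__name__)

#: PCORnet CDM sex codes accepted in PII extracts.
GENDER_CODES = frozenset({"F", "M", "OT", "UN"})

_NON_ALPHA = re.compile(r"[^A-Z]")
_NON_DIGIT = re.compile(r"[^0-9]")

# Date layouts accepted in raw extracts; output is always ISO.
_DATE_FORMATS = ("%Y-%m-%d", "%m/%d/%Y", "%Y%m%d", "%d-%b-%Y")


@dataclass(frozen=True)
class PIIRecord:
    """One patient's raw identifiers at a site.

    ``patid`` is the site-local pseudo-identifier and must be non-empty;
    every other field may be ``None`` (missing).
    """

    patid: str
    first_name: str | None = None
    last_name: str | None = None
    gender: str | None = None
    dob: str | None = None
    zip5: str | None = None
    ssn: str | None = None

    def __post_init__(self) -> None:
        if not self.patid:
            raise ValueError("patid must be non-empty")


@dataclass(frozen=True)
class NormalizedPII:
    """Normalized identifiers plus the derived fields token recipes need.

    Names are uppercase and purely alphabetic; ``dob_iso`` is ``YYYY-MM-DD``;
    ``zip3`` is the leading 3 digits of ``zip5``; soundex codes follow the
    American Soundex pattern (letter + 3 digits).
    """

    patid: str
    first_name: str | None = None
    last_name: str | None = None
    gender: str | None = None
    dob_iso: str | None = None
    zip5: str | None = None
    ssn: str | None = None
    first_initial: str | None = None
    first_soundex: str | None = None
    last_soundex: str | None = None
    zip3: str | None = None


# American Soundex digit classes.  H and W are transparent: codes separated
# only by H/W collapse as if adjacent; vowels (and Y) break adjacency.
_SOUNDEX_CODE = {}
for _letters, _digit in (
    ("BFPV", "1"),
    ("CGJKQSXZ", "2"),
    ("DT", "3"),
    ("L", "4"),
    ("MN", "5"),
    ("R", "6"),
):
    for _c in _letters:
        _SOUNDEX_CODE[_c] = _digit


def soundex(name: str) -> str | None:
    """American Soundex code of *name*: first letter + 3 digits.

    Returns ``None`` for input with no alphabetic characters.  Names that
    sound alike in English (Jon/John, Smith/Smyth) share a code, which is
    what makes the soundex token robust to spelling variants.
    """
    cleaned = _NON_ALPHA.sub("", name.upper())
    if not cleaned:
        return None
    first = cleaned[0]
    digits = []
    prev = _SOUNDEX_CODE.get(first, "")
    for ch in cleaned[1:]:
        code = _SOUNDEX_CODE.get(ch)
        if code is None:
            # vowels reset adjacency; H/W are transparent (prev survives)
            if ch not in "HW":
                prev = ""
            continue
        if code != prev:
            digits.append(code)
            prev = code
        if len(digits) == 3:
            break
    return first + "".join(digits).ljust(3, "0")


def _norm_name(value: str | None) -> str | None:
    if value is None:
        return None
    cleaned = _NON_ALPHA.sub("", value.upper())
    return cleaned or None


def _norm_digits(value: str | None, width: int) -> str | None:
    if value is None:
        return None
    cleaned = _NON_DIGIT.sub("", value)
    return cleaned if len(cleaned) == width else None


def _norm_dob(value: str | None, patid: str) -> str | None:
    if value is None or not value.strip():
        return None
    text = value.strip()
    for fmt in _DATE_FORMATS:
        try:
            return datetime.strptime(text, fmt).date().isoformat()
        except ValueError:
            continue
    logger.warning("unparseable date of birth for patid %s; treated as missing", patid)
    return None


def _norm_gender(value: str | None) -> str | None:
    if value is None:
        return None
    code = value.strip().upper()
    return code if code in GENDER_CODES else None


def normalize_pii(raw: PIIRecord) -> NormalizedPII:
    """Normalize a raw record deterministically.

    Case, surrounding whitespace, and punctuation never survive into the
    normalized form, so two extracts differing only in those produce
    identical token preimages.  Malformed fields (unparseable date, SSN that
    is not 9 digits after stripping) become missing rather than erroring:
    missingness is a value the token recipes know how to propagate.
    """
    first = _norm_name(raw.first_name)
    last = _norm_name(raw.last_name)
    zip5 = _norm_digits(raw.zip5, 5)
    return NormalizedPII(
        patid=raw.patid,
        first_name=first,
        last_name=last,
        gender=_norm_gender(raw.gender),
        dob_iso=_norm_dob(raw.dob, raw.patid),
        zip5=zip5,
        ssn=_norm_digits(raw.ssn, 9),
        first_initial=first[0] if first else None,
        first_soundex=soundex(first) if first else None,
        last_soundex=soundex(last) if last else None,
        zip3=zip5[:3] if zip5 else None,
    )
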