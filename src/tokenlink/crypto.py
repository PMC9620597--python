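"""Keyed hashing and the deterministic, invertible stage cipher.

Two primitives back the token lifecycle:

* ``hash_preimage`` — HMAC-SHA-256 of a token preimage under the shared
  master salt.  One-way and keyed: without the salt the 6 preimage recipes
  cannot be dictionary-attacked, and the same PII always yields the same
  32-byte digest at every site.

* ``encrypt_block`` / ``decrypt_block`` — a deterministic keyed permutation
  of the 32-byte digest, built as a 4-round balanced Feistel network whose
  round functions are HMAC-SHA-256 (a Luby–Rackoff construction).  Each
  encryption layer is equality-preserving (``E(a) == E(b)`` iff ``a == b``
  under one key), which is exactly the contract the coordinating center
  needs: compare tokens for equality without ever seeing the hash beneath.

Keys are arbitrary non-empty byte strings; all outputs are 32 bytes.
"""

from __future__ import annotations

import hashlib
import hmac

TOKEN_BYTES = 32
_HALF = TOKEN_BYTES // 2
_ROUNDS = 4


class KeyError_(Exception):
    """Raised for empty or missing key material."""


def hash_preimage(preimage: str, master_salt: bytes) -> bytes:
    """Keyed one-way hash of a preimage string; 32 bytes, deterministic."""
    if not master_salt:
        raise KeyError_("master salt must be non-empty")
    return hmac.new(master_salt, preimage.encode("utf-8"), hashlib.sha256).digest()


def _round_key(key: bytes, rnd: int) -> bytes:
    return hmac.new(key, b"feistel-round-%d" % rnd, hashlib.sha256).digest()


def _f(round_key: bytes, half: bytes) -> bytes:
    return hmac.new(round_key, half, hashlib.sha256).digest()[:_HALF]


def _xor(a: bytes, b: bytes) -> bytes:
    return bytes(x ^ y for x, y in zip(a, b))


def encrypt_block(token: bytes, key: bytes) -> bytes:
    """Apply one deterministic encryption layer to a 32-byte token."""
    if not key:
        raise KeyError_("encryption key must be non-empty")
    if len(token) != TOKEN_BYTES:
        raise ValueError(f"token must be {TOKEN_BYTES} bytes, got {len(token)}")
    left, right = token[:_HALF], token[_HALF:]
    for rnd in range(_ROUNDS):
        left, right = right, _xor(left, _f(_round_key(key, rnd), right))
    return left + right


def decrypt_block(token: bytes, key: bytes) -> bytes:
    """Invert :func:`encrypt_block` under the same key."""
    if not key:
        raise KeyError_("encryption key must be non-empty")
    if len(token) != TOKEN_BYTES:
        raise ValueError(f"token must be {TOKEN_BYTES} bytes, got {len(token)}")
    left, right = token[:_HALF], token[_HALF:]
    for rnd in reversed(range(_ROUNDS)):
        left, right = _xor(right, _f(_round_key(key, rnd), left)), left
    return left + right
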