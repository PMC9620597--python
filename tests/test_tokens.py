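import pandas as pd
import pytest

from tokenlink.crypto import TOKEN_BYTES, decrypt_block, encrypt_block, hash_preimage
from tokenlink.pii import PIIRecord, normalize_pii
from tokenlink.tokens import (
    KeyRing,
    decrypt_stage,
    encrypt_stage,
    hash_tokens,
    read_pii_extract,
    read_token_file,
    token_preimages,
    tokenize_records,
    tokenize_site_file,
    transform_to_cc,
)
from tokenlink.tokens import TokenFormatError


FULL = PIIRecord(patid="p1", first_name="Jane", last_name="Doe", gender="F",
                 dob="1980-02-29", zip5="02115", ssn="123456789")


def norm(**overrides):
    fields = dict(patid="p1", first_name="Jane", last_name="Doe", gender="F",
                  dob="1980-02-29", zip5="02115", ssn="123456789")
    fields.update(overrides)
    return normalize_pii(PIIRecord(**fields))


class TestPreimages:
    def test_complete_record_yields_all_six(self):
        pre = token_preimages(norm())
        assert all(p is not None for p in pre)
        assert pre[0] == "DOE|J|F|1980-02-29"
        assert pre[2] == "DOE|JANE|1980-02-29|021"
        assert pre[4] == "123456789|F|1980-02-29"
        assert pre[5] == "123456789|JANE"

    def test_missing_ssn_kills_slots_5_and_6_only(self):
        pre = token_preimages(norm(ssn=None))
        assert [p is None for p in pre] == [False, False, False, False, True, True]

    def test_missing_zip_kills_slot_3_only(self):
        pre = token_preimages(norm(zip5=None))
        assert [p is None for p in pre] == [False, False, True, False, False, False]

    def test_missing_gender_kills_slots_1_2_4_5(self):
        pre = token_preimages(norm(gender=None))
        assert [p is None for p in pre] == [True, True, False, True, True, False]


class TestHashing:
    def test_deterministic_under_same_salt(self):
        a = hash_tokens(norm(), b"salt-1")
        b = hash_tokens(norm(), b"salt-1")
        assert a.tokens == b.tokens

    def test_salt_changes_every_token(self):
        a = hash_tokens(norm(), b"salt-1")
        b = hash_tokens(norm(), b"salt-2")
        assert all(x != y for x, y in zip(a.tokens, b.tokens))

    def test_empty_salt_is_configuration_error(self):
        with pytest.raises(Exception):
            hash_tokens(norm(), b"")

    def test_avalanche_single_character_flip(self):
        """One-character preimage changes flip ~half the digest bits."""
        salt = b"avalanche-salt"
        diffs = []
        for i in range(200):
            base = f"SMITH|JOHN|M|19{i:02d}-01-01"
            mutated = base.replace("JOHN", "JOHM")
            h1 = hash_preimage(base, salt)
            h2 = hash_preimage(mutated, salt)
            bits = sum(bin(x ^ y).count("1") for x, y in zip(h1, h2))
            diffs.append(bits / (8 * TOKEN_BYTES))
        assert sum(diffs) / len(diffs) >= 0.40


class TestStageCipher:
    def test_encrypt_decrypt_roundtrip_block(self):
        token = hash_preimage("X", b"k")
        for key in (b"a", b"key-2", bytes(range(32))):
            assert decrypt_block(encrypt_block(token, key), key) == token

    def test_equality_preserving_and_injective(self):
        k = b"stage-key"
        t1 = hash_preimage("A", b"salt")
        t2 = hash_preimage("B", b"salt")
        assert encrypt_block(t1, k) == encrypt_block(t1, k)
        assert encrypt_block(t1, k) != encrypt_block(t2, k)

    def test_stage_roundtrip_preserves_tokenset(self):
        ts = hash_tokens(norm(), b"salt")
        enc = encrypt_stage(ts, b"site-key")
        assert enc.stage == "site"
        assert decrypt_stage(enc, b"site-key") == ts

    def test_missingness_mask_invariant_across_stages(self):
        ts = hash_tokens(norm(ssn=None), b"salt")
        enc = encrypt_stage(encrypt_stage(ts, b"k1"), b"k2")
        assert enc.missing_mask == ts.missing_mask

    def test_wrong_length_token_rejected(self):
        with pytest.raises(ValueError):
            encrypt_block(b"short", b"k")


class TestLifecycle:
    def test_same_patient_two_sites_site_tokens_all_differ(self, keyring):
        ts = {s: tokenize_records([FULL], s, keyring)[0] for s in ("S1", "S2")}
        assert all(a != b for a, b in zip(ts["S1"].tokens, ts["S2"].tokens))

    def test_same_patient_two_sites_cc_tokens_identical(self, keyring):
        cc = {}
        for s in ("S1", "S2"):
            site = tokenize_records([FULL], s, keyring)[0]
            transit = encrypt_stage(site, keyring.transit_keys[(s, "CC")])
            cc[s] = transform_to_cc(transit, keyring, s)
        assert cc["S1"].tokens == cc["S2"].tokens
        assert cc["S1"].stage == "cc"

    def test_distinct_patients_share_no_cc_slots(self, keyring):
        other = PIIRecord(patid="p2", first_name="John", last_name="Smith",
                          gender="M", dob="1975-05-05", zip5="60601", ssn="987654321")
        site = tokenize_records([FULL, other], "S1", keyring)
        cc = [
            transform_to_cc(encrypt_stage(t, keyring.transit_keys[("S1", "CC")]),
                            keyring, "S1")
            for t in site
        ]
        assert all(a != b for a, b in zip(cc[0].tokens, cc[1].tokens))

    def test_unknown_site_key_errors(self, keyring):
        with pytest.raises(KeyError):
            tokenize_records([FULL], "NOPE", keyring)


class TestFileOps:
    def test_row_conservation_and_roundtrip(self, tmp_path, keyring):
        pii = tmp_path / "pii.csv"
        pii.write_text(
            "PATID,FIRST_NAME,LAST_NAME,GENDER,DOB,ZIP5,SSN\n"
            "p1,Jane,Doe,F,1980-02-29,02115,123456789\n"
            "p2,John,Smith,M,1975-05-05,60601,\n"
        )
        out = tmp_path / "tok.csv"
        assert tokenize_site_file(pii, "S1", keyring, out) == 2
        back = read_token_file(out, "site")
        assert len(back) == 2
        assert back[1].tokens[4] is None and back[1].tokens[5] is None

    def test_all_rows_missing_ssn_empties_token_5_6_columns(self, tmp_path, keyring):
        pii = tmp_path / "pii.csv"
        pii.write_text(
            "PATID,FIRST_NAME,LAST_NAME,GENDER,DOB,ZIP5,SSN\n"
            "p1,Jane,Doe,F,1980-02-29,02115,\n"
            "p2,John,Smith,M,1975-05-05,60601,\n"
        )
        out = tmp_path / "tok.csv"
        tokenize_site_file(pii, "S1", keyring, out)
        df = pd.read_csv(out, dtype=str, keep_default_na=False)
        assert (df["TOKEN_05"] == "").all() and (df["TOKEN_06"] == "").all()
        assert (df["TOKEN_01"] != "").all()

    def test_empty_pii_file_gives_headered_empty_output(self, tmp_path, keyring):
        pii = tmp_path / "pii.csv"
        pii.write_text("PATID,FIRST_NAME,LAST_NAME,GENDER,DOB,ZIP5,SSN\n")
        out = tmp_path / "tok.csv"
        assert tokenize_site_file(pii, "S1", keyring, out) == 0
        df = pd.read_csv(out, dtype=str, keep_default_na=False)
        assert list(df.columns) == ["PATID"] + [f"TOKEN_{i:02d}" for i in range(1, 7)]
        assert len(df) == 0

    def test_duplicate_patid_within_site_is_error(self, keyring):
        with pytest.raises(TokenFormatError):
            tokenize_records([FULL, FULL], "S1", keyring)

    def test_missing_column_rejected(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("PATID,FIRST_NAME\np1,Jane\n")
        with pytest.raises(TokenFormatError):
            read_pii_extract(bad)


def test_keyring_file_roundtrip_without_leaking_tokens(tmp_path):
    ring = KeyRing.generate(["S1", "S2"], seed=3)
    path = tmp_path / "keys.yaml"
    ring.save(path)
    back = KeyRing.load(path)
    assert back == ring
    assert back.transit_keys[("S1", "CC")] == ring.transit_keys[("S1", "CC")]
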