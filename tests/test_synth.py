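import numpy as np
import pytest

from conftest import demographics_frame, pipeline_to_cc
from tokenlink.match import build_match_index, strip_tokens
from tokenlink.pii import PIIRecord, soundex
from tokenlink.synth import (
    LinkTruth,
    SimConfig,
    SimConfigError,
    corrupt_pii,
    evaluate_linkage,
    generate_population,
)


class TestConfigValidation:
    def test_infeasible_overlap_rejected(self):
        cfg = SimConfig(sites={"A": 10, "B": 10}, overlaps={("A", "B"): 1.0},
                        duplicate_rate=0.5, seed=1)
        with pytest.raises(SimConfigError):
            cfg.validate()

    def test_unknown_site_in_overlap_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(sites={"A": 10}, overlaps={("A", "Z"): 0.1}, seed=1).validate()

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(sites={"A": 10}, name_typo_rate=1.5, seed=1).validate()


class TestGeneration:
    def test_deterministic_given_seed(self, tmp_path):
        cfg = SimConfig(sites={"A": 50, "B": 60}, overlaps={("A", "B"): 0.1},
                        duplicate_rate=0.02, name_typo_rate=0.1, seed=9)
        p1 = generate_population(cfg)
        p2 = generate_population(cfg)
        d1 = p1.write_extracts(tmp_path / "r1")
        d2 = p2.write_extracts(tmp_path / "r2")
        for dmid in cfg.sites:
            assert d1[dmid]["pii"].read_bytes() == d2[dmid]["pii"].read_bytes()
            assert d1[dmid]["demographics"].read_bytes() == d2[dmid]["demographics"].read_bytes()

    def test_adding_a_site_leaves_existing_sites_unchanged(self, tmp_path):
        base = SimConfig(sites={"A": 40, "B": 40}, overlaps={("A", "B"): 0.1}, seed=3)
        grown = SimConfig(sites={"A": 40, "B": 40, "C": 40},
                          overlaps={("A", "B"): 0.1}, seed=3)
        da = generate_population(base).write_extracts(tmp_path / "base")
        db = generate_population(grown).write_extracts(tmp_path / "grown")
        for dmid in ("A", "B"):
            assert da[dmid]["pii"].read_bytes() == db[dmid]["pii"].read_bytes()

    def test_zero_overlap_zero_duplicates_is_all_singletons(self):
        cfg = SimConfig(sites={"A": 30, "B": 30}, seed=2)
        pop = generate_population(cfg)
        assert all(len(refs) == 1 for refs in pop.truth.appearances.values())

    def test_truth_partitions_all_records(self):
        cfg = SimConfig(sites={"A": 40, "B": 50}, overlaps={("A", "B"): 0.2},
                        duplicate_rate=0.05, seed=4)
        pop = generate_population(cfg)
        refs = {(d, r.patid) for d, recs in pop.pii.items() for r in recs}
        truth_refs = [ref for s in pop.truth.appearances.values() for ref in s]
        assert len(truth_refs) == len(refs)
        assert set(truth_refs) == refs

    def test_shared_persons_have_identical_base_pii(self):
        cfg = SimConfig(sites={"A": 40, "B": 40}, overlaps={("A", "B"): 0.25},
                        ssn_availability=1.0, seed=6)
        pop = generate_population(cfg)
        by_ref = {(d, r.patid): r for d, recs in pop.pii.items() for r in recs}
        shared = [refs for refs in pop.truth.appearances.values() if len(refs) > 1]
        assert shared
        for refs in shared:
            recs = [by_ref[ref] for ref in refs]
            assert len({(r.first_name, r.last_name, r.gender, r.dob, r.zip5, r.ssn)
                        for r in recs}) == 1

    def test_ssn_availability_zero_drops_all_ssns(self):
        cfg = SimConfig(sites={"A": 30}, ssn_availability=0.0, seed=8)
        pop = generate_population(cfg)
        assert all(r.ssn is None for r in pop.pii["A"])


class TestCorruption:
    def test_rate_zero_is_identity(self):
        rng = np.random.default_rng(0)
        rec = PIIRecord(patid="1", first_name="Jane", last_name="Doe",
                        gender="F", dob="1980-01-02", zip5="12345", ssn="123456789")
        assert corrupt_pii(rec, 0.0, 0.0, rng) is rec

    def test_typos_logged_with_soundex_class(self):
        rng = np.random.default_rng(1)
        rec = PIIRecord(patid="1", first_name="Johnathan", last_name="Witherspoon",
                        gender="M", dob="1970-03-04")
        log = []
        mutated = [corrupt_pii(rec, 1.0, 0.0, rng, log) for _ in range(50)]
        assert any(m.first_name != rec.first_name or m.last_name != rec.last_name
                   for m in mutated)
        assert log and all("soundex_preserved" in e for e in log)
        for entry, m in zip(log, mutated):
            field = entry["field"]
            before = getattr(rec, f"{field}_name")
            after = getattr(m, f"{field}_name")
            assert entry["soundex_preserved"] == (soundex(after) == soundex(before))

    def test_dob_daymonth_swap_produces_valid_date(self):
        rng = np.random.default_rng(2)
        rec = PIIRecord(patid="1", first_name="A", last_name="B",
                        gender="F", dob="1980-03-07")
        out = corrupt_pii(rec, 0.0, 1.0, rng)
        assert out.dob == "1980-07-03"


class TestEvaluation:
    def test_clean_population_gives_exact_precision_recall(
            self, small_population, small_cc_tokensets):
        mi = strip_tokens(build_match_index(small_cc_tokensets))
        metrics = evaluate_linkage(mi, small_population.truth)
        assert metrics["precision"] == 1.0
        assert metrics["recall"] == 1.0

    def test_zero_true_overlap_is_undefined_safe(self):
        truth = LinkTruth(appearances={0: {("A", "1")}, 1: {("A", "2")}})
        import pandas as pd
        mi = pd.DataFrame({"MATCH_ID": ["M1", "M2"], "DMID_PATID": ["A_1", "A_2"]})
        metrics = evaluate_linkage(mi, truth)
        assert metrics["precision"] == 1.0 and metrics["recall"] == 1.0

    def test_universe_mismatch_is_error(self):
        truth = LinkTruth(appearances={0: {("A", "1")}})
        import pandas as pd
        mi = pd.DataFrame({"MATCH_ID": ["M1"], "DMID_PATID": ["B_9"]})
        with pytest.raises(ValueError):
            evaluate_linkage(mi, truth)

    def test_ssn_presence_helps_recall_under_name_typos(self, keyring):
        """More comparable token slots can only help the majority rule."""
        recalls = {}
        for label, ssn_avail in (("with_ssn", 1.0), ("without_ssn", 0.0)):
            cfg = SimConfig(sites={"S1": 300, "S2": 300},
                            overlaps={("S1", "S2"): 0.2},
                            ssn_availability=ssn_avail,
                            name_typo_rate=0.25, seed=31)
            pop = generate_population(cfg)
            mi = strip_tokens(build_match_index(pipeline_to_cc(pop, keyring)))
            recalls[label] = evaluate_linkage(mi, pop.truth)["recall"]
        assert recalls["with_ssn"] >= recalls["without_ssn"]

    def test_demographic_discordance_reaches_the_table(self, keyring):
        from tokenlink.dedup import DISCORDANT, build_characteristics_table

        cfg = SimConfig(sites={"S1": 300, "S2": 300}, overlaps={("S1", "S2"): 0.3},
                        demographic_discordance_rate=0.5, seed=13)
        pop = generate_population(cfg)
        mi = strip_tokens(build_match_index(pipeline_to_cc(pop, keyring)))
        ct = build_characteristics_table(demographics_frame(pop), mi)
        assert ct.race[DISCORDANT][2] > 0
        assert ct.race[DISCORDANT][0] == 0
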