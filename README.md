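# tokenlink

Privacy-preserving record linkage (PPRL) for multi-site health research
networks. Patients in the United States often receive care at several
unaffiliated health systems, so any one site's records are incomplete;
linking records across sites answers "how many *unique* patients do we
have, and who appears where?" — but the sites cannot share names, birth
dates, or SSNs. `tokenlink` implements the standard token-based answer
end to end, for methodologists, network coordinating centers, and anyone
who wants a transparent, testable reference for how hash-token linkage
behaves.

## The method

Each site derives six **de-identified tokens** per patient. Token *i* is a
keyed one-way hash (HMAC-SHA-256 under a shared secret *master salt*) of a
fixed recipe of normalized PII:

| token | recipe |
|-------|--------|
| 1 | last name + first initial + gender + date of birth |
| 2 | last name (soundex) + first name (soundex) + gender + DOB |
| 3 | last name + first name + DOB + 3-digit ZIP |
| 4 | last name + first name + gender + DOB |
| 5 | SSN + gender + DOB |
| 6 | SSN + first name |

A token slot is missing iff any constituent field is missing. The hashes
are wrapped in deterministic encryption layers — a **site** layer (every
site's tokens are unique, so one site's breach exposes nothing
comparable), a **transit** layer for the wire, and finally a common
**coordinating-center (cc)** layer under which, and only under which,
tokens from different sites can be compared for equality.

Two records **match** when strictly more than half of the token slots
present in *both* records are equal (a majority rule; a 2-of-4 tie is a
non-match). Matches are clustered by transitive closure into a master
patient index (`MATCH_ID` ↔ `DMID_PATID`). A **token-free** version of
that index crosses the organizational privacy boundary to the analysis
team, which computes overlap statistics (patients in 1/2/3/≥4 sites,
within-site duplicates, pairwise shared-patient percentages) and an
aggregated-vs-deduplicated demographics table, consolidating each
cluster's age/sex/race by adjudication (conflicting informative values
of sex or race become `Discordant`; age resolves to the oldest category).

Because real PII cannot ship with the package, a synthetic-population
generator plants known cross-site overlap, within-site duplicates, SSN
missingness, and typos — with ground truth — so precision and recall of
the whole pipeline are measurable.

## Worked example

```bash
tokenlink simulate --config cfg.yaml --out sim          # cfg: 2 sites x 300, 5% overlap
tokenlink keygen --sites S1,S2 --seed 5 --out keys.yaml
for s in S1 S2; do
  tokenlink tokenize  --pii sim/pii_$s.csv --site $s --keys keys.yaml --out tok_$s.csv
  tokenlink transform --tokens tok_$s.csv     --site $s --keys keys.yaml --direction to   --out transit_$s.csv
  tokenlink transform --tokens transit_$s.csv --site $s --keys keys.yaml --direction from --out cc_$s.csv
done
tokenlink match --site-file S1=cc_S1.csv --site-file S2=cc_S2.csv --out index_full.csv
tokenlink strip --index index_full.csv --out index.csv
tokenlink overlap --index index.csv --out overlap.json
tokenlink evaluate --index index.csv --truth sim/truth.json
```

The final command prints (this exact run):

```json
{
  "precision": 1.0,
  "recall": 1.0,
  "true_pairs": 23.0,
  "predicted_pairs": 23.0
}
```

meaning every planted cross-site person and within-site duplicate (23
record pairs in total) was recovered, with no false merges — the expected
outcome for clean PII, since clean tokens match exactly. `overlap.json`
holds the site counts, the 1/2/3/≥4-site multiplicity distribution, and
pairwise overlap percentages; feeding `index_full.csv` (which still
carries token bytes) to `overlap`, `table`, or `evaluate` is refused with
exit code 4: those subcommands model the analysis team, which never
receives tokens.

## Layout

- `tokenlink.pii` — PII normalization and American Soundex
- `tokenlink.tokens` — token recipes, HMAC hashing, encryption lifecycle, key ring
- `tokenlink.match` — majority rule, blocking, union-find, Match Index
- `tokenlink.overlap` — multiplicity, within-site duplicates, pairwise overlap
- `tokenlink.dedup` — adjudication and the characteristics table
- `tokenlink.synth` — synthetic populations with ground truth
- `tokenlink.cli` — `tokenlink` subcommands wiring the two-team pipeline

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
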