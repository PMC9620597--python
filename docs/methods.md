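# Methods

## Problem setting

A research network of health systems ("sites", each with a DataMart ID or
DMID) wants de-duplicated patient counts and cross-site overlap statistics
without any site revealing personally identifiable information (PII). The
package implements the token-based architecture used for this in practice:
sites derive keyed salted hashes of fixed PII combinations, a
coordinating center compares them under a common encryption scheme, and an
analysis team that never sees token bytes consumes only the resulting
cluster assignments.

## Normalization and soundex

Token matching is exact-hash matching, so normalization is the only
tolerance mechanism apart from the phonetic token. Names are uppercased
and stripped of all non-alphabetic characters; SSNs and ZIPs are stripped
to digits and discarded (treated as missing) if not exactly 9 or 5 digits;
dates are parsed from a small set of layouts and serialized as ISO
`YYYY-MM-DD` (unambiguous, sortable, locale-free); gender is restricted to
the common data model codes `{F, M, OT, UN}`. Malformed values become
missing with a logged warning rather than an error, because missingness is
a first-class state the token recipes know how to propagate.

The phonetic code is classic American Soundex (first letter + three digits
from the consonant classes, H/W transparent, vowels breaking adjacency,
zero-padded), the conventional referent when "soundex" is unqualified.
Alternative phonetic schemes (metaphone, refined soundex) are out of
scope.

## Token construction

Preimage fields are joined with `|`, which normalization guarantees cannot
occur inside a field, so distinct field tuples always produce distinct
preimages; each preimage is additionally prefixed with its slot tag
(`T1|…` … `T6|…`) so two recipes that happen to serialize identically
(e.g. a one-letter first name making recipes 1 and 4 coincide) still hash
to independent values. A missing constituent makes the whole slot missing
— there is no sentinel inside preimages.

The one-way hash is HMAC-SHA-256 with the shared master salt as the HMAC
key: 32-byte output, deterministic across sites, and not dictionary-
attackable without the salt. The site/transit/cc layers each apply a
deterministic, invertible, equality-preserving keyed permutation of the
digest: a 4-round balanced Feistel network over the 32-byte block with
HMAC-SHA-256 round functions (the Luby–Rackoff construction), built
entirely from the standard library. Determinism is essential — the
coordinating center must compare ciphertexts for equality — and
invertibility lets the cc transform peel the transit and site layers
before applying the common layer. The cipher is a documented, substitutable
primitive: any deterministic keyed permutation of 32-byte blocks (e.g. two
AES-ECB block applications) satisfies the same contract. Token byte length
(32) is a package convention, not an interoperability claim; compatibility
with any commercial tokenization vendor is explicitly a non-goal.

In this desk-scale model the coordinating-center key ring holds the site
and transit keys needed for the `transform --direction from` step;
production deployments split key custody between the vendor and the
parties, which is organizational machinery outside this package's scope.

## Matching

Records match when strictly more than half of the *mutually available*
token slots agree (`m > |A|/2` with `|A| >= min_available`, default 1).
"Available" means present in both records: a slot missing on either side
cannot vote. The strict majority makes ties (2 of 4) non-matches — the
conservative choice. Matched pairs are clustered by transitive closure
with union-find; each connected component becomes one `MATCH_ID`. Labels
are assigned by sorting components on their lexicographically smallest
member reference ID, so output is deterministic and independent of input
file order.

Candidate generation blocks on exact token values (records sharing any
single token value): output-equivalent to all-pairs comparison because a
majority match requires at least one shared token, and verified against a
brute-force all-pairs oracle in the tests. Tokens vote with equal weight;
probabilistic (Fellegi–Sunter) scoring and per-token weights are
deliberately out of scope.

## Overlap statistics

All statistics are functions of the token-free index alone. Site
multiplicity counts distinct DMIDs per `MATCH_ID` (a patient duplicated
within one site is still a one-site patient). The within-site duplicate
rate for a site is the share of that site's *records* that belong to a
cluster with ≥ 2 records from that site. Pairwise overlap counts unique
patients with ≥ 1 record at each of the two sites and reports two
percentages per pair — the count over each site's own total — with
min/max/mean/median taken over all ordered percentages (the ordered
convention is configurable in principle; the summary spans 2·C(k,2)
values). Report percentages are rounded to one decimal; raw counts are
always emitted for exact downstream use.

## Deduplication and adjudication

Demographic extracts carry age *group*, sex, and race only — sites compute
age groups locally, so dates of birth never reach the analysis side. Per
cluster and per dimension, adjudication first drops uninformative values
(missing / `Other/Missing`); zero informative values survive as
`Other/Missing`; exactly one distinct informative value wins; two or more
distinct informative values become `Discordant` for sex and race. Age
resolves conflicts to the oldest category instead: age-group disagreement
across encounter periods is expected drift rather than an identity
conflict, and the output table has no discordant age bucket. This
missing-aware order (drop, then test discordance) is what lets a cluster
of {Female, Other/Missing} consolidate to Female — the behaviour the
published margins imply — and it is permutation-invariant.

The characteristics table reports each category's N and % twice: over all
records ("aggregated") and over one adjudicated record per cluster
("de-duplicated"). Headline percent reductions are reported to two
decimals (rounded); a truncating mode (17.676… → 17.6) is provided because
printed tables sometimes truncate. Records present in the demographics but
absent from the index are listed in a reconciliation field and, in strict
mode, excluded from the de-duplicated column; by default they count as
singleton clusters.

## Synthetic populations

`SimConfig` fixes the study conditions: per-site record counts, pairwise
overlap fractions (of the smaller site's count), a within-site duplicate
rate, per-site SSN availability (default 0.66, the middle of the wide
range observed across real sites, which spans roughly 0–99%), name-typo
and date-error rates, a demographic discordance rate, and a mandatory
seed. Shared persons get identical base PII at their sites *before*
corruption; corruption is applied independently per appearance and logged
(typos classified as soundex-preserving or soundex-breaking) so evaluation
can attribute failures. Names come from a bundled list of common US given
names and surnames; SSNs are unique per person by construction, and the
(first, last, gender, DOB) tuple is rejection-sampled to be unique per
person, so with zero corruption distinct persons share no token and the
planted partition is recovered *exactly* — precision = recall = 1.0 is an
exact property of clean data, not a statistical one. Each site (and each
overlapping pair) draws from its own seed substream keyed on the DMID, so
adding a site does not perturb existing sites' extracts.

The generator emulates what matters to token linkage — field availability,
typo structure, cross-site demographic discordance — and nothing else: no
encounter histories, geography, families, or longitudinal change. Passing
tests therefore demonstrate correctness of the machinery and its behaviour
under controlled error rates, not expected match rates on real
populations, where typo processes, nicknames, and shared addresses are
richer.

## Pipeline separation and the privacy boundary

The CLI mirrors the two-team organizational split: token-side subcommands
(`keygen`, `tokenize`, `transform`, `match`, `strip`) may read PII or
token bytes; analysis-side subcommands (`overlap`, `table`, `evaluate`)
refuse any index file containing token columns (exit code 4). The
boundary is enforced by input-format refusal rather than process
isolation — the artifact models an organizational control at desk scale.
Logs record row counts at every boundary, never token or PII values.

## Problem sizes and numerical conventions

The default test and reproduction runs use populations of 10,000–14,400
records across four sites and 100 randomized matcher-vs-oracle instances
of up to 200 records; these sizes make every property checkable in
seconds while leaving the algorithms identical at any scale (matching is
near-linear via blocking). Percentages are reported to one decimal, the
headline reduction to two; Python banker's rounding applies, and the
truncating formatter uses `floor` at the requested precision. Degenerate
inputs are defined rather than erroring where a convention exists: empty
extracts produce headered empty outputs, a single-site index yields an
empty pairwise section with a warning, and precision/recall over zero
pairs is reported as 1.0.

## Known limitations

- Exact-hash tokens tolerate only the variation that normalization and
  soundex absorb; address-based tokens, nickname dictionaries, and
  transliteration are out of scope.
- The majority rule with equal weights is the only matching strategy;
  `min_available` is the single exposed knob.
- Non-transitive match graphs are merged by transitive closure, which can
  chain distinct persons through a bridge record under heavy corruption;
  the master-patient-index semantics require a partition.
- Keys live in a YAML file; escrow, rotation, and HSMs are out of scope.
- The stage cipher is an equality-preserving deterministic scheme by
  design; like any such scheme it reveals equality patterns to the key
  holder — that is the functionality, not a flaw, but it means the cc
  index must itself be governed as sensitive.
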