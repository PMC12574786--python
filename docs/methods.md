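# Methods

## Problem setting

Medicolegal death investigations by medical examiner / coroner (ME/C)
offices record causes of death as short free-text phrases, often listing
several substances ("acute intoxication by the combined effects of fentanyl
and cocaine"). Offices that release these records as open data do so in
incompatible dialects. This package harmonizes such releases, mines the
cause-of-death text for contributing drugs, and derives the descriptive and
geospatial quantities overdose surveillance typically needs.

## Drug extraction model

Extraction is lexicon-driven. A `DrugLexicon` holds entries of
`(canonical_name, synonyms, classes)`; all strings are casefolded on load,
every canonical name is implicitly its own synonym, and a synonym claimed by
two entries is a load-time error (the vocabulary must be an unambiguous
function from surface form to substance). The class taxonomy is
`{opioid, stimulant, benzodiazepine, anti-depressant, alcohol, other}`;
entries with no stated class are assigned `other`, so class flags partition
cleanly. An entry may carry several classes (mitragynine/kratom is both
stimulant and opioid, reflecting its dose-dependent pharmacology). The
shipped default vocabulary (~44 entries) covers commonly implicated
substances and is a starting point meant to be replaced or extended per
deployment; incompleteness of the vocabulary bounds sensitivity, as the
anti-depressant evaluation row illustrates.

Each cause-of-death field is normalized (casefold, whitespace split,
punctuation stripped from token edges only — hyphens, brackets and commas
inside tokens are part of chemical names and abbreviations like `4-fibf`)
and scanned independently of the record's other fields, preserving the field
index. Candidate n-grams up to the longest synonym's token count are
compared against the vocabulary:

* exact synonym hit → match with score 1.0;
* otherwise, a fuzzy comparison against synonyms with the same token count
  using Jaro-Winkler similarity, accepted when the score ≥ `threshold`.

Jaro uses the classical conventions: match window
`floor(max(|s1|,|s2|)/2) − 1`, transpositions = half the matched characters
out of order; the Winkler prefix bonus `jw = jaro + l·p·(1 − jaro)` is
applied unconditionally with `p = 0.1` and prefix length capped at
`max_l = 4`. Overlapping candidate spans are resolved greedily and
deterministically: longest span, then highest score, then lexicographic
canonical name, then leftmost start.

Matches collapse to binary indicator flags: one column per canonical drug
(1 iff ≥ 1 match anywhere in the record), one per class (OR over member
drugs). "Drug mentions" count every matched span once, so the same drug in
two fields is two mentions but one flag.

### Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `threshold` | 0.95 | minimum accepted fuzzy similarity, in (0,1]. Drug names are long and chemically similar names abound (fentanyl analogs), so the bar is high to limit false positives; a single non-prefix edit in an 8+ character name still scores ≥ 0.95. |
| `min_fuzzy_len` | 5 chars | tokens shorter than this match exactly only; fuzzy similarity on abbreviations ("pcp", "4-fbf") is uninformative. |
| `p`, `max_l` | 0.1, 4 | classical Winkler prefix weighting; `p ≤ 0.25` keeps jw ≤ 1. |

Raising `threshold` never enlarges the match set (monotone filtering,
property-tested).

## Harmonization

A per-source `SourceConfig` (pydantic-validated JSON) maps raw columns onto
a fixed 21-column standard schema (identity, demographics, five
cause-of-death text slots, a location block, pending status), to which the
flag block is appended after extraction. Choices where the design was open:

* **Dates** are parsed against an ordered per-source pattern list;
  day/month ambiguity is resolved by the source's declared convention, and
  unparseable dates keep the record with a null date (logged), since a
  record without a date still contributes to non-temporal summaries.
* **Pending** is three-valued (`true`/`false`/`unknown`) because only some
  jurisdictions expose it; absence of the field is not evidence the case is
  closed.
* **Geographic resolution** is the finest populated unit
  (`point > address > zip > city > county > none`), with `point` iff both
  coordinates are present (half-present coordinate pairs are nulled).
* **Hard validation** (missing case id, out-of-range coordinates) routes
  rows to a reject table with reasons; row count is conserved
  (`records + rejects = raw rows`), never silently dropped.
* **Updates**: open-data releases overwrite pending records once toxicology
  is finalized, so `merge_update` is last-write-wins wholesale replacement
  keyed on `(source_id, case_id)`, idempotent by construction.
* Demographic strings pass through with only a small spelling-variant map;
  no recoding to fixed ontologies.

## Geospatial analysis

Distances are great-circle (haversine) on a sphere of radius **3958.8
miles** (mean Earth radius; fixed so results are bit-for-bit reproducible).
Buffer membership is geodesic point-to-point distance against the radius
(default 1/3 mile) rather than planar projected buffer polygons; at this
scale the two differ negligibly and the geodesic rule is projection-free.
GeoJSON export discretizes buffer circles at 64 vertices using local
degree scaling.

Geocoding is an interface; the shipped backend is an offline exact-match
gazetteer with deterministic address normalization (casefold, strip
punctuation, collapse whitespace) applied identically at build and query
time. Region aggregation counts records by their own zip/county value, or
assigns point-resolution records by point-in-polygon (shapely) against
user-supplied region polygons; a record coarser than the requested level is
counted in an explicit unaggregable bucket, never upscaled, and counts
always conserve.

## Evaluation

Cohen's kappa `(po − pe)/(1 − pe)` measures agreement between the two
annotators per class (pe from marginal frequencies; perfect agreement
short-circuits to 1). System flags are scored against consensus labels by
2×2 confusion matrices; sensitivity `tp/(tp+fn)`, precision `tp/(tp+fp)`,
NPV `tn/(tn+fn)`, F1 the harmonic mean. Zero-denominator metrics are
reported as missing rather than coerced to 0 or 1, and the macro average
(unweighted mean across classes) excludes undefined components pairwise
with a warning — coercion would silently bias the averages. Display
rounding is half-up (2 decimals for metrics, 1 for percentages); full
precision is kept internally and rounding is display-only. Note that an
unweighted macro NPV over classes with one imperfect class can round to
1.00 while a pooled (micro) NPV computed from summed counts rounds lower;
this package reports the unweighted mean and documents the distinction.

## Summaries

"Overdose-related text match" is operationalized as ≥ 1 drug flag from
extraction. Jurisdictions differ in whether pre-existing structured
overdose fields should also count; that inclusion is a configuration
decision upstream of these functions, which deliberately use only the
text-derived flags. Monthly series use the calendar month of the death
date; records without dates are excluded with a logged count, and months
with zero opioid-flagged deaths carry an undefined share rather than 0.

## Synthetic data: what it emulates, and what it does not

The generator emits six dialects mirroring real portal facets: 5/3/3/1/1/1
cause-of-death fields; coordinate-, address-, and zip-level geography;
ethnicity present or absent; pending status present or absent; Socrata-,
ArcGIS-, and custom-platform-style column names; per-source date formats.
Defaults: 500 records per source, 30% overdose fraction, 10% pending
fraction, class mix weighted toward opioids (0.45) and stimulants (0.25),
death dates uniform over January 2012 - September 2024. One seeded
`random.Random` threads through all draws (no global state), so output is
byte-identical for a fixed seed.

Cause-of-death strings are composed from a fixed set of short templates
with 1-3 lexicon drugs; non-overdose causes come from a fixed list of
natural/trauma phrases free of lexicon collisions. Typos are single
substitutions or adjacent transpositions injected per matched phrase at
`typo_rate`, never in the first 4 characters and only into names of ≥ 8
characters — a generator convention that keeps the Winkler prefix
assumption exercised as designed, not a claim about real error processes.
The buffer-analysis fixtures plant pharmacies ~2 miles apart with event
points placed 0.05-0.25 miles from a pharmacy (inside) or ≥ 0.6 miles from
all of them (outside), so the inside count is known by construction.

Consequently, passing end-to-end tests shows the pipeline's mechanics are
correct (harmonization is lossless, matching recovers planted names at the
stated similarity, counts conserve); it does **not** show field performance
on real records, whose misspellings, negations ("no drugs detected"),
dictionary gaps, and reporting lags are outside the generator's model.
Real-data performance is what the annotation evaluation module measures.

## Numerical and degenerate-input choices

* Jaro of two empty strings is 1 (identical), and 0 when exactly one is
  empty or no characters match.
* Similarity comparisons use `score ≥ threshold` (closed bound).
* Classification with zero resources raises (membership is undefined);
  zero points returns an empty frame.
* Empty record sets yield zero counts and undefined (None) percentages,
  never NaN arithmetic.
* Tie-breaks in overlap resolution are total and documented above, so
  extraction output is order-independent and reproducible.

## Known limitations

* No negation or causality handling: a mentioned substance is flagged
  regardless of its causal role, and amounts are unknown (any-dose
  assumption; kratom's dose-dependent class is a worked example).
* The default vocabulary is intentionally small; production use requires a
  curated dictionary.
* The gazetteer geocoder is exact-match only — it demonstrates and tests
  the spatial pathway but does not replace a fuzzy street geocoder.
* Network fetching from live portals is out of scope; adapters read local
  files (a URL in the config is treated as a path by the offline runner).
* The wide-format column layouts of specific real deployments are not
  reproduced column-for-column; the schema here is fixed and documented,
  with the same content blocks (identity, demographics, cause texts,
  location, pending, indicator flags).
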