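# Methods

## Screening by study characteristics

The package operationalises abstract screening as a deterministic
three-stage pipeline.

**1. Characteristic detection.** Each reference's title and abstract are
tokenized (casefolded; hyphens and slashes split tokens; numerals,
including comma-grouped forms like "1,234", become single NUMBER tokens).
Six per-characteristic dictionaries are matched with standard gazetteer
semantics: longest match wins at each position, scanning left to right,
with no overlap within one characteristic (overlaps across
characteristics are allowed — only existence matters downstream). Two
shallow patterns supplement the dictionaries:

- *population*: a NUMBER token followed within `max_pattern_window`
  (default 5) tokens by a person-class term from a built-in closed list
  ("children", "women", "participants", …);
- *confounder*: a token stemming to "adjust"/"controll", then "for", then
  at least one word within the same window.

The detector's output is reduced to a binary hit/miss flag per
characteristic; matched spans are kept only for auditing. This
lexicon-plus-patterns design is this package's own stand-in for richer
grammar-based extraction systems: what the screening stage consumes is
only the hit/miss interface, so any extractor with that interface can be
swapped in.

**2. Threshold screening.** A rule (S, k), S ⊆ {P, E, C, O}, includes a
reference iff ≥ k characteristics in S were hit. Country and study type
are extracted but never screened on: they do not define relevance to a
review question. Rules are monotone by construction (adding a hit can
never exclude), which yields the nesting used throughout the tests:
included(All4) ⊆ included(Any3) ⊆ included(Any2), etc.

**3. Evaluation.** Against gold inclusion labels, TP/FP/FN/TN are counted
over the abstract-bearing universe; precision, recall, work saved
(1 − (TP+FP)/N) and maximum work saved (1 − I/N) are held as exact
rationals (`fractions.Fraction`) and rounded only for display — integer
percent for precision/recall, one decimal for work saved, matching the
granularity used in published reports of this method. Precision with zero
flagged records renders "n/a" rather than 0 or 1; recall is likewise
undefined when the gold set is empty. Multi-corpus pooling is micro
(cells summed before metrics), and a pooled row is emitted only for rules
to which every corpus contributed.

## Data preparation

RIS and MEDLINE tagged formats are parsed with all tags preserved, so
parse → serialise → parse is a fixed point on the field multiset. Records
are de-duplicated on (normalized title, year-if-both-present), with a
shared DOI also forcing a duplicate; first occurrence wins, order is
preserved. References without abstracts are then set aside — reported,
never silently dropped — because a title-and-abstract screener cannot
score them; evaluation universes contain abstract-bearing records only.
Stable `ref_id`s come from PMID/accession when present, else a
deterministic per-source sequence, so gold-label joins survive round
trips. Input bytes are decoded as UTF-8 with a Latin-1 fallback, since
real exports are mixed.

## The benchmark grid

`pecoscreen.benchmark` ships the per-(review, rule) confusion cells
reported by a published evaluation of this screening method on three
environmental-health systematic reviews (Hamra 2014, outdoor particulate
matter and lung cancer, n = 615, I = 17; Johnson 2014, PFOA and fetal
growth, n = 2470, I = 17; Thayer 2013, BPA and obesity, n = 1880,
I = 11). The package stores only the cells; every metric column is
recomputed. Rows of the source table whose printed cells are
typographically inconsistent (they do not sum to n) are excluded from the
data file — this drops the Johnson All4/PEO/PE rows — so pooled rows
exist only for Any3, Any2 and EO. Two further oddities are retained but
documented: the source prints the Hamra PEO recall as 60% while its own
cells give 11/17 = 65% (the cells are kept, the printed figure ignored);
and the Thayer All4 and PE rows imply TP + FN = 20 although that review
has I = 11 — they are internally consistent as printed, so they ship, and
the per-corpus "Max" line uses the smallest TP + FN in the block as the
defensible gold count.

## The synthetic-corpus generator

The generator emulates exactly the structure the method is sensitive to,
and nothing else:

- a reference is truly included with probability `prevalence`
  (default 0.01; the benchmark reviews ranged 0.006–0.027);
- conditionally on inclusion status, each characteristic is mentioned
  independently with probability `p_mention_included[c]` /
  `p_mention_excluded[c]`. Defaults for included articles put exposure
  and outcome near-certain (0.97 each), population at 0.70 and
  confounders lowest (0.45) — abstracts routinely omit adjustment
  variables, which is the stated rationale for the PEO rule. Excluded
  articles mention each element far less often (0.08–0.30). These values
  were chosen once to put the six rules' operating points in the range
  observed on the benchmark reviews;
- a planted mention uses an out-of-dictionary synonym with probability
  `vocab_miss_rate` (default 0.02, the order of the single dictionary
  miss among 45 included studies in the benchmark). Mentions ride in
  neutral carrier sentences inserted among shuffled filler sentences; a
  planted phrase is repeated in the title with probability 0.3 to
  exercise title matching (placed before the record number so a
  person-term can never follow a numeral spuriously);
- filler and carrier text contain no numerals, no person-class terms, no
  adjustment language and no phrase-bank vocabulary, so with
  `vocab_miss_rate = 0` and lexicons ⊇ the in-lexicon phrase bank,
  extractor hits equal planted mentions *exactly* — the pipeline is
  noise-free by construction and any deviation is a bug.

Because mentions are independent, the probability that a rule (S, k)
passes is an exact Poisson-binomial tail over |S| ≤ 4 Bernoulli variables
with effective rates q_c = p_mention[c] · (1 − vocab_miss_rate),
evaluated by enumeration (`expected_operating_point`). Monte-Carlo runs
of the full pipeline agree with this closed form within three standard
errors at 5,000 references, which is the package's end-to-end validation.

What the generator does **not** emulate — and hence what passing tests do
not show about real corpora: correlation between characteristic mentions
(real abstracts that name an exposure usually name an outcome too),
linguistic variety (synonymy is reduced to a single in/out-of-dictionary
coin flip), rhetorical structure, and the long-tailed topic mix of real
search results. Operating points on real reviews depend on dictionary
quality in a way no synthetic corpus can certify.

## Numerical and design choices

- All randomness flows through one `numpy` Generator seeded explicitly;
  identical parameters give byte-identical corpora.
- Span offsets are 0-based half-open character offsets into the original
  field text, so every span slices back to its surface form verbatim.
- Stemming (off by default) is a deliberately crude suffix stripper
  (-ies/-ied → y, -ing, -ed, -s) applied to both text and dictionary
  tokens; it conflates close inflections without a full Porter pipeline,
  keeping dictionary behaviour auditable.
- Comma-grouped numerals normalize to a single NUMBER class, so a
  dictionary phrase containing a numeral matches any numeral in that
  position; dictionaries shipped here exploit this only for "pm2.5"-style
  terms.
- Duplicate handling keeps the first occurrence to preserve source order;
  the de-duplication criteria of specific reference managers are not
  reproduced, so removed-duplicate counts on real exports will differ
  from any particular tool's.
- Output files are written atomically (write-then-rename); a failed run
  never leaves a truncated TSV.

## Problem sizes

Tests and the acceptance script use 400–5,000 synthetic references: large
enough for three-standard-error Monte-Carlo bounds to be discriminating
(at 5,000 references and 1% prevalence, ~50 included), small enough that
the whole suite runs in well under a minute on one CPU. The benchmark
grid computations are exact rational arithmetic on printed integers and
run in milliseconds.

## Limitations

- The shipped dictionaries are small demonstrations assembled for the
  three benchmark topics, not validated instruments; real use requires
  review-specific exposure/outcome dictionaries, which is also the
  method's main labour cost.
- Hit/miss is existential: a single incidental phrase ("lung cancer" in a
  related-work sentence) counts as a hit, which is one source of the
  method's false positives.
- No abstract zoning, no negation handling, no MeSH/ontology expansion,
  no probabilistic scoring or ranking — the method is a hard filter, and
  its type-I errors (wrongly excluded included studies) are unrecoverable
  downstream, which is why rule choice should be driven by recall first.
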