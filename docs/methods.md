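# Methods

## Scope and model of the text

The extractor treats an abstract as a bag of sentences in two zones (title,
abstract) and assumes the facts it targets are expressed in one of a small
number of surface patterns: a kinetic expression connected to its value and
context entities through short connective words; enumerations of
same-category entities; or a fact spread over the sentence/abstract/title
levels with exactly one plausible filler per level.  No syntax, no
statistics, no learned weights: every decision is a dictionary lookup or an
explicit rule, which makes each output slot auditable (every filled slot
stores its linkage type and source span) and the whole pipeline exactly
reproducible.

## Preprocessing

Sentences split only at a dot followed by whitespace.  Exceptions: the
dot-terminated token (or its two-word extension, for forms like "et al.")
appears in the abbreviation list, or the dot sits between two digits.  No
other terminators are used — question or exclamation marks are rare in
abstracts.  Tokenization splits at whitespace runs, then (a) strips the
sentence-final period from the last token and (b) detaches a trailing comma
or semicolon into a punctuation token.  The comma detachment is the one
deliberate deviation from pure whitespace splitting: the linkage stop rule
and the negation window are defined on commas, so commas must be visible as
tokens.  Dictionary entries are tokenized with the same function, so entries
containing commas ("k(m), app") still match.  Tokens carry 0-based half-open
character spans in their zone; `zone_text[start:end] == surface` is enforced
by property tests.

## Dictionaries and tagging

Each category is a plain-text term list (`term[TAB]canonical`, `#` comments);
when the canonical column is absent the normalized surface serves as
canonical.  All entries are lowercased (documents are matched case-folded
too), accepting the ambiguity that folding introduces.  Terms landing in
more than one category are resolved by a deterministic policy: an ordered
category priority (kinetic expressions first, then EC number, enzyme name,
ligand, organism, localisation) plus an exclusion list of forms dropped
outright.  The default exclusions are the classic acronym traps `ipp`,
`ka`, `ki`, `km` (an enzyme/ligand homonym, two parameter symbols doubling
as compound acronyms, and a parameter symbol used as a rat-strain name).

Entries are indexed in a token-keyed trie whose terminal nodes carry
category flags and canonicals.  Tagging is a greedy left-to-right scan: at
each position the longest flagged prefix wins (falling back to the last
flagged node seen when the walk continues into a longer, uncompleted
phrase), the scan resumes after the match, and punctuation tokens never
start a match.  A brute-force leftmost-longest matcher serves as an
independent oracle in the tests; greedy trie scanning is checked to be
exactly equivalent on 1,000 random dictionary/sequence pairs.

## Numbers, units, pH and temperature

Number recognition runs only in sentences containing a kinetic-group
mention (the 14 parameter categories plus the pH and temperature
expressions).  The grammar accepts plain decimals, `5e-4`, `1.5 x 10(-3)`,
`10^-3`/`10(-3)`, `a +/- b`, and single-token ranges `2-5`.  Ranges keep
the low value plus `range_high` rather than a midpoint — lossless and
auditable.  A unit immediately following (longest match over the unit
tables) is fused with the number; the concentration unit list is shared by
K_M, K_i, K_d, IC_50, S_0.5 and K_a.  A number whose unit vouches for no
kinetic category present in the sentence is discarded.  Temperature units
are exempt from that discard: "37 degrees C" identifies its number as a
temperature by itself, whether or not a temperature expression occurs in
the sentence.  Unit lists are loaded outside the one-term-one-category rule
because one unit legitimately serves several categories (the same rate unit
backs V_max and specific activity).

Bare numbers are eligible only for pH, temperature, pI and the Hill
coefficient.  A bare number directly after a pH (temperature) expression
becomes a pH (temperature) value when it passes a plausibility bound —
pH in [0, 14], temperature in [−80, 150] °C, both configurable; pI and n_H
values link only inside the anchor's sentence, like pH and temperature.

Ligand mentions that follow a negation phrase are removed up to the next
comma or the sentence end; the comma boundary mirrors the comma's
clause-delimiting role in the linkage rules.  Only ligands are affected.

## Linkage

Direct linkage starts at the kinetic anchor and scans rightward.  From the
current position the scan may (i) cross a binding-phrase mention, (ii) cross
a comma followed by a continuation keyword (`which`, `that`; configurable),
(iii) link an item — an entity mention, a compatible united number, or the
pH/temperature expression together with its adjacent tagged number.  Each
linked item becomes the new chaining point; an item whose slot is already
filled is stepped over ("first fill wins").  Anything else stops the scan:
a plain token, a bare comma, a negation phrase, or another kinetic anchor
(whose context belongs to that anchor, not this one).  The left scan is the
token-for-token mirror.  "Direct neighbourhood" is therefore zero
intervening non-linkable tokens — adjacency is strict, mediated only by
binding phrases.

Enumerations are maximal same-category runs separated by comma tokens with
`and`/`or` before the last member; kinetic categories never enumerate.  The
equally-largest groups in a sentence pair element-wise in textual order,
producing one record per index with those slots tagged `listing`; slots
filled from single mentions broadcast unchanged; smaller groups are left to
indirect linkage (which then sees multiple candidates and abstains at that
level).  Value listings are not expanded — only entity categories itemize.

Indirect linkage fills an empty entity slot with the unique candidate of
its category at sentence, then abstract, then title level.  Uniqueness
counts *distinct canonical forms*: the same organism mentioned twice is
still one candidate, while two different organisms block the level (the
slot then stays empty unless a deeper level is unique).  The numeric value
may also fill indirectly, but only at sentence level, from the unique
number compatible with the anchor's unit classes; pH and temperature
likewise fill only at sentence level from their tagged numbers — outside
the sentence an unmarked number cannot be told apart from unrelated ones.

Enzyme↔EC completion uses a local two-column TSV (a stand-in for a live
database query); a name (or EC) mapping to exactly one counterpart fills
the missing slot with linkage `completed_lookup`, and ambiguous mappings
(the fixture ships amylase with two ECs) never fill.

## Synthetic corpus generator

The generator emits the study conditions the rules are designed for, with
known gold records including the linkage type a correct extractor should
report.  Default pattern mix per document: direct chain 0.35, enumeration
0.20, indirect-only 0.20, negation 0.15, distractor 0.10, ambiguous
acronym 0.0 (injected explicitly in the degradation experiments); within
value clauses: scientific notation 0.15, `±` errors 0.15, ranges 0.10;
pH/temperature clause 0.6; localisation sentence 0.4.  Values are sampled
log-uniformly over 10^−2.5 to 10^2 in the printed unit.  All draws come
from one seeded RNG, so a profile plus seed reproduces the corpus
byte-for-byte.

The ambiguous-acronym pattern reproduces the dominant false-positive
mechanism of dictionary-based tagging: a dictionary homonym ("TPA", the
phorbol-ester ligand) used in the text with its other (protein) meaning.
The extractor tags it, finds it to be the unique sentence-level ligand
candidate, and links it — a false positive that the uniqueness rule cannot
prevent, which is exactly the behaviour the degradation experiments
quantify.

What the generator does **not** emulate: real abstracts' syntactic variety
(relative clauses, passives with long-range dependencies), misspellings,
unit conversion, multi-anchor sentences with shared value lists, tables,
and production-scale dictionaries (hundreds of thousands of ligands and
organisms rather than dozens).  A perfect score on the synthetic corpus
therefore demonstrates that the rules are implemented exactly as specified
— not that real-corpus precision/recall would be perfect; on real text the
dictionaries and the pattern coverage, not the rule engine, dominate
performance.

## Evaluation

Records align by (pmid, kinetic category) in document order; scoring is
slot-level because the categories are evaluated separately.  A filled slot
matching gold (numeric slots at relative tolerance 1e-9; value slots also
compare error, range-high and unit) counts TP for its category; a wrong or
spurious filling counts FP (plus FN when gold was filled); a missed filling
counts FN.  Precision with zero predictions is reported as 1.0 with an
explicit `vacuous` flag rather than NaN.  Slot decisions also feed a
six-way error classification (none-in-abstract, correct, wrong with the
right one available, wrong with none available, incomplete-but-not-
incorrect — the prediction is a substring of gold — and missing), and
precision/recall are additionally broken down per linkage type.

## Problem sizes and numerical choices

The bundled corpora are intentionally small and fast: the acceptance run
uses 500 documents per condition (~0.3 s end to end), the oracle
equivalence check 1,000 random cases, and the degradation property 20 seeds
× 20 documents; these sizes give stable, reproducible figures for a
rule-based (noise-free given the seed) pipeline.  Floats are serialized via
`repr` and JSON, making every writer byte-deterministic; all iteration
orders are explicit (insertion or sorted), and no unordered set ever
reaches an output path.

## Known limitations

* Indirectly mentioned values ("50 times higher than the K_M") are out of
  reach of the number grammar by design.
* The binding-phrase list ships as a ~17-phrase seed; determiners are not
  binding phrases, so "of the enzyme" breaks a direct chain that "of
  hexokinase" would complete.  The list is user-extendable via the
  manifest.
* Enumerations assume well-formed comma/conjunction lists; "A and B, C"
  degrades to the longest valid prefix.
* The enzyme↔EC completion is only as good as the local mapping table.
* Sentence splitting trusts the abbreviation list; an unlisted dotted
  abbreviation splits a sentence early (harmless for tagging, but it can
  shrink an indirect-linkage sentence window).
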