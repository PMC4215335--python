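# Methods

## Model and assumptions

The method treats literature-derived biomarker discovery as a two-corpus
contrast. For a disease–biofluid pair, the positive set S1 contains every
abstract retrieved by `<disease> AND <biofluid>` and the negative set S2
every abstract retrieved by `<biofluid> NOT <disease>`. The working
assumptions are:

1. any marker mentioned in an S1 abstract is putatively related to both the
   disease and the biofluid (no relation extraction is attempted — mere
   co-occurrence within an abstract counts);
2. S2 estimates each marker's background mention frequency in that biofluid's
   literature, so markers discussed broadly (housekeeping proteins, assay
   reagents, markers of *other* diseases) are suppressed;
3. mentions are exchangeable across abstracts, so under the null a marker's
   dft total documents spread uniformly over S1 ∪ S2, giving the expectation
   ex = dft·|S1|/(|S1|+|S2|).

Counting is at the **document** level: a marker mentioned k ≥ 1 times in one
abstract contributes exactly 1 to that set's document frequency. The
normalized difference f = (df1 − ex)/dft is bounded in [−1, 1]; it is
standardized over Sp (the markers with df1 ≥ 1) into z-scores, and a marker
is significant when z strictly exceeds τ.

Because z is standardized per pair, scores are comparable *within* a
disease–biofluid pair, not across pairs; each pair is scored independently
(the per-pair summaries are what get compared across biofluids).

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| τ (threshold) | 1.0 | significance cut-off on z, strict `>`; a deliberately non-stringent value that maximizes recall of both known and new markers. `threshold_sweep` reports survivor counts over a τ grid so users can pick their own operating point. |
| SD divisor | n−1 | sample standard deviation; the spreadsheet-default convention for small marker sets. |
| entity classes kept | PROTEIN, DNA, RNA | gene-like mentions only; cell lines and cell types are parsed but filtered out by default. |
| title scanning | on | dictionary matching scans title + body; a flag restricts to the body. |
| cleaning rules | strip ASCII punctuation, keep intra-token hyphens | hyphenated marker names (`HER-2`) must survive; which punctuation to strip is configurable because no single rule fits all exports. |

## Dictionary matching and normalization

The bundled tagger is a gazetteer: every alias from the nomenclature
dictionary (plus each entry's own symbol) is matched case-insensitively at
token boundaries, where a token character is a letter, digit or hyphen — so
`CAT` cannot fire inside `catalytic` and `BRCA` cannot fire inside `BRCA1`.
Overlapping candidates resolve longest-match-first, then leftmost, giving
deterministic, non-overlapping, sorted spans. Output from an external CRF
tagger can be substituted via the tagged-SGML reader; that tagger's errors
are then inherited as-is.

Normalization maps each surface to its consensus gene symbol. An alias
carried by several entries (e.g. `CEA` on both CEACAM5 and CEACAM8) fans out
to **every** symbol: the resulting double counting is retained deliberately,
because the mention alone cannot disambiguate the family member, and
suppressing it would silently under-count whole families. Negation is not
handled; a marker mentioned as *absent* still counts.

## Synthetic corpus generator

The generator emulates exactly the statistical structure the score assumes:
marker M is mentioned in an S1 abstract with probability p1 and in an S2
abstract with probability p2, independently across abstracts and markers.
A mentioned marker is injected 1–3 times (uniform), which exercises the
count-once-per-abstract rule; injection sites are uniform over token
positions; filler tokens are drawn from a vocabulary that includes decoy
near-miss substrings of marker aliases to exercise token-boundary matching.
A ground-truth manifest records realized df1/df2 and every injection span,
and a tagged-SGML rendering wraps the injected surfaces.

The generator does **not** emulate natural-language syntax, MeSH indexing,
abbreviation coinage, sentence structure, negation, or realistic abstract
length and topic distributions. Passing tests on synthetic corpora therefore
demonstrate that the bookkeeping, matching and arithmetic are correct under
the model's own assumptions — not that the assumptions hold for real
PubMed text, where tagger recall, alias ambiguity and topical correlation
between abstracts dominate real-world accuracy.

The standard recovery design is one enriched marker (p1 = 0.3, p2 = 0.001)
against ten background markers (p1 = p2 = 0.01) with n1 = 200 and n2 = 2000
— biofluid corpora are background-dominated, with negative sets one to two
orders of magnitude larger than positive ones. Note the contrast is only
informative when n2 ≫ n1: as n2 → n1 the expectation for an S1-only marker
approaches dft/2 regardless of enrichment, and background markers that by
chance appear only in S1 tie the enriched one. Test problem sizes (100
replicates for recovery; ≤ 50 abstracts for oracle comparisons; 40/400 for
CLI integration) are the package's choices for fast, deterministic suites.

## Numerical and formatting choices

- **Rounding**: printed percentages use round-half-up to 2 decimals (87.93
  style); quantities quoted in running text to one decimal use half-up at one
  decimal of the same underlying ratio (29.3 style). Plain banker's rounding
  would disagree on exact ties.
- **Ordering**: score tables sort by z descending with ties broken by symbol
  ascending, so ranked lists are reproducible.
- **Degenerate inputs**: an all-equal f vector (SD = 0) and an Sp with fewer
  than two markers both raise errors rather than emitting fabricated zeros;
  an empty Sp yields an empty table with a warning; an empty positive corpus
  is an error at pair-assembly time.
- **Undefined percentages** (0/0 cells — e.g. a pair with nothing
  significant, or no known markers found) are reported as blank, not 0.
- **Duplicate PMIDs** across S1/S2 are resolved in favor of S1 (positive
  membership wins) with the removal count logged; a duplicate PMID *within*
  one file is an error.
- **Determinism**: the analysis path contains no randomness; the generator is
  byte-identical under a fixed seed (Python `random.Random`, text output with
  `\n` newlines).

## True-positive-rate aggregation

Manual verification records (did the abstract genuinely mention marker,
disease *and* biofluid?) are aggregated two ways, because the averaging unit
materially changes the answer: `per_biofluid_mean` (default) averages the
per-biofluid error rates and reports 100 minus that mean, weighting every
biofluid equally regardless of how many checks it received;
`pooled` is the plain pass fraction over all records. The per-biofluid mean
is sensitive to biofluids with few checked records (one failure out of two
checks contributes a 50% error rate at full weight); both numbers are
reported so the choice is explicit.

## Known limitations

- Co-occurrence is not a relation: a marker and disease can share an abstract
  for many reasons, so significant markers are *candidates* for curation,
  with supporting PMIDs retained for manual follow-up.
- A single mention in a huge negative set can push a genuinely relevant but
  commonly studied marker below threshold; disease-specific markers are
  favored by construction.
- Curated known-marker lists are incomplete, so the known/new partition
  undercounts "known"; verification quality is bounded by the source
  databases.
- Dictionary coverage bounds recall: a marker absent from the nomenclature
  file can never be found, and alias collisions inflate counts for protein
  families.
- Only abstracts are analyzed; full text would yield more (and differently
  distributed) mentions.
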