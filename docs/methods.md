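# Methods

## Gene affiliation

Evidence enters as one row per predicted gene: the free-text
taxonomy/organism name of its best protein-similarity hit and the hit's
bit-score (or a blank lineage for unannotatable genes). Affiliation to a
coarse taxon group is case-insensitive substring matching against an
ordered keyword lexicon. Groups are evaluated in the fixed priority order
**archaeal virus → eukaryotic virus → phage → cellular**, so specific
tokens ("halovirus", "fusellovir…") are never shadowed by the generic
"virus"/"phage" fallbacks in the phage set; permuting keywords *within*
one group never changes an affiliation, permuting group priority can. The
built-in lexicon covers the named archaeal virus isolates and families in
common reference databases and is a starting point — real studies should
tailor it, which is why the plain-text `group: keyword` format exists.

When raw BLAST tabular hits are supplied instead of a pre-reduced
annotation table, one best hit per gene is kept: highest bit-score, ties
by lowest e-value, remaining ties by file order. Query ids are assumed to
encode the contig id with the gene index as the final `_`-separated token
(configurable separator).

## Category rules and their edge cases

The decision thresholds are exact where the usual prints are rounded: the
majority bar is the rational 2/3 (strict, so a 4-of-6 archaeal share does
*not* qualify), the minority band is [1/3, 2/3] inclusive on both ends,
and the quality floor (default bit-score 75) and the archaeal-vs-phage
bit comparison are strict. Category 2's condition is therefore
`b_P ≥ b_A`, making categories 1 and 2 mutually exclusive, and the rules
are evaluated in precedence 1 → 2 → 3. Profiles store the archaeal share
as a `fractions.Fraction`, so boundary cases compare exactly rather than
through floating point.

Two deliberate interpretation choices:

- The denominator of the archaeal share is the **annotated** gene count
  (excluding eukaryotic-virus hits), not the total gene count. A long
  contig with 2 annotated genes of 52, both archaeal-virus, must be able
  to reach category 1 through the few-annotation clause, which forces
  this reading. Whether cellular-affiliated genes belong in the
  denominator is genuinely open; the default includes them, and
  `Thresholds(exclude_cellular_from_fraction=True)` flips it.
- The 1–2-annotation clause defaults to also enforcing the bit-score
  floor (`require_min_bit_in_clause=True`), the conservative reading; a
  flag waives it.

An independent truth-table restatement of the four rule sets lives in the
test suite and is compared against the implementation over a grid of more
than 1,000 profiles, including every fraction boundary and bit tie.

## Dereplication

ANI between two contigs is computed from their best local pairwise
alignment (biopython's `PairwiseAligner`, match +2 / mismatch −3 / gap
open −5 / extend −2, `N` scored 0 against everything): identities divided
by all alignment columns, internal gap columns included; `N` never counts
as an identity. The aligned fraction is the alignment's span on the
shorter sequence over that sequence's length — a true local measure, so
unrelated sequences fail the 80% coverage bar rather than being forced
into a global alignment. Tests cross-check the estimator against an
independent edit-distance alignment oracle (edlib) and require agreement
within 2 percentage points on mutated pairs up to 5 kb.

Clustering is greedy and longest-first with fixed representatives
(cd-hit-like): sort by length descending (ties by contig id, for
reproducibility), join the first representative matched at ≥ 95% ANI and
≥ 80% coverage, else found a new population. The boundary merges (ANI
exactly 95% joins). Greedy representative clustering is not transitive
single-linkage: a chain A~B~C where C only resembles B stays two
populations. Output is always a partition and is independent of input
order.

## Ecology

Abundance: `(depth_sum / contig_length) / sample_read_bases × scale`,
i.e. mean per-base coverage normalized by sequencing effort. The default
`scale = 1e9` simply brings typical virome values near unity; it is
explicit configuration because no canonical constant exists. The
`log10(1 + x)` transform (zero coverage → exactly 0) is for display;
diversity and Bray–Curtis use the linear matrix.

Alpha diversity uses proportions over the nonzero entries: richness
S = #nonzero, `H′ = −Σ p_i ln p_i` (natural log by default, matching the
common vegan convention; the base is an argument), `J = H′/ln S` with J
undefined (None) for S ≤ 1. Bray–Curtis is delegated to scipy's `pdist`
with the 0/0 → 0 convention for empty sample pairs.

The Mantel test is implemented in-package rather than borrowed because
the permutation stream must be reproducible from an explicit seed:
r is the Pearson correlation of upper-triangle entries, and the
one-tailed p is `(1 + #{r_perm ≥ r_obs}) / (1 + n_perm)` over seeded
row/column permutations of one matrix, so p ∈ (0, 1] and the test is
exact-conservative. Tests compare the Monte-Carlo p against an exhaustive
all-permutations computation on 5-label matrices and calibrate the type-I
error on 500 independent null pairs (6 samples, 999 permutations each),
requiring a rejection rate near the nominal 0.05.

## Synthetic benchmark

The generator emulates a labeled collection of viral contigs with known
hosts at annotation level (no nucleotide sequences — the classifier never
looks at them). Defaults: 127 archaeal-virus and 12,372 phage contigs
with 2 confusers; genes per contig Poisson with mean 20 (minimum 1);
annotated fractions uniform in 0.10–0.50 (archaeal) and 0.10–0.60
(phage), reflecting how sparse usable annotations are on environmental
viral contigs; log-normal bit-scores whose medians straddle the quality
floor (on-class hits: median 140 for archaeal-virus genes on archaeal
contigs, 120 for phage genes on phage contigs; off-class contaminants:
medians 55–65).

The two classes are generated *separably by construction*: every true
archaeal contig satisfies one category rule (its top archaeal bit is
resampled from the truncated upper tail whenever a draw would miss the
floor or lose to a phage bit — with a 0.2-bit margin so rounding to one
decimal cannot break a strict inequality), and every background phage
contig fails all rules (archaeal contamination capped strictly below the
1/3 band; 1–2-annotation contigs never all-archaeal). True archaeal
contigs are styled toward category 1, 2 or 3 with probabilities
0.95/0.01/0.04, mimicking the heavy category-1 skew observed in curated
data. On this substrate, exactly the configured confusers are
misclassified, so accuracy degrades by exactly `confuser_count / N` —
the property the scoring tests assert.

The confusers replicate the two known failure archetypes: a 52-gene
contig with only two annotations, both archaeal-virus (category 1 via the
few-annotation clause), and a 5-gene contig with three annotations whose
top hit is archaeal-virus (category 3). Their bits are fixed template
values; everything else derives from the single integer seed, and one
seed reproduces a byte-identical table.

What passing synthetic benchmarks does **not** show: performance on real
viromes, where annotation sparsity correlates with contig length and
database composition, where lineage strings are messier than the
keyword pools here, and where archaeal/phage bit-score distributions
overlap in ways no clean parametric family captures. The generator is a
harness for the decision logic, not a claim about real-data error rates.

## Problem sizes and numerics

The test suite runs the full 12,499-contig benchmark (a few seconds), a
1,000+-case rule grid, 50 seeded clustering sets of ~1 kb contigs, 20
ANI-oracle pairs up to 5 kb, and the 500-pair Mantel calibration. ANI on
megabase inputs is O(n·m) per pair and would need a k-mer prescreen that
this package deliberately does not include. Degenerate inputs are defined,
not special-cased: empty annotation tables classify to four empty sets, an
all-zero abundance vector has richness 0 and undefined evenness, and
empty sequences are rejected before alignment.
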