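# Methods

## Problem setting and model

The package classifies bibliographic records (title + abstract) into K
predefined categories plus a reserve category ETC, in settings where no
labelled training corpus exists. Supervision is replaced by *reference
keyword sets*: one ranked keyword list per category, distilled from a
per-category exemplar text. Classification is nearest-category by a
similarity score, guarded by an abstention gate.

### Text preparation

Records are joined as `title + " " + abstract`; records with neither field
are excluded (and counted). Records with a title but no abstract are kept —
the exclusion rule in the underlying study is stated only as "missing
values", and the permissive reading maximizes coverage; the drop count makes
the choice auditable. Tokenization is lowercase splitting on non-alphanumeric
boundaries — the simplest reproducible choice — and the English stopword list
ships as package data so results cannot drift with an external library
version. The 4-digit publication year is taken from the source field;
year-less records are classified but excluded from trend aggregation.

### Keyword extraction

The extractor implements the YAKE family of within-text statistical
features; no external corpus and no training are involved. For each term:
casing (acronym/mid-sentence-capital frequency, log-damped by term
frequency), position (ln ln(3 + median sentence index)), frequency (TF
normalized by the mean + 1 SD of non-stopword TFs), relatedness to context
(1 + (left + right co-occurrence diversity) · TF/maxTF, window 1), and
dispersion (fraction of sentences containing the term); the combined score
is rel·pos / (case + freq/rel + disp/rel), lower = more relevant. Candidates
are contiguous n-grams (default up to 3) containing no stopword and no pure
number, scored as prod(term scores) / (count · (1 + sum(term scores))).
Near-duplicates are suppressed by a Levenshtein-ratio filter (threshold
0.9). Ties in score break lexicographically, making extraction fully
deterministic. Because the extraction literature also describes keyword
lists as "most common keywords", a plain frequency-rank extractor is
selectable by config (`extractor="frequency"`); the statistical scorer is
the default.

### Reference building

Per category: extract top `first_k` (default 1000) → remove every keyword
appearing in ≥ 2 categories from *all* lists (removal, not
keep-in-best-list: the design goal is that exactly one category contains any
given keyword) → truncate to `budget` (default 500) to avoid bias from
unequal list lengths. Human review of lists is not automatable; optional
allow/deny lists provide the same lever. Multi-word keywords stay phrases
and are matched downstream as contiguous token runs.

### Scoring

Similarity scorer: each category's keywords are concatenated into a
pseudo-text (each list entry contributes its phrase tokens once); the score
is the soft cosine between the record's and pseudo-text's bag-of-words
vectors. The term-similarity kernel S has unit diagonal and off-diagonal
entries max(0, cos(vᵢ, vⱼ))^2 from the embedding provider, with the clip
threshold (0.0) and exponent (2.0) as config knobs — these follow the widely
used soft-cosine implementation convention. S is built lazily over the union
vocabulary of the two texts being compared, which is exactly equivalent to a
global-vocabulary kernel and much cheaper. Out-of-vocabulary terms
contribute only through exact matches (their off-diagonal similarity is 0;
they are never zero-filled silently). Counting scorer: occurrences of each
category's keywords in the token sequence, overlapping start positions all
counted.

### Abstention gate

The gate must decide, from K scalar scores, whether the maximum "stands
out". The default rule is a two-sided one-sample t-test of the K−1
non-maximal scores against the maximal score (df = K−2), assign on
p < alpha (default 0.05), else ETC. **Caveat:** a t-test over a handful of
scalar scores is statistically unusual, and the procedure it formalizes is
under-specified in the source description; this rule is the most literal
computable reading, not an endorsed inferential procedure. A margin rule
(assign when (max − second)/max exceeds a threshold, default 0.2) is
provided for users who reject the t-test framing, and is also the rule to
use with K = 2. Degenerate-case conventions (package decisions, not
inherited facts): tie at the maximum → ETC with gate p 1; remaining scores
identical and below the maximum → assign with gate p 0; all-zero score
vector → ETC flagged degenerate. Lowering alpha can only move records
toward ETC (tested).

### Trends

Per-category yearly counts (ETC included; year-less records counted and
excluded) and an OLS line fit over the full observed range, evaluated at the
next `horizon` years and floored at 0, matching spreadsheet
FORECAST.LINEAR semantics. Non-linear forecasting is out of scope.

## Agreement battery

All statistics run on a K×K contingency table (rows = method/rater 1,
columns = reference). Cohen's kappa uses p_o = Σnᵢᵢ/n, p_e = Σrᵢcᵢ/n²; the
standard error is the **chance-null** (Fleiss) form
se0 = √(p_e + p_e² − Σpᵢ₊p₊ᵢ(pᵢ₊+p₊ᵢ)) / ((1−p_e)√n), i.e. the SE for
testing κ = 0 (the non-null SE is out of scope); z = κ/se0 with one-sided
normal p. Bowker's symmetry statistic sums (nᵢⱼ−nⱼᵢ)²/(nᵢⱼ+nⱼᵢ) over
unordered pairs with nᵢⱼ+nⱼᵢ > 0, df = number of such pairs. Stuart–Maxwell
uses the marginal-difference vector with one category dropped (the last;
the statistic is invariant to the choice when the covariance is nonsingular,
asserted in tests) and categories empty in both margins removed before
inversion; a zero difference vector returns chi2 = 0 even when the
covariance is singular (perfect agreement). Per-category McNemar collapses
to 2×2; the exact p doubles the smaller binomial(b+c, ½) tail, capped at 1.
Sensitivity/specificity treat the columns as truth. The library returns full
precision; rounding to printed table precision happens only in comparison
layers (tests, report formatting).

A 6×6 example table (similarity classifier vs the agreed labels of two
human raters, n = 79, five neurosurgical subspecialties + ETC) ships as
package data and pins every statistic to known published values in the test
suite.

## Synthetic data generator

The generator defines the package's study conditions. Each of 5 categories
(default) owns a 40-term vocabulary pool; a 120-term shared pool is common.
A document of 60 tokens draws each token i.i.d. from its own pool with
probability `mixing` (default 0.8) else from the shared pool. Exemplar texts
(600 tokens) draw 90% from the own pool with Zipf-like weights — so keyword
extraction sees realistic frequency skew — and 10% from the shared pool,
which the reference-building dedup then removes wherever it lands in two or
more exemplars. Embeddings are 16-dimensional: own-pool vectors are a unit
category centroid plus Gaussian noise of scale 0.1, shared-pool vectors sit
near the origin, so cross-category term similarity is small but nonzero and
the soft-cosine kernel is exercised nontrivially. Raters corrupt true labels
independently with symmetric uniform confusion (default error 0.1), whose
closed-form kappa ((1−e)² + e²/(L−1) against chance 1/L) serves as the test
oracle. One seed feeds three named substreams (documents, embeddings,
raters) so a change in one component's draw count never perturbs the others.

What the generator does **not** emulate: word order and syntax, burstiness
(within-document token correlation), vocabulary overlap between category
*concepts* (pools are disjoint by construction; only the shared pool blurs
them), class imbalance, and annotation biases beyond uniform confusion.
Passing end-to-end tests therefore demonstrates correctness of the pipeline
mechanics and sane behaviour under controlled separability — not
classification quality on real literature, where category vocabularies
overlap heavily and abstention is common.

## Problem sizes and numerical choices

Tests and the acceptance script use 5 categories × 100 documents (mixing
0.9) for end-to-end recovery, reference lists of first_k 200 / budget 100
with unigram keywords for synthetic corpora, and smaller corpora (12–40
docs/category) for monotonicity sweeps — sizes chosen to exercise every code
path with comfortable margins. The acceptance criteria met at these
conditions: ≥ 95% recovery on non-abstained records at mixing 0.9 (measured
100%), ETC fraction non-increasing and macro-accuracy non-decreasing in the
mixing sweep {0.5, 0.7, 0.9}. Soft-cosine identity-kernel reduction is
asserted to 1e-12; exact McNemar matches brute-force binomial enumeration
for all b+c ≤ 20; kappa/Bowker/Stuart–Maxwell are cross-checked against an
independent statistics library on random tables.

## Known limitations

* The t-test gate's statistical meaning is debatable (see above); treat
  gate p-values as a ranking heuristic, not calibrated error rates.
* The keyword extractor implements the published feature set but is not
  guaranteed term-for-term identical to any specific third-party
  implementation's output (tokenization and dedup details differ between
  implementations).
* Embedding quality bounds similarity-scorer quality; contextual
  (transformer) embeddings are deliberately out of scope — scoring operates
  on word sets, not sentences.
* Keyword matching is exact at the token level (no stemming/lemmatization),
  so morphological variants count as distinct terms unless the embedding
  kernel links them.
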