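# Methods

This note documents the statistical model, procedures, parameter defaults, and
numerical choices implemented in `vaxdiscourse`.

## Data model

A **corpus** is a set of comments, each with a unique id, a platform name
(canonicalized to lowercase; platform order is first appearance), free text, a
non-negative integer reaction count, and an optional integer category label. A
**codebook** assigns ids and names to the categories; the default codebook has
15 categories with id 0 the positive/neutral category and ids 1–14 the
anti-vaccine argument categories. Corpora round-trip through CSV and JSONL.

Sampling helpers select the top `N` comments per platform by reaction count
(stable sort: ties keep input order; platforms with fewer than `N` comments
are kept whole with a warning; default `N = 250`).

## Preprocessing

Text is normalized in a fixed order:

1. **Markup stripping:** URLs (`http(s)://…`, `www.…`), `#hashtags`,
   `@mentions`, and emoji (Unicode blocks U+1F000–U+1FAFF, U+2600–U+27BF,
   regional indicators, variation selectors, zero-width joiners, skin-tone
   modifiers) are removed with regular expressions.
2. **Translation:** a pluggable hook (registry-based); the default is the
   identity, for corpora already in English.
3. **Tokenization:** lowercase, keep alphabetic characters only, split on
   everything else.
4. **Stopword removal:** a packaged list of ~125 English function words.
5. **Lemmatization:** a pluggable hook; the default is a rule-based English
   plural-suffix lemmatizer (`-ies -> -y`, `-sses/-shes/-ches/-xes/-zes/-oes
   -> strip -es`, trailing `-s` stripped except `-ss/-us/-is` or words of
   length <= 3, plus a small exception list). Lemmas that land on a stopword
   are dropped.

The lemmatizer and translator registries allow substituting stronger NLP
components without changing the pipeline contract.

## Inter-coder reliability

Krippendorff's alpha (nominal metric) is computed from the coincidence matrix.
For each item with `m >= 2` coded values, every ordered pair of its values
adds weight `1/(m - 1)` to the matrix; items with fewer than two values are
skipped and counted in a diagnostic. With marginals `n_c` and total pairable
values `n`:

```
D_o = (sum of off-diagonal coincidences) / n
D_e = (sum over c != k of n_c * n_k) / (n * (n - 1))
alpha = 1 - D_o / D_e
```

`alpha = 1` is returned exactly when `D_o = 0`; a degenerate-data error is
raised when `D_e <= 0` (fewer than two categories among pairable values). The
test suite verifies this implementation against an independent brute-force
enumeration of all pairable value pairs to 1e-12 on exhaustive small grids and
hundreds of random grids with missing data, and against an analytic
expectation for a copy-model coder (coder 2 copies the true label with
probability `q`, otherwise draws uniformly from the other categories).

Percent agreement is provided as a cross-check for the two-coder,
complete-data case only.

## Keyword relevance

Documents are pooled by category label. With `phi_kw` the probability of term
`w` within category `k` and `p_w` its marginal corpus probability, the
relevance at weight `lambda` (default 0.5) is

```
r(w, k | lambda) = lambda * ln(phi_kw) + (1 - lambda) * ln(phi_kw / p_w)
```

Natural logarithms are used; since changing the log base rescales both terms
by the same constant, rankings are base-invariant (tested). Term–category
pairs with `phi_kw = 0` are excluded rather than scored at minus infinity.
Within a category, terms are ranked by descending relevance with ties broken
lexicographically; the default list length is 6 terms per category.

## Platform comparison

**Cosine similarity.** For each platform, the anti-vaccine category counts
(positive category excluded) are normalized to a frequency vector over the 14
anti categories. Similarity of two platforms is the cosine of their vectors;
for non-negative vectors this lies in [0, 1] (clamped only against
floating-point overshoot). A platform with no anti-vaccine comments is an
error naming the platform. Cosine is invariant to the normalization, which the
tests verify against raw counts.

**Homogeneity test.** Pearson's chi-square test of homogeneity on the
platform-by-category table, computed with
`scipy.stats.chi2_contingency(correction=False)` (no continuity correction),
`df = (rows - 1)(columns - 1)`. Before testing, categories with a zero count
on two or more platforms are removed (this is the condition under which an
expected cell of zero can arise in a pairwise comparison); removed categories
are carried in the result and disclosed in reports. A remaining zero expected
cell raises an error instructing pruning.

**Post-hoc tests.** Each of the `m = C(4, 2) = 6` platform pairs is tested
separately: pruning is applied locally to the pair's two columns, then the
pairwise chi-square is computed and Bonferroni-adjusted,
`p_adj = min(1, m * p_raw)`. Pairs that become untestable after pruning are
recorded, not raised.

## Synthetic corpus generator

The generator emulates the statistical shape of a cross-platform coded
comment corpus. Per platform (defaults in parentheses):

- **Labels:** i.i.d. draws from a per-platform 15-category probability
  vector. The *null* configuration uses the same marginal vector
  (0.271, 0.156, 0.116, 0.102, 0.085, 0.084, 0.043, 0.036, 0.027, 0.021,
  0.020, 0.013, 0.012, 0.009, 0.005) on all platforms. The *distinct* preset
  gives each platform its own anti-category profile with designed structure:
  facebook/twitter most similar, twitter/tiktok most dissimilar, category 9
  absent on facebook and twitter, category 13 absent on tiktok and instagram,
  and a mean positive share of exactly 0.271.
- **Lengths:** Poisson word counts with platform means facebook 30,
  instagram 32, twitter 22, tiktok 12 (words).
- **Reactions:** discretized log-normal with `sigma = 1.5` and `mu = ln(mean)
  - sigma^2 / 2`, so the configured platform means are preserved while the
  distribution is heavy-tailed.
- **Tokens:** each word is, with planting probability 0.3, drawn from the
  comment's category keyword pool (6 canonical keywords per category,
  preprocessing fixed points), otherwise from a 200-word synthetic filler
  vocabulary with Zipf-like weights proportional to `1/(i + 10)`. Filler
  words are constructed from consonant–vowel syllables and verified disjoint
  from both the stopword list and all keyword pools.
- **Annotations:** a double-coded subset (default 100 items, sampled across
  platforms). Coder 1 reports the true label; coder 2 copies it with
  probability `q` (default 0.95) and otherwise draws uniformly from the 14
  other codebook categories.

All draws derive from a single integer seed (< 2^31) via
`numpy.random.default_rng`; corpora and annotations are bitwise reproducible.

The generator does **not** emulate: real lexical or syntactic structure,
topic drift over time, dependence between comments (threads, replies),
platform-specific orthography, correlation between reactions and content, or
coder biases beyond the uniform-error copy model.

## Numerical choices

- Alpha, relevance, cosine, and chi-square computations use float64
  throughout; acceptance tests pin worked examples to 1e-12 where the value
  is algebraically exact and 1e-4 where a published-precision constant is the
  reference.
- Cosine is clamped to [0, 1] only to absorb floating-point overshoot; no
  other result is clamped.
- The anti-vaccine share is computed as an exact integer ratio before
  conversion to float.

## Limitations

- The suffix lemmatizer handles regular English plurals only; irregular forms
  outside its exception list pass through unchanged.
- The chi-square test assumes independent observations; comment corpora with
  heavy reply structure violate this.
- The pruning rule removes sparse categories rather than pooling them;
  pooled-category alternatives are out of scope.
- Calibration and recovery rates quoted by `scripts/acceptance.py` are
  Monte-Carlo estimates with the replicate counts reported alongside them;
  they are not analytic guarantees.
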