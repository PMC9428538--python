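# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a statistical methods appendix.

## Data model

A transcript is purely symbolic: a *unit* is an opaque label from a closed
vocabulary; a *phrase* is a non-empty ordered string of units carrying a
*theme token* (positive integer plus optional lowercase variant letter,
e.g. `7a`); a singer's record is his ordered phrase list plus location,
year and recording duration. Theme variants are distinct sequence symbols
throughout (`7a ≠ 7b`): variants mark real structural differences between
phrase types, and collapsing them would merge repertoire elements that
field classifications keep apart.

Singers whose recording is shorter than `min_minutes` (default 10) are
flagged out of comparative analyses but never deleted; a missing duration
never excludes — only an explicit sub-threshold value does, since
exclusion should be based on evidence the song is incomplete, not on
missing metadata.

The *song string* is the singer's theme order with consecutive
repetitions collapsed. Runs collapse only when tokens are equal, so
alternations like `7a 7b 7a` survive. No attempt is made to divide the
sequence into individual songs: the whole recorded sequence is the unit of
comparison, which means cycle counts legitimately influence song-level
LSI.

## Similarity indices

Levenshtein distance uses unit costs and exact token equality — no
weighting by acoustic confusability, because the transcript level carries
no acoustic information. LSI normalizes by the *longer* sequence's
length, which bounds it in [0, 1] and makes `LSI = 1` equivalent to exact
equality.

DSI uses the classical Dice form `2C/(A+B)`. A variant without the
factor 2 appears in some descriptions; the two are related by an affine
map of the dissimilarities (`1 − C/(A+B) = ½ + ½(1 − 2C/(A+B))`), and
UPGMA merge order, tree topology and the CCC are all invariant under
positive affine transforms, so every downstream quantity is identical
either way. This invariance is asserted by direct computation in the test
suite.

Set medians maximize summed LSI to the whole group (self included), and
ties are broken by earliest input position for determinism. The
tie-break tolerates float summation-order noise: any total within 1e-9 of
the maximum is treated as tied, which is far below the minimum nonzero
gap between genuinely different rational LSI sums at realistic group
sizes.

## Clustering and validation

UPGMA (unweighted average linkage) is implemented directly so that merge
ties are deterministic: among equally close pairs, the pair whose
(smallest-leaf-label) representatives sort lexicographically first merges
first. Ties are real in this domain — LSI values are ratios of small
integers — and library implementations leave the order unspecified. The
implementation is cross-checked in tests against a brute-force reference
(averages recomputed from the original matrix) and against SciPy's
average-linkage on tie-free matrices.

The CCC is the Pearson correlation between the strict lower triangles of
the input and cophenetic matrices. With exactly one pair (two items) the
correlation is undefined; phrase-level validation defines it as 1 there,
since a single distance is always reproduced exactly. Zero-variance
inputs (all distances equal) are an error, not a silent NaN.

Newick export halves merge heights so leaf-to-leaf path lengths equal
cophenetic distances (the usual ultrametric dendrogram convention), and
writes `AU/BP` support as internal node labels.

The published practice of validating theme labels by eyeballing the
dendrogram is operationalized as *majority-subtree purity*: for each
theme, among subtrees in which that theme is the plurality label, take
the one containing most of the theme's phrases (smallest such subtree on
ties); purity is the contained fraction. Purity 1 for every theme means
each theme's phrases occupy their own subtree.

## Multiscale bootstrap

`bootstrap_support` resamples *feature rows* with replacement,
`round(r·m)` rows at each scale `r` in 0.5–1.4 (step 0.1), rebuilding the
UPGMA tree per replicate from Euclidean distances between the resampled
column profiles, and counting exact leafset matches per reference split
(no partial credit). When handed a square dissimilarity matrix, the
matrix itself is the feature matrix — each row is one item's
dissimilarity profile — matching the behaviour of the established
clustering-with-p-values package when given a square matrix, while the
reference tree is always built from the primary dissimilarities directly.
The scale grid and in-replicate distance are package conventions, not
facts about any particular dataset.

The AU fit clips each bootstrap proportion to
`[1/(n_boot+1), 1 − 1/(n_boot+1)]` to avoid infinite normal quantiles,
transforms `z_r = Φ⁻¹(1 − bp_r)`, and fits `z_r = v√r + c/√r` by least
squares weighted with the delta-method variance
`φ(z_r)² / (bp_r(1−bp_r)/n_boot)`; `AU = 1 − Φ(v − c)`, and the reported
BP is the raw proportion at `r = 1`. Splits counted in every replicate
(or none) at every scale short-circuit to AU 1 (or 0) with a
degenerate-fit flag. A single scale cannot separate `v` from `c`, so AU
is refused — never silently replaced by BP. Fit quality is the
chi-square tail probability of the weighted residuals.

Significance conventions: AU > 0.95 (split stable), BP > 0.70 (branching
stable). Calibration on exchangeable noise (no real clusters) keeps the
fraction of splits with AU > 0.95 at or below roughly 10%, asserted in
tests over 20 replicate datasets at `n_boot = 100`.

## Synthetic culture generator

The generator's defaults encode a two-population, three-year survey with
three singers per population per year, mirroring the scale of the system
the package targets. Each population's *canon* (its song type's
per-theme unit strings) is shared by all singers — conformity is the
defining feature of these song cultures — and evolves by independent
per-unit edits (substitution / insertion / deletion, equally likely) at
`unit_edit_rate` per unit per year (default 0.05, "slow" on the scale of
a 3–7-unit phrase). A scheduled revolution replaces a population's canon
with the *current evolved state* of the arriving type, copied from the
population already singing it, which is what creates the 1–2-year lag
signature between populations. Hybrid singers (probability
`hybrid_probability`, default 0.1, revolution years only) insert one
contiguous block of old-type themes into the new-type order — matching
the observation that hybrids combine whole theme blocks rather than
interleaving units. Transcription noise misclassifies each emitted unit
independently (default 0.02).

What the generator does *not* emulate: acoustic variability below the
unit level, within-population repertoire heterogeneity (other than
hybrids), singer-specific stylistic bias, and transmission dynamics
driven by population size. Passing recovery tests therefore shows the
pipeline recovers the intended structure when transcripts are faithful,
not that real field transcripts are this clean.

`make_phrase_fixture` gives each theme a canonical string drawn from its
own disjoint slice of the alphabet (hence `alphabet_size ≥ n_themes`), so
theme recovery has an unambiguous ground truth; `within_noise` counts
random edits applied to each copy.

## Bundled survey table

`whalesong/data/south_pacific_2016_2018_synthetic.tsv` is a synthetic
reconstruction of a published two-population survey layout whose
per-singer table is not machine-readable from the description available
here. Everything the description fixes is honoured: 21 transcribed /19
included singers, the four song types and their location-year
memberships, two hybrid singers, 41 distinct theme tokens, exactly three
themes (1, 5, 7a) shared between French Polynesian type-1 song in all
three years and Ecuadorian type-1 song in 2018, and themes 3/4/8 confined
to French Polynesia. The per-singer cycle counts and small omissions are
invented; quantities that depend on them — notably the exact cophenetic
correlations (this table yields 0.987 LSI / 0.996 DSI versus the
originally reported 0.962 / 0.966) — are reproduced only approximately,
while all qualitative cluster-membership structure is reproduced exactly.

## Problem sizes and determinism

Tests run phrase-level clustering at up to ~100 phrases, bootstrap
support at `n_boot = 100` over 10 scales, and AU parameter recovery at
`n_boot = 10000` on synthetic counts, sizes chosen so the full suite
completes in well under a minute while still exercising every code path;
the pipeline itself has been run at the published `n_boot = 1000`
without difficulty (a few seconds for 19 singers). All randomness flows
through explicit seeds: the generator, the bootstrap and the pipeline are
byte-identical across reruns with the same configuration.

## Known limitations

* Song-level LSI conflates repertoire, order and recording length; the
  DSI view is the designed complement, not a redundancy.
* Majority-subtree purity is one operationalization of a visual check;
  other choices (e.g. F-measure over all subtrees) would differ in edge
  cases.
* AU p-values inherit the asymptotics of the multiscale-bootstrap theory;
  at `n_boot = 100` they are noisy, and the package reports but does not
  correct for multiple testing across splits.
* The generator's revolution is instantaneous population-wide adoption;
  partial-season adoption dynamics are not modelled.
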