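# Methods

## The problem

Free-text clinical notes in mental-health EHRs often contain verbatim
speech inside quotation marks — a filtered but direct trace of the patient
voice. Two questions follow: *whose* records contain quoted text (a cohort
association problem), and *what* the quotations say (a content problem,
tackled here for one-word quotations, the most common length). This
package implements both analyses end to end, plus the synthetic data
needed to test them, since real records of this kind cannot leave their
provider's firewall.

## Quotation extraction

Spans are found by rule-based matching over Unicode code points with
0-based half-open offsets:

* **Straight double quotes** are paired greedily left to right: the first
  `"` opens, the next closes. An unmatched trailing opener yields no span.
* **Curly quotes** are matched as explicit open/close pairs (`“`…`”`).
* **Single quotes** are off by default because apostrophes make them the
  lowest-precision delimiter. When enabled, the opener must not follow a
  word character and the closer must not precede one (the apostrophe
  guard), so `patient's` never opens a span but `'low'` matches.
* Matching runs independently within each blank-line-delimited paragraph.
  A span therefore never crosses a paragraph break, and one stray
  unbalanced delimiter can only corrupt pairing inside its own paragraph —
  the damage-control behaviour the adversarial tests rely on.
* Nesting is not modelled: a differently-delimited quote inside a span is
  kept verbatim in the cleaned text.

Cleaning removes *blank* quotes (empty or whitespace-only content) and
*html artefacts* (content that is entirely markup tags, character entities
or attribute fragments). Punctuation-only quotes are **retained** with
word count 0: they are real quotations, and the word-length histogram has
a 0 bin for them. Word count is the number of maximal letter/digit runs,
with internal apostrophes not splitting a token (`don't` is one word).
Quotation-length summaries use the population SD (divisor n).

Extraction quality is scored span-by-span against gold annotations with
exact-offset matching by default (each gold span can match at most one
prediction); a text-overlap mode exists for more lenient audits. An empty
denominator reports the metric as 0 with an explicit undefined flag.

## Text normalization

Only spans with exactly one word feed the content analysis; each instance
counts once (no per-patient or per-note deduplication). Tokens are
lower-cased and lemmatized with a dictionary-based, noun-default
lemmatizer built into the package: an irregular-form table (feet→foot,
children→child, …) followed by regular suffix-detachment rules
(ies→y, ches/shes/xes/zes/sses→ −es, trailing s→ −s), with guards for
words of length ≤ 3, lexical s-forms (yes, news, …) and ss/us/is endings
(glass, status, crisis). Tokens containing digits or non-apostrophe
punctuation are lower-cased only. The mapping is idempotent, which the
property tests enforce. The vocabulary keeps lemmas with frequency
≥ `min_count` (default 20), ordered by descending frequency with
alphabetical tie-break.

## Embeddings and clustering

The clustering stage accepts any word2vec-text vector file; for
self-contained runs the package trains CBOW embeddings with negative
sampling in numpy (predict the centre word from the mean of the context
input vectors; noise words from the unigram distribution to the 3/4 power;
linearly decaying learning rate; single-threaded and deterministic given a
seed). Defaults — dimension 100, window 5, min_count 5, epochs 5,
5 negatives — are ordinary word2vec settings, configuration rather than
claims. Out-of-vocabulary words are dropped with logged counts.

K-means uses Lloyd iterations from k-means++ starts, best of 10 restarts
by inertia, at most 300 iterations (scikit-learn's implementation; the
centroid-fixed-point and assignment-optimality invariants are asserted in
tests). The mean silhouette coefficient uses Euclidean distance; points in
singleton clusters contribute 0, as do points with a = b = 0; the score is
undefined at k = 1, so the scan table reports inertia only there and the
scan starts at k = 2 by default. The production silhouette (scikit-learn's
vectorised routine behind the package's API) is checked against a
brute-force O(n²) recomputation from the definition to 1e-9.

Cluster-count selection mirrors the human-in-the-loop procedure: rank the
scanned k values by mean silhouette (ties prefer the smaller k, for
parsimony), emit each candidate's per-cluster report of the 20 most
frequent member words (frequency-descending, alphabetical tie-break;
smaller clusters list all members), and ask a labeler for labels and
homogeneity verdicts. The first k awarded at least one homogeneous cluster
wins; a labeler that rejects everything produces an explicit
"no homogeneous solution" outcome with the full audit trail, not an
exception. `make_purity_labeler` supplies an automatic labeler for
synthetic data: a cluster is homogeneous when ≥ 80% of its listed words
share one planted topic.

## Cohort statistics

Variables are derived at the patient level: five-group ethnicity from the
fine-grained UK census categories; ICD-10 chapter groups from the code's
first letter (and digit for F codes), with absent codes an explicit
"Not recorded" analysis category rather than missingness; age, contact
and referral-year bands as printed in the published tables; IMD bands with
inclusive upper boundaries (a score of exactly 20 is in the most-deprived
band, 30 in the middle band). Unmappable or absent values become an
explicit "missing" category that is retained in tables and excluded from
tests.

* **Pearson χ²** uses no continuity correction and excludes missing rows
  before forming margins; a zero margin raises an error naming the
  category. (The uncorrected form is what reproduces the published
  statistics from the printed counts.)
* **Linear trend** for ordinal variables is the Cochran–Armitage statistic
  in Mantel–Haenszel form, (N−1)·r² with r the subject-level correlation
  between the integer row score and the binary outcome, computed in closed
  form from the grouped counts; it never exceeds the Pearson χ² of the
  same table. Scores are ascending integers in category order — the
  standard choice where no spacing is specified.
* **2×2 odds ratios** use Wald CIs with z = 1.96; zero cells raise unless
  the Haldane 0.5 correction is opted into.
* **Logistic regression** is maximum likelihood via IRLS (statsmodels GLM,
  binomial family, tolerance 1e-8, ≤ 100 iterations), with nominal
  predictors dummy-coded against fixed references (Female, White European,
  F2x, no inpatient care) and ordinal predictors entered as single
  integer-score terms (the published adjusted model prints one OR per
  ordinal variable, which implies score entry). Grouped
  (successes/failures per category) and subject-level data give identical
  fits. Complete-case analysis drops any subject missing a value on a
  modelled variable. Perfect separation is flagged (`converged=False`,
  detected by boundary-drifting coefficients or exploding standard
  errors), never silently reported as an estimate.

The printed ordinal trend values in the source cohort table are orders of
magnitude larger than any value (N−1)·r² can take at N ≈ 33 000; whatever
produced them, they are not reproducible from the printed proportions, so
the package asserts the standard trend statistic against its closed form
and against independent oracles instead.

## Synthetic data: what it emulates, and what it does not

The registry generator draws each derived categorical variable from
configurable prevalence vectors (defaults shaped like a large urban
secondary mental-healthcare census cohort) and then draws the quote flag
from a logistic model over the *true* categories — intercept −1.0,
inpatient +2.28, Black ethnicity +0.79, male +0.19, F2x diagnosis +1.2,
per-category slopes +0.45 for contacts and −0.5 for referral recency,
echoing the direction and rough magnitude of the associations seen in
routine records. Missingness is injected afterwards, independently per
variable (MCAR) at rates matching the real cohort's missing shares — the
simplest mechanism that exercises missing-excluded and complete-case
logic. Partial configs merge over these defaults per variable.

Notes are template filler text with quotes planted at recorded offsets:
quote lengths follow a geometric-like positively skewed distribution with
P(1 word) ≈ 0.27 (matching the headline skew of real quotation lengths
without claiming distributional fidelity), delimiters follow a
straight/curly mix, and adversarial hazards (possessive apostrophes,
html-tag quotes, blank quotes, stray unbalanced delimiters) are planted at
configurable per-note rates. The gold annotations list exactly the
well-formed, non-blank, non-html spans — what a correct extract-and-clean
pass should retain. Flagged patients receive at least one well-formed
quotation (when the quote-count distribution allows any); unflagged
patients receive none, keeping the registry flag consistent with the
extracted database.

The topic corpus plants co-occurrence structure: each sentence fills 8–12
slots from one topic's word list with a 10% cross-topic noise rate, which
is enough for CBOW embeddings to separate the planted groups cleanly.

None of this emulates real clinical language: negation, reported speech,
formatting noise beyond the four planted hazards, longitudinal structure
or informative missingness are all absent. Passing tests therefore
demonstrate that the *pipeline machinery* is correct under the stated
statistical structure, not that extraction precision or cluster quality
would match on real records.

## Problem sizes and numerical choices

The test suite and examples run at deliberately modest scale — registries
of 300–30 000 patients, 3 000-sentence topic corpora, 50-dimensional CBOW
vectors for 3 epochs — sizes at which every stochastic check (parameter
recovery within 3 SE, purity ≥ 0.9, extraction floors) holds with
comfortable margin under the fixed seeds. Determinism contracts are
byte-level for the generators and exact for the k scan. Centroid and
assignment invariants use 1e-6/1e-9 slack; the silhouette oracle
comparison uses 1e-9; grouped-vs-subject-level logistic equivalence uses
1e-6 on coefficients. Pipeline runs write a manifest (configuration
snapshot and hash, library versions, stage funnel counts, timings) so any
output file is traceable to the run that produced it.

## Known limitations

* The lemmatizer is rule-plus-table, not a full morphological dictionary;
  rare irregular plurals outside its table pass through unchanged.
* Speaker attribution, sentence segmentation and spell correction are out
  of scope by design.
* The adjusted model's published coefficients cannot be reproduced without
  patient-level data; only direction and machinery are testable here.
* Single-quote extraction remains heuristic even with the apostrophe
  guard; it stays off by default.
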