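# Methods

## Problem setting

`pepal` addresses multi-label classification of multifunctional
therapeutic peptides under a labeling budget.  Each peptide sequence may
carry any subset of eight functional annotations — anti-angiogenic
(AAP), anti-bacterial (ABP), anti-cancer (ACP), anti-inflammatory (AIP),
anti-viral (AVP), cell-penetrating (CPP), polystyrene-binding (PBP) and
quorum-sensing (QSP) — and obtaining a label means running a wet-lab
assay.  Pool-based active learning aims to spend that assay budget on
the peptides whose labels most improve the model.

## Model and query strategy

The core is a query-by-committee scheme whose committee diversity comes
from *feature views* rather than from perturbing one model.  Nine
encoders map a peptide to fixed-length vectors (dimensions in
parentheses): amino-acid composition AAC (20), dipeptide composition
DPC (400), composition–transition–distribution CTD (273), pseudo
amino-acid composition PseAAC (25), reduced-alphabet distance pairs DP
(602), distance-based residue pairs DR (1220), one-hot positional
encoding (4200), k-spaced conjoint triads KSCTriad (343), and the
PSSM×PSFM profile cross-transformation PPCT (2000).

On each view a multi-label model is trained by binary relevance: L = 8
independent regularized logistic regressions (the base learner is
pluggable behind a fit / predict-probability contract).  For a sample x
the committee of V views yields votes v_{ij} ∈ {0,1} (probability
thresholded at 0.5, ties positive).  Disagreement is the vote entropy
summed over labels,

    E(x) = − Σ_j Σ_{c∈{0,1}} (C_{j,c}/V) · ln(C_{j,c}/V),    0·ln 0 = 0,

where C_{j,c} counts members voting c on label j.  E is zero iff the
committee is unanimous on every label and each evenly split label
contributes ln 2.  Each iteration the λ pool samples with the largest E
are sent to the (simulated) oracle, their true labels revealed, and the
committee retrained.  Final predictions average the member
probabilities and threshold at 0.5; the averaged probabilities are also
the ranking scores for all threshold-free metrics.

The loop uses a 20 / 4 / 76 % split of the full dataset into test /
initially-labeled / unlabeled pool, λ = 30 per batch, and stops once
the acquired labels reach 65 % of the initial pool (the final batch is
truncated, not skipped).  Iteration 0 — the committee trained on the
initial labeled set alone — is evaluated and recorded so learning
curves start at the pre-query baseline.  Results are averaged over
independent re-splits (default 10); a 5-fold test-rotation splitter is
also provided.

Baseline strategies share the batch contract: uniform random sampling;
label-cardinality inconsistency (LCI), |predicted cardinality − mean
labeled cardinality|, largest first; and maximum-margin uncertainty
(MMU), the gap between the smallest positive-side and largest
negative-side decision values, smallest first.  LCI and MMU operate on
a single binary-relevance model over the concatenation of all views.
Their operational formulas are reconstructions of the standard forms in
the active-learning literature — the originating papers are cited in
secondary sources without formulas — and are labelled as such.

## Evaluation metrics

Five rank-based multi-label metrics, all invariant to strictly monotone
transforms of the scores:

* **Macro-AUC** — mean over labels of pairwise concordance between
  positive and negative samples; labels with a single class in the test
  fold are skipped.
* **Micro-AUC** — the same concordance over all (sample, label) pairs
  flattened.
* **APS** — per sample, average precision over its relevant labels,
  where a label's rank is the number of labels scored at least as high.
* **One Error** — fraction of samples whose top-scored label is
  irrelevant (argmax ties break to the lowest label index).
* **Ranking Loss** — per sample, the fraction of (relevant, irrelevant)
  label pairs with f(relevant) ≤ f(irrelevant); the tie case counts as
  a loss, as the defining inequality states.  Samples whose relevant or
  irrelevant set is empty are excluded from the denominator.

Tie handling in the two AUCs follows the standard Mann–Whitney
convention: a tied pair earns half credit.  The printed definitions can
be read as giving ties full credit, but that reading awards a constant
scorer an AUC of 1.0 — and early active-learning iterations routinely
produce constant scorers (see the degenerate-label fallback below), so
full credit would systematically reward strategies that delay learning
rare labels.  Half credit restores the property that an uninformative
scorer earns 0.5 and matches what standard toolkits compute.

Query strategies are compared by the area under the learning curve of a
metric versus the fraction of training data labeled: a trapezoidal
integral over the traversed x-range, deliberately not divided by the
range width.

## Numerical and degenerate-input choices

* **Single-class labels.**  With 4 % initial labels, rare functions
  (PBP holds ~2.4 % of samples) often have no positive example.  The
  per-label classifier then falls back to a constant probability equal
  to the observed prior clipped to [0.01, 0.99].
* **Vote and decision ties.**  Probability exactly 0.5 votes positive;
  an MMU decision value of exactly 0 counts as the positive side.
* **Top-λ ties.**  Exact score ties (ubiquitous in early iterations,
  when many pool samples have entropy 0) are broken by a seeded shuffle
  before a stable sort, so runs are reproducible and an all-unanimous
  committee degrades gracefully to seeded random selection.
* **Standardization.**  Per-view column standardization is fitted on
  the current labeled rows only and applied to all partitions,
  preventing leakage from the pool or test set; constant columns are
  centred but not scaled.
* **Entropy logarithm.**  Natural log.  The base only rescales scores
  and never changes the selection ranking; it is fixed so reported
  entropy values are reproducible.
* **Seeds.**  Each run derives independent split / model / tie-break
  streams from one seed via `numpy` seed sequences, so components can
  be varied without perturbing the others.

## Reconstructed descriptors

The DP and PPCT encoders and the LCI/MMU formulas are not operationally
specified in the secondary literature this package follows; the
implementations are dimension-consistent reconstructions:

* **DP** uses a fixed 14-letter reduced alphabet (D/E, F/Y, I/V, K/R,
  L/M, S/T merged) with single-letter frequencies plus ordered-pair
  frequencies at distances 1–3 (14 + 3·14² = 602).
* **PPCT** squashes PSSM scores to (0,1) with a logistic map and, for
  each lag g ∈ {1..5} and ordered residue pair (u,v), averages
  pssm[u,i]·psfm[v,i+g] over positions (5·20·20 = 2000).
* **CTD** uses thirteen published three-class attribute partitions
  (seven hydrophobicity scales, van der Waals volume, polarity,
  polarizability, charge, secondary structure, solvent accessibility),
  each contributing 3 composition + 3 transition + 15 distribution
  descriptors (13·21 = 273); distribution positions are fractions of
  sequence length.
* **PseAAC** is the classical type-1 form with λ = 5 correlation
  factors from standardized hydrophobicity, hydrophilicity and
  side-chain mass, weight w = 0.05 (20 + 5 = 25 components summing
  to 1).

## Synthetic data generator

Real multifunctional-peptide corpora require an external download, so
all tests and benchmarks run on a generator that emulates the target
corpus's statistical shape: ~4,386 peptides of length 6–200 over the 20
standard residues; label cardinalities 1/2/3 in proportions
4279/90/17; per-label marginals proportional to the published category
counts (AIP most frequent at 1,678, PBP rarest at 104).  Labels are
drawn first (cardinality, then that many distinct labels proportional
to the marginals), then a sequence is sampled conditional on the held
labels.

Label signal is deliberately heterogeneous across labels so that
different views capture different labels — the committee-diversity
premise of multi-view disagreement sampling.  The eight labels cycle
through three channels: a whole-sequence residue-composition tilt, a
composition tilt restricted to the N-terminal half, and a first-order
residue-transition tilt with near-base stationary composition (visible
to pair/order views but barely to plain composition).  A
`composition` mode puts every label on the first channel, making the
plain composition view the single informative one; with the tilt
magnitude raised it reaches macro-AUC > 0.9 on a held-out split and
ranks first among views, which is the substrate for the per-view
quality-ranking tests.  `signal_strength = 0` is the null model.  The
default `signal_strength = 0.3` was chosen, once, so that the small
benchmark fixture starts in a moderately informative regime and is
still learning when the stopping rule fires — the regime in which
comparing query strategies is meaningful.

Profiles for the PPCT view are noise-perturbed one-hot matrices with
renormalized frequency columns: shape- and scale-correct but not
alignment-derived.  What passing tests show is therefore that the
machinery behaves correctly on data with realistic marginal structure
and view-heterogeneous signal; they do not certify performance on real
peptides, whose signal geometry (motifs, homology structure,
evolutionary profiles) the generator does not attempt to model, and
whose label assignments are correlated in ways the generator's
independent-given-cardinality draws are not.

## What the synthetic benchmarks do and do not show

Two regime-dependent findings, both computed by the test suite, frame
how the benchmark numbers should be read:

* **Committee size helps.**  The nine-view committee's final macro-AUC
  beats the three-view committee's in every paired re-split of the
  benchmark fixture, consistent with the ensemble-error analysis (the
  majority-vote bound below).
* **Query gains are noise-limited.**  With near-deterministic labels
  (`signal_strength = 1.0`) the committee query dominates random
  sampling — its learning curve is ahead at every iteration, most
  visibly early.  At the default moderate noise (`signal_strength =
  0.3`) the advantage disappears: committee disagreement then
  concentrates on samples whose labels are dominated by Bayes noise,
  the well-known noise-seeking failure mode of uncertainty-driven
  selection, and random sampling matches or beats it.  Real peptide
  corpora additionally contain homology redundancy, which rewards any
  selective strategy over random in a way an i.i.d. generator cannot
  reproduce.  Benchmark outcomes at the default noise level should
  therefore be read as a property of the noise regime, not of the
  selection machinery.

## Problem sizes

Benchmarks and the acceptance script run at n = 500 (test 100, initial
labeled 20, pool 380; nine views; λ = 30; stop at 65 % of the pool ⇒
247 labels over 9 iterations), averaged over 10 re-splits in the test
suite and 5 in the acceptance script.  Loop-bookkeeping checks run at
n = 1000 (pool 760 ⇒ 494 labels in 17 iterations) on three cheap views,
since the arithmetic under test does not depend on the view set.  These
sizes are the package's own desk-scale defaults; the library itself has
no such limits.

## Known limitations

* The base learner is linear; the committee's disagreement geometry
  with deep or kernel members is untested.
* Selection ignores label correlations and the growing class imbalance
  of the labeled set; both are known failure modes of entropy-summed
  committee selection on sparse multi-label data.
* The simulated oracle is noiseless and instantaneous; real assay
  labels are neither.
* LCI/MMU results depend on the reconstruction choices above and on
  concatenated-view scaling; they are baselines, not reference
  implementations of the cited originals.
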