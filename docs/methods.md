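# Methods

`kce` predicts therapeutically relevant (protein kinase, cancer) pairs from
biomedical literature. This note records the model, the choices behind every
tunable that matters, what the synthetic study generator does and does not
emulate, and the known limitations.

## Pipeline overview

1. **Corpus preparation.** Article records (PMID, year, MeSH descriptors,
   keywords, title, abstract) are filtered for relevance through a MeSH
   descriptor closure: an article qualifies if it carries a search descriptor
   (defaults D009369 *Neoplasms*, D011494 *Protein Kinases*) or any
   descendant, or a keyword equal (case-insensitively) to a label or synonym
   of one, and has a non-empty abstract. Concept spans recognized in
   title+abstract (PubTator-style offsets) are replaced by single concept
   tokens — `meshd002289`, `ncbigene1956`, `cvcl0023`, `rs334`, `taxon10090`
   — so multi-word concepts embed as one unit. Annotations of the human
   species (taxon 9606) are skipped to preserve gender- and age-bearing
   words. Text is then normalized: punctuation (including intra-word hyphens
   and underscores) removed with compound parts split; stop words removed in
   lower- and capitalized form while uppercase acronyms of length ≥ 2
   survive (the acronym *ALL* is retained although *all*/*All* are stop
   words); single letters dropped; tokens lemmatized; everything lowercased
   last.

2. **Embedding.** Skip-gram with negative sampling (SGNS) over the token
   corpus: for center c and context o within the window, maximize
   `log σ(u_o·v_c) + Σ_{i=1..K} log σ(−u_{n_i}·v_c)` with noise tokens drawn
   from the unigram distribution raised to the 0.75 power. The map `f(·)` is
   the input-vector table.

3. **Evidence catalog.** Drug–kinase activities (μM) are filtered to
   affinities **below 0.03 μM** and at most **5** kinases per inhibitor (the
   lowest-affinity, i.e. strongest-bound, five; ties broken by symbol;
   duplicate measurements collapse to the minimum). Clinical-trial rows
   (NCT id, inhibitor, cancer MeSH id, phase I–IV, years) are joined with
   the target map: every trial of inhibitor X against cancer C yields
   evidence on (PK, C) for each retained target PK of X.

4. **Historical split.** Fix a target year. Training positives are pairs
   with phase-IV evidence starting no later than the target year (only
   phase IV is ever used for training); training negatives are a uniform
   sample, 10× the positive count, of pairs without evidence up to the
   target year. Test positives are pairs whose first qualifying evidence
   (all phases, or phase IV only) starts inside a later window, with no
   any-phase evidence through the target year, and outside an exclusion set
   derived from *unfiltered* drug–kinase associations (any affinity, no
   cap) joined with trials up to the target year. Test negatives are drawn
   disjointly from all evidence pairs and from both training sets.

5. **Classification.** Each pair is the 100-dimensional difference vector
   `f(PK) − f(cancer)`. A random forest is tuned by randomized search
   (uniform over the space below) scored by cross-validated AUROC, refitted
   on all training rows. Evaluation reports ROC and precision–recall
   curves, AUROC (trapezoid) and average precision (step-weighted sum).
   Operating thresholds: `gmean` maximizes `sqrt(TPR·(1−FPR))`; `f1_opt`
   maximizes F1; ties resolve to the smallest threshold; the decision rule
   is `score ≥ threshold`.

6. **Baseline.** A pair is called positive when its two concepts co-occur
   in at least k abstracts, k = 1…25, counted at document level (an
   abstract with both concepts counts once no matter how often either is
   mentioned).

## Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| window | 5 | fixed context radius (no shrinking-window variant) |
| min_count | 5 | tokens below the floor receive no vector |
| batch size | 128 | mini-batch gradient updates (gradients computed at batch start, applied after) |
| negatives K | 20 | noise samples per observed pair |
| dimension | 100 | embedding width |
| epochs | 5 | convergence on the bundled corpus scales; configurable |
| learning rate | 0.025, linear decay to ~0 | standard SGNS schedule |
| noise exponent | 0.75 | standard unigram damping |
| subsampling | off | no frequent-word subsampling by default |
| affinity ceiling | 0.03 μM | potency threshold for calling a kinase a target |
| targets per inhibitor | 5 | strongest-bound five kept when more qualify |
| negative:positive ratio | 10 | class prior 1/11 in every split |
| RF search space | trees 100–1000 (step 100); depth none/10–100; max features sqrt/log2/0.1–1.0; min split 2/5/10; min leaf 1/2/4; bootstrap on/off | 100 iterations, 5-fold CV, AUROC scoring |

Input vectors initialize uniform in ±0.5/dim, output vectors at zero, both
seeded; training is single-threaded and reproducible per seed. The inner
loop runs through a compiled (numba) kernel; a vectorized numpy twin
implements identical math and serves as fallback.

Combined phase labels ("Phase 1/Phase 2") normalize to the **higher**
phase — conservative when phase IV is the efficacy criterion. Trial dating
uses the start year throughout; registration dates are not modelled.
Overlapping concept annotations resolve to the longest span (ties: leftmost,
then lexicographic id), applied in descending offset order. Title and
abstract are joined with a single space to form the annotation offset space.
The stop list ships as a versioned data file (standard English list plus all
single-letter tokens); the lemmatizer is a dictionary of irregular forms plus
conservative plural rules — its contract is only that plural nouns reduce to
singulars and listed comparative/superlative forms to bases.

Within one assembled split, a pair already drawn (blind) as a training
negative is not re-admitted as a test positive; this keeps the four sets
pairwise disjoint while preserving the no-look-ahead character of negative
sampling. Negative test sampling sizes itself after the positive test set is
final.

## The synthetic study generator

Real inputs (PubMed-scale corpora, DrugCentral and ClinicalTrials.gov
extracts) are too large to bundle, so `synth` fabricates all five input
tables with planted ground truth at desk scale: 30 kinases × 30 cancers, 40
true pairs, 60 signal documents per true pair, 3000 background documents,
seed 7.

The signal mechanism mirrors two features of the real literature:

* **Activity is a minority property.** Only a fraction (default 0.4) of
  kinases and cancers are "trial-active"; true pairs live on that subgrid.
  Signal documents give each side a shared, side-specific context
  signature: kinase-relation words appear adjacent to kinase mentions,
  disease-relation words adjacent to cancer mentions. Difference vectors of
  active pairs therefore concentrate around a common offset, while pairs
  with an inactive member land elsewhere — the axis-aligned structure a
  random forest can actually learn from a handful of positives.
* **Pair-specific shared context.** Each true pair additionally owns a
  small cluster of context words appearing in both halves of its signal
  documents (the half assignment is re-randomized per document so the
  cluster component cancels in the pair's difference vector), plus direct
  in-document co-occurrence of the two concept mentions.

One inhibitor per true pair carries a sub-threshold activity for the pair's
kinase plus decoy supra-threshold activities; a configurable number of
inhibitors exceed the 5-target cap to exercise the top-n filter. Each true
pair receives a phase-IV trial at its truth year (drawn from 2000–2020,
which decides its train/test era around the 2010 target year) and
earlier-phase trials shortly before; decoy inhibitors generate phase I–II
trials for non-true pairs only.

The end-to-end experiment evaluates recovery of the planted pairs with the
phase-IV-only test filter, because the truth is defined by phase-IV years;
decoy phase I–II trials deliberately carry no literature signal, so under
the all-phases filter they enter the positive test set by protocol and
measure decoy contamination rather than recovery (both filters are
implemented and tested). At fixture scale the randomized search is trimmed
to trees {100, 200, 300} and 20 iterations, keeping the full run in the
2–5 minute range on one CPU; the full-size space remains the library
default.

What the generator does **not** emulate: natural English (documents are
bags of symbol tokens with controlled placement), realistic affinity or
phase distributions, annotation errors or offset noise, concept ambiguity,
citation growth over time, or year-dependent corpora (embeddings are
trained on the whole synthetic corpus, whereas the real historical protocol
restricts abstracts to the target year). Passing tests therefore show that
the machinery — filtering, replacement, SGNS optimization, the evidence
join, the split protocol, the forest and the metrics — behaves correctly
and that a planted relational signal of realistic shape is recovered; they
do not certify performance on real literature.

A known and deliberate observation at the default scale: the forest
separates planted pairs from pairs with inactive members almost perfectly,
but active-kinase/wrong-active-cancer combinations remain largely
indistinguishable from true pairs. Difference-vector classification with
few positives rewards class-membership structure more than specific
pairings; the co-occurrence baseline, which sees the pairing directly, is
near-perfect on synthetic data (max F1 ≈ 1.0 at k = 1) precisely because
the generator plants noiseless co-occurrence — on real literature the same
baseline is weak because co-occurrence is pervasive and noisy.

## Numerical notes

* Sigmoid and log-sigmoid use sign-split formulations; no overflow for any
  input.
* The SGNS gradient surface (`sgns_loss_and_grad`) is pure numpy and is
  verified against central finite differences at relative tolerance 1e-4.
* Vocabulary indices are assigned by descending frequency with ties broken
  by token string, so vocabularies are reproducible across runs.
* Negative sampling uses inverse-CDF lookup (searchsorted) on the damped
  unigram distribution.
* AUROC/AP come from scikit-learn's curve sweep and are cross-checked in
  the test suite against hand-written concordance-pair and step-sum
  oracles; threshold selection scans every distinct score exhaustively.
* Degenerate inputs fail loudly: single-class training or evaluation sets,
  unknown tokens, non-positive affinities, out-of-range annotation offsets
  and infeasible negative-sample requests raise typed errors naming the
  offending record.

## Limitations

* The historical protocol here dates trials by start year only.
* Embeddings in the synthetic experiment are not year-restricted (see
  above); a year-faithful corpus split would require per-year corpus
  generation.
* The permutation control shuffles held-out labels around the trained
  model's scores (mean over 20 shuffles); it tests that measured AUROC is
  label-linked, not the full retraining null.
* Uniform negative sampling only, as in the underlying protocol; no
  degree- or propensity-matched negatives.
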