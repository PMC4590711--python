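# Methods

## Problem and model

The classifier infers a tumor's primary anatomical site from its
somatic mutations. The signal comes from three places: (i) recurrently
mutated cancer genes are hit at different rates in different tissues;
(ii) the mutational processes active in a tissue leave characteristic
single-base-substitution spectra, especially when substitutions are
resolved by trinucleotide context; (iii) somatic copy-number gains and
losses of cancer genes are likewise tissue-biased. Each information
source becomes a feature block, and a one-vs-rest ensemble of random
forests maps the combined vector to per-site scores.

### Feature definitions

* **Substitution classes.** Every SNV is standardized to the strand on
  which the reference base is a pyrimidine: 12 raw substitution types
  collapse to 6 (C>A, C>G, C>T, T>A, T>C, T>G). The 96 trinucleotide
  classes multiply these by the 4 × 4 flanking-base combinations, with
  the whole trinucleotide reverse-complemented when the center is a
  purine. Class order is fixed: substitution class, then 5′ flank, then
  3′ flank — the de-facto convention for signature vectors.
* **Spectra are relative frequencies.** A sample's 6- and 96-class
  vectors each sum to 1 over the contributing SNVs; a sample with no
  contributing SNVs gets an all-zero vector plus a machine-readable
  flag rather than an error, so single-sample classification never
  crashes (such calls are marked low-trust in reports). Only true SNVs
  contribute; multi-nucleotide substitutions are never decomposed,
  because their class assignment would be ambiguous. For the 96-class
  spectrum an SNV additionally needs an available context (not at a
  contig edge, no N) and a reference base agreeing with its ref allele;
  disagreements are excluded and counted rather than trusted.
* **Gene mutation status.** A panel gene counts as mutated when any
  variant's affected reference interval overlaps the gene interval and
  its consequence annotation is not in the silent set (default:
  "coding silent" and synonyms; unannotated variants qualify). Counts
  are kept internally; the classifier uses the binarized view by
  default, with the count view available as a switch, since both
  readings of "mutated" are defensible.
* **Copy-number status.** A gene takes the −1/0/+1 status of the
  overlapping segment covering the largest number of its bases;
  segments overlapping "entirely or partially" all compete. An exact
  tie between conflicting statuses resolves to 0 (no change), as does
  the absence of any overlapping segment.

### Ensemble

One binary forest per site, site vs rest. Per tree, m cases and m
non-cases are drawn **with replacement** (stratified bootstrap), with
m = round(0.632 × min(n_cases, n_non-cases)); 0.632 is the classical
expected fraction of distinct samples in a bootstrap and balances the
strata so no tree is dominated by the majority class. Trees are CART
classifiers considering ⌊√p⌋ candidate features per split (p = total
feature count, spanning all configured blocks). Defaults: 500 trees per
site. The per-site classification score is the fraction of that site's
trees voting "case"; scores are raw vote proportions, deliberately not
calibrated or normalized across sites — the binary forests are
independent, and two sites can both score high on one sample. The
predicted site is the score argmax with exact ties broken by site
order (lexicographic by default), and the confidence score is the gap
between the two top scores. Tie-break and the refusal to classify with
a single trained site are explicit contract decisions.

Determinism: per-site seed streams are spawned from
(random_state, site index), so a site's forest depends only on its own
position in the site order, and fixed seed + fixed inputs reproduce
predictions exactly.

## Cohort handling

Cohorts may contain multiple specimens of one tumor. Deduplication
keeps exactly one specimen per tumor id, maximizing the provenance
tuple (surgery_biopsy, primary, verified, exome_seq) compared
lexicographically — surgery biopsy beats xenograft, primary beats
relapse, verified beats unverified, exome-seq beats RNA-seq, in that
order of importance; remaining ties go to the smallest sample id. The
four flags are compared in their listed order because no other relative
ranking is documented for conflicts. VCF and SNV-table inputs given
together are merged as a union deduplicated on
(contig, position, ref, alt), with the overlap logged. VCF FILTER
handling defaults to keep-all, with a PASS-only switch.

## Synthetic cohorts

The simulator exists so that feature extraction, training and every
evaluation procedure run end-to-end with no external data, and so that
the pipeline's statistical behavior can be validated against known
generating parameters.

* **Reference and genes.** One uniform-random contig (default 150–200
  kb in the shipped experiments) with n non-overlapping genes (default
  20 × 1 kb) placed one per equal-width slot at a random offset.
* **Tumors.** SNV count per tumor is log-normal (default log-mean 4.6,
  log-sd 0.5 ≈ median 100 SNVs, heavy-tailed like real exome burdens).
  Each SNV draws a 96-class from the tissue's spectrum, then a genomic
  position uniformly among positions whose reference trinucleotide
  matches the class context on either strand; sampling from the
  reverse strand writes the complemented alt allele. Conditioning
  positions on matching contexts makes generation and extraction
  exactly consistent (the closure property the tests rely on); mutating
  random positions instead would distort the realized spectrum toward
  the genome's context composition. Each panel gene is additionally hit
  by a non-silent mutation with a per-tissue probability, and receives
  a gain/loss copy-number segment spanning the gene with per-tissue
  probabilities (single-gene segments for simplicity).
* **Separation.** Tissue profiles interpolate between a shared
  baseline and site-specific parameters with a single knob s ∈ [0, 1]:
  spectrum = (1−s)·base + s·(sparse site-specific spectrum on 6
  classes disjoint across sites); gene mutation probability = 0.05 +
  s·0.65 on each site's signature genes (0.05 elsewhere); CN gain
  probability = 0.05 + s·0.55 on a shifted signature-gene set so the
  CN block carries information of its own. At s = 0 all tissues are
  identical and held-out accuracy can only reach the 1/K random
  baseline; at s = 1 the spectra have disjoint support and tissues are
  essentially perfectly separable.

What the simulator does **not** emulate: real signature catalogs,
chromosome-scale SCNA structure, mutation hotspots, sequencing
artifacts, or inter-patient burden correlations. Passing tests
therefore demonstrate that the pipeline's machinery is correct and
internally consistent — not that any particular accuracy will be
attained on real cohorts, which depends on how distinct real tissue
spectra are.

## Evaluation

Stratified k-fold (default 5) and a stratified proportional hold-out
split mirror standard practice. Per-site sensitivity is
correct-s / actual-s and specificity is predicted-non-s / actual-non-s.
Cumulative top-n accuracy is reported against two baselines: sites
ranked by training-set frequency (training marginals are used, recorded
in the output metadata) and the uniform n/K expectation. Accuracy is
also stratified by confidence score (bins of width 0.1 by default) and
by called fraction: samples sorted by confidence descending (ties in
stable input order), prefix accuracies computed, and the largest
fraction still meeting a target accuracy (default 95%) reported.
Binomial confidence intervals use the Wilson score interval at 95%,
chosen for its behavior at small n and extreme proportions. Subgroup
comparisons use a two-sided Fisher exact test on the 2×2
correct/incorrect × in/out table.

## Shipped calibration experiments

`scripts/acceptance.py` (and the heavier end of the test suite) runs:
100 simulated tumors for the spectrum-oracle and marginalization
checks; chance-baseline recovery with 6 and 10 identical-profile
tissues at 100 tumors each (held-out fifth); parameter recovery with 3
fully separated tissues at 200 tumors each; and the PM vs PM+CN
comparison over five seeds at the same design. These sizes keep each
experiment in the tens of seconds while leaving the binomial bands
around the chance baselines tight enough to be informative.

## Known limitations

* Scores are uncalibrated vote proportions; the confidence score
  orders predictions well but is not a probability.
* The gene panel is user configuration; results depend entirely on its
  quality and on consistent coordinates between variants, reference
  and gene model (contig names are matched exactly, no "chr" aliasing).
* Indels contribute to gene mutation status but never to spectra.
* Training requires ≥ 2 samples per site and ≥ 2 sites; classes with
  very few samples yield unstable binary forests (the stratified
  bootstrap shrinks every tree to the smallest group's scale).
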