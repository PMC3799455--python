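# Methods

This note records the models implemented in `zfnscan`, the parameter
defaults and the reasoning behind choices the method description leaves
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Site model and feature windows

A composite ZFN site is written on the top strand as

    [flank + left core + flank]  spacer  [flank + right core + flank]

with 12-bp cores for the CCR5-targeted pair and 9-bp cores for the
VEGFA-targeted pair, and spacers of 5 or 6 nt. `SiteDefinition` carries the
two core sequences, the per-edge flank width and the allowed spacer
lengths.

Decisions made where the method description was open:

* **Flank width.** "Adjacent nucleotides" are included without a stated
  count; the width is exposed as a parameter (0–4 per half-site edge,
  default 1). All published composite site strings parse at flank 0.
* **Flank placement.** Flanks are taken adjacent to each core but *outside*
  the spacer, so the feature window and the spacer never share bases. This
  keeps the feature space fixed across the two spacer lengths and keeps the
  spacer available as an independent deduplication key.
* **Spacer exclusion.** Spacer bases are never classifier features. They
  are retained per record because (a) two otherwise identical windows with
  different spacers count as independent cleavage events, and (b) the
  spacer interval anchors indel calling downstream.
* **Deduplication.** Active windows are deduplicated on
  (features, spacer, provenance); records differing in spacer sequence or
  provenance tag survive as independent events. The preselection library is
  deduplicated the same way before subtraction. The inactive class is the
  library minus every window whose features appear in the active set.

## Position-wise Naive Bayes classifier

Positions are conditionally independent given the class. With Laplace
pseudocount α (default 1, configurable):

    P(b | p, c) = (count_{p,b,c} + α) / (n_c + 4α)

* **Score orientation.** The reported score is P(inactive | window),
  computed in log space and normalized with `logaddexp`, so scores live in
  (0, 1) whenever α > 0 and *lower* scores mean more likely cleaved. The
  orientation is fixed here by convention so that the 0→1 published scale
  reads the same way.
* **Priors.** Uniform (0.5/0.5) by default: the active set's size reflects
  sequencing depth of the selection, not any genomic prevalence, so
  empirical priors would encode an artifact. Empirical priors remain
  available as an option.
* **Cross-validation.** Stratified k-fold (default k = 10, seeded,
  scikit-learn fold assignment), retraining per fold; windows are
  classified active at score < 0.5 for the confusion matrix. The 0.5
  threshold is used *only* for CV metrics — genome binning always uses raw
  scores.
* **Serialization.** Versioned JSON with per-position probability tables;
  round-trips preserve scores to 1e-12.

## Genome scanning

Every (position, strand, spacer length) whose half-site windows contain
only A/C/G/T is a candidate; windows with ambiguity codes are skipped while
ambiguity inside the spacer is tolerated (the spacer is not a feature).
Enumeration order and output are deterministic: (chrom, start, + before −,
spacer ascending). Scoring streams in batches, so memory is constant in
genome size.

* **Heterodimer only.** The modeled ZFNs carry obligate-heterodimer
  EL/KK FokI variants, and the classifier is defined over the heterodimeric
  composite window, so homodimeric half-site pairings are not scanned —
  there is no trained model under which their scores would be meaningful.
* **Strandedness.** A site is reported on the strand where it reads
  left-window + spacer + right-window. A span that equals its own reverse
  complement is reported once (+ strand).
* **Coordinates.** 0-based half-open everywhere, including BED output.
* **Exon annotation.** A site is exonic when its full span overlaps any
  exon interval by ≥ 1 bp (interval tree; half-open semantics). Partial
  overlap behaviour was unstated; any-overlap is the least surprising rule.
* **Binning.** Left-closed bins [0, 0.1), …, [0.6, 0.7) with the final bin
  [0.7, 0.75] closed, matching the published row labels; scores above 0.75
  are outside the sampling plan. Ties inside a bin break by genomic order.
  Top-N per bin defaults to 13.

## Amplicon indel pipeline

* **Demultiplexing.** A read belongs to the amplicon whose forward primer
  matches its prefix within 2 mismatches (or whose reverse primer matches,
  in which case the read is reverse-complemented into reference
  orientation). Reads matching zero or several amplicons are counted as
  unassigned.
* **Alignment.** Global Needleman–Wunsch with affine gaps (three-state
  Gotoh, numba-jitted). A gap of length L costs `gap_open + L·gap_extend`;
  defaults +2/−2/−6/−1 were chosen so that one consolidated ≥2-nt gap beats
  two separate 1-nt gaps — the relevant regime for NHEJ scars. Traceback is
  deterministic: ties prefer diagonal > deletion > insertion. `N` always
  scores as a mismatch.
* **Left-normalization.** Indels are shifted to their smallest reference
  coordinate preserving the aligned sequences and score (VCF-style), so
  repeat-adjacent events have canonical intervals before the spacer rule is
  applied.
* **Coverage filter.** `ref_bases_aligned` counts reference bases paired
  with read bases (match + mismatch columns). Deletion columns are
  excluded deliberately: a global alignment always consumes the entire
  reference through deletions, so including them would make the <40-bp
  exclusion vacuous. 40 bp is the minimum combined primer length.
* **Depth gate.** Amplicons with fewer than 1500 usable reads in either arm
  are excluded. The gate is applied after the coverage filter and after
  cross-amplicon exclusion, so depth reflects reads that actually inform
  the call.
* **Cross-amplicon exclusion.** Each unique read sequence is re-scored
  against every other amplicon reference; reads scoring strictly higher
  elsewhere are excluded. This replaces an external genome-remapping
  verification step with a self-contained check of the same intent.
* **NHEJ rule.** An indel qualifies when it is ≥ 2 nt and originates from
  the spacer: deletions must intersect [s_start, s_end); insertion points
  are accepted inclusively at both spacer ends (s_start ≤ point ≤ s_end),
  since an insertion at either boundary is physically between spacer-flank
  bases. Counting is read-level: a read with two qualifying events counts
  once.
* **Significance.** One-sided Fisher's exact test (treated enrichment) on
  [[k1, n1−k1], [k0, n0−k0]]; significant iff p < 0.05 strictly. A
  two-sided alternative and Benjamini–Hochberg correction across amplicons
  exist as options but are off by default, matching per-site usage.

## Synthetic data

The generators define the study conditions used by the tests and the
acceptance script:

* **Selection library** (default n = 10,000, seed-controlled): each library
  member is the on-target window with every position substituted
  independently at the degeneracy rate (default 0.2). Cleavage truth is
  additive: a member is active when its summed per-position planted weights
  (default: 1 per on-target base) reach the threshold (default
  window length − 3, i.e. within 3 mismatches). With these defaults about a
  quarter of the library cleaves — a selection-like enrichment regime. This
  additive-threshold truth is the simplest model a position-wise classifier
  can learn and is a statistical stand-in, not ZFN biochemistry.
* **Genome**: i.i.d. background at a given GC content (default 0.41,
  human-like), with composite sites written at exact coordinates/strands;
  overlaps are rejected.
* **Amplicon reads**: full-length reference copies; with probability
  `indel_rate` one indel (length from a categorical over 1–15 nt, default
  geometric-like decay; one third insertions) is planted uniformly in the
  spacer; substitution errors (default 0.5% per base) are applied
  everywhere; constant Q30 qualities (the pipeline does not use qualities).
  The control arm uses an independent substream of the same seed with
  indel rate 0.

What passing tests on these fixtures do **not** show: robustness to PCR
bias, sequencing-run artifacts, paired-end insert-size effects, repeat
structure or chromatin context in real genomes, or non-additive
position interactions in real cleavage preferences.

## Numerical conventions and problem sizes

Scores are computed in log space and remain finite under extreme class
skew (1 vs 10⁶ training examples over 60 positions). Probability tables are
validated to sum to 1 within 1e-12. Percentages recomputed from published
count tables use integer rounding with halves rounded up, which reproduces
every printed value exactly.

The test suite and the acceptance script run on scaled-down problem sizes
chosen to exercise every statistical property with comfortable margins:
selection libraries of 10,000 members, genomes of 6–80 kb with 20–60
planted sites, amplicon experiments of 10,000 reads per arm, and exhaustive
alignment-oracle sweeps over all A/C string pairs up to length 5–6. These
sizes are the package's own validation conditions; the library itself
streams and is not limited to them.

## Known limitations

* The classifier assumes positional independence; it cannot represent
  pairwise base interactions, and scores are not calibrated cleavage rates.
* Scanning reports every unmasked candidate; repeats are neither masked nor
  collapsed.
* The indel caller targets spacer-origin indels only — substitutions and
  indels elsewhere are reported but never qualify, and UMI-based error
  correction is out of scope.
* Primer demultiplexing is prefix-Hamming only; it does not model primer
  indels.
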