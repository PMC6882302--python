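# Methods

## The activation model

The package scores pathway activity per sample as a signed sum over the
pathway's member genes: role weight × perturbation flag × decimal-log
expression ratio (see the README for the formula).  The model assumes

* pathway membership and a discrete activator/repressor role per gene are
  known (no network topology — edges contribute nothing to the score);
* expression ratios against a reference group are the meaningful signal,
  so any per-sample library-size scaling cancels out of the statistic;
* only genes that are *clearly* perturbed should contribute: the flag
  gates every term, making the score robust to the bulk of genes whose
  ratios fluctuate within the tolerance interval.

The flag is 1 for perturbed genes.  It requires both criteria at once:
the fold criterion (CNR ≤ 0.66 or ≥ 1.5, comparisons inclusive since the
thresholds are printed as bare numbers) and the tolerance-interval
criterion, realized as a two-sided Gaussian test on log2 abundance
against the reference group's mean and standard deviation.  A flag that
were instead *zero* for perturbed genes would make the score identically
zero on any real signal, so that reading is rejected.

`lg` is taken as log10; any other base would rescale every score by one
constant and change no comparison.  No division by pathway size is
applied (the statistic as defined has none); a size-normalized variant is
available behind an off-by-default option for cross-size comparisons.

## Numerical policy

* **Pseudocount** (default 1.0 on the normalized scale), added
  symmetrically to case and reference, keeps CNR finite and positive; an
  all-zero gene gets CNR exactly 1 and contributes nothing.
* **SD floor** (default 0.1 log2 units) bounds the reference standard
  deviation from below, so reference groups of n = 2–3 and zero-variance
  genes cannot produce arbitrarily small p-values.  The same floor is
  used when fitting the reference PAS distribution for per-sample
  p-values.
* **Reference samples are scored leave-self-in**: their CNR denominators
  include themselves.  This is what makes a reference PAS distribution
  available for the per-sample Gaussian test; with n ≥ 5 reference
  samples the self-inclusion bias is negligible.
* Missing pathways (no member gene present in the matrix) carry NaN, a
  deliberate sentinel distinct from a true 0, written as `NA` on disk;
  missing member genes are skipped and counted in a log message.
* Normalization default is CPM; the statistic depends only on
  case/reference ratios, which CPM preserves.  A median-of-ratios option
  (geometric-mean reference profile) is provided for robustness studies.

## Group statistics

Group significance per pathway is a two-sided Wilcoxon rank-sum test of
case PAS values against control/reference PAS values.  For combined group
size ≤ 12 the null distribution is enumerated exactly over all case/control
rank assignments using mid-ranks (so ties are handled); above that a
tie-corrected normal approximation is used.  Fully tied inputs degenerate
to p = 1 with a warning.  P-values are reported raw by default — with a
few hundred pathways at α = 0.05 some false positives are expected, and
the selection sets should be read accordingly; a Benjamini–Hochberg
switch (`multiple_testing="bh"`) is available for reuse.

The stringent ISP filter keeps pathways with group p < α and
**|group PAS| ≥ 0.1**.  The absolute value matters: repressed pathways
carry negative scores and must survive a magnitude filter.  Group PAS is
the arithmetic mean over case samples — the simplest aggregation
consistent with reporting one number per condition.

"Pearson" distance for clustering is 1 − Pearson product-moment
correlation (constant columns get the maximal distance 2, logged), with
average linkage; correlation matrices default to Pearson product-moment
with Kendall tau as an option.  PCA orients each loading vector so its
largest-magnitude entry is positive, making outputs deterministic.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical structure* the analysis
assumes: a multi-procedure time course (five procedures × five timepoints
× 3 replicates, plus a sham time-0 reference of 3), negative-binomial
counts with dispersion 0.05 (tight, pooled-sample-like), log-normal
per-gene baselines (median ≈ 200 reads, log-sd 1) and log-normal library
sizes (log-sd 0.2) to exercise normalization.  A planted "activated"
pathway multiplies its activators' means by the fold and its repressors'
by the inverse (and vice versa for "repressed"), so planted activations
have positive true PAS by construction.  Pathway collections default to
378 pathways of 10–60 genes with 10% of each pathway drawn from
previously used genes, giving realistic overlap.

It does **not** emulate a real liver transcriptome: no gene-gene
correlation beyond planted pathways, no batch structure, no
length/GC biases, no realistic pathway curation error.  Passing recovery
tests therefore demonstrate that the machinery is correct and well
calibrated under its own model — not that any biological conclusion from
real data is right.

## Calibration and recovery conditions

* **Null calibration** uses two unperturbed groups of n = 10 scored
  against an n = 5 reference, 1000 simulated datasets × 378 pathways.
  Group sizes of 10 are used deliberately: with n = 3 per group the exact
  rank-sum test's smallest two-sided p is 0.1, so a 0.05-level rejection
  rate is structurally zero — calibration is only observable in the
  near-continuous regime.  Observed type-I rate is ~0.05.
* **Recovery** plants 20 activated pathways of 378 at fold 3 with n = 3
  case and n = 3 reference samples, averaged over 20 seeds; ranking by
  |group PAS| recovers the planted set with AUROC ≈ 1.0, and planted
  pathways score positive in ~100% of affected samples.

These problem sizes are the package's chosen study conditions and are the
same in the test suite and in `scripts/acceptance.py`.

## Single-sample enrichment

The per-sample signature score is a Kolmogorov–Smirnov-style running sum
over the sample's abundance ranking (up 1/|in-set| on members, down
1/|out-of-set| otherwise; score = maximum deviation, signed).  The
kernel-density variant used by some established tools is intentionally
not reproduced: the questions asked of these scores here (which condition
rises first) are rank-ordering properties robust to the scorer.  Ties are
broken lexicographically by gene id, making scores deterministic even on
constant input.

## Design choices that were genuinely open

* **ARR domain** fixed to {−1, −0.5, 0, +0.5, +1}: the minimal discrete
  scheme distinguishing strong/weak activators and repressors plus
  neutral members; a gene listed twice in one pathway is an error (to
  surface knowledge-base bugs), while genes shared *across* pathways are
  expected — pathway overlap is exactly what the Jaccard coefficient
  measures.
* **Reference choice**: a single designated reference group (flagged in
  the design table) rather than time-matched sham per timepoint; both are
  expressible through the `is_reference` flag.
* **Pathway file dialect**: GMT-inspired TSV with `gene:arr` tokens,
  because standard GMT has no role weights; round-trips bit-exactly.
* **miRNA presence** reuses the read-count ≥ 10 detection convention
  (inclusive) as the only quantitative threshold in play; presence in a
  design cell means any replicate over threshold, which also covers
  pooled single-column designs.

## Known limitations

* The tolerance interval is Gaussian on log2 counts; for very low counts
  a count-model test would be better calibrated per gene.  The SD floor
  mitigates, not removes, small-n artifacts.
* Raw p-values across hundreds of pathways overstate confidence without
  the BH option.
* The enrichment score is not numerically comparable to kernel-density
  single-sample scores from other tools, only rank-comparable.
* Exclusivity logic treats "absent" as "below detection threshold";
  it cannot distinguish biological absence from shallow sequencing.
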