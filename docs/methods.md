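# Methods

`trfscan` re-implements, at desk scale and fully offline, the analysis chain
that leads from a raw small-RNA sequencing experiment to a characterised
tRNA-derived fragment (tRF) and its downstream molecular context. This note
documents the models, the parameter choices and their rationale, what the
synthetic data does and does not emulate, and the numerical conventions.

## The discovery chain

1. **Read-length spectrum.** Reads are length-filtered to a closed 18–41 nt
   window (the window in which small-RNA libraries are informative; the
   lower bound excludes adapter dimers, the upper bound is the library's
   practical ceiling). Per-sample spectra are counts per length, normalised
   to reads per million retained (RPM).
2. **Anomalous-peak screen.** A length outside the canonical miRNA window
   (20–24 nt) is called anomalous between two groups when it is (i) a local
   maximum of a group-mean RPM spectrum, (ii) at least `min_ratio = 0.25` of
   the canonical peak height in at least one group, (iii) significant in a
   plain two-sided two-sample t-test on per-sample RPM at `alpha = 0.05`,
   and (iv) at least `min_fold = 2` between groups in either direction.
   "Peak" has no standard definition in this setting; the local-maximum +
   height-ratio + test combination is the package's operationalisation, and
   every gate is configurable. The pooled-variance t-test is used here
   because it holds its nominal level at the tiny replicate counts
   (n = 3/group) typical of these designs, where the unequal-variance form
   is conservative. No multiple-testing correction is applied across
   lengths by default, mirroring single-length hypothesis practice; a
   Benjamini–Hochberg option exists behind a flag.
3. **Peak decomposition.** All reads of the called length are collapsed to
   unique sequences per group and pooled; entries are sorted by count
   (ties lexicographically) and reported as fractions of the peak.
   Sequences containing N are excluded because they cannot be placed on the
   genome exactly.
4. **Annotation.** The dominant sequence is placed on the genome by exact
   matching on both strands (minus-strand hits reported in forward
   coordinates). A Hamming-distance-1 mode exists for base polymorphisms
   but is off by default — the fragment of interest is a perfect tRNA
   prefix. Hits are intersected with a tRNA gene table; a hit pairs with a
   locus when it lies inside the gene extended by a 50 nt strand-aware 3'
   trailer (the RNase Z product zone). The fragment class follows the tRF
   taxonomy from the strand-aware 5' offset and length: offset ≤ 1 and
   length < 30 → `tRF-5`; offset ≤ 1 and 30–40 nt → `half-5`; 3'-anchored
   analogues → `tRF-3` / `half-3`; start past the gene 3' end → `tRF-1`;
   exact gene span → `full-length`; anything else → `internal`. The ±1 nt
   anchor tolerance and the 30–40 nt half window are package choices (the
   taxonomy in the literature gives no hard thresholds). A 32 nt 5'-anchored
   fragment is a 5' half by these rules; because the field and the source
   data name such molecules simply "tRF", 5'-anchored classes also carry
   the reported label `tRF` in output (both fields are emitted).
5. **Quantification and testing.** Fragments are quantified as exact
   sequence matches per sample (a desk-scale replacement for a
   feature-count step), RPM-normalised, and tested with a two-sided Welch
   t-test per sequence (unequal variances are the safer default once
   abundances differ by an order of magnitude between groups). qPCR
   relative expression follows 2^−ΔΔCt: ΔCt = Ct_target − Ct_reference per
   sample, ΔΔCt is the case-minus-control difference of group means, and
   the control group is 1 by construction. The reference gene is a column,
   not a constant, so different assays can use different references.
6. **Target prediction.** A miRanda-style local alignment of the fragment
   (5'→3') against the reverse of each UTR window: complementary pairs
   (A–U, G–C) score +5, G:U wobble +2, mismatch −3, affine gaps −9/−4, and
   all substitution scores are multiplied by 4.0 at fragment positions 2–8
   (the seed, kept at the miRNA convention even for a 32 nt query, because
   the fragment is modelled as a post-transcriptional repressor).
   Windows of width fragment+15 advance by 5 nt with one end-anchored
   window; overlapping surviving hits merge keeping the best score.
   Thermodynamic duplex energy is replaced by a stability proxy,
   `paired_fraction × (0.5 + 0.5 × GC_share)`, with threshold 0.6: on
   dinucleotide-preserving shuffles of site-bearing UTRs, chance hits above
   the score threshold plateau near 0.55 while intact end-to-end sites sit
   near 0.75, so 0.6 separates the two regimes. The score threshold (140)
   is the published miRanda convention. The affine aligner is checked in
   the tests against a brute-force dynamic program that enumerates gap
   lengths explicitly. One asymmetry worth knowing: the duplex score is
   invariant under reverse-complementing both strands only for
   Watson–Crick scoring; G:U wobble is chirally asymmetric ((G,U)
   complements to (C,A)), so the invariance property is asserted with
   wobble disabled.
7. **Proteome integration.** Differential proteins use the conventional TMT
   screen: linear-scale mean fold > 1.20 or < 0.83 together with p < 0.05
   from a two-sided t-test on log2 abundances (fold on the linear scale,
   test on the log scale — the common TMT practice; the two cutoffs are
   symmetric in log2). Predicted targets ∩ down-regulated proteins is
   reported as a count, a percentage of the down set, and a hypergeometric
   upper-tail p against the universe of quantified proteins (the natural
   default universe; configurable). Over-representation against
   user-supplied GMT gene sets is the one-tailed Fisher/hypergeometric
   test with BH correction across sets.
8. **Metabolome screen.** Fixed order: prevalence filter (> 50% nonzero in
   at least one group, QC excluded from the test, missing values imputed as
   zero beforehand) → total-intensity normalisation (each sample scaled to
   the median column sum) → Pareto scaling ((x − mean)/√sd, sample sd;
   constant features scale to zero with a warning) → PCA (SVD of the
   sample matrix; sign fixed so the largest-|loading| element is positive)
   and PLS-DA → the screen: VIP > 1 first, then a two-sided t-test at
   p < 0.05 on the VIP-passing subset. The discriminant model is plain
   PLS-DA (NIPALS, one binary response) with
   VIP_j = √(p·Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a); mean(VIP²) = 1 holds
   by construction and is asserted at 1e−6. **This is deliberately not
   OPLS-DA**: the orthogonal-variation filter is out of scope because the
   only consumed output is the VIP > 1 gate, and with a single binary
   response the discrimination-relevant ranking coincides. Model
   validation by cross-validation/permutation is likewise out of scope; a
   label-permutation utility ships for null calibration.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with the
statistical structure the analysis needs to be testable:

* **Genome/loci.** One random 71 nt tRNA gene embedded at 15 dispersed
  copies across 5 chromosomes, on both strands, in 1-based fully-closed
  coordinates (end − start + 1 = 71, the dialect of published tRNA locus
  tables; UCSC-style 0-based half-open input is converted on read).
  Flanks are random and rejection-checked so the gene's 5' 32-mer occurs
  exactly once per copy.
* **Reads.** Per sample, a three-component mixture at 1e5 reads: uniform
  background over 18–41 nt (the simplest null that makes peak detection
  non-trivial; the real background is structured but unmodelled), a 22 nt
  miRNA component (weight 0.35, a fixed 5-sequence panel), and a 32 nt
  fragment component whose weight is 0.30 in the coarse group and
  0.30/5.77 in the fine group, so the expected group ratio of component
  counts is exactly the configured fold. Within the component the
  5'-anchored tRNA prefix is emitted with probability 0.90 (coarse) or
  0.45 (fine — the data constrain only "higher in coarse"); the remainder
  splits over three decoy 32-mers drawn from non-tRNA genome regions so
  the annotator exercises its unannotated path. Because the uniform
  background also contributes at 32 nt, the dominant sequence is ~86% of
  all 32 nt reads when it is 90% of the component.
* **Proteome.** Log2 abundances Gaussian and homoscedastic (matching the
  downstream t-test's assumption), base N(7,1), noise sd 0.25, 400
  proteins, 20 shifted up and 40 down by 1 log2 unit in the coarse group,
  n = 3/group. Half of the down set plus 40 null proteins are flagged as
  planted fragment targets; target UTRs (300 nt) carry one embedded
  perfect complementary site.
* **Metabolome.** 120 features, log-normal intensities (log2 base
  N(17,1), noise sd 0.30), 12 discriminators shifted ±1.5 log2 with
  alternating sign, 10 mostly-zero features for the prevalence filter,
  n = 10/group, and 3 QC columns equal to the pooled mean profile times
  small log-normal technical noise (sd 0.02).
* **qPCR.** Reference Ct ~ 18, target ΔCt offset −log2(fold) in the case
  group, Gaussian Ct noise sd 0.1.

Ground truth (which entities carry effects) is written alongside the data
with a `.truth.json` suffix; every pipeline loader refuses such files, so
the analysis can only see what an experimenter would see.

What the generator does **not** emulate: sequencing error and adapter
contamination, the structured length distribution of real degradomes,
isotope/TMT channel effects, metabolite correlation structure, and batch
effects. Passing tests therefore demonstrate correctness of the inference
machinery under its stated assumptions, not robustness to real-data
pathologies.

## Known behaviour of the sequential VIP screen

The VIP > 1 and p < 0.05 gates are not independent filters: both are
monotone in the same group contrast, so null features that randomly
correlate with the class labels tend to pass both together. In the
package's recovery simulation (12 discriminators among 120 features,
n = 10/group) the screen's sensitivity is ≈ 0.99 but its realised false
discovery rate settles near 0.18 — the joint null pass rate is ~2.7%, not
the 5% × (VIP rate) a naive independence argument suggests, and with few
true discriminators those false passes are a material fraction of the
calls. This is a property of the screen design itself (it is how the
VIP-then-t convention behaves), not of the implementation; practitioners
wanting a controlled FDR should BH-correct the second gate.

## Numerical conventions and degenerate inputs

* Coordinates are 1-based fully closed everywhere inside the package.
* Zero-variance, equal-mean comparisons return p = 1 (not NaN).
* Empty spectra normalise to all-zero RPM with an `empty` flag.
* A zero second-group mean yields an infinite-fold sentinel flagged
  `fold_defined = False`.
* Peak-call ties sort by (p, length); composition ties lexicographically;
  duplex-alignment ties prefer the match state (fewer gaps), then the
  smaller UTR start; ORA ties sort by set id.
* PCA reduces k to the matrix rank with a warning; Pareto scaling of a
  constant feature returns zeros with a warning.
* All generators are deterministic given `SimConfig.seed`, with
  independent derived streams per generator so one table's sample count
  does not perturb another's draws.

## Problem sizes

Simulation-backed checks run at the design sizes above (1e5 reads/sample,
3 or 10 samples per group, 400 proteins, 120 metabolites); null
calibrations use 100–400 replicate draws and 10⁴ test rows. These sizes
make every stage's statistical behaviour measurable while keeping a full
run in seconds.

## Limitations

* Exact matching assumes the fragment is a perfect genomic substring;
  the distance-1 mode only covers single substitutions.
* The stability proxy is not a free-energy model; its threshold is
  calibrated on shuffle nulls, not thermodynamics.
* PLS-DA VIP approximates OPLS-DA VIP; with more than one response or
  strong orthogonal structure the rankings can diverge.
* The enrichment stage tests user-supplied gene sets only; it does not
  ship curated pathway databases.
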