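# Methods

## Scoring model

The pipeline treats a chemical-genetic screen as two parallel time courses —
a compound arm and a vehicle (DMSO) arm — seeded from one T0 pool, with
technical replicates kept independent throughout (never pooled at the count
level). Scoring proceeds per (compound, timepoint) "screen":

1. **Depth normalization.** Every sample column is scaled to a common target
   depth (default 1e7, counts-per-ten-million). At ~1000x coverage this keeps
   normalized counts at O(10^3), so the pseudocount below is negligible for
   typical guides.
2. **LFC.** Guide abundance vs the T0 baseline,
   `log2((norm + pc) / (norm_T0 + pc))` with pseudocount pc = 1.0 on the
   common-depth scale. Multiple T0 samples are averaged into one baseline
   first. The pseudocount makes the LFC of an unchanged guide exactly 0 and
   keeps zero counts finite.
3. **MA/loess correction.** Treated replicate r is paired with control
   replicate r; M = treated - control and A = their mean. The trend of M on A
   is estimated by a tricube-weighted local linear regression (span 0.4,
   3 robustifying iterations) and subtracted. An alternative equal-width
   binned-median smoother (64 A bins, linear interpolation between bin
   centers) is selectable via `smoother="binned"`; loess is the default.
   Corrected M averaged across replicates is the guide-level CGI.
4. **Gene aggregation and moderated t.** Gene CGI = unweighted mean over the
   gene's guides. The variance prior (d0, s0^2) is estimated per screen by
   moment matching of log s^2 against the log-F distribution implied by the
   hierarchical scaled-inverse-chi-square model, using digamma/trigamma
   moments and a Newton inversion of trigamma; d0 is capped at 1e6 when the
   between-gene spread of log variances does not exceed the chi-square
   sampling floor. With 3 guides the residual df is d_g = 2.
5. **FDR and hits.** BH step-up per screen across the library genes; hits are
   |CGI| > 0.7 and FDR < 0.1, both strict, signed by CGI direction.

### Order of replicate averaging

The treated/control pairing is required before an MA transform is defined, so
the pipeline loess-corrects each replicate pair and then averages corrected M
across replicates. Averaging first and correcting a single pooled pair is the
main alternative reading of the procedure; the pair-then-average order was
chosen because it preserves replicate independence through the correction and
leaves per-replicate diagnostics available.

### Degenerate and edge cases

- Guides with T0 normalized abundance < 30 are excluded from the trend fit
  (they dominate LFC noise) but still receive a correction evaluated at their
  A, and are never dropped from outputs.
- Fewer usable guides than `min_guides_for_fit` (default 30): the trend falls
  back to the global median of M.
- All A identical: the trend is the median of M (no slope is identifiable).
- A screen where every gene has zero guide variance (e.g. treated counts
  literally copied from control) cannot support prior estimation; scoring
  substitutes a point-mass prior with a tiny scale, which yields CGI = 0,
  p = 1 and no hits, with a warning.
- Genes with fewer than two finite guide values are flagged and assigned
  p = 1 rather than silently dropped.
- BH input outside [0, 1], mismatched guide vectors, zero-depth samples,
  missing T0, duplicate identifiers: all raise typed `ValidationError`s.

## Quality control

- **Replicate PCC** over all unordered replicate pairs (AB, AC, BC) of LFC or
  CGI vectors; constant vectors are flagged degenerate rather than scored.
- **Essential dropout AUC**: essential genes are the positive class, ranked
  by -LFC so depletion ranks first, computed via the Mann-Whitney rank-sum
  identity with midranks for ties.
- **WBC**: for screen s, wbc(s) = (r_w - mean(B)) / sd(B) with r_w the mean
  within-screen replicate correlation and B all correlations between s's
  replicates and other screens' replicates. This operationalizes the
  "increase in correlation among replicates relative to non-replicates" idea;
  it is computed on gene-level CGI profiles by default (guide-level input
  works unchanged). Exact agreement with any particular published WBC
  implementation is not claimed.

## Enrichment statistics

- **Fold enrichment** FE = (n/M)/(k/N) with a one-sided (upper)
  hypergeometric p-value; reported as log2 in summaries. The pooled variant
  sums compound-gene pairs across compounds (pairs treated as exchangeable
  draws) and can be restricted to negative/positive hits and to
  essential/non-essential strata.
- **Pathway z-score** z = (x̄ - μ)/(σ/√n) against the library-wide CGI mean
  and sd, two-tailed normal p, BH across pathways, significance flag at
  FDR < 0.1. Invariant to shifting all CGIs by a constant.
- **Over-representation** filters sets to 5-200 genes within the universe,
  hypergeometric p per set, BH, significance at p <= 0.05 and q <= 0.2.

## Benchmarking

- **SNR** = μ/σ with μ the mean |CGI| of gold-standard genes and σ the sd of
  the middle-80% background (CGI between the 10th and 90th percentiles,
  inclusive; 809-810 genes out of 1011). The mean *magnitude* is used because
  a mixed-sign gold set would otherwise cancel toward zero; a signed mode is
  available via `signed=True`.
- **Gold standard**: sign-matched intersection of a screen's hits (union
  across timepoints) with the corresponding genome-wide screen's hits, reused
  across that compound's timepoints.
- **Subset rescoring** re-applies BH at the subset's size on untouched raw
  p-values; the random-library null draws gene subsets without replacement
  and reports empirical_p = (1 + #{null >= observed}) / (1 + iterations).
- **Essential standard**: CERES score < -1 in strictly more than 60% of cell
  lines with data (missing values leave the denominator). All boundary
  inequalities in the package are strict, following the printed signs.
- **Guide support**: per gene, residuals of each guide's replicate-mean
  control LFC to the gene-mean control LFC per timepoint; one sd pooled over
  the gene's guides and timepoints (the pooling scope is a design choice);
  a guide is flagged when its uncorrected differential exceeds that sd at two
  or more timepoints; interactions are multi-guide (>= 2 flagged),
  single-guide (exactly 1), or unsupported.
- **Guide selection**: per gene, pairwise profile PCCs among its guides are
  summed per guide and the top k kept; ties break lexicographically; constant
  profiles contribute correlation 0 with a warning.

## Synthetic screens

The generator emulates the study design: 1011 genes x 3 guides, triplicates,
samples every 3 days to T18, depth 3.03e6 reads per sample (~1000x per
guide). Per guide: a lognormal baseline abundance (log2 sd 0.5, library
representation spread) and a guide-specific fitness offset
(N(0, 0.1) log2/passage, shared across arms, emulating guide efficiency).
Per gene: essential genes (fraction 55/1011, matching the essential-standard
share of the library) drift at N(-0.7, 0.2) log2/passage; non-essential genes
at N(0, 0.15) — a nonzero spread, because the library is by design composed
of genes with variable fitness effects, and a degenerate single-point A
distribution would make the MA trend unidentifiable. Planted CGI effects
(default 50 genes, |δ| uniform in [0.1, 0.4] log2/passage, random sign, on
non-essential genes) add δ per passage in the compound arm only, so the
expected CGI at timepoint t is δ·(t/3). Counts are Gamma-Poisson (negative
binomial) around the depth-scaled relative abundances with dispersion 0.01;
dispersion 0 means noise-free rounded expectations.

The **twofold presets** are definitional fixtures: one non-essential gene's
treated counts equal its control trajectory multiplied by a constant factor
(0.5 or 2.0) at every collected timepoint, with zero guide noise and
noise-free counts, so its true CGI is exactly log2(factor) = ∓1 at every
timepoint. The truth object records this as a constant-effect mode.

What the generator does **not** model: Cas9 cutting kinetics and editing
delays, multiplicity of infection, population bottlenecks at passaging, PCR
jackpotting, copy-number artifacts, or guide-specific off-target effects.
Passing recovery tests therefore demonstrates correctness of the scoring
machinery under an idealized overdispersed-count model, not robustness to
every artifact of real screens.

## Problem sizes used in tests

The test suite and acceptance script run the generator at the full study
design (1011 genes, triplicates, 6 timepoints) for the definitional and
recovery checks — a full pipeline run takes on the order of one second — and
at 20-400 genes for unit-level checks. Oracle comparisons (BH brute force,
hypergeometric enumeration for populations up to 12, moderated-t
transliteration, concordant-pair AUC) use sizes where exhaustive computation
is exact.

## Known limitations

- The loess span (0.4), pseudocount (1.0), target depth (1e7) and
  low-abundance threshold (30) are declared defaults, all configurable; none
  is claimed to match any particular prior analysis run.
- The WBC score and the guide-support sd pooling are operationalizations of
  verbally described procedures; alternatives are noted above.
- Gene symbols are compared case-sensitively after whitespace stripping; no
  alias resolution is attempted.
- The packaged library roster is synthetic (real DDR gene symbols plus
  generated fillers); analyses of real screens should supply the actual
  library table.
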