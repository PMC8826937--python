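# Methods

This note documents the statistical procedures `polyprof` implements, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## The measurement model

A polysome-profiling experiment separates the mRNA–ribosome complexes of a
culture on a 10–50% sucrose gradient, collected as 24 subfractions (top of
gradient first) and pooled into seven fractions A–G by ribosome load.
Fraction A contains free mRNA and free ribosomal subunits; B is the
monosome; successive peaks carry 2, 3, 4, … ribosomes.  Each pooled
fraction of each biological replicate is ribodepleted and sequenced, giving
a read count `N_raw(i, j, k)` for gene `i`, fraction `j`, replicate `k`.

The quantity of interest is the *distribution of a gene's mRNA copies over
ribosome loads*.  Counts are not directly comparable across libraries
because (a) sequencing depth varies, (b) a fixed 10 ng of ribodepleted RNA
is used per library regardless of the ribodepletion yield, and (c) a fixed
5 µg of total RNA enters ribodepletion regardless of how much RNA the
fraction held.  The normalization chain inverts each step:

1. `N_deseq = N_raw / s(j, k)` with `s` the median-of-ratios size factor of
   the library (median over genes, with positive geometric mean across
   libraries, of the count divided by that geometric mean).  Size factors
   are always estimated jointly over the 21 libraries of one growth phase;
   datasets from different phases are never normalized together.
2. `N_ribo = N_deseq × ribodepleted_ng(j, k) / 10`.
3. `N = N_ribo × total_rna_ug(j, k) / 5`.

Per-gene fraction proportions follow as
`p(i, j, k) = N(i, j, k) / Σ_j N(i, j, k) × 100`; each retained
(gene, replicate) profile sums to 100 exactly.  The chain is a composition
of per-library scalar multiplications, so the recovered proportions are
invariant to rescaling any library's counts (the size factor absorbs the
scale) — the property the synthetic round-trip tests exercise.

**Low-count filter.** Genes whose summed count across fractions stays below
10 reads in *every* replicate are excluded before normalization.  The
threshold is the conventional detection limit; applying it to
per-replicate totals rather than single libraries is the least destructive
reading of a total-count rule and is configurable (`scope="total"`
compares the grand sum instead).

**Degenerate profiles.** A gene with zero total signal in one replicate has
no defined proportion there; that replicate is dropped (NaN) with a logged
warning rather than imputed.  Genes with no signal anywhere are removed and
reported.

## Subfraction pooling

Fraction boundaries are derived from the per-subfraction 16S/23S rRNA
quantities.  The leading contiguous run whose 23S/16S ratio falls outside
[1.5, 2.1] — a symmetric window around the ≈ 1.8 ratio of whole ribosomes —
is pooled as fraction A (free subunits shift the ratio).  The remaining
trace of total rRNA (16S + 23S) is smoothed with a centred window-3 moving
average, and block boundaries are placed at its local minima, with plateau
runs of equal values counting as a single minimum at their first position;
this mirrors manual gating between successive polysome peaks on a
Bioanalyzer trace.  Peak blocks 1–4 become B–E.  The heavier material is
pooled into F and G: several remaining blocks are split into two contiguous
groups, a single remaining block is split at its midpoint, and no remaining
material is an error — a trace without enough resolvable structure cannot
support a seven-fraction analysis and is reported as unresolvable rather
than guessed at.

**Ribosome numbers.** A = 0 (untranslated), B = 1 (monosome), C–E = 2–4
(the 2nd–4th peaks).  F and G pool unresolved heavy polysomes, so their
ribosome numbers are extrapolations; the defaults F = 6 and G = 9 are
midpoints of plausible pooled ranges (5–7 and 8–10), always
user-overridable, and every metrics table records the map used.

## Ribosome occupancy and density

`RO(i, k) = Σ_{j=B..G} p(i, j, k) = 100 − p(i, A, k)` is the percentage of
gene `i`'s mRNA copies bound by at least one ribosome in replicate `k`; the
reported RO is the mean over replicates with its sample standard deviation.

**Peak fraction by residual bootstrap.** The peak fraction is the translated
fraction (B..G) with the highest mean proportion, validated against
replicate noise.  Residuals `r(j, k) = p(j, k) − mean_k p(j)` are computed
over all seven fractions and pooled within the gene; each of 1000 bootstrap
profiles adds one residual, drawn with replacement, to each fraction's mean,
and its peak is the argmax over B..G.  Design choices, in order of
consequence:

- *Confinement* is operationalized as the modal peak's relative frequency
  reaching 0.95 over the bootstrap data sets.  Only confined genes receive a
  density; the confinement frequency is always reported.
- One pooled residual is drawn independently per fraction (7 draws per
  profile), the literal reading of pooling residuals and reassigning them to
  fractions at random.
- Bootstrap profiles are *not* renormalized to 100 and negative values are
  *not* clipped: only the argmax is consumed, renormalization cannot change
  an argmax, and clipping could.
- Argmax ties resolve toward the lighter fraction (closer to B), a
  deterministic and conservative rule.  With a finite residual pool the tie
  probability is nonzero — in an exact two-way tie between adjacent
  fractions with 2 replicates the lighter fraction collects roughly 3–4
  percentage points of extra bootstrap mass this way (1/14 tie probability
  on 14 pooled residuals), which the degenerate-case tests account for.
- A single replicate leaves no residuals and is an error; a gene whose
  translated fractions are all exactly zero with zero residuals has an
  undetermined peak and is reported as such.

Per-gene bootstrap streams are spawned from one model-level seed
(`numpy` `SeedSequence.spawn`), making a full fit bit-for-bit reproducible.

**Density.** `RD(i) = ribosomes(peak fraction) / ORF length(i) × 100`
(ribosomes per 100 nt).  With a ribosome footprint of ~30 nt the packing
limit is `100/30 ≈ 3.3` ribosomes/100 nt; genes with RD strictly above the
limit are flagged as outliers and excluded from downstream summaries (the
boundary value itself is retained — the exclusion rule is strict).

## Induction comparisons and qPCR

For a gene measured at low and high transcription, the per-fraction log
ratio is `log₂((p_high + ε) / (p_low + ε))` on the mean profiles, with a
pseudo-proportion ε = 0.1 percentage points guarding empty fractions
(ε = 0 is allowed when all fractions are positive; the base and ε are
recorded in the output).  Negative values in fraction A with positive
values in D–G indicate a shift of mRNA copies toward heavier ribosome
loads.  The RO change is reported as `(RO_high − RO_low)/RO_low × 100`.
The two conditions are normalized separately — they are separate
experiments with separate size-factor structures.

qPCR abundances are computed against constant ERCC spike-ins as
`efficiency^(Ct_spike − Ct_target)` per primer pair, with a perfect-doubling
efficiency of 2 by default (configurable per assay).  Genes measured with
several primer pairs are combined by the geometric mean, the natural
average in the fold-change domain.  Fraction-resolved qPCR abundances are
rescaled by each fraction's total RNA over the 5 µg assay input before
proportions are computed.

## Covariate regression

RO and `log₁₀ RD` are modelled as linear functions of up to 17 gene-level
predictors.  Quantitative predictors (mRNA concentration, ORF length and
GC%, CAI, distance from OriC, GRAVY, 5′UTR length and GC%, TIR folding
energy) are log₁₀-transformed where flagged — by default mRNA
concentration, ORF length, CAI, 5′UTR length — and then centred and reduced
(sample sd), so coefficients are standardized effects.  The log base is
immaterial after standardization.  Qualitative predictors (strand,
essentiality, signal peptide, inner membrane, cell location, COG class,
CsrA target, purine/pyrimidine second 5′UTR nucleotide) enter with
sum-to-zero (deviation) coding: each level's coefficient is its deviation
from the mean of all levels, and reported level coefficients always sum to
zero.  Because RD is defined per unit ORF length, ORF length is excluded
from the RD model.  Genes with any missing value are dropped listwise with
a reported count.

Estimation is ordinary least squares with two-sided t-test p-values, R² and
AIC.  Model selection is stepwise by AIC, starting from the full model and
moving whole predictors (a qualitative predictor's contrast columns move as
a block — individual level columns are not independently meaningful) in
both directions while AIC strictly decreases, with deterministic tie-breaks
by predictor order; the selected model's AIC therefore never exceeds the
full model's.  Single-covariate screening uses Spearman rank correlation
(average ranks on ties) with Benjamini–Hochberg adjustment across the
covariate family.

## The synthetic-data generator

The generator produces datasets with known truth at the experiment's
design scale — 7 fractions × 3 replicates, 300 genes, 50 000 reads per
library by default — for parameter-recovery testing.

- **Profiles.** A gene's true profile puts `100 − RO` in fraction A and
  spreads the translated mass over B..G with a tempered binomial kernel:
  `w_m ∝ Binom(m; 5, p_peak)^(1/spread)`, mode at the true peak fraction.
  `spread = 1` is the plain binomial, `spread → 0` a point mass, larger
  values flatter.  The kernel is a two-parameter stand-in chosen for
  unimodality, not an inference about real profile shapes.  True RO values
  are drawn uniformly on [15, 100], matching the observed range of analysed
  genes; true peaks uniformly over B..G; ORF lengths log-normally around
  900 nt; mRNA abundances log-normally (σ = 0.6).
- **Counts.** Per replicate, each true profile is perturbed by a Dirichlet
  draw with concentration 200 × profile (overdispersion across replicates
  while respecting the sum constraint), each gene's reads are multinomially
  distributed over fractions around the perturbed profile, and each
  library's column is scaled by an arbitrary positive distortion factor.
  The RNA-quantity metadata are emitted consistently with the realized
  preparation: their product is proportional to the median-of-ratios size
  factor of the undistorted count matrix, which is precisely the rescaling
  the chain needs to undo the compositional bias of library-size
  normalization.  An `"expected"` sampling mode emits exact expected counts
  for algebraic (noise-free) round-trip tests.
- **Covariate studies.** Covariates are drawn from log-normal/uniform/
  multinomial distributions with realistic ranges; responses are
  `RO = clip(60 + Xβ + ε, 15, 100)` and `log₁₀ RD = −0.3 + Xβ′ + ε′` with X
  the standardized effect columns and ε ~ N(0, σ).  The default truth has
  five nonzero standardized effects (0.30, −0.25, 0.20, 0.15, −0.10) and
  σ = 0.822, putting the population R² at 0.25 — inside the 0.12–0.27 range
  typical of genome-wide translation-efficiency models, and high enough in
  that range that an 0.1 standardized effect is detectable at n = 800 with
  ~93% power, so sign-recovery rates measure the method rather than
  coin-flip sampling noise.
- **Induction pairs** move a stated share of fraction A into heavy
  fractions via an explicit shift rule and scale mRNA abundance by the
  induction fold, on top of an unperturbed background gene population that
  anchors normalization.
- **qPCR** tables follow `Ct_target = Ct_spike − log_eff(abundance) + noise`.

What the generator does *not* emulate — and therefore what passing
recovery tests do not show about real data: mechanistic translation
(initiation/elongation kinetics, ribosome collisions), sequence-level read
biases and mapping artifacts, rRNA depletion variability beyond a scalar
yield, operon structure (all simulated genes behave as monocistronic), and
real profile shapes beyond unimodality.  In particular, the metadata
consistency that makes the normalization chain exactly invertible is a
statement about the chain's algebra, not about how well measured ng/µg
quantities track true fraction content in a wet-lab experiment.

## Problem sizes and numerical choices

Test-suite and acceptance computations run at the design scale stated
above (300 genes × 21 libraries, 1000 bootstrap data sets; 25 regression
studies of n = 800; 50 stepwise runs), which keeps full runs to seconds
while leaving Monte-Carlo margins comfortably away from the asserted
bounds.  Proportion sums are validated to 10⁻⁶ percentage points; size
factors take the exact median (linear scale) of ratios; OLS is solved by
statsmodels' QR-based least squares, with rank deficiency reported by
naming the collinear columns.

## Known limitations

- Polycistronic genes are out of scope: ribosome load cannot be attributed
  to individual cistrons of an operon; the analysis assumes monocistronic
  input lists.
- The F/G ribosome numbers are configuration, not measurements; RD values
  for genes peaking in F or G inherit that uncertainty (the map is recorded
  with every output).
- Confinement at 0.95 is a selection rule, not an error bar: unconfined
  genes have no RD rather than an uncertain one.
- The regression models are descriptive; coefficients rank associations and
  make no causal claims.
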