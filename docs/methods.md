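# Methods

## The analysis in one paragraph

Endothelial cells are scored along two axes: a cell-cycle axis, derived
from bulk RNA-seq of FACS-sorted FUCCI reporter populations, and an
arterial–venous (AV) identity axis, derived from arterial/venous marker
programs after diffusion imputation. The association between the two —
does a cell's position between early and late G1 predict whether it looks
venous or arterial? — is then quantified with simple linear regression,
supplemented by ANOVA/Tukey and Welch tests for grouped comparisons.
Because the package is developed and validated against synthetic data, a
generator with known ground truth is a first-class component.

## Synthetic-data model

Each cell i carries a latent AV position `a_i ~ Uniform(−1, +1)`
(venous = −1, arterial = +1). Uniform is deliberately the
least-informative choice for a continuum with no known generative model.
Cell-cycle state is categorical over {Negative, Red-G1, Green-S/G2/M} with
softmax logits

```
logit(NEG)   = −β a_i
logit(RED)   = +β a_i
logit(GREEN) = logit(p_green) − β a_i
```

so β > 0 enriches late G1 on the arterial side and early G1 / S-G2-M on
the venous side, and β = 0 decouples state from fate exactly (the null
used for calibration checks). Default β = 1.5, p_green = 0.2.

Gene means are flat across genes at baseline (so every planted effect is
interpretable as a pure fold-change), then modulated multiplicatively:

- arterial program genes: `2^(δ_av · max(a_i, 0))`; venous program:
  `2^(δ_av · max(−a_i, 0))`; TGF genes ride the arterial factor and BMP
  genes the venous factor (the pathway enrichments the analysis should
  recover);
- each of the 100 per-state signature genes gains `2^δ_state` in cells of
  its own state. Defaults δ_av = δ_state = 1 (two-fold).

Counts are negative binomial, `Var = μ + φμ²`, as a gamma–Poisson mixture
around per-cell log-normal size factors (log-mean ln 10⁴, log-sd 0.3).
φ = 0.5 for single cells — typical droplet-data overdispersion, with
dropout arising from low means rather than explicit zero-inflation.
Sorted-bulk samples (3 states × 3 replicates, 10⁶ expected counts each)
use their own dispersion φ_bulk = 0.01: low-input amplified FACS-sorted
replicates are dominated by counting noise and are far less dispersed than
droplet single cells; a droplet-scale φ would make 3-replicate inference
impossible at any depth.

Reporter fluorescence is log-normal per state and channel (low log-mean
1.0, high 4.0, log-sd 0.35 — about 8.6 sd of separation, i.e. nearly
clean gating by default; overlap is tunable through `fluor_logsd`).

A small image fixture (vessel band, disk nuclei, gamma speckle) carries a
ground-truth nuclear-fluorescence fraction computed by direct pixel
summation, for validating the nuclear-localization statistic.

**What the generator does not emulate:** real gene-level mean/dispersion
heterogeneity, ambient RNA, doublets, batch effects, spatial geometry, or
any attempt to match the real datasets' parameters. Passing tests
demonstrate that the pipeline recovers structure it is pointed at under
clean NB noise — not that effect sizes in real retinas look like these.
One consequence of the flat baseline is that all planted genes share the
top expression bins, which makes the module-score control pools slightly
more contaminated by program genes than they would be in real data.

## Stage-by-stage choices

**Gating.** Thresholding is per channel; cells above both thresholds (the
G1/S overlap of FUCCI reporters) map to Green by default because Geminin
is present, with `SEPARATE`/`EXCLUDE` policies available. Automatic
thresholds are the nearest-rank 0.99 quantile of a reporter-negative
control — nearest-rank for determinism. With the default 0.99 quantile
about 2% of truly negative cells fall above one of the gates; that is the
cost of deriving gates from a finite control rather than an oracle.

**Bulk DE and signatures.** log₂(CPM+1) with pseudocount 1 and scale 10⁶;
per-gene one-way fixed-effects ANOVA on the log scale (genes with zero
total variance get F = 0, p = 1; zero within-group variance with
between-group signal gets p = 0); BH step-up q-values implemented directly
from the step-up formula. A gene joins the signature of the state where it
is significant (q < 0.05), strictly maximal in mean, and ≥ 0.5 log₂FC
above the mean of the other two states — argmax assignment makes the
three lists disjoint by construction. This stage deliberately replaces
transcript-level quantification-and-LRT machinery with a transparent
count-level test; the published gene counts from the real data are not a
reproduction target.

**Imputation.** Distances in a 20-component PCA of the log-normalized
matrix (full SVD, deterministic); affinity
`A_ij = exp(−(d_ij/σ_i)²)` over each cell's 15 nearest neighbors with
adaptive bandwidth σ_i = distance to the 4th neighbor; self-affinity 1;
symmetrization (A+Aᵀ)/2; row normalization; exact dense powering with
t = 4. Duplicate cells (σ = 0) get a floored bandwidth with a warning.
Row-stochasticity guarantees convexity (imputed values stay inside the
observed per-gene range) and constant-gene preservation to row-sum
rounding (~1e-15 relative); per-gene variance is non-increasing in t.

**Module scores.** Genes are ranked by mean expression and cut into 24
equal-frequency bins; each signature gene draws 100 controls from its bin,
seeded, without replacement, excluding itself (a signature gene as its own
control would cancel part of its signal by construction). The score is
mean(signature) − mean(pooled control multiset), hence exactly zero when a
set is indistinguishable from its bins and invariant to adding a constant
to the matrix. Cell-cycle and signaling scores run on non-imputed
log-normalized data; only AV scoring consumes the imputed matrix.

**AV scores.** "Relative expression" is the per-gene z-score across cells
(population sd; zero-variance genes contribute 0) on the imputed matrix;
S_art/S_ven are means over the program lists and S_av their difference,
exactly antisymmetric under swapping the lists. The default program lists
lead with canonical markers (Efnb2, Gja4, Gja5, Sox17, Bmx, Jag1, Hey1 /
Ephb4, Nrp2, Nr2f2, Ptgs1, Apoe, Slc38a5). Two variants of the TGF/BMP
lists circulate (a 7-gene TGF / 3-gene BMP set and a longer 8/5 variant);
the shorter set is the default and both ship as named constants.

**Statistics.** OLS is closed-form with a two-sided t on the slope
(n − 2 df). Tukey HSD uses the studentized-range distribution
(`scipy.stats.studentized_range`) with pooled within-group variance and
the Tukey–Kramer SE for unequal n. Welch's t floors zero variances at
1e-12 (with a warning) instead of returning NaN. ΔΔCt and
nuclear-localization are direct formula evaluations with validation.

**Pipeline.** Per-stage seeds are `SHA-256(global_seed ":" stage_tag)`
truncated below 2³¹, so adding stages never perturbs earlier streams.
Gating thresholds inside the pipeline default to the 0.99-quantile rule
applied to the simulated reporter-negative cells (the synthetic analogue
of a negative-control sample). The manifest records the config hash,
derived seeds and SHA-256 checksums of all outputs; identical configs
reproduce identical checksums.

## Problem sizes used in validation

The default study size is 2000 cells × 5000 genes (100 signature genes per
state, 50 arterial, 50 venous, 20 TGF, 20 BMP); one end-to-end run takes
tens of seconds. Multi-seed end-to-end checks in the test suite run at a
ratio-preserving 1000 × 2500 (half-size panels) over 20 fixed seeds, and
the acceptance script reports both a full-size single run and 10-seed
fractions at the reduced size — sizes chosen so the complete validation
remains a minutes-scale computation.

## Known limitations

- **Naive regression on imputed scores is anti-conservative.** Diffusion
  imputation averages each gene over graph neighborhoods, leaving AV
  scores with strongly cross-correlated residuals; the cell-cell graph is
  partly organized by cell-cycle state (the planted state programs shape
  the PCA space), so the state-driven ΔG1 regressor meets cluster-level,
  not cell-level, noise. Under a fully decoupled null (β = 0) the
  per-cell OLS p-values for S_art ~ ΔG1 and S_ven ~ ΔG1 are therefore
  inflated: measured at the default study size, only ~65–70% of null
  seeds give p > 0.05 (instead of the nominal 95%), and fewer at smaller
  sizes. The effect disappears when AV scores are computed without
  imputation, confirming smoothing-induced pseudoreplication as the
  cause. Interpret per-cell p-values on imputed scores as descriptive;
  effect directions and magnitudes remain meaningful, and the coupled
  (β > 0) recovery is unaffected. The acceptance script reports the
  measured null pass fractions rather than hiding them.
- Module-score calibration holds on null data, but when planted programs
  share expression bins the control pools absorb some program signal,
  slightly shrinking scores and (per seed) tilting ΔG1 by whichever
  program genes its controls happen to include.
- The ANOVA DE stage assumes approximately normal log-CPM within state —
  adequate at bulk depth with low dispersion, not a general-purpose
  RNA-seq DE method.
- Gating handles no spectral compensation and no FCS binary parsing;
  inputs are plain intensity tables.
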