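# Methods

## The problem and the model

The pipeline isolates an early hepatocellular-carcinoma (HCC) expression
signature from two dominant confounders of liver transcriptomes —
post-hepatectomy regeneration and ageing — and asks whether that signature
is conserved in independent human case/control cohorts and supported by
genomic copy-number alterations (CNA). The per-gene model on the rat side
is a fixed-effects two-way layout on log2 intensities:

    y_gijk = mu_g + treatment_gi + age_gj + (treatment x age)_gij + e_gijk,
    e ~ N(0, sigma_g^2)

with treatment in {HCC, REG, NORM} and age in {YOUNG, OLD}. Sums of squares
are computed in closed form from cell and marginal means on balanced
designs (where Type I/II/III coincide and the decomposition
SS_treatment + SS_age + SS_interaction + SS_residual = SS_total is exact);
unbalanced designs fall back to Type II model comparison on projection
residuals. Genes with no residual degrees of freedom or zero variance are
reported as missing ("untestable"), never as p = 1 — p = 1 would silently
count as "not DE" in the downstream set logic.

## Signature derivation

**Step 1 — treatment effect plus cross-age template match.** A gene enters
step 1 iff its ANOVA treatment p < 0.01 AND its profile matches the binary
HCC template at p < 0.01 *within both age cohorts, with the same sign*
(the combined p is the maximum of the two cohort p-values; the reported r
is the weaker cohort's). The within-cohort requirement is what makes the
step tumor-specific rather than merely treatment-associated:

- a regeneration-driven gene anti-matches the pooled 24-sample HCC template
  at r = -0.5 in the noise-free limit (p ≈ 0.013 — uncomfortably close to
  the cut), but within a 12-sample cohort r = -0.5 corresponds to p ≈ 0.10
  and never survives;
- a single-age tumor effect matches the pooled template at r ≈ 0.63
  (p < 0.001) but is flat in the other cohort and fails the two-cohort
  requirement.

The template-match p is the exact two-sided t-transform of the Pearson
correlation, t = r sqrt((n-2)/(1-r^2)) with n-2 df, so it is invariant to
affine rescaling of the profile.

**Step 2 — stratified Venn specificity.** Within each age cohort, a gene
enters a pairwise DE set iff it passes the detection/presence rule
(S/N > 3 and quality flag < 5000, strict, in at least half — non-strict —
of either group's samples), a Welch t-test at p < 0.02 (strict), and
|FC| > 1.8 on the linear scale. The HCC-specific set is
(HCC-vs-NORM ∩ HCC-vs-REG) \ REG-vs-NORM; its mirror image defines
regeneration-specific genes. An optional omnibus one-way-ANOVA AND-gate
(off by default) additionally requires the three-group F-test at the same
alpha. Directions come from the HCC-vs-NORM fold change.

**Combination.** Step 1 and the two step-2 sets are unioned; provenance is
kept per gene and direction conflicts are flagged, never dropped. ANOVA
and t statistics act on log2 intensities (variance stabilization); fold
changes are ratios of arithmetic means on the linear scale.

## Conservation, CNA, enrichment, qPCR

**Conservation.** Rat genes translate to human symbols through a
user-supplied ortholog table (first listed target wins; extra rows are
reported, not fatal — multi-mapping is the cross-platform reality).
Per human cohort, DE is a Welch t-test at p < 0.001 (fold-change gate
available, off by default). Overlap significance is the exact upper-tail
hypergeometric probability P(X >= k) with the universe fixed to
ortholog-mapped genes measured on that platform — the universe choice
dominates this p-value, so it is explicit and configurable — and
Bonferroni-adjusted over the number of cohorts. Conservation is
direction-agnostic by default, with a direction-matched mode. Tiers:
conserved-in-any (DE in >= 1 cohort) and shared-by-all (DE in every
cohort); shared_all ⊆ conserved_any always.

**CNA integration.** All coordinates are 0-based half-open; a gene is
copy-number supported iff its locus shares >= 1 base with a CNA interval on
the same chromosome (a minimum-overlap fraction can be required). The
interval-tree search is contract-tested against an all-pairs brute force.

**Enrichment.** Right-tailed Fisher exact (the same hypergeometric kernel
as the overlap test, by construction) and right-tailed binomial at
background rate K/N, per GMT set, no multiplicity correction by default;
the two converge as the universe grows at fixed rate.

**qPCR.** Replicate Ct values are averaged on the Ct scale per
(gene, sample); ΔCt = Ct_target − Ct_reference, ΔΔCt = ΔCt_case −
ΔCt_control, fold = E^(−ΔΔCt) with amplification efficiency E = 2 (one
doubling per cycle; configurable), so log2(fold) = −ΔΔCt exactly and a
global Ct shift cancels. Group-mean ΔCt is the default; a per-subject mode
exists (identical on complete tables). Concordance with the array is the
Pearson r of the paired log2 fold changes with its t-transform p.

## The synthetic study

The generator emulates the study conditions, not any particular dataset:

| parameter | default | meaning |
|---|---|---|
| n_genes | 2000 | desk-scale transcriptome |
| n_per_cell | 4 | replicates per treatment × age cell (24 samples) |
| baseline_log2_mean / sd | 8.0 / 1.5 | log-normal intensity background |
| noise_sd | 0.25 | within-group log2 noise |
| n_hcc_up / n_hcc_down | 30 / 15 | tumor genes, shifted in HCC of both ages |
| n_reg_specific | 25 | shifted in regenerated samples only |
| n_age_only | 200 | shifted in all old samples |
| n_interaction | 25 | shifted in one non-tumor (treatment, age) cell |
| effect_log2 | 2.0 | planted shift (4-fold); a per-gene range is available |
| detection_dropout_rate | 0.05 | per-cell Bernoulli loss of detectability |
| human cases / controls | (19,16,20) / (10,19,10) | three case/control cohorts |
| conservation_fractions | 0.5 each | P(tumor gene is DE in cohort d) |
| human_noise_sd | 0.5 | log2 noise in human cohorts |
| cna_cover_fraction | 0.5 | fraction of tumor genes inside CNA regions |
| ct_noise_sd | 0.2 | per-replicate Ct noise (cycles) |

Planted class counts follow roughly the proportions a ~27k-gene liver
study reports, rescaled to 2000 genes (tumor ≈ 2%, age ≈ 10%,
interaction ≈ 1%). Noise is Gaussian on the log2 scale (log-normal
intensities); no noise model is canonical here and this is the standard
neutral choice. Detection dropout is independent Bernoulli per cell —
thresholds are specified by the platform but a missingness mechanism is
not, and independence is the simplest calibratable one. Undetected cells
keep their intensities; the filters act at the gene level.

Interaction-class genes perturb exactly one *non-tumor* cell (REG or NORM
× one age). They emulate age-modulated regeneration/normal-liver biology;
an interaction planted inside an HCC cell would instead be an age-specific
tumor gene — a pattern the stratified Venn step is designed to *include*
— and would make "signature specificity against the interaction class"
self-contradictory as a test.

Human cohorts are generated directly on the human symbol namespace after
ortholog mapping, so rat genes without an ortholog are untestable
downstream by construction, matching cross-platform reality. CNA intervals
cover exactly the loci flagged in-CNA (padded by a margin that is halved
until no non-flagged locus is touched), so the copy-number-supported
fraction is exact geometry, not an estimate. Ct tables plant
Ct_case − Ct_control = −effect_log2 for targets and 0 for the reference.

**What the generator does not emulate:** probe-level chemistry, spatial or
batch artifacts, correlated gene modules, intensity-dependent variance,
non-independent dropout, or background DE in the human cohorts beyond the
planted conservation pattern. Passing recovery tests therefore shows the
procedure is correct and calibrated under its stated model — not that it
would achieve the same sensitivity on real arrays.

## Numerical and design choices

- Strict inequalities for every quoted "<"/">" threshold; "at least half"
  is non-strict. Degenerate limits: zero within-cell variance with a real
  effect reports p → 0; a fully constant gene is untestable (missing).
- log2 transform applies a floor (default 1.0) before the logarithm, which
  also guarantees positive group means for fold changes.
- Quantile normalization (optional, on by default) is the neutral
  platform-independent stand-in for array normalization; ties receive the
  mean of the quantile values they would occupy.
- Clustering: distance 1 − Pearson r, average linkage, items in input
  order (deterministic ties); PCA on gene-centered data via SVD.
- Hypergeometric/binomial tails come from scipy's exact survival
  functions; both are oracle-tested against integer enumeration and
  explicit partial sums.
- Problem sizes in the tests and acceptance script (2000 genes, 5–20 seeds
  per Monte Carlo property, 100 null seeds for the conservation null) were
  chosen so each property has clear resolution at its stated bound while a
  full run stays in the tens of seconds.
- Determinism: every generator output is a pure function of (params, seed);
  independent substreams per generator stage; result bundles are
  serialized deterministically and manifest checksums are asserted
  bit-identical across reruns.

## Known limitations

- The two-way ANOVA is fixed-effects only; no moderated/shrinkage variance
  (deliberately out of scope — the procedure under study uses raw per-gene
  tests), so very-low-replicate designs inherit the usual instability.
- Raw p-value cuts throughout the rat-side derivation (no multiplicity
  correction), mirroring the procedure being implemented; Bonferroni is
  applied only where it applies it (cross-cohort overlap tests).
- Per-gene cross-dataset p-values are not computed — only the list-level
  overlap test; a per-gene meta-analysis would need a different model.
- The ortholog table is taken at face value (first-target-wins); no
  sequence-level orthology inference.
- The probe→gene collapse rule (max mean intensity) available in the IO
  layer is a convention, not a modeled choice.
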