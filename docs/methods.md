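# Methods

This note documents the models, numerical choices and defaults behind
`sccmet`, in the order the pipeline runs them.

## Natural-abundance correction (`sccmet.isocorr`)

A measured isotopologue vector C(m+0) … C(m+n) of a metabolite with n_C
tracked carbons and n_N tracked nitrogens (n = n_C + n_N) mixes tracer
labelling with naturally occurring heavy isotopes. The correction matrix M
has entries M[j, k] = P(observed shift j | k tracer atoms), built from
independent binomials over the remaining unlabelled atoms, convolved:
a molecule with k tracer atoms has max(n_C − k, 0) carbons free to carry
natural ¹³C (probability p₁₃) and n_N − max(k − n_C, 0) nitrogens free to
carry ¹⁵N (p₁₅). Tracer atoms are attributed to carbons first, which is
exact for pure ¹³C tracers and for the single-nitrogen dual-tracer
metabolites modelled here. Because the observation window spans all tracked
atoms, every column of M sums to one.

Defaults: p₁₃ = 1.07 %, p₁₅ = 0.364 % (IUPAC representative values), both
configurable. Only heavy isotopes of C and N are modelled; O/H/S and
derivatization-agent atoms are excluded — the enrichment equations operate on
the metabolite skeleton after peak integration, and positional NMR data are
passed through uncorrected (`enrich_table(..., correct=False)`).

The inverse problem M·f ≈ raw/Σraw is solved by **non-negative least
squares**, not matrix inversion: inversion turns measurement noise into
negative abundances, while NNLS keeps f ≥ 0 by construction; f is then
renormalised to sum to one. On noise-free inputs the convolve→correct round
trip is identity to < 1e-8 (the acceptance script measures ≈ 1e-16).

Two enrichment readouts follow. Per isotopologue,
Enrichment(m+x) = C(m+x) / Σₖ C(m+k) × 100 %. Per molecule, the percent of
carbons enriched is the abundance-weighted mean number of labelled carbons
over the skeleton, ¹³C_met = Σₓ x·f(m+x) / n_C × 100 — the only reading of
"% carbons enriched" bounded by 100 %. Dual-tracer MIDs index nominal mass
shift; before computing ¹³C_met they are marginalised to carbon shifts by
attributing shifts beyond n_C to the nitrogen label (`carbon_marginal`).
This is exact whenever mixed C+N patterns at low shifts are rare; when the
joint label state is available (forward model), `LabelState.carbon_mid`
gives the exact carbon marginal instead.

## Atom-transition model (`sccmet.tracer`, `networks/core.yaml`)

The forward model is a **single-pass ("first turn") exact enumeration**: the
joint distribution of per-atom labels of each metabolite (≤ 6 C + 1 N, so at
most 128 patterns) is computed in topological order through a validated
atom map. Route weights are mixing fractions; atoms mapped from the same
substrate within a route share one substrate molecule (preserving
within-molecule correlations), distinct substrates are independent, and
scalar pools (CO₂, default unlabelled) are independent Bernoulli atoms.
Succinate and fumarate get a 50/50 atom-order randomisation for their
two-fold symmetry; citrate prochirality is ignored (MIDs are invariant, and
positional claims are made only for glutamate C4, lactate C3 and ribose C1).

First-turn semantics — rather than isotopic steady state — keeps the model
exact, enumerable and faithful to how tracer fates are read off pathway
diagrams: U-¹³C-glutamine yields citrate m+4 through the oxidative route
(OAA + unlabelled acetyl-CoA) and m+5 through reductive carboxylation
(αKG + CO₂); ATP-citrate-lyase cleavage of that m+5 citrate releases m+3
oxaloacetate, hence m+3 malate/fumarate; GOT transamination adds the ¹⁵N of
glutamate to the aspartate skeleton (m+4 → m+5). Multi-turn Krebs cycling is
out of scope. One consequence of forbidding cycles: the measured glutamate
pool derives from glutamine under the glutamine tracers but from
citrate-derived αKG (one oxidative turn) under the glucose tracer; the
built-in network encodes this with per-tracer route filters.

Mixing fractions (`PathwayParams`, all in [0, 1]): f_glc and f_gln (labelled
source-pool fractions), f_pdh (acetyl-CoA from pyruvate), f_pc (OAA from
pyruvate carboxylation), f_ox with f_red = 1 − f_ox (oxidative vs reductive
citrate), f_ser (de-novo serine), e_shmt (serine C3 exchange with the
one-carbon pool), t_got (aspartate amino-N from glutamate), t_psat (de-novo
serine amino-N from glutamate; the nitrogen is routed through PSAT with the
pool share exposed because the donor group is not observable from MIDs
alone), f_gsh (glutathione glutamyl from the glutamate pool), f_acl
(readout OAA/malate pool returned by citrate cleavage; default 0 so the
reductive signal lives in citrate unless the cleavage route is switched on),
and p_co2 (CO₂ pool labelling, default 0). Defaults (e.g. f_gln = 0.8,
f_ox = 0.8) are typical of tumour tissue-slice labelling experiments; the
synthetic generator's tissue presets plant f_red = 0.1 in NC and 0.3 in SCC.

`fit_fractions` / `TracerPathwayModel.fit()` estimates named fractions from
observed MIDs by bounded least squares (residuals stacked over replicates,
x₀ = 0.5, bounds [0, 1], tolerances 1e-12). **Identifiability** is checked
by profiling each free parameter over {0, 0.25, 0.5, 0.75, 1}: if the
residual norm varies by < 1e-10 the parameter is reported non-identifiable
(standard error NaN) instead of silently returning the starting value — the
canonical case being f_red when citrate is missing from the observed set and
the cleavage route is off. Standard errors otherwise come from the
Gauss-Newton covariance s²(JᵀJ)⁻¹.

An independent Monte-Carlo molecule sampler (`sccmet.tracer_mc`) draws
individual molecules through the same atom map with fresh substrate draws
per product molecule; enumeration and sampler agree within 3 SE per MID
entry at 10⁵ molecules. (With several hundred simultaneous entries the
largest |z| occasionally grazes 3 by chance; the acceptance script reports
the observed maximum rather than truncating it.)

## Synthetic cohorts (`sccmet.simulate`)

Expression: per-gene log2 baselines ~ U(6, 12); i.i.d. Gaussian log2 noise
(default SD 0.4, a typical per-gene spread for microarray intensity data);
planted log2 shifts of +1 on the 24 signature genes and the 5 Notch targets
in SCC samples only; default group sizes 65/45/27 (NC/AdC/SCC). Gene-gene
correlation is off by default; an equicorrelated Notch block (ρ = 0.5) is
available to emulate co-regulation. The generator does **not** emulate
probe effects, batch effects or RNA-seq count distributions — passing tests
show the selection machinery recovers planted structure under Gaussian
noise, not that it is robust to platform artefacts.

Tracer data: per subject, paired tumour and NC tissues; true MIDs from the
forward model per tissue's parameter preset, then natural-abundance
convolution, a shared per-subject intensity intercept (log2 SD 0.2, so
paired tests have subject-level variation to remove), and multiplicative
log-normal noise per isotopologue (CV 0.05 by default, mean-one
parameterisation). Ground truth (parameters and true MIDs) is retained on
the returned dataset object.

## Signature selection (`sccmet.signature`)

Expression is normalised gene-wise to the NC median (genes with
non-positive NC median dropped with a warning) and log2-transformed before
clustering and PCA — the scale on which over- and under-expression are
symmetric. Clustering uses the Eisen-Cluster defaults (uncentred
correlation distance, average linkage; zero-norm rows are guarded with
similarity 0), with flat clusters from a k = 8 tree cut (configurable; the
relevant structure is "the SCC-up clusters among a handful"). PCA is
mean-centred SVD over samples; R2X per component is its variance share and
loadings are unit-norm.

The three criteria: (1) |loading| in the top quartile (q = 0.25,
configurable) on PC1 or PC3 — the components separating cancer from NC and
SCC from AdC; (2) membership in a flat cluster whose SCC centroid exceeds
both NC and AdC centroids; (3) Tukey HSD SCC-vs-NC p (studentized-range
distribution at the ANOVA residual df, Tukey-Kramer for unequal n) scaled by
the Bonferroni factor for the number of genes, < 0.05, with the SCC mean
above NC. Benjamini–Hochberg is available as an alternative adjuster. The
signature is the intersection; per-gene flags are reported so near-misses
are visible. The per-gene screening uses a vectorised studentized-range
evaluation that is exactly the per-gene Tukey computation (asserted in the
tests).

Scoring: mean log2 ratio over signature genes; the upper-tertile flag marks
scores at or above the 67th percentile with midpoint interpolation (n = 9
flags exactly 3 — stated for bit-reproducibility). Cross-cohort overlap
(`overlap_top_genes`) takes the top 5 % of each ranked list and keeps genes
present in ≥ 3 lists.

## Notch calling (`sccmet.notch`)

"Overexpressed by 1 SD of the NC's median" is implemented as value >
NC median + sd_mult·SD on the NC-median-normalised scale, strict inequality,
sample SD with ddof = 1; scale ("ratio" vs "log2"), sd_mult and k are all
configurable since the construction admits several readings. "4 of 5" is
read as ≥ 4. The calibration null is per-gene Gaussian with the fitted NC
median/SD, genes independent — the simplest null consistent with the
thresholding construction (correlated nulls can be simulated via the cohort
generator). Under that null each gene exceeds its threshold with probability
1 − Φ(sd_mult) = 0.1587 at sd_mult = 1, giving the exact Poisson-binomial
tail α = P(X ≥ 4) ≈ 0.00277 for the default rule; the Monte-Carlo twin
converges to it. A published α of 0.046 has been quoted for an equivalent
rule without a stated derivation; it is not reproducible from the rule plus
an independent-Gaussian null (which gives ≈ 0.0028) and numerically equals
3/65, consistent with an empirical false-positive fraction in a 65-sample
NC cohort — this package therefore reports α only under its own explicit
nulls. Association of calls with histotype uses the exact hypergeometric
test for 2×2 tables and the Freeman–Halton enumeration for 2×3 (validated
against R's `fisher.test`), with the Pearson χ² and df reported alongside.

## Statistics (`sccmet.stats`)

All tests are two-tailed. Tumour vs matched NC: paired Student's t
(zero-variance differences flagged, p = 1 for identically zero differences).
AdC vs SCC: Welch t with Satterthwaite df on per-subject log2(tumour/NC)
ratios — the base cancels in the statistic. Gene screening: one-way ANOVA
with Tukey HSD from the studentized-range distribution (no simulation
fallback), then Bonferroni across genes, capped at 1. Benjamini–Hochberg
step-up is provided for FDR control. Pairs with a missing member are
dropped listwise with a logged count. qPCR relative expression uses
2^−ΔΔCt against a reference gene and a control-group mean ΔCt.

## Problem sizes and reproducibility

The validation suite uses the cohort sizes above (65/45/27 × 360 genes,
20 seeds for recovery medians), 10 paired subjects per tracer fit, 10⁵
molecules for the Monte-Carlo cross-check and 10⁴ replicates for type-I
calibration — sizes at which every check runs in seconds to a couple of
minutes on one CPU while keeping Monte-Carlo error well below the decision
margins. All generators and simulations are deterministic given their
seeds; the CLI's `run-all` derives per-stage seeds from one root seed and
its outputs are byte-identical across reruns.

## Known limitations

- First-turn label propagation cannot represent multi-turn Krebs isotope
  spreading or exchange fluxes; it is not a ¹³C-MFA replacement (no
  EMU/cumomer steady-state estimation, no compartmental pools).
- The natural-abundance model covers C and N only; metabolites measured as
  TMS/TBDMS derivatives with significant Si/O contributions need the raw
  vectors pre-reduced to skeleton shifts.
- The measurement-side carbon marginalisation of dual-tracer MIDs attributes
  super-carbon shifts to nitrogen; metabolites with several exchangeable
  nitrogens would need the joint model.
- The Gaussian calibration null ignores inter-gene correlation of the Notch
  targets; with strong co-regulation the realised false-positive rate of the
  k-of-n rule exceeds the independent-null α.
- Signature selection statistics are computed on log2 NC-median ratios and
  assume roughly homoscedastic noise; heavy-tailed platform artefacts are
  not modelled by the generator and hence not covered by the recovery tests.
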