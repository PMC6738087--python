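# sccmet

Lung squamous cell carcinomas (SCC) and adenocarcinomas (AdC) reprogramme
their metabolism in different directions, and that difference is visible both
in the expression of central-carbon-metabolism enzymes and in how the tumours
route ¹³C-glucose and ¹³C/¹⁵N-glutamine through their pathways. `sccmet` is a
toolkit for the three computational analyses such studies rest on:

1. **Metabolic gene-signature derivation.** From a genes × samples cohort
   (NC / AdC / SCC tissue classes), enzymes are filtered by catalytic GO
   function and metabolic process class, normalised to the NC median,
   clustered (Eisen defaults: uncentred correlation, average linkage), and
   decomposed by PCA. A gene enters the SCC-distinguishing signature when it
   (1) carries a top-quartile loading on PC1 or PC3, (2) sits in a gene
   cluster whose SCC centroid exceeds both NC and AdC, and (3) is
   significantly overexpressed in SCC vs NC (one-way ANOVA + Tukey HSD,
   Bonferroni-scaled across genes). Samples are scored by the mean log₂
   ratio over signature genes with an upper-tertile flag.

2. **k-of-n Notch-activity calling.** A sample is Notch-active when ≥ k of n
   target genes (HES1, HES2, HEY1, HEY2, NRARP; k = 4) exceed per-gene
   thresholds set at the NC median + 1 SD of NC-median-normalised
   expression. The rule's false-positive probability α under an explicit
   independent-Gaussian null is computed exactly as a Poisson-binomial tail
   P(X ≥ k), cross-checked by Monte Carlo, and calls are tested for
   association with histotype by exact contingency tests (Fisher for 2×2,
   Freeman–Halton for 2×3).

3. **Stable-isotope-resolved metabolomics (SIRM).** Raw mass-isotopologue
   intensities are corrected for natural ¹³C/¹⁵N abundance by non-negative
   least squares against an analytic correction matrix; enrichment is
   reported per isotopologue, Enrichment(m+x) = C(m+x) / Σₖ C(m+k) × 100 %,
   and per molecule, ¹³C_met = Σₓ x·f(m+x) / n_C × 100. A built-in
   atom-transition network propagates tracer label exactly (no sampling)
   through glycolysis, serine/glycine + SHMT exchange, the oxidative pentose
   phosphate branch, PDH/pyruvate-carboxylase entry, one oxidative Krebs
   span, oxidative vs reductive glutamine-to-citrate routes (m+4 vs m+5
   citrate), ATP-citrate-lyase cleavage, GOT transamination (aspartate
   m+4/m+5) and glutathione glutamyl incorporation. The inverse problem —
   e.g. estimating the reductive-carboxylation fraction `f_red` — is solved
   by bounded least squares with an explicit identifiability report.

A synthetic-data module generates expression cohorts and paired tumour/NC
tracer experiments with known planted structure, so every stage can be
validated against ground truth at desk scale.

## Worked example

```python
import numpy as np
from sccmet import (CohortSpec, SignatureModel, NotchModel,
                    generate_expression_cohort)
from sccmet.simulate import generate_annotation
from sccmet.signature import normalize_to_nc_median

spec = CohortSpec(seed=3, noise_sd=0.5)          # 65 NC / 45 AdC / 27 SCC
cohort = generate_expression_cohort(spec)
res = SignatureModel(cohort, generate_annotation(spec)).fit()
print(res.summary())

ratios = normalize_to_nc_median(cohort)
notch = NotchModel(ratios, cohort.tissue, n_sim=20_000, seed=1).fit()
print(notch.summary())
```

prints

```
Metabolic gene-signature selection
=============================================
genes after enzyme filter: 328
PCA: R2X[1]=6.2%, R2X[2]=1.9%, R2X[3]=1.8%
criterion1 (loadings):  141
criterion2 (clusters):  95
criterion3 (Tukey+adj): 29
selected (intersection): 29
---------------------------------------------
ALDOC, GAPDH, TPI1, PGAM1, G6PD, TALDO1, CTPS1, GMPS, UMPS, PAICS, PSAT1,
SHMT2, MTHFD2, AHCY, GCLM, GGH, GSS, GOT2, IDH2, MDH2, ME1, CKMT1, BDH1,
ASNS, HES1, HES2, HEY1, HEY2, NRARP
Notch k-of-n activity calling
=============================================
rule: >= 4 of 5 targets above NC median + 1.0 SD (ratio)
targets: HES1, HES2, HEY1, HEY2, NRARP
alpha (analytic Poisson-binomial): 0.00277
alpha (Monte-Carlo, se 0.00036): 0.00260
samples called active: 21 / 137
association with histotype: exact p = 1.024e-19, chi2 = 101.044, df = 2
```

All 24 planted signature genes are recovered (the five co-elevated Notch
targets are picked up alongside them, since they satisfy the same three
criteria by construction); the 4-of-5 rule fires on 21 of 27 SCC samples at
this noise level and essentially never on NC lung, matching its analytic
α ≈ 0.0028.

The full pipeline — simulation, signature, Notch, natural-abundance
correction, pathway-fraction fitting, paired/Welch statistics — also runs
from the shell:

```bash
sccmet run-all --seed 1 --out results/run1
```

and is byte-identical on rerun with the same seed.

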