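# Methods

## Scope and data model

The package analyses taxon-by-sample tables of non-negative integer
read counts (OTU or genus level) with rank-labelled lineages
(`p__…;f__…;g__…`) and per-sample metadata: subject, arm (FMT /
placebo / donor), week, site (fecal / pouch / ileum), relapse week and
antibiotic fields.  Counts are never rarefied; all metrics operate on
raw counts or per-sample fractions.

Two inclusion filters define the analysis set, applied rarity-first:

1. taxa whose dataset-wide relative abundance (taxon total over the
   grand total) is strictly under 0.001% are discarded;
2. samples with strictly under 10,000 reads are excluded.

Both thresholds read "under" as strict, so boundary cases are retained.
The rarity filter's scope (dataset-wide vs within-sample) is genuinely
ambiguous in tools of this kind; dataset-wide is the default and a
`rare_filter_scope="sample"` switch zeroes sub-threshold cells instead.
The two filter orders differ on real inputs (a sample can fall below
10,000 reads only after losing rare taxa); rarity-first is the default
because rare-read removal belongs to upstream read processing.

## Engraftment quantification

For each patient, OTUs present in the donor samples but absent from the
patient's baseline sample form the *transferable* set — the denominator
of engraftment.  Presence is count ≥ `min_count` (default 1, after the
global rarity filter).  Donor presence pools the six donor samples by
union (`donor_rule="any"`, default) or intersection (`"all"`); the
choice changes the denominator and both are reported in the sensitivity
analysis.  At each follow-up week the transferable OTUs detected in the
patient are *donor-derived*; the engraftment fraction is their
percentage of the transferable set.  Patients with no transferable OTUs
yield an undefined fraction, which is excluded from group means rather
than counted as zero.  Samples taken after a patient's relapse are
excluded throughout (the week-of-relapse sample is retained; both rules
are configurable).  Engraftment runs at OTU level by default since set
membership is diluted by aggregation; a rank argument allows
genus-level sensitivity checks.

Because presence is estimated from finite sequencing depth, the
measured fraction has a predictable background: an OTU present in the
patient at baseline but unseen at that depth is mis-counted as
transferable and later "detected".  In the placebo arm this background
is under ~1% at the default ~45,000-read depth.  The test suite carries
a depth-marginalised oracle — P(counted transferable) ×
P(detected), computed from the generator's true compositions via
1 − (1 − π)^d — and requires the measured mean to match it.

## Dissimilarity to the donor

Bray-Curtis on genus-level per-sample fractions,
BC = 1 − 2Σmin(xᵢ,yᵢ)/(Σxᵢ+Σyᵢ), averaged over the six donor samples
("average of pairwise distances"; the alternative reading, distance to
the mean donor profile, is available as `donor_reference =
"profile_mean"`).  Arm-by-week means over non-excluded patients form
the trajectory; the week-4 FMT-vs-placebo contrast uses the rank-sum
test, the two arms being independent groups.

## Ordination and permutation tests

*PCoA*: double-center −½D², eigendecompose, scale eigenvectors by
√λ.  Negative eigenvalues (usual for Bray-Curtis) are dropped with a
warning — no Lingoes/Cailliez correction, since only the leading axes
are interpreted.  Axis signs are fixed by making the largest-magnitude
loading positive; `prop_explained` is relative to the positive
eigenvalue sum.

*PERMANOVA* (one-way): SS_total = Σ_{i<j} d²ᵢⱼ/n, SS_within from
within-group pairs scaled by group size, pseudo-F with (a−1, n−a)
degrees of freedom, R² = SS_between/SS_total.  The null permutes group
labels: exhaustively over all distinct arrangements when their number
is ≤ `n_perm` (p is then the exact tail fraction, minimum 1/N), else
Monte Carlo with the add-one estimator (1+k)/(1+n_perm) so p is never
0.  Permutations are generated over samples in sorted-id order, making
the p-value invariant to the input ordering and to group relabelling.

*Dispersion homogeneity*: samples are embedded by PCoA (positive axes),
each sample's Euclidean distance to its group centroid is computed, and
a one-way ANOVA F over those distances is permuted.  Group centroids
(not spatial medians) are used — a simpler, documented divergence from
the spatial-median option some implementations default to.

## Rank statistics and FDR

Rank-sum, signed-rank and Kruskal-Wallis are implemented directly:
average ranks for ties; exact enumeration of the full permutation
distribution (all C(n, n₁) rank assignments, all 2ⁿ sign patterns) when
the pooled size is ≤ 12; otherwise the normal approximation with tie
and continuity corrections (chi-square for Kruskal-Wallis, with tie
correction).  Two-sided exact p-values count arrangements whose
statistic deviates from its null mean by at least the observed amount.
Degenerate inputs (all values tied, all differences zero) return p = 1
with a warning.  Benjamini-Hochberg q-values use the step-up rule with
monotonicity enforcement.  Per-taxon group tests run on per-sample
fractions with a prevalence filter (default: present in ≥ 10% of
samples) to stabilise the ranks; significance requires p < 0.05 and
q < 0.05.  One defined nonparametric procedure is used for every taxon
rather than per-taxon model selection among count models; results are
comparable in kind (statistic, p, q, fold change) but not numerically
to offset-based model fits.  Fold changes use a pseudo-fraction of half
the smallest nonzero observed fraction.

## Synthetic cohort generator

The generator is the package's ground-truth instrument, emulating a
single-donor FMT trial in chronic pouchitis:

- **Design**: 26 patients randomised 1:1 (FMT vs placebo), one donor
  with 6 longitudinal samples, fecal samples at weeks 0/4/12/26/52,
  pouch and ileum biopsies at weeks 0 and 52.
- **Donor**: log-normal proportions (σ = 0.8) over 300 taxa, rescaled
  so Proteobacteria < 1% and Bacteroidetes ≈ 17% of mass — a healthy,
  high-diversity profile.
- **Patient baselines**: 35% of donor taxa zeroed (creating the
  donor-only pool engraftment bookkeeping relies on), a patient-private
  bloom (60 taxa from a shared pool of 150, mostly Gammaproteobacteria
  families, 35% of pre-boost mass, σ = 2.2), Proteobacteria multiplied
  by exp(dysbiosis_strength) (default 2.0), log-normal inter-patient
  jitter (sd 0.3).  These settings jointly guarantee the constructed
  contrast the analysis assumes: the donor's inverse Simpson exceeds
  every patient's whenever dysbiosis_strength ≥ 1.
- **Engraftment**: each donor-only taxon transfers independently with
  probability e; post-treatment composition is
  (1−e)·baseline + e·donor restricted to transferred taxa, renormalised,
  with per-taxon log-normal temporal jitter (sd 0.35).  Placebo uses
  e = 0.  This mixture-with-Bernoulli-transfer model is the minimal
  construction that makes e a recoverable parameter while producing
  decreasing dissimilarity to the donor and partial OTU transfer; it is
  a modelling choice, not a mechanistic claim.  Default e = 0.3, chosen
  once so the emergent week-4 donor-derived percentage (~31%) sits at
  the level reported for this kind of single-donor pouchitis cohort.
- **Relapse**: after a patient's relapse week the composition reverts
  to baseline with Gammaproteobacteria-family taxa multiplied by 3
  (the antibiotic perturbation).  `SimConfig.relapse_schedule` is an
  explicit subject→week map (default empty); `study_relapse_schedule`
  draws the study-shaped version (~70% of patients relapse, mirroring
  the small non-relapsed fraction in such trials).
- **Sequencing**: depth ~ NegBin(mean 45,000, dispersion 2.5) —
  matching a fecal mean of ~45k reads with sd ~28k and putting ≈ 4.7%
  of samples under the 10,000-read filter so the inclusion logic is
  exercised — then multinomial counts.
- **Mucosa**: pouch and ileum samples are re-jittered copies of the
  luminal composition (sd 0.35); no site effect exists by default, so
  site contrasts are null under the generator.
- **Determinism**: every stream is keyed by (master seed, CRC32 of the
  subject/sample id, purpose tag); outputs are pure functions of the
  config, and adding patients never reshuffles existing ones.

What the generator does **not** emulate: strain-level transfer,
compositional zero-inflation beyond multinomial sampling, batch or
primer effects, diet/probiotic covariates, true site-specific mucosal
biology, and temporal autocorrelation beyond the shared baseline.
Passing tests therefore demonstrate correctness of the estimators under
a known mixture model, not robustness to every artefact of real 16S
data.

## Problem sizes and numerical choices

The test suite runs null calibrations at 1,000 PERMANOVA datasets
(n = 12, 199 permutations), 2,000 rank-sum null draws, 50 null taxon
families, and 30-seed cohort sweeps (40 patients for rate recovery, 26
for the arm contrast) — sizes at which the binomial error of the
checked proportions is well inside the asserted bands.  Floating-point
tolerances: oracle equivalence at 1e-8; column normalisation at 1e-12.
Ties in ranks use average ranks everywhere; permutation p-values use
the add-one estimator except under exact enumeration.

## Known limitations

- PERMANOVA is one-way only; factors are tested one at a time, with the
  dispersion check reported alongside (a significant dispersion
  difference can masquerade as a location effect).
- Bray-Curtis is not metric; PCoA drops negative eigenvalues rather
  than correcting them.
- The engraftment denominator is sensitive to sequencing depth at
  baseline; the background quantified above should be subtracted
  conceptually when interpreting small fractions.
- BIOM/HDF5 inputs and phylogeny-aware distances are out of scope; the
  interchange format is TSV with rank-prefixed lineage strings.
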