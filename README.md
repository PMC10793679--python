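# pouchtrack

Longitudinal microbiota analysis for fecal microbiota transplantation
(FMT) trials, built around the analysis design of a single-donor,
placebo-controlled FMT trial in chronic pouchitis: quantify donor
engraftment from OTU presence/absence, track each patient's
dissimilarity to the donor over a year of follow-up, and test which
clinical factors structure the community — all on taxon-by-sample count
tables, with a synthetic cohort generator that provides ground truth
for every stage.

It is aimed at microbiome researchers analysing 16S amplicon count
tables from longitudinal FMT or other intervention studies, and at
methodologists who want a testable, fully synthetic stand-in for such a
cohort.

## What it computes

**Engraftment by OTU set logic.** For patient *p* with baseline (pre-FMT)
sample *b* and donor samples *D* = {d₁…d₆}, the *transferable* set is

    T_p = { OTU t : t present in D (any/all rule) and absent in b }

and at follow-up week *w* with sample *s* the *donor-derived* set is
T_p ∩ present(s).  The engraftment fraction is 100·|T_p ∩ present(s)| / |T_p|.
Presence means count ≥ 1 (configurable).  Samples taken after a
patient's relapse are excluded; the week-of-relapse sample is retained.

**Dissimilarity to donor.** Genus-level Bray-Curtis
BC(x, y) = 1 − 2·Σᵢ min(xᵢ, yᵢ) / (Σᵢ xᵢ + Σᵢ yᵢ) on per-sample
fractions, averaged over the six donor samples, per patient and week.

**Community statistics.** Inverse Simpson diversity 1/Σ pᵢ²; PCoA
(classical scaling of the Bray-Curtis matrix); one-way PERMANOVA
(pseudo-F on distance variance partitions, label-permutation null,
exact enumeration on small designs) with a distance-to-centroid
dispersion homogeneity check; Wilcoxon rank-sum / signed-rank and
Kruskal-Wallis with exact small-sample enumeration; Benjamini-Hochberg
FDR across per-taxon families.

**Inclusion filters.** Taxa under 0.001% dataset-wide relative abundance
are discarded, then samples under 10,000 reads are excluded; both
thresholds are strict.

**Synthetic cohorts.** `SimConfig`/`generate_cohort` emulate the trial:
one high-diversity donor sampled six times, 26 patients with dysbiotic
Proteobacteria-enriched baselines, fecal sampling at weeks 0/4/12/26/52,
pouch and ileum biopsies at weeks 0 and 52, relapses with an antibiotic
perturbation, multinomial sequencing at negative-binomial depth.  Each
donor-only OTU transfers to an FMT patient independently with
probability *e* (the engraftment rate), so *e* is a recoverable ground
truth.

## Worked example

```sh
python analysis/01_simulate_cohort.py     # writes results/cohort/
python analysis/03_donor_trajectories.py
python analysis/04_engraftment.py
```

prints (seed 1):

```
week-4 contrast: FMT mean 0.566 vs placebo 0.744 (rank-sum p = 1.6e-05)

donor-derived OTU percentage (mean +/- sd of the transferable set):
       FMT wk 4:  31.5% (sd 4.2, n=13)
       FMT wk12:  31.4% (sd 4.3, n=12)
   placebo wk 4:   0.7% (sd 1.5, n=13)
```

Read: after FMT, patients' genus-level dissimilarity to the donor drops
from ~0.75 to ~0.57 while the placebo arm stays at ~0.74, and about 31%
of the OTUs that only the donor carried before treatment are detected
in FMT patients at week 4 (here the true simulated engraftment rate is
e = 0.3) versus under 1% in the placebo arm — the background rate from
OTUs that were merely missed by sequencing at baseline.

The same stages are scriptable via the CLI (`pouchtrack simulate`,
`diversity`, `beta`, `engraftment`, `test`, `run`) or the library
(`pouchtrack.run_pipeline`).

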