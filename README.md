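# epidrift

Quantitative analysis of long-term clonal dynamics in 3D epithelial
("epithelioid") cultures: neutral-drift modeling of multicolor
lineage-tracing data, clone-trajectory classification, cell-competition and
culture-assay statistics, and pooled CRISPR fitness-screen analysis — with
seeded synthetic-data generators so the whole pipeline runs with no
external data.

## Who this is for

Epithelioids are self-sustaining, months-long primary cultures of
stratified epithelium (esophagus and related tissues) in which labeled
clones — single-colored areas, **SCA** — can be imaged weekly, mutant
cells can compete against wild type, and CRISPR–Cas9 fitness screens can
be run in an organotypic setting. This package implements the statistics
such experiments need, end to end, for anyone analyzing (or simulating)
clone-size trajectories, competition proportions, or guide-count matrices.

## The model

A homeostatic squamous epithelium is maintained by a single progenitor
population: each progenitor divides at rate λ per week producing two
progenitors (probability *r*), two differentiating daughters (probability
*r*), or one of each (1 − 2*r*). Balanced fates make clone dynamics a
critical branching process with the composite drift rate **κ = rλ** as the
single governing parameter:

- clone survival: P(t) = 1 / (1 + κt)
- mean surviving clone size: n̄(t) = 1 + κt
- surviving clone sizes: geometric, P(n | surviving) = (κt)^(n−1) / (1 + κt)^n
- conservation: P(t) · n̄(t) = 1 — labeled mass is constant while clone
  number falls and survivors coarsen.

`epidrift.sp_model` provides these closed forms, the predicted cohort
summary curves, the one-parameter fit of κ to observed summaries, and a
Gillespie simulator of the critical birth–death process.
`epidrift.lattice` is the spatial counterpart: a voter-model lattice where
each division displaces a stratifying neighbor, conserving density and
producing the SCA coarsening seen in imaging. `epidrift.sca` implements
the weekly-trajectory windowing (mean areas over weeks 4–8, 10–13, 15–19)
and the six-way Decay1/Decay2/Decay3/Biphasic/Growing/Steady
classification, plus the matched-pairs Wilcoxon signed-rank comparison.
`epidrift.culture` covers relative fitness, stratification ratio, barrier
permeability, wound closure and serial-passaging expansion arithmetic.
`epidrift.screen` analyzes pooled-screen guide counts: CPM normalization,
log2 fold change, robust z-scores against nontargeting (NT) controls,
cumulative-fraction depletion AUC, and permutation-FDR gene calls
(enriched / depleted / unchanged at FDR < 0.1 and >10% fold change).
`epidrift.synthetic` generates inputs for every stage from seeded
configurations.

## Worked example

```python
from epidrift.sca import classify_cohort, cohort_summary
from epidrift.sp_model import fit_drift_kappa
from epidrift.synthetic import ConfettiCohortConfig, gen_confetti_trajectories

cohort = gen_confetti_trajectories(ConfettiCohortConfig(kappa=0.25, seed=11))
classes = classify_cohort(cohort)
for cls, prop in classes.class_proportions.items():
    print(f"{cls.value:9s} {100 * prop:5.1f}%")
fit = fit_drift_kappa(cohort_summary(cohort).curve, t0=0.0, seed=1)
print(f"kappa_hat = {fit.kappa_hat:.3f} /week")
```

prints

```
Decay1     44.4%
Decay2     15.1%
Decay3      6.8%
Biphasic   13.4%
Growing    14.2%
Steady      6.0%
kappa_hat = 0.286 /week
```

a 351-SCA cohort in which two thirds of clones shrink away (Decay1–3), a
minority grow transiently (Biphasic) or persistently (Growing), and the
drift fit recovers the generating rate κ = 0.25/week within its bootstrap
interval. The `examples/` directory has one short script per capability
(analytic model, lattice, classification + fit, competition metrics,
screen analysis); each prints its numbers with a line on what they mean.
A thin CLI mirrors the stages: `epidrift synth ...`, `epidrift
classify-sca`, `epidrift fit-drift`, `epidrift simulate-lattice`,
`epidrift screen-analyze`, `epidrift fitness` and `epidrift run` for the
end-to-end pipeline with a reproducibility manifest.

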