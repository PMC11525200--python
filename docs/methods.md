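# Methods

## Single-progenitor neutral drift

The package's core model treats the basal layer of a stratified squamous
epithelium as one functionally equivalent progenitor population. Each
progenitor divides at rate λ (per week) and the fate of the two daughters
is symmetric on average: both progenitors with probability *r*, both
differentiating with probability *r*, one of each otherwise. Averaging
over fates, a labeled clone performs a critical (birth rate = death rate =
κ = rλ per cell) branching process. The closed forms used throughout:
survival P(t) = 1/(1+κt), mean surviving size 1+κt, geometric conditional
size distribution. Their product P·n̄ = 1 expresses conservation of
labeled mass and is asserted exactly in tests. *r* and λ are not
separately identifiable from neutral summary curves — only κ is ever
fitted; when both are supplied they are validated against κ = rλ and used
only where the lattice needs a division rate.

Time is measured in weeks. The drift clock starts at labeling (induction),
t0 = 0; imaging typically begins at week 4–5, so fits must distinguish the
clock origin from the first observed point (below).

## The one-parameter drift fit

`fit_drift_kappa` minimizes the sum of squared *relative* residuals of the
mean surviving clone area and the surviving clone count jointly, with
equal weight, over time points with at least one survivor. Total labeled
area is excluded: it is the product of the other two and carries no
independent information. The amplitudes (n0, a0) are anchored at the first
observed time point rather than co-fitted, keeping the fit genuinely
single-parameter; the drift clock is anchored at t0. With observations
starting at week t1 > t0 the predictions are

    count(t) = n0 · (1 + κ(t1−t0)) / (1 + κ(t−t0))
    mean(t)  = a0 · (1 + κ(t−t0)) / (1 + κ(t1−t0))

which reduce to the t1 = t0 textbook forms. Anchoring at the first
observed week while keeping the clock at induction matters: treating the
first imaging week as the clock origin would bias κ̂ downward by a factor
1/(1+κ·t1). Optimization is a bounded scalar search on log κ
(κ ∈ [1e−6, 100], xatol 1e−12); a brute-force grid is used as a test
oracle, never in the implementation. The 95% CI is a seeded percentile
bootstrap (default 1,000 resamples) over time points; monotonically
increasing count series — incompatible with neutral decay — set a warning
flag rather than raising.

### Precision at the study scale

On synthetic cohorts of 351 clones observed weekly over weeks 4–19 at
κ = 0.25/week, the summary-level fit is unbiased but its per-cohort
relative error has a median near 10–11%. This is the information floor of
the summary design, not estimator slack: the count series alone carries
roughly 18% precision (interval-censored extinction likelihood), the mean
sizes roughly 15%, and their combination lands at ~11%; inverse-variance
GLS variants, a count-series extinction MLE and co-fitting the area
amplitude were all evaluated and performed the same or worse, so the
simple equal-weight relative-residual objective is retained. Precision
improves as 1/√(cohort size) — a tenfold larger cohort fits κ to ~5%.
Imaging noise at the default level contributes negligibly; the variance is
the drift stochasticity of a finite clone cohort.

## Lattice simulation

`epidrift.lattice` implements a minimal density-conserving spatial
version: a fully occupied rectangular lattice, one progenitor per site.
At total rate N·λ a site is chosen uniformly to divide; a second cell
stratifies (leaves the basal layer) and its site is taken by the daughter,
which inherits the mother's color. In `neighbor` mode the stratifying cell
is a von Neumann neighbor of the divider (a voter-model rule; neutral,
density-conserving, coarsens same-color patches into SCA). In
`mean_field` mode it is drawn uniformly from the whole lattice
(Moran-type); for clones much smaller than the lattice this reduces to the
critical birth–death process with per-cell rate λ, which is verified
against the closed forms in tests. Boundary is periodic by default
(reflecting available; out-of-bounds neighbor choices are redrawn
uniformly among valid neighbors). Events form a Poisson process with
exponential interarrival times; per sampling interval the event count is
drawn Poisson(N·λ·Δt), the same process in law, and event pairs are
applied sequentially by a kernel that is numba-JIT-compiled when numba is
importable (a pure-Python fallback is exact but slower). Occupancy is
conserved by construction and asserted at every sample.

SCA are connected components of identically colored sites
(`label_components`, scipy.ndimage, 4-connectivity by default; components
do not wrap at periodic boundaries — the conservative reading of an SCA as
a visually contiguous region). Areas are site counts × area_per_cell,
defaulting to 1/ρ.

## Trajectory classification

Window means A4–8, A10–13, A15–19 are arithmetic means of the available
weekly areas in each inclusive window; a fully missing window makes the
SCA ineligible (reported separately, never imputed) — recorded zeros mean
below-detection, missing weeks mean not measured. Rules are applied in
order: Decay1 (A10–13 = 0 and A15–19 = 0), Decay2 (A10–13 > 0 and
A15–19 = 0), Decay3 (A4–8 > A10–13 > A15–19), Biphasic
(A4–8 < A10–13 > A15–19), Growing (A4–8 < A10–13 < A15–19), Steady
(everything else). Equality cases deliberately fall through to the Steady
catch-all; strict inequalities are used exactly as stated. Classification
is deterministic, exhaustive and scale-invariant, and is tested against an
independently written 27-pattern decision table. Weeks 9 and 14 fall in no
window; they are stored and used by the summary curves but not by
classification.

Cohort summary curves count a clone as surviving at a week when its
recorded area exceeds the threshold (default 0, i.e. any positive area —
the detection limit is encoded upstream as recorded zeros). Weeks without
survivors report a missing mean, not zero.

The matched-pairs Wilcoxon signed-rank test (two-sided) drops zero
differences, uses the exact null for n ≤ 25 and the normal approximation
with continuity correction beyond; an all-zero difference vector returns
p = 1 with a warning.

## Culture and competition metrics

Relative fitness is the fold change of the focal subpopulation's
proportion versus its initial proportion (1 = neutral); a log variant is
provided but the proportion fold change is the primary statistic.
Permeability is the blank-subtracted percent of the no-cell control and is
*not* clipped to [0, 100] — out-of-range values are flagged, preserving
evidence of assay noise. Wound closure is the fraction of the day-0 area
closed, with an OLS slope (with intercept) as the overall rate. The
expansion projection is initial_fold · split_factor^rounds; headline
reporting rounds to 2 significant figures via `round_sig`.

## Screen analysis

Counts are normalized to counts-per-million after adding a 0.5 pseudocount
to every guide (standard protection for low-count guides); log2 fold
change (week 3 vs week 0) is computed per replicate and averaged (3
replicates by default). Robust z-scores use the NT guide distribution:
z = (lfc − median_NT)/(1.4826·MAD_NT), requiring ≥ 10 NT guides.

Depletion AUC ranks all guides by log2FC ascending (most depleted first,
ties broken lexically by guide id) and integrates the cumulative fraction
of a gene set found against the fraction of the list traversed (trapezoid
rule). Under this convention ~0.5 is no selection and the maximum for a
set of |S| guides among N is 1 − |S|/(2N); a strongly depleted set
approaches that ceiling. The ranking convention and tie rule are recorded
in the result metadata through the deterministic implementation.

Gene calls replace rank-aggregation machinery with a transparent
permutation test: the statistic is the mean guide log2FC per gene; the
null is the distribution of means of size-matched random draws from the
full guide pool (10,000 seeded permutations, shared across genes of equal
guide count); two-sided p-values are centered on the null mean (so a
uniform toxicity shift affecting all guides does not inflate calls),
BH-adjusted across genes. A gene is enriched/depleted only when
FDR < 0.1 *and* its median guide fold change differs from 1 by more than
10% (|2^median_lfc − 1| > 0.1); genes with fewer than two guides are
reported unchanged with a warning flag. Calibration (null screens call
≲ FDR fraction) and power (a strongly selected gene is called) are
exercised in the acceptance suite.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of their configuration including the
seed (byte-identical reruns).

**Lineage-tracing cohorts** (default 9 cultures × 39 SCA = 351, weekly
weeks 4–19, κ = 0.25/week): each clone's week-4 size is drawn from the
conditional geometric law at week 4 — tracking starts when clones are
already recognizable, not at single founders — then evolves by Gillespie.
Measured area = cells/ρ × lognormal multiplicative noise (CV 0.1);
areas below the 0.01 mm² detection floor are recorded as 0. The density
ρ = 50 units/mm² defines the model cell as a coarse-grained *detectable*
clonal unit (0.02 mm²) sitting just above the detection floor, mirroring a
cohort defined by visibility at the first imaging week; it is not a
literal keratinocyte density (true basal densities are 10³–10⁴ cells/mm²,
but sub-detection clones are unobservable by design). Not emulated: SCA
formation by merging of same-color neighbors, culture-level batch effects,
imaging segmentation errors, and mutant (non-neutral) clones — so passing
recovery tests demonstrate estimator correctness under the neutral model,
not robustness to those real-data features.

**Competition series**: replicator dynamics
p(t) = p0·e^{st}/(1−p0+p0·e^{st}) with binomial sampling of n cells per
time point (default 10⁴); s = 0 gives a martingale. Genetic drift of the
culture itself is not modeled (deterministic p(t) plus sampling noise).

**Screen counts**: 23 driver + 62 candidate + 50 essential genes ×
4 guides, plus 800 NT guides. The NT-rich composition is derived from the
depletion-AUC geometry: with 200 essential guides, a ceiling of
1 − |S|/(2N) ≈ 0.93 requires the essential set to be ~15% of the library,
matching the strong-depletion AUC values such screens report. Initial
abundances are Dirichlet-uniform; week-3 expected abundance multiplies by
exp(duration · s_g · (1 − targeted_fraction)) — the 13% targeted fraction
enters as a simple multiplicative attenuation of selection (targeted cells
mostly compete against untargeted neighbors; frequency-dependent effects
are out of scope) — and counts are negative-binomial (dispersion 0.2,
depth 500 reads/guide; dispersion 0 gives Poisson, depth=None returns
exact expected counts for closed-form validation). Noise magnitudes are
field-plausible stand-ins; no published per-guide measurement model was
available to copy.

## Numerical choices and edge cases

- Seeds: every stochastic routine takes a seed or Generator; the pipeline
  derives per-stage substreams from one global seed via SeedSequence.
- DriftCurve validates mean·count = total to 1e−9 relative wherever
  count > 0, and permits NaN means only where no clone survives.
- clone_size_pmf normalization is verified to 1e−6 under truncation far
  into the tail.
- Degenerate inputs raise typed errors naming the offending field (empty
  windows name the window; schema errors name the missing/extra columns
  and the malformed line).
- TSV IO parses numerics with correctly-rounded float conversion so
  write→read→write round trips are bit-exact.
- Test problem sizes (10⁵ Gillespie runs, 500 lattice replicates at 64×64,
  20-seed calibration loops) were chosen to keep Monte Carlo error well
  below the asserted tolerances while the full suite runs in minutes on a
  single CPU.

## Known limitations

- The lattice model is 2D with an implicit suprabasal sink; stratification
  geometry, cell mechanics and explicit suprabasal compartments are out of
  scope.
- Only neutral drift is modeled analytically; biased-drift (mutant
  advantage) fitting is deliberately excluded.
- The permutation gene caller assumes guides are exchangeable across genes
  under the null; gene-specific guide efficacy distributions are not
  modeled.
- Summary-level κ fitting cannot beat the ~10% information floor at the
  default cohort scale (see above); per-clone likelihood fitting would be
  needed for tighter precision and is not implemented.
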