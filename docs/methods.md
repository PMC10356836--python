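# Methods

## Scope and data model

The package analyses a species-by-sample count table, per-sample metadata
(temperature group and temperature in °C) and a rooted phylogeny whose tips
match the species ids.  The default design mirrors a geothermal outflow
survey: 8 temperature groups spanning 80 → 54.8 °C with 7 replicates each
(56 samples).  Only the two printed endpoint temperatures and a few interior
anchors are fixed by the design; the default interior values
(75.5, 72.1, 68, 63.9, 60.1, 57.2) interpolate the outflow profile and are
configurable — analyses depending on the exact interior temperatures should
set them explicitly.

## Occupancy permutation null and classification

Occupancy is defined at the group level: a species occupies a group when any
of the group's samples has a count at or above `min_count` (default 1, i.e.
presence/absence; species with total count below the threshold are
dropped).  The null model redraws each species' incidence set — which
samples it occupies, with its incidence count held fixed — uniformly among
all samples and recomputes group occupancy.  Because the resulting occupancy
law depends only on a species' incidence count and the group sizes, the
implementation derives that law exactly by inclusion–exclusion and samples
each permutation's class counts from it; this is distributionally identical
to literally redrawing every incidence set but runs the default 100,000
permutations in seconds.  The expected histogram is the mean over
permutations; per-class upper-tail p-values use the (b+1)/(B+1) correction;
exceedance is the strict inequality observed > expected, and ties count as
non-exceedance.

A stricter null that also preserves per-sample richness (curveball trades,
`null="fixedfixed"`) is available for sensitivity analysis; it is orders of
magnitude slower and intended for small permutation counts.

Classification reads the exceedance pattern: the maximal run of exceedance
classes starting at occupancy 1 defines "sensitive" (specialist) species,
the maximal run ending at G defines "resistant" (generalist) species,
everything else is "other".  An absent run leaves that label set empty with
a warning; the degenerate case where every class exceeds labels everything
"other".

## BiSSE likelihood and fitting

The binary-state speciation–extinction likelihood propagates the coupled
extinction/data ODEs along each branch (tip to root) with tip conditions
D_state = 1, D_other = 0, E = 0 (complete sampling of extant tips), joins
daughters at nodes as D_i ← D_i^left · D_i^right · λ_i, and combines root
states with weights proportional to D_i ("obs" mode; flat, equilibrium and
fixed-state weightings are options).  Survival conditioning (dividing by
Σ w_i λ_i (1−E_i)²) is on by default.  Both defaults follow the standard
reference implementation of the model and are recorded with every fit.

Numerics: branches are integrated by fixed-step classical RK4 with the step
count proportional to branch length × fastest total event rate (`mesh` = 100
steps per unit by default, minimum 10 and maximum 2000 steps per branch);
D-vectors are renormalized after every branch with the scale carried in log
space.  On the hand-integrable 3-tip case the error is below 1e-8, the
state-independent factorization identity holds to better than 1e-6 on trees
up to 50 tips, and doubling `mesh` moves test-tree log-likelihoods by less
than 1e-6.  Polytomies and negative branch lengths are rejected rather than
silently resolved — resolution order changes the likelihood.  Input trees
are made ultrametric by extending terminal branches when within 1% of the
tree depth; larger deviations are rejected, since silently linearizing a
strongly non-clock tree would change the rate units.  Rates are in events
per lineage per unit branch length of the input tree.

Maximum likelihood uses L-BFGS-B on log-rates (bounds 1e-8 to 1e3) with
jittered restarts (default 3; the Monte-Carlo studies in the test-suite use
1–2 restarts to stay within their runtime envelopes).  The heuristic start
fits a state-independent birth–death model by its closed-form likelihood and
sets q01 = q10 = λ̂/10.  The two-round protocol fits the constrained model
(λ0 = λ1, μ0 = μ1; transitions always free) and then the unconstrained
model started from the constrained optimum; the released pair of equality
constraints gives a likelihood-ratio test with 2 degrees of freedom.  The
"analysis of variance" comparison of the two rounds is implemented as this
LRT — the standard defined test for nested maximum-likelihood fits.

Per temperature group, the unified tree is pruned to the classified
(sensitive/resistant) species detected in that group; groups with fewer than
10 usable tips or a single state are skipped with a recorded reason.
Extinction rates are estimated freely (never fixed at zero), and both
sampling-fraction and root-treatment choices are exposed for sensitivity
analysis.

## MTE indices

DP = λ_focal + t − μ_focal and EP = μ_focal from the unconstrained
per-group rates, with DP computed for the sensitive state and EP for the
resistant state by default.  The direction of the transition term t in DP is
genuinely ambiguous; the default uses the transition *into* the focal state
(transitions add species of that state), and both orientations are always
computed and written side by side, so the choice is visible rather than
buried.  Activation energies come from OLS of ln(index) on 1/(kT_K),
k = 8.617×10⁻⁵ eV/K, E = −slope (the additive inverse, by dimensional
analysis of e^(−E/kT)).  Nonpositive index values are excluded from the log
regression with an explicit count; fewer than 3 positive points aborts the
fit with a flag.  On noiseless inputs slope(ln RS) = E_EP − E_DP holds
exactly (tested as an algebraic identity).

## Community phylogenetics and neutral model

MNTD is the mean patristic distance from each sample taxon to its nearest
co-occurring taxon, presence-based by default with an abundance-weighted
option.  The patristic matrix is computed once and cached; the null loop
never recomputes it.  NTI = −(MNTD_obs − mean_null)/sd_null with a
tip-shuffling null (999 draws by default) on the full pool tree, so richness
is held fixed; positive NTI means terminal clustering.  A degenerate null
(sd ≈ 0, e.g. the sample is the whole pool) reports NTI = 0 with a flag.

"Simpson diversity" is reported as inverse Simpson 1/Σp² by default —
community Simpson values above 1 are only meaningful on that scale — with
classical Simpson and Shannon alongside.  Levins breadth B = 1/Σp_h² uses
the 8 group-level abundance shares as resource states.  Blomberg's K uses
the Brownian-motion covariance implied by the tree and tip-permutation
p-values on the variance of phylogenetically independent contrasts; under
Brownian traits simulated on a fixed tree the mean K is 1 within sampling
error (checked by Monte Carlo).

The Sloan neutral model is fit by least squares of observed detection
frequencies on F(p) = 1 − BetaCDF(1/N; Nmp, Nm(1−p)) over species, with
N defaulting to the mean reads per sample and detection limit 1/N (both
overridable); this is the standard operationalization when no explicit
community size is known.  The 95% band is binomial sampling error around
F(p) at the observed sample count, and is approximate.  R² may be negative
— a structured (non-neutral) community is expected to produce exactly that.

## Synthetic generators: what they emulate, and what they do not

`simulate_bisse_tree` is an exact Gillespie simulation of the two-state
birth–death-transition process, pruned to extant tips.  With a target tip
count it conditions on reaching the target and stops just before the next
event after the target is first reached, so the youngest tips carry positive
pendant branches; draws that go extinct or miss the target are rejected
within a bounded retry budget.

`generate_community` plants occupancy structure with known truth labels:
specialists detectable only in their home group, generalists covering
between 5 and 8 groups.  Mirroring the rare-majority incidence structure of
real surveys, specialists occupy 1–3 of their 7 home-group samples and
generalists 1 sample per covered group, with the generalist occupancy
profile skewed toward the minimum (40/25/20/15% at occupancy 5/6/7/8,
allocated deterministically by largest remainder).  These defaults are what
make the permutation null single out occupancy 1 and ≥5 as non-random, i.e.
they reproduce the qualitative criteria shape of a strongly structured
community.  Abundances are lognormal (meanlog 0, sdlog 1), scaled to a
multinomial read draw of 20,000 reads per sample; per-sample dropout is off
by default and available as `detection_noise`.  The generator does not
simulate sequences, chimeras, taxonomy, or covariation with chemistry —
temperature is the only niche axis — and its species richness (a few
hundred) is desk-scale, far below a real survey.  Passing recovery tests
therefore demonstrates correctness of the statistical machinery on planted
structure, not performance on real sequencing noise.

`make_sloan_community` draws per-sample relative abundances from the Beta
law of the neutral model itself and converts them to counts by flooring at
the community size, so that detection (count ≥ 1) coincides exactly with the
model's detection limit.

## Problem sizes and seeds

The test-suite's Monte-Carlo studies use 500-tip trees (50 replicates) for
rate-ratio recovery, 100-tip trees (200 replicates) for LRT calibration,
200-tip trees (25 replicates) for power, 2000 species × 56 samples for the
neutral model, and 1000 draws for NTI calibration — sizes chosen so the full
suite completes on a single CPU in well under half an hour.  Every stochastic
component takes an explicit seed; the pipeline spawns independent
per-stage sub-seeds from one master seed, so stage results are unchanged
when unrelated stages are reconfigured, and reruns are byte-identical.

## Known limitations

* BiSSE rate units are inherited from the input tree's branch lengths; the
  package does not time-calibrate trees.
* The likelihood assumes complete sampling of extant tips; the sampling
  fraction is not yet a first-class parameter of the engine.
* The LRT's χ²(2) reference is slightly conservative when extinction rates
  sit near the zero boundary at small tree sizes.
* The curveball (fixed-fixed) null is not practical at 100,000 permutations.
* Blomberg's K requires a strictly binary tree (contrasts are undefined at
  polytomies); MNTD/NTI and the BM covariance accept polytomies.
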