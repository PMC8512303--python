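# Methods

This note documents the models, conventions and numerical choices behind
`acdkit`, and what the synthetic-data layer does and does not emulate.

## Units and study conventions

All lengths are µm, areas µm², times minutes, angles degrees. The fixed
conventions of the analysis are: the small-cell area threshold of 120 µm²
(strict `<`; a cell of exactly 120 µm² is not small — area is used in
place of volume because epidermal cell height is nearly uniform at the
stages analysed); clusters of **four or more** small cells in contact;
"in contact" meaning 4-connected pixel adjacency (a shared cell wall —
corner-only touching does not count); the polarization cut-off of σ < 60°
(strict); time measured relative to cytokinesis, with frame 00:00 = cell
plate formation; Bonferroni-corrected thresholds α/m reported both exact
and rounded to three decimals (0.05/3 → 0.017, 0.05/5 → 0.01).

## Crescent model and fitting

Cortical intensity around a cell outline is modelled as a circular
Gaussian `I(θ) = β + α·exp(−d(θ,μ)²/2σ²)` with `d` the wrapped angular
distance. θ parameterises the outline by the angle about the cell
centroid mapped to the full 360° circle (not arc length); this is the
simplest well-defined convention, and the 60° cut-off is applied on that
scale.

Fitting is nonlinear least squares (`scipy.optimize.least_squares`, trust
region reflective, analytic Jacobian). Initialisation: μ₀ = argmax bin,
β₀ = 5th percentile of intensities, α₀ = max − β₀, σ₀ = 30°; a second
start at σ₀ = 90° covers wide-crescent optima, and up to three further
jittered starts run only if neither converges. The profile is recentred
at its argmax so the optimiser never works across the 0/360° seam.
Bounds: α ≥ 0, σ ∈ (0, 240] — beyond σ ≈ 180° a circular Gaussian is
indistinguishable from a flat profile, so larger values carry no
information. Non-convergent fits are flagged and never called polarized.

**Angular sampling.** Profiles default to 1° bins (360 samples). This was
chosen from an information analysis: the least-squares estimator of σ
attains the Cramér–Rao bound, and at 72 bins the bound alone gives
SE(σ̂) ≈ 25° for wide crescents (σ = 120°, noise = amplitude/10), which
makes wide-crescent recovery hopeless; at 1° sampling it drops to ≈ 11°,
giving an integrated RMSE over σ ∈ [10°, 120°] of ≈ 4.7°. Outline-pixel
sampling of real cells (hundreds of boundary pixels) supports this
resolution.

**Polarization call.** `polarized = (bin width ≤ σ̂ < cutoff) AND
(α̂ > 3 × robust residual noise) AND (variance explained > 25/n_bins)`.
The three guards were calibrated on flat noisy profiles (the null):

- the *amplitude floor* uses 1.4826·MAD of the fit residuals as the noise
  scale; the factor 3 keeps the false-positive rate on flat profiles with
  noise s.d. 5 at 0.25% (a factor of 2 gives 2.25%);
- the *sampling floor* (σ̂ at least one bin width) removes degenerate
  sub-resolution spikes, whose amplitude is unconstrained between sample
  points;
- the *variance-explained floor* reflects that optimising μ and σ on pure
  noise explains at most ≈ 20/n_bins of the variance (measured on 400
  null profiles at both 72 and 360 bins), while genuine crescents with
  amplitude ≥ 3× noise explain ≥ 0.32; the threshold 25/n_bins therefore
  separates them with margin. This third guard is what makes per-frame
  calls reliable enough that a tracked time series of ~20 frames
  essentially never shows a spurious polarized frame.

**Tracking.** `track_crescent` takes per-frame fits plus the cytokinesis
frame and reports the first/last polarized frames and the polarized
duration before/after cytokinesis (frame count × frame interval; frames
at or after cytokinesis count as "after").

## Profile extraction from images

Boundary pixels (cell pixels with a 4-neighbour outside the cell) are
binned by their centroid angle; bin value = mean intensity of its
boundary pixels; empty bins are filled by circular linear interpolation.
Cells cut by the image border are flagged `reliable=False` rather than
rejected.

## Morphometry

- Adjacency is computed by comparing the label image against its one-pixel
  shifts — exact 4-connectivity, verified in tests against a brute-force
  all-pixel-pairs oracle.
- Cluster calling takes the connected components of the contact graph
  induced by small cells and keeps components of size ≥ 4; smaller
  components count toward the small-cell total but not the clustered
  total. The clustered fraction is defined as 0 when there are no small
  cells.
- The spacing angle α between two undirected axes is
  `min(|Δ| mod 180, 180 − |Δ| mod 180) ∈ [0, 90]`; the cumulative curve is
  evaluated at each integer degree 0..90.
- Size asymmetry: ratio = meristemoid/SLGC area measured in the first
  frame after cytokinesis, with fate assigned by the crescent (the
  crescent-bearing daughter is the SLGC); `reversed` requires the crescent
  daughter to be *strictly* smaller (ties are not reversed).
- Nuclear offset = |nucleus − cell centroid| / r_dir, where r_dir is the
  centroid-to-boundary distance along the centroid→nucleus ray. The
  directional normalisation (rather than an equivalent-circle radius)
  keeps the measure in [0, 1) for convex and most concave cells. The
  original measurement is defined only schematically, so this is an
  explicit interpretation. Polygon inputs are intersected exactly
  (shapely); mask inputs are ray-marched at 0.2 px steps.

## Lineage classification

A division is *entry* if the mother has no recorded parent division,
*gmc_symmetric* if the mother's fate is GMC, otherwise *amplifying* or
*spacing* according to whether the mother was the smaller or larger of
its sister pair at birth (areas from the first frame after the parent
division). Exact ties are resolved by the crescent annotation (crescent ⇒
SLGC ⇒ spacing); with no annotation the class is `ambiguous` — never
guessed. Cell-cycle length is division time minus the mother's birth
time; cells that never divide inside the window are excluded and counted
as right-censored.

Cluster origins: *fate error* iff two clustered stomata descend from the
two sisters of one division with at most one intervening symmetric GMC
division on each branch; otherwise *spacing error* iff a spacing division
occurs in a clustered stoma's history; otherwise unresolvable.

Pair outcomes: one record per tracked ACD, with `amp` = the meristemoid
underwent a subsequent *asymmetric* division (a GMC's symmetric division
does not count) and `spa` = the SLGC divided. Pairs with a daughter that
left the field are excluded and counted. The SLGC's fate is carried in
the output so callers can compute denominators that include or exclude
SLGCs that differentiated into pavement cells mid-window — whether the
study's denominators include them is not stated, so both are derivable.

## Coordination statistics

Obs[SPA], Obs[AMP], Obs[SPA+AMP] are plain frequencies over pairs;
Exp[SPA+AMP] = Obs[SPA]·Obs[AMP] exactly (an identity, asserted in
tests). The deficit Obs − Exp is negative under mutual
suppression/competition. The permutation test shuffles the SLGC column
across pairs (preserving both marginals), with two-sided
p = (1 + #{|deficit_perm| ≥ |deficit_obs|}) / (n_perm + 1); it is
seed-deterministic and its type-I error is calibrated under the
independence generator (0.03–0.07 at α = 0.05 over 1000 simulations of
200 pairs with 199 permutations). The underlying study compares Obs with
Exp descriptively; the test is an optional extension of this package.
Two-sample comparisons wrap `scipy.stats` Mann–Whitney U and Student's t;
identical constant samples return p = 1 and are flagged degenerate.

## Synthetic data: what it emulates, and what it does not

**Tissue.** A power diagram (additively weighted Voronoi) over jittered
lattice seeds, at 1 µm pixels over fields emulating the 388×388 µm²
acquisition scale. Small cells are produced by shrinking single lattice
cells; each planted cluster of k ≥ 4 cells is a tight ring of k sub-seeds
inside one site, so its members are small and mutually in contact. Cell
areas are calibrated by a proportional control loop on the power weights
(one shared weight per cluster — per-member weights are unstable at
ring-scale distances) until every planted small cell renders strictly
below 120 µm² and every normal cell at or above it. Stomata are type
annotations chosen on the *rendered* contact graph: planted pairs are
adjacent normal cells, all other stomata are kept out of mutual contact.
The generator verifies all planted structure against the rendered image
before returning, so ground truth is exhaustive by construction. The
default geometry (mean cell area ≈ 300 µm², small cells 50–100 µm²)
matches the analysed cotyledon stages.

**Profiles and time lapse.** Additive Gaussian noise per bin, clipped at
zero — the simplest model sufficient for parameter-recovery testing (the
actual noise characteristics of the imaging are not published). Frame
interval defaults to 40 min (the 30–45 min acquisition range). The three
expression variants place the polarity window as observed: `full` from a
few frames before cytokinesis to > 6 h after; `pre` ending within one
frame after cytokinesis; `post` starting at cytokinesis or one frame
(−00:40) earlier.

**Pairs.** Outcomes are drawn from the 2×2 distribution determined
analytically from the two marginals and an odds ratio (Plackett's
quadratic, machine-precision identity): odds ratio 1 gives exactly the
independence null; 0.1 emulates strong sister suppression. Default
marginals p_amp = 0.5, p_spa = 0.3 are in the range of wild-type division
frequencies; n > 500 pairs per condition matches the tracking scale.

**Lineages.** Two-generation forests: each founder entry-divides (daughter
order randomised; meristemoid/SLGC area ratio 0.5), the sister pair's
(amplifying, spacing) outcomes are drawn from the coupled 2×2 model, and
non-amplifying meristemoids may become GMCs. Meristemoid cycle times are
0.7× SLGC cycle times (lognormal, σ = 0.08) — the lineage's inverted
size/cycle relationship. Entry times and cycle scales are chosen so all
planted divisions fall inside the 48 h window; censoring is exercised by
dedicated tests, not the generator defaults. The independence round-trip
restricts to entry pairs, because only entry daughters get a full
observation window in this design — second-generation pairs are all
(false, false) and would manufacture spurious positive association under
the null.

**Not emulated:** optics (PSF, bleaching, z-projection artefacts),
segmentation errors, 3-D tissue, real spatial fate patterning, or
signalling dynamics. Passing tests therefore demonstrate correctness of
the measurement and classification layer on idealised inputs with known
truth — not robustness to segmentation noise or biological realism of the
generated tissues.

## Problem sizes

The verification workloads use 200 profiles for recovery, 100 random
fields of 80–400 cells for the cluster oracle, 10 000 pairs and 1000
permutation-test simulations (200 pairs, 199 permutations each) for
coordination, 100 trajectories per expression variant (16–18 frames
each), and 10 000 angles for the cumulative-curve band. These sizes give
comfortable statistical resolution for every stated property while
keeping a full run around a minute on one CPU.

## Known limitations

- The full-circle centroid-angle convention for θ may differ from
  arc-length parameterisations of the outline used elsewhere; σ values
  are comparable only under a fixed convention.
- σ̂ is information-limited for wide crescents; at the default noise
  level, individual σ̂ above ~100° carry standard errors of ~10°.
- The nuclear-offset normalisation is one explicit reading of a
  schematic-only definition.
- `classify_cluster_origin` requires the clustered stomata to be present
  in the trace; partially traced clusters return `unresolvable` rather
  than a guess.
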