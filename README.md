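# acdkit

Quantitative analysis of asymmetric cell divisions (ACDs) in the
*Arabidopsis* stomatal lineage.

In the leaf epidermis, stomatal-lineage cells divide asymmetrically: the
polarity protein BASL forms a cortical crescent before division and is
inherited by the larger daughter (the stomatal lineage ground cell, SLGC),
while the smaller daughter (the meristemoid) self-renews or differentiates.
Studies of this system quantify four things from segmented confocal images
and manual lineage traces, and `acdkit` implements all four as a tested,
reusable pipeline:

1. **Polarity crescents** (`acdkit.polarity`). Cortical fluorescence is
   sampled around the cell outline as intensity versus the angular position
   θ about the cell centroid and fitted to a circular Gaussian

       I(θ) = β + α · exp( −d(θ, μ)² / 2σ² ),

   with wrapped angular distance *d*, centre μ, amplitude α and baseline β.
   The fitted standard deviation σ is the crescent size; a cell is called
   *polarized* when σ < 60° (strict) and the amplitude is clearly above the
   residual noise. Time-lapse series are tracked relative to cytokinesis
   (frame 00:00 = cell-plate formation) to find the first and last
   polarized time points.
2. **Morphometrics and cluster calling** (`acdkit.morphometry`). Cell areas
   from label images (area = pixel count × pixel size²); *small cells* are
   those strictly below 120 µm²; *small-cell clusters* are four or more
   small cells in contact (4-connected pixel adjacency); stomatal
   clustering is the percentage of stomata in direct contact with another
   stoma. Also: daughter-size asymmetry (meristemoid/SLGC area ratio, with
   "reversed" divisions where the crescent sits in the smaller daughter),
   normalized nuclear offset, and the spacing-division angle α between the
   stomatal pore axis and the new division plane with its cumulative
   frequency curve over 0–90°.
3. **Lineage tracing** (`acdkit.lineage`). Lineage tables form a forest of
   cells and divisions. Divisions are classified as entry (no recorded
   parent), amplifying (mother was the smaller sister), spacing (mother was
   the larger sister) or symmetric GMC divisions; cell-cycle lengths are
   grouped by class; stomatal clusters are traced to their origin (*fate
   error*: both sisters of one division became stomata; *spacing error*: a
   misoriented spacing division placed a precursor beside an existing
   stoma).
4. **Sister-cell division coordination** (`acdkit.coordination`). For
   tracked sister pairs, Obs[SPA] and Obs[AMP] are the observed spacing and
   amplifying division frequencies, Obs[SPA+AMP] the joint frequency, and
   Exp[SPA+AMP] = Obs[SPA] × Obs[AMP] the independence expectation; a
   deficit of Obs below Exp indicates inhibition between sisters. A
   seed-deterministic permutation test (shuffling SLGC outcomes across
   pairs) is provided as an inferential extension, plus the study's
   statistical conventions (Mann–Whitney / t tests, Bonferroni thresholds
   reported to three decimals, e.g. 0.05/3 → 0.017).

No imaging data ships with the package. Instead `acdkit.synthetic`
generates every input with known ground truth: power-diagram epidermis
fields with planted small-cell clusters and stomatal pairs, angular
profiles and time-lapse polarity series, lineage forests with planted
division classes, coupled sister-pair outcomes (marginals + odds ratio;
odds ratio 1 is exactly the independence null), and spacing-division
geometries.

## Worked example

```python
from acdkit.synthetic import (ProfileSpec, generate_profiles, TissueSpec,
                              generate_epidermis, PairSimSpec,
                              generate_sister_pairs)
from acdkit import polarity as pol, morphometry as morph
from acdkit.coordination import (coordination_stats,
                                 coordination_permutation_test)

# 1. fit a noisy synthetic crescent (truth: sigma 35, mu 120, alpha 80, beta 12)
(profile,), _ = generate_profiles(ProfileSpec(
    sigma_deg=35, mu_deg=120, amplitude=80, baseline=12, noise_sd=4, seed=5), 1)
print(pol.fit_crescent(profile).summary())

# 2. call small-cell clusters on a synthetic field with two planted 4-cell clusters
labels, truth = generate_epidermis(TissueSpec(
    field_width_um=180, field_height_um=180, n_cells=100,
    small_cell_fraction=0.1, planted_clusters=[(4, 2)], seed=7))
cells = morph.measure_cells(labels, pixel_size_um=1.0)
report = morph.find_small_cell_clusters(cells, morph.build_adjacency(labels))
print([sorted(c) for c in report.clusters], round(report.fraction_in_clusters, 3))

# 3. sister-pair coordination under mutual suppression (odds ratio 0.3)
pairs = generate_sister_pairs(PairSimSpec(
    n_pairs=2000, p_amp=0.5, p_spa=0.3, coupling_or=0.3, seed=1))
stats = coordination_stats(pairs)
stats.p_perm = coordination_permutation_test(pairs, n_perm=999, seed=2)
print(stats.summary())
```

prints

```
Crescent Gaussian fit
---------------------
sigma (crescent s.d.) :     34.976 deg
mu (crescent centre)  :    120.535 deg
amplitude             :     80.387
baseline              :     11.690
residual sum sq.      :       5319
polarized             : True
[[41, 42, 43, 44], [87, 88, 89, 90]] 0.444
Sister-pair division coordination (n = 2000 pairs)
-----------------------------------------------------------
Obs[SPA]      (SLGC spacing division)        :  0.2965
Obs[AMP]      (meristemoid amplifying div.)  :  0.5010
Obs[SPA+AMP]  (both observed)                :  0.0875
Exp[SPA+AMP]  (independence: Obs*Obs)        :  0.1485
deficit Obs - Exp                            : -0.0610
permutation p-value (two-sided)              :  0.0010
```

The fit recovers the planted parameters (σ̂ = 34.98° vs 35°, polarized);
cluster calling returns exactly the two planted 4-cell groups; and the
suppressed pair simulation shows the expected deficit of the observed joint
division frequency below the independence expectation (0.088 vs 0.149,
permutation p ≈ 0.001).

## Command line

A thin umbrella CLI wraps the library:

```sh
acdkit simulate tissue --seed 7 --out out/            # synthetic inputs
acdkit morph clusters --labels out/labels.tif --pixel-size 1.0 --out clusters.json
acdkit polarity fit --profiles profiles.csv --cutoff 60 --out fits.csv
acdkit lineage classify --cells cells.csv --divisions divisions.csv --out classes.csv
acdkit coord stats --pairs pairs.csv --out stats.json
acdkit run --config pipeline.yaml --out report/       # full pipeline
```

`acdkit run` executes measure → cluster → polarity → lineage →
coordination and writes a report directory whose summary records the
configuration hash and all seeds; identical configurations produce
byte-identical reports.

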