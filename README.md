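# surfionomics

Surface ionomics of pretreated lignocellulose: linking the spatial
distribution of metal ions on sugarcane-bagasse surfaces — imaged by
ToF-SIMS — to the yield of enzymatic saccharification.

## The problem

Pretreatments (steam explosion, microwave:H₂SO₄, organosolv
EtOH:DMSO:ammonium-oxalate, NaOH) change not only the anatomy of the
cell-wall surface but also the composition and spatial arrangement of
adsorbed ions. Glycosyl-hydrolases need free –OH/O⁻ sites to act, so an
ion such as Li⁺ that co-locates with –OH can block hydrolysis even though
the same ion *activates* the enzymes in solution. This package implements
the complete analysis chain for that question, for anyone working with
exported per-ion chemical images (8-bit TIFF/PNG, µm-scale fields) and
reducing-sugar time courses:

1. **Image standardization** (`imgio`) — RGB exports are channel-summed
   and rescaled to 8-bit grayscale; images carry a pixel-size
   calibration.
2. **Segmentation** (`segmentation`) — automatic IsoData (iterative
   intermeans) thresholding, `T ← round((μ_{≤T} + μ_{>T})/2)`;
   connected-component particle analysis (count *N*, total area, mean
   aggregate size, densitometric intensity); coverage fractions such as
   the percent of –OH sites covered by Li⁺.
3. **Surface metrics** (`surface`) — plug-in differential entropy of the
   intensity distribution (nats) with a Gaussian-reference deficit
   ½ln(2πeσ²) − Ĥ; roughness/waviness split at a Gaussian cutoff
   (Ra, Rq, Wa); periodic-structure area fraction via windowed
   autocorrelation; circular-excavation statistics.
4. **Discrimination** (`discriminant`) — Mixture Discriminant Analysis:
   each pretreatment is a Gaussian mixture of R subclasses with one
   shared covariance, fitted by EM; class centroids are seriated along
   the leading discriminant axis into a *similarity string*; adjacent,
   statistically indistinguishable names get a 1 in a binary neighbor
   matrix; averaged matrices are clustered (average linkage) into a
   pretreatment tree; column-wise jackknifing attributes the
   discrimination to parameter groups.
5. **Saccharification curves** (`curves`) — penalized cubic spline
   smoothing (GCV); curve equality by an extra-sum-of-squares F-test
   between pooled and separate fits; fold changes at 10 h; post-10 h
   decay detection; ingestion of ion-in-solution activity tables.
6. **Synthetic data** (`synthetic`) — generates the whole study with
   known ground truth: five treatment image suites whose planted Li⁺
   signatures follow the bundled reference particle table, ion/–OH
   co-location pairs with requested coverage, and reducing-sugar curves
   with planted fold effects (2.04, 1.74, 0.9) and post-10 h decay.

Reference tables from the study (per-ion particle statistics, Li⁺-free
–OH area, ion-salt enzyme activities) ship with the package
(`surfionomics.datasets`).

## Worked example

The bundled demo reproduces the study end to end on synthetic data:

```sh
surfionomics all --seed 42 --outdir demo42
```

prints (abridged `summary.txt`):

```
similarity string : Control - EtOH_DMSO_AO - SteamExplosion - Microwave_H2SO4 - NaOH
merged groups     : [['Control', 'EtOH_DMSO_AO'], ['SteamExplosion', 'Microwave_H2SO4'], ['NaOH']]
training accuracy : 0.938
tree              : ((Microwave_H2SO4,SteamExplosion):0,(NaOH,(Control,EtOH_DMSO_AO):0):1);
top jackknife     : Li (38.5%)
fold changes @10h : Control=1.000, EtOH_DMSO_AO=0.896, SteamExplosion=1.733, Microwave_H2SO4=1.727, NaOH=2.024
decay after 10h   : ['Control', 'EtOH_DMSO_AO']
curve partition   : [['Control'], ['EtOH_DMSO_AO'], ['Microwave_H2SO4', 'SteamExplosion'], ['NaOH']]
```

Reading: the ionic MDA groups the untreated control with the organosolv
pretreatment, pairs steam explosion with microwave:acid, and isolates
NaOH; leaving the lithium parameter group out of the matrix costs the
discrimination the most (38.5% of the cross-validated score), so Li⁺
distribution is the best discriminating parameter; the smoothed curves
recover the planted fold effects at 10 h (2.02 ≈ 2.04 for NaOH,
1.73 ≈ 1.74 for steam/microwave) and flag the post-10 h decay of the
control and organosolv assays. Every stage is also available as its own
subcommand (`simulate`, `segment`, `metrics`, `discriminate`, `curves`)
and as plain library calls.

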