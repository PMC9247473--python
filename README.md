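# curvsort

Curvature-driven lipid sorting analysis for buckled coarse-grained
bilayers.

Biological membranes are curved, and different lipid species prefer
different curvatures: cone-shaped lipids such as phosphatidylethanolamine
or PIP2 enrich in bent regions, cylindrical lipids such as
phosphatidylcholine stay curvature-agnostic.  A standard computational way
to measure these preferences is to compress a bilayer along one box axis
so it buckles into a sustained sinusoid-like fold, then ask where each
species sits as a function of the local signed curvature.  `curvsort`
implements that analysis end to end for coarse-grained (Martini-style)
bilayers, together with a synthetic buckled-membrane generator with exact
ground truth, so every stage of the pipeline is verifiable.

## What it computes

Given coordinate frames (GRO format or in-memory) of a bilayer buckled
along x at compressional strain γ = (X0 − Xi)/X0:

* per-frame leaflet assignment against the local midplane (a buckled
  membrane's leaflets interleave in global z);
* a periodic cubic smoothing spline through each leaflet's headgroup
  positions in the XZ plane, and the signed pointwise curvature

  C(x) = f″(x) / (1 + f′(x)²)^{3/2}   [nm⁻¹]

  evaluated at every lipid's headgroup, with outer-leaflet values
  sign-inverted so concave/convex regions (seen from outside) are
  negative/positive for both leaflets;
* leaflet curvature histograms, normalized per-species enrichment
  profiles F_s(C) binned at 0.05 nm⁻¹ (F ≡ 1 means no sorting, bins
  holding <5% of leaflet lipids are masked), OLS partition slopes per
  species, mean curvature per species, fraction of |C| > 0.1 nm⁻¹, and
  localization along the buckle — all block-averaged (4 blocks, ± SD);
* lipid–lipid contact matrices (1.0 nm cutoff, normalized so random
  mixing is 1), P2 tail order parameters against the local membrane
  normal, splay angles, and descriptor–curvature Pearson correlations.

The synthetic generator builds an asymmetric eight-species plasma-membrane
model (outer leaflet: POPC/PAPC/POPE/DIPE/DPSM/CHOL, 1350 lipids; inner
leaflet adds PAPS and the PIP2 lipid PAP6, 1348 lipids) on a cosine buckle
whose amplitude conserves arc length, and places species with a prescribed
linear curvature-enrichment slope — so imposed sorting can be recovered by
the full measurement pipeline and compared against the imposed truth.

## Worked example

Impose known enrichment slopes on two species of a γ = 0.1 synthetic
buckle, run the full pipeline, and compare:

```bash
curvsort recover --gamma 0.1 --frames 2000 --seed 7 \
    --slope inner:PAP6=-0.393 --slope outer:PAPC=0.245
```

prints

```
leaflet species  imposed  recovered  recovered_sd     bias  n_frames
  inner    PAP6   -0.393  -0.332183       0.12172 0.060817      2000
  outer    PAPC    0.245   0.256033       0.05398 0.011033      2000
```

`recovered` is the 4-block mean OLS slope of the enrichment profile
F_s versus binned curvature and `recovered_sd` the block SD.  PAP6 is
rare (29 of 1348 inner lipids), so its slope estimate is noisy at 2000
frames (block SD 0.12, i.e. a ±0.06 standard error on the mean) — the
recovered −0.33 is consistent with the imposed −0.393 within one SE,
while the abundant PAPC recovers its +0.245 tightly.  More frames shrink
the error as 1/√n.

The same machinery is available as a library:

```python
from curvsort import (make_buckle_profile, plasma_membrane_composition,
                      SortingModel, generate_trajectory,
                      per_lipid_curvature, enrichment_profile,
                      partition_slope)

profile = make_buckle_profile(X0=40.0, gamma=0.1)
traj, truth = generate_trajectory(profile, plasma_membrane_composition(),
                                  SortingModel(), n_frames=100, seed=1)
table = per_lipid_curvature(traj)          # frame, lipid, leaflet, x, C
prof = enrichment_profile(table, "inner")  # F_s per curvature bin
print(partition_slope(prof, "POPE"))       # BlockStat(mean, sd, ...)
```

`curvsort generate` writes GRO frames plus a ground-truth CSV, and
`curvsort analyze` turns a directory of GRO frames into tidy CSV tables
(curvature table, enrichment, slopes, means, extreme fractions,
localization, contacts, descriptors).

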