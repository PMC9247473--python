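# Methods

## Problem and model

`curvsort` quantifies curvature-driven sorting of lipid species in a
buckled, compositionally asymmetric coarse-grained bilayer.  A membrane
compressed along x by strain γ = (X0 − Xi)/X0 buckles out of plane and
exposes a stationary spectrum of signed curvatures; species whose shape
prefers particular curvature accumulate there.  The pipeline measures this
accumulation from coordinate frames alone:

1. **Leaflet assignment.**  Each lipid is represented by one headgroup
   bead (phosphate bead for phospholipids, hydroxyl bead for cholesterol;
   configurable, because the measured curvature depends on the bead that
   defines the surface).  Headgroup z values are averaged in periodic x
   bins (2 nm default); a lipid above the local binned midplane is
   "outer", below is "inner".  The midplane is refined twice as the mean
   of the two per-leaflet binned surfaces, and labels are recomputed every
   frame (cholesterol flip-flops).  A buckled membrane's leaflets
   interleave in global z, which is why no global threshold appears
   anywhere.  The bin count adapts downward for sparse systems so every
   bin keeps ≈8 headgroups.

2. **Leaflet curves.**  Per frame and leaflet, all headgroup (x, z) pairs
   (y collapsed — the buckle is uniaxial) are averaged in 0.25 nm x cells
   and fitted with a periodic cubic smoothing spline, giving the C²
   continuity that a second derivative requires.  The cell abscissa is the
   within-cell mean x, not the cell center (a center abscissa aliases the
   local slope into height noise and roughens f″).  Weights are
   √(count)/ρ with roughness scale ρ (default 0.5 nm) and the FITPACK
   smoothing budget equals the number of cells (discrepancy principle):
   when the actual headgroup noise is at or below ρ the fitted curve
   tracks the surface without chasing noise.  ρ = 0 requests an
   interpolating spline through well-spaced noiseless points, which the
   analytic oracles (flat line, circle, cosine) use.

3. **Signed curvature.**  C(x) = f″(x)/(1 + f′(x)²)^{3/2}, evaluated at
   each lipid's own headgroup x on its own leaflet's curve.  Outer-leaflet
   values are multiplied by −1 so that for both leaflets regions concave /
   convex as seen from outside the cell are negative / positive.

4. **Statistics.**  All lipid C values make per-leaflet density
   histograms.  The enrichment profile bins C with width 0.05 nm⁻¹ and
   reports F_s(b) = [n_s(b)/n_all(b)] / [N_s/N_all]; F ≡ 1 means no
   sorting.  Bins whose mean per-frame occupancy is below 5% of the
   per-frame leaflet lipid count are masked out of every fit.  The
   partition slope is the unweighted OLS slope of F_s against the bin
   center, fitted independently in each of 4 contiguous frame blocks;
   mean ± sample SD over blocks is reported (block SD, not fit SE).
   Mean curvature per species, the fraction of |C| > 0.1 nm⁻¹, and the
   localization probability along x (1 nm bins) complete the summaries.

5. **Contacts and descriptors.**  Two same-leaflet lipids are in contact
   in a frame when any bead pair is within 1.0 nm (minimum image in x and
   y); each unordered pair counts once per frame.  Mean contact counts are
   normalized by the random-mixing expectation E(i,j) = T·f_i·f_j·(2−δ_ij)
   so ideal mixing is 1 in every cell.  Descriptors: bead count, head:tail
   bead ratio (head = headgroup + linker beads, tail = acyl beads — the
   split is a convention exposed in the registry), unsaturation fraction,
   P2 tail order parameter against the local leaflet normal (spline
   tangent rotated 90° in the XZ plane; reduces to global z on a flat
   membrane), and the splay angle between the two tail end-to-end vectors.
   Pearson correlations between per-species mean curvature and any
   descriptor support exclusion lists (e.g. cholesterol).

## Synthetic membranes

No public trajectories exist for this system, so testing rests on a
generator with exact ground truth.

* **Geometry.**  The buckled midplane is a single-period cosine
  z(x) = A·cos(2πx/Xi) with A solved (Brent, 10⁻⁶ nm) so the arc length
  over one period equals X0.  A cosine, not the Euler elastica of a
  compressed sheet: the closed-form derivatives make every downstream
  quantity an analytic oracle, and the statistics contract does not depend
  on the exact shape.  Leaflet surfaces are normal offsets at ±d/2
  (default 2.0 nm, a typical coarse-grained half-thickness).  The offset
  surface has curvature κ/(1 − tκ) and is regular only while |tκ| < 1;
  the generator refuses geometries with max |tκ| ≥ 0.95.  At γ = 0.4 the
  cosine crest radius (≈1.7 nm) is below the default d/2, so strongly
  buckled syntheses use γ ≤ 0.3 or a reduced d/2 — a property of the
  cosine stand-in, not of real membranes, whose equilibrium shape is less
  sharply peaked.

* **Placement.**  Lipid anchors are drawn uniformly in arc length on each
  leaflet surface (so surface density is uniform, as in a tensionless
  membrane); y is uniform; the headgroup bead gets Gaussian z noise
  σ_z (default 0.3 nm, a typical headgroup roughness); remaining beads
  stack inward along the local normal at 0.3 nm.  Species are drawn
  categorically with probability ∝ f_s·max(0, 1 + s·C(x)), renormalized at
  each x, with C the signed leaflet curvature.  If every slope is zero the
  composition counts are honoured exactly (shuffled assignment).  Frames
  are independent equilibrium draws — there is no autocorrelation, so
  block averaging is exercised against a stationary target and recovery
  tests are exact.  Per-frame seeds are spawned from the master seed with
  numpy's SeedSequence; runs are bit-reproducible.

* **Imposed-slope semantics.**  Because the categorical draw renormalizes
  at each x, a raw model parameter s realizes an enrichment slope of
  s·(1 − f) for a species with leaflet fraction f (its own contribution to
  the normalizer cancels).  The recovery harness therefore maps a target
  slope g to the model parameter g/(1 − f), so the synthetic data's true
  linear enrichment slope equals the imposed value.  This is verified
  directly against the generator's own probabilities in the test suite.

* **What the generator does not emulate:** thermal undulations and their
  spectrum, autocorrelated dynamics, leaflet flip-flop kinetics, solvent,
  lipid–lipid interaction physics (contact enrichments beyond those induced
  by curvature localization), and elastica geometry.  Passing tests
  demonstrate that the measurement pipeline is correct and unbiased under
  known sorting; they do not validate force-field-level behaviour.

## Numerical choices

* σ_z default 0.3 nm with ρ = 0.5 nm: with these defaults the measured
  per-lipid curvature is an essentially unbiased predictor of the true
  surface curvature (regression coefficient of truth on measurement
  0.99–1.02).  At σ_z comparable to ρ the fitted f″ becomes noisy enough
  that binning by measured C attenuates recovered slopes (classic
  errors-in-variables), which would bias parameter recovery by tens of
  percent — the default pairing avoids this regime.
* Curvature bins are aligned to multiples of the bin width; the occupancy
  mask is computed on the pooled profile so all blocks fit the same bins.
* Per-block OLS uses bins that are unmasked and nonempty in that block;
  fewer than 3 such bins is an error, mirroring the degenerate-fit
  precondition.
* Block SD uses the sample convention (ddof = 1) over 4 blocks; trailing
  remainder frames are dropped with a logged warning.
* Largest-remainder apportionment turns fractions into counts; ties go to
  the first-listed species.  Explicit counts always override fractions
  (the reference composition's printed counts are not reproducible from
  its printed fractions by any single rounding rule).
* GRO I/O is fixed-width with 3-decimal positions; the round trip is
  bit-stable and residue ids wrap at 100000 silently per the format.

## Statistical power of the recovery checks

A recovered partition slope is estimated from categorical draws of a
species with leaflet fraction f over a curvature spread σ_C ≈ 0.08 nm⁻¹
at γ = 0.1.  The information bound on the slope SE is roughly
1/(σ_C·√N_s) with N_s the number of records of that species; for the
rarest species (f ≈ 0.02, 27–29 lipids per frame) this is ≈0.09 at 400
frames and shrinks with √frames.  The acceptance script therefore uses
20000 / 16000 / 4000 frames for the PAP6 / POPE / PAPC recoveries, which
puts the Monte-Carlo SE near 0.02, comfortably inside the ±0.05
tolerance; the test suite uses 6000 / 6000 / 2500 frames with fixed
seeds.  These problem sizes are a design choice: the per-frame cost of
the pipeline is ~10 ms, so the full recovery sweep remains a few minutes
of compute.

## Known limitations

* The spline roughness scale materially affects the extreme-curvature
  tails of the leaflet histograms; it is a configuration constant, not an
  estimated quantity.
* Contact-matrix normalization is exact for the random-mixing contract
  but the absolute normalized values depend on the bead inventory used
  for the synthetic frames.
* The analysis is strictly uniaxial (one curve per leaflet per frame);
  y-resolved curvature tensors and mean-curvature maps are out of scope.
* Leaflet assignment needs ≈8 headgroups per x bin; extremely sparse or
  extremely noisy membranes (σ_z approaching d/2) will misclassify
  lipids near leaflet crossings.
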