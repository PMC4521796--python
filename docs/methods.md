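# Methods

`retmap` analyzes the spatial distribution of retinoblastoma tumors on the
retina. This note records the models it implements, the assumptions behind
them, the numerical choices, and what the synthetic-data generator does and
does not emulate.

## Coordinate system and geometry

The retina is modeled as a cap of the unit sphere with the fovea at the
pole. A retinal location is `(eccentricity, polar angle)`: eccentricity is
the arc angle from the fovea in degrees, treated as a central angle of the
sphere (clinical "degrees of visual angle" are taken at face value as arc
degrees); the polar angle is measured from the superior vertical meridian
(0°) increasing toward the nasal horizontal meridian (90°) in canonical
right-eye orientation, which places the optic disc near polar angle 88°.
The mapped window is the 60°-radius cap.

Flat maps use the azimuthal equidistant projection about the fovea,
`x = ecc·sin(angle)`, `y = ecc·cos(angle)`. This projection preserves
distances and directions from the fovea exactly and inflates every other
pairwise distance, so planar Euclidean distance ≥ great-circle distance,
with equality only through the fovea. Left eyes are pooled with right eyes
by reflecting across the vertical meridian (superior/inferior preserved,
nasal aligned with nasal); the reflection is an involution.

Areas and centroids of tumor regions are evaluated on the sphere to avoid
projection distortion. A region boundary is a closed polygon whose edges
are great-circle arcs, densified to ≤0.5° steps; the enclosed solid angle
and the first moment of position are computed by trapezoidal line
integrals of the antiderivatives of the spherical area element
(`∮(1−cosθ)dλ` for area, analogous forms for the moment), with the
longitude unwrapped so pole-containing regions are handled by their 2π
winding. Both quantities are validated against a rejection-sampling Monte
Carlo oracle (10⁶ points; agreement within 0.5% for area, 0.2° for the
centroid direction). The centroid is the normalized mean position vector
over the enclosed area (uniform surface density); a perimeter-only
(arc-length-weighted contour) centroid is available as an option because
clinical descriptions are ambiguous about which is meant. Area is reported
as the fraction of the window's spherical area, `2π(1−cos 60°)`.

A circular tumor covering fraction *a* of the window can have its center no
further out than where it touches the window rim. Two forms of this
constraint are provided: the flat-map approximation `60(1−√a)` and the
exact spherical inversion `60 − arccos(1 − a/2)`. They agree at a ∈ {0, 1}
and differ by at most 1.085° (at a ≈ 0.35), well under 2°.

## Tumor maps

Perimeters are recorded as ordered vertex lists. Interpolation between
vertices uses a periodic cubic spline in projected coordinates,
parameterized by cumulative chord length — matching how hand-drawn maps
are traced on the flat chart — while areas/centroids then go back to the
sphere. The spline choice is ours; any smooth closed interpolant through
the vertices would serve. Self-intersecting interpolants trigger a warning
and an even-odd style fill at rasterization.

Rasterization tests pixel centers (default pitch 0.25°, comparable to the
effective fidelity of digitized fundus charts) against the boundary in the
projection, which is a homeomorphism of the window and therefore preserves
region membership. Each pixel's spherical area is its planar area times the
projection Jacobian `sinθ/θ`, so rasterized areas converge to the exact
spherical area as the pitch shrinks (observed ~O(pitch)).

Cumulative burden at a pixel counts distinct *eyes* with tumor there
(several tumors in one eye count once); per-age-quartile maps report the
fraction of that quartile's tumors overlapping each pixel. Margin distance
between two tumors is the minimum great-circle distance between their
densified boundaries (0 with an overlap flag when the regions intersect);
for disjoint circular caps it equals the centroid distance minus the radii.

## Point-process model

Tumor centroids in the window are a marked point pattern (marks: mutation
type, age quartile, area quartile, eye). First-order structure is an
inhomogeneous Poisson process with log-polynomial intensity in the
projected coordinates:

    log λ(x, y) = Σ_{i+j≤d} β_ij x^i y^j

The process likelihood `Σ log λ(x_k) − ∫_W λ` is maximized with the
Berman–Turner device: a dummy grid (default 32×32 cells clipped to the
window, one dummy point per intersecting cell at the centroid of its
in-window part) plus the data points receive counting-measure weights,
cell area divided by points in the cell, normalized so the weights sum
exactly to the window area |W| = π·60². The weighted Poisson GLM
(statsmodels) then yields the maximum-likelihood β. Exact identity: a
degree-0 fit returns log(n/|W|) to numerical precision. Parameter recovery
for a log-linear intensity is verified by simulation (200 replicates, mean
within 2 SE of truth). Default degree is 2; the degree is configurable and
AIC is reported for comparison. Marked fits use the Poisson marking
property — the marked process splits into independent unmarked processes —
so each mark level gets its own intensity, with total log-likelihood/AIC
the sum over levels.

Fitting happens in the flat projection (Euclidean geometry), as is
standard for planar point-process software; the projection inflates
non-radial distances, which if anything *dilutes* apparent clustering, so
the diagnostics are conservative. Great-circle distances are used for the
nearest-neighbor and within-eye analyses where the metric itself is the
question.

Second-order diagnostics: Ripley's K, `K̂(r) = |W|/(n(n−1)) Σ e_ij 1[d_ij ≤ r]`,
with translation edge correction (closed-form disc-overlap weights for the
circular window) or uncorrected; the CSR reference is πr². Envelopes come
from conditional CSR simulations (exactly n uniform points), pointwise
rank envelopes, default 99 simulations with rank 1 (min/max); calibration
is verified by checking a CSR pattern stays inside a rank-3 (central 95%)
envelope at ≥90% of r values. Kernel relative-density maps use a Gaussian
kernel with the uniform (convolution) edge correction, divided by the CSR
intensity n/|W|; for a large CSR pattern the map is flat at 1 within
sampling error.

### Within-eye permutation test

The hypothesis is that multiple tumors within one eye repel each other.
Statistic: the mean great-circle nearest-neighbor distance among tumors
sharing an eye, over all eyes with ≥2 tumors. Null draws resample groups
matching the observed multiplet-size multiset from the full set of
centroids, without replacement within a draw (a with-replacement flag is
provided); `p = (1 + #{null ≥ obs})/(1 + B)`. Calibration at the cohort's
scale (18 pairs + 4 triples among ~129 points): type-I error 0.046 at the
0.05 level over 500 null data sets (B=199), power 1.0 against multiplets
forced to ≥40° pairwise separation (B=999). With only a handful of
multiplets the statistic is noisy and such repulsion is hard to detect;
the reported power applies at the cohort scale.

## Cohort statistics

Fisher's exact test: two-sided p by the point-probability rule (sum of the
probabilities of all margin-fixed tables no more probable than the
observed), for 2×K tables by depth-first enumeration over the multivariate
hypergeometric support; for 2×2 tables the reported odds ratio is the
conditional maximum-likelihood estimate under the noncentral
hypergeometric model (the convention of standard exact-test software; the
sample cross-product ratio is larger). Wilcoxon rank-sum statistics follow
the Mann–Whitney U convention (exact for small untied samples, normal
approximation with tie correction otherwise). Quartile splits cut at the
25/50/75 empirical percentiles with linear interpolation (configurable),
assigning values equal to a cut to the lower quartile; the assignment is
invariant under monotone transforms. Sector tallies cross superior/inferior
location with age quartile, excluding horizontal-meridian and macula
records, and report the exact 2×K p. Circular means of polar angles return
the mean direction and resultant length, with a degenerate-resultant flag.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not patient
data: 67 patients, 58% bilateral (bilateral ⇒ germline), 64% germline; ages
log-normal per mutation type with medians 7.9 (germline) and 21.6 months
(somatic), σ = 0.9 and 0.7 (our choice), clipped to plausible ranges; each
affected eye retained with probability 91/106 (at least one per patient);
germline eyes carry 1 + Poisson(0.54) tumors, others 1 — yielding ≈91 eyes
and ≈129 tumors in expectation. Centroids are drawn per age quartile from
Gaussian-kernel mixtures in the projection (macula + superonasal periphery;
inferotemporal posterior pole; inferonasal quadrant; nasal + superotemporal
periphery; plus a uniform background), giving median centroid eccentricity
increasing from the youngest to the oldest quartile. Kernel centers and
weights are plausible stand-ins encoded from qualitative cluster
descriptions — no fitted values exist — and are configuration, not
constants. Tumor areas are log-normal with medians decreasing by age
quartile (0.05→0.01 of the window) and with eccentricity, truncated so the
tumor fits the window; boundaries are star-shaped caps with low-order
Fourier radial noise (irregularity 0.25), rescaled to within ~1% of the
requested spherical area. Within-eye placements enforce a 20° minimum
separation by rejection (best candidate kept on failure). Fundoscopy-only
small tumors are assigned to sectors with an 84% anterior bias and a
superior share falling across age quartiles (0.65→0.30).

Because the published per-mutation age medians describe all enrolled
patients while the published quartile bins (5.6/8.8/13.2 months) describe
the mapped subset — which excluded older somatic patients — the two are
not mutually consistent for this mixture; the generator keeps the stated
per-mutation medians, so its emergent quartile cuts land somewhat higher
(~6.8/13.5/21.7 at defaults). The generator draws ages first, computes
quartiles per cohort, then samples locations given quartile; quartile
boundaries are therefore emergent, not imposed.

What passing tests on synthetic data show: that the pipeline's estimators
recover the structure the generator put in (intensity clusters, age
trends, repulsion) at realistic sample sizes. What they do not show:
anything about real tumor biology, measurement error of manual MRI
delineation, or the true effect sizes of age-related clustering, which the
generator only stands in for.

## Numerical choices and limitations

- Degrees externally, radians internally; boundary densification ≤0.5° for
  area/centroid, 0.25° for margins (the resolution of margin estimates).
- Raster pitch default 0.25°; pixel centers outside the window are masked.
- Quadrature: 32×32 dummy grid, 8×8 subsampling for clipped cell areas,
  weights renormalized to |W| exactly.
- Envelopes: 99 simulations, rank-1 (min/max) by default; seeds are
  explicit everywhere and all generator substreams derive from one seed.
- Degenerate inputs raise typed errors (out-of-window points, <3 distinct
  vertices, self-intersecting boundaries, antipodally balanced centroids,
  zero-resultant circular means flagged).
- Problem sizes used in the validation suite: Monte-Carlo oracles at 10⁶
  samples; parameter recovery at ~500 points × 200 replicates; permutation
  calibration at 500 data sets × B=199; cohort-structure checks at 200
  seeds — sizes at which the Monte-Carlo error is well below the asserted
  tolerances.
- Not modeled: tumor thickness perpendicular to the retina, the far
  periphery beyond 60°, eyeball biometry, mixed-effects/Tukey analyses of
  eccentricity and polar angle, and Gibbs/interaction point processes.
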