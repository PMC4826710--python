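# Methods

## Scope and data model

`nemasize` estimates four size measures of a nematode — silhouette
perimeter `p`, projected (silhouette) area `a`, body surface area `a_s`
and volume `v` — from routine morphometric measurements. The body is
treated as a solid of revolution: circular in cross-section, with a
radius `r(l)` that varies along the axial coordinate. Non-axisymmetric
features (bursae, lateral alae) are outside the model.

The canonical input is the `MorphometricProfile`: ordered
`(position, radius)` coordinates as fractions of the body length `L`,
plus `L` in metres. Everything internal is computed in these relative
units and scaled by `L`, `L²`, `L²`, `L³` on output, which makes the
estimators exactly scale-equivariant (verified by a property test).

Two published measurement schemes convert into profiles:

* **Cobb's ratios** — five landmark positions `l1..l5` and diameters
  `d1..d5`, both as percentages of `L`. Positions divide by 100,
  diameters by 200: Cobb records *diameters*, the model needs *radii*.
  Because this factor-of-two trap is the standing error of the
  literature, the file readers refuse to guess: CSV/JSON inputs must
  declare `units` (percent / fraction / absolute) and `value_kind`
  (radius / diameter) explicitly.
* **de Man indices** — `a`, `b`, `c`, `c′` determine only four Cobb
  entries (`l3 = 100/b`, `d4 = 200/a`, `l5 = 100(1 − 1/c)`,
  `d5 = 200/(c·c′)`); the converter returns a partial record with the
  rest flagged missing. Profiles with fewer interior coordinates remain
  valid, and the estimators degrade gracefully toward the classical
  two- and three-parameter forms.

Profiles are supplemented with `(0, 0)` and `(1, 0)` so the outline
closes at both tips. Duplicate axial positions are rejected (a radius
function admits no ties), as are zero interior radii.

## Estimators

### Classical

With `L`, maximum diameter `D`, labial (anterior) diameter `d` and the
fractional position `λ` of the widest point:

* cylinder: `v = πL(D/2)²`, with end caps `p = 2L + 2D`,
  `a_s = πDL + πD²/2`, `a = LD`;
* Andrássy: `V_A = 0.8 · πL(D/2)²`;
* Tsalolikhin: `V_T = (πL/24)[(d² + dD + D²) + D²]`, the mean of a cone
  and a frustum on the same `L, D, d`. Its `p`, `a`, `a_s` are computed
  from the explicit composite shape — anterior frustum `d → D` over
  `L/2`, posterior cone `D → 0` over `L/2` — whose volume equals `V_T`
  identically (property-tested to machine precision).

The midlength assumption (`λ = 1/2`) is relaxed by the weighted variant
`V_Tλ = (πL/3)[λ(d² + dD)/4 + D²/4]`, giving the closed-form relative
error `ε_T = (1/2)(1 − 2λ)/(λ + D²/(d² + dD))`, negative when the
widest point lies behind the midpoint. `ε_T` depends only on `d/D` and
`λ`; at `d = 0` the weighting drops out and `ε_T = 0`.

### Piecewise conical frusta

Linear interpolation of the profile decomposes the body into frusta;
their closed-form measures are summed (formulas in the README). Two
conventions matter and are deliberate:

* The perimeter and lateral-surface sums carry a factor 2 for the two
  mirror-symmetric flanks of the silhouette; only with it do the
  cylinder reductions hold.
* Terminal caps `2(r_0 + r_n)` and `π(r_0² + r_n²)` are included; they
  vanish for supplemented profiles and are required for the cylinder
  and composite-shape reductions. Inter-frustum interface discs cancel
  in pairs and are never formed.

The continuous-limit forms (`P`, `A`, `S`, `V` as integrals over
`r(l)`) are evaluated with adaptive quadrature (`scipy.integrate.quad`,
absolute tolerance `1e-12` in relative units, kink positions passed as
breakpoints). Piecewise-linear profiles integrate to the frustum sums
exactly; sphere and cylinder closed forms are recovered in tests.

### Bézier outline

The least-squares Bézier machinery follows the normal equations
`P = (B′WB)⁻¹B′WC` on the Bernstein collocation matrix
`B[j, i] = B_{i,n}(t_j)`; with node count `n + 1` this interpolates.
Three constructions are provided for a supplemented `m`-coordinate
profile (`m = 7` for Cobb data):

* `simple7`: degree `m − 1` through the upper coordinates at uniform
  nodes, mirrored. High-degree interpolation through the closely spaced
  anterior coordinates throws the curve across the body axis (the Runge
  phenomenon); the resulting outline self-intersection is detected by a
  segment-pair test on the mirrored ring (shapely) and reported as a
  warning — the construction is kept for illustration, not estimation.
* `extended13`: one closed degree `2m − 2` curve through the
  `2m − 1` clockwise-ordered boundary coordinates — anterior tip, upper
  flank anterior→posterior, posterior tip, lower flank
  posterior→anterior, closing at the tip — at uniform nodes `i/(2m−2)`.
  Starting and closing at the anterior tip is the only ordering we
  found that keeps the fit tame: open or posterior-started orderings
  put a node gap at a tip and the interpolant oscillates wildly. This
  closure makes the data and nodes mirror-symmetric under
  `t → 1 − t`, so the fitted curve is exactly symmetric.
* `edited`: the extended curve restricted to the lower arc between the
  posterior-tip node (`t = 1/2`) and the node of the anteriormost lower
  coordinate (`t = (2m−3)/(2m−2)`), mirrored for the upper boundary,
  with the remaining anterior gap closed by straight segments from the tip to
  `(l_1, ±r_1)`. This is the construction used for size estimation.

Measures come from the parametric integrals over the retained arc
(`P = 2∫ds`, `A = 2∫y x′dt`, `S = 2π∫|y|ds`, `V = π∫y²x′dt`) plus the
anterior cap's segment, triangle, cone-surface and cone-volume terms.
The surface integral uses the `2π` of a surface of revolution generated
by a single boundary arc; this is the only prefactor consistent with
the cylinder reduction and with the classical comparison table.
Quadrature is fixed-order Gauss–Legendre (64 nodes) with order doubling
until successive estimates agree to `1e-10` relative (polynomial
integrands converge immediately; the arc-length square root needs one
or two doublings). Signed integrals flip with traversal direction;
absolute values are taken after checking that the boundary does not
cross the axis, and the orientation is logged.

## Known systematic deviation of the Bézier measures

For the *A. antarcticus* reference data our edited construction
reproduces the degree-6 control points of the historical worked example
to every printed digit, and its perimeter and projected area agree with
the historical comparison table to ~1.5 %. Its converged surface area
(2.425e-8 m²) and volume (7.924e-14 m³) are, however, ~7 % above the
table's 2.26e-8 and 7.40e-14. We believe the table's Bézier entries
were computed from a coarsely sampled polygon of the same outline: a
~7-to-13-point polygonal evaluation of our retained arc passes through
exactly those printed values, and a polygon inscribed in the bulging
arc always under-measures it. Since no uniform sampling density
reproduces all four printed entries at once, and degrading the
quadrature to chase a historical rounding would be arbitrary, the
package reports the converged integrals. The corresponding checks in
`tests/test_acceptance.py` (Bézier `a_s`, `v`, and the +3.5 % volume
comparison) are left failing deliberately to keep the discrepancy
visible.

Related quirks of the reference table, handled explicitly:

* Its Tsalolikhin perimeter (1.188e-3 m) is below the hard lower bound
  `2L = 1.2e-3 m` that any closed outline of axial extent `L` must
  exceed; the package returns the true composite-shape perimeter,
  1.205e-3 m.
* Several of its entries are truncations rather than roundings of the
  full-precision values (e.g. the Tsalolikhin `a_s`, and the quoted
  percent differences). Table-reproduction tests therefore accept a
  printed value that is either the rounding or the truncation of the
  computed one at the printed precision.

The edited outline's arc overshoots the anterior tip by < 0.01 L (a
residue of the Runge oscillation); the straight anterior closure clips
this tiny excursion, so the fully capped ring technically
self-intersects there. The flanks themselves do not cross, and the
signed integrals are unaffected beyond this sub-percent region.

## Synthetic data

`make_fixture` generates profiles with known properties: cylinder, cone
and frustum (closed-form measures), a fusiform shape — smooth sine/
cosine taper from a blunt anterior radius to a maximum at configurable
`λ`, pointed posterior — for midlength-error studies, and seeded random
slender profiles (`random_monotone`: strictly increasing positions,
radii within (0, 0.05] of `L`, the slender-body regime of real
nematodes; radii at adjacent landmarks are drawn independently, which
is rougher than real animals). These fixtures exercise every code path
without external data; what passing tests show is correctness of the
geometry and algebra, not anything about measurement error, fixation
shrinkage or landmark-identification variance in real specimens.

The independent oracle (`revolve_oracle`) recomputes all four measures
from a dense sampled boundary with plain trapezoid/frustum sums written
directly on the arrays, sharing no code with the estimators; agreement
at `1e-10` relative on 200 random profiles, and O(n⁻²) convergence to
sphere closed forms, are part of the test suite.

## Numerical and design choices

* Normal-equation solve for the control points (the systems here are
  7×7 and 13×13; conditioning is benign). A singular system raises
  with advice rather than silently regularising.
* `classical_params()` derives `(L, D, d, λ)` from a profile as: `D`
  twice the greatest radius; `d` twice the first interior radius; `λ`
  the mean position at which the maximum is attained, clipped to
  [0.01, 0.99] so degenerate shapes (cylinders, cones) stay inside the
  valid domain.
* Reports default to 4 significant figures (`--full-precision`
  otherwise); emitted CSV uses `%.17g` so re-reading reproduces the
  numbers bit-for-bit.
* SVG export writes the sampled mirrored outline as a plain SVG 1.1
  path, with an optional vertical exaggeration factor (10× is the
  field's plotting convention for slender bodies).

## Limitations

* Circular cross-sections throughout; no bursae, alae or cuticular
  ornamentation.
* The Bézier constructions assume the five Cobb landmarks plus two tip
  coordinates; profiles with many more coordinates would push the
  single global high-degree fit further into Runge territory (splines
  are deliberately out of scope).
* Landmark detection, image analysis and Cobb's typographic "formula"
  notation parsing are out of scope; inputs are numeric tables.
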