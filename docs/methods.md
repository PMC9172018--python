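# Methods

## Chamber geometry

The vitreous chamber is a sphere of radius R = 12 mm truncated by the planar
lens indentation at z = R − h_lens (h_lens = 3 mm, so the lens plane sits at
z = 9 mm and the rim meets the sphere at polar angle ψ ≈ 41.4°). The wall is
a structured latitude/azimuth triangulation: polar rings from the rim to the
posterior pole plus a triangulated planar cap sharing the rim ring, which
makes the surface watertight by construction. Ring angles are snapped onto
the segmentation boundaries (60°, 90°, 160°, and the band's half-maximum
edges), so no face straddles a region boundary and discrete zone areas match
their closed forms to ~0.1 % (e.g. the 20° macular cone: 54.5 mm² computed
vs 2πR²(1 − cos 20°) = 54.6 mm²). Volumes and areas converge at second
order in the band width; the default refinement (subdivision 5, ≈ 10.8 k
faces) reproduces the truncated-sphere volume to 0.15 %.

Two axisymmetric, purely radial deformations generate the myopic variants:

* **Staphyloma** — outward displacement d(ψ) = D · s((ψ − ψ₀)/(180° − ψ₀))
  with D = 3.5 mm, onset ψ₀ = 140°, and s the cubic smoothstep: a C¹
  posterior pouch containing the macula, displacing the posterior pole by
  exactly D (axial length 24.5 mm from lens plane to pole).
* **Encircling band** — inward displacement D_c · exp(−(a/σ_c)²) with
  D_c = 1.5 mm, σ_c = half the 4 mm band width, and a the meridional arc
  distance from the equator.

The literature gives no canonical dimensions for either deformation (or the
lens vault); the defaults above are representative surgical values and are
all configurable. Because the deformations are radial, the pre-deformation
polar angle ψ identifies material points across variants: all three meshes
share vertex count and connectivity, and region labels are
deformation-invariant (faces carrying more than half the maximum band indent
are relabelled as the band in the cerclage variant). Hemifields split on the
sign of the face-centroid y; a centroid exactly at y = 0 counts as superior.

Region areas and contact percentages use the **retinal surface** denominator:
everything except the lens cap (the pars plana and the band indent are
included; whether the reference analyses included the pars plana is not
documented, which contributes a ~7 % denominator uncertainty to overall
percentages).

## Fluids and wetting convention

Silicone oil: ρ = 980 kg/m³, μ = 1000 mPa·s. Aqueous: ρ = 997 kg/m³,
μ = 1 mPa·s. Interfacial tension σ = 0.044 N/m; static contact angle at the
oil–water–retina line 16.2° with hysteresis bounds 11.2°/21.2° (the bounds
are carried on the data type but statics uses only the static angle). The
capillary length √(σ/Δρg) ≈ 16 mm is comparable to the eye radius, so
interfacial tension shapes the bubble at the scale of the whole chamber.

The 16.2° angle is read as measured **through the aqueous**: the retinal
surface is hydrophilic and the aqueous is the wetting phase, so the oil
meets the wall at 180° − 16.2°. This reading is what makes oil–retina
contact *lower* than the flat-interface estimate (a non-wetting buoyant
bubble is surrounded by an aqueous wedge climbing the walls), which is the
behaviour observed clinically and in reference simulations; the opposite
reading (oil wetting) would predict contact *above* the flat baseline at
every fill. The convention is a single `wetting_phase` switch on
`FluidProperties` for anyone preferring the through-oil reading.

Postures set the gravity direction in the eye frame: standing (0,−1,0),
supine (0,0,−1) (face-up, gravity toward the posterior pole), and a 45°
upward gaze midway between.

## Static equilibrium solver

Two solvers share the same contact-report interface:

1. **Flat interface** (zero-capillarity baseline): the horizontal plane
   perpendicular to gravity positioned by bisection so the buoyant side
   holds the oil volume (tolerance 10⁻⁶ of chamber volume), with exact
   triangle–plane clipping of every wall face. On a pure sphere it
   reproduces the spherical-cap closed forms (50 % fill → 50.0 % contact;
   95 % fill → 86.5 % vs the cubic-root value 86.8 %). It initialises and
   serves as the σ → 0 oracle for the capillary solver.

2. **Capillary energy minimiser**: the chamber is voxelised (cubic grid,
   default 64³ for tests and 96³ for reporting) by vertical-ray parity
   counting with a deterministic irrational sub-voxel jitter; the voxel
   volume matches the mesh volume to ~0.5 % at 64³, halving per refinement.
   The oil indicator minimises

       E[α] = σ·A(oil–aqueous) − σ cos θ_oil·A(oil-wetted wall)
              + Δρ g ∫_oil (−h) dV

   by volume-conserving threshold dynamics: each sweep Gaussian-diffuses the
   phase field (wall voxels carry the ghost value (1 + cos θ_oil)/2, which
   imposes Young's angle), adds the buoyancy potential scaled by
   γ = σ√(2π)/ε for kernel width ε, and selects the oil voxels as the
   top-k of the resulting score — conserving the oil count exactly at every
   sweep. At a fixed point the score is constant along the interface, which
   is the discrete Young–Laplace balance σκ + Δρ g h = const.

   Numerical choices:

   * **Kernel annealing** (6 → 3 → 1.5 voxels). Binary threshold dynamics
     pins as soon as the per-sweep displacement falls below one voxel; wide
     kernels let the meniscus travel, the final width sets the converged
     resolution. A sessile-drop validation (flat wall, zero gravity)
     reproduces imposed contact angles to ~5° across 16–120°.
   * **Graph topology** (default). The phase is projected after every sweep
     so that, within every contiguous vertical fluid column, oil lies above
     aqueous. This enforces hydrostatic stability (the dense phase cannot
     rest on the buoyant one) and restricts the solver to single-interface
     configurations — the class reachable by settled bulk transport from a
     horizontal initial interface, which is how two-phase transport solvers
     (and post-operative eyes on clinical timescales) actually reach their
     states. The unconstrained mode (`interface_topology="free"`) finds
     lower-energy states in which thin aqueous shells coat wall concavities.
   * **Convergence**: exact fixed point (no flips) or mean interface
     displacement below 0.25 voxel over 10 sweeps; a non-converged run
     returns the best-energy state flagged accordingly. In practice all
     study cases converge within ≈ 30–80 sweeps.
   * **Contact measurement**: a face is oil-wetted iff the trilinearly
     interpolated α one voxel pitch inside the wall is ≥ 0.5 (ties wetted);
     the field is first extended two voxels into the wall so boundary
     interpolation is not biased by outside-domain zeros.

   The solver is fully deterministic — fixed iteration order, no random
   numbers — so sweeps are byte-reproducible.

### What the equilibrium does and does not reproduce

The true constrained energy minimum differs from a transiently settled
two-phase state in two systematic ways, both consequences of near-complete
aqueous wetting (cos 16.2° = 0.96):

* **Concave pockets fill with aqueous.** For any pocket whose wall area
  exceeds its mouth area by more than 1/cos θ ≈ 1.04 — true of any
  staphyloma deeper than ~1.5 mm, and of the band grooves — coating the
  pocket wall and spanning the mouth lowers the energy by far more than the
  gravitational cost. The minimiser therefore predicts an aqueous-filled
  staphyloma pouch (macular contact ≈ 0) even for a standing patient,
  whereas finite-time simulations with contact-angle hysteresis, and
  plausibly real eyes on short timescales, leave oil in the pouch.
  Clinically, poor tamponade of deep staphylomas is a recognised failure
  mode; which state a given eye occupies is a relaxation-time question this
  static model cannot answer.
* **Wall wedges climb far.** With the capillary length comparable to the
  eye radius, the aqueous wedge around the inferior bubble margin spreads
  over much of the lower wall. This is why an 80 % fill touches only ≈ half
  the retina (the flat baseline would say 71 %), in line with reported
  contact figures; at high fill the predicted wedges are somewhat larger
  than transiently settled ones. Wedge extents at 96³ are still 1–2 voxel
  layers short of the continuum limit (contact drops ~5 points from 64³ to
  96³ at 95 % fill), so high-fill inferior contact carries the largest
  discretisation uncertainty.

The study-grid outcomes: overall contact spans ≈ 41–82 % over fills
80–95 %, minimum at the band + 45°-tilt combination; contact is monotone in
fill for every case; standing at ≥ 85 % fill fully wets the macula in the
emmetropic eye (partial at 80 %), while upward-tilt and supine postures
leave it aqueous-covered; supine postures strip the post-equatorial retina.
The staphyloma-pouch and band-groove coating states described above are the
known departures from transiently settled references.

## Saccade kinematics

θ(t) = Σ cᵢ tⁱ (quintic). The published coefficient set (c₂ = 2.01×10⁴,
c₃ = −3.29×10⁵, c₄ = 2.30×10⁶ in deg/sⁱ) evaluated at T = 0.137 s yields
≈ 341°, inconsistent with the stated 50° amplitude, and the printed
equation's c₅ is not tabulated. The default `boundary_condition` mode
therefore keeps c₀ = c₁ = 0 and the published initial acceleration c₂, and
solves c₃, c₄, c₅ from θ(T) = 50°, θ′(T) = θ″(T) = 0 exactly; the resulting
wave is monotone with peak velocity 686 deg/s (physiologic for a 50°
saccade). The raw published set remains available as `table2_verbatim` for
diagnostics. The state is clamped to rest for T < t ≤ 2T, the observation
window for fluid deceleration.

## Reduced-order wall shear

A deliberate surrogate for the unsteady two-phase momentum equation, built
for regional *orderings* only:

* each phase lags the wall as a rigid rotor, dΩ/dt = (ω − Ω)/τ_r with
  τ_r = R²/(k ν) and calibration constant k = 10 (configurable); oil
  (ν ≈ 1.02×10⁻³ m²/s) relaxes ~1000× faster than aqueous;
* per-face stress μ |ω − Ω| r⊥ / δ(t), with r⊥ the distance from the
  vertical rotation axis and δ(t) = min(√(ν max(t, 1 ms)), R) the developing
  boundary-layer depth;
* geometry factor f_geo = exp(−d_pocket/δ)(1 + p_ridge/δ): a recess
  (outward displacement — the staphyloma pouch) shelters the wall, a ridge
  (inward displacement — the band) is exposed. d_pocket additionally
  includes the shadow a taller ridge casts on its meridional neighbourhood
  (exponential decay over the band width): a bump in near-wall flow
  shelters its flanks, and without this term the band would leave
  pre-equatorial stress unchanged rather than reduce it.

The wetted mask comes from the standing 90 %-fill equilibrium (the shear
scenario studied); faces under aqueous see aqueous viscosity. Resulting
orderings: the band indent hosts the global shear maximum; the staphyloma
reduces macular shear (geometric sheltering compounded, in this model, by
the aqueous covering of the pouch); stress vanishes identically without
rotation. Absolute pascal values are not calibrated and should not be
quoted.

## Pipeline determinism and outputs

`run_sweep` emits one long-format row per (variant, posture, fill, region,
hemifield) plus an overall row, with provenance columns (resolution, sweep
count, convergence flag); identical configs produce byte-identical CSVs.
Figure-style pivots (overall vs fill per posture; quadrant curves; regional
bars at 90 % fill) are derived tables. Phase fields export as legacy-VTK
structured points; meshes as STL/OBJ.

## Known limitations

* Statics only: no interface motion during the saccade, no contact-angle
  hysteresis, no aqueous films below voxel resolution.
* The equilibrium-vs-settled distinction above is the dominant model
  uncertainty for deep pockets and high-fill wedges.
* Axisymmetric deformations only; the lens is a flat plane; no optic disc.
* Shear is a scaling surrogate; only orderings are meaningful.
* Reported resolutions: 64³ grids for the test suite, 96³ for the analysis
  drivers and headline statistics.
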