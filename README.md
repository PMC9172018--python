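# tamponade

Static silicone-oil tamponade behaviour in emmetropic and highly myopic
vitreous chambers, and the wall shear the oil exerts during a saccade.

After vitrectomy for retinal detachment, the vitreous cavity is filled with
silicone oil (SiO, density 980 kg/m³, viscosity 1000 mPa·s) that floats on
residual aqueous humour (997 kg/m³) and is meant to press against — and keep
aqueous away from — as much retina as possible. How much retina the oil
actually touches depends on the fill fraction, the patient's posture, and the
shape of the chamber: high myopia adds a posterior staphyloma (an outpouching
that contains the macula), and an encircling scleral band indents the equator.
This package computes, for each combination of those factors, the equilibrium
oil–aqueous configuration and the percentage of each retinal region wetted by
oil, plus a reduced-order estimate of saccadic wall shear stress. It is aimed
at vitreoretinal researchers who want desk-scale, reproducible tamponade
predictions without running a full CFD solver.

## Model

The chamber wall is a triangulated 24 mm sphere with a planar lens cap,
optionally deformed by a smooth radial staphyloma (depth 3.5 mm from a
140° onset) and/or a Gaussian equatorial band indent (1.5 mm deep, 4 mm
wide). The wall is partitioned into pars plana, pre-equatorial retina,
post-equatorial retina, macula (a 20° polar cone) and the band indent, each
split into superior/inferior hemifields.

The static two-phase configuration minimises the capillary energy of the oil
indicator α over a voxelised chamber,

    E[α] = σ A_ow − σ cos θ A_w + Δρ g ∫_oil (−h) dV ,

with σ = 0.044 N/m the interfacial tension, θ = 16.2° the static contact
angle (measured through the aqueous, the wetting phase), Δρ = 17 kg/m³ and
h the height along gravity. The minimiser is volume-conserving threshold
dynamics — Gaussian diffusion of the phase field, wall ghost values encoding
Young's angle, and re-thresholding at the volume-pinned level — annealed
coarse-to-fine and constrained to hydrostatically stable, single-interface
configurations (oil above aqueous in every fluid column). Its σ → 0 limit
reproduces the exact flat-interface solution, which also serves as the
initial condition. Per-region contact is read one voxel inside the wall at
each face centroid.

For the saccade (50° in 0.137 s, a quintic wave with exact rest boundary
conditions), each fluid lags the wall as a rigid rotor with relaxation time
R²/(k ν), and wall shear is estimated per face as
μ |ω − Ω| r⊥ / δ(t) · f_geo, where δ(t) is the developing Stokes-layer depth
and f_geo encodes recess sheltering (staphyloma pouch, ridge shadow) and
ridge exposure (band indent). Shear output is meaningful for orderings
between regions and geometries, not absolute magnitudes.

## Worked example

```bash
python analysis/01_build_geometry.py
python analysis/02_contact_sweep.py          # ~3 min at 96^3 voxels
python analysis/04_saccade_shear.py
```

The geometry step prints the three chamber variants:

```
            variant  faces  volume_mm3  wall_area_mm2  retina_area_mm2  axial_length_mm
         emmetropic  10816      6917.1         1780.0           1582.2             21.0
         staphyloma  10816      7184.9         1842.1           1644.3             24.5
staphyloma_cerclage  10816      6821.0         1826.1           1628.3             24.5
```

— the staphyloma adds 268 mm³ of posterior volume and 62 mm² of retinal
surface (one reason detachment risk rises in myopic eyes), and the band
indents 364 mm³ back. The contact sweep then reports

```
lowest contact:  40.8%  (staphyloma_cerclage, tilt45, 80% fill)
highest contact below complete fill: 81.9%  (staphyloma_cerclage, supine, 95% fill)
```

i.e. across all geometries and postures the oil touches between ~41 % and
~82 % of the retina for fills of 80–95 %: fill fraction, not geometry, is the
dominant factor, and the band is most disadvantageous when gazing 45°
upward. The shear step prints

```
emmetropic           peak shear  15.85 Pa in macula (inferior)
staphyloma_cerclage  peak shear  21.25 Pa in cerclage_band (inferior)
macular time-averaged shear: emmetropic 2.365 Pa vs staphyloma 0.000 Pa
```

— the band indentation concentrates the highest tangential stress, while the
staphyloma pouch shelters the macula (in its equilibrium the macula is
additionally covered by aqueous, so the oil exerts essentially no shear
there).

A CLI wraps the same pipeline (`tamponade sweep`, `tamponade static-contact`,
`tamponade saccade-shear`, `tamponade build-geometry`, `tamponade summarize`),
with YAML configs for every geometry, fluid and solver parameter.

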