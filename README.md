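# cardiosynth

Synthetic cohorts of aortic-valve and left-ventricle geometries for
cardiovascular simulation and machine learning, plus a monodomain
Aliev–Panfilov electrophysiology solver to exercise the generated anatomy.

Patient-specific cardiac geometries are scarce: segmenting multislice CT for
thousands of subjects is impractical, yet surrogate models of valve
hemodynamics need large, anatomically plausible training sets.  This package
generates such geometries algorithmically, from a handful of control
parameters with physiological ranges, so that arbitrarily many valve and
ventricle variants can be produced deterministically or pseudo-randomly.

## What it builds

**Aortic valve.**  Each of the three leaflets is swept from a logarithmic
generating curve in a radial plane,

```
z(x) = H · ln(1 + a·(1 − x/R)) / ln(1 + a),    x ∈ [0, R]
```

where `R` is the aortic (annulus) radius, `H` the leaflet height and `a`
bends the leaflet belly (`a → 0` gives the straight-line limit).  Sweeping
over the 120° sector, the free-edge exponent `k` scales the effective height
by `1 − (|θ|/60°)^k`, vanishing at the commissures.  The aortic root is a
surface of revolution with three sinus-of-Valsalva pockets
(`depth · sin²(πz/h_s) · max(0, cos 3θ)²`).

**Left ventricle.**  An ordered stack of control ellipses along the long
axis is lofted into the inner (endocardial) shell; offsetting every section
radially by the wall offset (default 10 mm) and lofting again gives the
outer shell, and the space between is the wall.  The shipped default profile
(circular sections every 10 mm, height 80 mm, outer radii 21–37.5 mm,
cavity ≈ 124 mL) anchors three systematic families — seven heights
(73–89 mm), seven wall offsets, seven x-shifted/rescaled shapes — for a
default cohort of 22 models, each measured (height, wall thickness,
outer radii, cavity volume) and validated against patient-data envelopes.

**Electrophysiology.**  The monodomain reaction–diffusion model

```
χ_m C_m ∂Φ/∂t = ∇·(D ∇Φ) − χ_m I_ion,    D = (d_iso C_m/χ_m) I + (d_ani C_m/χ_m) a₀⊗a₀
```

with Aliev–Panfilov kinetics `Ĩ_e = c φ(φ−α)(φ−1) + rφ`, a stretch-induced
current gated by fiber tension, the affine dimensionalization
`Φ = β_φ φ + δ_φ` (0 → −80 mV rest, 1 → +20 mV peak), an apex-to-base
activation-time rescaling of the local time scale, and an active-stress ODE
`∂S_a/∂t = ε(Φ)(k_T(Φ − Φ_r) − S_a)` whose tensor enters the second
Piola–Kirchhoff stress along fiber/sheet/normal directions.  Discretisation:
mass-lumped linear finite elements (surface meshes or 1D cables), zero-flux
boundaries, explicit forward Euler below the spectral stability bound.

## Worked example

```python
from cardiosynth import build_lv, default_profile, measure_lv

meas = measure_lv(build_lv(default_profile()))
print(f"height {meas.height:.1f} mm, outer radius {meas.radius_min:.1f}-{meas.radius_max:.1f} mm, "
      f"cavity {meas.cavity_volume_ml:.1f} mL")
```

prints

```
height 80.0 mm, outer radius 21.0-37.5 mm, cavity 123.6 mL
```

— the default ventricle is 80 mm tall, its outer surface spans radii from
21 mm (base/apex rings) to 37.5 mm (equator), and the endocardial cavity
holds 123.6 mL, inside the 108–140 mL physiological window.  The same
numbers are available from the shell:

```sh
cardiosynth generate-lv --out lv/ --format vtk
cardiosynth generate-cohort --default --out cohort/     # 22 models + manifest.csv
cardiosynth generate-valve --R 11.25 --H 12 --a 1 --k 2 --out valve/
cardiosynth simulate-ep --cable 100,401 --T 600 --out cable.csv
```

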