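# Methods

## Geometric conventions

All geometry lives in millimetres.  The ventricular long axis and the valve
axis are +Z; the LV base and the valve annulus plane sit at z = 0, the LV
apex at z = height.  Meshes are indexed triangle surfaces with
counter-clockwise faces seen from outside, so watertight meshes have
positive signed volume; watertightness means every undirected edge is
shared by exactly two faces.

Lofting stitches same-θ vertices of consecutive rings (no twist
minimisation) and caps ends with triangle fans to the section centroid.
Because lateral quads between two concentric n-gon rings are planar, the
discrete volume of any circular piecewise-linear radius profile equals the
analytic solid-of-revolution integral π∫r(z)²dz times the inscribed-polygon
factor (n/2π)·sin(2π/n) — an identity the tests verify to 1e-10 relative.
At the default n_θ = 96 the factor is 0.99928; volume-sensitive tests use
n_θ = 256 (0.9999) against a 0.5 % analytic tolerance.

## Mesh metrology

Height is the extent of vertex projections on the measurement axis.  Radius
statistics are taken over lateral (non-cap) vertices, excluding a 2 mm
apex-exclusion band so a rounded or tapering apex cannot drive the minimum
radius to zero; the average is area-weighted (one third of each lateral
face's area per corner).  For meshes re-imported from files, where builder
metadata is lost, cap vertices are inferred as vertices on an end plane
lying radially inside that plane's outermost ring.

Wall thickness is the nearest-point distance from each inner-shell lateral
vertex to the outer lateral surface (exact point–triangle distances over
KD-tree candidate faces).  This is deliberately a normal-type, not radial,
measurement: a uniform 10 mm radial offset yields sub-10 mm thickness where
the meridian slopes, down to 10·Δz/√(Δz²+Δr²) ≈ 7.81 mm on the steepest
default base segment.

Radii are reported for the **outer** shell.  This is an interpretation, not
a given: with outer radii 21–37.5 mm and a 10 mm wall the cavity volume
lands at ≈ 124 mL, inside the measured patient window of 108–140 mL,
whereas reading the same numbers as inner radii would roughly double the
volume.  Likewise "sections grow by 10 mm" is read as +10 mm radius, which
is consistent with near-10 mm maximal wall thickness.

## Valve model

The printed sources describe the guiding curves only as logarithmic; the
concrete family z(x) = H·ln(1 + a(1−x/R))/ln(1+a) is this package's
definition.  It satisfies the qualitative roles of the parameters — the
endpoints are pinned by R and H, `a` bends the belly, and the a → 0 limit
is the straight line — and is evaluated in the linear limit for a < 1e-8.
The free-edge exponent acts on the height profile f(θ) = 1 − (|θ|/60°)^k
(∂f/∂k > 0 at interior angles: larger k flattens and raises the edge); an
alternative reading, k shaping in-plane curvature, was considered and
rejected as underdetermined.  The generating plane rotates about the valve
axis, so the free edge is the axial locus x = 0 — the three leaflets meet
along the axis as in a closed (coapted) configuration, but contact is not
modelled and leaflets are zero-thickness midsurfaces.

Root: cylinder of annulus radius and bulb height; sinus pockets use the
axial window sin²(πz/h_sinus) with azimuthal sharpness max(0, cos 3θ)², and
the window's peak height is inserted into the axial grid so the maximal
radial coordinate equals annulus radius + sinus depth exactly.  Adult
defaults are range midpoints: radius 11.25 mm, bulb 21 mm, sinus height
18.5 mm, depth 2.25 mm.

## Default LV profile and families

The control-ellipse values behind the published 22-model table are not
public; the shipped default profile is a calibrated stand-in.  Inner radii
(11, 19, 24, 27, 27.5, 25.5, 22, 17, 11) mm at 10 mm spacing with a 10 mm
offset reproduce the printed height (80 mm) and outer-radius extremes
(21/37.5 mm) exactly and place the cavity volume physiologically; the
profile is linearly resampled to 65 rings before lofting.

Families: the height family rescales z affinely (computed as
z/height_old·height_new so target heights are attained exactly in floating
point) with radii unchanged; the thickness family replaces the wall offset
(8.5–11.5 mm); the shape family applies per-section centre shifts and mild
radius rescales, calibrated so variants keep height 80 mm, base/apex rings
(hence 21 mm minimum radius) untouched, and maximum radii within the
37–38.5 mm span of the systematic families.  The published per-row
thickness statistics (for example a 3.36 mm minimum for the default model)
are not derivable from a uniform radial offset under any thickness
definition we constructed; the package reports its own nearest-point
statistics instead.

Validation is two-tier: *hard* failures mark models outside the generation
design ranges (malformed synthetics, e.g. height outside 73–89 mm) or valve
parameters outside their population ranges; *warnings* mark dimensions
outside the measured patient envelope (height 75–85 mm, wall 8–11 mm,
radius 26–31 mm, volume 108–140 mL, ±15 % slack on volume), which the
families intentionally bracket.  The default cohort produces zero hard
failures.

Pseudo-random valve cohorts draw uniformly within the population ranges
(the distribution is unstated in the sources; uniform is this package's
choice) from numpy's PCG64 with a recorded seed.  Leaflet height samples
8–14 mm and the shape parameters a ∈ [0.1, 5], k ∈ [0.5, 4] — spans chosen
to cover visibly distinct bellies and edge shapes while respecting the
≤ 14 mm leaflet envelope.  A 70/30 mixture weighting the commonly observed
diameter sub-range is available behind a flag, default off.

## Electrophysiology

State: nondimensional potential φ (≈0 rest, ≈1 excited), recovery r, active
stress S_a.  Kinetic constants default to the canonical Aliev–Panfilov set
c = 8, α = b = 0.15, γ = 0.002, μ₁ = 0.2, μ₂ = 0.3.  The dimensionalization
Φ = β_φ φ + δ_φ is forced to β_φ = 100 mV, δ_φ = −80 mV by the printed
−80/+20 mV range.  The recovery equation is implemented in the canonical
form (γ + μ₁r/(μ₂ + φ))(−r − cφ(φ − b − 1)); the delay function as the
bounded double-exponential ε(Φ) = ε₀ + (ε₁ − ε₀)exp(−exp(−ζ(Φ − Φ_t)))
(the published form is typographically garbled; this is the standard
sigmoid matching its stated role, with the inner exponent clipped at ±700
to avoid float overflow in saturated tails).  The stretch gate θ is the
Heaviside tension switch H(λ − 1); λ defaults to 1 everywhere, so the
mechano-electric current vanishes unless a stretch field is supplied.

Time runs dimensionally (ms).  The reaction terms are divided by the local
time scale β_t = t_β(1 − τ₀(t_a − t₀)/(t₁ − t₀)) with apex-to-base
activation time t_a = t_α(1 − Z/Z_apex), Z measured from the base so the
apex activates first and, having the largest β_t, repolarizes last at the
apex/base extremes consistent with "last depolarized, first repolarized".
The constants t_α = 40 ms, t_β = 12.9 ms, τ₀ = 0.5, t₀ = 0, t₁ = 40 ms are
literature-style calibration knobs, unconstrained by the sources, as are
χ_m = C_m = 1 (model units), d_iso = 0.2, d_ani = 0.4 mm²/ms, G_s, φ_s and
the active-stress constants (k_T = 0.5 kPa/mV, ε₀ = 0.1, ε₁ = 1 ms⁻¹,
ζ = 0.1 mV⁻¹, η = (1, 0.4, 0.2)).  All are overridable.

Discretisation: P1 finite elements with the conductivity tensor projected
onto each element plane, lumped mass, zero-flux boundaries; the stiffness
matrix is symmetrised exactly, annihilates constants (hence pure diffusion
conserves the mass-weighted total potential to round-off), and the explicit
step is 0.9·2/λ_max with λ_max from 60 fixed-seed power iterations,
additionally capped by the reaction scale t_β/(2c).  Integration aborts
with a diagnostic if |φ| exceeds 2.  Default stimulation injects 0.5 ms⁻¹
for 2 ms (total ≈ 1 in φ units): enough to cross threshold, small enough
per explicit step.  The default fiber map is circumferential with an
optional helix angle — a generic map, acknowledged as a limitation since
real myofiber architecture is subject-specific.

Front speed obeys the √D reaction–diffusion law; the tests verify a
2.0 ± 5 % speed ratio between d_iso and 4·d_iso on a 100 mm, 401-node
cable, probed between x = 30 and 70 mm to avoid boundary transients.

## Problem sizes and determinism

Defaults balance fidelity against interactive runtimes: n_θ = 96 with 65
z-rings per LV shell (the 22-model cohort builds and measures in a few
seconds), n_θ = 256 for volume-convergence checks, 401-node cables for wave
tests.  Everything outside `sample_valve_cohort` is deterministic;
artifact-producing commands write byte-stable files (fixed formatting, no
timestamps) and record their full configuration, seed and package version
in a run manifest.

## Known limitations

No leaflet thickness, contact or material model; no deformation-based
closure; no valve-orifice boolean cut or LV/valve alignment; no volumetric
meshing; no passive finite-elasticity mechanics (so no pressure–volume or
strain loops); fluid–structure interaction and wall-shear-stress analysis
are out of scope.  Synthetic profiles emulate printed summary dimensions,
not real endocardial contours: passing tests show the generators hit their
calibrated measurements and the solver obeys its conservation/scaling laws,
not that any specific patient anatomy is reproduced.
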