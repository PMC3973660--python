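# Methods

`lvemech` simulates the contraction of an idealized rat left ventricle and
measures how the assumed tissue microstructure — the transmural rotation of
myocyte (fibre) orientation and the laminar (sheet) organisation — changes
global pump function and local strain. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Geometry

The left ventricle is a thick-walled truncated ellipsoid: the wall is the
region between an endocardial and an epicardial ellipsoid sharing a centre,
cut by a base plane perpendicular to the long axis (z; base at z ≥ 0, apex
at negative z). The default dimensions are the tabulated rat values
(epicardial semi-axes 0.34, 0.48, 0.95 cm; endocardial 0.16, 0.27, 0.79 cm;
truncation at the equator), which give a closed-form unloaded cavity volume
of 2/3·π·0.16·0.27·0.79 ≈ 0.0715 cm³ and an x-axis wall thickness of
0.18 cm. The truncation height is configurable; the equator is the default
because it reproduces both the printed cavity volume and wall thickness.
Lengths are centimetres throughout (configurable label only).

Meshes are structured: a transmural × azimuthal × apico-basal hexahedral
grid mapped onto the shell and subdivided into tetrahedra with the Kuhn
6-tet split (face-conforming, robust for the warped cells and the collapsed
apex ring). Box meshes (conduction wedges/bars) instead use a
parity-alternating 5-tet subdivision: the Kuhn split's uniform body
diagonal measurably skews travelling-wave arrival times across a wedge
cross-section at desk resolution, and the alternating split cancels that
bias. At the default edge length (0.05–0.06 cm) the discrete cavity and
tissue volumes are within ~0.5 % of the closed forms.

The normalized transmural depth w (0 at endocardium, 1 at epicardium) is
evaluated in closed form along the ray from the origin through each element
centroid, using the fact that the implicit ellipsoid coordinate scales
linearly along such rays; meshes without a generating ellipsoid fall back
to relative surface distances (facet-limited accuracy). Material axes are
r = ∇w/|∇w| (outward radial), l = long-axis direction orthogonalized
against r, c = l × r, a right-handed orthonormal triple; near the apex,
where l degenerates onto r, c falls back to the azimuthal direction.

## Microstructure

The helix angle follows the Streeter-type rule
θ(w) = R · sgn(1 − 2w) · |1 − 2w|ⁿ, i.e. +R at the endocardium, 0 at
midwall, −R at the epicardium, linear for n = 1 and cubic for n = 3. The
rule-based family is the 4 × 4 grid R ∈ {50, 60, 70, 80}°,
n ∈ {0.5, 1, 2, 3} (named Sn{n}R{R}), 16 models. The sheet angle β varies
either linearly between endocardial and epicardial values (default ±45°) or
as a sigmoidal "bimodal" step β(w) = β_endo + Δβ/(1 + e^{−k(w−1/2)}) with
k = 30, a distinct but smooth transition over roughly 0.15 of the wall.

Frames are built per element: f rotates c about r by θ; s rotates r about
f by β; n_vec = f × s. The n_vec = f × s convention keeps every (f, s, n)
triple right-handed (det +1); it flips the sheet-normal sign relative to
rotating l directly, which is immaterial because the sheet normal is an
axial quantity.

The subject-specific variant partitions the ventricle into 16 regions
(basal and mid thirds in 6 azimuthal sectors each, apical third in 4 — the
17-segment clinical scheme with the apex cap dropped) and fits one (R, n)
pair per region to axial fibre observations by minimizing the mean axial
angular error arccos|f_pred · v_obs|. The fit is a deterministic coarse
grid (R in 1° steps over [30, 90]; n log-spaced over [0.25, 4], 17 values;
ties break toward smaller n then smaller R) refined by Nelder–Mead clipped
to the grid box, with boundary solutions flagged. With the default
wrapped-Gaussian angular noise of 15° (the dispersion reported for rodent
DT-MRI primary eigenvectors) and a few hundred elements per region, R is
recovered within ±2° and n within ±0.1 in practice.

## Electrophysiology

Tissue voltage obeys the monodomain equation
χC_m ∂V/∂t = ∇·(σ∇V) − χI_ion + I_stim with
σ = σ_f ff' + σ_s ss' + σ_n nn'. Space: linear tetrahedra; time: Godunov
splitting with explicit nodal cell steps at dt_ode = 0.01 ms and an
implicit diffusion solve (consistent mass, prefactorized sparse LU) at
dt_pde = 0.1 ms. Activation time is the first upward crossing of −20 mV,
linearly interpolated between steps.

The cellular kinetics are pluggable; the bundled default is a two-variable
Mitchell–Schaeffer-type excitation model (v ∈ [0,1] with cubic upstroke,
recovery gate h; V = −80 + 100·v mV) with τ_in = 0.3, τ_out = 6,
τ_open = 60, τ_close = 31 ms, giving an action-potential duration near
50 ms — rat-like timing for the pipeline contract, not an ionic model. Two
consequences matter for experiment design: the ignition threshold is
v* = τ_in/τ_out ≈ 0.05, so the total injected stimulus charge divided by
the tissue volume must stay below v* or the whole domain self-ignites
(stimulus defaults respect this); and the front has a diffusive foot of
length ≈ D/CV that must clear any region where conduction velocity is
measured.

Conductivities are calibrated, not asserted: planar-wave simulations on a
thin structured bar (equivalent to the mid-section of a cubic wedge by
no-flux symmetry; 1.2 cm × 3 × 3 cells at dx = 0.0125 cm) measure CV as the
inverse slope of activation time versus distance over the central 30–70 %
window, and σ_f is rescaled by (CV_target/CV)² — the cable-theory
CV ∝ √σ law — until the fibre CV matches the target within 1 % (2–3 runs);
then σ_s = σ_n = σ_f/ratio². Defaults target CV_f = 0.06 cm/ms with a
fibre:cross-fibre ratio of 2 (rodent-plausible), giving σ_f ≈ 4.6 mS/cm
with χ = 1400 /cm and C_m = 1 µF/cm². Measured closure at desk resolution:
CV within 0.1 % of target, ratio within 0.5 %, and quadrupling σ doubles CV
to within 0.1 %.

The ventricular run stimulates the apical 15 % of the long axis
(30 µA/mm³-scale volumetric current for 1 ms) on the once-refined post-P
mesh and produces a full apex-to-base activation in ~25 ms.

## Mechanics

Quasi-static finite elasticity (inertia and gravity neglected) with the
exponential orthotropic strain-energy function

    W = C0/2 (e^Q − 1) + κ (J ln J − J + 1),
    Q = b_ff E_ff² + b_ss E_ss² + b_nn E_nn²
      + b_fs(E_fs²+E_sf²) + b_fn(E_fn²+E_nf²) + b_sn(E_sn²+E_ns²),

with E the Green–Lagrange strain in the (f, s, n) basis. Stiffness
exponents: orthotropic (6.0, 7.0, 3.0, 12.0, 3.0, 3.0) and transversely
isotropic (6.0, 4.3, 4.3, 7.5, 7.5, 4.3) in the order (ff, ss, nn, fs, fn,
sn); the transversely isotropic set is exactly invariant to rotations of
(s, n) about f, which is the operative meaning of averaging the orthotropic
parameters. C0 = 0.88 kPa and κ = 100 kPa are declared defaults; κ is a
convex volumetric penalty (zero and stationary at J = 1) validated by the
near-incompressibility of pressurized solves (median J within 0.2 % of 1).
Active contraction is a rank-one second Piola–Kirchhoff stress
S_a = T_a f⊗f along the reference fibre.

Discretization: 10-node quadratic tetrahedra with straight edges (affine
geometry), 4-point quadrature, total-Lagrangian Newton iterations with the
analytic consistent tangent (verified against finite differences of the
residual to 1e-8). The endocardial pressure is a follower load implemented
through its exact potential −p·V_cavity(u): the cavity is closed by the
endocardial surface plus a fan over the base rim to a fixed cap point, and
the gradient and Hessian of the enclosed volume (polynomial in the nodal
coordinates) enter the residual and tangent exactly, so Newton retains
quadratic convergence under pressure. A backtracking line search guards
against overshoot of the exponential stiffening; load steps halve on
failure. The base constraint fixes the long-axis displacement of the base
plane (in-plane motion free); three in-plane pin components on two base
nodes remove the remaining rigid modes (the metrics are rigid-motion
invariant, so the pin choice is immaterial).

The unloaded-geometry procedure shrinks a reference mesh by a uniform
factor s and passively inflates it to the preload (default 0.5 kPa),
bisecting on the cavity-volume mismatch until the inflated (post-P) cavity
is within 2 % of the reference; uniform scaling leaves w and all frames
unchanged, so the structure field is reused. The default coupled
configuration treats its geometry (the tabulated pre-P semi-axes) as
already unloaded and derives post-P by a single inflation.

## Coupling

One-way: (1) geometry and structure; (2) post-P inflation with a fixed
reference material law — fixed so that the activation map is identical
across the mechanics configurations being compared and electrophysiology
never depends on mechanics parameters; (3) monodomain solve on the refined
post-P mesh (linear tets); (4) nodal activation times mapped to mechanics
elements by nearest centroid in the post-P configuration; (5) mechanics
marched as warm-started quasi-static solves at dt_mech = 1 ms under the
sigmoidal cavity pressure p(t) = p_end/(1 + e^{−(t−t_mid)/τ}) (defaults
p_end = 1 kPa, t_mid = 30 ms, τ = 6 ms — deliberately below physiological
rat pressures, following the contraction-model literature) and the
per-element twitch T_a(t) = T_max sin²(π(t − t_act)/t_twitch) (T_max =
35 kPa, t_twitch = 90 ms). States, deformation gradients, cavity volume
and pressure are sampled every 2 ms.

The default duration is 70 ms: with apical activation complete by ~25 ms
and the sin² twitch peaking ~45 ms after local activation, 70 ms is
approximately the time at which full contraction (minimum cavity volume)
is achieved, which is how the simulation window is defined; past it the
twitch decays and the maintained pressure re-inflates the ventricle, so
metrics evaluated at later times no longer describe contraction.

## Metrics

Global, comparing the first and last sampled states: ejection fraction
EF = (V(t0) − V(t1))/V(t0) from the cavity-closure volume; wall thickening
WT as the change of the 4-ray mean wall thickness on the midventricular
short-axis slice (50 % of the long axis; rays at 0/90/180/270° from the
slice cavity centroid, epicardial minus endocardial hit distance); and
base-to-apex shortening SBA as the change in apico-basal length tracked at
the epicardial apex node (negative = shortening). Local: the Green–
Lagrange strain at element centroids rotated into the cylindrical basis
(circumferential, longitudinal, radial) — E_cc, E_cl, E_cr — averaged over
equal basal/mid/apical thirds, optionally with the first-sample (residual)
value subtracted so traces start at zero. On-axis elements (undefined
radial direction) are excluded. All metrics are invariant to rigid motion
and match closed forms on analytic motions to better than 0.5 %.

## Synthetic data

The generator replaces every external input. Fibre observations emulate
DT-MRI primary eigenvectors: the truth fibre rotated by a wrapped-Gaussian
angle (default sd 15°, the reported rodent dispersion) about a random
perpendicular axis, with a random sign flip (axial data); wrapped-Gaussian
noise is used rather than von Mises–Fisher because it controls the angular
standard deviation directly. The analytic motion composes in-plane
scaling, long-axis scaling and torsion, with the exact deformation
gradient available everywhere, so EF, WT, SBA, E_cc and E_cl all have
closed forms; this makes the metrics module testable without a physics
run. What passing these tests does *not* show: the noise model has no
spatially correlated tensor-fit artefacts, the analytic motions are
smoother than real wall motion, and the geometry has no papillary muscles
or right ventricle — agreement with the synthetic truths bounds
implementation error, not physiological fidelity.

## Problem sizes and determinism

Default desk-scale sizes: volume/fitting meshes ~15–30 k linear tets;
mechanics meshes 2 × 12 × 6 (or 2 × 10 × 5 for side-by-side comparison
batches) hex cells → ~700–850 quadratic tets (~4 k free dofs); EP meshes
the once-refined mechanics corners (~6 k tets); CV bars ~2 k nodes. A full
coupled 70 ms run completes in one to a few minutes on one core. Every
stage is deterministic given its configuration and seed; the only random
sources are the observation generator and test fixtures, all driven by
explicit `numpy` generators.

## Known limitations

The cell model is phenomenological (no ionic currents, no restitution
protocol fidelity); active tension is fibre-only (no cross-fibre
component); the pressure trace is prescribed (no circulation, no enforced
isovolumic constraint — near-isovolumic behaviour emerges from the sigmoid
timing); the coupling is strictly one-way (no deformation feedback on
conductivity, no mechano-electric feedback); and the geometry is an
idealized ellipsoid. Quantitative agreement with measured rodent strains
is out of scope; the pipeline is built for controlled comparisons between
microstructure models under identical conditions.
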