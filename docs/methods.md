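# Methods

`lvmech` estimates regional left-ventricular (LV) systolic material
properties from per-sector end-systolic strains and chamber volumes, and uses
the fitted model to simulate revascularization of ischemic myocardium.  This
note records the model, its assumptions, the numerical choices, and what the
synthetic verification does and does not demonstrate.

## Geometry

The computational domain is an idealized LV: a truncated prolate spheroid
whose endo- and epicardial surfaces are confocal-center ellipsoids (default
endocardial semi-axes 20 x 50 mm, 10 mm equatorial and 6 mm apical wall,
truncation at 50% of the long semi-axis above the equator).  The long axis is
+z, the base plane is z = 0 and the apex points to negative z; all lengths
are millimetres.  The wall is meshed with a structured grid of trilinear
hexahedra (transmural x circumferential x longitudinal) and the apical hole
is closed with a butterfly (O-grid) cap, which avoids collapsed nodes and the
singular Jacobians a polar closure would produce.  An idealized geometry is
used because the workflow this package implements normally starts from
patient-specific surface reconstructions that are not distributable; every
downstream computation (sectorization, fibers, solves, inversion) is
geometry-agnostic.

The interventricular septum is located by casting rays from epicardial facet
centroids along their outward normals against a right-ventricular endocardial
triangle surface (a synthetic RV half-shell generator is provided); facets
hitting the surface within 10 mm form the `septal_epi` set that carries RV
pressure.  An angular-wedge fallback (default +-60 degrees about -x) covers
the case of a missing RV surface.

The AHA 17-sector partition labels every element by its centroid:
basal/mid/apical thirds along z (6/6/4 circumferential sectors), apex cap =
sector 17.  The circumferential origin is the anterior RV insertion, taken as
the counter-clockwise edge (viewed from the base) of the septal facet wedge;
numbering advances across the septum so sectors 2-3 / 8-9 / 14 are septal.
Centroids exactly on a boundary take the lower-numbered sector — a
deterministic, mesh-independent tie-break.

Local cardiac frames per element: e_r is the outward transmural direction,
e_l the projection of +z onto the plane normal to e_r, e_c = e_l x e_r.
Myofibers follow the rule-based helix angle, linear in the transmural
coordinate from +60 degrees at the endocardium to -60 degrees at the
epicardium, evaluated per integration point.

Cavity volume is the divergence-theorem volume of the endocardial surface
closed by a fan cap over the basal rim; it is exactly invariant to rigid
motions and converges to the analytic half-ellipsoid value at better than
first order (observed roughly second order).

## Constitutive model

Passive myocardium is the transversely isotropic Fung-exponential law
W = C/2 (e^Q - 1) with
Q = b_f E11^2 + b_t (E22^2 + E33^2 + 2 E23^2) + b_fs (2 E12^2 + 2 E13^2)
in the fiber frame, b_f = 49.25, b_t = 19.25, b_fs = 17.44.  The material is
treated as nearly incompressible with a volumetric penalty
U(J) = kappa/2 (J-1)^2, kappa = 10^3 kPa by default (the element-average J of
converged states stays within [0.95, 1.05] at physiologic loads).

Active contraction is a time-varying elastance model evaluated at end
systole only: T0 = Tmax Ca0^2/(Ca0^2 + ECa50^2) Ct with the
length-dependent calcium sensitivity
ECa50 = (Ca0)max / sqrt(exp(B (l - l0)) - 1), sarcomere length
l = lR sqrt(2 E11 + 1), and defaults Ca0 = (Ca0)max = 4.35 umol/L,
B = 4.75 um^-1, l0 = 1.58 um, lR = 1.85 um, all configurable.  Ct is held at
its peak (end-systolic) value 1: the isovolumic phases and the
ED-to-ES path are not modeled, only the two equilibria.  Tension is clamped
to zero once l <= l0.  Active stress acts along the fiber direction only; a
`crossfiber_fraction` switch exists and defaults to 0.

Regional disease enters through two 17-sector maps.  Passive stiffness
scales with the LGE (infarct transmurality) score, C_n = C_H (1 + 9 LGE_n/4),
so a transmural infarct is ten times stiffer than healthy tissue.
Contractility scales with both LGE and the stress-perfusion score SP through
the ischemia effect alpha in [0, 1]:
Tmax_n = Tmax_H (1 - LGE_n/4)(1 - alpha SP_n/3).  With alpha = 0 the SP
score has no effect — that identity is what virtual revascularization
exploits.

## Forward solves

Quasi-static total-Lagrangian FEM on hex8 elements: full 2x2x2 Gauss
integration of the anisotropic stress, selective reduced integration of the
volumetric penalty at the element centroid.  (The latter is the practical
equivalent of a mean-dilatation/B-bar treatment for trilinear hexes and
prevents near-incompressible locking.)  Pressures are follower loads on the
endocardial (LV) and septal-epicardial (RV) facet sets, converted at
1 mmHg = 0.133322 kPa; their load-stiffness contribution is assembled, so
Newton convergence stays near quadratic.

Boundary conditions follow the apex-to-base contraction convention: basal
nodes are fixed axially (u_z = 0) but slide freely in-plane.  The one-sided
RV septal load then has no static reaction path, and — worse — it excites a
pendulum mode: the whole ventricle tips about its sliding base, resisted
only by wall bending at the basal ring, which is weak and strongly
mesh-dependent (uncontrolled, the apex swings by tens of millimetres and
contaminates longitudinal strains).  Both pathologies are removed by a weak
quadratic penalty (10^5 mN/mm on the mode amplitude) on the *whole-body*
mean lateral displacement (x and y) plus the basal-ring mean rotation about
z; physiological torsion (apex twisting against the base) is untouched.
The penalty carries the net lateral septal force with a mean drift of order
0.01 mm; it plays the stabilizing role the pericardium and right ventricle
play in vivo.

Nonlinear solution: damped Newton (backtracking line search, residual-norm
decrease enforced, trial states with inverted elements rejected) inside an
incremental load ramp (10 equal steps by default, automatic halving on
divergence, regrowth after easy steps), relative residual tolerance 1e-8.
End-systole is continued jointly in pressure and activation from the
converged ED state.  For very soft walls (C_H of order 0.01 kPa) the
cold-start tangent is nearly singular and load stepping alone stalls; the
passive solve then switches to a homotopy in the stiffness scale — solve at
s x C (s found adaptively), then walk s geometrically back to 1.  A 200-step
reference ramp agrees with the homotopy solution to 2e-9 mm, confirming both
land on the same equilibrium.  Everything in the solver path is
deterministic: identical inputs give bit-identical states.

The meshed geometry is taken as stress-free; no unloaded-state recovery is
attempted.  Reported strains are Green-Lagrange tensors of the ED-to-ES
deformation (F_ES F_ED^-1), rotated into the element frames and
volume-averaged per sector — consistent with tagged-CMR strain referenced to
tags laid at end-diastole.  Whether sector averages should instead be
midwall-sampled is an open convention; volume weighting was chosen as the
less noisy estimator on coarse meshes.  Longitudinal strain in the basal
rings is contaminated by the sliding valve-plane constraint (it can even be
positive there); circumferential and radial strains are unaffected, and the
sign conventions (E_cc < 0, E_rr > 0 in a contracting healthy model) hold in
all sectors.

## Inverse problem

Stage 1: C_H is calibrated so the model EDV matches the measured EDV, by
Brent root finding on log10 C_H (EDV is strictly decreasing in C_H), bracket
[1e-4, 1e2] kPa, volume tolerance 0.1%.

Stage 2: (Tmax_H, alpha) minimize
J = 1/(2N) sum_n [(Ecc_n - Ecc_n*)^2 + (Ell_n - Ell_n*)^2]
    + W ((V_ES - V_ES*)/V_ES*)^2
over the N = 16 non-apical sectors, W = 10.  The optimizer works on
normalized coordinates (Tmax_H/350 kPa, alpha) with bounds
Tmax_H in [1, 1200] kPa, alpha in [0, 1]: a coarse grid scan of the bounded
domain (Tmax_H in {100, 350, 600} kPa x alpha in {0, 0.5, 1}, plus the
user's initial guess) seeds a bounded Nelder-Mead refinement with an
explicit, well-scaled initial simplex, absolute tolerance 1e-3 on the
normalized parameters and an evaluation budget of 200.  The global pre-scan
matters: the strain/volume MSE surface can develop a secondary valley at
alpha = 0 with depressed Tmax_H (uniformly weaker contraction partially
mimics ischemia-patterned weakness), and a purely local simplex started near
that valley converges into it.  A derivative-free method was chosen because
each objective evaluation is a nonlinear FE solve and the objective has a
kink wherever a sector crosses the active-tension clamp.
Failed forward solves are penalized, not fatal.  When no sector has SP > 0,
alpha cancels out of the contractility map and is frozen at 0 rather than
pseudo-estimated.  ED states depend only on C_H, so stage 2 reuses one
cached ED solve; ES solves warm-start from the previous trial, which cuts a
typical evaluation to a few damped-Newton iterations.

Caching is keyed on (C_H, Tmax_H, alpha) per mesh; C_H stays fixed during
stage 2 (no joint refinement), matching the two-stage design.

## Virtual revascularization

For a fitted model with alpha > 0 the end-systolic solve is repeated with
alpha = 0 and all else fixed.  Per-sector radial strains before/after are
compared with the wall-motion-based estimate
E_rr_WM = E_rr_BL (1 + 0.5 dWM), dWM = WM_baseline - WM_followup (positive =
improvement; the sign convention is fixed by the rule's anchoring in a
normal grade meaning at least 50% thickening).  The rule is applied in every
sector including dyskinetic ones (E_rr_BL < 0); excluding them is a
reasonable alternative convention the report's per-sector table makes easy
to apply downstream.

## Synthetic verification — what it shows

The synthetic module forward-simulates with known (C_H, Tmax_H, alpha) using
the published per-subject pressures and 17-segment LGE/SP score maps, and
the resulting strain/volume tables become the optimization targets
(optionally with seeded Gaussian strain noise; noiseless by default, as in
the original verification protocol).  Recovery is exercised for ground-truth
alpha in {0, 1} and several initial guesses; on the test-scale mesh the
recovered Tmax_H and alpha agree with the truth to well under 1% and the
fitted ESV to well under 2%.  The density-ladder estimation study reports
the per-level parameters and their relative changes; its behaviour at desk
scale is described under "Discretization behaviour" above.

These are inverse-crime tests by construction: targets and model share the
discretization and constitutive family, so they validate the estimation
machinery (identifiability, optimizer, two-stage split), not the model's
fidelity to real hearts.  Real CMR strains carry measurement noise,
segmentation and registration error, breathing artifacts and
model-mismatch (border zones, transmural property gradients, residual
stress), none of which the generator emulates beyond optional i.i.d. strain
noise.

## Discretization behaviour at test scale

Forward volumes converge monotonically with refinement (EDV moves by ~2.8%
then ~1.8% along the 162/432/900-element ladder), and circumferential sector
strains are stable to a few percent.  Longitudinal sector strains are the
slow quantity: the sliding valve-plane constraint creates a bending boundary
layer at the base whose small-magnitude E_ll dominates the mean
longitudinal discrepancy between coarse levels.  Consequently the
density-ladder estimation study (the analogue of a clinical-scale mesh
convergence study) still shows several-percent movement of the recovered
Tmax_H between desk-scale levels — sub-2% parameter stability requires
meshes in the thousands of elements, consistent with clinical-scale ladders
that only stabilize beyond ~8000 elements.  alpha, by contrast, is recovered
exactly at every density.  Sector domains are made density-stable by
anchoring the AHA origin and the apical offset on facet node lines, so the
ladder comparison isolates field discretization rather than relabeling
noise.

## Problem sizes

The default test-scale mesh is 2 x 12 x 6 (162 elements, ~800 dof), the
convergence ladder adds 3 x 16 x 8 (432 elements); generators accept any
density (the 3 x 40 x 22 configuration reproduces the coarse end of the
clinical meshing ladder).  These sizes keep a full recovery run in the
minutes range on one CPU while populating every AHA sector with several
elements; parameter-recovery accuracy is tolerance-limited, not
density-limited, at this scale.

## Known limitations

- End-systole-only activation: no isovolumic phases, no ejection dynamics.
- Idealized geometry; no patient surface import.
- No border-zone model between infarcted and healthy sectors.
- Passive exponents (b_f, b_t, b_fs) fixed; only C_H is estimated, from EDV
  alone (no diastolic strain data).
- Basal longitudinal strains reflect the valve-plane constraint.
- The calcium/length constants of the active law are literature defaults,
  configurable but not identified from data.
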