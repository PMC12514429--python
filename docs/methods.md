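# Methods

This note documents the physical model, the numerical choices behind it,
and what the package's tests do and do not establish.

## Physical model and assumptions

The simulated system is one periodic unit cell of a "top-bottom" electrode
pair: a comb finger of width `w` on the bottom wall of a chamber of height
`H`, facing a planar counter-electrode that spans the entire top wall. The
cell width is one comb period, `W = w + gap`, and the side walls are
symmetry planes, so the cell represents an infinite parallel array of
fingers. Everything is 2-D: the comb fingers are assumed long compared to
the chamber height, and end effects are ignored.

Assumptions inherited from the linear electrokinetic framework:

* **Ideally polarizable electrodes.** No faradaic reactions; the
  electrode/electrolyte interface is a pure capacitor.
* **Linear double layer.** The double-layer voltage is treated as small
  (order of the thermal voltage), so the charging dynamics are linear and
  the bulk remains electroneutral and purely resistive. At multi-volt
  drive this is quantitatively wrong, which is precisely why the slip
  carries an empirical correction factor (below).
* **Thin double layer.** The Debye length (tens of nm here) is vanishingly
  small compared with the geometry, so the double layer enters only
  through its surface impedance and the slip velocity evaluated at the
  outer edge of the layer.
* **Stokes flow.** `Re ~ 1e-2` for 100 µm/s velocities in 100 µm
  geometry; inertia is dropped. The time-averaged slip removes oscillatory
  forcing, so the flow is steady.
* **Dilute particles.** Tracers do not disturb the field or the flow and
  do not interact with each other; electrode saturation is not modeled.

### Electrostatics

The potential phasor satisfies Laplace's equation with a Robin condition
on each electrode expressing continuity between the bulk ohmic current and
the double-layer charging current:

    sigma dphi/dn_out = j omega C_DL (V_j - phi),

with `V_j = +V0` on the bottom finger and `-V0` on the top wall
(anti-symmetric drive, `V0 = v_pp/2`; phasors carry peak amplitude).
Non-electrode wall portions are insulating; side walls are symmetry
planes. The outward-normal form is used on both walls; its sign was
verified against a hand-derived 1-D circuit model (below).

`C_DL = Lambda * eps_m / lambda_D` where `lambda_D` is the Debye length of
the electrolyte and `Lambda = Cs/(Cd+Cs)` is the Stern/total capacitance
ratio. `Lambda` defaults to 0.25, a typical value for gold electrodes in
dilute KCl; it is **not** a fitted or literature-certified value for this
device and is fully configurable (including a direct `C_DL` override).
The KCl content is derived from the configured conductivity through the
limiting molar conductivity of KCl (149.85 S cm²/mol) unless given
explicitly — the natural closure for KCl-adjusted DI water.

### Slip

The time-averaged electroosmotic slip on an electrode is

    u(x) = -(eps_m / (4 eta)) * Lambda_eff * d/dx |phi(x) - V_j|^2 .

The 1/4 prefactor embeds the time average for peak-amplitude phasors.
`Lambda_eff` (default 0.02) is a single multiplicative correction factor
standing in for both the capacitance-ratio weighting of the double-layer
voltage and the empirical overprediction of linear theory at several
volts. Collapsing the two into one factor avoids double-counting a
quantity that cannot be separated experimentally; users who want the
explicit composition can set `Lambda_eff = Lambda_exp * Lambda` by hand.

### Stokes flow

Stream-function/vorticity formulation: `lap(psi) = -w`, `lap(w) = 0`, with
`psi = 0` on all boundaries (closed cell), Thom wall-vorticity formulas
imposing the tangential slip on the top/bottom walls, `w = 0` on symmetry
side walls (an option switches the side walls to no-slip for verification
cavities). Velocities are `u = dpsi/dy`, `v = -dpsi/dx`, which makes the
discrete field divergence-free to round-off. Pressure is recovered
diagnostically by line integration of `grad p = mu (-dw/dy, dw/dx)` and
gauged to zero at the bottom-left corner — a single gauge point is
mathematically sufficient, whereas pinning several corners would
over-determine the problem.

### DEP and particle tracing

DEP uses the point-dipole force with the bulk (outer-region) field;
`|E_rms|^2 = |E_peak|^2 / 2`. The particle conductivity follows the
surface-conductance model `sigma_p = sigma_bulk + 2 Ks / r` with defaults
`sigma_bulk = 0`, `Ks = 1 nS` for latex — declared defaults that put the
1 µm bead's DEP crossover at 4 mS/m, not certified material constants.

Tracing is overdamped (Stokes number << 1): `dx/dt = u_fluid + F/(6 pi eta
r)` with plain Stokes drag (no Faxén wall corrections), integrated by
fixed-step RK4. Gravity, buoyancy and Brownian motion are excluded by
default (Brownian displacement ~0.7 µm/s^1/2 against ~100 µm/s flow); a
seeded Brownian term is available for sensitivity studies. A particle
sticks permanently when its center comes within one radius of the top or
bottom wall; all wall portions stick (modeling irreversible adhesion), but
only electrode sticks count as "trapped". Side symmetry planes reflect.

## Numerical choices

* **Grid.** Tensor-product, geometrically graded from `min_spacing`
  (0.75 µm) at the electrode edges and both walls up to `target_spacing`
  (3 µm) in the bulk; electrode edges are grid nodes. The potential solve
  is a conservative finite-volume scheme (discrete maximum principle
  holds); the sparse complex system is solved by LU.
* **Mesh default.** Chosen by a convergence study of the trapped-proportion
  metric over 6/4/3 µm target spacings; at 6 µm the geometry-optimum
  location was not yet mesh-converged, at 3 µm it is stable.
* **Stokes conditioning.** The psi rows are O(1) while vorticity rows are
  O(1/h²); the assembled system is equilibrated (max-abs row and column
  scaling) and polished with one iterative-refinement step, restoring
  linearity in the slip to ~1e-9 relative.
* **Slip edge treatment.** The field has an integrable singularity at the
  electrode edges; the endpoint derivative of `|phi - V_j|^2` is one-sided
  and clamped to the adjacent interior value (configurable) to avoid
  mesh-dependent blow-up. Slip grid-convergence is asserted away from the
  outermost 5% of the electrode.
* **Advection sampling.** Particle velocities are sampled as derivatives
  of a bicubic spline of the stream function, so the interpolated field is
  exactly divergence-free and tangent to streamlines: advected particles
  conserve psi to well under 1% of its range over 10 s, and halving the
  time step moves free particles by far less than 1 µm. (Naive
  component-wise bilinear interpolation fails both properties — particles
  spiral across streamlines and stick spuriously.)
* **Time step.** `dt = cfl * target_spacing / v_max` (cfl = 0.4). The DEP
  drift speed entering `v_max` (and the sampled drift itself) is capped at
  `dep_drift_cap` (default 2) times the peak fluid speed: the point-dipole
  force diverges at the edge corners, which would otherwise drive the step
  to zero under refinement, while any particle inside that few-µm corner
  zone is in the process of being captured regardless — the cap preserves
  force direction and capture outcomes.
* **Degenerate inputs.** A bottom electrode spanning the full cell width
  gives the parallel-plate (1-D) problem used for verification; zero slip
  gives identically zero flow; a release pitch larger than the chamber is
  rejected.

## Verification oracles

Two closed-form solutions derived by hand anchor the solvers:

1. **Parallel-plate circuit model.** For a full-width bottom electrode the
   problem reduces to two double-layer capacitors in series with a bulk
   resistor: `Delta phi_bulk / 2 V0 = Z / (2 + Z)`, `Z = j omega C_DL H /
   sigma`. The 2-D solver matches this across four decades of frequency
   (the finite-volume scheme is exact for fields linear in y).
2. **Couette–Poiseuille cavity.** A closed long cavity with uniform bottom
   slip `u0` has the zero-net-flux profile `u(y) = u0 (1 - 4 y/H +
   3 (y/H)^2)` at mid-cavity; the Stokes solver agrees to < 2%.

The Clausius–Mossotti implementation is checked against its analytic low-
and high-frequency limits to 1e-9, and its bounds `[-1/2, 1]` by a
randomized property test.

## Study conditions and problem sizes

The geometry studies run the full chain per swept value at the reference
drive (6 V_pp, 1 kHz, 1 mS/m, `Lambda_eff = 0.02`, 100 µm electrode):
heights {50, 90, 120, 160, 220, 300, 420} µm at 200 µm gap, and gaps
{30, 60, 100, 160, 240, 320, 400} µm at 160 µm height. Particles are
released at t = 0 on a 15 µm lattice offset half a pitch from the walls
(60–560 particles depending on chamber size) and traced for 60 s. The
7-point grids are deliberately coarse: the claim defended is the location
of the trapping optimum, not point-wise curve values. For the height sweep
the gap is held at 200 µm by default; a 100 µm variant is equally runnable
through the configuration.

The trapped-proportion counts are granular (one particle = 0.3–1.7
percentage points), which is the dominant uncertainty of the sweep curves;
the release lattice is part of the study conditions and is not refined to
polish them.

## What the synthetic data does and does not emulate

The velocimetry fixtures (constant-velocity, solid-body-rotation and
flow-field-advected track generators) emulate the *geometry* of tracked
bead data: frame-sampled positions in pixel or physical units, optional
positional jitter, TrackMate-style column dialects. They do not emulate
detection/linking failures, fluorescence blinking, depth-of-field losses
or the image saturation that makes slip hard to track near the electrode
in real experiments, so passing velocimetry tests shows the
post-processing is correct, not that tracking errors are handled.

## Known limitations

* 2-D model: no axial flow along the fingers, no comb-end effects.
* No electrothermal body force — at higher conductivity/voltage a second
  vortex regime appears in experiments that this model cannot produce.
* No faradaic reactions; predictions below ~100 Hz at these voltages are
  qualitative at best.
* The experimental slip magnitude enters only through `Lambda_eff`; the
  package reproduces trends and optimum locations, not absolute
  velocities, unless `Lambda_eff` is calibrated against measurements.
* Stick-on-contact plus point-dipole DEP concentrates many captures at
  the electrode edge corners; captured-position *distributions* along the
  electrode are therefore less reliable than capture *counts*.
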