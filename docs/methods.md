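# Methods

`pulsewave` couples a forward model — one-dimensional pulse-wave propagation
in networks of compliant tubes — with an inverse method that locates and
sizes a fusiform aneurysm from waveforms measured at accessible sites.  This
note records the model, its assumptions, the numerical choices, and what the
synthetic fixtures do and do not represent.

## Forward model

### Governing equations

Each vessel segment is a thin-walled, axisymmetric elastic tube.  With
cross-sectional area `A(x,t)`, mean axial velocity `u(x,t)` and internal
pressure `p`, mass and momentum conservation give

    A_t + (A u)_x = 0
    u_t + (u^2/2 + p/rho)_x = -8 pi mu u / (rho A)

closed by the elastic tube law

    p = p_ext + beta(x) (sqrt(A) - sqrt(A0(x))),
    beta = sqrt(pi) h E' / A0,   E' = E/(1 - sigma^2).

The friction term assumes a Poiseuille profile.  The local pulse-wave speed
is `c^2 = beta sqrt(A)/(2 rho)`; at the reference area this is the
Moens–Korteweg-type speed `c0^2 = h E' / (2 rho a0)` with lumen radius `a0`.
The system is strictly hyperbolic and subcritical (`|u| < c`); its Riemann
invariants `w_{f,b} = u ± 4c` advect at `u ± c` and carry all boundary
coupling.

Spatial variability (taper, aneurysm bump, thickness laws) enters through
`A0(x)` and `beta(x)`.  Because pressure is evaluated from the *local* tube
law inside the momentum flux, the scheme solves the tapered-vessel momentum
equation without a separate geometric source term.

### Discretization

Interior nodes advance with a two-step MacCormack predictor–corrector
(forward-difference predictor, backward-difference corrector), second-order
accurate on smooth solutions; the friction source is integrated pointwise in
both stages.  The grid-convergence test confirms better than first-order
error reduction under mesh halving, and a small-amplitude inviscid pulse
propagates at `c0` within 0.1 % with < 1 % shape error over 1.6 m — the
d'Alembert benchmark.

The time step is adaptive, `dt = CFL · min(dx / (|u| + c))` over all nodes
(default CFL 0.5).  Each segment has its own uniform spacing; short,
almost-rigid fittings (wave speed ~790 m/s) are deliberately meshed at two
cells via a per-segment spacing hint so they do not throttle the global
step — their internal wave dynamics (transit time ~0.1 ms) is irrelevant,
while their junction impedance, which is what reflects, is treated exactly
by the junction solver.  Monitored quantities are recorded every step and
resampled to a uniform 1 kHz output grid by linear interpolation.

### Boundary conditions

* **Inlet** — a prescribed velocity, pressure or flow series.  The outgoing
  (backward) invariant is advected from the interior foot point; combined
  with the prescribed quantity this fixes `(A, u)` at the node.  Prescribed
  pressure is converted through the linearized forward-wave relation
  (`dw = 2 dp / (rho c0)`); exact inversion of the tube law is available via
  a flag.  A prescribed series is held at rest beyond its end (with a
  warning); in periodic mode the series is wrapped modulo the period.
* **Junctions** (2- or 3-way) — continuity of flow rate and of total
  pressure `p + rho u^2/2` across all incident ends, solved by damped Newton
  iteration together with each end's outgoing invariant (relative residual
  1e-10, warm-started from the previous step; a static-pressure variant
  exists for sensitivity checks).  Measured area-step reflection matches the
  transmission-line coefficient `(Y1-Y2)/(Y1+Y2)` to ~1e-4.
* **Terminals** — `nonreflecting` freezes the incoming invariant at its rest
  value; `windkessel` couples the outgoing invariant to a three-element
  R1–(C ∥ R2) load integrated implicitly (the capacitor state is eliminated
  in closed form each step).  `R2 = 0` degenerates to a pure resistor; with
  `R1` equal to the characteristic impedance `rho c0 / A0` an incident pulse
  is absorbed to < 1 %.

Periodic runs can start from a uniform elevated pressure (warm start) so
that a repeating solution is reached within the standard three cycles; the
aortic-chain fixture verifies cycle-2 vs cycle-3 agreement within 2 % of
pulse pressure.

## Aneurysm model and indicators

A fusiform aneurysm adds an outward bump to the healthy radius.  Two
families are implemented:

* **arc** — the laboratory shape: a central circular arc tangentially
  conjugated to the straight wall through arcs of radius `R_s`; the free
  radius follows in closed form from the tangency constraint,
  `R_A = ((L_A/2)^2 + d^2 - 2 d R_s)/(2d)` with `d = D/2 - a_v`, and the
  profile is C1 everywhere.
* **cosine** — `a = a0(x) [1 + (k/2)(1 - cos 2π(x-x1)/L_A)]`; `k = 1`
  doubles and `k = 2` triples the local radius.

For pulse wavelengths much longer than `L_A` the bump acts as a lumped
excess compliance

    dC_A = ∫ (2π a_A^3/(E'_A h_A) - 2π a_v^3/(E'_v h_v)) dx,

reducing, for a uniform wall, to `dC_A = (2π a_v^3 L_A / E'h) K` with the
dimensionless profile ratio

    K = (1/L_A) ∫ ((a_A/a_v)^3 - 1) dx

taken pointwise so that vessel taper cancels when the bump scales the local
radius.  For the cosine family `K = (3/2)k + (9/8)k^2 + (5/16)k^3` exactly
(2.9375 for `k=1`, 10 for `k=2`).  The reflection kernel of such a lumped
compliance is, in the frequency domain,

    R(omega) = (i omega tau / (1 - i omega tau)) e^{i omega Dt},
    tau = rho c0 dC_A / (2 A0) = (L_A / 2 c0) K,
    Dt  = 2 x_A / c0,

i.e. an inverted, delayed copy of the incident wave plus an exponential
relaxation tail `-delta(t-Dt) + H(t-Dt) e^{-(t-Dt)/tau}/tau`.

### Known model limitation: the inertance term

The lumped derivation matches pressure across the insertion and balances
the flow-rate jump against the compliance alone.  A widened section also
*reduces* the flow inertance by `|dL| = rho ∫ (1/A_v - 1/A_A) dx`, which
adds to the reflectivity.  For a small radius increment `δ` the compliance
scales as `3δ` and the inertance as `2δ`, so the true low-frequency
reflection exceeds the compliance-only kernel by a factor approaching
`1 + 1/3` — uniformly in frequency.  An exact linear transmission-line
oracle (impedance recursion over the bump profile) confirms this: for the
smallest laboratory bump (D = 24 mm) the simulated backward wave is ~4/3 of
the kernel prediction (L2 mismatch ~22–32 % depending on viscosity), while
for D = 50 mm, where the cubic compliance dominates, the kernel matches to
~12 %.  The same factor appears as a systematic ~1.3–1.5× overestimate of
fitted `tau` for small aneurysms.  The kernel is kept compliance-only —
that is the method under study — and the bias is documented rather than
corrected.

## Inverse method

### Pipeline

For a co-sited pressure/velocity pair the pipeline is: locate the pulse
onset `t0`; separate forward and backward waves; optionally Gaussian
high-pass both; least-squares fit `p_f * R(·; tau, Dt) + B` to the backward
wave over the window `[t0 + Dt, t0 + Dt + f_w T]` (default `f_w = 1/3` of
the period `T`), the window tracking the candidate lag.  For a lone
velocity waveform (e.g. carotid), where forward and reflected waves travel
together and separation is impossible, the filtered velocity itself serves
as both convolution source and fit target.  Fitted `(tau, Dt)` convert to
`dC_A = 2 A0 tau/(rho c0)`, `K = 2 c0 tau / L_A` (for an assumed aneurysm
length) and distance `x_A = c0 Dt / 2`.

### Numerical choices

* **Onset detection** — first crossing of a threshold (default 5 %) on the
  smoothed derivative marks the first upstroke; the foot is back-projected
  to the pre-onset baseline along the tangent at the upstroke's steepest
  point.  Flat or noise-only records raise rather than return a guess.
* **Separation** — the classic linear split `p_{f,b} = (dp ± rho c0 du)/2`
  is the default.  A `characteristic` variant separates in Riemann-invariant
  space of the tube law (`c(p) = c0 sqrt(1 + dp/(2 rho c0^2))`), needs no
  extra parameters, and is exact for finite-amplitude simple waves, where
  the linear split leaks `~dp^2/(16 rho c0^2)` of the forward wave into the
  backward channel.  The laboratory fixtures (pulse amplitude `u/c0 ≈ 5 %`)
  use the characteristic variant.  Pressures are referenced to the mean
  over a pre-pulse baseline window (default 50 ms).
* **High-pass** — `w - G*w` with a Gaussian of width `delta = 6 tau_expected`,
  kernel normalized to unit sum.  Record ends are reflect-padded by default;
  a `wrap` mode performs exact circular filtering and is used for records
  holding one heartbeat period.  Filtering is applied to the convolution
  source as well (it commutes with the kernel), keeping the fit
  self-consistent; a flag restores the variant that convolves the raw,
  unfiltered forward wave.
* **Kernel convolution** — the delta term is an index/spline shift of the
  incident wave; the exponential tail uses the exact one-pole recursion for
  piecewise-linear input (stable for any `tau/dt`).  Fractional-sample lags
  interpolate the unshifted response with a cubic spline — adequate for
  these smooth, well-sampled signals and free of the ringing an FFT shift
  can introduce at the rest-to-pulse transition.
* **Optimiser** — exhaustive grid (lag step = one sample; 30 log-spaced
  `tau` values over the configured range) with the linear background `B`
  solved in closed form at each node, then a Nelder–Mead polish of
  `(log tau, Dt)`.  Fully deterministic; noiseless synthetic fits recover
  `tau` to < 1 % and the lag to within one sample.
* **Degenerate inputs** — a flat target returns a background-only fit with
  `tau` flagged undefined; windows that would extend past the record raise.

## Synthetic fixtures

The fixtures module generates every study condition programmatically.

* **Laboratory rig** (`rig-control`, `rig-D24/34/44/50`) — water-filled
  elastic main tube (ID 17 mm, wall 2 mm, E 2.8 MPa, 2 m long, measured-type
  wave speed 21 m/s), an exchangeable 14 cm segment carrying the arc bump
  (`L_A` 9 cm, `R_s` 10 mm, peak diameters 24–50 mm) centred 57 cm from the
  inlet, a ~rigid fitting (E×1000, ID 12 mm), a 6.5 m discharge tube and a
  wide (10× area) reservoir with a non-reflecting outlet.  The piston
  stroke (100 cm^3 over 0.6 s) is imposed as an inlet velocity; its
  two-humped shape — a half-sine with a smooth mid-stroke notch —
  qualitatively emulates the load-modulated pump.  The Poisson ratio of the
  rubber-like tube is taken as 0.5 (incompressible), and the fitting length
  (10 cm) is a declared assumption.  Monitors sit 2, 10, 25 and 50 cm from
  the main-tube inlet; detection uses the 2 cm site, an unfiltered backward
  wave, and a lag window that closes before the distal-fitting reflection
  (round trip ~0.19 s) returns.
* **Aortic chain** (`aorta-chain-healthy/-AAA2/-AAA3`) — a serial reduction
  of a systemic arterial tree: the fifteen aortic segments from arch to
  abdominal bifurcation with their tabulated lengths and inlet/outlet
  diameters, the two common carotids branching at the arch, wall thickness
  from the radius-dependent arterial law `h = a0(0.2802 e^{-5.053 a0} +
  0.1324 e^{-0.1114 a0})` (radius in cm), E = 225 kPa, sigma = 0.5, blood
  density 1.04 g/cm^3, viscosity 4 mPa s.  Per-segment mean wave speeds
  recomputed from these laws agree with the tabulated values to ~0.1 %.
  The AAA is the cosine bump (`L_A` 10.4 cm, starting 1 mm into the
  10.6 cm Abdominal Aorta IV segment); AAA-2/AAA-3 give `tau` = 35.0 /
  119.2 ms at the segment's mean `c0` = 4.36 m/s.  Omitted side branches
  are absorbed into three-element Windkessel terminals: matched proximal
  resistance `R1 = rho c0/A0`, total resistance set by a 12.5 kPa mean
  pressure at 85 ml/s mean inflow split 85 %/7.5 %/7.5 % between the distal
  aorta and the carotids, and `R2 C = 1 s`.  The inlet is a periodic
  `sin^2` systolic flow pulse (ejection 0.3 s, heartbeat 1 s); runs last
  three cycles from a 10 kPa warm start and analyse the final cycle.
  Carotid detection is velocity-mode at mid-carotid with `wrap` filtering
  and `tau_expected` = 35 ms.

Ground truths (K, `dC_A`, `tau`, per-site round-trip lags over the
tabulated segment speeds) are recomputed from the geometry module at build
time; nothing is hard-coded.

### What the fixtures do not represent

The chain is a deliberate reduction: with the side branches lumped into
matched terminals, its background reflections are weaker than a full
arterial tree's, so the healthy-chain detection floor here (AAA-2 ≈ 13×
above it) bounds the method's intrinsic, not clinical, specificity.  The
pump is kinematic (no crank/load feedback; the per-aneurysm waveform
differences of the experiment are not reproduced), wall viscoelasticity and
3-D flow are absent, and measured-data artefacts (probe noise, alignment
jitter) appear only through the seeded `add_noise` helper.

### Observed detection behaviour at the shipped conditions

Simulate → detect on the four rig fixtures recovers the aneurysm distance
within 10 % (fitted lags 48.8–50.4 ms vs the 52.5 ms round trip to the
bump centre) and orders the severities strictly; fitted `tau` exceeds the
geometric value by the expected inertance factor (e.g. 3.6 vs 2.4 ms at
D = 24).  On the chain, AAA-2/AAA-3 carotid fits give `tau` = 41/96 ms vs
35/119 ms geometric.  The aneurysm-free fixtures set the floors: the
healthy chain reports ~13× less excess compliance than AAA-2, while the
control rig floor is higher (~3× below D24) — there the fitter picks up
the real friction-supporting pressure ramp of the pulse flow through ~9 m
of downstream tubing, a background that high-pass filtering cannot remove
from these short single-pulse records without destroying the echo itself.
Both floors are computed, not asserted, by the test suite.
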