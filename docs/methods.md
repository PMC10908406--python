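# Methods

`hemopulse` couples three model layers into a beating circulation and then
interrogates the converged beat with standard pulse-wave analysis. This
note records the governing equations, the numerical choices, what the
shipped synthetic arterial tree does and does not represent, and the design
decisions taken where the literature leaves room.

## 1-D vessel model

Each vessel segment carries cross-sectional area A(x, t) and
cross-sectionally averaged axial velocity U(x, t) (flow rate Q = A U):

    dA/dt = -d(AU)/dx
    dU/dt = -U dU/dx - (1/rho) dP/dx - 2 (xi + 2) pi mu U / (rho A)

with constant blood density rho = 1050 kg/m^3, viscosity mu = 4 mPa s, and
velocity-profile constant xi (default 9, which yields the 22 pi mu U /
(rho A) friction commonly used for large arteries; xi is configurable
because the profile assumption is a modelling choice, not a measurement).
The system is closed by the thin-wall elastic tube law

    P = Pext + beta(x)/Ad(x) (sqrt(A) - sqrt(Ad(x))),
    beta = (4/3) sqrt(pi) E h,

so the local wave speed is c = sqrt(beta sqrt(A) / (2 rho Ad)) and the
diastolic speed c0 = sqrt(beta / (2 rho sqrt(Ad))). `Pext` is the reference
pressure at which A = Ad (75 mmHg in the fixtures, i.e. Ad is the
diastolic area). Ad and beta taper linearly in x between proximal and
distal values; the file schema stores diameters and wall description per
end in SI units so that a network file round-trips bit-exactly.

Aortic stiffening is modelled as a multiplicative factor m on the PWV of
the segments flagged `aortic`: beta (through E) is scaled by m^2, so c0
scales by m. Which segments count as "aortic" is an explicit per-segment
flag in the network file; the shipped fixture flags the ascending aorta,
arch, and descending/abdominal aorta.

## Numerical scheme

Interior nodes advance with a MacCormack predictor-corrector (forward-
difference predictor, backward-difference corrector), second order in space
and time for smooth solutions; the verification suite measures the observed
order by grid refinement on a travelling pulse and requires >= 2. Wave
steepening to shocks is outside the intended regime (physiological
amplitudes only), so no limiter is used.

Boundaries are closed characteristically. The outgoing Riemann invariant
W+- = U +- 4c is evaluated at the foot of the characteristic (linear
interpolation toward the interior) **plus the source terms of the
characteristic equation**,

    DW+-/Dt = -(1/rho) dP/dx|_A - f  +-  4 (U +- c) dc/dx|_A,

where the geometric derivatives are taken at fixed area. On tapered
segments these terms are not optional: dropping them biases the boundary
state and visibly leaks mean flow (about 20% end-to-end on the shipped
tree when omitted; ~0.5% with them).

The incoming information is supplied by the attached 0-D element:

* **junctions** - Newton solve for the attached end areas enforcing equal
  total pressure P + rho U^2/2 and zero net flow sum(s_i A_i U_i) (s = +1
  at distal ends), while preserving each end's outgoing invariant; iterated
  to round-off (mass residual ~1e-14 of the local flow scale each step).
  Bifurcations and trifurcations (up to 6 ends) are supported.
* **Windkessel beds** - scalar Newton for the boundary area satisfying
  P(A) = Pc + R1 Q.
* **heart inlet / prescribed inflow** - scalar Newton for A U = Q_in.
* **sealed caps** (verification fixtures) - U = 0.

The time step is chosen from the CFL number (default 0.8) against an upper
estimate of |U| + c; the kernel monitors the actual Courant number and a
cycle is automatically retried with a smaller step if it is exceeded.
Divergence (non-positive area, non-finite state) and junction-solver
failure raise diagnostics naming the segment and time. The compiled inner
loop (numba) advances a full cardiac period per call.

A run is declared periodic when the relative L2 distance between
successive cycles' pressure at all monitored sites, normalized by the
pulsatile amplitude, falls below `tol` (default 1e-3). The last cycle is
returned resampled at 1 kHz (configurable) regardless of the solver step.

## Heart model

Four elastance chambers: P = Ppc + (Enat/Esep) P* + Enat (V - V_P0) - Rs q,
with Enat(t) = Emin + e(t) (Ees - Emin). The activation e(t) is a
normalized double-Hill waveform per chamber (atria lead the ventricles by
0.15 T). Septal coupling uses the contralateral pressure from the previous
solver substep (explicit); pericardial pressure is K exp((Vtot - V0)/phi)
in the total four-chamber volume. Valves carry an opening-fraction state
zeta driven by the transvalvular gradient (opening rate K_open, closing
rate K_close) and a Bernoulli-resistance/inertance flow law integrated
semi-implicitly; an ideal-diode mode exists for debugging. The closing
rate default (0.6 /(Pa s)) is fast enough that valve regurgitant volume is
negligible (< 0.1% of stroke volume) and the aortic incisura (dicrotic
notch) is reproduced.

**Timing vs heart rate.** The activation time constants scale as
(T/T_ref)^p with T_ref = 0.8 s. The default is p = 1 (systole a fixed
fraction of the cycle), the convention of the lumped heart models this one
descends from; p = 0.5 reproduces the square-root law of ECG interval
formulas and is available per chamber (`timing_exponent`). The choice
matters: with p = 0.5, ejection occupies an ever-larger fraction of short
cycles and the high-heart-rate carotid waveforms lose the pulsatility
growth that the fixed-fraction law produces.

Two filling (preload) modes exist. Open loop (default for the fixtures):
the left atrium fills from a constant pulmonary venous pressure P_pv
through a resistance, and beds drain to a fixed venous pressure - P_pv is
the preload clamp that all CO/LVEDV fixing adjusts. Closed loop: beds
drain into a lumped venous compliance feeding the right atrium, with a
lumped pulmonary compartment returning to the left atrium.

`fix_cardiac_output` performs damped secant iteration on P_pv until the
converged-cycle CO (or, alternatively, LVEDV) hits a target within
tolerance (default 1%; the contractility/steady-power experiment uses 0.4%
so that the CO residual does not dominate the steady-power comparison).

## Vascular beds

Generic three-element Windkessel everywhere: C dPc/dt = Q_in -
(Pc - P_out)/R2, interface pressure Pc + R1 Q_in, forward-Euler at the
solver step (dt is far below R2 C). `match_characteristic_impedance` sets
R1 = rho c0 / Ad of the attached end (preserving R1 + R2) for
reflection-free verification terminals.

## The reduced arterial tree (synthetic fixture)

The fixture stands in for a full anatomical dataset, which the network file
format supports but the package does not bundle. It contains an ascending
aorta / arch / three-segment descending aorta trunk (aortic flag set), the
three arch branches, two common carotids and two vertebrals ending in
cerebral beds, two brachial conduits (arm beds), and a single lumped
bilateral iliac-femoral conduit to the lower-body bed, driven by the
elastance heart at the aortic root. Its calibration targets, all encoded in
`FixtureSpec`:

* baseline aortic diastolic wave speed 4.66 m/s (exact at segment ends by
  construction: beta_end = 2 rho sqrt(Ad_end) c0^2);
* control operating point CO 5.6 L/min, LVEDV ~136 mL, MAP ~93 mmHg at
  75 beats/min and Ees 2.5 mmHg/mL (the frozen preload clamp
  P_pv = 10.05 mmHg realizes CO 5.60 / LVEDV 136.4 / aortic 111/74 mmHg);
* regional flow fractions: 5% of CO per carotid, 1.7% per vertebral (total
  cerebral 13.4%), 5% per arm, remainder to the lower body. Bed DC
  resistance is sized from these fractions at the target mean pressure,
  with the terminal conduit's own viscous resistance subtracted so the
  path total is exact.

Two fixture choices deserve emphasis because the heart-aorta-brain
phenomenology depends on them:

* **Beds are reflective, not impedance-matched**: R1 is 25% of each bed's
  total resistance and the compartment RC time is short (0.15 s; most
  compliance lives in the distensible 1-D aorta, whose tube-law compliance
  is ~1 mL/mmHg). The cerebral/peripheral impedance mismatch this creates
  is the physical mechanism that partially shields the brain from
  pulsatile energy and shapes its frequency dependence. With perfectly
  matched terminals the carotid pulsatility trends with heart rate
  flatten and invert.
* **The lower-body path has anatomical extent**: the lumped iliac-femoral
  conduit (0.8 m, c0 7 m/s) places the dominant lower-body reflection site
  at its real distance from the heart, which sets the timing of the
  reflected waves that interfere with ejection at different heart rates.

With these in place the fixture reproduces, at fixed CO, the documented
qualitative behaviour: carotid pulsatile power is minimized at an interior
heart-rate optimum at 75 beats/min for aortic PWV multiples 1-3 (the
acceptance sweep), pulsatile power rises with stiffness and with
contractility while steady power stays put, the pulsatility index rises
with heart rate, the carotid wave-intensity pattern shows the
FCWI(+)/BCWI(-)/FEWI(+) sequence, and cerebral flow falls with stiffness
at fixed preload - more steeply when contractility is low.

What the fixture does **not** claim: quantitative agreement with
full-anatomy tables. With ~16 segments instead of hundreds, its reflection
index (~48% at control) and pulsatility index (~6.2) sit above
full-network values, and absolute carotid pulsatile power (3.3 mW at
control) is the right order of magnitude but not the same number. Passing
the test battery therefore demonstrates the mechanisms and the pipeline,
not patient-level prediction; a full parameter set dropped into the
network schema is required for the latter.

## Analysis layer

All metrics operate on one uniformly sampled converged cycle (trapezoidal
integration):

* power decomposition: total (1/T) int P Q dt, steady Pmean Qmean, and
  their difference, the pulsatile power (CPP at the carotid site, reported
  in mW);
* wave intensity dI = (dP/dt)(dU/dt), with 4th-order central derivatives
  (a 2nd-order stencil moves the peaks by ~0.5% between 1 and 2 kHz
  sampling; the 4th-order one is sampling-stable). Peaks: FCWI = global
  positive maximum, BCWI = magnitude of the most negative excursion within
  0.3 T after it, FEWI = positive peak between the BCW trough and the
  end-systolic window; flat signals return NaN peaks with an `ok=False`
  flag;
* wave power: pulsatile product (P - Pmean)(Q - Qmean); FCWP is its first
  systolic peak, windowed by the FCWI timing. The pulsatile-product form
  is used (rather than raw P Q) following the wave-power literature; the
  raw product differs only by the steady offset;
* wave separation about cycle means with the single-point diastolic wave
  speed c0 of the site: dPf,b = (dP +- rho c dU)/2, cumulatively summed,
  anchored so Pf + Pb = P exactly (forward carries the absolute level);
* reflection index: peak-to-trough amplitude of Pb over that of P, in %
  (default); a peak-over-peak convention is provided because the verbal
  definition is ambiguous between the two;
* carotid pulsatility index (qmax - qmin)/Qmean; cerebral blood flow: sum
  of cycle-mean flow over the four brain-supplying arteries (L/min).

The analysis site is the midpoint of the left common carotid (the only
cerebral branch arising directly from the arch); cerebral flows are taken
at the four terminal faces.

## Experiments

`run_sweep` iterates Ees x HR x PWV-multiple grids, warm-starting each
simulation from the previous grid point, with three CO protocols:
`fixed_co` (preload re-fixed at every point - the isolated-contractility
and optimal-HR designs), `fixed_lvedv` (CO fixed at baseline stiffness,
LVEDV then held as stiffness rises - the perfusion design), and `free`.
Non-convergent points are recorded with diagnostics, not fatal. Everything
is deterministic; repeated sweeps are bit-identical.

Default problem sizes: ~1 cm spatial resolution (about 230 nodes on the
reduced tree), CFL-limited steps of ~0.5 ms, limit cycles in 5-25 beats
with warm starts. A full 15-point CO-fixed HR sweep completes in well
under a minute of compute after JIT compilation.

## Known limitations

Purely elastic walls (no viscoelasticity); no cerebral autoregulation or
baroreflex (deliberate: the study design isolates passive transmission);
the open-loop venous side is a constant-pressure sink; valve and
activation parameter values are model-family defaults rather than fitted
constants; the characteristic boundary closure is locally first-order in
the foot interpolation (the interior scheme carries the 2nd-order
convergence test); and the reduced tree's quantitative indices are
fixture-specific as discussed above.
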