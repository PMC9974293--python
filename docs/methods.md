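# Methods

`pulsewave` simulates one-dimensional arterial pulse waves on a vessel tree
and analyses the resulting pressure/flow signals with the standard
wave-separation, wave-intensity and reflection-coefficient toolkit, with a
static head-up-tilt transform connecting a supine and a standing state.
This note records the model, its assumptions, the numerical choices, and
what the bundled synthetic networks do and do not represent.

## Governing equations and wall model

Each vessel solves the 1D mass and momentum balance

    dA/dt + dQ/dx = 0
    dQ/dt + d(alpha Q^2/A)/dx + (A/rho) dP/dx = -K_R Q/A + A g sin(phi) sin(theta)

with cross-section A, flow Q, blood density rho = 1050 kg/m^3, momentum
correction alpha = 1 and viscous source coefficient K_R = 22*pi*mu/rho
(Womersley-motivated flat-core profile, mu = 4 mPa s). Gravity enters by
Stevino's law through the vessel inclination phi (defined for the upright
body) scaled by sin of the tilt angle theta, so theta = 0 is supine and
theta = 90 deg upright; intermediate tilts scale the whole hydrostatic
field by sin(theta).

The wall follows the beta tube law with a Voigt viscoelastic term,

    P = P_ext + (beta/A0(x)) (sqrt(A) - sqrt(A0(x))) + Gamma/(A0 sqrt(A)) dA/dt,

with A0 linearly tapered along the vessel and beta, Gamma constant per
vessel. The elastic branch gives the closed-form wave speed
c = sqrt(beta/(2 rho A0)) A^(1/4), equivalently c^2 = c0^2 + P/(2 rho):
the wall stiffens with distension, so hydrostatic loading raises local wave
speed with no explicit stiffness rescaling. This emergent mechanism is the
core of the posture study: standing raises mean pressure (and hence c)
below heart level and lowers it in the elevated cerebral branch.

Wall viscosity matters on a small network: a purely elastic 20-vessel tree
rings through diastole, and at the periodic steady state the ringing wraps
into early systole where it contaminates the loop estimators with
posture-dependent artifacts. The bundled arterial tree therefore carries
Gamma = k*sqrt(A0) with wall-viscosity scale k = 100 Pa s, sized so
ring-down is fast against the beat while the ejection wave itself is barely
attenuated.

## Numerics

* Richtmyer two-step Lax–Wendroff on (A, Q) in conservation form; the
  elastic pressure gradient is absorbed into the flux (b/3) A^(3/2) with
  b = beta/(rho A0), leaving taper terms as geometric sources.
* The viscoelastic term is operator-split and integrated implicitly (one
  tridiagonal solve per vessel per step, zero viscous flux at vessel ends),
  so the advective CFL condition still sizes the time step. dt is fixed per
  beat from the running maximum of |U| + c with headroom; a Courant number
  above 1 aborts with diagnostics.
* Boundaries use outgoing Riemann invariants W± = U ± 4c. The interior
  state is extrapolated to the vessel end by carrying its pressure through
  the half-cell hydrostatic increment and re-inverting the boundary-local
  tube law; this respects both tilt and taper (without it, tilted vessels
  equilibrate with an O(dx) pressure offset per boundary and tapered
  vessels see a spurious momentum source at junctions). Zero-flow tilted
  columns then satisfy the Stevino profile to ~0.002%.
* Junctions enforce mass conservation and total-pressure continuity
  (P + rho U^2/2) by a damped Newton solve on the connected end areas
  (analytic Jacobian, relative residuals ~1e-11).
* Terminals are RCR Windkessels coupled through the outgoing
  characteristic, with the compliance pressure advanced implicitly; C = 0
  degrades gracefully to a pure resistor. The terminal outflow pressure
  follows the local hydrostatic column (the venous side tilts with the
  body): without this, tilting creates an unphysical siphon that drains
  arterial pressure at the root.
* Beats repeat until the pressure waveform at three monitored nodes is
  periodic to a relative L2 tolerance of 1e-3 (at most 30 beats; the run
  warns and flags if unconverged), then one recording beat is resampled to
  a uniform 1 kHz grid at every cell midpoint.
* Fields initialise at the estimated mean pressure (mean flow times total
  peripheral resistance) plus the hydrostatic field, with Windkessel nodes
  at their DC values, which removes most of the slow compliance transient.

Grid convergence: halving dx (and dt through the CFL) moves the mid-aortic
beat peak pressure by under 1% at the bundled resolution.

## Wave analysis

* PQ-loop / PU-loop: the slope of P vs Q (resp. P vs U) over the
  early-systolic, nearly reflection-free tract estimates Z_c (resp.
  rho c). The foot is found by walking back from the maximum upstroke
  slope until dP/dt falls below 8% of its maximum — a rule robust to slow
  diastolic oscillations — and the fit window spans 30% of the
  foot-to-peak time, widened in 5% steps until R^2 >= 0.98 (up to 60%,
  then flagged).
* Separation: P_f,b = (P ± Z_c Q)/2, Q_f,b = (Q ± P/Z_c)/2 applied to the
  raw signals with means retained (the posture study reports shifts of the
  mean forward/backward pressures); PP-based indices are insensitive to
  this choice. RM = PP_b/PP_f and RI = RM/(1+RM) use cell-mean pulse
  pressures per vessel.
* Augmentation index: the inflection point is detected on the low-pass
  filtered (zero-phase, 25 Hz) dP/dt as the first prominent local minimum
  on the upstroke (early shoulder, AP > 0) or local maximum on the early
  downslope (late shoulder, AP < 0); a single-humped pulse is signalled as
  undefined rather than reported as zero.
* Reflection coefficients: junction forward R_p from the parallel daughter
  impedance, backward per daughter against the parent-in-parallel-with-
  siblings (junction level: mean of magnitudes — the aggregation behind a
  single positive backward value per bifurcation is a convention, recorded
  here); taper R_p as the telescoped per-interface sum; terminal
  R_p = (R_down − Z_c,out)/(R_down + Z_c,out).
* Wave intensity: WI_f,b = ±(1/4 rho c)(dP/dt ± rho c dU/dt)^2 with
  centred differences; peaks above 2% prominence are classified
  FCW/FDW/BCW/BDW by the sign of the separated-pressure derivative.
* Trapping: t_back is the WI_b-energy-weighted mean arrival over the full
  beat, ToR = t_back − t_FCW (t_FCW = first forward-compression WI peak),
  and PoR = ToR * c_down/2 with c_down the mean PU-loop speed over the
  aortic sites from the current one (inclusive; this makes the last site's
  value its local speed, matching the convention in which the iliac
  downstream mean equals the iliac speed) to the end of the path. The
  exclusive variant is selectable.

## Statistics

Paired Wilcoxon signed-rank tests are exact (dynamic programming over the
2^n sign assignments, midranks for ties, zeros dropped) for n <= 25 and
normal-approximated with continuity and tie corrections above; n monotone
same-sign differences give the two-sided minimum 2*2^-n, which is why the
per-vessel segment counts determine the attainable p-values (0.125 at n=4
up to 0.002 at n=10). ANCOVA on arrival-time regression lines is an OLS
F-test on the group-by-distance interaction (slopes) and, under a common
slope, on the group offset (intercepts), delegated to statsmodels.

## Synthetic study conditions

All inputs are generated programmatically; there is no patient data.

* `uniform_tube` / `tapered_tube`: single vessels with matched RCR loads
  (R1 equals the outlet characteristic impedance at the operating point).
  For the reflection-free oracles the compliance node is made quasi-static
  (long R2 C), since a finite Windkessel reflects low frequencies even with
  a matched R1.
* `murray_tree`: symmetric tree with r_d = 2^(-1/3) r_p and
  beta_d = 2^(1/3) beta_p, which matches daughter-parallel impedance to the
  parent at the reference state; built stiff enough that beat-mean areas
  stay near reference, so the forward area ratio reproduces the ~1.25
  branching optimum and forward junction reflection stays below 0.02.
* `single_reflector`: an abrupt wave-speed step at 0.4 m with a long
  matched distal segment; driven by a cosine-front, slow-decay ejection so
  the wavefront carries the WI energy and its peak time coincides with its
  energy centroid. The recovered point of reflection is accurate to ~4%;
  physiological blood viscosity is required, because without dissipation
  multiply-reflected echoes persist at the periodic steady state.
* `mini_aorta`: a 20-vessel adult tree — an 11-vessel aortic path with the
  study's site numbering (1, 63, 2, 14, 18, 27, 28, 35, 37, 39, 41), a
  lumped cerebral branch rising 0.45 m above the heart, an arm branch, a
  visceral (celiac-renal) trunk carrying a third of cardiac output, and two
  legs that bifurcate (femoral into two tibial-calibre daughters) so leg
  reflections are trapped at junctions as in the real tree. Geometry comes
  from a standard open adult parameter set, trimmed; radii and wave speeds
  are anchored at the supine mean pressure (93 mmHg), per-vessel cell
  counts supply the paired-test segment numbers, total terminal compliance
  is ~2.7 ml/mmHg and the outflow reference pressure 33 mmHg. Supine beat:
  RR = 0.8 s, stroke volume 70 ml, half-sine ejection over 35% of the beat.

## Posture transform

The standing preset applies the steady-state set-points of the short-term
reflexes: RR/1.23, stroke volume x0.68 (cardiac output x0.836), cerebral
arteriolar resistance x0.88 and cerebral compliance x1.65, non-cerebral
terminal compliance x0.75, and a uniform factor on the non-cerebral
arteriolar resistances solved by bisection (0.1% tolerance) so the parallel
total of all terminal resistances rises by exactly +39%. Vasomotor factors
act on the distal resistor R2 only: R1 represents the vessel-terminal
interface impedance, not a regulated bed, and scaling it would introduce a
spurious high-frequency terminal mismatch on tilt. Applying the preset and
inverting the solved factors restores the supine parameters exactly.
Closed-loop quantities (cardiac elastance +6%, venous volumes, central
venous pressure) have no representation in an open arterial model; their
omission is logged when the preset is applied.

## What the synthetic tree does and does not show

The bundled tree reproduces the study's qualitative supine-to-standing
pattern: wave speed rises at every aortic/leg site below heart level and
falls at the carotid; terminal reflection coefficients rise at non-cerebral
and fall at cerebral terminals; the ascending-aortic reflection magnitude
falls; and the point of reflection shifts downstream at the aortic sites
from the mid-arch to the iliac bifurcation with broadly stable ToR.

Two known limitations, both consequences of trimming a ~55-vessel tree to
20 vessels:

* PU-loop estimates carry near-field reflection bias of order 10-20% at
  sites close to junctions or strong tapers (the quantitative per-site
  values are estimator-specific; the analytic tube-law speeds carry the
  clean signal).
* At the three supra-diaphragm sites (root, ascending aorta, proximal
  arch) the backward WI energy tracks the reflection of the whole ejection
  waveform rather than discrete near-field echoes — the nearest strong
  reflectors are simply too far on a trimmed tree — so t_back scales with
  the beat period and ToR inherits roughly the −19% heart-rate rescaling
  on standing; PoR consequently dips a few percent there instead of
  rising. On the full-scale tree the root ToR is travel-dominated
  (~0.1 s) and insensitive to heart rate.

Passing tests on these fixtures demonstrate internal consistency of the
solver and analysis chain and the qualitative posture physics; they do not
calibrate against any individual's haemodynamics, and absolute ToR/PoR
values are specific to the trimmed geometry.
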