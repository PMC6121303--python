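# Methods

This note documents the models implemented in `pumploop`, the choices
made where the design was open, and what the tests do and do not show.

## 1. Discrete-time conformation chain (`pumploop.markov`)

**Model.** The conformation of a single Na/K-ATPase unit is treated as
memoryless: a discrete-time Markov chain `{X_n}` over the four
Post-Albers states in the canonical order E1, E1P, E2P, E2, with
row-stochastic one-step matrix `P` and nominal step interval `dt`.
`dt` is metadata in arbitrary units; no calibration to physical
turnover time is attempted (real pumps hydrolyze ATP fast enough that
any such calibration would be speculative at this level of
abstraction). The assumption of independence from neighbouring pump
conformations is a simplification; no non-Markov alternative is
implemented.

**Numerics.** The stationary distribution is found by power iteration
on the lazy chain `(P + I)/2`, which has the same fixed vector but is
aperiodic, so deterministic cycles converge too; the residual
`max|πP − π|` is measured on the original `P` (default tolerance
1e-10, max 10⁶ iterations). Irreducibility is checked by
strongly-connected components of the positive-entry graph; reducible
chains are rejected rather than silently returning one of many
stationary vectors. An independent direct linear solve of
`(πP = π, Σπ = 1)` is kept as a cross-check oracle in the tests.

**Hidden states.** Conformational substates (e.g. differing numbers of
bound Na/K ions) are supported structurally as edge refinements: an
`EdgeSplit` reroutes edge probability `p(src→dst)` through a hidden
state with a geometric dwell, conserving the total path probability
for any dwell in [0, 1). No biological parameterization of hidden
states is asserted. In the fast-hidden limit (dwell → 0) the
renormalized visible stationary occupancy reproduces the original
chain's, which the tests verify.

**Default matrix.** The shipped 4-state matrix is a strongly cyclic,
forward-biased illustration (large E1→E1P→E2P→E2 entries, small
reverse/dwell probabilities). It is *illustrative*: no published
per-transition probabilities exist to fit at this granularity.

## 2. Kinetic cycle thermodynamics (`pumploop.thermo`)

**Model.** The cycle is a closed unicycle of `n` states with forward
rates `k_i⁺` (edge i → i+1 mod n) and backward rates `k_i⁻`. The
master equation `dp/dt = G p` uses the generator built from these
rates. At the nonequilibrium steady state the net current
`J = π_i k_i⁺ − π_{i+1} k_i⁻` is the same on every edge (tested to
1e-10) and is reported as the cycle flux, the number of net forward
reactions per unit time. Entropy production is
`e_p = J · ln(Πk⁺/Πk⁻)`, dimensionless (natural-log affinity units ×
flux; no k_BT factor is applied, since none is defined for arbitrary
rate units).

**Why flux-from-stationary-solve.** Closed-form unicycle flux
expressions have denominators of mixed rate products that are easy to
mistype and hard to audit. The package instead computes the exact
stationary density of the generator (least-squares null-space solve
with the normalization row appended) and reads the current off an
edge. The unambiguous closed forms on 2-cycles
(`J = (k₁⁺k₂⁺ − k₁⁻k₂⁻)/(k₁⁺+k₂⁺+k₁⁻+k₂⁻)`) and symmetric 3-cycles
(`k⁺=(2,2,2), k⁻=(1,1,1) → J = 1/3, e_p = ln(8)/3`) are asserted in
the tests, and a fully independent oracle — relaxing the master
equation to long time and measuring the current — agrees with the
null-space route.

**A symmetry worth noting.** Swapping `k⁺ ↔ k⁻` negates the affinity
exactly and flips the sign of the flux, but does *not* negate the flux
magnitude on cycles longer than two states: the stationary density
denominator is not symmetric under the swap. Intuition that treats the
swap as time reversal is correct only up to a state relabeling that
general (non-palindromic) rate sets do not admit. The tests assert the
exact 2-cycle antisymmetry and the general sign flip.

**Time-dependent rates** are accepted by the integrator (a callable
`t → RateSet`); flux and entropy production are defined only for
constant rates, since a NESS requires stationarity. The forward map
rates → `e_p` is provided; inferring rates from a measured `e_p` is
out of scope.

## 3. Plane-wave pool superposition (`pumploop.waves`)

**Model.** Two pump pools are laid end to end in space: signaling
(caveolar; 250 arb. units, 150 Hz) and pumping (500 units, 500 Hz).
Each is a complex plane wave `A·exp(i(2πft − kx + φ))` on its domain,
zero elsewhere, with one spatial wavelength per domain (the spatial
factor does not affect the temporal spectrum). Real part ↔ E1↔E2
transition coordinate, imaginary part ↔ phosphorylation. The wave
picture is an illustration of frequency/space separation between
pools, not a claim of physical quantum behaviour.

**Spectrum.** Plain rectangular FFT along time (no window), power
`|X_k|²/N²` averaged over spatial positions. With this normalization
total spectral power equals the time-domain mean square field
amplitude exactly (Parseval), which every test field asserts at 1e-8
relative. Default grids: 1 s duration at 4096 Hz sampling (1 Hz bins,
Nyquist-safe for 500 Hz), 1 unit spatial resolution. Unit tests use a
0.5 s window (2 Hz bins) that keeps both default tones exactly on bin
centers.

**Peak detection** takes the tallest strict local maxima; the
right-hand comparison allows equality so a tone split evenly between
two bins still registers once, within one bin of the true frequency.

**Ouabain shift.** "Shifting the E2:E1 state by 5 %" is modelled as
scaling the signaling-pool amplitude by (1 − shift): ouabain moves
signaling pumps out of the Src-inhibiting E1 contribution. Frequency-
or phase-shift alternatives were rejected because the observable to
reproduce is a *diminished* signaling peak at an unchanged pumping
peak. The signaling peak is kept at 150 Hz; a 180 Hz figure appears
once in the source figure captions, inconsistently with the 150 Hz
configuration, and we do not guess an intent behind it.

## 4. Oxidant amplification loop (`pumploop.loop`)

**States.** `N_E1`, `N_E2` (plasma pumps by conformation), `N_endo`
(endocytosed pumps), `Src_p` (phosphorylated Src), `ROS`, `Age`. Counts
for pumps; arbitrary units for Src, ROS, Age; time in arbitrary
"ticks" (the perturbation convention t = 2500 fixes the scale).

**Equations** (see the module docstring for the full right-hand side):
pumps are synthesized into E1 at `synth_rate`, interconvert with basal
rates `k_12`, `k_21`, and experience an added E1→E2 rate
`g_ros_shift·ROS + g_cts_shift·occ`, where `occ = conc/(conc + IC50)`
is instantaneous-equilibrium ouabain occupancy (Hill 1, IC50 = 1 mM so
100 µM ≈ 9 % occupancy). ROS drives endocytosis at `g_endo·ROS` from
both conformations proportionally (an `e2_only` switch exists for
sensitivity analysis); endocytosed pumps degrade at `deg_endo` and do
not recycle. ROS has a basal source `rho_basal`, a Src-driven source
`g_src_ros·Src_p` (the Src→EGFR→ROS cascade lumped into one gain), and
first-order detoxification `delta_ros·ROS`. Aging integrates
`a_ros·(ROS + 1000·endocytosis flux)` — endocytosis is taken as three
orders of magnitude more efficient per unit than free ROS at inducing
the aging signal, with the weighting applied to the flux term.

**Src coupling.** Half the Src pool (`frac_src_controlled = 0.5`) is
under pump control. The dis-inhibited fraction is
`D = 1 − N_E1/(N_E1 + N_E2 + N_endo)`: E1 pumps tonically inhibit
their Src, while E2 pumps *and endocytosed pumps* release it — the
denominator includes `N_endo` precisely so that endocytosis produces
the net Src dis-inhibition it is observed to produce (with a
plasma-only denominator, proportional endocytosis would leave the
dis-inhibited fraction unchanged, contradicting that observation).
Activation drives the dis-inhibited, not-yet-phosphorylated Src
(`k_src_act·max(0, D·pool − Src_p)`), keeping `Src_p` bounded by the
controllable pool; decay is first-order (`delta_srcp`).

**Whether ROS acts additively or multiplicatively** on the E1→E2 rate
is not established; additive-in-rate is the default and a
`ros_shift_mode="multiplicative"` switch exposes the alternative
without claiming it.

**Calibration.** Published rate constants for this loop do not exist
at this abstraction level; `calibrate_basal` sets `k_21` and
`synth_rate` so that the basal fixed point has an E1 plasma fraction
of 0.50 (tolerance 0.01), a plasma pump total of 2×10⁶ ("2 M surface
pumps" read as 2 mega-units per cell, typical of epithelial lines),
and relaxes a 5 % ROS excursion back to stationarity
(residual < 1e-6 × state scale) before the t = 2500 perturbation
horizon. If the supplied parameters already meet the anchors they are
returned unchanged; otherwise the joint fixed-point/anchor system is
solved deterministically (`scipy.optimize.root`, with an
ODE-relaxation continuation fallback for strongly driven parameter
sets). The shipped defaults are themselves such a calibrated set; the
remaining gains were chosen once to give a clearly visible but
subcritical response to the 100 µM ouabain step (E1 fraction
0.50 → ≈ 0.28, ROS +14 %, ≈ 10 % pump internalization over 2500
ticks) and are labelled calibrated, not measured.

**Solver.** `solve_ivp` (LSODA), rtol 1e-8, per-state absolute
tolerances scaled to pump counts; the integration is split at
perturbation onsets so steps and boluses are applied exactly. The ODE
is deterministic; seeds play no role. Trajectories are clipped at zero
only to remove solver-level negative round-off; divergence beyond
1e12 × scale is flagged as `runaway` rather than raised.

**Stability of the loop.** The feed-forward loop (E2 shift → Src
release → ROS → further E2 shift) is *self-limiting* in this
formulation: at the fixed point the DC loop gain through the additive
rate coupling is bounded by the E1 fraction (< 1), because the ROS
level that the gain product generates also raises the E1→E2 rate that
sits in the gain's denominator, and the Src pool saturates. A numeric
scan confirms the leading Jacobian eigenvalue becomes *more* negative
as `g_src_ros·g_ros_shift` is scaled up to 10⁶×, while steady-state
ROS rises monotonically. There is therefore no finite instability
threshold in that product; "amplification" manifests as a monotone
increase of the operating point, not a bifurcation, and the tests
assert exactly that. The `runaway` flag remains for parameter regimes
outside this structure (e.g. user-modified couplings).

**Identifiability smoke test.** `(g_src_ros, delta_ros)` are recovered
to well within 5 % by simulation-based least squares from a single
noise-free perturbed trajectory (161 samples, 800 ticks); this is a
desk-scale identifiability check, not a statement about noisy data.

## 5. Scenarios, fixtures, determinism

Scenario runs (`fig3`, `fig4`, `fig6_basal`, `fig6_ouabain`,
`thermo_ness`) write CSV/JSON plus a SHA-256 manifest; identical
invocations are byte-identical. All fixture inputs used by the test
suite are generated programmatically (`generate_fixtures`, seeded).
The only stochastic operation in the package is Markov path sampling,
which takes an explicit seed and is bit-reproducible.

Problem sizes used by the test suite and the acceptance script —
2500–5000 tick ODE horizons at 5-tick sampling, 1 s / 4096 Hz wave
grids, 100 random chains and 1000 random rate sets for the property
sweeps, 10⁵-step path sampling — were chosen as the smallest sizes at
which every tolerance above is comfortably resolved.

## Known limitations

- No ion-gradient dynamics: Na/K concentrations are fixed; transition
  probabilities/rates do not depend on them.
- No recycling of endocytosed pumps, and no state preference of
  endocytosis by default.
- The signal cascade between Src and ROS (EGFR, Shc, Grb2, FAK, SOS,
  Ras) is lumped into a single gain.
- ROS, Src and aging units are arbitrary; only directions and
  calibrated anchors are quantitative.
- The wave-pool picture is a visualization device for
  frequency/space-separated pools; peak heights measure pool
  amplitude × spatial share, nothing more.
- The default Markov matrix and kinetic rates are illustrative; none
  of the defaults are fitted to experimental turnover data.
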