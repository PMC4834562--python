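# Methods

## Photocycle models

`opsinkit` implements three functional Markov models of the opsin
photocycle, selected by their number of states:

* **3-state** (C → O → D → C): closed, open, desensitized. Light drives
  C → O (rate `Ga(phi)`) and D → C recovery (`Gr(phi) = kr·H_q(phi) + Gr0`);
  O → D deactivation is the single dark rate `Gd`. The model is second
  order, so its off-phase decay is single-exponential and it admits a
  closed-form solution under constant light.
* **4-state** (C1 ⇄ O1 ⇄ O2 ⇄ C2, C2 → C1): two closed / two open states,
  reproducing biexponential deactivation and light adaptation. The second
  open state conducts with relative conductance `gamma = g_O2/g_O1`.
* **6-state**: the 4-state scheme with intermediate (pre-open) states I1,
  I2 between each closed and open state, entered at light-driven rates and
  drained at the opsin activation rates `Go1`, `Go2`. The extra states
  reproduce the lag of the current peak behind the end of a brief pulse.

All light-dependent rates follow the Hill form
`k·phi^e / (phi^e + phi_m^e) (+ dark baseline)` with a shared
half-saturation flux `phi_m` and exponents `p` (activation) and `q`
(inter-open/recovery transitions).

The photocurrent factorizes as

    I = g0 · f_phi(phi, t) · f_v(v) · (v − E) · 1e−6    [nA]

with `f_phi = O` (3-state) or `O1 + gamma·O2`, and the empirical inward
rectification factor

    f_v(v) = (v1/(v − E)) · (1 − exp(−(v − E)/v0)).

`f_v` is normalized to 1 at −70 mV, which ties
`v1 = (70 + E)/(exp((70 + E)/v0) − 1)`; this constraint is active by
default in both simulation and fitting and can be released explicitly.
The removable singularity at `v = E` is evaluated by a second-order series
for `|v − E| < 1e−3·|v0|` to avoid catastrophic cancellation; the limit is
`v1/v0`. For large `v0` the factor degenerates to the constant `v1/v0`
(ohmic, non-rectifying channels).

Units are fixed package-wide: ms, ms⁻¹, mV, pS, nA and
photons·mm⁻²·s⁻¹; the single pS·mV → nA factor (1e−6) lives in
`kinetics.current`.

## Simulation engine

The master equation is linear in the state occupancies, with coefficients
set by the instantaneous flux. The engine splits every stimulus at its
discontinuity points and treats each piece separately, so a rectangular
pulse edge never falls inside a solver step:

* **constant-flux pieces** (the default for all pulse protocols) are
  propagated exactly through the eigendecomposition of the generator
  matrix (with a `scipy.linalg.expm` fallback for defective matrices);
* **time-varying pieces** (ramps, sinusoids, chirps) use
  `scipy.integrate.solve_ivp` (BDF, analytic Jacobian, rtol 1e−8 /
  atol 1e−10), with rates evaluated continuously inside the RHS.

The adaptive solver is also available for every piece
(`method="numerical"`) and serves as the independent numerical oracle in
the test suite; the analytically derived 3-state solution (eigen-solution
of the reduced 2×2 system after eliminating one state by conservation) is
a third route. The three agree to < 1e−6 maximum absolute state error on
a 500 ms step, which is how the closed-form derivation is validated.

Output is sampled on a uniform grid with
`dt = min(shortest pulse, shortest gap)/10` clipped to [1e−3, 0.1] ms;
every stimulus edge is added to the grid exactly. Initial conditions
default to the fully dark-adapted ground state (C1 = 1).

## Characterization protocols

Default protocol settings mirror standard voltage-clamp characterization
of ChR2-like channels:

| protocol | run dimension | defaults |
|---|---|---|
| `step` | flux | irradiances {0.1, 0.5, 1, 5, 10, 50, 100} mW/mm² at 470 nm, 500 ms on / 500 ms off, V = −70 mV |
| `rectifier` | voltage | V ∈ {−100, −70, −40, −10, 20, 50, 80} mV, one flux |
| `recovery` | inter-pulse interval | IPIs {0.5, 1, 2.5, 5, 10} s, two 250 ms pulses, V = −70 mV |
| `shortPulse` | pulse duration | {0.5, 1, 2, 3, 5, 8, 10} ms |

Irradiance ↔ photon-flux conversion requires a wavelength; the default is
470 nm (`E_photon = hc/λ`), overridable. Pulses are half-open intervals
`[t_on, t_off)`. Sinusoid and chirp stimuli use raised-cosine forms so
`phi(t) ≥ 0` everywhere; their amplitude/frequency defaults are arbitrary
documented choices (5 Hz; 0.5 → 50 Hz sweep).

## Feature extraction

* **Peak**: sample of maximal |I| at/after the first pulse onset, sign
  preserved (the same code serves depolarizing and hyperpolarizing
  opsins); ties go to the earliest sample.
* **Plateau (steady-state) current**: mean of the final 10% of the
  on-phase, accepted only if a straight-line fit over that window has a
  slope below 1% of |mean| per 100 ms; otherwise flagged not-at-plateau
  (the window fraction and slope threshold are named constants). At least
  50 on-phase samples are required.
* **Phase segmentation**: half-open index ranges per pulse; the off-range
  of pulse k ends at pulse k+1's onset or the end of the trace.
* No smoothing is applied by default; an optional moving average exists
  for noisy recordings and is off in every test.

## Staged fitting pipeline

`fit_models` follows the protocol-dissection order an experimentalist
would use; stages whose protocol is missing are skipped with flags and
keep their initial values. The flux-dependence (`step`) set is the
minimal requirement; with a single flux the flux-dependence parameters
(`phi_m`, `p`, `q`) are fixed to their initial values.

1. **Rectifier** → (E, v0, v1). E is seeded by linear interpolation of
   the zero crossing of I_ss(V) and then released in the nonlinear fit of
   `I_ss = c·f_v(V)·(V − E)` (the I–V relation is curved, so the pure
   interpolation estimate carries a bias of a few mV at 30 mV spacing);
   `v1` stays tied to the −70 mV normalization. Voltages within 10 mV of
   E are down-weighted. Requires ≥ 5 voltages spanning the reversal.
2. **Conductance** → g0 by inverting the maximal-flux peak,
   `g0 = |I_p| / (f_open_max · f_v(v) · |v − E| · 1e−6)`. Before the
   kinetic stages exist, `f_open_max` falls back to the constant 0.8
   (typical maximal open fraction of wild-type ChR2 under saturating
   light). From the on-curve stage onward g0 is tied *self-consistently*:
   every objective evaluation simulates the maximal-flux trial with the
   candidate kinetics, reads off its maximal photocycle factor at the full
   data resolution, and re-inverts the observed peak. This subsumes the
   conductance correction factor — at convergence the correction is exact
   on self-generated data — and removes g0 as a free parameter.
3. **Recovery** → Gr0 by nonlinear least squares of
   `I_peak(t) = I_peak0 − a·exp(−Gr0·t)` on second-pulse peaks aligned to
   the first-pulse offset; `a` stays free because the expression is exact
   only with empty open states, and intervals below 100 ms (configurable)
   are excluded for the same reason. Flat peak sequences are flagged
   unidentifiable.
4. **Off-curves** → dark deactivation rates, from per-trial biexponential
   fits (variable projection over the two rates with a fixed log-spaced
   3-point multi-start; amplitudes solved linearly; ties broken by lowest
   residual then lowest fast rate). For the 3-state model the two rates
   collapse to one `Gd` by amplitude weighting, averaged across trials.
   For 4/6-state models the fitted rates are identified with the
   eigenvalues of the dark O1/O2 subsystem
   `[[−(Gd1+Gf0), Gb0], [Gf0, −(Gd2+Gb0)]]`: holding (Gf0, Gb0) at their
   current estimates, the trace/determinant relations give a quadratic
   whose roots yield (Gd1, Gd2), with Gd1 on the fast branch. The decay
   eigenvalues alone cannot split all four dark rates, so (Gf0, Gb0) —
   and with them the Gd estimates — are re-fit in the on-curve and
   refinement stages.
5. **Activation** (6-state) → Go1 by 1-D lag matching on the shortest
   pulse (≤ 3 ms): bisection on Go1 (with Go2 = Go1) until the simulated
   peak lag matches the observed one within half an output step. A
   non-positive observed lag means activation is unidentifiably fast; Go1
   is pinned at its upper bound and flagged. Go2 stays tied to Go1 until
   refinement — single-pulse protocols barely constrain it.
6. **On-curves** → remaining light-dependence parameters (`phi_m, k1, k2,
   p, kf, q, kb, gamma, Gf0, Gb0`; `ka, kr` for the 3-state model) by a
   joint fit of the simulated on-phases across all fluxes, each trial
   simulated from the dark ground state. Residuals are normalized per
   trial by its steady-state magnitude so high-flux trials do not
   dominate. The scalar optimizer is configurable (default `powell`).
7. **Post-fit refinement** (optional, on by default): joint
   re-optimization over every trial of every protocol, with
   dark/activation parameters (`Gd1, Gd2, Gf0, Gb0, Go1, Go2`) bounded to
   50–200% of their stage values (both fractions configurable). The
   refinement runs in two sub-phases: the configured scalar optimizer
   first, then a Levenberg–Marquardt polish of the same bounded
   least-squares objective — the direction-set search alone crawls in the
   long curved valleys created by the strongly correlated
   light-dependence parameters (`phi_m` against the rate coefficients),
   while the derivative-based polish converges sharply once inside the
   basin. If the total residual would increase, the pre-refinement values
   are kept, so refinement never degrades a fit.

Long trials are subsampled to at most 600 residual points each in the
joint stages (the g0 anchor trial keeps full resolution); this keeps the
objective cheap without losing the curve shapes. All optimizers and
multi-starts are deterministic — the pipeline needs no random seed, and
identical data plus configuration reproduce identical results.

For inhibitory (hyperpolarizing) opsins the current sign flips; the
pipeline detects a polarity mismatch between data and model at the
reference trial and fits the magnitude-consistent model, leaving the
kinetic parameters unchanged under global sign inversion.

## Synthetic data and what the verification shows

`synthgen` generates protocol data sets by running the forward models,
optionally adding i.i.d. Gaussian noise to the current (seed required
whenever noise > 0; noiseless output is bit-identical to the engine's).
The wild-type ChR2 6-state parameter set ships as a fixture together with
a round-number initial-guess set; the 3-/4-state fixtures are package
defaults for a ChR2-like channel (the 4-state record reuses the 6-state
kinetic fields, its fast-activation limit) and are synthetic rather than
experimentally anchored.

The verification data set uses six log-spaced fluxes spanning
2.21e15–2.65e17 photons·mm⁻²·s⁻¹ (the printed endpoints of the ChR2
characterization range; the intermediate values are the package's
choice), the 7-voltage rectifier, the 5-interval recovery protocol and
four short pulses. Problem sizes (500 ms pulses at 0.1 ms output
sampling, ≤ 600 residual samples per trial in joint fits) were chosen so
a full 6-state round trip completes in minutes on one core.

The generator emulates ideal voltage-clamp recordings. It does **not**
emulate capacitive transients, series-resistance artifacts, baseline
drift, filtering, or cell-to-cell variability, so parameter-recovery
results on these data demonstrate the identifiability and correctness of
the pipeline under the model's own assumptions — not its robustness to
every artifact of real electrophysiology. The noise option exists for
graceful-degradation checks only.

## Numerical choices and degenerate inputs

* Hill rates are evaluated via `1/(1 + (phi_m/phi)^e)` to avoid overflow
  at high flux × exponent.
* Steady states come from the null space of the generator matrix; a
  reducible chain (e.g. `phi = 0` with no dark recovery path) has no
  unique stationary distribution and raises a dedicated error.
* Repeated eigenvalues in the analytic 3-state solution (a measure-zero
  parameter set) fall back to numerical integration, flagged on the
  result.
* The g0 inversion requires a trial clamped away from the reversal
  potential; `v = E` is rejected.
* Biexponential fits on off-segments require ≥ 20 samples; segments whose
  |I| grows by more than 5% of its initial value are excluded with a
  warning.
* `gamma` may be exactly 0 (the wild-type ChR2 fit is ~1e−15); no epsilon
  floor is imposed.

## Known limitations

* Temperature, pH and wavelength dependencies of the conductance are not
  modelled; neither is a five-state variant.
* `Go2` is structurally hard to constrain from single-pulse protocols;
  expect wide uncertainty on it even when everything else recovers
  tightly.
* The exporters emit structurally complete NMODL mechanisms and
  network-simulator equation text, but running them inside external
  simulators is out of scope and untested here.
* Real electrophysiology file formats (ABF etc.) are not read; traces
  enter via CSV or the `PhotoCurrent` constructor.
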