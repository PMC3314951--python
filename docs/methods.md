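# Methods

## Signal models

### DW-SE

The spin-echo signal is modeled as separable:

    S = L(TR − TE) · exp(−TE/T2) · [exp(−b·D)]

with the longitudinal factor `L` computed over the recovery period TR − TE
(the refocusing pulses are treated as destroying longitudinal recovery until
the echo).  Two recovery models are offered: the spoiled steady state
`sin α (1−E1)/(1−cos α·E1)` with `E1 = exp(−(TR−TE)/T1)` — the default, with
α set to the Ernst angle when the protocol requests "optimal" — and simple
saturation recovery `1 − E1`.  Both converge for TR ≫ T1 and reproduce the
long-TR 2D example (6.65% of M0 at TR = 17 s, TE = 122 ms) exactly.  The
diffusion factor `exp(−bD)` is **excluded by default**: all SNR-efficiency
bookkeeping in this package is done on the raw (non-diffusion-weighted)
amplitude (see "Efficiency conventions" below), and a flag restores it.

Absolute DW-SE amplitudes at intermediate b-values depend on the minimum
achievable echo time, which is scanner-specific.  TE(b) is interpolated
monotonically (PCHIP) on b^{1/3} through three trusted anchors
(b = 1000 → 91 ms, 4500 → 122 ms, 10000 → 148 ms); the cube root reflects
the sublinear growth of the diffusion-preparation duration with b at fixed
gradient amplitude.  Because the exact longitudinal model and TE(b) curve
behind the reference tabulation are under-determined, absolute DW-SE signals
carry a documented ±15% model tolerance; all sharper DW-SE statements in the
test suite are arithmetic identities (η = S·√ρ) or the exactly reproducible
long-TR case.

### DW-SSFP

The sequence model is Buxton's: constant-phase RF pulses every TR, one
rectangular diffusion gradient lobe (duration δ, amplitude G, moment
q = γGδ) between excitation and readout, and measurement of the SSFP echo —
the coherence pathway that refocuses just before the next pulse.
Decomposing the magnetization into configuration states F_k/Z_k, the steady
state obeys a linear recursion in the dephasing order k with per-order
diffusion attenuation:

* transverse transit k → k+1 through the lobe:
  `exp(−D q² [δ(k² + k + 1/3) + (TR − δ)(k+1)²])`
* longitudinal order k over one TR: `exp(−D q² k² TR)`

`dwssfp_signal` solves this recursion **exactly** by a direct linear solve
(orders truncated adaptively; the boundary amplitude is checked).  At D = 0
the recursion collapses to constant coefficients and the classic SSFP echo
closed form follows from the decaying eigenvalue of the two-state transfer
matrix (`ssfp_echo_ideal`); the solver reproduces it to ~10⁻⁹.

A deliberate design choice: the widely cited approximate closed form for
this model linearizes the order-dependence of the attenuation factors.  We
solve the recursion exactly instead, because the package's own validation
contract — agreement with an independent extended-phase-graph simulation to
better than 0.5% everywhere — cannot be met by the approximation, whose
error reaches several percent at strong diffusion weighting.  The practical
consequences are confined to the strongest-weighting regime; see
"Reference-value agreement" below.

The **EPG oracle** (`epg_steady_state`) iterates the same physics TR by TR
with the standard complex EPG operators (RF mixing, per-order attenuation,
order shift, relaxation/recovery) until the echo amplitude is stable for
five consecutive periods (tolerance 10⁻⁸ relative, iteration cap 10⁵).  The
two routes — direct solve of the steady-state equations versus convergence
of the transient — share no code beyond the attenuation expressions and
agree to ~10⁻⁸, which validates both transcriptions.

### Effective b-value

`b_eff = −(1/D)·ln[S(D)/S(D=0)]`, the DW-SE b-value with the same
fractional attenuation for the stated tissue.  The denominator keeps the
gradient's spoiling (configuration structure) and removes only the diffusion
attenuation, which equals the printed δ → 0 convention in the closed-form
limit.  b_eff is independent of M0 and readout, strictly increasing in δ and
G, and only weakly dependent on D itself (<5% over the fixed-tissue range).
It is undefined at D = 0 and the code says so rather than returning 0/0.

## Efficiency conventions

SNR efficiency is `η = S[% of M0] · √ρ` with readout efficiency
`ρ = T_acq/TR`.  Two conventions needed pinning down:

1. **Raw amplitude.**  The η values tabulated for sequence comparison use
   the *non-diffusion-weighted* steady-state amplitude S (the "raw signal").
   On the b_eff-constraint manifold this is equivalent to optimizing the
   diffusion-weighted SNR — the two objectives differ by the constant
   `exp(−b_eff·D)` — so optimum locations are unaffected.  This convention
   was verified against the reference tabulation, whose signal column
   matches the raw amplitude at the constrained optimum across all rows.
2. **Echo reference.**  S is the echo amplitude immediately before the next
   RF pulse (the Buxton M⁻ convention), as a fraction of M0.

For DW-SSFP the readout is assumed to fill the TR: T_acq = TR − δ − T_dead
with a conservative T_dead = 5 ms, capped at 30 ms (longer EPI readouts
distort).  DW-SE fixes T_acq = 30 ms.

## Optimization

* `optimize_dwssfp(beff_target)`: for each candidate (TR, α), δ is solved by
  bisection so the protocol achieves the target b_eff (b_eff is strictly
  increasing in δ; tolerance 10⁻³ relative, enforced on the result).  η is
  then maximized over α (bounded scalar search, 1–90°) and TR (grid step
  0.5 ms over 10–200 ms, then local refinement at 0.1 ms; ties break toward
  shorter TR).  The search is deterministic and was checked against an
  exhaustive 4×-finer brute-force grid.
* `optimize_dwse(b)`: TE from the anchor table, α at the Ernst angle, η
  maximized over TR (unimodal; coarse grid plus bounded refinement, checked
  against a 0.1 ms brute-force grid).
* `evaluate_ssfp_protocol(TR, δ)`: at fixed timing, "optimal" α maximizes
  the *diffusion-weighted* amplitude (the physical DW SNR; ρ is fixed), and
  η is reported on the raw-amplitude convention.
* `match_te_equal_efficiency(b)`: root-finds the TE at which TR-reoptimized
  DW-SE equals the DW-SSFP optimum at the same b — the echo time a
  single-refocused (Stejskal–Tanner) preparation would need.
* `required_tr_2d(n, TE)`: `n · (TE + T_acq/2 + T_dead)`, the 2D multi-slice
  feasibility bound behind the 2D-versus-3D example.
* `efficiency_landscape`: both optimizers over a (b, T1, T2) grid; the
  DW-SSFP search uses a coarser TR grid (2 ms, then refinement) because the
  optimum is broad; this costs <0.3% in η.

## Reference-value agreement

With the conventions above, the exact-physics model reproduces the published
protocol numbers closely: b_eff = 4453 versus the printed 4470 s/mm²
(−0.4%); η = 1.69 versus 1.68 at the duty-cycle-limited TR/δ = 42/16.7 ms;
the constrained optimum at b_eff = 4500 lands at TR/δ = 32.9/17.1 ms with
η = 1.86 versus the printed 33/17.1 and 1.87; and the tabulated optima at
b_eff = 1000/3000/5000 agree to within 2%.  Two printed values do not
reconcile with exact physics under any attenuation-rule variant we tested:
the low-b protocol's b_eff (printed 18, exact 19.95 s/mm²) and the
b_eff = 10,000 optimum (printed η = 1.24, exact maximum 1.17).  Both
discrepancies have the size and sign expected of the linearized attenuation
approximation in the strong-weighting/high-order regime, and both are
reported honestly by the acceptance machinery rather than tuned away.

## Synthetic voxels and Bayesian fitting

The generator emulates the study acquisition: 54 electrostatically
optimized, antipodally symmetric gradient directions at b (or b_eff) ≈ 4500
s/mm², plus 6 (DW-SE, b = 0) or 30 (DW-SSFP, TR = 27 ms/δ = 1.2 ms spoiler
protocol) low-b volumes; fixed-tissue parameters throughout; Rician
magnitude noise, optionally averaged over repeats.  Single-fiber voxels use
a stick fraction f₁ = 0.70 (typical deep white matter) with the ball/stick
diffusivity equal to the tissue ADC.

**SNR convention.**  Simulation SNR is defined per volume on the *mean
diffusion-weighted amplitude*.  The DW-SSFP low-b protocol has roughly twice
the amplitude of its DW volumes (shorter TR), so an SNR pegged to the low-b
volume would silently halve the SSFP arm's effective SNR and make the two
forward models incomparable at equal nominal SNR.

**Fitting** is component-wise random-walk Metropolis–Hastings over
(S0, log d, {f_j, θ_j, φ_j}, log σ) under a Gaussian likelihood with unknown
σ — adequate for magnitude data at SNR ≳ 5, a documented limitation at very
low SNR.  Priors: positive-uniform S0, broad log-uniform d and σ,
uniform [0, 1] fractions with Σf ≤ 1, area-correct sin θ orientation prior.
ARD places a 1/f shrinkage prior on fractions beyond the first, with the
posterior-mean support rule f₂ ≥ 0.05.  Proposal widths adapt during
burn-in toward ~50% acceptance; defaults are burn-in 1000 (single fiber) or
4000 (multi-fiber: shrinkage of an unsupported secondary fraction converges
slowly, and shorter burn-ins leave transient split-fiber states that inflate
apparent second-fiber support), then 1250 iterations thinned by 25 (50
retained draws); the recorded seed reproduces the chain bit-for-bit.  The
second-fiber support statistic uses per-draw fraction-sorted labels, the
standard convention for ranking fiber populations.  Stick amplitudes for the DW-SSFP forward model come
from a cubic-spline table of the exact echo amplitude versus diffusivity
(rebuilt per protocol/tissue; ~10⁻⁵ relative accuracy), keeping a
100-voxel experiment to a few minutes.

The **cone of uncertainty** is the 95th percentile of angles between
posterior orientation draws and their mean direction, the principal
eigenvector of the mean dyadic ⟨vvᵀ⟩ (antipodally symmetric).  The
matched-scan-time comparison simulates the same voxels through both arms
with the per-volume SNR ratio set to the computed SNR-efficiency ratio of
the implemented protocols, fits each voxel, and reports the voxel-wise
percent difference `100·(u_SE − u_SSFP)/mean(u_SE, u_SSFP)` (positive:
DW-SSFP less uncertain).

**What passing tests show — and don't.**  The synthetic experiment isolates
the SNR-efficiency mechanism: identical anatomy, perfect coregistration, no
eddy currents, B1 or susceptibility effects, single-compartment relaxation,
and noise exactly Rician.  Passing it demonstrates that the fitted
uncertainty responds to sequence SNR efficiency as predicted, not that any
real scanner will realize the full gain.  Two information-theoretic limits
of the study conditions are documented deliberately: at per-volume SNR 20
the single-voxel orientation error distribution has a ~7° 95th percentile
(mean ~4°) — maximum-likelihood fits on the same data do no better, so this
is the data's limit, not the sampler's — and at fixed-tissue contrast
(b·d ≈ 0.36) the orientations of two 90°-crossed sticks are only weakly
determined (ML errors averaging ~19° at SNR 30), consistent with such data
being marginal for second-fiber support.  The acceptance suite states both
facts as measured.

Problem sizes in the shipped tests (54 directions, 100-voxel experiments,
10-voxel crossing study, 3×3×3 efficiency landscape) were chosen so the
whole suite completes in minutes on one CPU while keeping every Monte-Carlo
margin comfortable.

## Known limitations

* Rectangular gradient lobes (no ramps); no finite-RF, slice-profile, B1 or
  off-resonance effects; single-compartment relaxation.
* Gradient duty-cycle/heating physics enters only through user-imposed
  bounds (e.g. fixing TR/δ = 42/16.7 ms), not a thermal model.
* The Gaussian likelihood under Rician noise biases d slightly at very low
  SNR.
* DW-SE absolute amplitudes inherit the TE(b) anchor table; between anchors
  they are interpolation, not scanner truth.
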