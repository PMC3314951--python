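# pmdwi

Sequence choice and protocol optimization for diffusion MRI of whole,
formalin-fixed *post-mortem* human brains.

Fixation and room-temperature scanning change tissue drastically: T2 drops to
~45 ms, T1 to ~400 ms, and the apparent diffusion coefficient falls roughly
tenfold to ~0.08 × 10⁻³ mm²/s.  Conventional diffusion-weighted spin echo
(DW-SE) suffers badly in this regime, because reaching a useful b-value costs
a long echo time that short-T2 tissue cannot afford.  Diffusion-weighted
steady-state free precession (DW-SSFP) accumulates diffusion sensitivity over
many short repetition periods with a single gradient lobe per TR, and is
therefore a strong candidate for *post-mortem* work.  `pmdwi` provides the
quantitative machinery to make that comparison and to plan protocols:

* **Steady-state signal models.**  Closed-form DW-SE signal (Ernst-angle or
  saturation recovery over TR − TE, `exp(−TE/T2)` decay, optional
  `exp(−bD)`), and the exact steady state of the Buxton sequence model for
  DW-SSFP (one rectangular diffusion lobe of moment `q = γGδ` per TR,
  constant RF phase, echo pathway), solved directly from the
  configuration-state recursion with per-order diffusion attenuation.
* **Effective b-value.**  `b_eff = −(1/D)·ln[S(D)/S(0)]`, the DW-SE b-value
  giving the same fractional attenuation for the stated tissue.
* **SNR-efficiency optimization.**  `η = S[% of M0]·√(T_acq/TR)`, maximized
  over (TR, δ, α) subject to a b_eff constraint for DW-SSFP, and over TR at
  the minimum achievable TE for DW-SE.
* **EPG oracle.**  An independent extended-phase-graph power-iteration
  simulator validates the closed-form solver to ~10⁻⁸ relative.
* **Bayesian voxel fitting.**  A ball-and-stick mixture with
  sequence-appropriate forward physics (the DW-SSFP version takes T1/T2 as
  inputs), fitted by Metropolis–Hastings MCMC in the statsmodels idiom
  (`BallStickModel(...).fit()` → results object with `summary()`, 95% cone
  of uncertainty, ARD support for a second fiber).

## Worked example

```python
from pmdwi import (FIXED_TISSUE, SSFPProtocol, beff,
                   evaluate_ssfp_protocol, optimize_dwssfp, optimize_dwse)

# the implemented whole-brain DW-SSFP protocol
proto = SSFPProtocol(TR=42, alpha=37, delta=16.7, G=38)
print(round(beff(proto, FIXED_TISSUE)))          # 4453  (s/mm^2)

# its SNR efficiency with the flip angle optimized at fixed timing
r = evaluate_ssfp_protocol(42, 16.7)
print(round(r.eta, 2))                           # 1.69

# the unconstrained optimum at b_eff = 4500 s/mm^2 ...
opt = optimize_dwssfp(4500)
print(round(opt.protocol.TR, 1), round(opt.protocol.delta, 2),
      round(opt.eta, 2))                         # 32.9 17.14 1.86

# ... versus the best DW-SE can do at the same b-value
se = optimize_dwse(4500)
print(round(se.eta, 2), round(opt.eta / se.eta, 2))   # 1.09 1.71
```

Reading: the implemented DW-SSFP protocol carries an effective b-value of
about 4.5 ms/µm² for fixed white matter; the optimizer places the ideal
protocol at TR/δ ≈ 33/17.1 ms with SNR efficiency η ≈ 1.86 (percent-M0
units), roughly 1.7× what an optimized DW-SE sequence achieves at the same
diffusion weighting — the predicted advantage that motivates DW-SSFP for
*post-mortem* tractography.

The same comparison is available from the shell:

```bash
pmdwi table1                 # optimal eta for both sequences at several b
pmdwi beff --tr 42 --alpha 37 --delta 16.7
pmdwi validate               # closed form vs EPG oracle over a grid
pmdwi compare-uncertainty --n-voxels 20 --seed 1
```

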