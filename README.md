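# hybridmt

Unconstrained two-pool quantitative magnetization-transfer (qMT) modeling
with hybrid-state pulse sequences: fingerprint simulation, Cramér-Rao-bound
experiment design, and voxel-wise parameter fitting.

## The problem

Longitudinal relaxation in brain tissue is not mono-exponential.  Water
protons (the *free* pool, fraction `m0f`) exchange magnetization with
protons bound in macromolecules (the *semi-solid* pool, fraction
`m0s = 1 - m0f`), whose transverse relaxation time `T2s ≈ 10 µs` makes them
invisible to direct acquisition.  Classical qMT methods constrain the two
longitudinal rates to be equal (`R1s = R1f`) to tame noise amplification,
but in white matter `T1s ≈ 0.34 s` is actually far shorter than
`T1f ≈ 1.84 s` — so the constrained model reports biased *apparent*
parameters.  This package implements the machinery to work with the
unconstrained model on a voxel-by-voxel basis, for researchers developing
or analyzing qMT/MR-fingerprinting experiments.

## The model

The homogeneous-coordinate Bloch-McConnell equation for the state
`M = (xf, yf, zf, xs, zs, 1)ᵀ`:

```
∂t M = [ -R2f   -ωz    ωy      0            0           0      ]
       [  ωz    -R2f   0       0            0           0      ]
       [ -ωy    0     -R1f-Rx·m0s  0        Rx·m0f      m0f·R1f] · M
       [  0     0      0      -R2s,l        ωy          0      ]
       [  0     0      Rx·m0s -ωy          -R1s-Rx·m0f  m0s·R1s]
       [  0     0      0       0            0           0      ]
```

The semi-solid pool's non-exponential decay under RF (super-Lorentzian
lineshape) is handled with the generalized Bloch model — a Volterra
integro-differential equation in the lineshape's Green's function — and
linearized into an effective exponential rate `R2s,l(R2s, α, TRF)` that
reproduces the end-of-pulse magnetization exactly.  Pulse trains are
anti-periodic balanced-SSFP cycles (π-phase cycling, a T2s-selective π
inversion every cycle, 1142 pulses at TR = 3.5 ms by default); the periodic
steady cycle is solved exactly as a linear fixed point, and the per-TR
complex signal is the *fingerprint* that encodes all model parameters.

Around that core: Cramér-Rao bounds and CRB-driven flip-angle/TRF
optimization (`encoding`), dictionary + SVD-subspace compression and
bounded variable-projection NLLS fitting of all 9 real unknowns
(`estimation`), apparent-parameter conversion, phantom GLM, cohort
statistics and lesion PCA (`analysis`), and synthetic BSA-phantom /
digital-brain generators with seeded complex Gaussian noise (`synthio`).

## Worked example

```bash
python examples/apparent_parameters.py
```

```
reference point: m0s=0.2, R1f=0.5/s, R1s=3/s, Rx=15/s
  linear MT correction term      0.500/s
  apparent R1f (order 1 / 2 / exact)  1.000 / 0.9333 / 0.9396 1/s
  apparent exchange rate (order 2 / exact)  17.57 / 17.56 1/s
  apparent pool size m0s_a       0.1467  (true m0s = 0.2)
  -> the constrained model roughly doubles R1f and shrinks m0s by a quarter

white-matter means: m0s=0.212, T1f=1.84 s, T1s=0.34 s, Rx=13.6/s
  apparent T1f  1.019 s   (unconstrained T1f = 1.84 s)
  apparent Rx   16.1 1/s
  apparent m0s  0.153

free-pool-normalized pool size 0.094 corresponds to a total-pool fraction 0.086
```

The first block is the didactic reference point: because
`m0s·(R1s − R1f) = 0.5/s` is as large as `R1f` itself, magnetization
transfer *is* a dominant driver of the observed longitudinal relaxation,
and a constrained fit would report `R1f ≈ 1/s` and `m0s ≈ 0.15` for a
tissue whose true values are `0.5/s` and `0.2`.  The second block applies
the same conversion to healthy white-matter means.

The other examples simulate a full fingerprint
(`simulate_fingerprint.py`), compute and optimize CRBs
(`crb_experiment_design.py`), fit a noisy voxel end to end
(`fit_single_voxel.py`), and run the phantom GLM / cohort / lesion-PCA
analyses (`phantom_and_cohort_analysis.py`).

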