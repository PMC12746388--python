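# mcgre

Simultaneous bone-selective, T1-weighted and T2-weighted MRI from a single
dual-pass, dual-echo, partially RF-spoiled gradient-echo (PSGRE) steady-state
acquisition — simulation, k-space synthesis, model-based reconstruction and
retrospective contrast extraction, exercised end to end on Bloch-simulated
digital phantoms.

## The problem

Craniofacial imaging often needs both CT (bone) and MRI (soft tissue).
A PSGRE pulse train with a small quadratic RF phase increment

    phi(n) = phi(n-1) + n * theta,        theta ~ +1.5 deg

leaves residual transverse coherence whose steady-state phase grows
monotonically with tissue T2, while the magnitude stays T1-weighted.  The
complex steady-state image `x` therefore encodes *both* weightings; any
soft-tissue contrast is extracted retrospectively by a phase modulation
`psi`:

    x_psi = | Re( x * exp(i psi) ) |,     psi in [0, 180) deg (pi-periodic)

Acquiring each pulse at two echo times — an ultrashort echo (UTE, 80 us)
that still sees the rapidly decaying bone-water signal (T2 ~ 0.3-0.4 ms) and
a conventional echo (CTE, 2.38 ms) that does not — yields a bone-selective
image by normalized echo subtraction, which for mono-exponential decay is
exactly proton-density independent:

    x_s = (|x_UTE| - |x_CTE|) / (|x_UTE| + |x_CTE|) = tanh(dTE / (2 T2))

A spatially varying background phase `exp(i phi(r))` would corrupt the
encoding; it is removed by acquiring two passes with opposite increments
(+theta gives `x`, -theta gives `conj(x)`), estimating
`phi = angle(x_+ * x_-) / 2` and averaging the corrected passes.  The four
(echo, pass) k-space datasets `y_{k,l} = F S exp(i phi) x_{k,l}` are
reconstructed jointly with a joint-L0 wavelet penalty (all four images share
one wavelet support), solved by a fixed-iteration primal-dual scheme with
the joint hard threshold as proximal step.

## Layout

| module | contents |
|---|---|
| `mcgre.sequence_sim` | EPG + brute-force isochromat steady-state simulators, phase schedules, phase-vs-T2 curves, weighting-interval detection |
| `mcgre.phantom` | seeded head-like digital phantoms, coil maps, background phase, ideal (echo, pass) images |
| `mcgre.encoding` | golden-angle center-out ramp-up radial + Cartesian trajectories, Kaiser-Bessel gridding NUFFT, multi-coil forward/adjoint operators |
| `mcgre.recon` | CG least squares, joint hard thresholding, joint PDHG reconstruction |
| `mcgre.contrast` | background-phase estimation, pass combination, contrast extraction |
| `mcgre.bone` | direct and weighted-least-squares normalized echo subtraction |
| `mcgre.io`, `mcgre.pipeline`, `mcgre.cli` | HDF5 k-space container, NIfTI volumes, YAML-configured end-to-end driver, `mcgre` command line |

## Worked example

```python
import numpy as np
from mcgre import (SequenceParams, simulate_steady_state_epg,
                   weighting_intervals, DEFAULT_TISSUES, tanh_bone_value)

seq = SequenceParams()   # TR 5.5 ms, TE (80 us, 2.38 ms), flip 24 deg, theta +1.5 deg
for name in ("wm", "gm", "csf", "bone"):
    t = DEFAULT_TISSUES[name]
    s = simulate_steady_state_epg(seq, t)
    print(f"{name:5s} |s_ute|={abs(s.s_ute):.4f}  phase={np.degrees(np.angle(s.s_ute)):6.1f} deg"
          f"  xs={tanh_bone_value(seq.te[0], seq.te[1], t.t2):.3f}")
brain = [DEFAULT_TISSUES[k] for k in ("wm", "gm", "csf")]
print(weighting_intervals(seq, brain))
```

prints

```
wm    |s_ute|=0.0611  phase=  35.0 deg  xs=0.016
gm    |s_ute|=0.0540  phase=  42.6 deg  xs=0.013
csf   |s_ute|=0.0347  phase=  80.8 deg  xs=0.001
bone  |s_ute|=0.0114  phase=   0.0 deg  xs=0.997
((101.0, 179.0), (52.0, 87.0))
```

The signal phase rises with T2 (WM 35 deg -> CSF 81 deg) while bone, whose
coherence dies within one TR, stays at zero phase: that is the entire
contrast mechanism.  The last line gives the phase-modulation intervals in
which extraction is strictly T1-weighted (here 101-179 deg: magnitude
decreasing in T1) and strictly T2-weighted (52-87 deg).  `xs` is the
analytic bone-selectivity value: ~1 for bone, ~0 for soft tissue.

The full synthetic chain (phantom -> k-space -> joint recon -> phase
removal -> contrasts -> bone maps, with NIfTI/HDF5/JSON outputs):

```sh
mcgre pipeline config.yaml      # or: from mcgre import run_pipeline
```

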