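# fewviewct

Few-view fan-beam CT reconstruction with SART and soft-threshold filtering
of total-difference (TD) and weighted-total-difference (WTD) regularizers.

## The problem

In computed tomography the radiation dose scales with the number of
projection views, so there is strong interest in reconstructing from
sparsely sampled angles ("few-view CT"). With only a few dozen views the
linear system `A f = p` — where `f` is the image, `p` the measured ray
sums and `A` the sparse matrix of ray–pixel intersection lengths — is
severely underdetermined, and classical algebraic methods such as SART
leave strong streak artifacts. Compressed-sensing reconstructions add a
sparsity-promoting regularizer on the image gradient. The *total
difference*

    TD(f) = Σ |D₁f| + |D₂f|

(ℓ₁ of the horizontal and vertical pixel differences) is a cheap
anisotropic surrogate for total variation, but it only enforces gradient
sparsity along the axes. The *weighted total difference* adds the two
diagonal partial differences with weight α,

    WTD(f) = Σ (|D₁f| + |D₂f|) + α Σ (|D₃f| + |D₄f|),

so that both gradient sparsity and directional gradient continuity are
penalized; edges are preserved along more directions and diagonal streaks
are suppressed more effectively.

This package implements, end to end and with no external data:

* an analytic low-contrast head-phantom slice (elliptical primitives,
  skull 1.80 / brain 1.05 / CSF 1.045 / air 0, fine high-contrast
  inner-ear structure), rasterized with supersampled anti-aliasing;
* the fan-beam geometry (circular source trajectory, equi-distance virtual
  detector through the rotation axis) and a Siddon intersection-length
  projector producing the sparse system matrix;
* sinogram simulation with optional zero-mean Gaussian noise
  (σ a fraction of the sinogram maximum);
* three reconstructors sharing one alternating loop — plain **SART**,
  **TDM-STF** (SART + TD soft-threshold filtering + momentum) and
  **WTDM-STF** (the same with the WTD filter, α = 1) — with a geometric
  threshold schedule and FISTA-style acceleration;
* RMSE / PSNR / NRMSD / NMAD quality measures and 1-D profile extraction;
* a CLI (`fewviewct`) and an experiment runner that writes windowed PNGs,
  metric traces, summary and relative-gain tables.

## Worked example

```python
import numpy as np
import fewviewct as fv

truth = fv.build_forbild_head_slice(128, 0.4)          # 128² slice, 0.4 cm pixels
geom = fv.FanBeamGeometry(293.1, 257, 0.2, fv.view_angles(40))
A = fv.build_system_matrix(geom, truth)
sino = fv.simulate_projections(truth, A)               # noise-free p = A f*

for alg in ("sart", "tdm-stf", "wtdm-stf"):
    cfg = fv.ReconstructionConfig(algorithm=alg, max_iterations=150, trace_every=0)
    res = fv.reconstruct(A, sino, cfg)
    r = fv.evaluate(res.image, truth)
    print(f"{alg:9s} rmse={r.rmse:.4e} psnr={r.psnr:.2f} "
          f"nrmsd={r.nrmsd:.4e} nmad={r.nmad:.4e}")
```

prints

```
sart      rmse=6.9851e-02 psnr=28.22 nrmsd=1.7666e-01 nmad=3.2409e-01
tdm-stf   rmse=8.8458e-03 psnr=46.17 nrmsd=2.2371e-02 nmad=3.3394e-02
wtdm-stf  rmse=5.0680e-03 psnr=51.01 nrmsd=1.2817e-02 nmad=1.6869e-02
```

Both filtered variants suppress the streak artifacts that dominate the
SART image (an order of magnitude lower RMSE), and the WTD filter — which
also penalizes the diagonal differences — beats the TD filter on every
measure at equal iteration count. The same comparison at full scale (512²
phantom, 1025 detector bins, 400 iterations) is run by the acceptance
script below and by `tests/test_acceptance.py`.

The same pipeline is available from the shell:

```sh
fewviewct experiment --n 512 --views 40 --iterations 400 --out runs/noise-free
fewviewct experiment --n 512 --views 40 --iterations 400 \
    --noise-percent 0.0005 --seeds 1,2,3 --out runs/noisy
```

Each run directory contains the phantom and reconstructions (raw float +
windowed PNG, display window [1.03, 1.08]), per-iteration metric traces,
`summary.csv`, and `gains.csv` with the relative improvement of the WTD
variant over the TD variant.

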