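# bltmds — multispectral differential bioluminescence tomography

Bioluminescence tomography (BLT) reconstructs an internal luminescent source
distribution from multispectral surface light measurements of a small animal.
Reconstruction accuracy is limited by three compounding problems: the
diffusion-equation (DE) forward model only approximates radiative transfer,
the CCD measurement carries sampling and offset noise, and the linear inverse
problem is severely ill-posed.

This package implements and compares three multispectral stacking strategies
around a finite-element DE forward model:

* **TM** (traditional multispectral): stack the energy-weighted
  per-wavelength systems, `[η_n A_λn] S = [Φ_λn]`;
* **SD** (spectral derivative): stack adjacent-wavelength differences;
* **MDS** (multispectral differential): stack *all* pairwise differences,
  `[η_j A_λj − η_k A_λk] S = [Φ_λj − Φ_λk]` for every pair `j < k`.

Because light at similar wavelengths sees a near-identical system response,
differencing cancels the wavelength-independent part of both the forward
model error and the CCD offset noise (`Ot = photon + readout + dark
current`), while the enlarged stack lowers the condition number of the
inverse problem.

The source is recovered by non-convex sparse regularization,

    min_S  ½‖A S − Φ‖₂² + τ‖S‖ₚᵖ ,  0 < p < 1,

solved by iteratively reweighted weighted-L1 subproblems
(`λ_i = ζ·p/(|S_i|+ε)^{1−p}`), each handled by (monotone, optionally
FISTA-accelerated) iterative shrinkage-thresholding with a non-negative
shrink operator `max(a − z, 0)`.

Everything runs on synthetic box phantoms produced by the built-in generator
(structured Kuhn tetrahedralization, organ-like region labels, spherical
sources); no external data are required.

## Worked example

```python
from bltmds import pipeline as pl

cfg = pl.ExperimentConfig(seed=1)   # 20 mm muscle phantom, 1 mm source at
                                    # (10, 10, 14.8) mm, 4 wavelengths
                                    # (610–670 nm), 1% spot + 0.5% offset noise
table = pl.run_experiment(cfg)
print(table.to_string())
```

prints (one row per stacking strategy):

```
          n_blocks          cond  LE_mm      dice  CNR     time_s
strategy
tm               4  4.579879e+08    0.8  0.666667  inf  35.221990
sd               3  6.500420e+06    0.8  0.666667  inf  25.619012
mds              6  1.453092e+07    0.8  0.666667  inf  56.652683
```

`cond` is the effective 2-norm condition number of each stacked system — the
all-pairs differential stack is an order of magnitude better conditioned
than the traditional stack (4.6e8 → 1.5e7), which is the mechanism by which
differencing alleviates ill-posedness.  `LE_mm` is the distance between the
energy-weighted centre of the reconstruction and the true source centre
(0.8 mm here, under one mesh spacing), `dice` the overlap between the
reconstructed region (≥ 10% of peak) and the true source nodes, and `CNR`
the contrast-to-noise ratio (infinite when the background reconstructs to
exactly zero).

The same pipeline is exposed as a CLI:

```sh
blt experiment --config config.yaml --seed 1 --out results/
blt reconstruct --config config.yaml --strategy mds
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's main computation from scratch: the full TM/SD/MDS
comparison on the default phantom (forward simulation with CCD noise,
stacking, reconstruction, metrics) and the model-mismatch experiment in
which fine-mesh reference data are compared against a 2× coarser model to
show that spectral differencing shrinks correlated forward-model error.  It
writes the requested JSON to `--out` and a human-readable summary alongside
it.

## Layout

| module | contents |
| --- | --- |
| `bltmds.mesh` | phantom meshes, region labelling, spherical sources, VTK/plain-text I/O |
| `bltmds.optics` | per-region per-wavelength optical properties, diffusion coefficient, spectral weights η |
| `bltmds.forward` | P1 FEM assembly (Robin boundary), fluence solves, system matrices, CCD noise model, analytic oracle |
| `bltmds.stacking` | TM / SD / MDS stacking and condition numbers |
| `bltmds.recon` | shrink operator, (M)ISTA, reweighted-L1 Lp solver |
| `bltmds.metrics` | energy difference, cosine similarity, location error, Dice, CNR |
| `bltmds.pipeline`, `bltmds.cli` | experiment orchestration, YAML configs, `blt` CLI |

See `docs/methods.md` for the model details, parameter choices, and known
limitations.
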