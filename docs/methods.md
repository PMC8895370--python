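# Methods

## Forward model

Photon transport is modelled by the steady-state diffusion equation

    −∇·(D ∇Φ) + μ_a Φ = q,     D = 1 / (3 (μ_a + μ_s′)),

valid in highly scattering tissue away from sources and boundaries.  The
domain is a tetrahedral phantom with piecewise-constant optical properties
per region label (standing in for segmented organs).  Discretization uses P1
(linear) elements:

* **stiffness**: exact element integrals `D_t V (∇φ_i · ∇φ_j)`;
* **absorption mass**: *lumped* (`μ_a V/4` per vertex).  Lumping, combined
  with the nonobtuse Kuhn tetrahedra of the structured generator, makes the
  system matrix an M-matrix, so a non-negative source always yields a
  non-negative discrete fluence.  The consistent mass matrix violates this
  by ~1e−4 relative at box corners; accuracy against the analytic oracle is
  unaffected (max 6.0% vs 6.4% on the validation phantom);
* **boundary**: Robin (type-III) condition `−D ∂Φ/∂n = Φ/(2A_n)` with
  `A_n = (1+R_eff)/(1−R_eff)` and `R_eff` from the Groenhuis polynomial in
  the relative refractive index (tissue default 1.37, air 1.0), also with a
  lumped surface mass (`area/3` per vertex).  A Dirichlet option exists
  (diagonal penalty) for comparison.

The load vector is the lumped-volume weighting of the nodal source density,
so the integral of any embedded source equals its nominal power exactly.
Systems are solved by sparse LU (MMD ordering; CG fallback) and validated
against the infinite-medium Green's function
`Φ(r) = P exp(−μ_eff r)/(4π D r)`: on a homogeneous 40 mm box at 1 mm
spacing the FEM solution agrees to better than 10% for radii 3–8 mm from
the source, and the error decreases under mesh refinement.

Per-wavelength system matrices `A_λ` (detector fluence per unit nodal source
density) are built by one adjoint solve per detector, exploiting the
symmetry of the operator; the construction is cross-checked against
brute-force per-column solves.

## Optical properties

The builtin table covers six mouse torso tissues (muscle, heart, stomach,
liver, kidneys, lungs) at 610/630/650/670 nm.  Its scattering column is
interpreted as already-reduced scattering (g = 0) by default, because the
values feed the diffusion coefficient directly; an `anisotropy` argument
reinterprets them as raw μ_s with μ_s′ = μ_s(1−g).  Absorption decreases
monotonically with wavelength for every tissue, which is what makes the
multi-wavelength stack informative.

Spectral energy fractions η (the share of total emission per band) default
to uniform when no emission spectrum is supplied; they can be set from
measured band energies.  η multiplies the matrix blocks only — the data
blocks are raw (differences of) measurements — matching the stacked system
definitions.

## Measurement noise

A surface measurement at wavelength λ is Φ = M + s(λ) + Ot:

* `s(λ)`: sampling error — a Gaussian light-spot profile centred on the
  brightest detector, amplitude 1% of that wavelength's peak signal,
  width `5 mm · λ/λ_min` (wider spots at longer wavelengths), modulated by
  20% per-detector Gaussian jitter; realizations differ per wavelength;
* `Ot`: wavelength-independent CCD offset (photon + readout + dark
  current) — a constant dark level (0.5% of the global peak) plus a
  per-detector Gaussian component (20% of the level), drawn *once* per
  simulation and reused bitwise at every wavelength;
* digitization: signal and offset are rounded to a shared power-of-two grid
  (2⁻⁴⁰ of the global peak, ~1e−12 relative — far below any physical
  effect).  On a common fixed-point grid float64 sums and differences are
  exact, so the shared offset cancels *bitwise* under spectral
  differencing, which is the discrete analogue of the offset term dropping
  out of the differential noise budget.  Setting the quantum to zero
  recovers the plain Φ = M + s + Ot.

The noise magnitudes are package defaults (the source experiments do not
state theirs); all are config-exposed.

## Stacking strategies

For wavelengths λ₁ < … < λ_n:

* `tm`: n blocks `η_i A_i`, data `Φ_i`;
* `sd`: n−1 adjacent-pair difference blocks (the spectral-derivative
  comparison method is approximated by adjacent differencing; ratio-based
  variants are out of scope);
* `mds`: all n(n−1)/2 ordered pair differences `η_j A_j − η_k A_k`, data
  `Φ_j − Φ_k`, in the canonical order (1,2),(1,3),…,(n−1,n).

Conditioning is reported as the 2-norm condition number σ_max/σ_min of the
stacked (rectangular) matrix, plus an "effective" value that drops singular
values below 1e−12·σ_max.  No row or block normalization is applied by
default.

## Reconstruction

The Lp (0 < p < 1, default 0.5) regularized problem is solved by
iteratively reweighted weighted-L1:

1. first outer pass: uniform weights λ_i = ζ (plain L1), with
   ζ = 1e−3·‖Aᵀb‖∞ by default;
2. subsequent passes: λ_i = ζ·p·(|S_i| + ε)^{p−1} (ε = 1e−10, capped at
   ζ·1e4), the exact majorization slope of ζ|s|^p, warm-started from the
   previous iterate.  The objective ½‖AS−b‖² + ζ‖S‖ₚᵖ is non-increasing
   across passes.  (A published variant with weights ∝ |S|^{1−p} — which
   vanishes at zero and penalizes large entries more — is available behind
   `paper_literal_weights` for comparison; it is not a descent scheme.)

Each subproblem is solved by ISTA:
`S ← shrink(S + 2ξ Aᵀ(b − AS), 2ξλ)` with the one-sided non-negative
shrink `max(a − z, 0)` (source power is physically non-negative; a
two-sided operator is available).  The automatic step is
ξ = 0.495/‖AᵀA‖₂ (spectral norm by seeded power iteration), so the
effective gradient step 2ξ stays within the majorization bound 1/‖AᵀA‖₂
and the objective decreases monotonically; ξ ≥ 1/‖AᵀA‖₂ is rejected.
Stopping requires relative changes of both iterate and objective below
`rel_tol` (1e−6), with caps of 3000 inner and 5 outer iterations.

Two practical options, both off at the raw-solver level and on in the
pipeline defaults:

* **sensitivity (column-norm) compensation** — solve on A·D⁻¹ with
  D = diag(‖a_j‖₂) and map back.  Deep-node columns are exponentially
  small, and an unweighted sparsity penalty otherwise drags sources to the
  surface (observed 4–8 mm localization error on noise-free data; ~0 with
  compensation).  Equivalent to per-unknown ζ_i ∝ ‖a_i‖₂.
* **monotone FISTA acceleration** — extrapolated gradient point with a
  descent safeguard (an ascending step is rejected and the momentum
  restarted), preserving every ISTA invariant while converging orders of
  magnitude faster on the ill-conditioned stacks.

## Evaluation metrics

* **energy difference** (per detector): specific mode `|Φ_ref − Φ_model|`;
  differential mode `||Φ_ref_j − Φ_ref_k| − |Φ_model_j − Φ_model_k||`;
* **cosine similarity** of two surface-energy vectors (scale-free);
* **location error**: distance between the energy-weighted centre of the
  reconstruction (nodes above a configurable fraction of peak; all positive
  nodes by default) and the true centre.  With several sources,
  reconstruction nodes are attributed to the nearest true centre and the
  mean per-source error is reported;
* **Dice**: overlap `2|X∩Y|/(|X|+|Y|)` between the reconstructed region
  (≥ 10% of peak by default) and the nodes inside the true source sphere;
* **CNR**: `|μ_ROI − μ_BCK| / √(w_ROI σ²_ROI + w_BCK σ²_BCK)` with
  node-count-fraction weights and population variances (the convention is
  not standardized; this one is symmetric and parameter-free).  A
  reconstruction whose background is exactly zero has infinite CNR, which
  is reported as such.

## Model-mismatch experiment

The claim that differencing cancels correlated forward-model error is
tested with a mesh-mismatch stand-in for transport-vs-diffusion error:
reference surface data from a fine mesh (1.25 mm), model data from a 2×
coarser mesh of the same phantom, compared at the shared boundary nodes.
Each wavelength's maps are expressed in units of that wavelength's
reference peak before comparison.  This is deliberate: absolute per-band
emission is unknown in practice, the cosine-similarity comparator is
scale-free for the same reason, and discretization error is proportional to
the signal, whose magnitude varies ~14× across 610–670 nm through 5 mm of
muscle — on raw data the wide pairs could never cancel, which would test
signal dynamics rather than error correlation.  In normalized units the
specific error is largest at 610 nm and decreases with wavelength, and all
six pairwise differential errors fall below the mean of their constituent
specific errors.

## Synthetic phantoms — what they do and do not establish

The generator produces structured box phantoms (optionally carved to
cylinders, with sphere/box/cylinder organ-like regions) with a 1 mm
spherical source of unit power placed ~5 mm below the top face at an
off-lattice position, mirroring typical implanted-source simulations at
610–670 nm depths.  Defaults: 20 mm box, 1 mm spacing, homogeneous muscle,
four wavelengths, every 8th boundary node as a detector, interior nodes as
the permissible region.

Green tests on these phantoms establish the *relative* behaviour of the
stacking strategies — conditioning, noise cancellation, localization —
under a diffusion-consistent forward model with synthetic CCD noise.  They
do not establish performance on real anatomy (curved boundaries, organ
heterogeneity, Monte-Carlo-grade transport near sources), absolute
quantitation of source power, or robustness to detector-position error;
measurement data here are simulated by the same discretization family used
for inversion (the mismatch experiment varies only mesh resolution).

## Numerical choices and degenerate inputs

* All randomness flows from one integer seed per run through named
  substreams (offset draws use a fixed substream so they are
  wavelength-independent); runs are bit-reproducible.
* Nearest-node ties (source fallback) resolve to the lowest node index.
* Spheres use closed balls (≤ radius); region specs are applied in order,
  later ones overwriting earlier labels.
* A zero stacked matrix, empty detector/permissible sets, non-finite
  inputs, negative thresholds, and missing property entries raise
  immediately with specific messages.
* CNR of two constant equal-mean regions returns 0 with a warning (0/0).
* Mesh files are VTK legacy ASCII (tet cells, integer `region` cell array)
  or a plain-text `N_nodes N_tets` header format; write→read round-trips
  are exact for connectivity and labels and to 1e−9 for coordinates.

## Known limitations

* The spectral-derivative comparison is implemented as adjacent-pair
  differencing, not the original ratio formulation.
* Curved phantom boundaries are stair-stepped (cell masking), which
  perturbs the Robin boundary area slightly.
* The CLI emits tables and VTK/CSV/JSON files; no plotting is bundled.
* Permissible regions are geometric (interior/all); anatomical priors are
  out of scope.
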