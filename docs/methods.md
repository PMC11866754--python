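# Methods

## Model overview

`osvnet` predicts molecular correlation energies through an exact pairwise
decomposition: the MP2 correlation energy is written as a sum of energies
`e_ij` of localized-occupied-orbital pairs, a neural functional maps a
compact per-pair descriptor to `e_ij`, and the molecular prediction is the
plain sum of pair predictions. Because every pair is supervised directly
(mean absolute error with equal weight per pair), per-pair errors are
approximately symmetric around zero and the total-energy error grows like
√N_pairs rather than N_pairs — the error-cancellation property that makes
the functional transferable from small training molecules to much larger
systems. Fine-tuning on one or a few molecules of a new regime then adapts
the functional by retraining only a small fraction of its parameters.

## Mean-field backend

A minimal restricted Hartree–Fock engine supplies everything the featurizer
needs: McMurchie–Davidson one- and two-electron integrals over contracted
s/p Gaussians (Boys function via series + downward recursion below t = 35,
asymptotic + upward recursion above), DIIS-accelerated SCF converged to
1e−10 Eh, and a final re-diagonalization so the exported orbitals and Fock
matrix form an exact eigenpair (rotation-invariance checks then hold at
machine precision). STO-3G and 6-31G parameters for H/C/N/O are embedded;
the backend sits behind a single narrow `ScfContext` contract so another
engine can be swapped in. Supported systems are closed-shell singlets up to
roughly 30 atoms (full in-memory ERI transformation, no density fitting).

* **Frozen core** — 1s orbitals of C/N/O are excluded from correlation by
  default (configurable). The convention is declared, not derived.
* **Localization** — Pipek–Mezey by Jacobi 2×2 sweeps on Mulliken
  populations, converged to 1e−10 in the metric. Determinism conventions:
  LMOs ordered by descending largest per-atom population (ties broken by
  owning-atom index, then the population vector), sign fixed so the
  largest-magnitude AO coefficient is positive.
* **Units** — Hartree everywhere internally; kcal/mol
  (1 Eh = 627.509474 kcal/mol) only in reports.

## OSV descriptors

For each LMO *i* the diagonal semicanonical amplitudes
`t_ii^{ab} = −(ia|ib)/(ε_a + ε_b − 2 f_ii)` are SVD-factorized; the leading
`n_osv` singular vectors (default 8, configurable 1…n_virt) form the
orbital-specific virtual space. Conventions and choices:

* Singular values sorted descending; each OSV's sign is fixed by making its
  first significant component positive (degenerate values are ordered
  stably). Feature tensors are nevertheless gauge-invariant under arbitrary
  OSV sign flips — a tested invariant, not an assumption.
* **Pair screening** — a pair *ij* is kept iff the largest singular value of
  the OSV cross-overlap block `q_iᵀ q_j` reaches the cutoff (default
  3.2e−5); the Frobenius norm is available as an alternative statistic.
  Diagonal pairs are always kept. Kept-pair sets are monotone in the cutoff.
* **Channels** — the four exchange-integral blocks
  (i μ̄_i | j ν̄_j), (i μ̄_j | j ν̄_i), (i μ̄_i | j ν̄_i), (i μ̄_j | j ν̄_j)
  are two-sided rotations of the canonical-virtual block (ia|jb). The
  pseudo-amplitudes divide each block by
  `−(f_μ̄μ̄ + f_ν̄ν̄ − f_ii − f_jj)`, written virtual-minus-occupied exactly
  parallel to the diagonal amplitudes so that the element-wise products
  `K̃ ∘ (2T̃ − T̃ᵀ)` sum to a (negative) crude pair-energy estimate; for
  diagonal pairs this estimate rank-correlates with the exact pair energies
  at Spearman ≥ 0.8 across conformer ensembles.
* **Transpose convention** — swapping the OSV indices of the vertical
  channel lands in the exchange channel's index set, so those two channels
  are each other's transpose partners in the contravariant combination; the
  charge-transfer channels transpose within their own square blocks. This is
  the unique assignment consistent with gauge invariance and with the
  diagonal-pair limit where all four channels coincide.
* Denominators below 1e−10 raise a near-degeneracy error rather than
  producing silent outliers.

## Exact pair-energy labels

Canonical MP2 amplitudes and integrals are rotated into the LMO occupied
basis; pair contributions are accumulated per unordered pair i ≤ j with the
full ij + ji weight, so the table's plain sum equals `E_c`. The
noncanonical iterative local-MP2 route would give identical pair energies at
convergence and is deliberately not implemented — the canonical-rotation
route is exact and far simpler. Label tables round-trip through TSV
(`i`, `j`, `e_ij_hartree`, `E_corr` footer) and the HDF5 container;
externally computed higher-level pair energies can be loaded from the same
schema but are never computed here.

## Network functional

Per pair population (diagonal / off-diagonal), a feed-forward MLP maps the
flattened descriptor (channel-major, then row-major) to the pair energy:

* 10 hidden layers × 50 ReLU units; He-uniform weight init, zero biases.
* Per-element feature standardization and scalar label standardization,
  fitted on the training split only (zero-variance elements clamp to scale 1
  with a warning). Granularity is a declared choice.
* Adam, batch 64, per-pair MAE loss; default schedule 1000 epochs split over
  learning rates 1e−3 and 1e−4. Training is bitwise deterministic per seed.
* Validation split 10 % (declared; used only for model selection), and
  `train_base` keeps the best of R seeded repetitions (default 3) by
  validation MAE.
* The total energy never enters the loss; `E_c` is the sum of pair
  predictions and screened-out pairs contribute exactly zero.

A practical note on accuracy floors: a piecewise-linear ReLU network fitted
with the sign-gradient MAE loss plateaus at a few-percent standardized
validation MAE even on exactly linear synthetic mappings; tests and
experiment thresholds account for this model-class floor.

## Fine-tuning family

All methods minimize the same per-pair MAE against exact labels of the new
regime; the base standardizer is reused, never refitted. At initialization
every tuned model reproduces the base bitwise (zero-initialized adapters),
and parameters outside a method's trainable set are bitwise frozen — both
are hard regression tests.

* **Residual head** — a linear map from the last hidden activation added to
  the output, `W^R`/`b^R` zero-initialized.
* **LoRA-R** — per-layer `ΔW = B·A`, `A` zero-init, `B` He-uniform, applied
  to every weight matrix including the output layer (whose rank caps at 1);
  trained together with the head. Default rank 1, which gives 1308 trainable
  parameters (3.6 %) on the reference 256-input architecture — inside the
  intended few-percent budget window.
* **ResLoRA-R** — additionally feeds the LoRA branch of each
  dimension-matched layer the sum of the previous and current layer inputs
  (`x^{n−1} + x^n`); the frozen `W0` path still sees `x^n`, which is the
  only reading compatible with the exact step-0 identity. The first hidden
  layer (dimension mismatch) is excluded; the output layer is included.
* **BitFit / BitFit-R** — additive offsets on every bias (501 parameters on
  the reference net), optionally with the head; implemented as offsets so
  `b0` itself is never mutated.
* **Δ-ML** — a fresh network trained on residuals `e_exact − e^P`;
  prediction adds the base back, so combined = base + Δ by construction.
* Default fine-tuning schedule 200 epochs at 1e−5 then 800 at 1e−6;
  diagonal and off-diagonal models are tuned separately with shared
  hyperparameters.

## Synthetic fixtures and the transfer experiment

The generator produces two kinds of fixtures, both bitwise reproducible from
(seed, parameters):

* **Perturbed conformers** — iid Gaussian Cartesian displacements of a
  reference geometry (default σ = 0.02 Å, a realistic thermal spread for
  O–H bonds), minimum interatomic distance 0.7 Å enforced by resampling.
  They emulate thermal ensembles; they do not emulate reaction events or
  conformational transitions.
* **Synthetic pair regimes** — (4, n, n) tensors with iid channel entries
  from a bulk + long-range-tail Gaussian mixture, and labels from a fixed,
  versioned saturating map `e = −depth·(1 + erf(gain·(Σ_c w_c s_c −
  pivot)))/2` (+ noise σ = 1e−5), whose Gaussian expectation is available in
  closed form for moment tests. Diagonal pairs carry 2× channel means.
  The default *shift* standing in for small→large transfer compresses the
  bulk channel means/spreads to 0.3× and adds a 50 % tail component at 5×
  spread with shifted means: in large systems the bulk of pairs is weak and
  remote, while a population of strongly interacting long-range
  configurations appears that small-molecule training never sampled. The
  label map itself is unchanged — transfer is a pure covariate-shift
  problem, mirroring the premise that the pairwise mapping barely changes
  with system size.

The transfer experiment (frozen conditions in
`osvnet.experiments.TransferConditions`): per seed, a 10×50 base model is
trained on 2000 bulk-regime pairs (200 epochs at 1e−3 + 80 at 1e−4),
evaluated on 1000 shifted-regime pairs, and fine-tuned with LoRA-R rank 1 on
1/10/20 shifted "molecules" of 150 pairs each (150 epochs at 1e−3 + 150 at
1e−4). These sizes and the faster-learning schedule are the experiment's
declared desk-scale conditions — the synthetic labels are standardized and
noiseless compared with quantum data, so the conservative default rates
would merely slow the same convergence. Under these conditions the shift
degrades the base model ~3.5× relative to its in-domain error, one molecule
of fine-tuning at least halves the out-of-domain median MAE over five seeds,
and the median improves monotonically with 1 → 10 → 20 molecules.

What passing these tests shows — and what it does not: the synthetic regime
exercises covariate shift with a fixed pair-energy mapping, which is the
mechanism the fine-tuning methods target; it does not emulate basis-set or
theory-level changes of the label map, periodic boundary conditions, or the
correlated (non-iid) feature structure of real orbital pairs. The quantum
smoke test (30 perturbed water monomers, minimal basis, held-out `E_c`
prediction beating the ensemble-mean baseline) covers the real-data path end
to end at small scale.

## Diagnostics

* Per-layer Frobenius ratios `‖ΔW‖_F/‖W0‖_F` (LoRA: `‖B·A‖`; full: tuned −
  base; bias methods: zero), with the residual head reported as
  `‖W^R‖/‖W_out0‖` in a final slot. Invariant under joint sign flips of
  (A, B).
* Pair-error kernel densities with Scott's-rule bandwidth (recorded in the
  output); mean/median/skew summaries are exact.
* MAE reports convert at 627.509474 kcal/mol per Hartree; per-system only
  (no per-unit-cell normalization).

## Known limitations

* s/p basis functions only (no d shells ⇒ no polarization bases); minimal
  and small double-zeta chemistry, closed-shell singlets, ≤ ~30 atoms.
* MP2 labels only are computed internally; coupled-cluster-quality labels
  must be supplied externally.
* No periodic boundary conditions, gradients/forces, or OSV amplitude
  optimization (the OSVs are descriptors, not a converged local-MP2 ansatz).
* CPU-only training sized for 10²–10⁴ pairs; no hyperparameter search
  beyond the stated grids and seeded repetitions.
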