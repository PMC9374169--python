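# Methods

## Model and loss

The package factorizes each view (modality × subject × optional condition)
of a multichannel time series as `X ≈ X̃_f C S`, with a column-stochastic
generator `C` shared across views and a column-stochastic mixing matrix `S`
per view. The loss for one view is

    L_W = − Σ_n ( x_nᵀ x̂_n / ‖x̂_n‖₂ )²,    x̂_n = X̃_f C s_n,

and the multiview loss is the plain sum over views. Because only the
squared cosine between sample and reconstruction enters, the loss is
invariant to the polarity of both, matching the axial symmetry of the
Watson distribution on the projective hypersphere; the density's
normalization constant plays no role and is not computed. Raw samples keep
their norms in the loss, so each contributes with weight `κ_n = ‖x_n‖²`
(high-amplitude, high-SNR time points dominate) while the archetype
dictionary `X̃_f` itself is scale-free.

**Assumptions.** (i) Topographic patterns are meaningful up to scale and
sign; (ii) views of one dataset share the *timing* of archetype generation
(one `C`), while topographies and mixing may differ per view; (iii) the
data's convex hull is not degenerate on the sphere — an archetype at the
origin makes the sphere projection meaningless, a failure mode the
`with_origin` generator exhibits on purpose.

## Preprocessing

Per view, in this order:

1. **Frobenius scaling** `X ← X/‖X‖_F` equalizes each view's total squared
   norm (hence its weight in the multiview loss) at 1.
2. **Sphere normalization** of the *scaled* matrix gives `X̃` and
   `κ_n = ‖x_n‖²`; computing κ after scaling makes precisions comparable
   across views (per-view κ sums to 1). Zero-norm samples are a hard
   error, never clamped: an ε-norm sample would receive an arbitrary
   direction with nonzero weight.
3. **Hemisphere flipping**: the dominant direction `u` is the top
   eigenvector of `X̃X̃ᵀ`, its sign fixed so its largest-magnitude entry is
   positive (making the transform deterministic); columns with `uᵀx̃ < 0`
   are negated, exact zeros are left alone. Flipping is idempotent and
   invariant to sign flips of the input columns.

## Optimization

Both `C` and each `S` column live on the probability simplex. Gradients of
the minimized loss are, with `z_n = x_nᵀx̂_n`, `q_n = x̂_nᵀx̂_n`,
`V = D_z D_q^{−1/2}` and `T = X D_q^{−1/2} − X̂ D_q^{−3/2} D_z`:

    ∇_C = −2 X̃_fᵀ T V Sᵀ (summed over views),   ∇_S = −2 Cᵀ X̃_fᵀ T V.

The signs follow from differentiating `−Σ z²/q` and are pinned by a
central-finite-difference oracle in the test suite rather than trusted on
paper. Updates run in l1-normalization-invariant variables: for a simplex
column `w`, the recast gradient is `g − (wᵀg)·1` (quotient rule at
`Σw = 1`); the projected step is `w ← normalize(max(w − μ g, 0))`, with a
column that collapses to all zeros falling back to its previous value.

- **C update:** one shared step size `μ_C`. A candidate is accepted only if
  the *total* loss strictly decreases (then `μ_C ← 1.1 μ_C`); otherwise the
  step is halved and retried, up to 20 times, after which the old `C` is
  kept for that iteration. An exactly unchanged loss counts as "not lower"
  (rejected) — ties never move the iterate.
- **S update:** per view and per sample; each column is accepted only if
  its own loss term strictly decreases, with per-sample step sizes grown
  (×1.1) or shrunk (×½) independently. Step sizes are shared across the K
  entries of a column.
- **Order:** after initialization one S sweep runs first, then each
  iteration updates C, then S.
- **Per-iteration caches:** each C update recomputes `A = X̃_f C`, `AᵀA`
  and `XᵀA` per view; loss terms and S gradients then cost O(NK²) per view
  without touching the channel dimension.

Initialization draws `C` and one `S` (copied to every view) i.i.d. from a
rate-1 exponential distribution and normalizes columns to the simplex; a
shared S draw means identical views follow identical update paths. Initial
step sizes are 1. Reconstruction norms are guarded by `ε_q = 1e−12` added
to `q_n`, so degenerate generators yield finite losses instead of NaN.

Convergence: the fit stops when the relative loss change stays below
`rel_tol` for 3 consecutive iterations (a single zero-change iteration can
just mean every candidate step was rejected while step sizes adapt), or at
`max_iter`. Defaults are `rel_tol = 1e−8`, `max_iter = 10000`; the
experiment protocols in `daa.experiments` use `1e−7` and 500, which these
three-dimensional problems reach well before the cap.

**Restart protocol.** A fit is the best of `n_restarts` random
initializations (default 100); `n_outer` such best-of fits (default 5)
feed the consistency analysis. Seeds are spawned hierarchically
(`SeedSequence → outer → restart`), so raising `n_restarts` extends the
stream without perturbing earlier draws.

**Sharing modes.** `per_condition_S` ties all views (including conditions)
to one `C`; `concat_conditions` concatenates conditions in time per
(modality, subject), giving a `(ΣN_c)×K` generator and recording the
per-condition sample slices; `no_correspondence` fits every view
independently (per-view `C`).

## Baselines

**Directional clustering** replaces the l1 constraint on `S` with an l0
one: each sample is assigned to the centroid `X̃_f c_k` maximizing the
squared normalized inner product — the polarity-invariant k-means rule —
and the C update runs unchanged with the one-hot `S`. The assignment is the
exact per-sample optimum given `C`, so the loss trace stays non-increasing.
An archetype with zero occupation has its generator column redrawn from the
exponential initializer; the redraw is kept only if the reassigned loss
improves, otherwise reverted, preserving monotonicity at the cost of
possibly leaving a cluster empty.

**Euclidean AA** minimizes `Σ_views ‖X − X C S‖_F²` with the raw
(Frobenius-scaled) `X` as its own archetype dictionary — no sphere
projection or flipping, so the model sees and reproduces scale. It reuses
the identical recast/projected-gradient/step-adaptation machinery rather
than an active-set solver: one optimizer codebase, loss-comparable outputs.

## Evaluation

**Soft NMI.** With `p(k,k′) = (1/N) Σ_n s^r_{kn} s^{r′}_{k′n}`,
`NMI = 2·MI(S_r,S_{r′}) / (MI(S_r,S_r) + MI(S_{r′},S_{r′}))`. The inner
sum runs over samples — the only dimensionally consistent reading — and MI
uses natural logarithms (the normalization cancels the base). `0·log 0`
is 0; if both self-MI terms vanish (e.g. K = 1) the inputs are identical
degenerate assignments and the value is defined as 1. Consistency across
`R` outer runs is measured on the cyclic adjacent pairs 1–2, 2–3, …, R–1
only, averaged over views, avoiding dependent all-pairs comparisons.

**Archetype recovery** is the mean |cosine| under the optimal one-to-one
matching (Hungarian assignment on the |cosine| matrix); the absolute value
makes it polarity-invariant.

**Knee criterion.** Loss curves in these experiments bend rather than
minimize, so model order is read from the drop ratio
`(L(K−1) − L(K)) / (L(K) − L(K+1) + ε)` with `ε = 1e−12·|L(K_min)|`,
maximized over interior K, ties to the smallest K. The rule is this
package's own deterministic operationalization of "the corner of the loss
curve"; it is invariant to positive affine transforms of the loss (up to
the negligible ε) and is deliberately simple — a near-flat tail with
restart noise can defeat it, which is why the experiment protocols vote
over replicate datasets.

**Trajectories.** Archetypes are anchored at equal angles on the unit
circle and each mixing column maps to the convex combination of anchors.
Optional rectangular smoothing averages each row over a centered window,
truncated at the edges; since every row is averaged over the same
positions, column sums (and hence the simplex) are preserved.

## Synthetic generators

All families draw convex weights `w ~ Dirichlet(α·1)` over the true
archetypes, add isotropic Gaussian noise of standard deviation `noise_sd`,
and (for the spherical families) project back to the sphere. The sampling
law of the original three-dimensional illustrations is not prescribed
anywhere; Dirichlet weights with α = 1 (uniform on the simplex) plus a
small perturbation are the simplest law producing full corner occupancy.
Defaults are n = 1000 and noise_sd = 0.05. The antipodal family multiplies
each sample by an independent Rademacher sign drawn from a separate
substream, so stripping the stored signs reproduces the octant draw
exactly.

The `multiview_erp` family emulates the *structure* of event-related
multimodal recordings: a shared sparse generator (each archetype built from
one contiguous post-stimulus window), a shared smooth simplex trajectory
with Gaussian activation bumps, per-modality random unit-norm topographic
maps with per-subject perturbations (σ = 0.1), a low-amplitude
pre-stimulus segment (20 % of samples at amplitude 0.15), white sensor
noise, and per-sample polarity flips. Default sizes (8–12 channels,
200 samples, 2 modalities × 3 subjects) are desk-scale. It does **not**
emulate volume conduction or leadfield physics, spatially correlated
sensor noise, latency jitter across subjects, or 1/f background activity —
so passing recovery tests demonstrate correctness of the factorization
machinery under the stated generative law, not performance on real
recordings.

## Numerical choices and edge cases

- Simplex feasibility asserted at 1e−8; NMI inputs validated at 1e−6.
- Zero data columns, all-zero views, mismatched sample counts, K > N, and
  non-finite losses are hard errors with the offending view/sample named.
- Hemisphere-flip ties (`uᵀx̃ = 0`) are not flipped; eigenvector sign fixed
  by the largest-magnitude-entry convention.
- Hard-assignment ties resolve to the smallest archetype index.
- Knee ties resolve to the smallest K; occupation-ordering ties keep the
  original archetype order (stable sort).

## Experiment problem sizes

The packaged protocols (`daa.experiments`, `scripts/acceptance.py`) use
n = 1000 samples, 20 restarts per K, 5 replicate datasets, optimizer caps
max_iter = 500 / rel_tol = 1e−7, and majority votes over replicates. These
sizes give unanimous knee votes across the master seeds we ran while
keeping a full sweep within minutes on one CPU.

## Known limitations

- The Watson-loss objective is non-convex in each block (the sphere
  normalization breaks the per-block convexity least-squares AA enjoys);
  restarts are essential, and consistency (NMI) should be checked rather
  than assumed.
- Shared-generator modeling assumes zero latency shift across views; no
  shift-invariant extension is provided.
- The knee criterion is undefined off consecutive-K grids and can be
  misled by non-monotone tails at small restart counts.
- No estimation of the Watson concentration parameter; κ enters only as a
  fixed per-sample weight.
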