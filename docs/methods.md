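# Methods

## The prediction problem

A drug–target interaction experiment produces a matrix `Y` whose entry
`Y[d, t]` quantifies how strongly compound `d` binds protein `t` — a
dissociation or inhibition constant (Kd/Ki, in nM, smaller = tighter), a
transformed affinity, or a binary interaction call.  Side information comes
as two square similarity matrices: drug–drug chemical similarity (2D/3D or
ECFP4 Tanimoto coefficients) and target–target sequence similarity
(Smith–Waterman alignment scores, usually normalized to a unit diagonal).
`kronpair` treats these similarity matrices directly as kernel Gram
matrices and learns a function over drug–target *pairs*.

## The model: Kronecker kernel ridge regression

KronRLS minimizes

    J(f) = Σ_i (y_i − f(x_i))² + λ ‖f‖²_k ,

where the pair kernel is the product of the drug and target kernels,
`k((d,t),(d′,t′)) = Kd(d,d′) · Kt(t,t′)` — the Kronecker product at the
Gram-matrix level.  For a complete label matrix the dual coefficients
solve `(Kt ⊗ Kd + λI) vec(A) = vec(Y)` (column-major vec, so
`vec(Kd·A·Ktᵀ) = (Kt ⊗ Kd)·vec(A)`); with eigendecompositions
`Kd = Vd diag(s_d) Vdᵀ` and `Kt = Vt diag(s_t) Vtᵀ`,

    A = Vd [ (Vdᵀ Y Vt) ⊘ (s_d s_tᵀ + λ) ] Vtᵀ ,

computed in `O(n_d³ + n_t³ + n_d n_t (n_d + n_t))` instead of
`O((n_d n_t)³)`.  Predictions for arbitrary (possibly unseen) drugs and
targets are `Kd_cross · A · Kt_crossᵀ`, with cross blocks holding
test-versus-training kernel values.  Correctness of the factorized solve is
pinned in the test suite against an explicit Kronecker-system solve on
small instances.

Parameters that matter:

* `lambda_reg` (λ, unitless, default 1.0) — ridge weight.  The default is
  the customary choice in pairwise RLS studies; on quantitative affinity
  data much larger values (2²⁵–2³⁰) can be optimal, which is why the
  default selection grid spans 2⁻¹⁵…2³⁰ in powers of two.
* `psd_policy` (`keep`/`clip`, default `keep`) — similarity matrices are
  used as kernels without a PSD guarantee.  `keep` retains negative
  eigenvalues and guards every solver denominator `s_d·s_t + λ` against
  magnitudes below 1e-12 (a `ConditioningError`, never a silent
  pseudo-inverse); `clip` projects onto the PSD cone first.
* Asymmetric inputs (raw Smith–Waterman scores) are never silently fixed:
  loading flags asymmetry with a warning, `symmetrize()` averages with the
  transpose, and `decompose()` refuses matrices asymmetric beyond 1e-8.

### Incomplete labels

Unmeasured entries are mean-imputed from the measured *training* entries
before the complete-matrix solve; the pre-imputation mask is kept so that
evaluation only ever scores genuinely measured pairs.  Inside
cross-validation the imputation mean is computed from the training pairs of
the current split only — never from test or discarded entries, which would
leak.  A consequence worth knowing: in setting S1 the held-out cells of the
training matrix are themselves imputed, which slightly biases the fit even
at zero label noise (the noiseless-recovery property test documents the
measured effect, CI ≈ 0.98 rather than 1.0).  An exact incomplete-label
solver (Kronecker conjugate gradients) is deliberately out of scope; mean
imputation is the protocol this framework evaluates.

## Experimental settings S1–S4

Pairwise inputs make "held-out data" ambiguous, and the ambiguity is the
whole story.  A test pair's drug and target may be

* S1 — both seen in training: random hold-out of matrix entries
  (k-fold over pairs; minimal variant LOO);
* S2 — drug unseen: hold out whole rows (k-fold over drugs; LDO);
* S3 — target unseen: hold out whole columns (k-fold over targets; LTO);
* S4 — both unseen: partition drugs into `kd` and targets into `kt` groups;
  split (i, j) tests the block (i, j), trains on pairs outside both groups,
  and *discards* pairs sharing exactly one of the two groups — those can
  serve neither role without breaking the setting.

Fold construction is driven by one integer seed through
`numpy.random.default_rng`; fold sizes differ by at most one; there is no
stratification.  Every measured pair is tested exactly once per plan, and
an independent checker in the tests re-derives the constraints from the raw
index sets.

## Evaluation metrics

The concordance index (CI) is the probability that two randomly drawn
pairs with different labels are ranked correctly:
`CI = (1/Z) Σ_{y_i>y_j} h(f_i − f_j)` with `h = 1, ½, 0` for positive,
zero, negative argument and `Z` the number of label-discordant pairs;
0.5 is chance, 1.0 perfect.  On binary labels CI equals ROC AUC; `auc()`
computes the Mann–Whitney rank-sum route independently so the identity is a
cross-check, not an alias.  AUC-PR uses the average-precision convention:
thresholds sweep distinct prediction values descending, ties grouped, area
`Σ (R_k − R_{k−1}) P_k`.  A permutation test (predictions permuted against
fixed labels, one-sided, add-one correction) supplies significance.

Metrics undefined on a fold (all labels equal, single class, no positives)
return a typed `UNDEFINED` marker.  The averaging CV strategy skips such
folds and counts them; the pooling strategy concatenates all test
predictions and scores once — the fallback required by the minimal-fold
variants (LDO/LTO), whose per-drug or per-target folds often have constant
labels.

## Nested cross-validation and selection bias

If the same cross-validation estimate both selects a hyperparameter (or a
feature subset) and reports performance, the report is optimistic.  Nested
CV separates the roles: outer folds estimate, and within each outer
training set an inner fold plan — built under the same setting's
constraints — selects λ (grid search, ties toward the smaller value) or the
number of greedily added tensor-product features.  Inner fold counts
default to the outer counts.  The selection-bias experiment in the
acceptance tests makes the phenomenon concrete: on pure-noise features and
labels (true CI exactly 0.5), the simple-CV curve maximum of greedy forward
selection is systematically above independent-test CI, while the nested
estimate is statistically indistinguishable from it.

## The synthetic generator

`generate(SyntheticSpec(...))` draws latent vectors `u_d, v_t` of rank `r`,
sets `truth = U Σ Vᵀ` for a fixed positive diagonal Σ (descending weights
1.5…0.5), adds Gaussian label noise, masks a uniform fraction of entries,
and optionally binarizes.  Kernels are the Gram matrices of the latent
vectors, so they are symmetric PSD by construction and the bilinear truth
is exactly representable by the pair-kernel model — enabling sharp recovery
tests.

`kernel_noise_sd` (default 0) corrupts the latent vectors used for the
*kernels* only.  This matters: with exact Gram kernels every setting S1–S4
is equally easy, because the kernel hands the model each entity's true
latent coordinates — the setting-difficulty ordering cannot exist in that
world.  Real chemical and sequence similarities capture binding-relevant
structure only partially; `kernel_noise_sd = 0.5` (noise comparable to the
unit latent scale) is the condition under which the ordering experiments
run, and it reproduces the qualitative phenomena: S1 easiest, S4 hardest,
and S2/S4 collapsing to chance when the drug kernel is replaced by the
identity (δ) kernel.

What the generator does *not* emulate: non-uniform missingness (real panels
miss entries systematically), heavy-tailed affinity distributions, kernel
indefiniteness, and drug/target family structure.  Passing tests therefore
validate the machinery and its qualitative behavior, not quantitative
performance on real kinase data.

Fixture shapes (`make_fixture_like`): a 20×60 complete quantitative panel,
a 40×12 panel with 30 % missing entries, and a 12×6 binary set — echoing,
at reduced scale, the shape regimes of the public benchmark matrices
(drug:target ratios from ≈0.15 to ≈9, complete vs partially measured,
quantitative vs binary).

## Numerical and design choices

* Binarization is strict `<` (affinity below cutoff = interaction); the
  boundary value maps to non-interaction.  Cutoffs like Kd < 30.00 nM /
  Ki < 28.18 nM are the user's to supply.
* Imputation uses the global training mean (not per-row/column): the
  simplest defensible reading, and the one the leak-avoidance rules make
  unambiguous inside CV.
* The model regresses labels as supplied.  Loaders carry a
  `larger_is_stronger` orientation flag; `negate`/`neglog10` transforms
  flip it.  CI is invariant to monotone label transforms, but the fitted
  regression is not, so the choice of transform is explicit and recorded.
* Eigendecomposition orders eigenvalues descending with stable tie order;
  reconstruction is tested to 1e-8 relative.
* All tie-breaks in selection (λ, features) are deterministic: smaller λ,
  lower feature index.
* Serialization is plain text throughout (TSV grids, `%.17g` floats for
  exact double round-trips, YAML manifests); two runs with the same config
  and seed produce byte-identical outputs.

## Problem sizes

The test and acceptance experiments run at desk scale, chosen so the full
suite completes in well under a minute of compute per experiment: solver
oracles at ≤ 8×8, splitter checks at ≤ 12×10, setting-ordering at 24×18
over 20 seeds, selection bias at 500 training pairs × 30 features over 20
seeds, CI chance-level estimation over 10,000 replicates of 50 labels.  The
implementation itself comfortably handles a few thousand drugs × targets
(the eigentrick keeps the solve cubic in each dimension separately).

## Known limitations

* No exact solver for incomplete labels (mean imputation is the protocol).
* No multiple-kernel learning; one drug kernel, one target kernel.
* No extrapolation across drug or target families; all evaluation is
  within the supplied matrix.
* The permutation test pools scores as given; within-fold permutation
  schemes are not provided.
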