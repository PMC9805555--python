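# Methods

## Model

A group of `N` samples over `S` chromatin states on `G` genomic bins is
summarized by an ensemble of `N` multinomial logistic regression
classifiers. Classifier `n` treats sample `n`'s per-bin state as the
response and the one-hot encoded states of the other `N−1` samples at the
same bin as predictors, plus a constant intercept — `(N−1)·S + 1` predictor
variables. Probabilities come from the softmax over per-state coefficient
vectors. Each classifier is trained on one shared random subset of bins and
predicts genome-wide; the `N` prediction matrices are averaged into the
`G × S` summary matrix `R` (rows sum to 1 by construction, since each
prediction matrix is row-stochastic). The representative state map is the
per-row argmax of `R`.

The modeling assumption doing the work: state assignments of biologically
similar samples co-occur in genome-wide patterns (sample A's enhancer state
tends to coincide with sample B's enhancer or flanking states), so a
regression on other samples' states can de-noise an individual sample better
than a per-bin majority. The counting baseline `base_count`
(`R[i, s] = #{n : C_{i,n} = s} / N`) ignores all cross-bin information and is
the natural control.

The differential matrix between two groups is `D12 = R1 − R2`, computed
only between summaries produced by the same method. Entries are bounded by
±1, the matrix is antisymmetric under group swap, and rows sum to ~0
(difference of two row-stochastic matrices).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `bin_size` | 200 bp | resolution of the binned state maps; matches common segmentation output |
| `fraction` | 0.1 | fraction of bins sampled (without replacement) for training; raising it adds runtime without materially improving accuracy |
| `l2_strength` | 1.0 | inverse-regularization strength `C`; penalty = `(1/(2C))·‖β‖²` on non-intercept coefficients |
| `seed` | — | controls the training-bin draw (and, in the generator, all sampling) |

## Numerical conventions

- **Softmax parameterization.** The symmetric form (one coefficient vector
  per state) as fit by scikit-learn's multinomial `LogisticRegression`
  (L-BFGS, tol 1e−6, max 1000 iterations, deterministic), recorded as
  `parameterization_tag="symmetric"`. A reference-class parameterization
  (state `S` as baseline) gives slightly different L2 fits; the prediction
  differences are below evaluation noise. For `S = 2` the fit reduces to
  standard binary logistic regression. The test-suite oracle — a full-batch
  gradient-descent optimizer of the identical penalized likelihood — pins
  this convention independently of the solver.
- **Intercept.** The feature matrix carries an explicit constant-1 column;
  the fit strips it and uses the solver's unpenalized intercept. The stored
  coefficient layout keeps the intercept as the last entry of each state's
  vector.
- **One shared training draw per group.** All `N` classifiers train on the
  same bin subset. This makes summaries exactly invariant (to solver
  tolerance) under permutation of member order and keeps one seed per group.
- **States absent from a training draw** receive probability exactly 0 from
  that classifier (no smoothing); a single-class training draw degenerates
  to a constant predictor with a warning. Both are edge cases at the default
  fraction on realistic inputs.
- **Argmax ties** break to the lowest state index.
- **Bin grid.** Coordinates are 0-based half-open; bin `i` covers
  `[i·bin_size, (i+1)·bin_size)`; trailing partial bins are kept. A
  segmentation record assigns a bin iff it covers the bin's start
  coordinate — deterministic for records not aligned to the grid. Uncovered
  bins are an error unless an explicit fill state is requested, so data gaps
  cannot pass silently.
- **bedGraph output** is written at 4 decimal places with equal-value runs
  merged; this is below the meaningful precision of the model.
- **AUROC** uses average ranks: tied positive/negative pairs contribute 0.5.
  Stated explicitly because counting-based tracks at small `N` take only
  `N+1` distinct values, so the tie convention visibly moves results.
  Leave-one-out (member, state) pairs whose held-out indicator is
  single-class are skipped and reported, never imputed as 0/1.
- **Per-position tests** operate on the binary "in state s" indicator per
  sample (a categorical label has no order for a rank test). Fisher's exact
  test is two-sided via hypergeometric enumeration of the 2×2 table; the
  Mann–Whitney U test uses the tie-corrected normal approximation with
  continuity correction, two-sided (exact enumeration is degenerate under
  the heavy ties of binary data); complete-tie bins get p = 1. p-values are
  used as rankers; a Benjamini–Hochberg utility exists but is off by
  default.

## Synthetic data generator

The generator emulates the structure the summarizer exploits: a hidden
segmental consensus (geometric segment lengths, mean 10 bins by default; a
segment's state is uniform over the states other than its predecessor),
per-sample bin-wise confusion noise (default: 88% diagonal, remainder spread
uniformly), optional sample-specific structured noise (default scenario: one
of three samples mis-reports state 1 as state 2 with probability 0.3), and
planted regions where group 2's consensus is rewritten to a different state.
Defaults are `S=5`, `G=2000`, `N=3` with all randomness derived from one
seed through spawned generators, so every artifact is reproducible
bit-for-bit.

What it deliberately does not emulate: autocorrelated (segmental) noise —
noise is independent across bins given the consensus, so all spatial
structure lives in the consensus itself; real state frequencies or
mark-signal tracks; inter-state similarity structure. Consequently, passing
tests show the machinery is correct and that the ensemble-vs-counting
contrast behaves as designed under confusion noise; they do not certify
effect sizes on real compendia, where noise is spatially structured and
state usage is far from uniform.

## Problem sizes

Unit and property tests run on genomes of 40–6,000 bins. The directional
benchmarks (leave-one-out comparison under structured noise, planted-region
recovery) use `G = 5,000`, `N = 3`, `S = 5` — small-N being the regime where
the ensemble's advantage is expected and observed. The acceptance script
reproduces its quantities at `G = 2,000`.

## Design choices

- The pipeline is a plain YAML config plus subcommand CLI rather than a
  workflow engine; a manifest (config hash, seed, version, per-file
  checksums) makes rerun identity checkable.
- `pybedtools` is not used; BED4/BED9/bedGraph are simple line formats and
  are read/written directly, which keeps the I/O dependency-free and easy to
  audit.
- Genome-wide prediction deduplicates feature rows: bins sharing the other
  samples' state combination share one softmax evaluation (at most
  `S^(N−1)` distinct rows), which makes prediction cost essentially
  independent of `G` for small `N`.

## Limitations

- Differential scores compare summaries; they carry no significance
  calibration themselves (the per-position tests exist for that, with the
  quantization caveats above).
- The ensemble needs `N ≥ 2` (leave-one-out evaluation of it, `N ≥ 3`);
  `base_count` works from `N = 1`.
- Groups must share the same state alphabet; no mapping between different
  state models is attempted.
- No use of upstream posterior probabilities or raw mark signals; the input
  is the hard state assignment only.
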