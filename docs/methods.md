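# Methods

This note documents the models and procedures implemented in `gbogwo`,
the parameter choices that matter, what the synthetic generators emulate,
and the numerical conventions adopted where the underlying method
descriptions are ambiguous.

## Optimizers

All three optimizers minimize a black-box objective over a box
`[lb, ub]^D` with a population of `N` agents for `MaxIt` iterations. One
`numpy` Generator seeded from `SearchSettings.seed` drives every draw; the
draw order within a member update is fixed and documented in
`optimizers.py`, so runs are bit-reproducible and the hybrid with `pr = 1`
coincides exactly with plain GBO.

**GBO.** Per member `i`, four distinct member indices `r1..r4` are drawn
and three candidates are built by the gradient search rule (GSR): a
Newton-like displacement `GSR = randn·ρ2·(2Δx·x_i)/(y_p − y_q + ε)` where
`Δx` scales with the spread `|mean(x_r1..r4) − x_i|` and the distance to
the best solution, and `ρ1, ρ2` are uniform on `[−α, α]` with
`α = |β sin(3π/2 + sin(3πβ/2))|` and the cubic schedule
`β(t) = β_min + (β_max − β_min)(1 − (t/T)³)²` (endpoints hit exactly:
`β(0) = β_max`, `β(T) = β_min`). The three candidates are combined with
fresh uniform weights, and the member is then perturbed by the local
escaping operator (LEO): `base + f1·W1 + f2·ρ1·W3 + u2·W2/2` with
`W1 = u1·x_b − u2·x_k`, `W2 = x_r1 − x_r2`, `W3 = u3·(x2 − x1)`;
`f1 ~ U(−1,1)`, `f2 ~ N(0,1)`, `L1, L2 ~ Bernoulli(0.5)` gate the `u`
coefficients and whether `x_k` is a population member or a fresh uniform
position. The branch base is the incumbent `x_i` when `u < pr` and the
best `x_b` otherwise. The published pseudocode for this family is loose on
two points and this package resolves them explicitly:

- the escape step is applied to every member each iteration, with the
  `u < pr` draw choosing the branch (rather than gating the operator);
- the combined candidate of the weighting step is constructed (and its
  draws consumed) but the accepted proposal is the escape output — the
  candidates enter the proposal through `W3`.

- the "random vector of dimension N" multiplying the GSR spread is read as
  a vector over the *problem* dimension `D` (it multiplies a length-`D`
  vector), and every occurrence of a bare "rand" consumes a fresh draw
  while named scalars (`ρ1`, `ρ2`, `δ`, the GSR) are drawn once per member
  update and reused.

**GWO.** Each member moves to the average of three leader-attraction
positions `X_k − B_k·|A_k·X_k − x_i|` over the current top-3 solutions,
with scalar coefficients `A = 2q2`, `B = 2b·q1 − b` drawn independently
per leader and `b = 2 − 2t/t_max` decaying linearly (so `b(0) = 2`,
`b(t_max) = 0` and late iterations exploit).

**Hybrid.** GBO's candidate construction runs unchanged; the escape step
is GBO's LEO with probability `pr` (default 0.75) and a GWO hunt
otherwise, per member per iteration. Leaders and best/worst are refreshed
after each full population sweep (order-independent and cheaper than
per-member refresh).

**Shared conventions.** Proposals are clipped to the box before
evaluation; replacement is greedy keep-better in *all* variants, which
makes the best-fitness trace non-increasing — a property the tests rely
on. A non-finite objective value aborts the run with the member and
iteration named. `ε` defaults to `1e−8` (the sources never set it); it
only guards denominators, and any small positive value behaves
identically at the scales involved.

## Wrapper fitness

A position binarizes by strict threshold (`bit = 1 iff x_j > thr`). With
the symmetric default box `[−10, 10]` the default threshold is 0, which
makes a bit a fair coin at initialization; the alternative convention
`thr = 0.5` (natural for a `[0, 1]` box) is a config field. All-zero
masks are repaired by switching on one uniformly chosen bit, since an
empty mask leaves nothing to train on.

Fitness is `λ(1 − PR) + (1 − λ)|mask|/D` with `λ = 0.99` by default. `PR`
is **macro-averaged precision** from an internal stratified evaluation —
3-fold CV by default — *not* from any final test split, to keep the
search honest about leakage; a `fixed_test` protocol exists for users who
deliberately want to score against a held-out table. Evaluations are
memoized by mask bit-string, so a mask revisited by the optimizer costs
nothing; classifier fits are seeded from the run seed. Note that the
reported per-run precision is therefore an internal cross-validation
estimate, slightly pessimistic relative to training-set protocols.

## Evaluation conventions

Confusion matrices are stored rows-predicted / columns-true, the layout
of the HAR reporting convention this package mirrors. In that layout the
convention's "precision" of a class is diagonal/column-sum and its
"sensitivity" is diagonal/row-sum — the transpose of textbook naming —
so `class_rates` exposes both namings (`*_paper` and `*_std`) and the
overall macro precision is the unweighted mean of the per-class
column-sum rates. Specificity uses `FP` = column off-diagonal and
`TN = total − rowsum − colsum + diag`. Per-class accuracy follows the
standard `(TP + TN)/total` (one published variant omits `TN` from the
numerator; that is treated as a typo). Zero rows or columns yield NaN
("undefined"), never 0, and are excluded from macro averages with a
warning.

The *t*-test filter scores each feature by its largest absolute
one-vs-rest Welch statistic across classes (the multiclass reduction is
unspecified in the sources; max-|t| is the conservative choice) and keeps
features whose best p-value clears a configurable cut-off. ReliefF is the
standard multiclass variant: min-max feature normalization, every
instance sampled, `k = 10` nearest hits and per-class misses by Manhattan
distance, miss contributions weighted by class priors; selection keeps
non-negative weights by default. Ties in neighbor distance break by
instance order, making the weights order-invariant.

Run-to-run comparison uses the Wilcoxon rank-sum z-test
(`scipy.stats.ranksums`, normal approximation) with `H = 1` iff
`p < 0.05`. At very small run counts (3 vs 3) the normal approximation is
anticonservative relative to exact enumeration; comparisons at ≥ 10 runs
per side are recommended.

## Signal features

Preprocessing: order-3 zero-phase Butterworth low-pass for denoising
(corner 20 Hz at the reference 50 Hz sampling rate; at a 20 Hz sampling
rate choose a corner below the 10 Hz Nyquist, e.g. 9 Hz, or skip),
gravity = order-3 zero-phase low-pass at 0.3 Hz with body = input −
gravity (exact additivity by construction), 128-sample windows with 50 %
overlap, window label by majority vote with first-seen tie-break.

Each source signal (body and gravity) yields 66 time-domain and 9
frequency-domain features — 150 columns total, in a stable documented
order. Definitional choices where names alone underdetermine the
quantity:

- AR(4) coefficients per axis and of the magnitude signal via the Burg
  method (constant axes return zeros with a warning);
- "acceleration" = mean Euclidean norm of the jerk vector
  (jerk = first difference × fs);
- "entropy of jerk" = Shannon entropy (nats) of the normalized one-sided
  power spectrum of the per-axis jerk; zero-power signals give 0;
- histogram = 5 equal-width bins over the axis's own range, counts
  normalized by window length (constant axes put all mass in the middle
  bin);
- mean absolute difference = mean |v − mean(v)|; "power" = mean squared
  value per axis; SMA = (Σ|x| + Σ|y| + Σ|z|)/L;
- tilt angle = angle (degrees) between the window's mean vector and the
  z axis, taken as vertical; zero mean vectors give 0;
- frequency features from the one-sided power spectrum (DC included):
  power-weighted mean frequency, argmax-bin frequency, and the bin where
  cumulative power crosses half; zero-power axes report 0 with a warning.

Degenerate inputs never produce NaN: kurtosis and skewness of constant
axes fall back to 0 by convention.

## Synthetic generators

`simulate_recording` concatenates per-class segments of a 9.8-unit
gravity vector rotated to a class-specific orientation, per-axis
sinusoids at a class fundamental frequency with `1/h`-weighted harmonics
and random phases, and white Gaussian noise. The three default classes
(walk 2 Hz, jog 2.8 Hz, sit ~static) differ in rhythm, intensity, and
orientation, so spectral, amplitude, and tilt features are all
class-informative by design. What it does *not* emulate: biomechanical
waveform shape, stride variability, subject heterogeneity, sensor drift
or gravity-axis wander within a class. Passing tests therefore show that
the pipeline recovers the kinds of structure it targets, not that any
particular accuracy transfers to real recordings.

`make_fs_problem` builds tabular problems: informative feature `j` shifts
the class mean by `effect_size` standard deviations across the class cut
`1 + (j mod (K−1))` — a thermometer code over the `K` ordered classes.
With `n_informative = K − 1` every informative feature is the *only* one
separating one adjacent class pair, so "recovering the informative set"
is well defined: dropping any informative feature must cost precision.
Redundant copies (same class-mean pattern repeated) would make recovery
an ill-posed target, which is why the cuts cycle rather than repeat. At
`effect_size = 0` the informative labels are exchangeable with noise
columns, giving an exact chance baseline for null calibration. Column
positions are shuffled so informativeness is not positional.

The two bundled confusion-count fixtures store raw counts only; every
rate in the reports is recomputed from them, never hard-coded. One
fixture's source table reports a grand total inconsistent with its own
column sums (2974 vs 2947); the counts, whose arithmetic is internally
consistent at 2947, are authoritative here.

## Experiment sizes

The behavioral test experiments use problem sizes chosen to exercise the
claims at meaningful statistical resolution while remaining desk-scale:
sphere-function contracts at `N = 30`, `MaxIt = 50` over 10 seeds;
recovery at 200 instances, 50 features, `N = 20`, `MaxIt = 30`, 10 seeds
with a 10-tree random-forest fitness; null calibration at 20 seeds with a
reduced search (`N = 10`, `MaxIt = 8`, holdout protocol), which suffices
because the null hypothesis concerns the selected mask's composition, not
search quality.

## Known limitations

- The optimizers treat the GWO coefficients as scalars per leader (as the
  update equations print them); some GWO implementations draw them
  per-dimension, which explores more aggressively.
- The wrapper's internal precision is an in-search estimate; model
  selection on it still overfits slightly, and an external held-out
  evaluation is the user's responsibility.
- ReliefF is O(n²·d) per call; it is intended for tables up to a few
  thousand instances.
- The feature pipeline assumes uniformly sampled input; irregular
  timestamps must be resampled upstream.
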