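# Methods notes

This note records the statistical model behind `wavefeat`, the defaults
and why they were chosen, what the synthetic cohort generator does and
does not emulate, and the numerical conventions that make results
deterministic.

## Data model and weighting

A dataset holds trials of a step-down-and-pivot style task: each
(participant, trial) carries all 16 biomechanical variables (8 joint
angles, degrees; 8 joint moments, %BW·HT = 100·M/(m·g·h), g = 9.81 m/s²)
on a common 101-sample axis of percent task time. Resampling onto that
axis is piecewise-linear on a uniform phase grid: monotone, overshoot-free
and exact at shared nodes, which matters because the curves are already
low-pass filtered and spline overshoot would manufacture structure.
Missing samples within a trial are not imputed; such trials are rejected.

Trials are pooled across groups with weights w = 1/(P·nᵢ) (P participants,
nᵢ trials for participant i), so each participant contributes total weight
1/P and prolific participants cannot dominate the pooled estimator. This
equal-participant regime is the simplest one consistent with weighting "by
the trial counts of each participant"; the weighting function is pluggable
(`equal_trial` and user callables are accepted) because other regimes are
defensible. For descriptive output, control participants' left- and
right-limb trials are averaged per participant; the selection stages
always consume unaveraged trials.

## Weighted-correlation PCA

Per variable, the trials × 101 matrix is standardized sample-wise with the
weighted mean μ(t) and the weights-sum-to-one (biased) weighted SD σ(t);
the biased estimator is used because any variance normalization constant
cancels in the correlation matrix. The PCs are unit eigenvectors of
R = Σⱼ wⱼ z_j z_jᵀ. Numerical conventions:

- Eigendecomposition via symmetric `eigh` on the explicitly symmetrized R;
  eigenvalues clipped at zero and sorted descending. The trace identity
  Σλ = 101 holds to 1e−6 and is tested.
- Sign convention: each coefficient vector is flipped so its
  largest-magnitude entry is positive, ties broken by earliest sample.
  Eigenvector sign is otherwise arbitrary and backend-dependent; this
  makes scores, quartile assignments and figures reproducible.
- A time sample with σ(t) = 0 aborts the fit (degenerate-variable error)
  rather than being dropped: sample indices are percent task time and
  silently renumbering them would corrupt every downstream window.
- Scores are stored as trial means of the per-sample products
  z_j(t)·c_k(t), i.e. the classical projection divided by 101. All
  downstream statistics use trial-mean scores, so this scale choice is
  harmless, but it is fixed and documented; reconstruction therefore reads
  z_j = 101·Σ_k s_jk c_k.
- The squared-correlation curve r²_k(t) — the fraction of pointwise
  variance a PC explains — equals λ_k c_k(t)² in closed form; the
  empirical weighted-Pearson version is provided separately and the
  identity is verified in tests to 1e−6.

## Feature selection

**Parallel analysis.** The null reference is the mean descending
eigenvalue spectrum of 100 weighted-correlation PCAs of standard-normal
matrices with the same trial count *and the same trial weights* as the
data, so the null matches the estimator actually used. PC k is kept iff
λ_k strictly exceeds the reference mean (Horn's original mean criterion;
no percentile variant). Because the reference depends only on the trial
count and weights, one reference spectrum is computed per dataset and
shared by all 16 variables; the standalone function accepts a per-call
seed when that sharing is not wanted. Retention is evaluated per
component, not truncated at the first failure.

**Screening.** Welch's t on trial-mean scores with the trial as the unit
of analysis, two-sided, kept at |t| ≥ 2.0 (≈ α = 0.05). A threshold
stated as t ≥ 2.0 only makes sense two-sided, since informative features
can separate groups in either direction. Zero-variance degeneracies give
|t| = ∞ and are retained with a logged warning.

**Sequential selection.** Each of 1000 iterations draws fresh stratified
10-fold assignments (folds stratified by group because of the ~2:1 class
imbalance; the fold unit is the trial, mirroring the pooled design — the
resulting within-participant pseudo-replication is a property of the
design being reproduced, not an oversight, and participant-level
inference is available, see below). Greedy forward selection adds the
candidate minimizing the pooled CV misclassification rate of a Gaussian
naive Bayes classifier (class-conditional means and ML variances plus
class priors from the training fold; training-fold class variances of
zero are floored at 1e−9 × the pooled training variance). "Did not
improve" is read as *strictly decrease*: plateaus stop selection, so the
empty set survives when no feature beats the majority-class rule. The
final set of each iteration increments its features' counters; the main
features are the ≤ 10 highest-count features, ties broken by larger
screening |t| then lexicographic (variable, PC). Candidate order inside
the greedy step follows the same rule, which fixes argmin tie-breaks.
The implementation exploits the additivity of naive Bayes log-likelihoods
across features: per-feature per-fold log densities are computed once per
iteration and greedy steps evaluate all candidates with one broadcast,
which is what keeps 1000 iterations at a few seconds.

## Inference and associated features

Main-feature inference uses Welch's t (Welch–Satterthwaite df, two-sided
p, CI = diff ± t₀.₉₇₅(df)·SE) at α = 0.001 and Hedges g with
J = 1 − 3/(4N − 9). The default unit of analysis is the trial (mean
difference = symptomatic − control over 193/107-style pooled trials);
participant-level aggregation (`inference_unit="participant"`) is provided
because trial pooling pseudo-replicates within participants and CIs built
from trial-level SEs can be optimistic. Neither unit is asserted as
uniquely correct; the default mirrors the pooled design.

Associated features: for each main feature, Pearson ρ against every other
post-parallel feature across pooled trials; bands are moderate
(0.5 ≤ |ρ| < 0.7) and strong (|ρ| ≥ 0.7, boundary inclusive to strong);
correlation significance via the t transform of r with n − 2 df at
α = 0.05; flagged "significant associated" when the associated feature's
own group |t| ≥ 2.0.

The pointwise waveform comparison averages trials per participant first
(controls: both limbs together), then runs an equal-variance two-sample t
per time sample at Bonferroni α = 0.05/16 = 0.003125. It is deliberately
labelled a *pointwise surrogate*: it fills the descriptive role of
one-dimensional SPM but performs no random-field or cluster-level
inference, so its significance masks are anti-conservative on smooth
curves and are used for description only.

The permutation calibration permutes trial group labels, keeps the
main-feature set fixed, and re-tests: it checks the calibration of the
final inference stage (no feature should reach α = 0.001 under the null)
and of screening (≈ 5% retention). It deliberately does not re-run
selection inside each permutation — that would test a different (and far
more expensive) null.

## Interpretation

Quartile waveforms default to `representative_trial` — the observed trial
whose score is nearest the 75th/25th percentile of pooled trial-mean
scores (earliest trial on ties) — because showing real trials is the more
conservative reading; `reconstruction` (μ + 101·q·σ·c_k) is provided as
the idealized alternative, and the two agree up to trial noise. Group
quartile assignment uses *weighted* group mean scores, whose signs are
necessarily opposite because the weighted pooled mean is zero.

Influence windows are maximal runs where both |c_k(t)| and r²_k(t) are at
least a fraction (default 0.5) of their maxima; the fraction is a
reporting threshold with no inferential content. The mode-of-variation
fit — grid search over integer shifts C with least-squares A, B inside
the window, dominant mode from the largest of |A−1|, |B|/range,
|C|/length, "mixed" when the top two are within 20% — is a quantitative
operationalization of an otherwise qualitative visual reading and is
flagged as such in outputs. Identical upper/lower curves make all three
deviations zero and are labelled "mixed" (maximally ambiguous). Small
|C| is preferred on residual ties so the identity map never reports a
spurious shift. On noise-free curves the fit recovers planted (A, B, C)
exactly (A, B to 1e−8, C on the integer grid), which is tested.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:

- 36 symptomatic participants contributing one limb and 11 controls
  contributing both limbs, 3–7 trials per limb (uniform), matching a
  ~190/110 pooled trial split;
- smooth per-variable template curves (fixed, documented truncated
  Fourier series, three harmonics) qualitatively shaped like task curves
  (hip flexion high at step-down and descending through the pivot, knee
  flexion deepest mid-task, plantarflexor moment peaking in the pivot);
  exact shapes are free choices — only the covariance structure matters
  downstream;
- participant-level constant offsets (normal, SD 3.0° for angles,
  0.75 %BW·HT for moments) and trial-level stationary smooth noise (white
  noise convolved with a Gaussian kernel, correlation length 8 samples,
  marginal SD 1.5° / 0.4 %BW·HT, exactly calibrated) standing in for
  10 Hz-filtered measurement and execution variability;
- group effects injected as y = A·f(t−C) + B inside cosine-tapered
  windows (taper 15% of window length, ≥ 2 samples), so injected
  differences are as smooth as the filtered signals they imitate.

The default planted scenario is one effect per elementary mode:
translation B = 4.5° on hip flexion angle in samples [15, 45] (3× the
trial noise SD), scaling A = 1.15 on ankle dorsiflexion moment in
[35, 65], temporal shift C = 3 samples on knee extension angle in
[55, 90]; every magnitude is ≥ 1.5× the affected variable's trial noise
SD. The offset and effect scales were set once so that standardized group
effects land in the small-effect, heavily overlapping regime typical of
symptomatic-vs-control movement data (trial-level |g| roughly 0.25–2):
strong enough that every planted effect is recovered across seeds, weak
enough that classification stays imperfect and repeated selection
exercises genuine instability — with implausibly strong effects the
classifier converges on the same few features every iteration and the
frequency ranking degenerates. Phase boundaries default to samples 33
and 66 (step-down | pivot | step-forward); events PFS1/NFS2/PFO3 are
planted at those boundaries.

What the generator does **not** emulate: biomechanical consistency (no
dynamics, no ground-reaction coupling between angles and moments),
inter-variable correlation beyond what shared participants induce,
heteroscedastic or phase-dependent noise, missing or mislabelled trials,
and sex or age structure. Passing tests therefore demonstrate that the
statistical machinery recovers planted structure under the assumed noise
model — not that the pipeline is robust to the full messiness of
laboratory data.

## Determinism and problem sizes

A single top-level seed drives every stochastic stage through spawned
`SeedSequence` children (parallel-analysis replicates, all fold draws
across iterations, permutations, cohort synthesis); two runs from one
seed produce byte-identical results JSON, and `report` re-renders from
that JSON without recomputing. Default problem sizes — 47 participants,
~290 trials, 100 parallel-analysis replicates, 1000 selection iterations,
200 calibration permutations — run the full pipeline in a few seconds on
one core; they are the package's standard demonstration scale and match
the cohort structure described above.

## Known limitations

- Trial-level inference ignores within-participant correlation; the
  participant-level switch exists but has far fewer effective units.
- Parallel analysis uses independent-normal references; for strongly
  smooth data this null is conservative for trailing components.
- The pointwise comparison is not SPM and must not be quoted as
  cluster-corrected inference.
- Mode labels are fitted on two quartile curves only; with representative
  trials they inherit those trials' noise, and windows shorter than 5
  samples are not classified.
- The naive Bayes classifier assumes conditionally independent Gaussian
  features; it is the stopping criterion the selection procedure is
  defined around, not a claim about the best attainable classifier.
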