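# Methods

## Scores and scales

Both measurement routes land on Russell's circumplex: valence and arousal
in (−1, 1).  Questionnaire marks are integers on a nine-point metric whose
endpoints anchor at −1 (very negative / calm) and +1 (very positive /
aroused) with the midpoint at 0; the affine map (u − 5)/4 is the unique
monotone map through those three anchors, it is a bijection onto
{−1, −0.75, …, 1}, and fractional marks are rejected rather than rounded.
The EEG route produces a continuous score per trial (below); a
participant's score is the unweighted mean over their ten 10 s stimulus
epochs, clipped to [−1, 1].  How the original experiment aggregated over
epochs is not recorded; the unweighted mean is the simplest defensible
choice and is permutation-invariant over epochs.

## Statistics

Between-group comparisons (photographic vs illustrated, n = 20 per group)
use the equal-variance two-sample Student t with df = n₁ + n₂ − 2;
between-method comparisons (EEG vs rescaled questionnaire, within group)
use the same test on the common scale.  A Welch variant is available
behind `equal_var=False`.  No multiple-testing correction is applied (the
analysis replicated applies none); α is configurable, default 0.05.

Cohen's d uses the pooled SD with the **total-n** denominator,
√((SSx + SSy)/(nx + ny)).  This convention — not the more common
unbiased (n−2) form — is what reproduces the published between-method
valence effect sizes (0.12 / 0.06) from the packaged table; the (n−2)
form gives 0.11 for the first and is available behind
`denominator="n-2"`.  Degenerate inputs are resolved explicitly:
identical constant samples give t = 0, p = 1, d = 0; zero pooled SD with
unequal means is an error for d and an infinite t with the p value
reported as an underflow bound (p values below 1e−300 are never printed
as 0).

t and d are linked: for equal n, |t| = |d| · √(n/2) when d uses the
(n−2)-denominator SD.  The unit tests verify this identity, the scale
invariance of d under positive affine transforms, and agreement of the
analytic p with a permutation oracle on small samples.

## The packaged experiment table

The 40-row per-participant score table (20 photographic, 20 illustrated;
EEG valence/arousal on (−1, 1), questionnaire marks 1–9) is shipped as a
CSV resource and checksum-verified on every load.  Column statistics
(e.g. photographic-group EEG valence mean −0.8315) are covered by tests
computed independently by direct arithmetic over the printed rows.

Not everything printed in the original analysis is reproducible from its
own per-participant table: the published between-group d values (1.78,
1.01, 1.82, 1.37) are far smaller than what the stated effect-size
formula gives at per-participant granularity (≈ 4.2 / 4.8 / 1.2 / 2.0),
and two of the published between-method cells (0.23, 0.64) likewise
differ (computed 0.02 / 0.96), suggesting a different granularity or
convention that the original analysis does not record.  The package therefore asserts only the oracle-confirmed
cells (0.12, 0.06), the published qualitative bounds (between-group
|d| > 0.8; between-method (i)–(iii) ≤ 0.23), and the published test
verdicts; the remaining cells are reported as computed.

## Synthetic EEG model

Each channel is 1/f ("pink") background + band-limited Gaussian
oscillations in theta (4–8), alpha (8–13), beta (13–30) and gamma
(30–45 Hz) + white sensor noise, in microvolts.  Defaults: background
SD 8 µV, sensor noise 2 µV, band base SDs θ 2 / α 3 / β 3 / γ 1.5 µV.
Band-limited components are white noise masked in the frequency domain,
so band powers are exact by construction and a Welch periodogram serves
as an independent oracle in tests.

Affect enters through band power.  A trial labelled (v, a) ∈ [1, 9]²
scales the alpha power by `valence_power_ratio ** ((v − 1)/8)` and beta
power by the arousal analogue: label 1 leaves base power, label 9
multiplies it by the full ratio, monotonically in between.  Crucially,
each dimension modulates **its own scalp-channel group** — valence on the
anterior half of the 32-channel montage, arousal on the posterior half
(echoing frontal-alpha-asymmetry and central/parietal beta arousal
markers).  Without this separation the two labels are nearly
unidentifiable after per-window amplitude normalization: a high-arousal
trial's beta power inflates every channel's total variance and masks the
alpha *fraction* that carries valence.  The 8 peripheral channels carry
only background and noise.

Labels are drawn uniformly on [1, 9] per trial (continuous
self-assessments); binary classes are derived downstream with the
high-iff-label-≥ 5 convention, midpoint assigned to high.  All randomness
flows from one integer seed through `numpy.random.SeedSequence` spawning
(subject → trial), so identical (seed, params) reproduce corpora bit for
bit.

Two-group cohorts draw one latent (valence, arousal) per participant from
group-specific normals truncated to (−1, 1), constant across the ten
10 s epochs of the 100 s clip; signals use the same coupling model via
u = 5 + 4v.  Default group parameters are the empirical mean/SD of the
packaged table's EEG columns, so simulated cohorts land in the observed
regime.  A statistics-only observation model bypasses signals entirely:
EEG score = latent + N(0, 0.05) clipped, questionnaire mark = nine-point
rounding of latent + N(0, 0.15) — used when only the statistics stage is
under study.

What the generator does **not** emulate: eye blinks, EMG, electrode
drift, line noise, inter-subject anatomical variability, and any
nonstationarity of affect within a trial.  Passing recognition tests on
this corpus therefore demonstrates that the pipeline recovers band-power
structure it is pointed at, not that it would reach published accuracies
on real recordings.

## Preprocessing

4th-order Butterworth 4.0–45.0 Hz, applied forward–backward (zero phase)
— standard EEG practice.  Downsampling (e.g. 512 → 128 Hz) is polyphase
with built-in anti-aliasing.  Channel reduction keeps the 32 scalp
electrodes of the 40-channel layout and drops the 8 peripheral channels.
Windows are non-overlapping 32-sample slices (stride = length = 32),
offset 0, giving 240 windows per 60 s trial; edge transients of the
zero-phase filter are retained (no trimming).  Each window is z-scored
per channel (ε-guarded for flat channels) before the model — necessary
for stable training, and it makes recognition rely on spectral shape
rather than raw amplitude.

## The voting ensemble

Five columns share one architecture and differ only in seeded
initialization, data subsampling and shuffling order.  Each column is a
compact convolutional network in plain numpy: four conv stages (8, 16,
16, 16 maps) with kernels (3×7, 3×5, 3×3, 3×3) — wider along time so the
earliest filters can resolve oscillation frequency — ReLU, 2×2 average
pooling between stages, then pooling over the **time axis only** with the
coarse channel axis flattened (channel position carries meaning: which
scalp region a feature came from), dropout 0.1, and two independent
2-way softmax heads.  Training is mini-batch Adam (lr 2e-3, batch 256)
on the summed cross-entropy of both heads, early stopping on validation
loss (patience 5, max 30 epochs), best-epoch weights restored.  A
central-difference gradient check covers every layer in the tests.

Decision rule: per column and head, majority over a trial's windows
(ties break toward low); ensemble class = majority of the five column
votes (odd, so never tied).  The continuous trial score defaults to the
pooled window fraction 2·(high windows / total window votes) − 1, which
yields fine-grained (−1, 1) values; a coarser column-vote mode
(2·n_high/5 − 1, six levels) is selectable.  Accuracy is trial-level:
the fraction of trials whose ensemble class matches the binarized label.

The canonical subject split is 22/5/5 of 32 subjects (880/200/200
trials), subject-level so no participant's trials straddle partitions.

## Problem sizes and reduced-scale choices

Training at the benchmark's full scale is not the goal here; the
recognition tests run a reduced configuration chosen as the smallest
setting where recovery is comfortably demonstrable: 8 subjects × 40
trials of 12 s (48 windows per trial), split 4/2/2, strong-coupling
generator preset (power ratio 16 across the label range, background
4 µV, sensor noise 1 µV), 16 windows per trial subsampled for training,
all windows used at prediction.  Under this preset a single column
reaches ≈ 0.95 trial accuracy with residual errors confined to labels
within ~0.25 of the class boundary, where window-level contrast vanishes
by construction.  The label-shuffled control uses identical settings and
stays at chance.

## Known limitations

* The five columns differ only by initialization; the multi-column
  design's original module diversity (if any) is not documented and is
  not reproduced.
* Whether published accuracies are window- or trial-level is not
  recorded; trial-level is implemented.
* The ensemble's continuous score quantizes at 1/(5·n_windows) steps,
  so scored cohorts have slightly granular score distributions.
* Statistical verdicts on synthetic cohorts inherit the observation
  model's noise parameters; they demonstrate the statistics stage, not
  empirical effect sizes.
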