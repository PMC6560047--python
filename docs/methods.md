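# Methods

## The experimental model

`ringmem` simulates and analyzes a context-dependent associative-memory
experiment. Seven abstract stimuli are arranged on a ring; each stimulus is
associated with its two ring neighbors (seven undirected links). A second
memory uses the same stimuli against a different background color, with the
ring positions of two stimuli (3 and 6 by default) exchanged. Because the
swapped stimuli sit at ring distance 3, four of the seven links differ
between the memories and three are shared. Every unordered stimulus pair is
classified per context as *associated in both* memories, *associated in the
current context only*, *hidden* (unassociated now, directly associated in
the alternative memory), or *unassociated in both*; pairs containing a
swapped stimulus are *unstable*. Hidden pairs are where a stored but
currently irrelevant association can intrude — the neural signature of
memory interference — and unstable pairs are where the two memories make
conflicting relational predictions.

Swaps at ring distance 1 or 2 change only two links (the swapped stimuli
keep or trade links with each other); the generator exposes the swap as a
free parameter but the category counts {3, 4, 4, 10} that the contrasts
rely on hold only for distance-3 swaps, and only that configuration is
validated. Per simulated participant, stimulus allocation is randomized by
a label bijection applied to both rings and the swap, which preserves the
category structure while decorrelating stimulus identity from role; the
pair taxonomy is recomputed per participant.

## Task design generation

The scan task presents each of the 21 non-repeating pairs 4 times per
context and each repeating pair (i, i) twice per context: 196 trials, each
stimulus in 52 trials. Rotations (0/90/180/270 degrees) are assigned by
per-stimulus balanced queues so every stimulus appears exactly 13 times at
each rotation; repeated stimuli within a repeat trial share the trial's
rotation. If altered repetition counts make a stimulus's occurrence count
indivisible by four, generation fails loudly rather than unbalancing.
7% of trials (rounded: 14) are flagged as oddballs — a trial whose stimulus
is replaced by a shape outside the trained set — without changing the trial
count or onsets; oddball placement is re-drawn in the rare event it would
leave a pair-by-context design cell empty. Inter-trial intervals follow a
gamma distribution with shape fixed at 4, truncated to [1.5 s, 9.7 s], with
the scale solved numerically (Brent's method on the closed-form truncated
mean) so the truncated mean is 2.9 s; draws are by rejection. The number of
volumes per block is derived from the realized sequence as
ceil((last offset + 16 s)/TR) at TR = 1.512 s, which lands in the 644–723
range a 20-minute acquisition produces; a fixed count would occasionally be
overrun by the stochastic ITI total.

Training blocks are 100 three-alternative forced-choice trials probing each
association at least 14 times; the two lures are never ring neighbors of the
probe. The memory test is 100 no-feedback trials, 50 per context, each
association probed at least 7 times. Where the probe's neighbor sets differ
between contexts, a *foil* option — correct only in the alternative
context — is inserted with probability `foil_fraction` (default 0.5; the
proportion is not constrained by the study description, and 0.5 yields
roughly 40 foil trials per participant, enough to estimate a per-subject
foil-error rate). One stimulus (label 1 in the canonical layout) has
identical neighbors in both contexts and can never yield a foil trial.

## Synthetic data

**Patterns.** Each stimulus-by-context condition evokes a voxel pattern
equal to a constant amplitude (1, in units where the HRF has unit peak)
plus a zero-mean multivoxel component with unit variance. The 14x14
correlation matrix of the components is: `rho_within` (0.25) between
different stimuli within a context, `rho_between` (0.05) between different
stimuli across contexts, `rho_same_cross` (0.30) for the same stimulus
across contexts, reduced by `delta_swap` (0.25) for the swapped stimuli.
Patterns are drawn through an eigendecomposition of the target matrix so
that positive semidefinite but singular structures are allowed — the
no-effect null sets the same-stimulus cross-context correlation to exactly
1 (a stimulus evokes the identical pattern in both contexts). Anything
below 1 *is* context coding, and the context-separation test is expected to
detect it.

**BOLD.** Each trial contributes one HRF-convolved delta at trial onset
carrying the first stimulus's pattern plus the second's scaled by
(1 - suppression). Both stimuli are modeled at the trial onset: the GLM
models trials, not stimuli, and the 300 ms gap between stimuli is
negligible on the HRF's timescale; keeping the forward model inside the
span of the trial-level design means planted amplitude effects map onto
contrasts exactly in the noiseless limit, which the exactness tests use.
Suppression is `delta_suppress` (0.15) for pairs associated in both
contexts (both blocks), plus `kappa_couple x gaba_drop` for hidden pairs in
block 2 only — the interference signal unmasked by the stimulation-induced
GABA drop. In the hippocampal ROI, unstable-pair trials add a spatially
uniform response of `beta_unstable` (0.35), with a per-subject block-1
component tied to the interference trait (below). Noise is AR(1)
(coefficient 0.3) driven by white noise of standard deviation `noise_sd`
(1.0), plus a random linear drift per voxel (removed by the high-pass
filter). The HRF is the canonical SPM double-gamma (peak 6 s, undershoot
16 s), normalized to unit peak so betas read in response-amplitude units.

**Cohort couplings.** One standard-normal latent trait q per participant
drives the cross-subject structure: the realized GABA:Cr drop is
0.02 + 0.02 q, the memory-test foil weight is 1.0 + 0.8 q, the correct-
option strength is 2.2 - 0.4 q, and the block-1 hippocampal boost gains
0.15 q (block 2 uses an independent draw, so only block 1 predicts
behavior, mirroring the reported dissociation). Memory-test choices are a
softmax over {correct, foil, other} with utilities {strength, foil weight,
0}; at the defaults mean accuracy is ~73%. Training accuracy follows a
saturating exposure curve p = 1 - (2/3) exp(-0.05 E) from 8 initial
(passive-phase) exposures; blocks continue until at least five are complete
and every association is at or above 90% within a block, capped at 12
blocks with a warning.

**Metabolites.** Nineteen metabolite:Cr ratios at three timepoints with
plausible baselines; GABA:Cr dips by the subject's realized drop at t2
(during stimulation) and returns to baseline at t3; Glu:Cr rises by 0.04 at
t3. Each measurement carries a CRLB (GABA ~ N(15, 4)%, clipped positive)
and a linewidth; a 6/26 fraction of subjects is flagged GABA-inestimable
with broadened linewidth and is excluded from analyses that use MRS.
MRS measurement noise is 0.005 (GABA:Cr units) per timepoint.

These defaults were calibrated once so that, at n = 24, the four planted
group effects sit in a >= 90%-power regime while null configurations reject
at about 5%; single-subject effect magnitudes are not constrained by the
study (which reports only group statistics on real data), so the defaults
make no claim to reproduce specific t-values.

## GLM and contrasts

The pairwise model has one regressor per unordered pair per context (42),
four nuisance regressors (repeat and oddball trials by context), and six
motion columns when motion parameters are supplied (the simulator produces
none; the interface accepts them for real event tables). The trialwise
model has one regressor per trial. Events are delta functions at trial
onset convolved with the HRF. A discrete-cosine basis with a 128 s cutoff
is regressed out of both data and design before a QR-based OLS fit; no
prewhitening is applied by default (group inference on subject-level
contrast means is robust to the AR(1) noise, and the trialwise residuals
feed the RSA noise covariance regardless). Rank deficiency raises an error
naming the collinear columns. Degrees of freedom are volumes minus design
columns minus drift-basis columns.

Contrasts (equal mean weights, summing to zero): *expression* =
unassociated-in-both minus associated-in-both (both contexts), the
cross-stimulus-suppression index of memory expression; *interference* =
unassociated-in-both (control) minus hidden, so more suppression on hidden
pairs gives a larger positive index, and the block 2 minus block 1
difference is the per-subject neural-interference change; *opportunity* =
unstable minus stable pairs, the hippocampal response to conflict between
the memories. Expression and interference are evaluated in the aLOC ROI,
opportunity in the hippocampal ROI.

## RSA

Trialwise betas from both blocks are whitened by a pooled shrinkage
estimate of the voxel noise covariance (sample covariance of the trialwise
residuals shrunk toward its diagonal; analytic Schafer–Strimmer intensity,
overridable). The default dissimilarity is one minus the Pearson
correlation of whitened patterns; plain whitened-Euclidean (Mahalanobis)
distance is selectable — the study's description names both and is
internally ambiguous, so both readings are implemented and tested.

The trial RDM is pooled into 14 conditions (stimulus x context), each
collecting all non-oddball trials of that context containing the stimulus.
Two exclusions keep the within/between comparison unbiased: trial
self-pairs, and all pairs of trials presenting the same unordered stimulus
pair. Self-pairs exist only inside within-context cells, so excluding them
alone deflates within-context dissimilarity and biases the context
comparison (about -0.08 in tau at the defaults); excluding identical-
content pairs everywhere makes within- and between-context cells average
over the same population of stimulus pairings, so the context tau is
centered at zero under the null. The plain self-pair-only variant remains
available (`exclude_same_pair=False`).

Model RDMs: the *context-separation* model codes within-context cells 0 and
between-context cells 1, with same-stimulus cross-context cells masked
(they index stimulus identity, have no within-context counterpart, and
would bias the comparison); a variant excluding the swapped stimuli
entirely checks that context separation does not hinge on them. The
*relational-separation* model is encoded on the seven same-stimulus
cross-context cells only: swapped stimuli 1, others 0, everything else
masked; a graded variant marks every cross-context cell involving a swapped
stimulus. Model fit is the Kendall tau-a over unmasked upper-triangle
cells — tau-a rather than tau-b because the models are predominantly tied,
with the consequence that a binary model's best achievable fit is its
self-fit, below 1. Group inference is a two-sided Wilcoxon signed-rank test
across participants: exact by sign enumeration up to n = 12 (valid under
ties via midranks), normal approximation with continuity and tie
corrections beyond.

## Statistics

Foil errors are the percentage of foil trials on which the foil was chosen;
normalized foil errors subtract the percentage of other-error (never-
correct) choices on foil trials, so the symmetric-error null is centered at
zero. Learning accuracy is the participant's best training-block accuracy.
Partial correlations residualize each outcome on its own nuisance set by
OLS and correlate the residuals (Pearson or Spearman); the p-value uses a
t reference on n - 2 - k degrees of freedom with k the larger nuisance
column count, and plotting residuals are shifted by intercept plus outcome
mean. The permutation test for the difference between two correlations
sharing an outcome permutes the outcome's subject labels — independently
for the two correlations within each iteration by default (a paired variant
reuses one permutation) — with the add-one p estimator over 10,000
iterations by default, so p is never exactly zero. Exclusions: below 80%
scan-task accuracy on either block (boundary inclusive: exactly 80% is
retained) removes a subject from fMRI analyses; an inestimable GABA fit
removes them from MRS-involving analyses; metabolite records with
CRLB > 50% are dropped. The pipeline mirrors the study's analysis set,
including the partial-correlation chain (GABA drop vs
interference change accounting for glutamate; interference change vs foil
errors and accuracy accounting for learning, GABA, and glutamate) and the
permutation test comparing the block-1 and block-2 hippocampus-behavior
correlations.

## Problem sizes and what the tests show

The acceptance suite simulates 100 effect and 100 null cohorts of 24
participants at the full task size (two 196-trial blocks, about 660 volumes
per block, 200 voxels per ROI) — roughly 4,800 end-to-end subject analyses,
a few minutes of compute — plus 200 runs of 500 permutations for the
permutation-calibration check and 100,000 draws for the ITI check. Unit
tests use half-length blocks (112 trials) and 10–50 voxels.

Passing these tests shows that the pipeline recovers effects *of the kind
and size it plants* under its own noise model: Gaussian AR(1) voxel noise,
no spatial structure within an ROI, no motion or physiological artifacts,
no registration error, softmax choice behavior, and couplings driven by a
single latent trait. None of that certifies performance on real fMRI data,
where noise is heavier-tailed and structured; the analysis-side code
(design matrices, OLS, RDMs, statistics) is data-agnostic and is the part
the tests pin down exactly.

## Known limitations

- Only the 7-stimulus, distance-3-swap configuration is validated; other
  ring sizes run but are not checked against the study's constants.
- ROI voxel sets are unstructured index sets; there is no searchlight, no
  whole-brain mapping, and no multiple-comparison machinery beyond the
  specific tests reported.
- The pooled two-block GLM is realized as per-block fits (block-separable
  regressors make the pooled fit equivalent); nuisance regressors are per
  block.
- The MRS inestimability exclusion is an explicit flag (with elevated
  linewidth as its observable), not a linewidth threshold, since the study
  reports the exclusion as a group difference rather than a cutoff.
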