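# ringmem

Simulation and analysis of **memory interference between two overlapping,
context-dependent associative memories**, for cognitive-neuroimaging
methods work: fMRI task design, cross-stimulus-suppression GLM contrasts,
noise-normalized representational similarity analysis (RSA), behavioral
foil-error statistics, and MRS (metabolite) quality control — exercised
end-to-end on a synthetic-data generator that plants the effects the
analysis is built to detect.

## The model

Seven stimuli are arranged on a ring; each is associated with its two
neighbors (memory 1). A second memory uses the same stimuli with the ring
positions of stimuli 3 and 6 exchanged, so 4 of 7 associations differ. Each
unordered pair (i, j) is, per context, **associated in both** memories,
**associated in the current context only**, **hidden** (unassociated now
but associated in the other memory), or **unassociated in both**; pairs
containing a swapped stimulus are **unstable**.

Three contrasts on pair-level GLM betas β (one regressor per pair per
context, delta at trial onset convolved with the canonical HRF):

- *expression* = mean β(unassociated) − mean β(associated-both) — cross-
  stimulus suppression (XSS) between directly associated stimuli;
- *interference* = mean β(unassociated) − mean β(hidden) — XSS on hidden
  pairs, the neural index of memory interference; its block 2 − block 1
  change tracks the stimulation-induced GABA drop;
- *opportunity* = mean β(unstable) − mean β(stable) — the hippocampal
  response when the two memories conflict.

RSA whitens trialwise betas by a shrinkage noise covariance Σ̂ (Mahalanobis
/ crossnobis normalization), pools trials into 7 stimuli × 2 contexts, and
scores two model RDMs with Kendall's τ-a: contextual pattern separation
(within < between context dissimilarity) and relational separation (extra
cross-context separation for the swapped stimuli). Behavioral interference
is the **foil error** rate: choosing, on a memory-test trial, the option
that is correct only in the alternative context. Cross-subject inference
uses Wilcoxon signed-rank tests, partial correlations (OLS
residualization), and a label-permutation test for the difference between
two correlations.

## Worked example

Simulate and analyze a small demonstration cohort (6 subjects, 50 voxels
per ROI), then print the group statistics:

```bash
ringmem fixtures --out demo --seed 0
ringmem report --results demo
```

```
context_tau                                   stat=  +2.102 p=0.0312 n=6 (Wilcoxon signed-rank (Z))
context_tau_excl_swapped                      stat=  +2.120 p=0.0312 n=6 (Wilcoxon signed-rank (Z))
relational_tau                                stat=  +2.120 p=0.0312 n=6 (Wilcoxon signed-rank (Z))
opportunity_both_blocks                       stat=  +5.235 p=0.0034 n=6 (one-sample t)
expression_both_blocks                        stat=  +5.073 p=0.0019 n=6 (one-sample t)
interference_b2_minus_b1                      stat= +11.177 p=0.0001 n=6 (one-sample t)
gaba_t1_gt_t2                                 stat=  +9.491 p=0.0003 n=5 (paired t)
glu_t3_vs_t1                                  stat=  +3.938 p=0.0170 n=5 (paired t)
gaba_drop_vs_interference                     stat=  +0.300 p=0.7000 n=5 (partial Spearman)
hippocampus_b1_vs_foil_errors                 stat=  +0.422 p=0.5783 n=6 (partial Pearson)
hippocampus_block_correlation_difference      stat=  +0.473 p=0.5110 n=6 (permutation (500 iterations))
```

Reading the output: the RSA rows are group signed-rank Z statistics on
per-subject τ-a model fits — context and relational pattern separation are
both detected even in this tiny cohort (p = 2/2⁶ = 0.031, the smallest
two-sided p six subjects allow). The contrast rows are one-sample t tests
on ROI-mean contrast values: the planted hippocampal conflict response
(`opportunity`), cross-stimulus suppression (`expression`), and the block-2
rise in neural interference are all positive. `gaba_t1_gt_t2` confirms the
planted GABA:Cr dip during stimulation (n = 5 because one subject's GABA
fit is flagged inestimable, mirroring real MRS attrition). The
cross-subject correlation rows are underpowered at n = 6 by design — they
need cohort-scale samples (n = 24), at which the acceptance suite verifies
they are recovered in ≥ 90% of cohorts.

The same stages are available as a library:

```python
import ringmem as rm

rings = rm.build_memory_rings(range(1, 8), (3, 6))
tax = rm.link_taxonomy(*rings)                    # 21 pairs x 2 contexts
events = rm.generate_scan_block(tax, rm.DesignParams(), seed=1)  # 196 trials
specs = rm.contrast_specs(tax)                    # expression/interference/opportunity
```

Other subcommands: `ringmem simulate-design` (write a scan/training/test
events table), `ringmem simulate-cohort` (per-subject data directories,
optional NIfTI), `ringmem analyze` (full pipeline with a YAML config).

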