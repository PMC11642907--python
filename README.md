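# detcon — detectable fMRI connectivity from time-course reliability

Functional connectivity is usually reported as the Pearson correlation
between two brain regions' BOLD time courses. But a correlation between two
measured signals cannot exceed the precision with which each signal is
measured: if ρ_A and ρ_B are the *within-subject test-retest reliabilities*
of the two node time courses, then

    connectivity upper bound(A, B) = √(ρ_A · ρ_B)

(the classical attenuation bound). `detcon` implements the full analysis
that follows from taking this bound seriously in task fMRI:

- **within-subject time-course reliability** — Pearson r between the test-run
  and retest-run time course of each node in each subject;
- **detectable connectivity** — observed connectivity capped at
  √(ρ_A·ρ_B), with the observed sign preserved and paths zeroed when a node
  reliability is negative;
- **AR(1) prewhitening** — residual lag-1 autocorrelation of each series
  pair is estimated (both regression directions, averaged) and removed by
  subtracting the ρ-weighted lagged series;
- **stationary block bootstrap** — confidence intervals for every
  correlation, with the expected block length selected automatically by the
  flat-top lag-window rule and one joint index vector per replicate so
  cross-series alignment is preserved;
- **group reproducibility** — per-path one-sample t tests of Fisher-z
  correlations, conjunction analysis (min-t / max-p over sessions), Dice
  overlap of thresholded maps over the exponential threshold grid
  p = 0.05^(0.1·n), effect-size maps, and Monte-Carlo experiments over
  sample size and random connectome selection;
- **synthetic cohorts** — a generator for test/retest node time courses
  (task cycles convolved with a hemodynamic response, heterogeneous subject
  gains, latent network factors, AR(1) noise, nuisance series) and
  behavioral response times whose reliability is coupled to the fMRI
  reliability, so the entire pipeline is testable without any data download.

The package targets methodologists who want to ask, for a task-fMRI study
design: *given how reliable single-subject time courses actually are, how
much connectivity is detectable, and what does that do to group-level
reproducibility claims?*

## Worked example

Simulate a small cohort (16 subjects, 10 nodes, 488 volumes at TR = 1.24 s,
24 task cycles) and run the whole pipeline with 300 bootstrap replicates:

```sh
cat > demo.yaml <<EOF
n_subjects: 16
n_nodes: 10
EOF
detcon simulate --config demo.yaml --seed 42 --out demo_cohort
detcon run-all --in demo_cohort --out demo_out --nboot 300 --seed 42
```

`demo_out/summary.json` then contains (abridged; ~50 s on one CPU):

```
grand_mean_reliability        raw 0.210   ar1 0.102
table1 mean connectivity      observed_test 0.420   ar1_test 0.353
                              detectable_test 0.189 detectable_ar1_test 0.088
conventional_group_reliability_mean  0.710
median_conj_t                 observed 16.10  detectable_ar1 5.88
bonferroni (p = 0.05/45)      n_conj 45/45 paths, dice 1.0 (observed)
```

Reading it: the cohort's mean within-subject time-course reliability is
r ≈ 0.21 and drops to ≈ 0.10 after AR(1) correction, so although ordinary
connectivity averages r ≈ 0.42, only r ≈ 0.09 is *detectable* once
reliability and autocorrelation are accounted for — yet every path still
reproduces across sessions at the Bonferroni-corrected threshold, because
group NHST aggregates 16 subjects. Conventional *group-level* path
reliability (0.71) is far higher than the single-subject time-course
reliability that limits detection. This is the central dissociation the
package quantifies: high group reproducibility is compatible with very
little detectable single-subject connectivity.

The same machinery is available as a library (`detcon.generate_cohort`,
`detcon.within_subject_reliability`, `detcon.detectable_connectivity_tensor`,
`detcon.sample_size_experiment`, ...); the CLI subcommands `simulate`,
`preprocess`, `connectivity`, `groupstats`, `montecarlo` and `run-all` are
thin wrappers over it.

## Conventions

Sessions are 0 = test, 1 = retest. Paths are the lower triangle of the node
correlation matrix, ordered (i, j) with i > j; edge lists use 1-based node
indices. Negative reliabilities enter the attenuation bound as zero; a path
counts as negative in distribution summaries only when the upper bound of
its bootstrap CI is below zero.
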