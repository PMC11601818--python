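# ch4subtype

Tools for subtyping Parkinson's disease with mild cognitive impairment
(PD-MCI) by MRI evidence of cholinergic nucleus 4 (Ch4) degeneration.  Ch4 —
the cell group comprising most of the nucleus basalis of Meynert — is the
main cholinergic projection to cortex, and its grey-matter loss on
voxel-based morphometry marks the patients whose cognition declines fastest.
The package is aimed at neuroimaging researchers who have already run a VBM
pipeline (normalized, modulated grey-matter maps) and want the downstream
analytic chain as tested, reusable code.

## What it computes

1. **Region GMD** (`ch4subtype.gmd`) — the probabilistic-mask-weighted mean
   grey matter, `GMD = Σᵥ gm[v]·w[v] / Σᵥ w[v]`, from NIfTI volumes on a
   shared grid (mismatched grids are refused, never resampled), plus a
   simple tissue-sum TIV.
2. **Regression-based norming** (`ch4subtype.norming`) — healthy-control
   GMD is mapped to scaled scores (mean 10, SD 3 on the reference), scaled
   scores are regressed on age, sex, scanner type (GE/Philips vs Siemens)
   and TIV, and each patient gets an adjusted z-score
   `z = (scaled_actual − scaled_predicted)/RMSE`; patients with `z ≤ −1`
   are classified **low Ch4**, the rest **normal Ch4**.
3. **Data-driven subtypes** (`ch4subtype.subtyping`) — diffuse malignant /
   intermediate / mild motor predominant from duration-specific 75th
   percentiles of a composite motor score (MDS-UPDRS II + III) and three
   non-motor axes (SCOPA-AUT, RBDSQ, cognitive burden `30 − MoCA`).
4. **Cognitive milestones & survival** (`ch4subtype.survival`) — time to
   the first of six milestones (MoCA < 21; MDS-UPDRS items 1.1/1.2/1.5 ≥ 3;
   clinical or composite dementia) with Kaplan-Meier curves, the log-rank
   test, and a Cox model adjusted for age, sex and baseline MoCA.
5. **Group statistics** (`ch4subtype.stats`) — median (IQR) with
   Kruskal-Wallis, uncorrected Pearson chi-square on binarized symptoms,
   and noncentral-t two-sample power.
6. **Synthetic cohorts** (`ch4subtype.simulate`) — PPMI-like control and
   PD-MCI cohorts with planted GMD coefficients, clinical shifts and a
   proportional-hazards milestone process, so the whole chain runs and is
   validated end to end without any data download.

`ch4subtype.pipeline.run_full_pipeline` chains all stages from a config and
writes stage outputs plus a manifest; a thin CLI (`ch4subtype --help`)
exposes each stage as a subcommand.

## Worked example

`examples/` holds one short script per capability.  The survival example:

```bash
python examples/05_milestone_survival.py
```

prints (seed 1):

```
first_milestone_type
none                  58
moca_lt_cutoff        50
updrs_1_1             14
updrs_1_2             11
updrs_1_5              9
dementia_composite     3
dementia_clinical      3
low Ch4: n=40, events=27, milestone-free at 36 months: 0.36
normal Ch4: n=108, events=63, milestone-free at 36 months: 0.56
log-rank: chi2=1.98, p=0.1589
adjusted Cox: HR=1.31 (95% CI 0.83-2.07), p=0.250
```

Reading it: of 148 simulated PD-MCI patients, 90 reach a cognitive
milestone within 60 months of 6-monthly visits (most often MoCA dropping
below 21).  Patients classified low Ch4 are milestone-free less often at 36
months (36% vs 56%).  The adjusted hazard ratio of 1.31 for the *classified*
low group is attenuated relative to the generator's planted hazard ratio of
1.95 for the *latent* low group — classification noise and a single-cohort
sample size do that; the parameter-recovery tests in
`tests/test_acceptance.py` show the Cox estimator recovers the planted
effect without bias at n = 2000 over 500 replicates.

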