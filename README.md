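# mtdnet

Multi-threshold derivative (MTD) characterization of dynamic brain
functional networks, with an SSA-optimized SVM classification framework.

## The problem

Resting-state fMRI studies of cognitive impairment summarize a subject's
brain as a functional network: regions of interest (ROIs) are nodes, and
pairwise Pearson correlations of their time series are edge weights.
Comparing such networks between a patient group and healthy controls
usually requires binarizing the weighted network at a threshold — and the
choice of that single threshold is arbitrary and strongly affects every
downstream graph statistic.

`mtdnet` implements a framework that sidesteps the single-threshold
problem. Sliding-window networks are binarized over an entire grid of
thresholds *pr*; four topological properties — clustering coefficient (cc),
global efficiency (E\_global), local efficiency (E\_local), and
characteristic path length (L\_p) — are traced as curves over the grid; the
curves are smoothed with penalized B-splines,

> min over c:  Σ\_j (y\_j − cᵀφ(t\_j))² + λ ∫ (cᵀφ″(t))² dt,

and the **first derivative of each fitted curve**, sampled on the grid, is
the MTD feature: how rapidly a network property collapses as the filtration
tightens. The four derivative vectors are linearly fused (concatenated) and
fed to lasso feature selection and an RBF-kernel SVM whose hyperparameters
(C, Gamma) are tuned by the sparrow search algorithm (SSA), a swarm
optimizer with discoverer/follower/alerter roles. Performance is reported
as ACC/SEN/SPE/AUC over repeated stratified 10-fold cross-validation.

Because patient fMRI cohorts of this kind are private, the package ships a
first-class synthetic-cohort generator: two groups of multivariate Gaussian
ROI time series whose covariance has modular structure, with the patient
group's within-module correlation weakened by a controllable `effect`.
Every pipeline stage is exercised end-to-end on these cohorts.

Audience: methods researchers in network neuroscience and anyone needing a
tested, reproducible reference implementation of threshold-filtration
derivative features and SSA-SVM model selection.

## Worked example

```python
import numpy as np
import mtdnet

# two groups of 20 subjects, 20 regions in 4 modules, 100 timepoints;
# patients have within-module correlation reduced by 0.3
cohort = mtdnet.generate_cohort(20, 20, 100, mtdnet.default_spec(),
                                effect=0.3, seed=7)

# sliding-window networks (L=85, s=3 -> D=6 windows), Fisher R-Z on
nets = mtdnet.build_networks(cohort, window_length=85, step=3)

# topological curves over 35 thresholds, then fused MTD features
grid = mtdnet.ThresholdGrid(0.01, 0.35, 0.01)
curves = mtdnet.build_curves(nets, grid)
mtd = mtdnet.extract_mtd(curves)
X = np.vstack([
    mtdnet.fuse_features([mtd[c.subject_id][m] for m in mtdnet.METRICS]).values
    for c in curves])                     # shape (40, 140)

report = mtdnet.cross_validate(X, cohort.labels, k=10, repeats=1, seed=0)
print(report)
```

Output:

```
ClassificationReport(n=40, ACC=1.000+/-0.000, SEN=1.000+/-0.000, SPE=1.000+/-0.000, AUC=1.000+/-0.000)
```

A 0.3 within-module correlation deficit is a large, clean effect, so the
fused MTD features separate the synthetic groups perfectly; with
`effect=0.0` the same pipeline reports accuracy at chance (~0.5). The
report's records frame holds per-fold confusion counts and the (C, Gamma)
chosen by SSA in each fold.

The same pipeline is available from the shell:

```bash
mtdnet simulate --n-pos 20 --n-ctrl 20 --effect 0.3 --seed 7 --out cohort/
mtdnet curves --cohort cohort/manifest.csv -L 85 -s 3 --out curves.csv
mtdnet mtd --curves curves.csv --out mtd.tsv
mtdnet classify --features mtd.tsv --cohort cohort/manifest.csv --out report.csv
mtdnet sweep --cohort cohort/manifest.csv --out sweep.csv   # (L, s) grid
```

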