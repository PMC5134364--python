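# groupvar

**Does a subject's spatially normalized brain map depend on who else was in
the study?** When voxel-based morphometry (VBM) normalizes structural-MRI
tissue maps to a *study-specific* group template, the template is an average
of the very subjects being normalized. A subject's final normalized tissue
map (FINTM) therefore depends not only on their own anatomy but on the
composition of the group — its age range, its case/control ratio, even which
particular individuals happened to be resampled. `groupvar` quantifies that
dependence end to end, at desk scale, on synthetic cohorts.

The package is aimed at methods researchers and pipeline auditors who want
to measure template-driven variability without a full SPM/DARTEL toolchain
or access to a clinical dataset.

## What it computes

For a *constant subject* c processed in run r with group G_r, the pipeline
produces

```
FINTM_c(r) = K_fwhm * [ (m_c ∘ φ_{c,r}) · |D φ_{c,r}| ]
```

where m_c is the subject's native tissue-concentration map, φ_{c,r} is the
diffeomorphic template→subject deformation estimated against the group
template T(G_r), |Dφ| is the Jacobian determinant (the optional *modulation*
factor that preserves total tissue amount), and K_fwhm is an isotropic
Gaussian with full width at half maximum `fwhm` mm. The analysis statistic
is the across-run voxel-wise sample standard deviation of GM concentration,

```
SD(x) = std_{r} [ FINTM_c(r)(x) ],   over voxels with mean GM > 0.1,
```

summarized as mean/median/max over the mask, plus an SD histogram and a
sorted mean/SD profile.

Components:

- `synthetic_cohort` — brain-like 2-D (or small 3-D) phantoms: CSF
  ventricle, WM body, GM cortical ribbon with subject-unique sinusoidal
  folding; ribbon thins and ventricle dilates with age; case subjects carry
  focal GM reductions at fixed loci; all deterministic from seeds.
- `registration_engine` — stationary-velocity log-demons registration with
  scaling-and-squaring exponentiation, pull-back warping and Jacobian
  determinants; SSD never increases during a fit.
- `groupwise_template` — iterative mean/re-register template construction.
- `normalization` — warp, Jacobian modulation, FWHM smoothing.
- `experiment_protocols` — the six resampling protocols: similar
  demographics (E1), sliding age window (E2), case/control ratio sweep
  (E3), full-pool group difference (E4), modulation off (E5), 4/8 mm
  kernels (E6).
- `variability_stats` — SD maps, summaries, histograms, profiles, group
  difference maps, age t-tests.
- `cli` — `groupvar cohort|run|stats|diff|report`.

## Worked example

```python
import groupvar as gv

cohort = gv.generate_cohort(gv.CohortParams(master_seed=11))
reg = gv.RegParams(n_iterations=12)

spec = gv.make_exp2_spec(cohort)          # sliding-age protocol, 15 runs
results = gv.execute_experiment(spec, cohort, reg, n_outer=4)

for sid in spec.constant_ids:
    res = gv.voxelwise_sd([results[r][sid] for r in results])
    print(sid, round(res.summary["mean_sd"], 4))
```

prints (constant subjects are the three youngest controls; their raw maps
are bit-identical across all 15 runs — only the group changed):

```
TDC01 0.0393
TDC02 0.0387
TDC03 0.0369
```

i.e. sliding the group's age window up by ~10 years changes the constant
subjects' normalized GM concentration by ~0.04 per voxel on average. The
matched similar-demographics baseline (E1) on the same cohort gives ~0.024,
and turning modulation off or widening the smoothing kernel damps the
variability — the same qualitative structure reported for real cohorts.

The same workflow is available from the shell:

```bash
groupvar cohort --config cohort.yaml --out cohort/
groupvar run --experiment E2 --config cfg.yaml --out exp2/
groupvar stats --fintm-dir exp2/fintm --out stats/
groupvar report --stats-dir stats/ --out figures/
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the cohort from the seed, executes scaled versions of all six
protocols from scratch (the modulation-off and kernel variants reuse each
sliding-age run's template and velocities, as they are re-normalizations),
prints the per-condition variability summary table and the group-difference
exceedance fractions, and writes the JSON result file. Runtime is a few
minutes on one CPU.

## Scope

The package deliberately does not segment raw T1 images, perform affine/MNI
pre-registration, or reproduce SPM's numerics; phantoms are generated
already segmented on a shared lattice. See `docs/methods.md` for the model,
parameter defaults, and known limitations.
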