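# traitconn

Seed-based resting-state functional connectivity (RSFC) analysis with
simultaneous personality-trait covariates — plus a synthetic BOLD cohort
simulator that makes the whole chain testable without any data downloads.

## Who this is for

Researchers relating stable behavioural phenotypes (here: the five NEO
personality domains — Neuroticism, Extraversion, Openness, Agreeableness,
Conscientiousness) to individual differences in resting-state connectivity
of a priori seed regions (anterior cingulate / precuneus style analyses),
and methodologists who want a small, fully deterministic sandbox in which
every stage of such a pipeline has a known ground truth.

## The model

For subject *i* and seed *s*, the preprocessed BOLD run yields a whole-brain
Fisher-z connectivity map `z_i(v) = atanh(corr(seed-mean_i, voxel_i(v)))`,
averaged over the subject's motion-retained runs. Group inference is a
voxelwise OLS model with all five demeaned domain scores as simultaneous
covariates plus nuisance terms:

    z_i(v) = β₀(v) + Σ_d β_d(v)·(score_id − mean_d)
             + β_age·age_i + β_sex·sex_i + β_ns·(nscans_i − mean) + ε_i(v)

t maps are converted to Z exactly and corrected by Gaussian-random-field
cluster-extent inference at Z > 2.3, corrected p < 0.05, separately for
positive and negative effects. Significant association voxels are sorted by
the valence of group-mean connectivity (invariant-positive /
invariant-negative / variable), conjunction maps count overlap across
domains, and every significant connection is re-checked by split-half
verification and a 5000-pairing permutation test (one-sided in the
direction of the primary effect, p floored at 1/(n_perm+1)). Kendall's W
quantifies concordance between the simultaneous model and five separate
single-domain models.

The synthetic cohort plants seed–target couplings
`c = baseline + Σ_d slope_d·(score_d − mean_d)` realized exactly as the
population correlation, on top of removable nuisance structure (drift,
global/tissue signals, motion-locked artifact) and band-limited AR(1)
observation noise. See `docs/methods.md` for the full generative model and
its limitations.

## Worked example

```python
import traitconn as tc

cfg = tc.default_config(rng_seed=2026)   # 39 subjects, 1-5 runs, 3 seeds
study = tc.simulate_study(cfg)
res = tc.analyze_study(study, n_perm=1000)

print(len(res.subjects), "subjects analyzed")
print(res.kendall_w.kendalls_w.round(2).tolist())
print({d: v.histogram for (s, d), v in res.valence.items() if s == "acc"})
print("five-way overlap:", res.conjunction.level_counts[5])
```

prints (seed 2026):

```
39 subjects analyzed
[0.93, 0.88, 0.91, 0.93, 0.85, 0.94, 0.93, 0.95, 0.95, 0.9, 0.95, 0.93, 0.93, 0.97, 0.88]
{'neuroticism': {'invariant_pos': 6, 'invariant_neg': 3, 'variable': 535},
 'extraversion': {'invariant_pos': 0, 'invariant_neg': 9, 'variable': 391},
 'openness': {'invariant_pos': 83, 'invariant_neg': 0, 'variable': 6},
 'agreeableness': {'invariant_pos': 0, 'invariant_neg': 0, 'variable': 0},
 'conscientiousness': {'invariant_pos': 0, 'invariant_neg': 0, 'variable': 272}}
five-way overlap: 0
```

Reading this: all 39 synthetic subjects survive motion QC with at least one
run; the simultaneous and separate group models rank voxels almost
identically (W ≈ 0.85–0.97 across all 15 seed–domain pairs); for the
anterior-cingulate-like seed, the Neuroticism, Extraversion and
Conscientiousness associations land almost entirely on *variable*-valence
connections (where they were planted), while the planted invariant-positive
Openness connection shows up in the `invariant_pos` bin; and no voxel is
associated with all five domains, because the planted domain targets are
disjoint.

The same analysis is scriptable from the shell:

```bash
traitconn run-all --out results/demo --seed 2026
traitconn synth --out study_dir          # or: synth-cohort --out study_dir
traitconn validate --config my_study.yaml
```

The shipped study design (annotated) lives at
`src/traitconn/data/default_study.yaml`.

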