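# strokedti

Atlas-based lesion mapping and DTI structural-connectivity analysis for
longitudinal mouse stroke studies — with a synthetic-study generator so
the entire pipeline runs and is verifiable without any imaging download.

## The scientific problem

Photothrombotic stroke produces a focal cortical lesion whose size and
location shape both the behavioral deficit and the routes the brain uses
to recover. Tracking that process in vivo requires combining several
analyses over a common atlas space:

- **Lesion mapping** — per-region incidence across a cohort (fraction of
  mice whose stroke mask touches an atlas label), percent-infarct per
  region, lesion volumetry, and the day-1→day-7 *consolidation slope*
  `(p₇ − p₁)/6` in %/day.
- **Diffusion-tensor metrics** — from each voxel's tensor eigenvalues
  λ₁ ≥ λ₂ ≥ λ₃: MD = (λ₁+λ₂+λ₃)/3, AD = λ₁, RD = (λ₂+λ₃)/2, and
  FA = √(3/2)·‖λ − MD‖/‖λ‖, aggregated per region and expressed as
  hemispheric asymmetry `(ipsi − contra)/contra × 100 %`. Elevated
  thalamic RD marks secondary neurodegeneration in the sensory-motor
  thalamus (DORsm) remote from the cortical lesion.
- **Deterministic tractography** — FACT-style tensor-line streamlines
  (fixed Euler step along the principal eigenvector, FA / turning-angle
  stops), with region-pair *fiber density* = streamlines reaching the
  target / seeds, validated against a viral-tracer projection-density
  reference (sample covariance and Pearson ρ).
- **Statistics** — Welch t with Holm–Šídák step-down
  (p₍ᵢ₎ → 1 − (1 − p₍ᵢ₎)^(m−i+1)), split-plot repeated-measures ANOVA
  (mixed model when unbalanced) with Bonferroni-gated per-day contrasts,
  Kruskal–Wallis + Dunn, Mann–Whitney, Pearson/Spearman correlation, and
  Ward minimum-variance clustering of lesion profiles.

The synthetic generator (`strokedti.synthetic`) emulates the two-protocol
longitudinal design this analysis assumes — small vs. large cortical
strokes plus sham controls, scanned at baseline and days 1/3/7/14/21/28 —
with calibrated lesion shrinkage, thalamic degeneration, contralesional
connectivity gain, and lesion-coupled behavior.

## Worked example

```python
from strokedti.synthetic import StudyDesign, generate_study
from strokedti.pipeline import PipelineConfig, run_study

study = generate_study(StudyDesign(rng_seed=1))           # 5 small + 4 large + 4 sham
result = run_study(PipelineConfig(out_dir="out", diffusion_days=(1, 28)),
                   study=study)
```

Mean lesion volumes (mm³) show the calibrated dynamics — strong early
shrinkage in the small group, weak in the large group:

```
day       1      7      28
large  31.51  19.36  13.67
small  19.58   4.64   3.36
```

so the small protocol consolidates by factor 19.58/4.64 ≈ 4.2 between
days 1 and 7 versus 31.51/19.36 ≈ 1.6 for the large protocol, and the
day-1 group separation is 31.51/19.58 ≈ 1.6. Motor-cortex involvement at
day 7 splits the protocols (mean MOp percent-infarct 75.1 % large vs.
3.4 % small), and Ward clustering of the day-7 lesion profiles recovers
the two protocols exactly (`clusters_match_protocols: True`).

Mean summed fiber densities per pathway reproduce the planted
longitudinal story: the ipsilesional thalamocortical pathway of the large
group collapses by day 28 (0.206 → 0.012 vs. control 0.23) while its
midline-crossing contralesional pathway recovers to above the small
group (0.025 vs. 0.000); control tractography correlates positively with
the tracer reference (mean ρ = 0.71 over 4 controls). The statistical
battery flags the matching group effects, e.g.

```
               test                            comparison   statistic        p_adj  significant
split-plot RM-ANOVA          foot_faults_pct: group x day  166.761344 8.462164e-35         True
            welch_t foot_faults_pct day 3: small vs large   -9.814797 6.941295e-04         True
            welch_t   lesion volume day 1: small vs large   -2.697494 4.845514e-02         True
```

i.e. a strong group×time interaction in behavior, a large early deficit
difference that disappears by day 28, and a day-1 volume difference
between protocols.

The same run is available from a shell:

```bash
strokedti make-study --out study --seed 1
strokedti run-all --study study --out out --figures
```

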