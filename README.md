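# gutcog

Reusable analysis pipeline for longitudinal gut microbiome / cognition
studies: mixed-effects random forest (MERF) prediction of cognitive
outcomes from microbiome features, Boruta all-relevant feature
selection, cross-validated permutation importance with empirical-null
significance, composite visit-standardized cognitive z-scores, inverse
Simpson diversity with random-intercept mixed models, per-species
clinical-covariate screening, and KEGG-ortholog enrichment — all
exercisable end to end on a bundled synthetic-cohort generator with
full ground-truth bookkeeping.

## Layout

| module | contents |
| --- | --- |
| `gutcog.io_formats` | MetaPhlAn-style profile reader, HUMAnN-style (stratified) table reader, per-visit metadata reader/writer; the `AbundanceTable` / `VisitRecord` types all other modules consume |
| `gutcog.synthetic_cohort` | group-structured longitudinal cohort simulator with compositional feature tables, subject random intercepts, planted feature→outcome effects and a permuted-outcome negative control |
| `gutcog.cohort_prep` | HC/MCI/AD subject classification, memory and executive-function composite z-scores, inverse Simpson diversity, exact profiled-REML random-intercept LMM |
| `gutcog.merf_core` | mixed-effects random forest: EM-style alternation of a forest fit on the fixed part with closed-form random-intercept and variance-component updates |
| `gutcog.feature_selection` | Boruta with shadow features and per-tree OOB permutation-importance Z-scores |
| `gutcog.importance_stats` | cluster-grouped cross-validated permutation importance, mirrored-null and outcome-permutation p-values, Spearman/BH-FDR annotation, hypergeometric KO enrichment |
| `gutcog.pipeline` | leave-one-sample-per-subject longitudinal split, the per-group multi-seed cognitive pipeline with a union-feature final model, the per-species covariate screen, cross-outcome rank comparison |
| `gutcog.cli` | the `gutcog` command-line interface |

## CLI

All commands take `--seed` and write TSV outputs plus a `manifest.json`
(seed, config hash, library versions — no timestamps, so identical
seeds give byte-identical outputs).

```bash
# generate a synthetic cohort (YAML config optional; --null permutes outcomes)
gutcog simulate --config config.yaml --seed 1 --outdir sim/

# subject classification, composite z-scores, score-stability mixed model
gutcog prep --metadata sim/metadata.tsv --outdir prep/

# inverse Simpson diversity + diversity mixed model
gutcog diversity --metadata sim/metadata.tsv --species sim/species.tsv --outdir div/

# the cognitive pipeline: per-seed split/Boruta/MERF + annotated final model
gutcog fit-cognitive --metadata sim/metadata.tsv --features sim/species.tsv \
    --feature-kind species --group MCI --outcome adas_cog_13 \
    --config config.yaml --seed 1 --outdir fit/

# per-species covariate screen (includes medication classes)
gutcog screen-covariates --metadata sim/metadata.tsv --species sim/species.tsv \
    --seed 1 --outdir screen/

# enrichment of the combined top-15 KO predictors
gutcog enrich-ko --importance fit_ko_adas/importance.tsv \
    --importance fit_ko_mem/importance.tsv \
    --map sim/ko_pathway_map.tsv --background sim/ko.tsv --outdir enrich/

# cross-outcome rank/correlation matrix; aggregate run summaries
gutcog compare --importance a/importance.tsv --importance b/importance.tsv \
    --labels adas,memory --outdir cmp/
gutcog report --rundir fit_a --rundir fit_b --out summary.tsv
```

Example config (`config.yaml`):

```yaml
simulate:
  n_per_group: {HC: 158, MCI: 40, AD: 25}
  n_species: 150
  planted:
    - feature_id: "k__Bacteria|...|s__Sim_species_0000"
      effect_size: 6.0
pipeline:
  n_seeds: 10
  boruta_max_runs: 50
  merf: {n_trees: 150, max_em_iterations: 10}
```

## Notes on modeling choices

- **Personalized prediction.** Test samples come from subjects seen in
  training (the longitudinal split leaves one sample per subject out),
  and MERF predictions add the subject's learned random intercept for
  known subjects. Reported test correlations therefore measure the
  model's ability to extend individual trajectories, not generalization
  to unseen subjects.
- **Importance p-values.** The default is a mirrored empirical null
  built from non-positive held-out importances (requires >= 10 of them);
  small models fall back to an outcome-permutation (refitting) variant,
  or report NaN when disabled. The strength/significance flags on the
  annotated ranking are Spearman-based (|rho| >= 0.4; p <= 0.05 with
  FDR < 0.1) and never depend on importance p-values.
- **Composite z-scores** are standardized within visit index across all
  subjects using the sample SD; visits whose pooled group is degenerate
  (size 1 or zero spread) raise by default and are dropped inside the
  pipeline.
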