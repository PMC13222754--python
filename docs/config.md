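# Study configuration

`panelnet run --config study.yaml` reads a YAML mapping with the fields
of `panelnet.pipeline.StudyConfig`. All fields are optional; defaults in
parentheses.

```yaml
# input
mode: simulate          # simulate | csv
scenario: shared        # shared | group_divergent | null   (simulate mode)
n_per_group: 400        # equal group size; omit for study sizes 1167/614/627
scores_csv: null        # path to a score table (csv mode)
items: true             # also emit item-level Likert responses (simulate)

# design
groups: [G1, G2, G3]
waves: [3, 5, 9]

# estimators
gamma: 0.5              # EBIC hyperparameter
n_lambda: 100           # penalty-grid size
prune_alpha: 0.01       # Wald pruning threshold
n_boot: 200             # bootstrap replicates (1000 with --paper-scale)
n_perm: 200             # permutations per comparison (1000 with --paper-scale)

# stages
run_nct: true
run_longitudinal_permutation: true
covariates: []          # optional demographic covariate columns to carry

# reproducibility / output
seed: 0
out: out
verbosity: INFO
```

Notes

- `--paper-scale` (CLI) or `paper_scale: true` forces
  `n_boot = n_perm = 1000`.
- In `csv` mode the score table must have the header
  `person_id,group,wave,irr,pstr,nVio,psyAgg,phyAs,neg,cAtt,cPra,included`
  with empty fields for missing values; `included` is optional (the
  inclusion filter is recomputed from irritability coverage either way).
- Stage outputs are cached in `out/` keyed by a hash of the config
  (excluding `out` and `verbosity`); rerunning with the same config
  resumes from finished stages, and `report.json` is byte-identical
  across reruns.
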