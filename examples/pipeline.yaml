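# Demo configuration for the end-to-end pipeline:
#   hupred all --config examples/pipeline.yaml
seed: 7
outdir: hupred_out
simulate:
  n_patients: 600
  seed: 7
  interaction_effect: 2.0
  n_ineligible: 14
model:
  n_trees: 200
  seed: 7
  importance_method: impurity
synergy:
  top_k: 10
  pair_max_candidates: 20
risk_rule:
  rdw_threshold: 17.0
  hgb_threshold: 15.5
make_plots: true
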