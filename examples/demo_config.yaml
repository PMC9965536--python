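# Demo pipeline configuration: 200 mg immediate-release tablet,
# fed vs fasted, with the packaged compound record.
#
#   pbbm run --config examples/demo_config.yaml --out pbbm_out --seed 1

seed: 1
compound: default
media_set: oa_ch

simulation:
  n_bins: 20
  t_end_h: 36.0

scenarios:
  - {study: FoodEffect, dose_mg: 200, state: fed}
  - {study: FoodEffect, dose_mg: 200, state: fasted}
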