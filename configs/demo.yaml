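# Full synthetic study at the published design scale:
# 36 patients / ~41 tendons, endpoint (0 h / 48 h) imaging, blot and
# zymograph gels, regression layer on age, gender and tendon type.
seed: 3
out_dir: runs/demo
cohort:
  n_patients: 36
stats:
  alpha: 0.05
  exclude_outliers: sensitivity
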