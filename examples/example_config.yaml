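# Example coagsim run configuration.
# Reproduces the study design at a reduced population size: 20-day
# once-daily dosing, trough blood draw, PT/INR for warfarin and aPTT for
# rivaroxaban.

table: default            # or a path to your own parameter TSV
output_dir: coagsim_out
draw_day: 20

population:
  n: 100                  # subjects per scenario (paper design: 1000)
  seed: 1
  cv: 0.20                # inter-individual variability on production + PK
  cyp2c9: {"*1": 0.72, "*2": 0.19, "*3": 0.09}
  vkorc1: {GG: 0.53, GA: 0.36, AA: 0.11}

assay:
  tf_trigger_nM: 300
  ca_trigger_nM: 300
  clot_auc_threshold: 1500    # nM*s fibrin exposure defining the clot
  isi: 1.0
  max_assay_s: 300

scenarios:
  - {drug: warfarin, dose_mg: 2.5}
  - {drug: warfarin, dose_mg: 5}
  - {drug: warfarin, dose_mg: 7.5}
  - {drug: rivaroxaban, dose_mg: 15}
  - {drug: rivaroxaban, dose_mg: 20}
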