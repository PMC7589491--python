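# Demonstration configuration for the franzperm CLI.
#
# Geometry of the standard Franz cell: 1.77 cm^2 membrane, 1 mL donor,
# 7 mL receiver.  The 1.0 mL sample volume is an assumption (the withdrawn
# volume is not specified for the reference assay) and should be set to the
# instrument's actual value for real data.
geometry:
  area_cm2: 1.77
  donor_volume_ml: 1.0
  receiver_volume_ml: 7.0
  sample_volume_ml: 1.0

# 12 h sampling schedule of the reference assay.
schedule:
  times_h: [0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 10.0, 12.0]

simulation:
  true_peff_cm_s: 1.0e-5
  donor_concentration_ug_ml: 10000.0   # 10 mg/mL donor load
  n_replicates: 3
  noise_cv: 0.05
  seed: 42
  drug_name: simdrug

fitting:
  method: both            # sink | nonsink | both
  qtotal_mode: mass-conserving

correlation:
  x_column: papp_franz
  form: log-linear
  exclude: []
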