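# Demonstration configuration: the full 5-treatment x 4-tank x 5-fish
# design, with shortened 4-h respirometry sessions and a reduced optode
# sampling rate so the run finishes in seconds.  Mortality is disabled
# so every treatment keeps an even group size, which lets the
# median-gap split rule demonstrate the within-treatment bimodality and
# the downstream ecotype association.
seed: 2
out_dir: demo_out
occupancy_h: 4.0
water_samples_per_treatment: 4
cohort:
  seed: 2
  mortality_probs: {control: 0.0, low_salinity: 0.0, high_temp: 0.0,
                    low_pH: 0.0, multi_stressor: 0.0}
respirometer:
  sampling_hz: 0.2
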