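{
  "base_pct": 40.0,
  "d_pred": 7.85,
  "d_main_mid": 9.78,
  "d_mid_detail": 5.61,
  "d_format": 6.83,
  "d_clarity": 4.78,
  "interaction_atten": 0.55,
  "sd_participant": 8.0,
  "sd_item": 5.0,
  "sd_item_slope": 2.0,
  "sd_resid": 0.0,
  "rspan_loading": 0.5,
  "pause_loading_between": 0.6,
  "pause_loading_within": 0.3
}
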