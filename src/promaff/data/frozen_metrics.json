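{
  "tables_hash": "5c25402d7471ed10",
  "n_anchors": 173,
  "anchor_spearman": 0.767143,
  "n_significant_pairs": 82,
  "n_direction_concordant": 66,
  "direction_discordant_snp_ids": [
    "rs11557611",
    "rs11872014",
    "rs200209906",
    "rs201362083",
    "rs34500389",
    "rs5505",
    "rs553179073",
    "rs563207167",
    "rs568801899",
    "rs749691733",
    "rs750789679",
    "rs754814507",
    "rs756747509",
    "rs757035851",
    "rs758661090",
    "rs796710298"
  ],
  "z_scale_ok": 78,
  "z_scale_total": 87,
  "z_scale_rate": 0.896552,
  "tpi1_wt_pred_kd_nM": 1.873889,
  "synth_seed": 20170720,
  "synth_n": 200,
  "synth_recovery_rates": {
    "decrease_affinity": 0.970149,
    "increase_affinity": 0.940299,
    "neutral": 0.772727
  },
  "synth_offset_recovery_rate": 0.895
}
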