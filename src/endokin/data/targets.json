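[
 {"id": "rab7_at_t0_pct",
  "description": "Ensemble mean normalized Rab7 at the Rab5-peak-aligned t=0 bin, percent of maximum (fig4_conversion, 27 endosomes)",
  "cmp": "eq", "expected": 50.0, "tol": 5.0},
 {"id": "conversion_median_min",
  "description": "Median per-endosome Rab conversion duration, minutes (10% thresholds)",
  "cmp": "le", "expected": 4.0, "tol": null},
 {"id": "conversion_frac_le_4min",
  "description": "Fraction of endosomes completing conversion within 4 minutes",
  "cmp": "ge", "expected": 0.9, "tol": null},
 {"id": "ph_pre_mean",
  "description": "Mean luminal pH before Rab5 recruitment (fig11_ph, calibrated ratiometric readout)",
  "cmp": "eq", "expected": 6.6, "tol": 0.15},
 {"id": "ph_post_mean",
  "description": "Mean luminal pH over the post-conversion Rab7 plateau (fig11_ph)",
  "cmp": "eq", "expected": 5.7, "tol": 0.15},
 {"id": "golgi_ph",
  "description": "pH assigned to the Golgi-ribbon structure via the segmented-line band ROI",
  "cmp": "eq", "expected": 6.2, "tol": 0.15}
]
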