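{
  "synthetic": {
    "grid": {"lat_min": -60, "lat_max": 60, "lon_min": -30, "lon_max": 30,
             "resolution": 2.5},
    "n_species": 350,
    "n_posterior": 3,
    "clade_fractions": [0.6, 0.4],
    "clade_rates": [0.05, 0.8],
    "clade_anchor_lat": [null, 45.0],
    "size_mean_log": 2.0,
    "size_sd_log": 0.8,
    "n_bioregions": 16,
    "seed": 42
  }
}
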