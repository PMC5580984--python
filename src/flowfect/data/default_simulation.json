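{
  "version": 1,
  "comment": "Default synthetic-cytometry conditions: a 293T-like chemical transfection acquired on a 4-laser analyzer, arbitrary linear units. Sigmas are log10 standard deviations of lognormal distributions.",
  "channels": {
    "fsc_a": "FSC-A",
    "fsc_h": "FSC-H",
    "ssc_a": "SSC-A",
    "dna_label": "FITC-A",
    "protein": "mCherry-A",
    "viability": "Ghost780-A"
  },
  "baseline": {
    "viable_fsc_a": [100000.0, 0.11],
    "viable_ssc_a": [50000.0, 0.13],
    "hw_ratio": 0.95,
    "hw_ratio_cv": 0.03,
    "dead_fsc_scale": 0.4,
    "dead_ssc_scale": 2.5,
    "debris_fsc_a": [5000.0, 0.22],
    "debris_ssc_a": [3000.0, 0.22],
    "autofluor_dna_label": [100.0, 0.18],
    "autofluor_protein": [120.0, 0.18],
    "dye_negative": [150.0, 0.15],
    "dye_dead": [15000.0, 0.20],
    "positive_sigma_dna_label": 0.30,
    "positive_sigma_protein": 0.35
  },
  "defaults": {
    "transfected_fraction": 0.7,
    "protein_only_fraction": 0.0,
    "dead_fraction": 0.15,
    "untransfected_dead_fraction": 0.05,
    "debris_fraction": 0.03,
    "doublet_fraction": 0.05,
    "fitc_shift": 30.0,
    "protein_shift": 25.0,
    "dna_protein_rank_corr": 0.7
  },
  "kinetics": {
    "uptake_peak_h": 12.0,
    "uptake_shape": 2.0,
    "protein_t50_h": 16.0,
    "protein_hill": 2.0,
    "protein_saturation_h": 48.0
  }
}
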