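[
  {
    "eq_id": "cane1987_bee_itd",
    "response": "dry_weight_mg",
    "predictor": "itd_mm",
    "alpha": 0.6453450966281666,
    "beta": 2.4691358024691357,
    "scope": {"taxon": "Apoidea"},
    "sigma_resid": null,
    "source": "Cane (1987) J. Kansas Entomol. Soc. 60:145-147; published as ITD = 0.77 * W^0.405 (W in mg), inverted to ln W = (ln ITD - ln 0.77)/0.405"
  },
  {
    "eq_id": "synthetic_foraging_typical_itd",
    "response": "foraging_distance_km",
    "predictor": "itd_mm",
    "alpha": -0.9,
    "beta": 1.6,
    "scope": {"taxon": "Apoidea"},
    "sigma_resid": 0.5,
    "source": "synthetic example equation (illustrative coefficients, not published values)"
  },
  {
    "eq_id": "synthetic_tongue_apidae_itd",
    "response": "tongue_length_mm",
    "predictor": "itd_mm",
    "alpha": 0.7,
    "beta": 0.96,
    "scope": {"taxon": "Apidae"},
    "sigma_resid": 0.12,
    "source": "synthetic example equation (illustrative coefficients, not published values)"
  },
  {
    "eq_id": "synthetic_tongue_megachilidae_itd",
    "response": "tongue_length_mm",
    "predictor": "itd_mm",
    "alpha": 0.55,
    "beta": 0.9,
    "scope": {"taxon": "Megachilidae"},
    "sigma_resid": 0.15,
    "source": "synthetic example equation (illustrative coefficients, not published values)"
  },
  {
    "eq_id": "synthetic_wing_loading_itd",
    "response": "wing_loading",
    "predictor": "itd_mm",
    "alpha": -1.1,
    "beta": 1.3,
    "scope": {"taxon": "Apoidea"},
    "sigma_resid": null,
    "source": "synthetic example equation (illustrative coefficients, not published values)"
  },
  {
    "eq_id": "synthetic_nectar_load_itd",
    "response": "nectar_load_mg",
    "predictor": "itd_mm",
    "alpha": 1.2,
    "beta": 2.1,
    "scope": {"taxon": "Apoidea", "sex": "female"},
    "sigma_resid": 0.4,
    "source": "synthetic example equation (illustrative coefficients, not published values)"
  },
  {
    "eq_id": "synthetic_diptera_bl",
    "response": "dry_weight_mg",
    "predictor": "body_length_mm",
    "alpha": -3.1,
    "beta": 2.3,
    "scope": {"taxon": "Diptera"},
    "sigma_resid": 0.45,
    "source": "synthetic example equation (illustrative coefficients, not published values)"
  },
  {
    "eq_id": "synthetic_hymenoptera_bl",
    "response": "dry_weight_mg",
    "predictor": "body_length_mm",
    "alpha": -2.7,
    "beta": 2.5,
    "scope": {"taxon": "Hymenoptera"},
    "sigma_resid": 0.5,
    "source": "synthetic example equation (illustrative coefficients, not published values)"
  }
]
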