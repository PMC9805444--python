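{
  "probes": [
    {"name": "MYC",   "role": "gene_target",        "chromosome_arm": "8q24",  "fluor": "Aqua",   "panel_id": "1"},
    {"name": "FHIT",  "role": "gene_target",        "chromosome_arm": "3p14",  "fluor": "Aqua",   "panel_id": "2"},
    {"name": "CCND1", "role": "gene_target",        "chromosome_arm": "11q13", "fluor": "Green",  "panel_id": "1"},
    {"name": "TERT",  "role": "gene_target",        "chromosome_arm": "5p15",  "fluor": "Green",  "panel_id": "2"},
    {"name": "TP53",  "role": "gene_target",        "chromosome_arm": "17p13", "fluor": "Gold",   "panel_id": "1"},
    {"name": "MET",   "role": "gene_target",        "chromosome_arm": "7q31",  "fluor": "Gold",   "panel_id": "2"},
    {"name": "HER2",  "role": "gene_target",        "chromosome_arm": "17q12", "fluor": "Red",    "panel_id": "1"},
    {"name": "WWOX",  "role": "gene_target",        "chromosome_arm": "16q23", "fluor": "Red",    "panel_id": "2"},
    {"name": "CEP3",  "role": "centromere_control", "chromosome_arm": "3cen",  "fluor": "FarRed", "panel_id": "1"},
    {"name": "CEP10", "role": "centromere_control", "chromosome_arm": "10cen", "fluor": "FarRed", "panel_id": "2"}
  ]
}
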