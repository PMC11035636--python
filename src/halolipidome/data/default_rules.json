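{
  "comment": "Diagnostic-fragment rules for archaeal lipid classes. Anchor masses are the printed exemplars: AR core 653.681 / lysoAR-glycerol 373.368, 1G-AR 832.760, 2G-AR 994.813, bacterioruberin 741.581, CL-AR-AR 1522.313, MK(8:8) 717.560, PG-AR 807.684, PGP-Me-AR 901.666, PG-PG-AR 961.687. Head-group reporter ions and family fragment sets below the exemplar anchors are synthetic template values used for rule matching and spectrum simulation. Rules are matched first-to-last; most specific first.",
  "family_fragments": {
    "bilayer": [[653.681, 95.0], [373.368, 60.0]],
    "quinone": [[69.07, 55.0], [95.086, 45.0]],
    "carotenoid": [],
    "isoprenoid": []
  },
  "rules": [
    {
      "name": "PGP-Me-AR",
      "lipid_class": "PGP-Me",
      "core": "AR",
      "family": "bilayer",
      "base_mz": 901.666,
      "formula": "C47H99O11P2+",
      "required_fragments": [[248.99, 100.0], [171.006, 85.0], [124.999, 70.0]],
      "extra_fragments": [],
      "decode": "bilayer"
    },
    {
      "name": "PG-PG-AR",
      "lipid_class": "PGPG",
      "core": "AR",
      "family": "bilayer",
      "base_mz": 961.687,
      "formula": "C49H103O13P2+",
      "required_fragments": [[308.997, 100.0], [385.02, 85.0], [227.012, 70.0]],
      "extra_fragments": [],
      "decode": "bilayer"
    },
    {
      "name": "CL-AR-AR",
      "lipid_class": "CL",
      "core": "AR",
      "family": "bilayer",
      "base_mz": 1522.313,
      "formula": "C89H183O13P2+",
      "required_fragments": [[868.661, 100.0], [406.541, 85.0], [758.602, 70.0]],
      "extra_fragments": [],
      "decode": "bilayer"
    },
    {
      "name": "PGS-AR",
      "lipid_class": "PGS",
      "core": "AR",
      "family": "bilayer",
      "base_mz": 887.641,
      "formula": "",
      "required_fragments": [[234.968, 100.0], [96.96, 85.0], [316.925, 70.0]],
      "extra_fragments": [],
      "decode": "bilayer"
    },
    {
      "name": "PG-AR",
      "lipid_class": "PG",
      "core": "AR",
      "family": "bilayer",
      "base_mz": 807.684,
      "formula": "C46H96O8P+",
      "required_fragments": [[155.011, 100.0], [227.033, 85.0], [99.008, 70.0]],
      "extra_fragments": [],
      "decode": "bilayer"
    },
    {
      "name": "PA-AR",
      "lipid_class": "PA",
      "core": "AR",
      "family": "bilayer",
      "base_mz": 731.653,
      "formula": "",
      "required_fragments": [[98.984, 100.0], [78.959, 85.0], [176.935, 70.0]],
      "extra_fragments": [],
      "decode": "bilayer"
    },
    {
      "name": "2G-AR",
      "lipid_class": "2G",
      "core": "AR",
      "family": "bilayer",
      "base_mz": 994.813,
      "formula": "C55H112O13N+",
      "required_fragments": [[342.139, 100.0], [324.779, 85.0], [307.425, 70.0]],
      "extra_fragments": [],
      "decode": "bilayer"
    },
    {
      "name": "1G-AR",
      "lipid_class": "1G",
      "core": "AR",
      "family": "bilayer",
      "base_mz": 832.76,
      "formula": "C49H102O8N+",
      "required_fragments": [[180.086, 100.0], [162.076, 85.0], [144.065, 70.0]],
      "extra_fragments": [],
      "decode": "bilayer"
    },
    {
      "name": "S-AR",
      "lipid_class": "S",
      "core": "AR",
      "family": "bilayer",
      "base_mz": 1074.77,
      "formula": "",
      "required_fragments": [[422.096, 100.0], [241.002, 70.0], [259.013, 55.0]],
      "extra_fragments": [],
      "decode": "bilayer"
    },
    {
      "name": "AR-core",
      "lipid_class": "AR",
      "core": "AR",
      "family": "bilayer",
      "base_mz": 653.681,
      "formula": "C43H89O3+",
      "required_fragments": [[653.681, 95.0], [373.368, 60.0]],
      "extra_fragments": [[297.279, 50.0], [57.07, 35.0]],
      "decode": "bilayer"
    },
    {
      "name": "lysoAR-glycerol",
      "lipid_class": "AR",
      "core": "lysoAR",
      "family": "bilayer",
      "base_mz": 373.368,
      "formula": "C23H49O3+",
      "required_fragments": [[373.368, 60.0]],
      "extra_fragments": [],
      "precursor_window": [300.0, 460.0],
      "decode": null,
      "generate": false
    },
    {
      "name": "MK",
      "lipid_class": "MK",
      "core": "none",
      "family": "quinone",
      "base_mz": 717.56,
      "formula": "C51H73O2+",
      "required_fragments": [[187.075, 100.0], [225.091, 85.0], [306.162, 70.0]],
      "extra_fragments": [],
      "decode": "mk"
    },
    {
      "name": "DMK",
      "lipid_class": "DMK",
      "core": "none",
      "family": "quinone",
      "base_mz": 703.545,
      "formula": "",
      "required_fragments": [[168.329, 100.0], [204.518, 85.0], [297.841, 70.0]],
      "extra_fragments": [],
      "decode": "mk"
    },
    {
      "name": "MMK",
      "lipid_class": "MMK",
      "core": "none",
      "family": "quinone",
      "base_mz": 731.576,
      "formula": "",
      "required_fragments": [[196.723, 100.0], [241.366, 85.0], [319.504, 70.0]],
      "extra_fragments": [],
      "decode": "mk"
    },
    {
      "name": "DMMK",
      "lipid_class": "DMMK",
      "core": "none",
      "family": "quinone",
      "base_mz": 745.592,
      "formula": "",
      "required_fragments": [[212.914, 100.0], [254.687, 85.0], [337.292, 70.0]],
      "extra_fragments": [],
      "decode": "mk"
    },
    {
      "name": "bacterioruberin",
      "lipid_class": "bacterioruberin",
      "core": "none",
      "family": "carotenoid",
      "base_mz": 741.581,
      "formula": "C50H77O4+",
      "required_fragments": [[119.086, 100.0], [157.101, 85.0], [177.164, 70.0]],
      "extra_fragments": [[133.101, 50.0], [213.164, 35.0]],
      "decode": null
    },
    {
      "name": "squalene",
      "lipid_class": "squalene",
      "core": "none",
      "family": "isoprenoid",
      "base_mz": 411.399,
      "formula": "C30H51+",
      "required_fragments": [[81.07, 100.0], [149.133, 85.0], [121.101, 70.0]],
      "extra_fragments": [[189.164, 50.0], [231.211, 35.0]],
      "decode": null
    }
  ]
}
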