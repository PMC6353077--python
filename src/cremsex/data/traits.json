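{
  "description": "Registry of the 24 osteometric traits measurable on calcined adult remains, with the published inter-observer error statistics (grand mean over both observers, absolute TEM) from the Late Bronze Age / Iron Age Italian reference study. 'retained' marks the 21 traits whose relative TEM falls below the 5% acceptance threshold.",
  "unit": "mm",
  "traits": [
    {"code": "MA-C-W",    "bone": "Mandible",         "description": "condyle width",                       "observer_mean_mm": 16.16, "observer_tem_mm": 0.199, "retained": true},
    {"code": "MA-C-TH",   "bone": "Mandible",         "description": "condyle thickness",                   "observer_mean_mm": 6.85,  "observer_tem_mm": 0.348, "retained": false},
    {"code": "AX-D-H",    "bone": "Axis",             "description": "dens height",                         "observer_mean_mm": 12.25, "observer_tem_mm": 1.444, "retained": false},
    {"code": "AX-D-APD",  "bone": "Axis",             "description": "dens anteroposterior diameter",       "observer_mean_mm": 9.50,  "observer_tem_mm": 0.147, "retained": true},
    {"code": "AX-D-TD",   "bone": "Axis",             "description": "dens transverse diameter",            "observer_mean_mm": 8.70,  "observer_tem_mm": 0.063, "retained": true},
    {"code": "HU-H-VD",   "bone": "Humerus",          "description": "head vertical diameter",              "observer_mean_mm": 36.99, "observer_tem_mm": 0.213, "retained": true},
    {"code": "HU-H-TD",   "bone": "Humerus",          "description": "head transverse diameter",            "observer_mean_mm": 33.45, "observer_tem_mm": 1.850, "retained": false},
    {"code": "HU-T-MXD",  "bone": "Humerus",          "description": "trochlea maximum diameter",           "observer_mean_mm": 19.83, "observer_tem_mm": 0.226, "retained": true},
    {"code": "HU-T-MID",  "bone": "Humerus",          "description": "trochlea minimum diameter",           "observer_mean_mm": 12.79, "observer_tem_mm": 0.234, "retained": true},
    {"code": "HU-C-MXD",  "bone": "Humerus",          "description": "capitulum maximum diameter",          "observer_mean_mm": 16.04, "observer_tem_mm": 0.369, "retained": true},
    {"code": "RD-H-MD",   "bone": "Radius",           "description": "head maximum diameter",               "observer_mean_mm": 18.15, "observer_tem_mm": 0.207, "retained": true},
    {"code": "LU-MXW",    "bone": "Lunate",           "description": "maximum width",                       "observer_mean_mm": 13.65, "observer_tem_mm": 0.110, "retained": true},
    {"code": "LU-MXL",    "bone": "Lunate",           "description": "maximum length",                      "observer_mean_mm": 13.42, "observer_tem_mm": 0.328, "retained": true},
    {"code": "FE-H-VD",   "bone": "Femur",            "description": "head vertical diameter",              "observer_mean_mm": 37.70, "observer_tem_mm": 0.193, "retained": true},
    {"code": "PA-MXH",    "bone": "Patella",          "description": "maximum height",                      "observer_mean_mm": 35.51, "observer_tem_mm": 0.281, "retained": true},
    {"code": "PA-MXW",    "bone": "Patella",          "description": "maximum width",                       "observer_mean_mm": 35.87, "observer_tem_mm": 0.232, "retained": true},
    {"code": "PA-MXTH",   "bone": "Patella",          "description": "maximum thickness",                   "observer_mean_mm": 15.35, "observer_tem_mm": 0.340, "retained": true},
    {"code": "TA-TL",     "bone": "Talus",            "description": "maximum length",                      "observer_mean_mm": 45.74, "observer_tem_mm": 0.315, "retained": true},
    {"code": "TA-HN-L",   "bone": "Talus",            "description": "head-neck length",                    "observer_mean_mm": 19.23, "observer_tem_mm": 0.272, "retained": true},
    {"code": "TA-TR-L",   "bone": "Talus",            "description": "trochlea length",                     "observer_mean_mm": 29.87, "observer_tem_mm": 0.403, "retained": true},
    {"code": "TA-TR-W",   "bone": "Talus",            "description": "trochlea width",                      "observer_mean_mm": 27.20, "observer_tem_mm": 0.291, "retained": true},
    {"code": "NA-MXL",    "bone": "Navicular",        "description": "maximum length",                      "observer_mean_mm": 12.89, "observer_tem_mm": 0.477, "retained": true},
    {"code": "MT1-H-DPW", "bone": "First metatarsal", "description": "dorso-plantar width of head",         "observer_mean_mm": 16.01, "observer_tem_mm": 0.320, "retained": true},
    {"code": "MT1-H-MLW", "bone": "First metatarsal", "description": "medio-lateral width of head",         "observer_mean_mm": 17.40, "observer_tem_mm": 0.611, "retained": true}
  ]
}
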