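{
  "description": "Bundled osteometric reference standards: per-trait, per-sex sample size, mean (mm) and sample SD (mm), with the published cut-off point where available. 'published' blocks carry the additional statistics reported alongside each standard (Welch t, df, non-overlap index D, its SD, per-sex precision, accuracy) for cross-checking recomputation.",
  "standards": {
    "present-study": {
      "label": "present-study",
      "description": "Late Bronze Age / Iron Age Italian cremated series (124 adults, 50 M / 74 F, gender assigned from grave goods); 21 traits surviving the 5% RTEM screen.",
      "traits": [
        {"code": "MA-C-W",    "male": {"n": 17, "mean": 17.15, "sd": 1.38}, "female": {"n": 17, "mean": 14.66, "sd": 1.60}, "cutoff": 15.87, "published": {"t": -4.87, "df": 31.29, "D": 0.60, "D_sd": 0.14}},
        {"code": "AX-D-APD",  "male": {"n": 27, "mean": 10.00, "sd": 0.88}, "female": {"n": 20, "mean": 9.04,  "sd": 0.83}, "cutoff": 9.55,  "published": {"t": -3.82, "df": 42.25, "D": 0.43, "D_sd": 0.13}},
        {"code": "AX-D-TD",   "male": {"n": 26, "mean": 9.08,  "sd": 0.79}, "female": {"n": 20, "mean": 8.82,  "sd": 0.74}, "cutoff": 9.10,  "published": {"t": -1.18, "df": 42.35, "D": 0.14, "D_sd": 0.14}},
        {"code": "HU-H-VD",   "male": {"n": 10, "mean": 40.37, "sd": 2.52}, "female": {"n": 15, "mean": 35.42, "sd": 2.26}, "cutoff": 37.88, "published": {"t": -5.01, "df": 17.88, "D": 0.70, "D_sd": 0.15}},
        {"code": "HU-T-MXD",  "male": {"n": 13, "mean": 20.91, "sd": 1.75}, "female": {"n": 18, "mean": 18.81, "sd": 1.37}, "cutoff": 20.00, "published": {"t": -3.61, "df": 21.84, "D": 0.51, "D_sd": 0.16}},
        {"code": "HU-T-MID",  "male": {"n": 25, "mean": 13.85, "sd": 1.69}, "female": {"n": 31, "mean": 12.23, "sd": 1.28}, "cutoff": 13.28, "published": {"t": -3.96, "df": 43.96, "D": 0.43, "D_sd": 0.12}},
        {"code": "HU-C-MXD",  "male": {"n": 12, "mean": 17.07, "sd": 1.33}, "female": {"n": 14, "mean": 15.03, "sd": 1.13}, "cutoff": 16.09, "published": {"t": -4.19, "df": 21.81, "D": 0.60, "D_sd": 0.16}},
        {"code": "RD-H-MD",   "male": {"n": 26, "mean": 19.76, "sd": 1.31}, "female": {"n": 34, "mean": 16.91, "sd": 1.21}, "cutoff": 18.32, "published": {"t": -8.62, "df": 51.70, "D": 0.74, "D_sd": 0.09, "D3": 0.741}},
        {"code": "LU-MXW",    "male": {"n": 8,  "mean": 15.32, "sd": 0.91}, "female": {"n": 8,  "mean": 13.29, "sd": 1.18}, "cutoff": 14.30, "published": {"t": -3.84, "df": 13.15, "D": 0.67, "D_sd": 0.18, "D3": 0.671}},
        {"code": "LU-MXL",    "male": {"n": 6,  "mean": 14.83, "sd": 0.81}, "female": {"n": 11, "mean": 12.79, "sd": 1.24}, "cutoff": 13.82, "published": {"t": -4.10, "df": 14.27, "D": 0.69, "D_sd": 0.17, "D3": 0.692}},
        {"code": "FE-H-VD",   "male": {"n": 10, "mean": 42.10, "sd": 3.31}, "female": {"n": 15, "mean": 36.60, "sd": 3.06}, "cutoff": 39.39, "published": {"t": -4.19, "df": 18.33, "D": 0.61, "D_sd": 0.16, "D3": 0.613}},
        {"code": "PA-MXH",    "male": {"n": 7,  "mean": 37.22, "sd": 3.30}, "female": {"n": 12, "mean": 33.51, "sd": 2.57}, "cutoff": 35.68, "published": {"t": -2.56, "df": 10.30, "D": 0.48, "D_sd": 0.21}},
        {"code": "PA-MXW",    "male": {"n": 8,  "mean": 38.92, "sd": 2.37}, "female": {"n": 13, "mean": 34.59, "sd": 1.47}, "cutoff": 36.61, "published": {"t": -4.65, "df": 10.38, "D": 0.75, "D_sd": 0.15, "D3": 0.750}},
        {"code": "PA-MXTH",   "male": {"n": 22, "mean": 16.67, "sd": 2.32}, "female": {"n": 38, "mean": 14.70, "sd": 1.71}, "cutoff": 16.10, "published": {"t": -3.48, "df": 34.35, "D": 0.39, "D_sd": 0.12}},
        {"code": "TA-TL",     "male": {"n": 6,  "mean": 48.84, "sd": 2.41}, "female": {"n": 11, "mean": 44.93, "sd": 2.50}, "cutoff": 46.87, "published": {"t": -3.15, "df": 10.72, "D": 0.57, "D_sd": 0.21}},
        {"code": "TA-HN-L",   "male": {"n": 8,  "mean": 18.76, "sd": 2.71}, "female": {"n": 12, "mean": 17.54, "sd": 3.68}, "cutoff": 16.51, "published": {"t": -0.85, "df": 17.73, "D": 0.20, "D_sd": 0.21}},
        {"code": "TA-TR-L",   "male": {"n": 10, "mean": 31.14, "sd": 2.01}, "female": {"n": 14, "mean": 26.68, "sd": 2.27}, "cutoff": 28.92, "published": {"t": -5.07, "df": 20.85, "D": 0.70, "D_sd": 0.15, "D3": 0.703}},
        {"code": "TA-TR-W",   "male": {"n": 18, "mean": 28.99, "sd": 2.71}, "female": {"n": 29, "mean": 25.72, "sd": 2.35}, "cutoff": 27.52, "published": {"t": -4.22, "df": 32.22, "D": 0.48, "D_sd": 0.13}},
        {"code": "NA-MXL",    "male": {"n": 15, "mean": 14.00, "sd": 2.46}, "female": {"n": 23, "mean": 11.94, "sd": 1.61}, "cutoff": 13.46, "published": {"t": -2.86, "df": 21.86, "D": 0.41, "D_sd": 0.15}},
        {"code": "MT1-H-DPW", "male": {"n": 23, "mean": 17.14, "sd": 1.41}, "female": {"n": 31, "mean": 15.13, "sd": 1.29}, "cutoff": 16.17, "published": {"t": -5.38, "df": 45.14, "D": 0.54, "D_sd": 0.12}},
        {"code": "MT1-H-MLW", "male": {"n": 17, "mean": 18.19, "sd": 1.32}, "female": {"n": 21, "mean": 15.93, "sd": 1.52}, "cutoff": 17.02, "published": {"t": -4.89, "df": 35.76, "D": 0.57, "D_sd": 0.13}}
      ]
    },
    "external-modern-1": {
      "label": "external-modern-1",
      "description": "Contemporary Portuguese cremated series of known sex (Goncalves et al.): three traits shared with the present study.",
      "traits": [
        {"code": "HU-H-VD", "male": {"n": 62, "mean": 43.51, "sd": 2.89}, "female": {"n": 62, "mean": 37.74, "sd": 2.98}, "published": {"D": 0.67, "precision_male": 86.0, "precision_female": 100.0, "accuracy": 88.1}},
        {"code": "FE-H-VD", "male": {"n": 55, "mean": 43.02, "sd": 3.34}, "female": {"n": 55, "mean": 37.64, "sd": 2.18}, "published": {"D": 0.68, "precision_male": 87.5, "precision_female": 90.0, "accuracy": 87.5}},
        {"code": "TA-TL",   "male": {"n": 30, "mean": 50.97, "sd": 3.15}, "female": {"n": 30, "mean": 45.57, "sd": 2.93}, "published": {"D": 0.63, "precision_male": 75.0, "precision_female": 100.0, "accuracy": 75.8}}
      ]
    },
    "external-modern-2": {
      "label": "external-modern-2",
      "description": "Contemporary Swedish cremated series of known sex (Van Vark): two traits shared with the present study.",
      "traits": [
        {"code": "HU-H-VD", "male": {"n": 103, "mean": 44.9, "sd": 2.7}, "female": {"n": 108, "mean": 38.7, "sd": 2.7}, "published": {"D": 0.75, "precision_male": 88.0, "precision_female": 88.0, "accuracy": 87.0}},
        {"code": "FE-H-VD", "male": {"n": 104, "mean": 45.9, "sd": 2.3}, "female": {"n": 108, "mean": 39.9, "sd": 2.7}, "published": {"D": 0.77, "precision_male": 91.0, "precision_female": 88.0, "accuracy": 90.0}}
      ]
    }
  }
}
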