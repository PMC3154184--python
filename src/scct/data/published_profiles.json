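{
 "description": "Published group-level SCCT score profiles: per-item, subscale, index and total means (and SDs) for healthy controls and patients with schizophrenia. 'age_split' blocks stratify at age 40 (40 belongs to the younger stratum); 'whole_sample' holds the unstratified subscale/index comparison.",
 "age_split": {
  "below_41": {
   "control": {
    "n": 60,
    "mean": {
     "RLT-A": 100.0,
     "RLT-B": 84.14,
     "SCCT-1": 100.0,
     "SCCT-2": 63.1,
     "SCCT-3": 57.06,
     "SCCT-4": 100.0,
     "SCCT-5": 66.42,
     "SCCT-6": 60.52,
     "SCCT-7": 100.0,
     "SCCT-8": 56.95,
     "SCCT-9": 77.11,
     "SCCT-10": 68.63,
     "SCCT-11": 100.0,
     "SCCT-12": 85.81,
     "SCCT-13": 95.35,
     "SCCT-14": 100.0,
     "SCCT": 1128.77,
     "DcI": 496.63,
     "ME": 400.0,
     "M": 96.63,
     "DfI": 182.6,
     "D": 450.14,
     "R": 85.96,
     "CiI": 100.0,
     "CI": 100.0
    },
    "sd": {
     "RLT-A": 0.0,
     "RLT-B": 21.31,
     "SCCT-1": 0.0,
     "SCCT-2": 35.2,
     "SCCT-3": 30.57,
     "SCCT-4": 0.0,
     "SCCT-5": 36.94,
     "SCCT-6": 34.46,
     "SCCT-7": 0.0,
     "SCCT-8": 31.41,
     "SCCT-9": 15.34,
     "SCCT-10": 19.27,
     "SCCT-11": 0.0,
     "SCCT-12": 30.81,
     "SCCT-13": 20.77,
     "SCCT-14": 0.0,
     "SCCT": 145.22,
     "DcI": 17.82,
     "ME": 0.0,
     "M": 17.82,
     "DfI": 34.11,
     "D": 138.94,
     "R": 30.7,
     "CiI": 0.0,
     "CI": 0.0
    }
   },
   "patient": {
    "n": 101,
    "mean": {
     "RLT-A": 71.43,
     "RLT-B": 65.0,
     "SCCT-1": 79.16,
     "SCCT-2": 41.7,
     "SCCT-3": 41.14,
     "SCCT-4": 71.83,
     "SCCT-5": 31.45,
     "SCCT-6": 45.74,
     "SCCT-7": 76.39,
     "SCCT-8": 40.1,
     "SCCT-9": 79.89,
     "SCCT-10": 65.43,
     "SCCT-11": 79.3,
     "SCCT-12": 84.76,
     "SCCT-13": 85.37,
     "SCCT-14": 100.0,
     "SCCT": 922.26,
     "DcI": 395.61,
     "ME": 310.82,
     "M": 84.79,
     "DfI": 169.74,
     "D": 343.06,
     "R": 84.95,
     "CiI": 100.0,
     "CI": 100.0
    },
    "sd": {
     "RLT-A": 45.72,
     "RLT-B": 40.05,
     "SCCT-1": 40.67,
     "SCCT-2": 35.12,
     "SCCT-3": 29.21,
     "SCCT-4": 44.76,
     "SCCT-5": 30.23,
     "SCCT-6": 38.96,
     "SCCT-7": 42.44,
     "SCCT-8": 30.86,
     "SCCT-9": 16.18,
     "SCCT-10": 19.66,
     "SCCT-11": 40.4,
     "SCCT-12": 31.56,
     "SCCT-13": 34.67,
     "SCCT-14": 0.0,
     "SCCT": 212.89,
     "DcI": 150.78,
     "ME": 153.23,
     "M": 35.23,
     "DfI": 47.19,
     "D": 137.32,
     "R": 31.42,
     "CiI": 0.0,
     "CI": 0.0
    }
   }
  },
  "above_40": {
   "control": {
    "n": 33,
    "mean": {
     "RLT-A": 96.77,
     "RLT-B": 87.13,
     "SCCT-1": 93.65,
     "SCCT-2": 61.68,
     "SCCT-3": 53.39,
     "SCCT-4": 93.68,
     "SCCT-5": 58.0,
     "SCCT-6": 54.65,
     "SCCT-7": 93.65,
     "SCCT-8": 58.61,
     "SCCT-9": 78.71,
     "SCCT-10": 63.23,
     "SCCT-11": 90.61,
     "SCCT-12": 79.35,
     "SCCT-13": 96.9,
     "SCCT-14": 100.0,
     "SCCT": 1076.1,
     "DcI": 470.19,
     "ME": 375.53,
     "M": 94.67,
     "DfI": 174.67,
     "D": 427.53,
     "R": 80.0,
     "CiI": 100.0,
     "CI": 100.0
    },
    "sd": {
     "RLT-A": 17.96,
     "RLT-B": 15.98,
     "SCCT-1": 24.6,
     "SCCT-2": 29.48,
     "SCCT-3": 30.58,
     "SCCT-4": 24.47,
     "SCCT-5": 38.12,
     "SCCT-6": 35.07,
     "SCCT-7": 24.6,
     "SCCT-8": 32.58,
     "SCCT-9": 16.05,
     "SCCT-10": 18.42,
     "SCCT-11": 29.15,
     "SCCT-12": 35.58,
     "SCCT-13": 17.24,
     "SCCT-14": 0.0,
     "SCCT": 190.59,
     "DcI": 93.07,
     "ME": 91.84,
     "M": 22.3,
     "DfI": 38.89,
     "D": 143.18,
     "R": 35.13,
     "CiI": 0.0,
     "CI": 0.0
    }
   },
   "patient": {
    "n": 26,
    "mean": {
     "RLT-A": 84.62,
     "RLT-B": 62.46,
     "SCCT-1": 77.23,
     "SCCT-2": 39.65,
     "SCCT-3": 27.69,
     "SCCT-4": 58.38,
     "SCCT-5": 33.12,
     "SCCT-6": 32.15,
     "SCCT-7": 73.46,
     "SCCT-8": 31.77,
     "SCCT-9": 77.15,
     "SCCT-10": 56.73,
     "SCCT-11": 73.42,
     "SCCT-12": 72.31,
     "SCCT-13": 96.31,
     "SCCT-14": 100.0,
     "SCCT": 849.38,
     "DcI": 368.6,
     "ME": 271.8,
     "M": 96.8,
     "DfI": 170.13,
     "D": 312.57,
     "R": 73.33,
     "CiI": 100.0,
     "CI": 100.0
    },
    "sd": {
     "RLT-A": 37.55,
     "RLT-B": 43.0,
     "SCCT-1": 42.4,
     "SCCT-2": 38.03,
     "SCCT-3": 26.87,
     "SCCT-4": 49.56,
     "SCCT-5": 26.16,
     "SCCT-6": 30.93,
     "SCCT-7": 44.59,
     "SCCT-8": 31.08,
     "SCCT-9": 15.53,
     "SCCT-10": 15.1,
     "SCCT-11": 44.66,
     "SCCT-12": 38.81,
     "SCCT-13": 18.83,
     "SCCT-14": 0.0,
     "SCCT": 188.07,
     "DcI": 164.78,
     "ME": 164.47,
     "M": 17.53,
     "DfI": 46.17,
     "D": 126.38,
     "R": 38.36,
     "CiI": 0.0,
     "CI": 0.0
    }
   }
  }
 },
 "whole_sample": {
  "control": {
   "n": 93,
   "mean": {
    "DcI": 486.4,
    "ME": 390.53,
    "M": 95.87,
    "DfI": 179.53,
    "D": 441.29,
    "R": 83.66,
    "CiI": 100.0,
    "CI": 100.0
   },
   "sd": {
    "DcI": 60.47,
    "ME": 57.9,
    "M": 19.58,
    "DfI": 36.04,
    "D": 140.27,
    "R": 32.43,
    "CiI": 0.0,
    "CI": 0.0
   }
  },
  "patient": {
   "n": 127,
   "mean": {
    "DcI": 386.87,
    "ME": 298.96,
    "M": 87.91,
    "DfI": 170.13,
    "D": 334.48,
    "R": 82.22,
    "CiI": 100.0,
    "CI": 100.0
   },
   "sd": {
    "DcI": 154.59,
    "ME": 156.95,
    "M": 31.97,
    "DfI": 46.5,
    "D": 134.2,
    "R": 33.38,
    "CiI": 0.0,
    "CI": 0.0
   }
  }
 }
}
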