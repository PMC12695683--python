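{
  "meta": {
    "name": "rtimagerisk default organ parameter registry",
    "version": "1.0",
    "note": "Literature-derived stand-in values with citations. These defaults are placeholders intended to be overridden per institution; pass a user registry file to replace any organ's record. gamma50 entries are normalized dose-response slopes converted internally to the per-Gy logistic slope gamma = 4*gamma50/D50. EAR0 in excess cases per 10^4 person-years per Sv at reference ages e0=30, a0=70.",
    "roi_map": {
      "Breast_CNTR": "breast",
      "Breast_IPSI": "breast",
      "Lung_IPSI": "lung",
      "Lung_CNTR": "lung",
      "Heart": "heart",
      "Rectum": "rectum",
      "Bladder": "bladder",
      "Bowel_Bag": "bowel",
      "Parotid_L": "parotid",
      "Parotid_R": "parotid",
      "SpinalCord": "spinal_cord",
      "Brainstem": "brainstem",
      "OpticNerve_L": "optic_nerve",
      "OpticNerve_R": "optic_nerve"
    }
  },
  "ntcp": {
    "breast": {
      "model": "logistic",
      "d50": 55.0,
      "gamma50": 2.0,
      "source": "Emami B et al. Int J Radiat Oncol Biol Phys 1991;21:109-122 (fibrosis endpoint); stand-in"
    },
    "lung": {
      "model": "logistic",
      "d50": 30.8,
      "gamma50": 0.97,
      "source": "Marks LB et al. (QUANTEC lung) Int J Radiat Oncol Biol Phys 2010;76:S70-S76, mean-dose pneumonitis logistic fit; stand-in"
    },
    "heart": {
      "model": "logistic",
      "d50": 48.0,
      "gamma50": 3.1,
      "source": "Burman C et al. Int J Radiat Oncol Biol Phys 1991;21:123-135 (pericarditis); stand-in"
    },
    "rectum": {
      "model": "lkb",
      "d50": 76.9,
      "m": 0.13,
      "n": 0.09,
      "source": "Michalski JM et al. (QUANTEC rectum) Int J Radiat Oncol Biol Phys 2010;76:S123-S129; stand-in"
    },
    "bladder": {
      "model": "lkb",
      "d50": 80.0,
      "m": 0.11,
      "n": 0.5,
      "source": "Burman C et al. Int J Radiat Oncol Biol Phys 1991;21:123-135; stand-in"
    },
    "bowel": {
      "model": "lkb",
      "d50": 55.0,
      "m": 0.16,
      "n": 0.15,
      "source": "Burman C et al. 1991 (small intestine obstruction/perforation); stand-in"
    },
    "parotid": {
      "model": "lkb",
      "d50": 39.9,
      "m": 0.40,
      "n": 1.0,
      "source": "Deasy JO et al. (QUANTEC salivary) Int J Radiat Oncol Biol Phys 2010;76:S58-S63; stand-in"
    },
    "spinal_cord": {
      "model": "lkb",
      "d50": 66.5,
      "m": 0.175,
      "n": 0.05,
      "source": "Burman C et al. 1991 (myelitis/necrosis); stand-in"
    },
    "brainstem": {
      "model": "lkb",
      "d50": 65.0,
      "m": 0.14,
      "n": 0.16,
      "source": "Burman C et al. 1991 (necrosis/infarction); stand-in"
    },
    "optic_nerve": {
      "model": "lkb",
      "d50": 65.0,
      "m": 0.14,
      "n": 0.25,
      "source": "Burman C et al. 1991 (blindness); stand-in"
    }
  },
  "ear": {
    "breast": {
      "ear0": 9.4,
      "gamma_e": -0.037,
      "gamma_a": 1.7,
      "source": "BEIR VII (NRC 2006) breast incidence; Schneider et al. Theor Biol Med Model 2011;8:27; stand-in"
    },
    "lung": {
      "ear0": 7.5,
      "gamma_e": -0.024,
      "gamma_a": 2.38,
      "source": "BEIR VII (NRC 2006) lung incidence; Schneider et al. 2011; stand-in"
    },
    "heart": {
      "ear0": 1.0,
      "gamma_e": -0.024,
      "gamma_a": 2.38,
      "source": "BEIR VII (NRC 2006) solid-cancer (soft tissue) coefficients; stand-in"
    },
    "rectum": {
      "ear0": 3.2,
      "gamma_e": -0.041,
      "gamma_a": 2.38,
      "source": "BEIR VII (NRC 2006) colon incidence applied to rectum; stand-in"
    },
    "bladder": {
      "ear0": 1.2,
      "gamma_e": -0.024,
      "gamma_a": 2.38,
      "source": "BEIR VII (NRC 2006) bladder incidence; stand-in"
    },
    "bowel": {
      "ear0": 3.2,
      "gamma_e": -0.041,
      "gamma_a": 2.38,
      "source": "BEIR VII (NRC 2006) colon incidence; stand-in"
    },
    "parotid": {
      "ear0": 0.7,
      "gamma_e": -0.046,
      "gamma_a": 0.6,
      "source": "Schneider et al. 2011 salivary-gland coefficients; stand-in"
    },
    "spinal_cord": {
      "ear0": 0.5,
      "gamma_e": -0.024,
      "gamma_a": 2.38,
      "source": "BEIR VII (NRC 2006) CNS/other solid coefficients; stand-in"
    },
    "brainstem": {
      "ear0": 0.5,
      "gamma_e": -0.024,
      "gamma_a": 2.38,
      "source": "BEIR VII (NRC 2006) CNS/other solid coefficients; stand-in"
    },
    "optic_nerve": {
      "ear0": 0.5,
      "gamma_e": -0.024,
      "gamma_a": 2.38,
      "source": "BEIR VII (NRC 2006) CNS/other solid coefficients; stand-in"
    }
  }
}
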