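"""Summary-level reference values from the motivating case-control study.

These are the published, aggregate numbers (counts and adjusted odds
ratios) of the frequency-matched childhood-obesity study the package
emulates (1123 cases / 1231 controls).  They serve as inputs to
desk-check reproductions — crude odds ratios from printed 2x2 counts,
descriptive chi-squares from printed margins, and the RERI/AP/IOR closed
forms applied to the printed adjusted odds ratios.  Individual-level
data were never released; everything individual-level in this package is
synthetic.
"""

from __future__ import annotations

# -------- descriptive margins (cases: adequate/inadequate, controls: same)
LIFESTYLE_2X2 = {
    "physical_activity": {"cases": (144, 964), "controls": (171, 1045)},
    "sleep": {"cases": (204, 902), "controls": (252, 960)},
}

# -------- GRS components: risk alleles and additive-model log-odds weights
GRS_RISK_ALLELES = {
    "rs17782313": "C",
    "rs12970134": "A",
    "rs1137101": "A",
    "rs6713532": "T",
}
GRS_BETAS = {
    "rs17782313": 0.268,
    "rs12970134": 0.217,
    "rs1137101": 0.110,
    "rs6713532": 0.044,
}

# -------- GRS category case/control counts (unweighted and weighted scores)
GRS_CATEGORY_COUNTS = {
    "unweighted": {
        "low": (195, 233),      # score 0
        "medium": (577, 695),   # scores 1-2
        "high": (350, 300),     # scores 3-6
    },
    "weighted": {
        "low": (195, 233),      # score 0
        "medium": (567, 670),   # 0.044-0.485
        "high": (360, 324),     # 0.486-1.190
    },
}

# -------- crossover blocks: published adjusted ORs (reference cell = 1.00)
# keys: (grs type, lifestyle factor); or10 = high GRS + adequate,
# or01 = low/medium GRS + inadequate, or11 = high GRS + inadequate
CROSSOVER_ADJUSTED_OR = {
    ("unweighted", "sleep"): {"or10": 1.40, "or01": 1.16, "or11": 1.70},
    ("unweighted", "physical_activity"): {"or10": 1.83, "or01": 1.16,
                                          "or11": 1.59},
    ("weighted", "sleep"): {"or10": 1.07, "or01": 1.07, "or11": 1.51},
    ("weighted", "physical_activity"): {"or10": 1.77, "or01": 1.20,
                                        "or11": 1.52},
}

# analyzed sample size per crossover block (sum of the four printed cells)
CROSSOVER_N = {
    ("unweighted", "sleep"): 132 + 181 + 627 + 737 + 72 + 70 + 274 + 221,
    ("unweighted", "physical_activity"):
        100 + 137 + 659 + 780 + 44 + 34 + 304 + 263,
    ("weighted", "sleep"): 137 + 172 + 615 + 721 + 67 + 79 + 286 + 237,
    ("weighted", "physical_activity"):
        95 + 132 + 656 + 761 + 49 + 39 + 307 + 282,
}
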