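"""Published reference constants embedded as machine-readable fixtures.

The source study reports four per-species QSAR equations for acute PFAS
toxicity, hazardous concentrations (HC5) and PNECs for six PFASs, measured
river concentrations, and site risk quotients.  Those printed values are
frozen here so the derivation chain (HC5 -> PNEC -> RQ -> risk grade) can
be re-run and audited without any external download.

All concentrations are mg/L except MECs (ng/L); RQ tables are in units of
1e-6 as printed.
"""

from __future__ import annotations

import copy
from typing import Any

#: Per-species QSAR equations: log10 LC(EC)50 [mg/L] as a linear function of
#: molecular descriptors (some log10-transformed), with validation stats.
QSAR_EQUATIONS: dict[str, dict[str, Any]] = {
    "eq4_psubcapitata": {
        "species": "Pseudokirchneriella subcapitata",
        "species_class": "alga",
        "endpoint": "EC50",
        "terms": [["Kow", "log10", -8.82], ["TE", "identity", 47.8],
                  ["ELUMO", "log10", 1.47], ["ECCR", "identity", -39.7]],
        "intercept": 50.3,
        "stats": {"n": 14, "R2": 0.770, "r2": 0.742, "q2": 0.701, "p": 0.006},
    },
    "eq5_cvulgaris": {
        "species": "Chlorella vulgaris",
        "species_class": "alga",
        "endpoint": "EC50",
        "terms": [["Kow", "identity", -4.18], ["ECCR", "identity", -0.332]],
        "intercept": -4.29,
        "stats": {"n": 10, "R2": 0.592, "r2": 0.751, "q2": 0.673, "p": 0.043},
    },
    "eq6_dmagna": {
        "species": "Daphnia magna",
        "species_class": "invertebrate",
        "endpoint": "LC50",
        "terms": [["Kow", "identity", -4.09], ["TE", "log10", 9.75],
                  ["ECCR", "identity", -7.03], ["ELUMO", "log10", 1.63]],
        "intercept": 1.95,
        "stats": {"n": 10, "R2": 0.370, "r2": 0.605, "q2": 0.580, "p": 0.045},
    },
    "eq7_drerio": {
        "species": "Danio rerio",
        "species_class": "fish",
        "endpoint": "LC50",
        "terms": [["Kow", "identity", -1.03], ["ECCR", "identity", -1.04],
                  ["ELUMO", "identity", 0.318]],
        "intercept": 2.94,
        "stats": {"n": 12, "R2": 0.558, "r2": 0.722, "q2": 0.630, "p": 0.046},
    },
}

#: QSAR-predicted acute toxicity (mg/L) per chemical x species, reference
#: only: the descriptor values behind them were not published, so they are
#: not reproducible from the equations alone.
QSAR_PREDICTIONS_MG_L: dict[str, dict[str, float]] = {
    "PFBA": {"Pseudokirchneriella subcapitata": 67.1, "Chlorella vulgaris": 112,
             "Daphnia magna": 37.4, "Danio rerio": 1410},
    "PFOA": {"Pseudokirchneriella subcapitata": 478, "Chlorella vulgaris": 150,
             "Daphnia magna": 570, "Danio rerio": 98.5},
    "PFBS": {"Pseudokirchneriella subcapitata": 2840, "Chlorella vulgaris": 222,
             "Daphnia magna": 487, "Danio rerio": 1000},
    "PFHxS": {"Pseudokirchneriella subcapitata": 1030, "Chlorella vulgaris": 258,
              "Daphnia magna": 821, "Danio rerio": 256},
    "PFOS": {"Pseudokirchneriella subcapitata": 53, "Chlorella vulgaris": 309,
             "Daphnia magna": 173, "Danio rerio": 61.3},
    "6:2 Cl-PFESA": {"Pseudokirchneriella subcapitata": 1.3, "Chlorella vulgaris": 84.9,
                     "Daphnia magna": 10.9, "Danio rerio": 32.7},
}

#: HC5 (mg/L) from SSDs on predicted (QSAR-ICE) data; "*_measured" entries
#: are SSDs on measured data only, for cross-validation of the composite model.
HC5_MG_L: dict[str, float] = {
    "PFBA": 4.02,
    "PFOA": 31.4,
    "PFOA_measured": 27.0,
    "PFBS": 50.5,
    "PFHxS": 64.5,
    "PFOS": 10.5,
    "PFOS_measured": 8.72,
    "6:2 Cl-PFESA": 1.27,
}

#: PNEC (mg/L) = HC5 / 5 as printed.
PNEC_MG_L: dict[str, float] = {
    "PFBA": 0.804,
    "PFOA": 6.27,
    "PFBS": 10.1,
    "PFHxS": 12.9,
    "PFOS": 2.09,
    "6:2 Cl-PFESA": 0.254,
}

#: Assessment factor applied to HC5.
ASSESSMENT_FACTOR = 5.0

#: Mean measured environmental concentrations (ng/L) in the study river.
MEAN_MEC_NG_L: dict[str, float] = {"PFOS": 254.0, "PFBS": 132.0, "PFHxS": 9.18}

#: Risk-quotient summary (x 1e-6): per-chemical range and mean for the study
#: river ("this_study") and four literature electroplating areas.
RQ_TABLE_1E6: dict[str, dict[str, dict[str, Any]]] = {
    "this_study": {
        "PFBA": {"range": [11.5, 60.9], "mean": 29.1},
        "PFOA": {"range": [3.25, 15.8], "mean": 7.26},
        "PFBS": {"range": [9.0, 20.0], "mean": 13.1},
        "PFHxS": {"range": [0.23, 1.83], "mean": 0.71},
        "PFOS": {"range": [15.3, 297.0], "mean": 121.0},
        "6:2 Cl-PFESA": {"range": [5.1, 49.8], "mean": 19.1},
    },
}


def published_values() -> dict[str, Any]:
    """Deep copy of the embedded reference bundle (JSON-serialisable)."""
    return copy.deepcopy(
        {
            "qsar_equations": QSAR_EQUATIONS,
            "qsar_predictions_mg_L": QSAR_PREDICTIONS_MG_L,
            "hc5_mg_L": HC5_MG_L,
            "pnec_mg_L": PNEC_MG_L,
            "assessment_factor": ASSESSMENT_FACTOR,
            "mean_mec_ng_L": MEAN_MEC_NG_L,
            "rq_table_1e6": RQ_TABLE_1E6,
        }
    )
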