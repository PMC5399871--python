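"""Packaged study tables: prey counts for two sympatric *Xenopus* populations.

Published diet and availability tables for *Xenopus laevis* and *X. gilli* at
two South African sites — the Cape of Good Hope (CoGH) and Kleinmond — as
transcribed from the study's printed per-site prey tables. For each taxon:
the pooled environmental sample (Ne items, summed volume Ve mm^3) and, per
predator species, the stomach totals (N items, summed volume V mm^3, Freq =
number of stomachs containing the taxon). Sloughed skin, plant matter and
stones are excluded, as in the printed tables.

These tables are the worked-example inputs for the electivity, diversity,
anurophagy and overlap statistics; the habitat-class assignments are ours
(the printed tables pool them).
"""

from __future__ import annotations

from .core_data import ENVIRONMENT, AbundanceTable, group_label, table_from_arrays
from .prey_metrics import UtilizationProfile, make_profile

#: predators examined per (site, species)
N_PREDATORS = {
    ("CoGH", "X_laevis"): 94,
    ("CoGH", "X_gilli"): 111,
    ("Kleinmond", "X_laevis"): 89,
    ("Kleinmond", "X_gilli"): 105,
}

HABITAT_OF = {
    "Anisoptera": "nekton",
    "Annelida": "benthos",
    "Anura": "nekton",
    "Acari": "benthos",
    "Amphipoda": "benthos",
    "Aranae": "terrestrial",
    "Blattodea": "terrestrial",
    "Brachycera": "terrestrial",
    "Coleoptera": "nekton",
    "Collembola": "terrestrial",
    "Daphnia": "zooplankton",
    "Ephemeroptera": "benthos",
    "Heteroptera": "nekton",
    "Hymenoptera": "terrestrial",
    "Nematocera": "nekton",
    "Neuroptera": "terrestrial",
    "Ostracoda": "benthos",
    "Psocoptera": "terrestrial",
    "Pseudoscorpiones": "terrestrial",
    "Scorpiones": "terrestrial",
    "Sternorrhyncha": "terrestrial",
    "Thysanoptera": "terrestrial",
    "Trichoptera": "benthos",
    "Zygentoma": "terrestrial",
    "Zygoptera": "nekton",
}

# taxon: (Ne, Ve, N_laevis, V_laevis, Freq_laevis, N_gilli, V_gilli, Freq_gilli)
COGH = {
    "Anisoptera": (38, 2656.01, 27, 1394.94, 14, 11, 343.08, 6),
    "Brachycera": (0, 0.0, 3, 56.93, 1, 0, 0.0, 0),
    "Coleoptera": (9, 8405.49, 20, 199.16, 11, 30, 195.34, 22),
    "Ephemeroptera": (8, 59.36, 0, 0.0, 0, 3, 0.16, 3),
    "Heteroptera": (61, 660.07, 15, 152.81, 8, 1, 0.70, 1),
    "Hymenoptera": (0, 0.0, 9, 8.15, 4, 3, 0.0, 3),
    "Nematocera": (49, 68.42, 65, 19.39, 19, 23, 7.89, 15),
    "Neuroptera": (0, 0.0, 1, 0.0, 1, 0, 0.0, 0),
    "Psocoptera": (1, 0.78, 0, 0.0, 0, 0, 0.0, 0),
    "Trichoptera": (29, 106.48, 14, 55.18, 7, 40, 94.52, 23),
    "Zygoptera": (2368, 55275.07, 24, 390.33, 15, 113, 1983.17, 37),
    "Zygentoma": (1, 1.41, 0, 0.0, 0, 0, 0.0, 0),
    "Amphipoda": (7, 14.26, 43, 416.45, 10, 497, 1463.16, 29),
    "Daphnia": (98, 139.67, 0, 0.0, 0, 493, 91.84, 6),
    "Ostracoda": (173, 26.24, 586, 88.87, 34, 352, 53.38, 25),
    "Aranae": (1, 1.28, 0, 0.0, 0, 0, 0.0, 0),
    "Acari": (13, 0.42, 139, 4.61, 28, 51, 1.37, 8),
    "Scorpiones": (0, 0.0, 0, 0.0, 0, 0, 0.0, 0),
    "Anura": (17, 3092.02, 68, 12368.1, 49, 24, 4365.2, 22),
}

KLEINMOND = {
    "Blattodea": (0, 0.0, 0, 0.0, 0, 2, 62.38, 1),
    "Brachycera": (0, 0.0, 1, 0.0, 1, 0, 0.0, 0),
    "Coleoptera": (260, 4.45, 65, 1053.55, 33, 123, 1127.53, 41),
    "Collembola": (0, 0.0, 0, 0.0, 0, 1, 0.07, 1),
    "Ephemeroptera": (9, 0.08, 0, 0.0, 0, 0, 0.0, 0),
    "Heteroptera": (166, 1.16, 22, 231.21, 11, 12, 65.84, 7),
    "Hymenoptera": (1, 0.0, 0, 0.0, 0, 0, 0.0, 0),
    "Nematocera": (2, 0.0, 9, 5.55, 6, 14, 113.53, 10),
    "Sternorrhyncha": (0, 0.0, 0, 0.0, 0, 1, 0.29, 1),
    "Thysanoptera": (0, 0.0, 0, 0.0, 0, 1, 0.05, 1),
    "Trichoptera": (0, 0.0, 3, 2.08, 2, 6, 11.29, 4),
    "Zygoptera": (0, 0.0, 1, 24.05, 1, 0, 0.0, 0),
    "Amphipoda": (496, 0.93, 6, 18.09, 6, 32, 590.05, 13),
    "Daphnia": (1, 0.0, 440, 1115.18, 4, 235, 581.89, 15),
    "Ostracoda": (0, 0.0, 1, 0.15, 1, 23, 3.49, 10),
    "Acari": (11, 0.03, 1, 1.41, 1, 4, 7.54, 3),
    "Aranae": (0, 0.0, 0, 0.0, 0, 1, 0.43, 1),
    "Pseudoscorpiones": (1, 0.0, 0, 0.0, 0, 0, 0.0, 0),
    "Annelida": (0, 0.0, 0, 0.0, 0, 1, 485.36, 1),
    "Anura": (776, 93.35, 1131, 12692.76, 66, 412, 9697.35, 63),
}

_TABLES = {"CoGH": COGH, "Kleinmond": KLEINMOND}
SITES = tuple(_TABLES)


def study_table(site: str) -> AbundanceTable:
    """Abundance table for one site: environment + both species' diets."""
    if site not in _TABLES:
        raise KeyError(f"unknown site {site!r}; have {SITES}")
    rows = _TABLES[site]
    taxa = list(rows)
    env = group_label(ENVIRONMENT, site)
    laevis = group_label("X_laevis", site)
    gilli = group_label("X_gilli", site)
    groups = {
        env: {
            "N": [rows[t][0] for t in taxa],
            "V": [rows[t][1] for t in taxa],
        },
        laevis: {
            "N": [rows[t][2] for t in taxa],
            "V": [rows[t][3] for t in taxa],
            "Freq": [rows[t][4] for t in taxa],
        },
        gilli: {
            "N": [rows[t][5] for t in taxa],
            "V": [rows[t][6] for t in taxa],
            "Freq": [rows[t][7] for t in taxa],
        },
    }
    n_pred = {
        env: 0,
        laevis: N_PREDATORS[(site, "X_laevis")],
        gilli: N_PREDATORS[(site, "X_gilli")],
    }
    return table_from_arrays(taxa, groups, n_pred)


def diet_profile(site: str, species: str) -> UtilizationProfile:
    """Count-basis diet profile (r_i over identified prey) for one group."""
    return make_profile(study_table(site), group_label(species, site))


def availability_profile(site: str) -> UtilizationProfile:
    """Count-basis environmental availability profile (p_i) for one site."""
    return make_profile(study_table(site), group_label(ENVIRONMENT, site))
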