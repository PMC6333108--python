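"""Published cohort summary statistics for the three diagnostic groups.

These are the reported per-group mean ± SD values (per-eye measurements) from
the clinical study this package reanalyses: papilledema (41 eyes of 21
subjects), pseudopapilledema (27 eyes of 15 subjects), and healthy controls
(44 eyes of 44 subjects).  They parameterise the synthetic cohort generator
and the simulation-based reproduction of the reported discrimination (AUC)
results; no per-eye raw data were deposited.
"""

GROUPS = ("papilledema", "pseudopapilledema", "control")

#: (n_subjects, n_eyes) per diagnostic group.
GROUP_SIZES = {
    "papilledema": (21, 41),
    "pseudopapilledema": (15, 27),
    "control": (44, 44),
}

#: metric -> group -> (mean, sd).  Units: um for RNFL thickness, percent for
#: all densities.  Density metrics are from the inner-retinal (irVD) slab
#: unless suffixed otherwise; "commercial" = total vascular density,
#: "pcd"/"capillary" = after large-vessel removal.
GROUP_SUMMARIES = {
    "rnfl_average_um": {
        "papilledema": (150.1, 27.9),
        "pseudopapilledema": (107.3, 16.1),
        "control": (101.7, 7.0),
    },
    "capillary_whole_image_irvd": {
        "papilledema": (28.1, 8.2),
        "pseudopapilledema": (23.2, 6.8),
        "control": (28.8, 6.9),
    },
    "pcd_whole_irvd": {
        "papilledema": (29.8, 9.4),
        "pseudopapilledema": (25.5, 8.3),
        "control": (31.8, 7.4),
    },
    "pcd_nasal_irvd": {
        "papilledema": (28.4, 10.1),
        "pseudopapilledema": (21.8, 8.4),
        "control": (28.5, 8.2),
    },
    "commercial_whole_irvd": {
        "papilledema": (58.5, 6.1),
        "pseudopapilledema": (58.9, 4.7),
        "control": (63.2, 3.1),
    },
    "commercial_whole_trvd": {
        "papilledema": (56.4, 5.9),
        "pseudopapilledema": (58.1, 4.3),
        "control": (61.4, 2.3),
    },
}

#: Reported AUCs for discriminating papilledema (higher values) from
#: pseudopapilledema, eye-level.
REPORTED_AUC = {
    "rnfl_average_um": 0.91,
    "pcd_nasal_irvd": 0.68,
    "capillary_whole_image_irvd": 0.66,
}

#: Reported Bland-Altman agreement between commercial-style and capillary
#: peripapillary measurements (difference = commercial - custom), percent:
#: slab -> (bias, loa_low, loa_high).  Bias at the plotted precision.
REPORTED_BLAND_ALTMAN = {
    "trVD": (25.51, 8.35, 42.67),
    "irVD": (30.76, 15.5, 46.02),
}
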