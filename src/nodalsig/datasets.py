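"""Reference clinico-pathological tables from the motivating cohort.

A 28-patient endometrioid endometrial carcinoma (EEC) case-control series
(12 without lymph-node metastasis, N-; 16 with, N+), 1:1 matched on tumor
size, grade and myometrial invasion.  The published group-comparison tables
are reproduced here as plain counts: they drive the clinical-statistics
acceptance checks and supply the sampling frequencies for the synthetic
metadata generator.

Each categorical covariate maps level -> (count in N-, count in N+).
"""

from __future__ import annotations

N_NEG = 12
N_POS = 16

# covariate -> {level: (n in N-, n in N+)}
CATEGORICAL_TABLES: dict[str, dict[str, tuple[int, int]]] = {
    "histological_grade": {"low": (3, 5), "high": (9, 11)},
    "myometrial_invasion": {"le50": (4, 6), "gt50": (8, 10)},
    "angioinvasion": {
        "absence": (9, 3),
        "non_substantial": (1, 4),
        "substantial": (2, 9),
    },
    "stromal_reaction": {"presence": (5, 12), "absence": (7, 4)},
    "melf_pattern": {"presence": (3, 10), "absence": (9, 6)},
    "inflammatory_infiltration": {"presence": (5, 6), "absence": (7, 10)},
    "perinervous_invasion": {"presence": (1, 4), "absence": (11, 12)},
    "molecular_class": {
        "POLE_ultramutated": (0, 0),
        "MSI_hypermutated": (4, 9),
        "TP53_serous_like": (0, 3),
        "NSMP": (8, 4),
    },
    "ctnnb1_mutation": {"pathogenic": (5, 2), "none": (7, 14)},
}

# covariate -> ((mean, sd) in N-, (mean, sd) in N+), units: mm
CONTINUOUS_SUMMARIES: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "tumor_size_mm": ((46.8, 22.5), (50.1, 25.9)),
}


def contingency_counts(covariate: str) -> list[list[int]]:
    """Levels x 2 (N-, N+) count matrix for a categorical covariate."""
    table = CATEGORICAL_TABLES[covariate]
    return [list(pair) for pair in table.values()]
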