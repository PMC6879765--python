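"""Published input tables shipped with the package.

The TP53 sex-disparity table combines, for 13 non-reproductive cancers, the
TCGA cohort sizes and TP53-mutant counts per sex with the SEER population
incidence rate (cases per 100,000) for the same cancer and sex. These are the
published *inputs* of the incidence integration — the derived per-100k mutant
frequencies and M/F ratios are always recomputed from them at full precision.

HNSC incidence uses the registry's oral-cavity-and-pharynx category; mapping
registry categories to cohort cancer codes is the data's responsibility, not
recomputed here.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["tp53_seer_tcga_inputs", "DISPARITY_CANCERS"]

# cancer_type, sex, n_total (TCGA), n_mut (TCGA TP53-mutant), seer rate /100k
_TP53_ROWS = [
    ("ESCA", "female", 27, 19, 1.7),
    ("ESCA", "male", 158, 137, 7.6),
    ("LIHC", "female", 121, 26, 4.3),
    ("LIHC", "male", 252, 89, 12.7),
    ("BLCA", "female", 108, 56, 8.7),
    ("BLCA", "male", 303, 147, 35.8),
    ("HNSC", "female", 138, 98, 6.3),
    ("HNSC", "male", 371, 267, 16.5),
    ("LUSC", "female", 129, 102, 7.4),
    ("LUSC", "male", 362, 323, 17.0),
    ("SKCM", "female", 179, 23, 16.8),
    ("SKCM", "male", 286, 48, 28.2),
    ("STAD", "female", 157, 74, 5.3),
    ("STAD", "male", 280, 139, 10.1),
    ("LGG", "female", 227, 98, 5.0),
    ("LGG", "male", 281, 141, 7.2),
    ("READ", "female", 77, 57, 9.7),
    ("READ", "male", 89, 70, 15.3),
    ("COAD", "female", 215, 114, 27.4),
    ("COAD", "male", 234, 138, 33.5),
    ("PAAD", "female", 79, 51, 11.0),
    ("PAAD", "male", 102, 66, 14.0),
    ("LUAD", "female", 277, 143, 17.4),
    ("LUAD", "male", 239, 129, 21.7),
    ("KIRC", "female", 179, 5, 10.8),
    ("KIRC", "male", 314, 5, 21.3),
]

#: The 12 cancers with male-biased TP53-mutant incidence (KIRC is the
#: near-parity outlier kept in the 13-cancer table).
DISPARITY_CANCERS = [
    "ESCA", "LIHC", "BLCA", "HNSC", "LUSC", "SKCM",
    "STAD", "LGG", "READ", "COAD", "PAAD", "LUAD",
]


def tp53_seer_tcga_inputs() -> pd.DataFrame:
    """Published TCGA counts and SEER rates for the 13-cancer TP53 analysis."""
    return pd.DataFrame(
        _TP53_ROWS, columns=["cancer_type", "sex", "n_total", "n_mut", "seer_rate"]
    )
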