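"""Population-scale incidence of TP53-mutant cancer by sex.

Combines a cancer registry's per-100,000 incidence rates with a sequenced
cohort's TP53 mutation frequencies:

    per100k_mut(cancer, sex) = seer_rate(cancer, sex) * n_mut / n_total

and the male/female disparity ratio of those per-100k frequencies. All
arithmetic is done at full precision; rounding (half-away-from-zero) is a pure
rendering step, because ratios computed from pre-rounded intermediates differ
visibly from the correct values.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = [
    "mutation_frequency",
    "per100k",
    "mf_ratio",
    "eligible_cancers",
    "build_table",
    "render_table",
    "round_half_away",
]

MIN_CELL = 5  # eligibility: at least this many patients in each sex x status cell


def round_half_away(x: float, ndigits: int) -> float:
    """Round with ties going away from zero (printed-table convention)."""
    factor = 10.0**ndigits
    scaled = x * factor
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / factor


def mutation_frequency(n_mut: int, n_total: int) -> float:
    """Fraction of cohort patients carrying a TP53 mutation (unrounded)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_mut <= n_total:
        raise ValueError("need 0 <= n_mut <= n_total")
    return n_mut / n_total


def per100k(seer_rate: float, mut_freq: float) -> float:
    """Population frequency of mutant-TP53 cancer per 100,000 (unrounded)."""
    if seer_rate < 0:
        raise ValueError("incidence rate must be non-negative")
    return seer_rate * mut_freq


def mf_ratio(male_per100k: float, female_per100k: float) -> float:
    """Male/female ratio of per-100k mutant-cancer frequencies.

    Must be fed unrounded per-100k values.
    """
    if female_per100k <= 0:
        raise ValueError("female per-100k rate must be positive (ratio undefined)")
    return male_per100k / female_per100k


def eligible_cancers(clinical: pd.DataFrame, min_cell: int = MIN_CELL) -> set[str]:
    """Cancers with >= ``min_cell`` patients in every sex x TP53-status cell.

    Patients with unknown TP53 status do not count toward any cell.
    """
    known = clinical[clinical["tp53_status"].isin(["wt", "mutant"])]
    eligible = set()
    for cancer, sub in known.groupby("cancer_type"):
        cells = sub.groupby(["sex", "tp53_status"]).size()
        full = cells.reindex(
            pd.MultiIndex.from_product([["female", "male"], ["wt", "mutant"]]),
            fill_value=0,
        )
        if full.min() >= min_cell:
            eligible.add(cancer)
    return eligible


def build_table(inputs: pd.DataFrame) -> pd.DataFrame:
    """Build the full per-cancer, per-sex disparity table.

    ``inputs`` columns: cancer_type, sex, n_total, n_mut, seer_rate — one row
    per cancer x sex, both sexes present for every cancer. Output adds
    ``mut_freq``, ``per100k_mut`` and the per-cancer ``ratio_mf`` (male/female
    per-100k, attached to both rows), ordered by descending ratio. All derived
    columns are full precision; see :func:`render_table` for printing.
    """
    required = {"cancer_type", "sex", "n_total", "n_mut", "seer_rate"}
    missing = required - set(inputs.columns)
    if missing:
        raise ValueError(f"incidence inputs missing columns: {sorted(missing)}")
    df = inputs.copy()
    df["mut_freq"] = [
        mutation_frequency(m, t) for m, t in zip(df["n_mut"], df["n_total"])
    ]
    df["per100k_mut"] = [
        per100k(r, f) for r, f in zip(df["seer_rate"], df["mut_freq"])
    ]

    ratios = {}
    for cancer, sub in df.groupby("cancer_type"):
        by_sex = sub.set_index("sex")["per100k_mut"]
        for sex in ("male", "female"):
            if sex not in by_sex.index:
                raise ValueError(f"missing incidence row for {cancer}/{sex}")
        ratios[cancer] = mf_ratio(by_sex["male"], by_sex["female"])
    df["ratio_mf"] = df["cancer_type"].map(ratios)

    df = df.sort_values(
        ["ratio_mf", "cancer_type", "sex"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return df


def render_table(table: pd.DataFrame) -> pd.DataFrame:
    """Rounded view for display: frequencies 2 dp, per-100k and ratio 1 dp."""
    out = table.copy()
    out["mut_freq"] = [round_half_away(v, 2) for v in out["mut_freq"]]
    out["per100k_mut"] = [round_half_away(v, 1) for v in out["per100k_mut"]]
    out["ratio_mf"] = [round_half_away(v, 1) for v in out["ratio_mf"]]
    return out
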