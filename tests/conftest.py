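"""Shared fixtures: small simulated bundles and a rule-exercise cohort.

The rule-exercise cohort is a hand-designed 200-mutation fixture covering
every branch of the RMAF classification logic (deep coverage at and around
both thresholds, the <10-read fallback with its expressed-gene check,
knockdown z-scores on either side of the cut, multi-mutation genes with
ties). Statuses are verified against a literal brute-force oracle written
independently in the test module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from xdisp.simulate import SimConfig, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle():
    """13-cancer bundle, 10 patients per cancer per sex (260 patients)."""
    return simulate_cohort(SimConfig(n_per_group=10), seed=7)


@pytest.fixture(scope="session")
def big_bundle():
    """Study-scale bundle: 77 patients per cancer per sex = 2002 patients."""
    return simulate_cohort(SimConfig(n_per_group=77), seed=11)


def _rule_cpm() -> pd.DataFrame:
    """CPM matrix for the rule-exercise cohort (10 samples per sex).

    Genes:
      GEXP  — high, uniform expression (fallback z near 0)
      GVAR  — expressed with spread; selected samples far below the mean
      GLOW  — zero everywhere (never expressed)
      GMAJ  — exactly 5 CPM in 6/10 samples per sex (majority -> expressed)
      GMIN  — exactly 5 CPM in 5/10 samples per sex (no majority -> not)
      GDEEP — high expression; used by deep-coverage mutations
    """
    samples = [f"F{i:02d}" for i in range(10)] + [f"M{i:02d}" for i in range(10)]
    rows = {}
    rows["GEXP"] = [100.0] * 20
    gvar = [80.0, 90.0, 100.0, 110.0, 120.0, 95.0, 105.0, 85.0, 115.0, 100.0]
    # F00 and M00 get a crashed value -> z far below -4 within their cohort
    gvar_f = [0.4] + gvar[1:]
    gvar_m = [0.4] + gvar[1:]
    rows["GVAR"] = gvar_f + gvar_m
    rows["GLOW"] = [0.0] * 20
    rows["GMAJ"] = ([5.0] * 6 + [1.0] * 4) * 2
    rows["GMIN"] = ([5.0] * 5 + [1.0] * 5) * 2
    rows["GDEEP"] = [200.0] * 20
    return pd.DataFrame(rows, index=samples).T


@pytest.fixture(scope="session")
def rule_cohort():
    """(clinical, mutations, pileups, cpm) exercising every RMAF rule, 200 mutations."""
    samples = [f"F{i:02d}" for i in range(10)] + [f"M{i:02d}" for i in range(10)]
    clinical = pd.DataFrame(
        {
            "patient_id": samples,
            "sex": ["female"] * 10 + ["male"] * 10,
            "cancer_type": "TST",
            "age": 60.0,
            "race": "white",
            "smoking": "non-smoker",
            "stage": "II",
            "tp53_status": "wt",
            "os_time": 1000.0,
            "os_event": True,
        }
    )
    cpm = _rule_cpm()

    rng = np.random.default_rng(42)
    muts, piles = [], []
    pos = 1000

    def add(sample, gene, ref, alt, with_pileup=True):
        nonlocal pos
        pos += 7
        muts.append(
            {
                "patient_id": sample,
                "gene": gene,
                "chrom": "X",
                "pos": pos,
                "ref_allele": "A",
                "alt_allele": "G",
                "var_class": "Missense_Mutation",
            }
        )
        if with_pileup:
            piles.append(
                {
                    "patient_id": sample,
                    "chrom": "X",
                    "pos": pos,
                    "ref_reads": ref,
                    "alt_reads": alt,
                }
            )
        return pos

    # 1) deep coverage at and around both thresholds (boundary inclusive)
    boundary = [
        (8, 2),    # rmaf 0.20 -> NEM
        (15, 5),   # 0.25 -> intermediate
        (5, 15),   # 0.75 -> EM
        (6, 14),   # 0.70 -> intermediate
        (50, 0),   # 0.0 -> NEM
        (0, 50),   # 1.0 -> EM
        (5, 5),    # total exactly 10 -> direct quotient, 0.5 intermediate
        (42, 58),  # 0.58 -> intermediate
    ]
    for i, (r, a) in enumerate(boundary * 8):  # 64 mutations
        add(samples[i % 20], "GDEEP", r, a)

    # 2) random deep-coverage pileups (56 mutations)
    for i in range(56):
        total = int(rng.integers(10, 120))
        alt = int(rng.integers(0, total + 1))
        add(samples[i % 20], "GEXP", total - alt, alt)

    # 3) low coverage, gene expressed, z near 0 -> discarded (20)
    for i in range(1, 10):
        add(f"F{i:02d}", "GVAR", 3, 2)
        add(f"M{i:02d}", "GVAR", 0, 4)
    add("F01", "GEXP", 1, 1)
    add("M01", "GEXP", 0, 0)

    # 4) low coverage, gene expressed, crashed expression -> knockdown EM (2)
    add("F00", "GVAR", 2, 1)
    add("M00", "GVAR", 0, 2)

    # 5) low coverage, gene never expressed -> discarded (20)
    for i in range(10):
        add(f"F{i:02d}", "GLOW", 1, 2)
        add(f"M{i:02d}", "GLOW", 0, 1)

    # 6) majority-rule boundary: GMAJ expressed (6/10), GMIN not (5/10) (20)
    for i in range(10):
        add(samples[i], "GMAJ", 4, 3)
        add(samples[10 + i], "GMIN", 4, 3)

    # 7) missing pileup rows entirely -> zero coverage fallback (8)
    for i in range(4):
        add(f"F{i:02d}", "GEXP", 0, 0, with_pileup=False)
        add(f"M{i:02d}", "GLOW", 0, 0, with_pileup=False)

    # 8) multi-mutation genes: highest RMAF wins, ties to smaller pos (10)
    add("F05", "GDEEP2", 90, 10)   # 0.10
    add("F05", "GDEEP2", 10, 90)   # 0.90 <- winner
    add("M05", "GDEEP2", 50, 50)   # tie 0.5 at smaller pos <- winner
    add("M05", "GDEEP2", 150, 150)
    add("F06", "GDEEP2", 20, 0)
    add("F07", "GDEEP2", 0, 20)
    add("M06", "GDEEP2", 30, 10)
    add("M07", "GDEEP2", 10, 30)
    add("F08", "GDEEP2", 12, 4)
    add("M08", "GDEEP2", 4, 12)

    cpm = pd.concat(
        [cpm, pd.DataFrame({s: [150.0] for s in samples}, index=["GDEEP2"])]
    )
    mutations = pd.DataFrame(muts)
    pileups = pd.DataFrame(piles)
    assert len(mutations) == 200
    return clinical, mutations, pileups, cpm
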