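"""RNA-mutated allele frequency (RMAF) and NEM/EM classification.

RMAF is the mRNA analogue of the DNA variant allele frequency: for a somatic
mutation called in the exome, the fraction of RNA-seq reads piled up at that
genomic position that carry the mutant allele,

    rmaf = alt_reads / (ref_reads + alt_reads).

A mutation with rmaf <= 0.20 is a *non-expressed mutation* (NEM: present in
DNA, absent or rare in mRNA — e.g. on the inactive X copy in a female tumour);
rmaf >= 0.75 is an *expressed mutation* (EM). Both boundaries are inclusive;
everything strictly between is *intermediate* and excluded from NEM/EM
statistics (but still reported).

When fewer than ``min_reads`` RNA reads cover the position, the direct
quotient is unreliable and a gene-expression fallback applies, evaluated
within the patient's own cohort (same sex, same cancer type):

1. If the gene is not generally expressed in that cohort (below the CPM
   threshold in at least half the cohort's samples), the mutation is
   discarded — absence of reads carries no information (``not_expressed_gene``).
2. Otherwise a z-score of the patient's expression of the gene relative to
   the cohort is computed (on log2(CPM+1)). A severe deficit (z <= z_cut,
   default −4) is read as the mutation having knocked the gene down, and the
   mutation gets rmaf = 1 (``knockdown_assigned`` — an EM by construction).
3. Otherwise the mutation is discarded as unassessable (``insufficient_info``).

When one patient carries several mutations in the same gene, only the
mutation with the highest RMAF represents the gene (ties broken by smaller
genomic position, for order-independent output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import filter_low_expression

__all__ = [
    "RmafThresholds",
    "STATUS_NEM",
    "STATUS_EM",
    "STATUS_INTERMEDIATE",
    "STATUS_DISCARDED",
    "compute_rmaf",
    "classify",
    "low_coverage_fallback",
    "classify_mutations",
    "resolve_gene_level",
    "rmaf_summary",
    "nem_em_fractions",
]

STATUS_NEM = "NEM"
STATUS_EM = "EM"
STATUS_INTERMEDIATE = "intermediate"
STATUS_DISCARDED = "discarded"

RULE_PILEUP = "pileup"
RULE_KNOCKDOWN = "knockdown_assigned"
RULE_NOT_EXPRESSED = "not_expressed_gene"
RULE_INSUFFICIENT = "insufficient_info"

RECORD_COLUMNS = [
    "patient_id",
    "gene",
    "chrom",
    "pos",
    "rmaf",
    "status",
    "rule",
    "total_reads",
]


@dataclass(frozen=True)
class RmafThresholds:
    """Classification thresholds; defaults are the study's operating point."""

    em_min: float = 0.75
    nem_max: float = 0.20
    min_reads: int = 10
    cpm_min: float = 5.0
    z_cut: float = -4.0
    min_cohort: int = 3  # below this the cohort SD is too unstable for a z-score

    def __post_init__(self) -> None:
        if not 0 <= self.nem_max < self.em_min <= 1:
            raise ValueError("need 0 <= nem_max < em_min <= 1")


def compute_rmaf(ref_reads: int, alt_reads: int, min_reads: int = 10):
    """Direct RMAF quotient; ``None`` when coverage is below ``min_reads``.

    Exactly ``min_reads`` total reads uses the quotient (the cap is strict).
    """
    total = ref_reads + alt_reads
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    if total < min_reads:
        return None
    return alt_reads / total


def classify(rmaf: float, thresholds: RmafThresholds = RmafThresholds()) -> str:
    if not 0 <= rmaf <= 1:
        raise ValueError(f"rmaf must lie in [0, 1], got {rmaf}")
    if rmaf >= thresholds.em_min:
        return STATUS_EM
    if rmaf <= thresholds.nem_max:
        return STATUS_NEM
    return STATUS_INTERMEDIATE


def low_coverage_fallback(
    gene: str,
    sample: str,
    cpm: pd.DataFrame,
    cohort_samples,
    thresholds: RmafThresholds = RmafThresholds(),
) -> tuple[float | None, str]:
    """Resolve a low-coverage mutation from cohort-level gene expression.

    Returns ``(rmaf, rule)``: ``(1.0, knockdown_assigned)`` or
    ``(None, not_expressed_gene | insufficient_info)``.
    """
    cohort_samples = [s for s in cohort_samples if s in cpm.columns]
    if gene not in cpm.index or not cohort_samples:
        return None, RULE_NOT_EXPRESSED
    expressed = filter_low_expression(
        cpm.loc[[gene]], threshold=thresholds.cpm_min, samples=cohort_samples
    )
    if gene not in expressed:
        return None, RULE_NOT_EXPRESSED
    if sample not in cpm.columns or len(cohort_samples) < thresholds.min_cohort:
        return None, RULE_INSUFFICIENT
    # z-score on log2(CPM+1): variance-stabilised expression scale. The query
    # sample is excluded from the reference mean/sd — with it included the
    # z-score is bounded by (n-1)/sqrt(n) and a severe deficit in a small
    # cohort could never reach the cut.
    reference = [s for s in cohort_samples if s != sample]
    if len(reference) < thresholds.min_cohort - 1:
        return None, RULE_INSUFFICIENT
    values = np.log2(cpm.loc[gene, reference].to_numpy(dtype=float) + 1.0)
    sd = values.std(ddof=1)
    if sd == 0:
        return None, RULE_INSUFFICIENT
    z = (np.log2(float(cpm.loc[gene, sample]) + 1.0) - values.mean()) / sd
    if z <= thresholds.z_cut:
        return 1.0, RULE_KNOCKDOWN
    return None, RULE_INSUFFICIENT


def classify_mutations(
    mutations: pd.DataFrame,
    pileups: pd.DataFrame,
    cpm: pd.DataFrame,
    clinical: pd.DataFrame,
    thresholds: RmafThresholds = RmafThresholds(),
    chroms: tuple[str, ...] = ("X",),
) -> pd.DataFrame:
    """Classify every mutation on ``chroms`` as NEM/EM/intermediate/discarded.

    Joins each mutation to its RNA pileup (missing pileup = zero coverage),
    applies the direct quotient at adequate coverage and the expression
    fallback otherwise. The fallback cohort is the patient's sex-and-cancer
    stratum from ``clinical``. Returns one record per mutation with ``rmaf``
    (NaN when discarded), ``status``, provenance ``rule`` and ``total_reads``.
    """
    muts = mutations[mutations["chrom"].isin(chroms)].copy()
    if muts.empty:
        return pd.DataFrame(columns=RECORD_COLUMNS)

    merged = muts.merge(
        pileups, on=["patient_id", "chrom", "pos"], how="left", validate="m:1"
    )
    merged[["ref_reads", "alt_reads"]] = (
        merged[["ref_reads", "alt_reads"]].fillna(0).astype(int)
    )
    merged["total_reads"] = merged["ref_reads"] + merged["alt_reads"]

    strata = clinical.set_index("patient_id")[["sex", "cancer_type"]]
    merged = merged.join(strata, on="patient_id")

    cohort_cache: dict[tuple[str, str], list[str]] = {}

    def cohort_of(sex: str, cancer: str) -> list[str]:
        key = (sex, cancer)
        if key not in cohort_cache:
            ids = clinical.loc[
                (clinical["sex"] == sex) & (clinical["cancer_type"] == cancer),
                "patient_id",
            ]
            cohort_cache[key] = [s for s in ids if s in cpm.columns]
        return cohort_cache[key]

    rmafs = np.full(len(merged), np.nan)
    rules = np.empty(len(merged), dtype=object)
    statuses = np.empty(len(merged), dtype=object)

    deep = merged["total_reads"] >= thresholds.min_reads
    rmafs[deep.to_numpy()] = (
        merged.loc[deep, "alt_reads"] / merged.loc[deep, "total_reads"]
    )
    rules[deep.to_numpy()] = RULE_PILEUP

    for i in np.flatnonzero(~deep.to_numpy()):
        row = merged.iloc[i]
        if pd.isna(row["sex"]) or pd.isna(row["cancer_type"]):
            rmafs[i], rules[i] = np.nan, RULE_INSUFFICIENT
            continue
        value, rule = low_coverage_fallback(
            row["gene"],
            row["patient_id"],
            cpm,
            cohort_of(row["sex"], row["cancer_type"]),
            thresholds,
        )
        rmafs[i] = np.nan if value is None else value
        rules[i] = rule

    for i, v in enumerate(rmafs):
        statuses[i] = STATUS_DISCARDED if np.isnan(v) else classify(v, thresholds)

    out = merged[["patient_id", "gene", "chrom", "pos", "total_reads"]].copy()
    out["rmaf"] = rmafs
    out["status"] = statuses
    out["rule"] = rules
    return out[RECORD_COLUMNS].reset_index(drop=True)


def resolve_gene_level(records: pd.DataFrame) -> pd.DataFrame:
    """One record per (patient, gene): the highest-RMAF non-discarded mutation.

    Ties on RMAF go to the smaller genomic position. Patients whose every
    mutation in a gene was discarded contribute nothing for that gene.
    """
    usable = records[records["status"] != STATUS_DISCARDED]
    if usable.empty:
        return usable.reset_index(drop=True)
    best = (
        usable.sort_values(
            ["patient_id", "gene", "rmaf", "pos"],
            ascending=[True, True, False, True],
            kind="mergesort",
        )
        .groupby(["patient_id", "gene"], as_index=False, sort=True)
        .head(1)
    )
    return best.reset_index(drop=True)


def rmaf_summary(records: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-sex summary of RMAF values: n, zero fraction, median.

    Only records with a numeric RMAF contribute (discarded ones carry none).
    """
    sex = clinical.set_index("patient_id")["sex"]
    df = records.join(sex, on="patient_id")
    df = df[df["rmaf"].notna()]
    rows = []
    for s, sub in df.groupby("sex"):
        n = len(sub)
        n_zero = int((sub["rmaf"] == 0).sum())
        rows.append(
            {
                "sex": s,
                "n": n,
                "n_zero": n_zero,
                "n_positive": n - n_zero,
                "frac_zero": n_zero / n,
                "frac_positive": (n - n_zero) / n,
                "median_rmaf": float(sub["rmaf"].median()),
            }
        )
    return pd.DataFrame(rows)


def nem_em_fractions(records: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-sex NEM and EM fractions among threshold-classified mutations.

    Intermediates and discards are excluded from the denominator, matching
    how the two threshold classes are analysed.
    """
    sex = clinical.set_index("patient_id")["sex"]
    df = records.join(sex, on="patient_id")
    df = df[df["status"].isin([STATUS_NEM, STATUS_EM])]
    rows = []
    for s, sub in df.groupby("sex"):
        n = len(sub)
        n_nem = int((sub["status"] == STATUS_NEM).sum())
        rows.append(
            {
                "sex": s,
                "n_classified": n,
                "n_nem": n_nem,
                "n_em": n - n_nem,
                "nem_fraction": n_nem / n,
                "em_fraction": (n - n_nem) / n,
            }
        )
    return pd.DataFrame(rows)
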