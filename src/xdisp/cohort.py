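"""Cohort data model: clinical, mutation, pileup and expression tables.

All tables are plain pandas DataFrames with fixed column schemas so that every
downstream stage (RMAF classification, propensity weighting, incidence
integration, survival) can rely on the same vocabulary:

* clinical   — one row per patient: ``patient_id, sex, cancer_type, age, race,
               smoking, stage, tp53_status, os_time, os_event``
* mutations  — one row per somatic exome variant call (MAF-like)
* pileups    — one row per (patient, genomic position) RNA pileup
* counts     — genes x samples raw count matrix (index = gene symbol)

Sex is mandatory: clinical rows without a recognisable sex annotation are
dropped at load time and counted in a :class:`LoadReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ALLOWED_VARIANT_CLASSES",
    "CLINICAL_COLUMNS",
    "MUTATION_COLUMNS",
    "PILEUP_COLUMNS",
    "LoadReport",
    "SchemaError",
    "read_clinical",
    "read_mutations",
    "read_maf",
    "read_pileups",
    "read_counts",
    "write_table",
    "filter_mutations",
    "cpm_normalize",
    "filter_low_expression",
]

#: Variant classifications retained for the expressed/non-expressed analysis
#: (functionally consequential classes from Oncotator-style annotation).
ALLOWED_VARIANT_CLASSES = frozenset(
    {
        "3'UTR",
        "5'UTR",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Splice_Region",
        "Splice_Site",
    }
)

#: Patients with at least this many somatic calls are removed entirely
#: (hypermutators distort per-patient burden comparisons).
MAX_MUTATIONS_PER_PATIENT = 15_000

CLINICAL_COLUMNS = [
    "patient_id",
    "sex",
    "cancer_type",
    "age",
    "race",
    "smoking",
    "stage",
    "tp53_status",
    "os_time",
    "os_event",
]
MUTATION_COLUMNS = [
    "patient_id",
    "gene",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "var_class",
]
PILEUP_COLUMNS = ["patient_id", "chrom", "pos", "ref_reads", "alt_reads"]

_SEX_TOKENS = {
    "f": "female",
    "female": "female",
    "m": "male",
    "male": "male",
}
_TP53_TOKENS = {
    "wt": "wt",
    "wild-type": "wt",
    "wildtype": "wt",
    "mutant": "mutant",
    "mut": "mutant",
    "unknown": "unknown",
    "": "unknown",
}

# MAF convention: 1-based inclusive coordinates, these header names.
_MAF_RENAME = {
    "Hugo_Symbol": "gene",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref_allele",
    "Tumor_Seq_Allele2": "alt_allele",
    "Variant_Classification": "var_class",
    "Tumor_Sample_Barcode": "patient_id",
}


class SchemaError(ValueError):
    """An input table is missing required columns or malformed."""


@dataclass
class LoadReport:
    """Accounting of rows dropped while loading a clinical table."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped_missing_sex: int = 0
    n_dropped_bad_sex: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_missing_sex + self.n_dropped_bad_sex

    def summary(self) -> str:
        return (
            f"{self.n_kept}/{self.n_read} patients kept "
            f"({self.n_dropped} dropped: {self.n_dropped_missing_sex} missing sex, "
            f"{self.n_dropped_bad_sex} unrecognised sex)"
        )


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required columns: {missing}")


def read_clinical(path) -> tuple[pd.DataFrame, LoadReport]:
    """Read a clinical TSV, dropping and counting rows without a valid sex.

    Returns the validated table and a :class:`LoadReport`. Unknown sex tokens
    are rejected per row (with a warning recorded), never coerced.
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    _require_columns(df, ["patient_id", "sex", "cancer_type"], "clinical")
    report = LoadReport(n_read=len(df))

    sex_raw = df["sex"].astype("string").str.strip().str.lower()
    missing = sex_raw.isna() | (sex_raw == "")
    mapped = sex_raw.map(_SEX_TOKENS)
    bad = ~missing & mapped.isna()
    report.n_dropped_missing_sex = int(missing.sum())
    report.n_dropped_bad_sex = int(bad.sum())
    for tok in sex_raw[bad].unique():
        report.warnings.append(f"unknown sex token {tok!r}: row(s) rejected")

    df = df.loc[~(missing | bad)].copy()
    df["sex"] = mapped.loc[df.index]

    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise SchemaError(f"duplicate patient_id(s) in clinical table: {dupes[:5]}")

    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    if "tp53_status" in df.columns:
        tp53 = df["tp53_status"].astype("string").str.strip().str.lower()
        df["tp53_status"] = tp53.fillna("unknown").map(
            lambda t: _TP53_TOKENS.get(t, "unknown")
        )
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    df["os_time"] = pd.to_numeric(df["os_time"], errors="coerce")
    if (df["os_time"].dropna() < 0).any():
        raise SchemaError("negative os_time in clinical table")
    ev = df["os_event"].astype("string").str.strip().str.lower()
    df["os_event"] = ev.map(
        {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}
    ).astype(object)

    report.n_kept = len(df)
    return df[CLINICAL_COLUMNS].reset_index(drop=True), report


def read_mutations(path) -> pd.DataFrame:
    """Read a mutation TSV already in the internal column vocabulary."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "chrom": str})
    _require_columns(df, MUTATION_COLUMNS, "mutation")
    return _validate_mutations(df[MUTATION_COLUMNS].copy())


def read_maf(path) -> pd.DataFrame:
    """Read a MAF-like TSV (Hugo_Symbol/Chromosome/... headers)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _require_columns(df, list(_MAF_RENAME), "MAF")
    df = df.rename(columns=_MAF_RENAME)[MUTATION_COLUMNS].copy()
    return _validate_mutations(df)


def _validate_mutations(df: pd.DataFrame) -> pd.DataFrame:
    df["chrom"] = df["chrom"].astype(str).str.removeprefix("chr")
    valid_chroms = {str(i) for i in range(1, 23)} | {"X", "Y"}
    bad = ~df["chrom"].isin(valid_chroms)
    if bad.any():
        raise SchemaError(
            f"invalid chromosome name(s): {sorted(df.loc[bad, 'chrom'].unique())[:5]}"
        )
    df["pos"] = pd.to_numeric(df["pos"]).astype(int)
    if (df["pos"] < 1).any():
        raise SchemaError("mutation positions must be >= 1 (1-based inclusive)")
    if (df["var_class"].astype(str).str.strip() == "").any():
        raise SchemaError("empty var_class in mutation table")
    return df.reset_index(drop=True)


def read_pileups(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "chrom": str})
    _require_columns(df, PILEUP_COLUMNS, "pileup")
    df = df[PILEUP_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str).str.removeprefix("chr")
    for col in ("ref_reads", "alt_reads"):
        df[col] = pd.to_numeric(df[col]).astype(int)
        if (df[col] < 0).any():
            raise SchemaError(f"negative {col} in pileup table")
    df["pos"] = pd.to_numeric(df["pos"]).astype(int)
    return df.reset_index(drop=True)


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples raw-count matrix TSV (first column = gene)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise SchemaError("empty counts matrix")
    if (df.to_numpy() < 0).any():
        raise SchemaError("negative counts in expression matrix")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def filter_mutations(
    mutations: pd.DataFrame,
    allowed_classes=ALLOWED_VARIANT_CLASSES,
    max_per_patient: int = MAX_MUTATIONS_PER_PATIENT,
    exclude_y: bool = False,
) -> pd.DataFrame:
    """Apply the mutation-class filter and the hypermutator cap.

    Keeps only variant classes in ``allowed_classes``; removes *all* mutations
    of any patient whose total somatic call count (before class filtering) is
    ``>= max_per_patient`` — the cap is strict, a patient at exactly the cap is
    excluded. With ``exclude_y`` the Y chromosome is dropped, as in analyses
    restricted to the shared chromosomes.

    Idempotent: applying twice equals applying once.
    """
    if mutations.empty:
        return mutations.copy()
    per_patient = mutations.groupby("patient_id")["gene"].size()
    hypermutators = set(per_patient[per_patient >= max_per_patient].index)
    keep = mutations["var_class"].isin(allowed_classes) & ~mutations[
        "patient_id"
    ].isin(hypermutators)
    if exclude_y:
        keep &= mutations["chrom"] != "Y"
    return mutations.loc[keep].reset_index(drop=True)


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert a raw-count matrix to counts per million (CPM).

    ``cpm[g, s] = counts[g, s] / colsum(s) * 1e6``; every column of the result
    sums to 1e6. An all-zero sample column has no defined library size and is
    reported by name.
    """
    if counts.empty:
        raise ValueError("cannot CPM-normalize an empty matrix")
    colsums = counts.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)[:5]}")
    return counts.div(colsums, axis=1) * 1e6


def filter_low_expression(
    cpm: pd.DataFrame, threshold: float = 5.0, samples=None
) -> pd.Index:
    """Genes expressed at >= ``threshold`` CPM in a majority of samples.

    "Majority" is strict: more than 50% of the (optionally restricted) sample
    set. The boundary is inclusive — a gene at exactly 5 CPM everywhere is
    retained. Returns the retained gene index.
    """
    if cpm.empty:
        raise ValueError("empty CPM matrix")
    if samples is not None:
        samples = [s for s in samples if s in cpm.columns]
        if not samples:
            raise ValueError("no requested samples present in CPM matrix")
        cpm = cpm[samples]
    frac = (cpm >= threshold).mean(axis=1)
    return cpm.index[frac > 0.5]
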