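"""Synthetic cancer-cohort generator with X-inactivation structure.

Generates the full input bundle the analysis consumes — clinical table,
somatic mutation list, RNA pileups at mutated positions, gene x sample count
matrix and a per-cancer/per-sex population incidence table — with the
statistical structure the method assumes:

* TP53 mutation probability differs by cancer and sex (defaults are the
  published cohort frequencies for the 13 non-reproductive cancers).
* Females carry about twice as many somatic X-chromosome mutations as males
  (two X copies), placed on genes proportionally to gene length.
* Each female X mutation lands on the inactive copy with probability
  ``xi_silencing_prob`` (silenced: zero mutant-allele expression) unless its
  gene escapes X-inactivation (default 15% of genes), in which case both
  copies express and the mutant-allele fraction is ``escape_expression_frac``.
  Male X mutations are hemizygous and fully expressed.
* A small fraction of mutations knock their gene's expression down, emitting
  no reads and a suppressed counts column — exercising the z-score fallback.
* Read depth at each mutated position is negative binomial; mutant reads are
  binomial in the expressed-allele fraction.
* Survival is exponential with a configurable hazard ratio for TP53-mutant
  patients, with uniform administrative censoring.
* Age and smoking are sex-confounded so that propensity weighting has real
  work to do.

Every quantity is drawn from a single ``numpy`` Generator, so a fixed seed
reproduces the bundle exactly. A ground-truth table records each simulated
mutation's Xi/expression state for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    ALLOWED_VARIANT_CLASSES,
    read_clinical,
    read_counts,
    read_mutations,
    read_pileups,
    write_table,
)
from .datasets import tp53_seer_tcga_inputs

__all__ = [
    "SimConfig",
    "CohortBundle",
    "make_gene_catalog",
    "simulate_cohort",
    "simulate_pileup",
    "make_incidence_table",
    "truth_table",
    "write_bundle",
    "read_bundle",
]

_DAYS_PER_YEAR = 365.25

# class frequencies loosely follow exome annotation proportions; "Silent"
# exercises the class filter and is dropped by the analysis
_VAR_CLASSES = [
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
    "Splice_Region",
    "3'UTR",
    "5'UTR",
    "Silent",
]
_VAR_CLASS_P = [0.50, 0.08, 0.05, 0.04, 0.04, 0.04, 0.10, 0.05, 0.10]


def _default_rates() -> dict[tuple[str, str], float]:
    tab = tp53_seer_tcga_inputs()
    return {
        (r.cancer_type, r.sex): float(r.seer_rate) for r in tab.itertuples()
    }


def _default_tp53_probs() -> dict[tuple[str, str], float]:
    tab = tp53_seer_tcga_inputs()
    return {
        (r.cancer_type, r.sex): r.n_mut / r.n_total for r in tab.itertuples()
    }


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions being emulated."""

    cancers: tuple[str, ...] = (
        "ESCA", "LIHC", "BLCA", "HNSC", "LUSC", "SKCM", "STAD",
        "LGG", "READ", "COAD", "PAAD", "LUAD", "KIRC",
    )
    n_per_group: int = 75  # patients per cancer per sex
    tp53_mut_prob: dict = field(default_factory=_default_tp53_probs)
    seer_rates: dict = field(default_factory=_default_rates)

    # mutation burden: females carry ~2x the X-linked exome mutations
    x_mutation_rate_female: float = 4.0
    x_mutation_rate_male: float = 2.0
    autosome_mutation_rate: float = 30.0  # both sexes; near-parity genome-wide

    # X-inactivation model
    xi_silencing_prob: float = 0.5
    escape_gene_fraction: float = 0.15
    escape_expression_frac: float = 0.5
    knockdown_prob: float = 0.02
    knockdown_factor: float = 2.0**-6  # counts suppression for knockdowns

    # RNA coverage at mutated positions: negative binomial
    depth_mean: float = 50.0
    depth_dispersion: float = 5.0  # NB size; smaller = more overdispersed

    # gene catalog
    n_genes: int = 600
    n_string_set: int = 90

    # sex-confounded covariates
    age_mean_female: float = 61.0
    age_mean_male: float = 64.0
    age_sd: float = 11.0
    smoking_prob_female: float = 0.35
    smoking_prob_male: float = 0.60
    race_probs: dict = field(
        default_factory=lambda: {"white": 0.73, "black": 0.10, "asian": 0.08, "other": 0.09}
    )
    stage_probs: dict = field(
        default_factory=lambda: {"I": 0.25, "II": 0.30, "III": 0.28, "IV": 0.17}
    )

    # survival: exponential, administrative censoring over the follow-up window
    survival_median_wt_years: float = 5.0
    survival_hazard_ratio: float = 1.6
    followup_years: float = 14.0

    def validate(self) -> None:
        probs = [
            self.xi_silencing_prob,
            self.escape_gene_fraction,
            self.escape_expression_frac,
            self.knockdown_prob,
            self.smoking_prob_female,
            self.smoking_prob_male,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_per_group <= 0:
            raise ValueError("need at least one patient per group")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth distribution must be positive")
        for key, rate in self.seer_rates.items():
            if rate < 0:
                raise ValueError(f"negative incidence rate for {key}")


@dataclass
class CohortBundle:
    """Everything the analysis pipeline consumes, plus ground truth."""

    clinical: pd.DataFrame
    mutations: pd.DataFrame
    pileups: pd.DataFrame
    counts: pd.DataFrame
    incidence: pd.DataFrame
    gene_catalog: pd.DataFrame
    truth: pd.DataFrame


def make_gene_catalog(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """X-linked gene catalog: symbol, span, length, escape and set flags.

    Lengths are log-normal (median ~30 kb); genes are laid end to end along a
    synthetic chrX so mutation positions are unique and ordered. A designated
    subset of ``n_string_set`` genes stands in for the p53-associated set; it
    is a synthetic stand-in for the published 90-gene list, not that list.
    """
    lengths = np.round(rng.lognormal(np.log(3e4), 0.8, config.n_genes)).astype(int)
    lengths = np.maximum(lengths, 500)
    starts = 1 + np.concatenate([[0], np.cumsum(lengths[:-1] + 1000)])
    is_escape = rng.random(config.n_genes) < config.escape_gene_fraction
    in_set = np.zeros(config.n_genes, dtype=bool)
    in_set[rng.choice(config.n_genes, size=config.n_string_set, replace=False)] = True
    # baseline expression (mean CPM-scale): most genes comfortably expressed
    base_expr = rng.lognormal(np.log(40.0), 1.0, config.n_genes)
    return pd.DataFrame(
        {
            "gene": [f"XG{i:04d}" for i in range(config.n_genes)],
            "chrom": "X",
            "start": starts,
            "length": lengths,
            "is_escape": is_escape,
            "is_string_set": in_set,
            "base_expr": base_expr,
        }
    )


def simulate_pileup(
    total_reads: int, p_alt: float, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw (ref_reads, alt_reads) for one mutated position."""
    alt = int(rng.binomial(total_reads, p_alt)) if total_reads > 0 else 0
    return total_reads - alt, alt


def make_incidence_table(config: SimConfig) -> pd.DataFrame:
    """Per-cancer, per-sex population incidence rates (cases per 100,000)."""
    config.validate()
    rows = []
    for cancer in config.cancers:
        for sex in ("female", "male"):
            rate = config.seer_rates.get((cancer, sex))
            if rate is None:
                raise ValueError(f"no incidence rate configured for {cancer}/{sex}")
            rows.append({"cancer_type": cancer, "sex": sex, "rate_per_100k": rate})
    return pd.DataFrame(rows)


def simulate_cohort(config: SimConfig, seed: int) -> CohortBundle:
    """Generate a full cohort bundle; byte-identical for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(seed)
    catalog = make_gene_catalog(config, rng)

    clinical_rows = []
    mut_rows = []
    pileup_rows = []
    truth_rows = []
    knockdowns: list[tuple[str, str]] = []  # (patient, gene) with suppressed counts

    gene_p = (catalog["length"] / catalog["length"].sum()).to_numpy()
    lam_wt = np.log(2.0) / (config.survival_median_wt_years * _DAYS_PER_YEAR)
    horizon_days = config.followup_years * _DAYS_PER_YEAR

    pid = 0
    for cancer in config.cancers:
        for sex in ("female", "male"):
            tp53_p = config.tp53_mut_prob.get((cancer, sex), 0.5)
            for _ in range(config.n_per_group):
                patient = f"P{pid:05d}"
                pid += 1
                age_mean = (
                    config.age_mean_female if sex == "female" else config.age_mean_male
                )
                smoke_p = (
                    config.smoking_prob_female
                    if sex == "female"
                    else config.smoking_prob_male
                )
                tp53 = "mutant" if rng.random() < tp53_p else "wt"
                lam = lam_wt * (
                    config.survival_hazard_ratio if tp53 == "mutant" else 1.0
                )
                event_time = rng.exponential(1.0 / lam)
                censor_time = rng.uniform(0.25 * horizon_days, horizon_days)
                clinical_rows.append(
                    {
                        "patient_id": patient,
                        "sex": sex,
                        "cancer_type": cancer,
                        "age": round(float(rng.normal(age_mean, config.age_sd)), 1),
                        "race": rng.choice(
                            list(config.race_probs), p=list(config.race_probs.values())
                        ),
                        "smoking": "smoker" if rng.random() < smoke_p else "non-smoker",
                        "stage": rng.choice(
                            list(config.stage_probs), p=list(config.stage_probs.values())
                        ),
                        "tp53_status": tp53,
                        "os_time": round(min(event_time, censor_time), 1),
                        "os_event": bool(event_time <= censor_time),
                    }
                )

                # --- X-chromosome mutations -------------------------------
                rate = (
                    config.x_mutation_rate_female
                    if sex == "female"
                    else config.x_mutation_rate_male
                )
                n_x = rng.poisson(rate)
                gene_idx = rng.choice(len(catalog), size=n_x, p=gene_p)
                for gi in gene_idx:
                    g = catalog.iloc[gi]
                    pos = int(g["start"] + rng.integers(0, g["length"]))
                    var_class = rng.choice(_VAR_CLASSES, p=_VAR_CLASS_P)
                    if sex == "female":
                        if g["is_escape"]:
                            xi_state = "escape"
                        elif rng.random() < config.xi_silencing_prob:
                            xi_state = "silenced"
                        else:
                            xi_state = "active"
                    else:
                        xi_state = "active"
                    knockdown = (
                        xi_state != "silenced"
                        and rng.random() < config.knockdown_prob
                    )
                    p_alt = {
                        "silenced": 0.0,
                        "active": 1.0,
                        "escape": config.escape_expression_frac,
                    }[xi_state]
                    if knockdown:
                        total = 0
                        knockdowns.append((patient, g["gene"]))
                    else:
                        total = int(
                            rng.negative_binomial(
                                config.depth_dispersion,
                                config.depth_dispersion
                                / (config.depth_dispersion + config.depth_mean),
                            )
                        )
                    ref, alt = simulate_pileup(total, p_alt, rng)
                    mut_rows.append(
                        {
                            "patient_id": patient,
                            "gene": g["gene"],
                            "chrom": "X",
                            "pos": pos,
                            "ref_allele": "A",
                            "alt_allele": "G",
                            "var_class": var_class,
                        }
                    )
                    pileup_rows.append(
                        {
                            "patient_id": patient,
                            "chrom": "X",
                            "pos": pos,
                            "ref_reads": ref,
                            "alt_reads": alt,
                        }
                    )
                    truth_rows.append(
                        {
                            "patient_id": patient,
                            "gene": g["gene"],
                            "chrom": "X",
                            "pos": pos,
                            "sex": sex,
                            "xi_state": xi_state,
                            "knockdown": knockdown,
                            "var_class": var_class,
                            "total_reads": total,
                            "expected_status": _expected_status(
                                xi_state, knockdown, config
                            ),
                        }
                    )

                # --- autosomal mutations (burden background) ---------------
                n_auto = rng.poisson(config.autosome_mutation_rate)
                chroms = rng.integers(1, 23, size=n_auto)
                positions = rng.integers(1, 100_000_000, size=n_auto)
                classes = rng.choice(_VAR_CLASSES, p=_VAR_CLASS_P, size=n_auto)
                for c, p, vc in zip(chroms, positions, classes):
                    mut_rows.append(
                        {
                            "patient_id": patient,
                            "gene": f"AG{int(c):02d}_{int(p) % 997:03d}",
                            "chrom": str(int(c)),
                            "pos": int(p),
                            "ref_allele": "C",
                            "alt_allele": "T",
                            "var_class": vc,
                        }
                    )

    clinical = pd.DataFrame(clinical_rows)
    mutations = pd.DataFrame(mut_rows)
    pileups = pd.DataFrame(pileup_rows).drop_duplicates(
        subset=["patient_id", "chrom", "pos"], keep="first"
    )
    # a patient can be hit twice at the same position only by coincidence;
    # keep the first call so the pileup join stays one-to-one
    mutations = mutations.drop_duplicates(
        subset=["patient_id", "chrom", "pos"], keep="first"
    )
    truth = pd.DataFrame(truth_rows).drop_duplicates(
        subset=["patient_id", "chrom", "pos"], keep="first"
    )

    counts = _simulate_counts(config, catalog, clinical, knockdowns, rng)
    incidence = make_incidence_table(config)
    return CohortBundle(
        clinical, mutations, pileups, counts, incidence, catalog, truth
    )


def _expected_status(xi_state: str, knockdown: bool, config: SimConfig) -> str:
    if knockdown:
        return "EM"  # rmaf 1 via the knockdown fallback rule
    if xi_state == "silenced":
        return "NEM"
    if xi_state == "active":
        return "EM"
    f = config.escape_expression_frac
    if f >= 0.75:
        return "EM"
    if f <= 0.20:
        return "NEM"
    return "intermediate"


def _simulate_counts(
    config: SimConfig,
    catalog: pd.DataFrame,
    clinical: pd.DataFrame,
    knockdowns: list[tuple[str, str]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Gene x sample raw counts: NB noise around each gene's baseline,
    library-size variation per sample, knockdown genes suppressed."""
    genes = catalog["gene"].to_numpy()
    base = catalog["base_expr"].to_numpy()
    samples = clinical["patient_id"].to_numpy()
    lib = rng.lognormal(0.0, 0.25, len(samples))
    mean = np.outer(base, lib)

    kd_mask = np.zeros(mean.shape, dtype=bool)
    gene_pos = {g: i for i, g in enumerate(genes)}
    sample_pos = {s: j for j, s in enumerate(samples)}
    for patient, gene in knockdowns:
        kd_mask[gene_pos[gene], sample_pos[patient]] = True
    mean = np.where(kd_mask, mean * config.knockdown_factor, mean)

    size = 10.0  # counts-level NB dispersion
    counts = rng.negative_binomial(size, size / (size + mean))
    return pd.DataFrame(counts, index=genes, columns=samples)


def truth_table(bundle: CohortBundle) -> pd.DataFrame:
    """Ground-truth Xi/expression state per simulated X mutation."""
    return bundle.truth.copy()


def write_bundle(bundle: CohortBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(bundle.clinical, out / "clinical.tsv")
    write_table(bundle.mutations, out / "mutations.tsv")
    write_table(bundle.pileups, out / "pileups.tsv")
    bundle.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene")
    write_table(bundle.incidence, out / "incidence.tsv")
    write_table(bundle.gene_catalog, out / "gene_catalog.tsv")
    write_table(bundle.truth, out / "truth.tsv")


def read_bundle(in_dir) -> CohortBundle:
    d = Path(in_dir)
    clinical, _ = read_clinical(d / "clinical.tsv")
    return CohortBundle(
        clinical=clinical,
        mutations=read_mutations(d / "mutations.tsv"),
        pileups=read_pileups(d / "pileups.tsv"),
        counts=read_counts(d / "counts.tsv"),
        incidence=pd.read_csv(d / "incidence.tsv", sep="\t"),
        gene_catalog=pd.read_csv(d / "gene_catalog.tsv", sep="\t"),
        truth=pd.read_csv(d / "truth.tsv", sep="\t"),
    )
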