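"""Synthetic study generator.

Clinical trial data of this kind cannot be archived, so every downstream
stage is exercised on simulated data carrying the statistical structure the
analysis assumes: blocky linkage disequilibrium from a first-order Markov
haplotype model, GWAS summary weights with a genome-wide-significant causal
subset, and a two-arm cohort whose gestational-diabetes risk follows a
liability (logit) model with a PRS x intervention interaction. OGTT values
and postpartum glucose are drawn conditionally on the sampled diagnosis
labels (truncated at the diagnostic thresholds) so the phenotype
classifiers recover the planted labels exactly.

Randomness is organised as named substreams of one master seed: adding a
new generator never perturbs the draws of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit

from .containers import GenotypeMatrix, validate_weights
from .errors import ValidationError
from .gxe_analysis import TERTILE_LABELS, assign_tertiles

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "simulate_genotypes",
    "simulate_gwas_weights",
    "simulate_cohort",
    "inject_missingness",
    "simulate_study",
    "substream",
]

#: Genome-wide significance threshold used to mark causal weights.
GENOME_WIDE_P = 5e-8

_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child stream of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


def substream_seed(seed: int, name: str) -> int:
    """A plain integer seed (< 2^31) derived from a named substream."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


class SimConfig(BaseModel):
    """Generative parameters of a simulated study.

    Defaults emulate the emulated trial's conditions: 529 genotyped women,
    a 200-SNP panel of which a quarter (50) reach genome-wide significance
    and enter the score, GDM prevalence near 49%, an odds ratio of ~1.32
    per SD of PRS, no intervention main effect, and a negative
    PRS x intervention interaction on the log-odds scale.
    """

    n_samples: int = Field(default=529, ge=2)
    n_blocks: int = Field(default=50, ge=1)
    snps_per_block: int = Field(default=4, ge=1)
    within_block_ld: float = Field(default=0.7, ge=0.0, le=1.0)
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_causal: float = Field(default=0.25, ge=0.0, le=1.0)
    beta_sd: float = Field(default=0.1, gt=0.0)
    intercept_logit: float = -0.05
    beta_prs: float = 0.28
    beta_group: float = 0.0
    beta_interaction: float = -0.45
    #: Optional per-tertile intervention log-OR (low, medium, high); when
    #: set it replaces the linear ``beta_group + beta_interaction * s``
    #: group term with a step function of the true-score tertile.
    tertile_group_log_or: Optional[tuple[float, float, float]] = None
    covariate_effects: dict[str, float] = Field(default_factory=dict)
    #: Baseline log-odds of the 12-month postpartum glycaemic abnormality.
    intercept_pp_logit: float = -1.8
    missing_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} must satisfy 0 < lo <= hi <= 0.5")
        known = {"age", "bmi", "parity", "smoking", "education_years"}
        unknown = set(self.covariate_effects) - known
        if unknown:
            raise ValueError(f"unknown covariates in covariate_effects: {sorted(unknown)}")
        return self


@dataclass
class SimulatedStudy:
    """Complete simulated inputs plus the generative ground truth.

    ``truth`` round-trips the config (key ``config``) and records the true
    standardized score (``true_score_z``), the causal SNP ids and the
    planted outcome labels.
    """

    genotypes: GenotypeMatrix
    weights: pd.DataFrame
    cohort: pd.DataFrame
    truth: dict


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw unphased dosages from a blocky haplotype-chain LD model.

    Every variant in a block shares the block's allele frequency; along a
    block each haplotype allele copies its left neighbour with probability
    ``within_block_ld`` and is redrawn otherwise, giving adjacent-variant
    haplotype correlation exactly ``within_block_ld`` and dosage r-squared
    of about its square. Blocks are independent and placed >250 kb apart on
    one chromosome; within-block variants sit <250 kb apart.
    """
    rng = substream(config.seed, "genotypes")
    n, b, k = config.n_samples, config.n_blocks, config.snps_per_block
    rho = config.within_block_ld
    lo, hi = config.maf_range

    dosage_blocks = []
    for _ in range(b):
        f = rng.uniform(lo, hi) if hi > lo else lo
        hap = np.empty((2 * n, k), dtype=np.int8)
        hap[:, 0] = rng.random(2 * n) < f
        for j in range(1, k):
            copy = rng.random(2 * n) < rho
            fresh = rng.random(2 * n) < f
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        dosage_blocks.append(hap[0::2] + hap[1::2])
    dosages = np.concatenate(dosage_blocks, axis=1).astype(float)

    spacing = min(5000, 240_000 // max(1, k - 1))
    ids, chroms, poss, refs, alts = [], [], [], [], []
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=b * k)
    for i in range(b * k):
        block, offset = divmod(i, k)
        ids.append(f"snp{i:04d}")
        chroms.append("1")
        poss.append(1 + block * 1_000_000 + offset * spacing)
        ref, alt = _NONPALINDROMIC_PAIRS[pair_idx[i]]
        refs.append(ref)
        alts.append(alt)
    variants = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    )
    samples = [f"S{i:04d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, samples=samples, variants=variants)


def simulate_gwas_weights(variants: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Draw base summary statistics for the variant panel.

    Exactly ``round(frac_causal * m)`` variants are causal: effect size
    ``beta ~ Normal(0, beta_sd)`` and association p-value below the
    genome-wide threshold 5e-8. The rest get near-zero effects and
    p >= 5e-8. The effect allele is chosen at random between the variant's
    two alleles, exercising downstream allele alignment.
    """
    if len(variants) == 0:
        raise ValidationError("variant list is empty")
    rng = substream(config.seed, "weights")
    m = len(variants)
    n_causal = int(round(config.frac_causal * m))
    causal = np.zeros(m, dtype=bool)
    causal[rng.choice(m, size=n_causal, replace=False)] = True

    beta = np.where(
        causal,
        rng.normal(0.0, config.beta_sd, size=m),
        rng.normal(0.0, config.beta_sd * 0.05, size=m),
    )
    log_hi = np.log10(GENOME_WIDE_P)
    p = np.where(
        causal,
        10.0 ** rng.uniform(-30.0, log_hi - 1e-6, size=m),
        rng.uniform(GENOME_WIDE_P, 1.0, size=m),
    )
    effect_is_alt = rng.random(m) < 0.5
    eff = np.where(effect_is_alt, variants["alt"], variants["ref"])
    oth = np.where(effect_is_alt, variants["ref"], variants["alt"])
    return pd.DataFrame(
        {
            "snp": variants["id"].to_numpy(),
            "chrom": variants["chrom"].to_numpy(),
            "pos": variants["pos"].to_numpy(),
            "effect_allele": eff,
            "other_allele": oth,
            "beta": beta,
            "p": p,
        }
    )


def true_score(genotypes: GenotypeMatrix, weights: pd.DataFrame) -> np.ndarray:
    """Standardized generative score: z of sum(beta x effect dosage) over
    the causal (genome-wide-significant) variants."""
    w = validate_weights(weights)
    if list(w["snp"]) != list(genotypes.variants["id"]):
        raise ValidationError("weights are not aligned to the genotype panel")
    alt = genotypes.variants["alt"].to_numpy()
    eff_is_alt = w["effect_allele"].to_numpy() == alt
    d = genotypes.dosages
    eff_d = np.where(eff_is_alt[None, :], d, 2.0 - d)
    if np.isnan(eff_d).any():
        col_mean = np.nanmean(eff_d, axis=0)
        eff_d = np.where(np.isnan(eff_d), col_mean[None, :], eff_d)
    use = (w["p"] < GENOME_WIDE_P).to_numpy()
    raw = eff_d[:, use] @ w.loc[use, "beta"].to_numpy()
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValidationError("true score is constant; no causal variation")
    return (raw - raw.mean()) / sd


def _group_term(config: SimConfig, s: np.ndarray) -> np.ndarray:
    """Per-sample intervention log-OR (applied only to the treated arm)."""
    if config.tertile_group_log_or is not None:
        tert = assign_tertiles(s)
        lut = dict(zip(TERTILE_LABELS, config.tertile_group_log_or))
        return np.array([lut[lab] for lab in tert.labels])
    return config.beta_group + config.beta_interaction * s


def _negative_ogtt(rng: np.random.Generator, s: float) -> tuple[float, float, float]:
    g0 = float(np.clip(rng.normal(4.95 + 0.04 * s, 0.25), 3.8, 5.28))
    g1 = float(np.clip(rng.normal(7.4 + 0.10 * s, 1.0), 4.0, 9.95))
    g2 = float(np.clip(rng.normal(6.3 + 0.10 * s, 0.9), 3.9, 8.55))
    return g0, g1, g2


def _positive_ogtt(rng: np.random.Generator, s: float) -> tuple[float, float, float]:
    g0, g1, g2 = _negative_ogtt(rng, s)
    which = rng.choice(3, p=(0.5, 0.2, 0.3))
    bump = abs(rng.normal(0.0, 0.7)) + 0.02
    if which == 0:
        g0 = 5.3 + bump
    elif which == 1:
        g1 = 10.0 + bump
    else:
        g2 = 8.6 + bump
    return g0, g1, g2


def simulate_cohort(
    genotypes: GenotypeMatrix, weights: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Generate the per-subject phenotype table.

    The GDM label follows ``P = expit(intercept + beta_prs*s + group term +
    covariate terms)``; OGTT triples, postpartum glucose, visit-level
    glycaemic markers (fasting glucose and HbA1c rising in s, HOMA-B
    falling in s), and diet/activity items are then drawn consistently with
    the sampled labels.
    """
    s = true_score(genotypes, weights)
    n = genotypes.n_samples
    rng_arm = substream(config.seed, "cohort/arm")
    rng_cov = substream(config.seed, "cohort/covariates")
    rng_out = substream(config.seed, "cohort/outcome")
    rng_ogtt = substream(config.seed, "cohort/ogtt")
    rng_mark = substream(config.seed, "cohort/markers")
    rng_diet = substream(config.seed, "cohort/diet")
    rng_pp = substream(config.seed, "cohort/pp")

    g = rng_arm.integers(0, 2, size=n)
    recruitment = np.where(
        rng_arm.random(n) < 0.5, "early_pregnancy", "pre_pregnancy"
    )

    cov = pd.DataFrame(
        {
            "age": np.clip(rng_cov.normal(32.2, 4.5, n), 18, 45),
            "bmi": np.clip(rng_cov.normal(31.5, 6.0, n), 18, 55),
            "parity": np.clip(rng_cov.poisson(1.2, n), 0, 6),
            "smoking": rng_cov.binomial(1, 0.05, n),
            "education_years": np.clip(rng_cov.normal(14.5, 2.1, n), 9, 20),
        }
    )

    eta = config.intercept_logit + config.beta_prs * s + g * _group_term(config, s)
    for name, eff in config.covariate_effects.items():
        x = cov[name].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        eta = eta + eff * ((x - x.mean()) / sd if sd > 0 else 0.0)
    gdm = rng_out.binomial(1, expit(eta))

    # Diagnosis stage: a GDM case surfaces either at the first-trimester
    # OGTT (for early-pregnancy recruits this is the enrolment = booking
    # visit) or at the second-trimester one.
    stage_t1 = rng_out.random(n) < 0.6
    early_gdm = (gdm == 1) & stage_t1
    booking_gdm = early_gdm & (recruitment == "early_pregnancy")

    ogtt_t1 = np.full((n, 3), np.nan)
    ogtt_t2 = np.full((n, 3), np.nan)
    for i in range(n):
        if early_gdm[i]:
            ogtt_t1[i] = _positive_ogtt(rng_ogtt, s[i])
            # diagnosed in T1: no second-trimester OGTT is performed
        else:
            ogtt_t1[i] = _negative_ogtt(rng_ogtt, s[i])
            if gdm[i]:
                ogtt_t2[i] = _positive_ogtt(rng_ogtt, s[i])
            else:
                ogtt_t2[i] = _negative_ogtt(rng_ogtt, s[i])

    # 12-month postpartum glycaemic abnormality.
    eta_pp = config.intercept_pp_logit + config.beta_prs * s + g * _group_term(config, s)
    pp_abn = rng_pp.binomial(1, expit(eta_pp))
    fg_pp12 = np.empty(n)
    g2h_pp12 = np.empty(n)
    physician = np.zeros(n, dtype=int)
    for i in range(n):
        if not pp_abn[i]:
            fg_pp12[i] = np.clip(rng_pp.normal(5.4 + 0.05 * s[i], 0.35), 4.2, 6.05)
            g2h_pp12[i] = np.clip(rng_pp.normal(6.2 + 0.10 * s[i], 0.8), 4.0, 7.75)
            continue
        kind = rng_pp.choice(4, p=(0.45, 0.35, 0.15, 0.05))
        if kind == 0:  # IFG
            fg_pp12[i] = np.clip(6.1 + abs(rng_pp.normal(0, 0.3)), 6.1, 6.9)
            g2h_pp12[i] = np.clip(rng_pp.normal(6.2, 0.8), 4.0, 7.75)
        elif kind == 1:  # IGT
            fg_pp12[i] = np.clip(rng_pp.normal(5.4, 0.35), 4.2, 6.05)
            g2h_pp12[i] = np.clip(7.8 + abs(rng_pp.normal(0, 0.9)), 7.8, 11.0)
        elif kind == 2:  # T2D
            fg_pp12[i] = 7.0 + abs(rng_pp.normal(0, 0.5))
            g2h_pp12[i] = 11.1 + abs(rng_pp.normal(0, 1.0))
        else:  # physician-diagnosed, glucose not measured
            fg_pp12[i] = np.nan
            g2h_pp12[i] = np.nan
            physician[i] = 1

    # Visit-level markers: glycaemia rises, beta-cell secretion falls in s.
    markers: dict[str, np.ndarray] = {}
    fg_mu = {"t1": 5.05, "t2": 4.9, "t3": 5.0}
    for visit, mu in fg_mu.items():
        fg = np.clip(rng_mark.normal(mu + 0.04 * s, 0.38), 3.8, 8.0)
        homab = np.clip(rng_mark.normal(110.0 - 8.0 * s, 30.0), 15.0, 300.0)
        markers[f"fg_{visit}"] = fg
        markers[f"insulin_{visit}"] = homab * (fg - 3.5) / 20.0 * 6.0
    # Postpartum insulin is tied to the diagnostic fasting glucose so the
    # HOMA indices and the IFG/IGT classification describe the same draw.
    homab_pp = np.clip(rng_mark.normal(110.0 - 8.0 * s, 30.0), 15.0, 300.0)
    markers["insulin_pp12"] = homab_pp * (fg_pp12 - 3.5) / 20.0 * 6.0
    for visit in ("t1", "t3", "pp12"):
        markers[f"hba1c_{visit}"] = np.clip(
            rng_mark.normal(5.27 + 0.03 * s, 0.29), 4.3, 7.5
        )

    # Diet quality and lifestyle-goal inputs; intervention arm shifted
    # towards the goals.
    diet = {
        "hfii_snacks": rng_diet.binomial(2, 0.5 + 0.07 * g),
        "hfii_ssb": rng_diet.binomial(1, 0.5 + 0.07 * g),
        "hfii_fast_food": rng_diet.binomial(1, 0.5 + 0.07 * g),
        "hfii_grains": rng_diet.binomial(2, 0.5 + 0.07 * g),
        "hfii_fat_spread": rng_diet.binomial(2, 0.5 + 0.07 * g),
        "hfii_cheese": rng_diet.binomial(1, 0.5 + 0.07 * g),
        "hfii_milk": rng_diet.binomial(2, 0.5 + 0.07 * g),
        "hfii_fish": rng_diet.binomial(2, 0.5 + 0.07 * g),
        "hfii_meat": rng_diet.binomial(2, 0.5 + 0.07 * g),
        "hfii_vegetables": rng_diet.binomial(2, 0.5 + 0.07 * g),
        "hfii_fruits": rng_diet.binomial(1, 0.5 + 0.07 * g),
        "fibre_g": np.clip(rng_diet.normal(24.0 + 4.0 * g, 7.0), 5.0, 60.0),
        "fruit_veg_portions": rng_diet.poisson(2.8 + 0.8 * g),
        "sat_fat_pct": np.clip(rng_diet.normal(12.5 - 1.5 * g, 2.6), 4.0, 25.0),
        "gwg_category": np.array(
            [
                rng_diet.choice(
                    ["below", "adequate", "above"],
                    p=(0.18, 0.55, 0.27) if gi else (0.15, 0.50, 0.35),
                )
                for gi in g
            ]
        ),
        "pa_min_week": np.abs(rng_diet.normal(90.0 + 30.0 * g, 60.0)),
    }

    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "group": g,
            "recruitment": recruitment,
            **{c: cov[c] for c in cov.columns},
            "prs_true_z": s,
            "ogtt_t1_0h": ogtt_t1[:, 0],
            "ogtt_t1_1h": ogtt_t1[:, 1],
            "ogtt_t1_2h": ogtt_t1[:, 2],
            "ogtt_t2_0h": ogtt_t2[:, 0],
            "ogtt_t2_1h": ogtt_t2[:, 1],
            "ogtt_t2_2h": ogtt_t2[:, 2],
            "fg_pp12": fg_pp12,
            "g2h_pp12": g2h_pp12,
            "physician_diabetes": physician,
            **markers,
            **diet,
            "true_gdm": gdm,
            "true_early_gdm": early_gdm.astype(int),
            "true_booking_gdm": booking_gdm.astype(int),
            "true_pp12_abnormal": pp_abn,
        }
    )
    return cohort


def inject_missingness(
    genotypes: GenotypeMatrix, rate: float, seed: int
) -> GenotypeMatrix:
    """Set each dosage entry missing independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValidationError(f"missingness rate {rate} outside [0, 1]")
    out = genotypes.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.dosages.shape) < rate
    out.dosages[mask] = np.nan
    return out


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate genotypes, weights and cohort under one master seed.

    The cohort (and the recorded true score) is computed from the complete
    genotypes; missingness is injected into the released genotype matrix
    afterwards, emulating genotyping dropout on top of the true biology.
    """
    genotypes = simulate_genotypes(config)
    weights = simulate_gwas_weights(genotypes.variants, config)
    cohort = simulate_cohort(genotypes, weights, config)
    released = inject_missingness(
        genotypes, config.missing_rate, substream_seed(config.seed, "missingness")
    )
    truth = {
        "config": config.model_dump(),
        "true_score_z": cohort["prs_true_z"].to_numpy().copy(),
        "causal_snps": weights.loc[weights["p"] < GENOME_WIDE_P, "snp"].tolist(),
        "labels": cohort[
            ["true_gdm", "true_early_gdm", "true_booking_gdm", "true_pp12_abnormal"]
        ].copy(),
    }
    return SimulatedStudy(
        genotypes=released, weights=weights, cohort=cohort, truth=truth
    )
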