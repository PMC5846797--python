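"""Synthetic case-control genotype/phenotype generator.

Emulates the statistical structure a stratified case-control GWAS assumes,
so every downstream stage is testable end to end without access to
restricted individual-level data:

* biallelic variants with allele frequencies drawn from a configurable MAF
  spectrum, genotypes under Hardy-Weinberg equilibrium, optionally with
  imputation-like dosage jitter bounded in [0, 2];
* an optional block-LD mode (haplotype copying with a decay parameter, so
  adjacent-variant genotype correlation equals ``decay`` and r^2 equals
  ``decay**2``), needed for meaningful clumping/fine-mapping tests;
* a logistic disease model in which selected causal variants carry
  stratum-specific log-odds-ratios; case-control status is drawn by
  rejection sampling from a population with configurable prevalence
  (default 5%) — the design is retrospective, so absolute risk is not the
  target, but the retrospective sampling leaves the genotype log-OR intact;
* group-wise age distributions arranged so that a median-split of the
  generated sample reproduces the configured group sizes exactly (ties at
  the cutoff are created deliberately, as they are in real age data
  recorded to 0.1 years);
* nuisance covariates: two standard-normal principal components and a
  Bernoulli whole-genome-amplification flag.

The generator is fully reproducible: the same :class:`SimConfig` (including
seed) yields byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "SimConfig",
    "LDConfig",
    "AgeModel",
    "CovariateModel",
    "SyntheticDataset",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
]


@dataclass(frozen=True)
class LDConfig:
    """Block-LD structure: haplotype copying with geometric decay.

    Variants are grouped into consecutive blocks of ``block_size`` sharing
    one allele frequency; within a block each haplotype allele copies its
    left neighbour with probability ``decay`` and is otherwise drawn fresh,
    giving adjacent-variant correlation ``decay``.
    """

    block_size: int = 10
    decay: float = 0.9

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if not 0.0 <= self.decay < 1.0:
            raise ValueError("decay must be in [0, 1)")


@dataclass(frozen=True)
class AgeModel:
    """Group age distributions for the age-stratified design.

    ``case_cutoff`` / ``control_cutoff`` are the intended median-split
    cutoffs; group means/sds shape the distributions on either side. Ages
    are recorded to 0.1 years, like clinical exam ages.
    """

    case_cutoff: float = 77.8
    control_cutoff: float = 71.0
    case_young: tuple[float, float] = (71.0, 6.0)
    case_old: tuple[float, float] = (84.0, 5.0)
    control_young: tuple[float, float] = (64.0, 6.0)
    control_old: tuple[float, float] = (78.0, 5.0)


@dataclass(frozen=True)
class CovariateModel:
    """Nuisance covariate distributions and (optional) disease effects."""

    pc_sd: float = 1.0
    wga_prob: float = 0.1
    beta_pc1: float = 0.0
    beta_pc2: float = 0.0
    beta_wga: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic dataset.

    Attributes
    ----------
    n_variants : number of variants to simulate.
    maf_range : (low, high) allele-frequency interval in (0, 0.5].
    samples_per_group : counts for (stratum-A cases, stratum-A controls,
        stratum-B cases, stratum-B controls); for the age axis A = younger,
        B = older, for the sex axis A = female, B = male.
    causal_effects : list of (variant index, logOR in stratum A, logOR in
        stratum B).
    axis : "age" or "sex".
    prevalence : population disease prevalence for the logistic model.
    dosage_jitter_sd : sd of truncated-normal dosage noise (0 = hard calls).
    ld : optional block-LD structure; None simulates independent variants.
    seed : RNG seed; identical configs reproduce identical datasets.
    """

    n_variants: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    samples_per_group: tuple[int, int, int, int] = (1000, 1000, 1000, 1000)
    causal_effects: list[tuple[int, float, float]] = field(default_factory=list)
    axis: str = "age"
    age_model: AgeModel = field(default_factory=AgeModel)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    prevalence: float = 0.05
    dosage_jitter_sd: float = 0.0
    ld: LDConfig | None = None
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_spacing: int = 10_000
    female_prob: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if any(n <= 0 for n in self.samples_per_group):
            raise ValueError("all group sizes must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.axis not in ("age", "sex"):
            raise ValueError("axis must be 'age' or 'sex'")
        for idx, _, _ in self.causal_effects:
            if not 0 <= idx < self.n_variants:
                raise ValueError(f"causal variant index {idx} out of range")
        if self.dosage_jitter_sd < 0:
            raise ValueError("dosage_jitter_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_group))

    @property
    def stratum_names(self) -> tuple[str, str]:
        return ("younger", "older") if self.axis == "age" else ("female", "male")


@dataclass
class SyntheticDataset:
    """A generated dataset plus the truth that produced it."""

    variants: pd.DataFrame
    dosages: np.ndarray
    samples: pd.DataFrame
    truth: list[tuple[int, float, float]]
    config: SimConfig


def _rngs(config: SimConfig) -> tuple[np.random.Generator, np.random.Generator]:
    child_geno, child_pheno = np.random.SeedSequence(config.seed).spawn(2)
    return np.random.default_rng(child_geno), np.random.default_rng(child_pheno)


def _variant_table(config: SimConfig, mafs: np.ndarray) -> pd.DataFrame:
    n = config.n_variants
    return pd.DataFrame(
        {
            "variant_id": [f"v{i + 1:06d}" for i in range(n)],
            "chr": config.chrom,
            "pos": config.pos_start + config.pos_spacing * np.arange(n, dtype=np.int64),
            "ea": "A",
            "oa": "G",
            "maf": mafs,
        }
    )


def _draw_mafs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.maf_range
    if config.ld is None:
        return rng.uniform(lo, hi, size=config.n_variants)
    # one frequency per LD block so the copying chain is stationary
    n_blocks = -(-config.n_variants // config.ld.block_size)
    block_maf = rng.uniform(lo, hi, size=n_blocks)
    return np.repeat(block_maf, config.ld.block_size)[: config.n_variants]


def _haplotype_block(
    maf: float, n_var: int, n_hap: int, decay: float, rng: np.random.Generator
) -> np.ndarray:
    """(n_var, n_hap) haplotype alleles from the copying chain."""
    h = np.empty((n_var, n_hap), dtype=np.int8)
    h[0] = rng.random(n_hap) < maf
    for j in range(1, n_var):
        copy = rng.random(n_hap) < decay
        fresh = rng.random(n_hap) < maf
        h[j] = np.where(copy, h[j - 1], fresh)
    return h


def _jitter(dos: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd <= 0:
        return dos
    return np.clip(dos + rng.normal(0.0, sd, size=dos.shape), 0.0, 2.0)


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw the (n_variants, n_samples) dosage matrix and variant metadata.

    Genotypes are unconditional Hardy-Weinberg draws (status-conditional
    structure at causal variants is imposed later by
    :func:`simulate_phenotypes`). With ``config.ld`` set, variants within a
    block are correlated through haplotype copying.
    """
    if rng is None:
        rng, _ = _rngs(config)
    mafs = _draw_mafs(config, rng)
    n_var, n_samp = config.n_variants, config.n_samples
    if config.ld is None:
        g = (
            (rng.random((n_var, n_samp)) < mafs[:, None]).astype(np.int8)
            + (rng.random((n_var, n_samp)) < mafs[:, None]).astype(np.int8)
        ).astype(float)
    else:
        g = np.empty((n_var, n_samp), dtype=float)
        bs = config.ld.block_size
        for start in range(0, n_var, bs):
            stop = min(start + bs, n_var)
            maf = float(mafs[start])
            ha = _haplotype_block(maf, stop - start, n_samp, config.ld.decay, rng)
            hb = _haplotype_block(maf, stop - start, n_samp, config.ld.decay, rng)
            g[start:stop] = ha + hb
    g = _jitter(g, config.dosage_jitter_sd, rng)
    return g, _variant_table(config, mafs)


def _hwe_probs(maf: float) -> np.ndarray:
    return np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])


def _conditional_block(
    causal_local: int,
    block_len: int,
    causal_geno: np.ndarray,
    maf: float,
    decay: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Regenerate an LD block's genotypes conditional on the causal column."""
    n = causal_geno.size
    ha = np.empty((block_len, n), dtype=np.int8)
    hb = np.empty((block_len, n), dtype=np.int8)
    # phase the causal genotype onto two haplotypes (random phase for hets)
    het_phase = rng.random(n) < 0.5
    ha[causal_local] = np.where(causal_geno == 2, 1, np.where(causal_geno == 1, het_phase, 0))
    hb[causal_local] = causal_geno.astype(np.int8) - ha[causal_local]
    # the copying chain is reversible at stationarity, so propagate the same
    # rule forward and backward from the causal position
    for h in (ha, hb):
        for j in range(causal_local + 1, block_len):
            copy = rng.random(n) < decay
            fresh = rng.random(n) < maf
            h[j] = np.where(copy, h[j - 1], fresh)
        for j in range(causal_local - 1, -1, -1):
            copy = rng.random(n) < decay
            fresh = rng.random(n) < maf
            h[j] = np.where(copy, h[j + 1], fresh)
    return (ha + hb).astype(float)


def _pin_ages(
    n_young: int,
    n_old: int,
    cutoff: float,
    young_ms: tuple[float, float],
    old_ms: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ages so that splitting at the pooled median recovers the counts.

    Younger ages live strictly below the cutoff and older strictly above;
    where the median rank falls inside the younger group, just enough
    younger ages are tied exactly at the cutoff to make the pooled median
    equal it. Ages are recorded to 0.1 years.
    """
    young = np.round(rng.normal(*young_ms, size=n_young), 1)
    young = np.minimum(young, cutoff - 0.1)
    old = np.round(rng.normal(*old_ms, size=n_old), 1)
    old = np.maximum(old, cutoff + 0.1)
    n = n_young + n_old
    if n_old == 0:
        return young, old
    if n % 2 == 1:
        rank = (n + 1) // 2
        if n_young < rank:
            raise ValueError(
                f"group sizes ({n_young} young, {n_old} old) cannot be produced "
                "by a median split: the younger side must hold the median"
            )
        n_pin = n_young - rank + 1
    else:
        half = n // 2
        if n_young == half:
            return young, old  # median falls between the groups
        if n_young < half:
            raise ValueError(
                f"group sizes ({n_young} young, {n_old} old) cannot be produced "
                "by a median split: the younger side must hold the median"
            )
        n_pin = n_young - half + 1
    young[np.argsort(young, kind="stable")[-n_pin:]] = cutoff
    return young, old


def simulate_phenotypes(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    max_batches: int = 200,
) -> pd.DataFrame:
    """Assign status, ages, sex and covariates; condition causal genotypes.

    Status is drawn by rejection sampling from a logistic population model
    ``P(case | g) = expit(logit(prevalence) + sum_v beta_{stratum,v} g_v
    + covariate terms)`` until each group's quota of cases and controls is
    met. Because only the causal variants inform status, their columns of
    ``dosages`` are regenerated status-conditionally **in place** (together
    with their LD blocks in block-LD mode); all other columns are
    independent of status and keep their unconditional draws.

    Raises after ``max_batches`` rejection rounds if a quota is unattainable
    (e.g. enormous protective effects with a tiny prevalence).
    """
    if rng is None:
        _, rng = _rngs(config)
    n_var, n_samp = dosages.shape
    if n_samp != config.n_samples:
        raise ValueError("dosage matrix does not match the configured sample count")

    cidx = [idx for idx, _, _ in config.causal_effects]
    betas = {
        0: np.array([b for _, b, _ in config.causal_effects]),
        1: np.array([b for _, _, b in config.causal_effects]),
    }
    mafs = variants["maf"].to_numpy(dtype=float)[cidx] if cidx else np.empty(0)
    alpha = float(logit(config.prevalence))
    cm = config.covariate_model
    quotas = {  # (stratum index, status) -> quota
        (0, 1): config.samples_per_group[0],
        (0, 0): config.samples_per_group[1],
        (1, 1): config.samples_per_group[2],
        (1, 0): config.samples_per_group[3],
    }

    frames: list[pd.DataFrame] = []
    causal_cols: list[np.ndarray] = []
    for (stratum_i, status), quota in quotas.items():
        kept_g = np.empty((0, len(cidx)))
        kept_cov = np.empty((0, 3))
        rate = config.prevalence if status == 1 else 1.0 - config.prevalence
        for _ in range(max_batches):
            short = quota - kept_g.shape[0]
            if short <= 0:
                break
            m = int(min(5_000_000, max(2000, 2.5 * short / max(rate, 1e-6))))
            g = (
                (rng.random((m, len(cidx))) < mafs).astype(np.int8)
                + (rng.random((m, len(cidx))) < mafs).astype(np.int8)
            ).astype(float)
            pc1 = rng.normal(0.0, cm.pc_sd, size=m)
            pc2 = rng.normal(0.0, cm.pc_sd, size=m)
            wga = (rng.random(m) < cm.wga_prob).astype(float)
            eta = alpha + g @ betas[stratum_i] if cidx else np.full(m, alpha)
            eta = eta + cm.beta_pc1 * pc1 + cm.beta_pc2 * pc2 + cm.beta_wga * wga
            is_case = rng.random(m) < expit(eta)
            take = np.flatnonzero(is_case == bool(status))[:short]
            kept_g = np.vstack([kept_g, g[take]])
            kept_cov = np.vstack([kept_cov, np.column_stack([pc1, pc2, wga])[take]])
        if kept_g.shape[0] < quota:
            raise RuntimeError(
                f"could not fill quota for stratum {config.stratum_names[stratum_i]!r} "
                f"status={status} after {max_batches} rejection batches; "
                "the disease model makes this group too rare"
            )
        frames.append(
            pd.DataFrame(
                {
                    "status": status,
                    "group": 2 * stratum_i + (1 - status),
                    "stratum_truth": config.stratum_names[stratum_i],
                    "pc1": kept_cov[:, 0],
                    "pc2": kept_cov[:, 1],
                    "wga": kept_cov[:, 2].astype(int),
                }
            )
        )
        causal_cols.append(kept_g)

    samples = pd.concat(frames, ignore_index=True)
    samples.insert(0, "sample_id", [f"S{i + 1:06d}" for i in range(len(samples))])

    # ages and sex
    am = config.age_model
    if config.axis == "age":
        grp = samples["group"].to_numpy()
        case_y, case_o = _pin_ages(
            quotas[(0, 1)], quotas[(1, 1)], am.case_cutoff,
            am.case_young, am.case_old, rng,
        )
        ctrl_y, ctrl_o = _pin_ages(
            quotas[(0, 0)], quotas[(1, 0)], am.control_cutoff,
            am.control_young, am.control_old, rng,
        )
        age = np.empty(len(samples))
        age[grp == 0] = case_y
        age[grp == 1] = ctrl_y
        age[grp == 2] = case_o
        age[grp == 3] = ctrl_o
        samples["age"] = age
        samples["sex"] = np.where(rng.random(len(samples)) < config.female_prob, "F", "M")
    else:
        status = samples["status"].to_numpy()
        n = len(samples)
        age_case = rng.normal(*am.case_old, size=n)
        age_ctrl = rng.normal(*am.control_old, size=n)
        samples["age"] = np.round(np.where(status == 1, age_case, age_ctrl), 1)
        samples["sex"] = np.where(samples["group"] < 2, "F", "M")

    samples = samples[
        ["sample_id", "status", "age", "sex", "pc1", "pc2", "wga",
         "group", "stratum_truth"]
    ]

    # write the status-conditional causal columns (and LD blocks) back
    if cidx:
        all_causal = np.vstack(causal_cols).T  # (n_causal, n_samples)
        for k, idx in enumerate(cidx):
            if config.ld is None:
                dosages[idx] = _jitter(all_causal[k], config.dosage_jitter_sd, rng)
            else:
                bs = config.ld.block_size
                start = (idx // bs) * bs
                stop = min(start + bs, n_var)
                block = _conditional_block(
                    idx - start, stop - start, all_causal[k],
                    float(variants["maf"].iloc[start]), config.ld.decay, rng,
                )
                block[idx - start] = all_causal[k]
                dosages[start:stop] = _jitter(block, config.dosage_jitter_sd, rng)
    return samples


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate a complete dataset (genotypes, phenotypes, truth)."""
    rng_g, rng_p = _rngs(config)
    dosages, variant_df = simulate_genotypes(config, rng_g)
    samples = simulate_phenotypes(dosages, variant_df, config, rng_p)
    return SyntheticDataset(
        variants=variant_df,
        dosages=dosages,
        samples=samples,
        truth=list(config.causal_effects),
        config=config,
    )
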