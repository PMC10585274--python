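"""Synthetic GWAS summary statistics under a known causal chain.

The generator emulates the statistical structure of the three-cohort
two-sample MR setting — an exposure, a mediator and an outcome measured in
independent samples — at a vastly reduced number of variants:

* per-SNP true exposure effects ``gamma_j ~ Normal(0, sigma_gamma²)``;
* a causal chain ``exposure -(beta_xm)-> mediator -(beta_my)-> outcome``
  plus an optional direct exposure->outcome path ``beta_xy_direct``;
* optional horizontal pleiotropy: a ``prop_invalid`` fraction of SNPs
  carries direct SNP->mediator and SNP->outcome effects drawn from
  ``Normal(pleiotropy_mean, pleiotropy_sd²)`` in the exposure-increasing
  orientation (directional when the mean is nonzero, balanced otherwise);
* allele-frequency-dependent standard errors
  ``se = 1 / sqrt(2·EAF·(1−EAF)·N)`` per trait, with observed effects
  ``beta = true effect + Normal(0, se²)``;
* block-diagonal LD with within-block ``r² = ld_rho^|i−k|``;
* random nucleotide alleles, a ``prop_palindromic`` fraction forced to
  A/T or G/C pairs, and independent per-table randomization of which
  allele is labelled the effect allele — so harmonization is load-bearing
  for every downstream consumer.

Everything is driven by a single integer seed; identical configurations
produce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .io import CANONICAL_COLUMNS, write_summary_stats
from .instruments import PairwiseLD

_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic three-trait study.

    Defaults emulate the motivating study design at reduced variant count:
    200 variants truly associated with the exposure; biobank-scale cohorts
    (100,000) for the continuous exposure and mediator; a much smaller
    effective sample (20,000) for the outcome, as is typical for a binary
    case-control GWAS whose effective size is ``4·p·(1−p)·N``; exposure-
    effect spread 0.05 in standardized units (so ~200 causal SNPs imply a
    SNP heritability near 0.5); a moderate causal chain
    (exposure->mediator 0.3, mediator->outcome 0.2); no direct path and no
    pleiotropy — the regime in which IVW is consistent by construction and
    recovery can be checked against ground truth.
    """

    n_snps: int = 200
    n_exposure: int = 100_000
    n_mediator: int = 100_000
    n_outcome: int = 20_000
    sigma_gamma: float = 0.05
    beta_xm: float = 0.3
    beta_my: float = 0.2
    beta_xy_direct: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    prop_invalid: float = 0.0
    eaf_range: tuple[float, float] = (0.05, 0.95)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    prop_palindromic: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 2:
            raise ConfigError(f"n_snps must be >= 2, got {self.n_snps}")
        for name in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) < 3:
                raise ConfigError(f"{name} must be >= 3, got {getattr(self, name)}")
        lo, hi = self.eaf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError(f"eaf_range must lie within (0, 1), got {self.eaf_range}")
        if not 0.0 <= self.prop_invalid <= 1.0:
            raise ConfigError(f"prop_invalid must lie in [0, 1], got {self.prop_invalid}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigError(f"ld_rho must lie in [0, 1), got {self.ld_rho}")
        if not 0.0 <= self.prop_palindromic <= 1.0:
            raise ConfigError(f"prop_palindromic must lie in [0, 1], got {self.prop_palindromic}")
        if self.sigma_gamma <= 0:
            raise ConfigError(f"sigma_gamma must be positive, got {self.sigma_gamma}")
        if self.pleiotropy_sd < 0:
            raise ConfigError(f"pleiotropy_sd must be >= 0, got {self.pleiotropy_sd}")
        if self.ld_block_size < 1:
            raise ConfigError(f"ld_block_size must be >= 1, got {self.ld_block_size}")


@dataclass
class StudyTruth:
    """Realized ground truth behind one simulated study."""

    config: SimulationConfig
    gamma: np.ndarray                # true SNP -> exposure effects
    alpha_mediator: np.ndarray       # oriented pleiotropic SNP -> mediator effects
    alpha_outcome: np.ndarray        # oriented pleiotropic SNP -> outcome effects
    beta_exp_true: np.ndarray
    beta_med_true: np.ndarray
    beta_out_true: np.ndarray
    invalid_mask: np.ndarray


@dataclass
class SimulatedStudy:
    """Three coherent summary-statistics tables plus their ground truth."""

    exposure_stats: pd.DataFrame
    mediator_stats: pd.DataFrame
    outcome_stats: pd.DataFrame
    truth: StudyTruth
    ld_matrix: np.ndarray
    snp_ids: list[str] = field(default_factory=list)

    def pairwise_ld(self) -> PairwiseLD:
        return PairwiseLD.from_dense(self.snp_ids, self.ld_matrix)


def _block_ld(n_snps: int, block_size: int, rho: float) -> np.ndarray:
    ld = np.eye(n_snps)
    if block_size > 1 and rho > 0:
        for start in range(0, n_snps, block_size):
            stop = min(start + block_size, n_snps)
            idx = np.arange(start, stop)
            ld[np.ix_(idx, idx)] = rho ** np.abs(idx[:, None] - idx[None, :])
    return ld


def _positions(n_snps: int, block_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome and position per SNP: one LD block per locus, blocks
    rotated over chromosomes 1..22, 20 Mb apart so distinct blocks never
    fall in the same clumping window."""
    n_blocks = -(-n_snps // block_size)
    chroms = np.empty(n_snps, dtype=object)
    pos = np.empty(n_snps, dtype=np.int64)
    cursor: dict[str, int] = {}
    for b in range(n_blocks):
        chrom = str(b % 22 + 1)
        base = cursor.get(chrom, 1_000_000)
        lo, hi = b * block_size, min((b + 1) * block_size, n_snps)
        for offset, j in enumerate(range(lo, hi)):
            chroms[j] = chrom
            pos[j] = base + offset * 100_000
        cursor[chrom] = base + block_size * 100_000 + 20_000_000
    return chroms, pos


def _alleles(rng: np.random.Generator, n_snps: int, prop_palindromic: float):
    ea = rng.choice(_BASES, size=n_snps)
    shift = rng.integers(1, 4, size=n_snps)  # non-identical other allele
    oa = _BASES[(np.searchsorted(_BASES, ea) + shift) % 4]
    pal = rng.random(n_snps) < prop_palindromic
    ea[pal] = rng.choice(_BASES, size=int(pal.sum()))
    oa[pal] = np.array([_COMPLEMENT[a] for a in ea[pal]])
    return ea.astype(object), oa.astype(object)


def _trait_table(
    rng: np.random.Generator,
    snp_ids, chroms, pos, ea, oa, eaf,
    true_beta: np.ndarray,
    n_sample: int,
) -> pd.DataFrame:
    """Observed table for one trait with independently randomized allele
    labelling (swapping labels negates beta and complements EAF)."""
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_sample)
    beta = true_beta + rng.normal(0.0, se)
    flip = rng.random(len(snp_ids)) < 0.5
    table = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chroms,
            "pos": pos,
            "effect_allele": np.where(flip, oa, ea),
            "other_allele": np.where(flip, ea, oa),
            "eaf": np.where(flip, 1.0 - eaf, eaf),
            "beta": np.where(flip, -beta, beta),
            "se": se,
            # clamp away from 0 so extreme z-scores stay valid p-values
            "pval": np.maximum(2.0 * stats.norm.sf(np.abs(beta) / se), 1e-300),
            "n": float(n_sample),
        },
        columns=list(CANONICAL_COLUMNS),
    )
    return table


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate one three-trait study under ``config`` (seeded, deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    j = config.n_snps
    snp_ids = [f"rs{100000 + i}" for i in range(j)]
    chroms, pos = _positions(j, config.ld_block_size)
    ea, oa = _alleles(rng, j, config.prop_palindromic)
    eaf = rng.uniform(*config.eaf_range, size=j)

    gamma = rng.normal(0.0, config.sigma_gamma, size=j)
    invalid = rng.random(j) < config.prop_invalid
    alpha_m = np.where(invalid, rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=j), 0.0)
    alpha_y = np.where(invalid, rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=j), 0.0)
    # pleiotropy is directional w.r.t. the exposure-increasing allele:
    orient = np.where(gamma < 0, -1.0, 1.0)
    alpha_m = orient * alpha_m
    alpha_y = orient * alpha_y

    beta_exp_true = gamma
    beta_med_true = config.beta_xm * gamma + alpha_m
    beta_out_true = (
        (config.beta_xy_direct + config.beta_my * config.beta_xm) * gamma
        + config.beta_my * alpha_m
        + alpha_y
    )

    exposure = _trait_table(rng, snp_ids, chroms, pos, ea, oa, eaf, beta_exp_true, config.n_exposure)
    mediator = _trait_table(rng, snp_ids, chroms, pos, ea, oa, eaf, beta_med_true, config.n_mediator)
    outcome = _trait_table(rng, snp_ids, chroms, pos, ea, oa, eaf, beta_out_true, config.n_outcome)

    truth = StudyTruth(
        config=config,
        gamma=gamma,
        alpha_mediator=alpha_m,
        alpha_outcome=alpha_y,
        beta_exp_true=beta_exp_true,
        beta_med_true=beta_med_true,
        beta_out_true=beta_out_true,
        invalid_mask=invalid,
    )
    ld = _block_ld(j, config.ld_block_size, config.ld_rho)
    return SimulatedStudy(
        exposure_stats=exposure,
        mediator_stats=mediator,
        outcome_stats=outcome,
        truth=truth,
        ld_matrix=ld,
        snp_ids=snp_ids,
    )


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the three tables, the LD pairs and the truth/config key-value
    file under ``out_dir``; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": write_summary_stats(study.exposure_stats, out_dir / "exposure.tsv"),
        "mediator": write_summary_stats(study.mediator_stats, out_dir / "mediator.tsv"),
        "outcome": write_summary_stats(study.outcome_stats, out_dir / "outcome.tsv"),
        "ld": study.pairwise_ld().to_pairs_tsv(out_dir / "ld.tsv"),
    }
    truth_path = out_dir / "truth.txt"
    with open(truth_path, "w") as fh:
        for key, value in asdict(study.truth.config).items():
            fh.write(f"config.{key}\t{value}\n")
        for name, vec in (
            ("gamma", study.truth.gamma),
            ("alpha_mediator", study.truth.alpha_mediator),
            ("alpha_outcome", study.truth.alpha_outcome),
            ("beta_exp_true", study.truth.beta_exp_true),
            ("beta_med_true", study.truth.beta_med_true),
            ("beta_out_true", study.truth.beta_out_true),
        ):
            for snp, v in zip(study.snp_ids, vec):
                fh.write(f"{name}.{snp}\t{v!r}\n")
    paths["truth"] = truth_path
    return paths
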